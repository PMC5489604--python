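"""Synthetic inputs: μ-suppression simulation, two-class ERD epochs, ICA fixtures.

Three generators cover every downstream stage without external recordings:

* :func:`generate_fig2_simulation` — a 6-channel sum-of-sinusoids EEG
  surrogate (0-20 Hz, larger amplitudes at low frequencies) in which the
  μ-rhythm (8-12 Hz) is suppressed on a chosen channel subset, emulating
  event-related desynchronization confined to part of a hemisphere.
* :func:`generate_mi_epochs` — labeled two-class motor-imagery epochs built
  in source space (a narrowband μ source per hemisphere, pink-noise
  background, optional class-independent oscillator) under full-rank
  volume-conduction mixing, with contralateral μ-power reduction (ERD).
* :func:`generate_ica_mixture` — instantaneous linear mixtures of
  independent super-Gaussian sources with the ground-truth mixing matrix,
  for blind-source-separation recovery checks.

All generators are pure functions of their configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .preprocess_io import EpochSet

__all__ = [
    "SimConfig",
    "MIGenConfig",
    "generate_fig2_simulation",
    "generate_mi_epochs",
    "generate_ica_mixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the 6-channel μ-suppression simulation.

    Every channel is a sum of sinusoids on ``freq_grid`` (within 0-20 Hz)
    with amplitude proportional to ``f ** -amp_decay`` and uniformly random
    phases; on ``suppressed_channels`` the sinusoids inside ``mu_band`` are
    scaled by ``1 - suppression_depth``.  The whole record is globally
    rescaled so every channel satisfies ``max(x) + min(x) < amplitude_cap``
    (microvolts).
    """

    n_channels: int = 6
    fs: float = 250.0
    duration: float = 4.0
    freq_grid: tuple[float, ...] = tuple(float(f) for f in range(1, 21))
    amp_decay: float = 0.5
    mu_band: tuple[float, float] = (8.0, 12.0)
    suppressed_channels: tuple[int, ...] = (5, 6)  # 1-based
    suppression_depth: float = 0.7
    amplitude_cap: float = 12.0
    peak_amplitude: float = 5.0  # µV target for the global rescale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("n_channels must be positive")
        if any(not 0 <= f <= 20 for f in self.freq_grid):
            raise ConfigError("freq_grid must lie within [0, 20] Hz")
        if not 0 <= self.suppression_depth <= 1:
            raise ConfigError("suppression_depth must be in [0, 1]")
        bad = [c for c in self.suppressed_channels if not 1 <= c <= self.n_channels]
        if bad:
            raise ConfigError(f"suppressed_channels out of range 1..{self.n_channels}: {bad}")
        if 2 * self.peak_amplitude >= self.amplitude_cap:
            raise ConfigError("peak_amplitude must be below amplitude_cap / 2")


def generate_fig2_simulation(config: SimConfig = SimConfig()) -> EpochSet:
    """Generate one unlabeled trial of the μ-suppression simulation."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration))
    t = np.arange(n) / config.fs
    freqs = np.asarray(config.freq_grid, dtype=float)
    base_amp = np.where(freqs > 0, freqs, 1.0) ** (-config.amp_decay)
    lo, hi = config.mu_band
    in_mu = (freqs >= lo) & (freqs <= hi)
    suppressed = {c - 1 for c in config.suppressed_channels}

    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
        amp = base_amp.copy()
        if ch in suppressed:
            amp[in_mu] *= 1.0 - config.suppression_depth
        data[ch] = (
            amp[:, None] * np.cos(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        ).sum(axis=0)

    # one global scale so relative channel structure is preserved
    peak = np.abs(data).max()
    if peak > 0:
        data *= config.peak_amplitude / peak
    worst = (data.max(axis=1) + data.min(axis=1)).max()
    if worst >= config.amplitude_cap:  # pragma: no cover - cap << 2*peak by config check
        data *= 0.9 * config.amplitude_cap / worst
    return EpochSet(data=data[None, :, :], fs=config.fs)


@dataclass(frozen=True)
class MIGenConfig:
    """Configuration of the two-class motor-imagery epoch generator.

    Class 1 emulates left-hand imagery (μ-power over the *right* hemisphere
    reduced by ``erd_depth``), class 2 right-hand imagery (left hemisphere
    reduced).  ``erd_depth = 0`` makes the two class-conditional generating
    distributions identical.
    """

    n_trials_per_class: int = 50
    n_channels: int = 6
    fs: float = 250.0
    duration: float = 2.0
    erd_depth: float = 0.8
    mixing: np.ndarray | None = None
    noise_sd: float = 0.5
    irrelevant_source: bool = False
    mu_amplitude: float = 3.0
    background_amplitude: float = 1.5
    background_jitter: float = 0.0
    irrelevant_max_amplitude: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ConfigError("n_trials_per_class must be positive")
        if self.n_channels % 2 or self.n_channels < 4:
            raise ConfigError("n_channels must be even and >= 4 (>= 2 per hemisphere)")
        if not 0 <= self.erd_depth <= 1:
            raise ConfigError("erd_depth must be in [0, 1]")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.shape != (self.n_channels, self.n_channels):
                raise ConfigError("mixing must be square n_channels x n_channels")
            if np.linalg.matrix_rank(m) < self.n_channels:
                raise ConfigError("mixing must be full rank")
            object.__setattr__(self, "mixing", m)


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (zero-phase filtered)."""
    x = rng.standard_normal(n + 2 * int(fs))  # pad against filter edge effects
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)[int(fs):int(fs) + n]
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.arange(spec.size, dtype=float)
    f[0] = 1.0
    y = np.fft.irfft(spec / np.sqrt(f), n=n)
    return y / np.sqrt(np.mean(y**2))


def _default_mixing(rng: np.random.Generator, n_half: int) -> np.ndarray:
    """Well-conditioned within-hemisphere volume-conduction mixing (block diag)."""
    def block() -> np.ndarray:
        for _ in range(100):
            m = np.eye(n_half) + 0.6 * rng.standard_normal((n_half, n_half)) / np.sqrt(n_half)
            if np.linalg.cond(m) < 15:
                return m
        raise RuntimeError("failed to draw a well-conditioned mixing block")

    out = np.zeros((2 * n_half, 2 * n_half))
    out[:n_half, :n_half] = block()
    out[n_half:, n_half:] = block()
    return out


def generate_mi_epochs(config: MIGenConfig = MIGenConfig()) -> EpochSet:
    """Generate a labeled, label-balanced two-class ERD epoch set."""
    rng = np.random.default_rng(config.seed)
    n_half = config.n_channels // 2
    n = int(round(config.fs * config.duration))
    n_total = 2 * config.n_trials_per_class

    mixing = config.mixing if config.mixing is not None else _default_mixing(rng, n_half)

    labels = np.repeat([1, 2], config.n_trials_per_class)
    rng.shuffle(labels)

    erd_gain = np.sqrt(1.0 - config.erd_depth)
    data = np.empty((n_total, config.n_channels, n))
    for k in range(n_total):
        sources = np.zeros((config.n_channels, n))
        for hemi, sl in (("left", slice(0, n_half)), ("right", slice(n_half, None))):
            # contralateral ERD: left-hand imagery (label 1) suppresses the
            # right-hemisphere mu source and vice versa
            contralateral = (labels[k] == 1 and hemi == "right") or (
                labels[k] == 2 and hemi == "left"
            )
            amp = config.mu_amplitude * float(np.exp(0.1 * rng.standard_normal()))
            if contralateral:
                amp *= erd_gain
            rows = np.zeros((n_half, n))
            rows[0] = amp * _narrowband_noise(rng, n, config.fs, (8.0, 12.0))
            for j in range(1, n_half):
                if config.irrelevant_source and j == n_half - 1:
                    # class-independent in-band (20-24 Hz) oscillator whose
                    # amplitude varies trial to trial
                    a = rng.uniform(0.0, config.irrelevant_max_amplitude)
                    rows[j] = a * _narrowband_noise(rng, n, config.fs, (20.0, 24.0))
                else:
                    # background (1/f) activity; background_jitter > 0 makes its
                    # per-trial amplitude lognormal, emulating the nonstationary
                    # band power of resting EEG
                    a = config.background_amplitude * float(
                        np.exp(config.background_jitter * rng.standard_normal())
                    )
                    rows[j] = a * _pink_noise(rng, n)
            sources[sl] = rows
        data[k] = mixing @ sources + config.noise_sd * rng.standard_normal(
            (config.n_channels, n)
        )

    names = tuple(f"L{i + 1}" for i in range(n_half)) + tuple(
        f"R{i + 1}" for i in range(n_half)
    )
    y = np.linspace(-0.5, 0.5, n_half)
    positions = np.concatenate(
        [np.column_stack([np.full(n_half, -0.5), y]),
         np.column_stack([np.full(n_half, 0.5), y])]
    )
    return EpochSet(data=data, fs=config.fs, channel_names=names,
                    channel_positions=positions, labels=labels)


def generate_ica_mixture(
    n_sources: int, n_channels: int, n_samples: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instantaneous linear mixture of independent super-Gaussian sources.

    Sources are unit-scale Laplace (kurtosis 3 above Gaussian), the mixing
    matrix is Gaussian with a minimum-singular-value guard so its columns
    are well separated.  Returns ``(mixed, true_mixing, true_sources)`` with
    ``mixed = true_mixing @ true_sources`` exactly.
    """
    if n_sources > n_channels:
        raise ConfigError(f"n_sources={n_sources} exceeds n_channels={n_channels}")
    if n_sources < 1 or n_samples < 2:
        raise ConfigError("need n_sources >= 1 and n_samples >= 2")
    rng = np.random.default_rng(seed)
    sources = rng.laplace(0.0, 1.0, size=(n_sources, n_samples))
    for _ in range(100):
        mixing = rng.standard_normal((n_channels, n_sources))
        sv = np.linalg.svd(mixing, compute_uv=False)
        if sv[-1] > 0.3 * sv[0]:
            break
    else:  # pragma: no cover
        raise RuntimeError("failed to draw a well-conditioned mixing matrix")
    return mixing @ sources, mixing, sources
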