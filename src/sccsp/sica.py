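"""Spectral independent component analysis (SICA).

The method learns a 2 x m demixing matrix W per hemisphere on single-sided
amplitude spectra of the band-passed EEG: frequency bins act as
observations and channels as variables, so W captures how μ-band
(8-12 Hz) content is spatially distributed rather than how time samples
mix.  W is obtained by principal-axis whitening to two dimensions followed
by natural-gradient information-maximization (infomax) with a logistic
nonlinearity.  Because the discrete Fourier transform is linear, applying W
to the time-domain channels is identical to demixing the complex spectra
and inverse-transforming — the amplitude spectra are used only to *learn*
W, never to resynthesize signals from magnitude alone.

Component conventions: components are ordered by their μ-band contrast
(the component whose spectrum shows the μ-band deficit first) and each
demixing row is scaled/signed so its scalp pattern (column of the
pseudo-inverse of W) has unit norm with a positive largest-magnitude entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, RankDeficiencyError, ValidationError

__all__ = [
    "AmplitudeSpectrum",
    "SpectralICAModel",
    "amplitude_spectrum",
    "fit_infomax",
    "apply_components",
    "mu_band_contrast",
    "amari_index",
]


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """Single-sided DFT modulus of a multichannel signal.

    ``values`` is ``channels x bins`` (non-negative, unnormalized modulus),
    ``freqs`` the bin frequencies in Hz (strictly increasing, within
    ``[0, fs/2]``), ``n_fft`` the transform length (= signal length; no
    zero padding, no taper).
    """

    values: np.ndarray
    freqs: np.ndarray
    n_fft: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        freqs = np.asarray(self.freqs, dtype=np.float64)
        if values.ndim != 2 or freqs.ndim != 1 or values.shape[1] != freqs.size:
            raise ValidationError("values must be channels x bins matching freqs")
        if np.any(values < 0):
            raise ValidationError("amplitude spectrum entries must be >= 0")
        if np.any(np.diff(freqs) <= 0):
            raise ValidationError("freqs must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "freqs", freqs)


def amplitude_spectrum(signal: np.ndarray, fs: float) -> AmplitudeSpectrum:
    """Single-sided unnormalized DFT modulus, bins ``0..floor(N/2)``."""
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    if signal.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    if not np.all(np.isfinite(signal)):
        raise ValidationError("signal contains non-finite values")
    values = np.abs(np.fft.rfft(signal, axis=1))
    freqs = np.fft.rfftfreq(signal.shape[1], d=1.0 / fs)
    return AmplitudeSpectrum(values=values, freqs=freqs, n_fft=signal.shape[1])


def mu_band_contrast(
    values: np.ndarray,
    freqs: np.ndarray,
    mu_band: tuple[float, float] = (8.0, 12.0),
    flanks: tuple[tuple[float, float], tuple[float, float]] = ((5.0, 8.0), (12.0, 15.0)),
) -> float:
    """Ratio of mean amplitude inside the μ band to mean amplitude in flanks.

    Flank bands are half-open away from the μ band (``[5, 8)`` and
    ``(12, 15]`` by default).  A lower ratio means stronger μ suppression;
    a flat spectrum gives exactly 1.0.
    """
    values = np.abs(np.asarray(values, dtype=np.float64)).ravel()
    freqs = np.asarray(freqs, dtype=np.float64)
    if values.size != freqs.size:
        raise ValidationError("values and freqs must have equal length")
    lo, hi = mu_band
    in_mu = (freqs >= lo) & (freqs <= hi)
    (f1lo, f1hi), (f2lo, f2hi) = flanks
    in_flank = ((freqs >= f1lo) & (freqs < f1hi)) | ((freqs > f2lo) & (freqs <= f2hi))
    if not in_mu.any() or not in_flank.any():
        raise ConfigError("μ band or flank band contains no frequency bins")
    flank_mean = values[in_flank].mean()
    if flank_mean == 0:
        return float("inf") if values[in_mu].mean() > 0 else 1.0
    return float(values[in_mu].mean() / flank_mean)


@dataclass(frozen=True)
class SpectralICAModel:
    """Fitted 2-component spectral demixing for one hemisphere.

    ``W`` (2 x m) demixes channels into components; ``mixing_pinv`` (m x 2)
    holds the scalp pattern of each component.  Rows of ``W`` follow
    ``component_order`` (μ-deficit component first when frequency
    information was available) and are scaled so each scalp pattern has
    unit Euclidean norm and a positive largest-magnitude entry.
    """

    W: np.ndarray
    mixing_pinv: np.ndarray
    component_order: tuple[int, ...]
    mu_contrast: tuple[float, ...] | None
    hemisphere: str | None = None
    converged: bool = True
    n_iter: int = 0

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


def _coerce_spectra(
    spectra: AmplitudeSpectrum | Sequence[AmplitudeSpectrum] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack fitting input into (m x observations, per-column freqs or None)."""
    if isinstance(spectra, AmplitudeSpectrum):
        spectra = [spectra]
    if isinstance(spectra, np.ndarray):
        X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
        return X, None
    mats, freqs = [], []
    for s in spectra:
        mats.append(s.values)
        freqs.append(s.freqs)
    X = np.concatenate(mats, axis=1)
    return X, np.concatenate(freqs)


def fit_infomax(
    spectra: AmplitudeSpectrum | Sequence[AmplitudeSpectrum] | np.ndarray,
    n_components: int = 2,
    *,
    seed: int = 0,
    lr: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-7,
    anneal: float = 0.98,
    anneal_deg: float = 60.0,
    max_obs: int | None = None,
    mu_band: tuple[float, float] = (8.0, 12.0),
    hemisphere: str | None = None,
) -> SpectralICAModel:
    """Fit the spectral infomax demixing matrix.

    Pipeline: center each channel row across bins (DC bins excluded),
    reduce to ``n_components`` dimensions by principal-axis whitening, then
    rotate by natural-gradient infomax with a logistic nonlinearity until
    the weight change drops below ``tol`` or ``max_iter`` is reached.  The
    learning rate is annealed (x ``anneal``) whenever the natural-gradient
    direction turns by more than ``anneal_deg`` degrees, which keeps the
    iteration stable without collapsing the step size on benign curvature.

    ``max_obs`` caps the number of spectral observation columns used in the
    iteration (seeded subsample) to bound runtime on long recordings; the
    whitening always uses all columns.
    """
    X, freqs = _coerce_spectra(spectra)
    m = X.shape[0]
    if m < n_components:
        raise ConfigError(f"need >= {n_components} channels, got {m}")
    if freqs is not None:
        keep = freqs > 0  # DC carries the (arbitrary) offset, not rhythm structure
        X_fit = X[:, keep]
        freqs_fit = freqs[keep]
    else:
        X_fit, freqs_fit = X, None
    if X_fit.shape[1] < 10 * n_components:
        raise ConfigError(
            f"need >= {10 * n_components} spectral observations, got {X_fit.shape[1]}"
        )

    rng = np.random.default_rng(seed)
    Xc = X_fit - X_fit.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / Xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    lead = evals[order]
    if lead[-1] <= 1e-10 * max(lead[0], 1.0) or lead[-1] <= 0:
        raise RankDeficiencyError(
            "spectra are numerically rank deficient for the requested number of "
            "components; consider adding a small ridge to the data covariance"
        )
    whitener = (evecs[:, order] / np.sqrt(lead)).T  # n_components x m
    Xw = whitener @ Xc

    if max_obs is not None and Xw.shape[1] > max_obs:
        sel = rng.choice(Xw.shape[1], size=max_obs, replace=False)
        Xw_it = Xw[:, sel]
    else:
        Xw_it = Xw
    n_obs = Xw_it.shape[1]

    R, _ = np.linalg.qr(rng.standard_normal((n_components, n_components)))
    eye = np.eye(n_components)
    cos_limit = np.cos(np.deg2rad(anneal_deg))
    prev_grad = None
    converged = False
    step = lr
    it = 0
    for it in range(1, max_iter + 1):
        U = R @ Xw_it
        Y = 1.0 / (1.0 + np.exp(-U))
        grad = (eye + (1.0 - 2.0 * Y) @ U.T / n_obs) @ R
        R = R + step * grad
        gnorm = float(np.linalg.norm(grad))
        if prev_grad is not None and gnorm > 0:
            cos = float((grad * prev_grad).sum()) / (
                gnorm * np.linalg.norm(prev_grad) + 1e-300
            )
            if cos < cos_limit:
                step *= anneal
        prev_grad = grad
        if step * gnorm < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"infomax did not converge within {max_iter} iterations "
            f"(last weight change {step * gnorm:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )

    W = R @ whitener  # n_components x m

    # canonical ordering by μ-band contrast of the component spectra
    contrasts: tuple[float, ...] | None = None
    comp_order = tuple(range(n_components))
    if freqs_fit is not None:
        comp_spec = np.abs(W @ X_fit)
        vals = [mu_band_contrast(comp_spec[c], freqs_fit, mu_band) for c in range(n_components)]
        comp_order = tuple(int(i) for i in np.argsort(vals, kind="stable"))
        W = W[list(comp_order)]
        contrasts = tuple(float(vals[i]) for i in comp_order)

    # per-row scale and sign: unit-norm scalp pattern, largest entry positive
    patterns = np.linalg.pinv(W)  # m x n_components
    for c in range(n_components):
        col = patterns[:, c]
        scale = np.linalg.norm(col)
        sign = np.sign(col[np.argmax(np.abs(col))]) or 1.0
        W[c] *= scale * sign
    patterns = np.linalg.pinv(W)

    return SpectralICAModel(
        W=W,
        mixing_pinv=patterns,
        component_order=comp_order,
        mu_contrast=contrasts,
        hemisphere=hemisphere,
        converged=converged,
        n_iter=it,
    )


def apply_components(model: SpectralICAModel, time_signal: np.ndarray) -> np.ndarray:
    """Demix a time-domain signal into temporal components (rows of W @ x).

    Equivalent, by DFT linearity, to demixing the complex spectra with W and
    inverse-transforming.
    """
    x = np.atleast_2d(np.asarray(time_signal, dtype=np.float64))
    if x.shape[0] != model.n_channels:
        raise ValidationError(
            f"signal has {x.shape[0]} channels, model expects {model.n_channels}"
        )
    return model.W @ x


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of ``P = W @ A_true``.

    0 means perfect separation up to permutation and scale; normalized by
    ``2 n (n - 1)`` so a random matrix scores near 1.
    """
    P = np.abs(np.asarray(P, dtype=np.float64))
    n = P.shape[0]
    if P.shape != (n, n) or n < 2:
        raise ValidationError("amari_index needs a square matrix of size >= 2")
    rows = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * n * (n - 1)))
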