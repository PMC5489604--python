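"""Epoch containers, portable I/O, band-pass filtering and hemisphere handling.

The central container is :class:`EpochSet`, a ``trials x channels x samples``
array of EEG amplitudes in microvolts plus montage metadata.  Epochs can be
round-tripped through a portable container (``.npz`` array file + JSON
sidecar) and read from EDF/GDF recordings (via :mod:`mne`, optional
dependency).  Preprocessing follows standard offline motor-imagery practice:
zero-phase Butterworth band-pass (default 5-30 Hz, order 4), extraction of
the imagery window, and a split of the montage into left- and
right-hemisphere channel groups.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
from scipy import signal as sps

from .errors import ConfigError, FormatError, ValidationError

__all__ = [
    "EpochSet",
    "HemisphereSplit",
    "read_epochs",
    "write_epochs",
    "bandpass_filter",
    "extract_window",
    "split_hemispheres",
]

#: Midline tolerance, as a fraction of the unit head radius.
MIDLINE_EPS = 1e-6


@dataclass(frozen=True)
class EpochSet:
    """Labeled or unlabeled epoch-segmented multichannel EEG.

    Parameters
    ----------
    data:
        ``(n_trials, n_channels, n_samples)`` float array, microvolts.
    fs:
        Sampling rate in Hz.
    channel_names:
        Montage labels, one per channel.
    channel_positions:
        Optional ``(n_channels, 2)`` scalp coordinates on the unit head
        radius; x runs left (negative) to right (positive), y posterior to
        anterior.
    labels:
        Optional per-trial class labels; when present, exactly two distinct
        classes (conventionally 1 and 2) and every trial labeled.
    window:
        Optional ``(t_start, t_end)`` seconds relative to trial onset that
        ``data`` covers.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ()
    channel_positions: np.ndarray | None = None
    labels: np.ndarray | None = None
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValidationError(
                f"data must be (trials, channels, samples); got ndim={data.ndim}"
            )
        object.__setattr__(self, "data", data)
        if not self.fs > 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        names = tuple(self.channel_names) if self.channel_names else tuple(
            f"ch{i + 1}" for i in range(data.shape[1])
        )
        if len(names) != data.shape[1]:
            raise ValidationError("channel_names length must match channel count")
        object.__setattr__(self, "channel_names", names)
        if self.channel_positions is not None:
            pos = np.asarray(self.channel_positions, dtype=np.float64)
            if pos.shape != (data.shape[1], 2):
                raise ValidationError("channel_positions must be (n_channels, 2)")
            object.__setattr__(self, "channel_positions", pos)
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=np.int64)
            if labels.shape != (data.shape[0],):
                raise ValidationError("labels must have one entry per trial")
            if len(np.unique(labels)) != 2:
                raise ValidationError(
                    f"labels must contain exactly 2 classes, got {np.unique(labels)}"
                )
            object.__setattr__(self, "labels", labels)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_indices(self) -> dict[int, np.ndarray]:
        """Trial indices per class label, keyed by label value."""
        if self.labels is None:
            raise ValidationError("EpochSet has no labels")
        return {int(c): np.flatnonzero(self.labels == c) for c in np.unique(self.labels)}


@dataclass(frozen=True)
class HemisphereSplit:
    """Partition of channel indices into left / right / excluded (midline)."""

    left_idx: tuple[int, ...]
    right_idx: tuple[int, ...]
    excluded_idx: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        groups = (set(self.left_idx), set(self.right_idx), set(self.excluded_idx))
        total = sum(len(g) for g in groups)
        union = set().union(*groups)
        if total != len(union):
            raise ConfigError("hemisphere index sets must be pairwise disjoint")
        if not self.left_idx or not self.right_idx:
            raise ConfigError("left and right hemisphere index sets must be non-empty")

    def validate_for(self, n_channels: int) -> None:
        union = set(self.left_idx) | set(self.right_idx) | set(self.excluded_idx)
        if union != set(range(n_channels)):
            raise ConfigError(
                f"split must cover all {n_channels} channels exactly; covers {sorted(union)}"
            )


# ---------------------------------------------------------------------------
# portable container I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write the portable container: ``<path>.npz`` + JSON sidecar.

    Refuses to write empty (0-trial) sets.  Returns the array-file path.
    """
    if epochs.n_trials == 0:
        raise ValidationError("refusing to write an EpochSet with 0 trials")
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez_compressed(path, data=epochs.data)
    meta: dict = {
        "fs": float(epochs.fs),
        "channel_names": list(epochs.channel_names),
    }
    if epochs.channel_positions is not None:
        meta["channel_positions"] = epochs.channel_positions.tolist()
    if epochs.labels is not None:
        meta["labels"] = [int(x) for x in epochs.labels]
    if epochs.window is not None:
        meta["window"] = [float(epochs.window[0]), float(epochs.window[1])]
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_portable(path: Path) -> EpochSet:
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "channel_names"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field '{key}'")
    with np.load(path) as npz:
        data = npz["data"]
    return EpochSet(
        data=data,
        fs=meta["fs"],
        channel_names=tuple(meta["channel_names"]),
        channel_positions=(
            np.asarray(meta["channel_positions"]) if "channel_positions" in meta else None
        ),
        labels=np.asarray(meta["labels"]) if "labels" in meta else None,
        window=tuple(meta["window"]) if "window" in meta else None,
    )


#: Default annotation-description to class-label map.  769/770 are the
#: standard left/right-hand cue codes of the BCI competition GDF files.
DEFAULT_EVENT_ID = {"769": 1, "770": 2, "left": 1, "right": 2}


def _read_mne(path: Path, fmt: str, event_id: dict[str, int] | None,
              tmin: float, tmax: float | None) -> EpochSet:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError("reading EDF/GDF files requires the 'mne' package") from exc

    reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_gdf
    raw = reader(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    wanted = dict(DEFAULT_EVENT_ID if event_id is None else event_id)
    try:
        events, desc_map = mne.events_from_annotations(raw, verbose="error")
    except ValueError:
        events, desc_map = np.empty((0, 3), dtype=int), {}
    # keep only annotations whose description maps to a class label
    code_to_label = {code: wanted[desc] for desc, code in desc_map.items() if desc in wanted}
    if not code_to_label:
        raise FormatError(
            f"no trial events found in {path.name}: no annotation matches "
            f"descriptions {sorted(wanted)} (field: annotations/events)"
        )
    keep = np.isin(events[:, 2], list(code_to_label))
    events = events[keep]
    if tmax is None:
        raise ConfigError("tmax (trial duration in s, relative to cue) is required")
    picks = mne.pick_types(raw.info, eeg=True, misc=False, stim=False, eog=False)
    ep = mne.Epochs(
        raw, events, tmin=tmin, tmax=tmax, baseline=None, proj=False,
        picks=picks, preload=True, verbose="error",
    )
    data_uv = ep.get_data(copy=True) * 1e6  # mne works in volts
    data_uv = data_uv[:, :, :-1]  # mne includes the tmax sample; keep half-open
    labels = np.array([code_to_label[c] for c in ep.events[:, 2]], dtype=np.int64)
    names = tuple(ep.ch_names)
    return EpochSet(data=data_uv, fs=fs, channel_names=names, labels=labels,
                    window=(tmin, tmax))


def read_epochs(path: str | Path, format: str = "portable", *,
                event_id: dict[str, int] | None = None,
                tmin: float = 0.0, tmax: float | None = None) -> EpochSet:
    """Read an :class:`EpochSet` from disk.

    Parameters
    ----------
    format:
        ``"portable"`` (``.npz`` + JSON sidecar written by
        :func:`write_epochs`), ``"edf"`` or ``"gdf"``.  For EDF/GDF the
        trial onsets and class labels are taken from annotations whose
        description appears in ``event_id`` (default: the BCI-competition
        cue codes 769/770 and the literals "left"/"right"), and each trial
        spans ``[tmin, tmax)`` seconds relative to its cue.
    """
    path = Path(path)
    if format == "portable":
        return _read_portable(path)
    if format in ("edf", "gdf"):
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_mne(path, format, event_id, tmin, tmax)
    raise ConfigError(f"unknown format {format!r}; expected portable/edf/gdf")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bandpass_filter(epochs: EpochSet, low: float = 5.0, high: float = 30.0,
                    order: int = 4, *, zero_phase: bool = True) -> EpochSet:
    """Butterworth band-pass per channel and trial.

    Zero-phase (forward-backward) by default, the standard for offline BCI
    analysis; set ``zero_phase=False`` for a causal filter.
    """
    if not 0 < low < high:
        raise ConfigError(f"need 0 < low < high, got ({low}, {high})")
    if high >= epochs.fs / 2:
        raise ConfigError(f"high={high} Hz must be below Nyquist {epochs.fs / 2} Hz")
    if order < 1:
        raise ConfigError("order must be >= 1")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=epochs.fs, output="sos")
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, epochs.data, axis=-1)
    else:
        filtered = sps.sosfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=np.ascontiguousarray(filtered))


def extract_window(epochs: EpochSet, t_start: float, t_end: float) -> EpochSet:
    """Restrict every trial to the half-open time window ``[t_start, t_end)``.

    Sample indices are ``floor(t * fs)``.
    """
    if not 0 <= t_start < t_end:
        raise ConfigError(f"need 0 <= t_start < t_end, got ({t_start}, {t_end})")
    i0 = math.floor(t_start * epochs.fs)
    i1 = math.floor(t_end * epochs.fs)
    if i1 > epochs.n_samples:
        raise ConfigError(
            f"window [{t_start}, {t_end}) s exceeds trial duration "
            f"{epochs.n_samples / epochs.fs} s"
        )
    return replace(epochs, data=epochs.data[:, :, i0:i1].copy(), window=(t_start, t_end))


def _auto_split(positions: np.ndarray) -> HemisphereSplit:
    x = positions[:, 0]
    left = tuple(int(i) for i in np.flatnonzero(x < -MIDLINE_EPS))
    right = tuple(int(i) for i in np.flatnonzero(x > MIDLINE_EPS))
    mid = tuple(int(i) for i in np.flatnonzero(np.abs(x) <= MIDLINE_EPS))
    return HemisphereSplit(left_idx=left, right_idx=right, excluded_idx=mid)


def split_hemispheres(
    epochs: EpochSet, split: HemisphereSplit | str = "auto"
) -> tuple[EpochSet, EpochSet]:
    """Split channels into left- and right-hemisphere epoch sets.

    With ``split="auto"`` the montage x-coordinate decides: x < 0 left,
    x > 0 right, midline channels excluded from both.  Each hemisphere must
    retain at least 2 channels (the spectral ICA needs >= 2 observed
    channels).
    """
    if isinstance(split, str):
        if split != "auto":
            raise ConfigError(f"split must be 'auto' or a HemisphereSplit, got {split!r}")
        if epochs.channel_positions is None:
            raise ConfigError("auto hemisphere split requires channel_positions")
        split = _auto_split(epochs.channel_positions)
    split.validate_for(epochs.n_channels)
    out = []
    for idx in (split.left_idx, split.right_idx):
        if len(idx) < 2:
            raise ConfigError(
                f"hemisphere with channels {idx} has fewer than 2 channels"
            )
        sel = np.asarray(idx, dtype=int)
        out.append(
            EpochSet(
                data=epochs.data[:, sel, :].copy(),
                fs=epochs.fs,
                channel_names=tuple(epochs.channel_names[i] for i in idx),
                channel_positions=(
                    epochs.channel_positions[sel] if epochs.channel_positions is not None else None
                ),
                labels=None if epochs.labels is None else epochs.labels.copy(),
                window=epochs.window,
            )
        )
    return out[0], out[1]
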