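"""Band-pass filtering and fixed-window trial segmentation.

Motor-imagery ERD/ERS lives in the mu (8-13 Hz) and beta (14-30 Hz)
rhythms, so the pipeline filters every channel to 8-30 Hz with a
third-order Butterworth design before anything else looks at the data.
Filtering is zero-phase (the order-3 design applied forward and backward):
offline analysis has no causality constraint and the downstream criterion
is variance-based, hence phase-insensitive.

Trials are cut from the continuous recording with fixed windows relative
to trial onset.  The shipped presets follow the public BCI competition
recordings this pipeline targets (times in seconds from trial start):

========== ===========
preset     window
========== ===========
iv1        2-6
iii-iiia   3-6
iii-iva    0-3
iv-2a      3-6
========== ===========

All sample indices are 0-based, windows half-open; seconds-to-samples
conversion rounds half-up so fixtures are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import Montage, MontageError

__all__ = [
    "EpochedEEG",
    "EventList",
    "PreprocessError",
    "WINDOW_PRESETS",
    "bandpass",
    "segment",
]

WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "iv1": (2.0, 6.0),
    "iii-iiia": (3.0, 6.0),
    "iii-iva": (0.0, 3.0),
    "iv-2a": (3.0, 6.0),
}


class PreprocessError(ValueError):
    """Invalid filter parameters, events or segmentation windows."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class EventList:
    """Event onsets (sample indices into a continuous recording) + classes."""

    onsets: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.classes = np.asarray(self.classes)
        if self.onsets.ndim != 1 or self.classes.shape != self.onsets.shape:
            raise PreprocessError("onsets and classes must be 1-D, same length")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise PreprocessError("event onsets must be strictly increasing")
        if self.onsets.size and self.onsets[0] < 0:
            raise PreprocessError("negative event onset")

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass
class EpochedEEG:
    """Two-class epoched EEG: ``trials x channels x samples`` (µV).

    ``labels`` holds the per-trial class in {0, 1}; by the convention of
    the synthetic generator 0 = left-hand imagery, 1 = right-hand imagery.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise PreprocessError(
                f"data must be trials x channels x samples, got {self.data.shape}"
            )
        if self.data.shape[2] < 2:
            raise PreprocessError("trials must have at least 2 samples")
        if not self.fs > 0:
            raise PreprocessError("sampling rate must be positive")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.data.shape[0],):
            raise PreprocessError("labels must have one entry per trial")
        if self.montage is not None and self.montage.n_channels != self.data.shape[1]:
            raise PreprocessError("montage size does not match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def ordinals(self) -> tuple[int, ...]:
        """Acquisition ordinals of the channels present."""
        if self.montage is not None:
            return self.montage.ordinals
        return tuple(range(self.n_channels))

    def restrict(self, subset: list[int] | tuple[int, ...]) -> "EpochedEEG":
        """Channel subset by acquisition ordinal (canonical, sorted order)."""
        from .montage import restrict as restrict_montage

        ords = self.ordinals
        try:
            positions = sorted(ords.index(int(s)) for s in set(map(int, subset)))
        except ValueError as exc:
            raise MontageError(f"subset ordinal not in epochs: {exc}") from None
        if len(positions) != len(subset):
            raise MontageError("duplicate ordinals in subset")
        sub_montage = None
        if self.montage is not None:
            sub_montage = restrict_montage(
                self.montage, [ords[p] for p in positions]
            )
        return EpochedEEG(
            data=self.data[:, positions, :],
            fs=self.fs,
            labels=self.labels,
            montage=sub_montage,
        )


def bandpass(
    data: np.ndarray,
    fs: float,
    low: float = 8.0,
    high: float = 30.0,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last (time) axis.

    `order` is the order of the one-direction design; forward-backward
    application doubles the effective attenuation and cancels phase.
    Accepts continuous ``(channels, samples)`` arrays, epoched
    ``(trials, channels, samples)`` arrays, or plain 1-D signals.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise PreprocessError("non-finite values in input signal")
    if not (0 < low < high):
        raise PreprocessError(f"need 0 < low < high, got {low}, {high}")
    if high >= fs / 2:
        raise PreprocessError(
            f"high edge {high} Hz must be below Nyquist ({fs / 2} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def segment(
    recording: np.ndarray,
    fs: float,
    events: EventList,
    window: tuple[float, float],
    montage: Montage | None = None,
) -> EpochedEEG:
    """Cut fixed windows around event onsets from a continuous recording.

    Trial ``t`` receives samples
    ``[onset_t + round(t_start*fs), onset_t + round(t_end*fs))``
    (half-open, 0-based, round half-up).  The extracted samples are exact
    copies of the recording — no filtering or scaling happens here.
    """
    recording = np.asarray(recording, dtype=float)
    if recording.ndim != 2:
        raise PreprocessError("recording must be channels x samples")
    t_start, t_end = float(window[0]), float(window[1])
    if not t_end > t_start:
        raise PreprocessError(f"window end must exceed start, got {window}")
    off0 = _round_half_up(t_start * fs)
    off1 = _round_half_up(t_end * fs)
    n_samples = recording.shape[1]
    trials = []
    for idx, onset in enumerate(events.onsets):
        lo, hi = int(onset) + off0, int(onset) + off1
        if lo < 0 or hi > n_samples:
            raise PreprocessError(
                f"event {idx} (onset {int(onset)}): window [{lo}, {hi}) "
                f"outside recording of {n_samples} samples"
            )
        trials.append(recording[:, lo:hi])
    if not trials:
        raise PreprocessError("no events to segment")
    return EpochedEEG(
        data=np.stack(trials, axis=0),
        fs=fs,
        labels=np.asarray(events.classes, dtype=np.int64),
        montage=montage,
    )
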