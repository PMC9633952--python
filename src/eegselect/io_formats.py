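"""Readers and writers: EDF/GDF recordings, text fixtures, result reports.

Real recordings (the public BCI competition sets ship as GDF/EDF) are
read best-effort through MNE's parsers; the delimited-text fixture format
written by :func:`eegselect.synthetic.make_fixture` is the canonical test
surface and round-trips losslessly at its stated precision.

All writers are atomic (temp file + rename) so a crashed run never
leaves a partial file that looks complete.  All sample indices are
0-based, half-open.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .floating_search import SelectionTrace, best_subset
from .montage import Montage
from .preprocess import EpochedEEG, EventList

__all__ = [
    "RecordingHandle",
    "FormatError",
    "read_edf",
    "read_gdf",
    "read_fixture",
    "write_results",
]


class FormatError(ValueError):
    """Unreadable or malformed input file."""


@dataclass
class RecordingHandle:
    """Continuous recording: ``channels x samples`` + header metadata."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    events: EventList | None = None
    annotations: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("recording data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise FormatError("one label per channel required")
        if not self.fs > 0:
            raise FormatError("sampling rate must be positive")

    @property
    def montage(self) -> Montage:
        return Montage(labels=self.channel_labels)


def _read_raw(path, kind: str, event_map: dict[str, int] | None) -> RecordingHandle:
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    import mne  # deferred: heavy import, only needed for real recordings

    readers = {"edf": mne.io.read_raw_edf, "gdf": mne.io.read_raw_gdf}
    try:
        raw = readers[kind](path, preload=True, verbose="ERROR")
    except Exception as exc:
        raise FormatError(f"cannot parse {kind.upper()} file {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    try:
        data = raw.get_data(units="uV")  # package-wide amplitude unit
    except ValueError:  # non-voltage channels present; MNE stores volts
        data = raw.get_data() * 1e6
    annotations = tuple(
        (int(np.floor(onset * fs + 0.5)), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    )
    events = None
    if event_map is not None:
        pairs = [(s, event_map[d]) for s, d in annotations if d in event_map]
        pairs.sort()
        events = EventList(
            onsets=np.array([p[0] for p in pairs], dtype=np.int64),
            classes=np.array([p[1] for p in pairs], dtype=np.int64),
        )
    return RecordingHandle(
        data=data,
        fs=fs,
        channel_labels=tuple(raw.ch_names),
        events=events,
        annotations=annotations,
    )


def read_edf(path, event_map: dict[str, int] | None = None) -> RecordingHandle:
    """Read an EDF/EDF+ recording.

    `event_map` optionally maps annotation descriptions to integer class
    labels, populating ``handle.events``; unmapped annotations stay
    available in ``handle.annotations``.
    """
    return _read_raw(path, "edf", event_map)


def read_gdf(path, event_map: dict[str, int] | None = None) -> RecordingHandle:
    """Read a GDF recording (BCI competition IV distribution format)."""
    return _read_raw(path, "gdf", event_map)


# -- fixture format -------------------------------------------------------

_META_KEYS = ("fs", "labels", "channel_labels", "n_trials")


def read_fixture(directory) -> EpochedEEG:
    """Load a ``data_trial<k>.csv`` + ``meta.json`` fixture directory."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.is_file():
        raise FormatError(f"missing meta.json in {directory}")
    meta = json.loads(meta_path.read_text())
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"meta.json missing keys: {missing}")
    n_trials = int(meta["n_trials"])
    if len(meta["labels"]) != n_trials:
        raise FormatError("labels length does not match n_trials")
    trials = []
    for t in range(n_trials):
        f = directory / f"data_trial{t}.csv"
        if not f.is_file():
            raise FormatError(f"missing trial file {f.name}")
        trials.append(np.atleast_2d(np.loadtxt(f, delimiter=",")))
    montage = Montage(
        labels=tuple(meta["channel_labels"]),
        coords=np.asarray(meta["coords"]) if meta.get("coords") else None,
    )
    return EpochedEEG(
        data=np.stack(trials, axis=0),
        fs=float(meta["fs"]),
        labels=np.asarray(meta["labels"], dtype=np.int64),
        montage=montage,
    )


# -- result reports -------------------------------------------------------


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sorted_by_position(ordinals, montage: Montage | None) -> list[int]:
    """Anterior-to-posterior, left-to-right; file order when no coords."""
    ordinals = list(ordinals)
    if montage is None:
        return sorted(ordinals)
    if montage.coords is None:
        return sorted(ordinals)
    def key(o):
        xy = montage.coords[montage.position_of(o)]
        return (-xy[1], xy[0])
    return sorted(ordinals, key=key)


def write_results(
    trace: SelectionTrace,
    directory,
    montage: Montage | None = None,
) -> dict[str, Path]:
    """Write ``trace.json``, ``curve.csv`` and ``channels.txt``.

    ``curve.csv`` is the accuracy-vs-k record (descending k; sizes a
    pair-wise search never visited are simply absent).  ``channels.txt``
    lists the finally selected channels, sorted by scalp position when
    coordinates are known.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "trace": directory / "trace.json",
        "curve": directory / "curve.csv",
        "channels": directory / "channels.txt",
    }
    _atomic_write(paths["trace"], trace.to_json() + "\n")

    def label_of(o: int) -> str:
        return montage.label_of(o) if montage is not None else str(o)

    lines = ["k,accuracy,channels"]
    for k in sorted(trace.best_per_size, reverse=True):
        rec = trace.best_per_size[k]
        labels = " ".join(label_of(o) for o in rec.subset)
        lines.append(f"{k},{rec.J!r},{labels}")
    _atomic_write(paths["curve"], "\n".join(lines) + "\n")

    _, subset, _ = best_subset(trace)
    ordered = _sorted_by_position(subset, montage)
    _atomic_write(
        paths["channels"], "\n".join(label_of(o) for o in ordered) + "\n"
    )
    return paths
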