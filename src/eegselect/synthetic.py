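"""Synthetic two-class motor-imagery EEG with planted lateralized ERD.

The generator emulates the single phenomenon the selection pipeline
exploits: event-related desynchronization (ERD), i.e. band-power
suppression of the sensorimotor rhythm contralateral to the imagined
hand.  Each channel carries independent band-limited noise (white noise
band-passed to 8-30 Hz).  On a left-hand trial (class 0) the *right*-
hemisphere planted channels have their source variance scaled by
``1 - erd_depth``; on a right-hand trial (class 1) the left-hemisphere
planted channels are suppressed.  A fixed random symmetric mixing matrix
``A = I + mixing_strength * M`` then smears sources across channels the
way volume conduction does.

This is deliberately minimal: variance suppression is the sufficient
statistic CSP detects, so spectral realism, artifacts, trial-to-trial
ERD variability and non-stationarity are out of scope.  Everything is
a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .montage import Montage
from .preprocess import EpochedEEG, bandpass

__all__ = ["SimConfig", "SimError", "default_montage", "simulate_mi", "make_fixture"]


class SimError(ValueError):
    """Invalid simulation configuration."""


#: 16-channel sensorimotor grid used by the default configuration.
#: x < 0 is the left hemisphere; y > 0 anterior. All left-right pairs.
_GRID16: tuple[tuple[str, float, float], ...] = (
    ("FC3", -0.5, 0.4), ("FC4", 0.5, 0.4),
    ("FC1", -0.2, 0.4), ("FC2", 0.2, 0.4),
    ("C5", -0.8, 0.0), ("C6", 0.8, 0.0),
    ("C3", -0.5, 0.0), ("C4", 0.5, 0.0),
    ("C1", -0.2, 0.0), ("C2", 0.2, 0.0),
    ("CP3", -0.5, -0.4), ("CP4", 0.5, -0.4),
    ("CP1", -0.2, -0.4), ("CP2", 0.2, -0.4),
    ("P3", -0.5, -0.8), ("P4", 0.5, -0.8),
)


def default_montage(n_channels: int = 16) -> Montage:
    """Montage for simulated data.

    16 channels gives the sensorimotor 10-20 grid above.  Other channel
    counts get generic mirrored labels (L1/R1, L2/R2, ..., plus a midline
    Mz channel when the count is odd) whose coordinates let the
    coordinate-mirroring rule recover the pairs.
    """
    if n_channels < 2:
        raise SimError("need at least 2 channels")
    if n_channels == 16:
        labels = tuple(g[0] for g in _GRID16)
        coords = np.array([[g[1], g[2]] for g in _GRID16])
        return Montage(labels=labels, coords=coords)
    labels: list[str] = []
    coords: list[list[float]] = []
    n_pairs = n_channels // 2
    for i in range(n_pairs):
        y = 0.8 - 1.6 * i / max(n_pairs - 1, 1)
        labels += [f"L{i + 1}", f"R{i + 1}"]
        coords += [[-0.5, y], [0.5, y]]
    if n_channels % 2:
        labels.append("Mz")
        coords.append([0.0, 0.0])
    return Montage(labels=tuple(labels), coords=np.array(coords))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated motor-imagery experiment.

    n_channels
        Electrodes in the montage (default 16: sensorimotor grid).
    n_trials
        Trials *per class* (default 60, i.e. 120 trials total).
    fs, trial_seconds
        100 Hz sampling and 3 s imagery windows, matching the downsampled
        public MI recordings this pipeline targets.
    planted_left, planted_right
        Channel indices carrying the class-dependent rhythm.  Defaults on
        the 16-channel grid: C3+CP3 on the left, C4+CP4 on the right —
        the hand-area electrodes where ERD is strongest.
    erd_depth
        Fractional variance suppression of a planted channel during its
        contralateral class, in [0, 1).  0.8 is a strong, clearly
        detectable effect; 0 makes the classes identical.
    mixing_strength
        Off-diagonal spatial mixing ``A = I + mixing_strength * M`` with
        ``M = (G + Gᵀ) / (2 sqrt(n))``, G standard normal.  The scaling
        puts the per-channel leakage variance at about
        ``mixing_strength² / 2`` relative to the direct signal; the
        default 0.3 is mild, realistic smearing that keeps A well away
        from singular.
    noise_sd
        Standard deviation of each channel's source noise before
        band-limiting.
    """

    n_channels: int = 16
    n_trials: int = 60
    fs: float = 100.0
    trial_seconds: float = 3.0
    planted_left: tuple[int, ...] | None = None
    planted_right: tuple[int, ...] | None = None
    erd_depth: float = 0.8
    mixing_strength: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise SimError("n_channels must be >= 2")
        if self.n_trials < 1:
            raise SimError("n_trials must be >= 1")
        if not (self.fs > 0 and self.trial_seconds > 0):
            raise SimError("fs and trial_seconds must be positive")
        if not 0 <= self.erd_depth < 1:
            raise SimError("erd_depth must be in [0, 1)")
        if not 0 <= self.mixing_strength < 1:
            raise SimError("mixing_strength must be in [0, 1)")
        if self.noise_sd <= 0:
            raise SimError("noise_sd must be positive")
        if self.planted_left is None:
            left = (6, 10) if self.n_channels == 16 else (0,)
            object.__setattr__(self, "planted_left", left)
        else:
            object.__setattr__(self, "planted_left",
                               tuple(int(c) for c in self.planted_left))
        if self.planted_right is None:
            right = (7, 11) if self.n_channels == 16 else (1,)
            object.__setattr__(self, "planted_right", right)
        else:
            object.__setattr__(self, "planted_right",
                               tuple(int(c) for c in self.planted_right))
        planted = self.planted_left + self.planted_right
        if len(set(planted)) != len(planted):
            raise SimError("planted_left and planted_right must be disjoint")
        if planted and not (0 <= min(planted) and max(planted) < self.n_channels):
            raise SimError("planted channel index out of range")

    @property
    def planted(self) -> tuple[int, ...]:
        return tuple(sorted(self.planted_left + self.planted_right))

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "n_trials": self.n_trials,
            "fs": self.fs,
            "trial_seconds": self.trial_seconds,
            "planted_left": list(self.planted_left),
            "planted_right": list(self.planted_right),
            "erd_depth": self.erd_depth,
            "mixing_strength": self.mixing_strength,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("planted_left", "planted_right"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def simulate_mi(config: SimConfig) -> EpochedEEG:
    """Generate epoched two-class MI-like EEG from `config`.

    Trials alternate left (0) / right (1); each class gets
    ``config.n_trials`` trials.  One second of padding on both sides of
    every trial is generated, filtered and discarded so the retained
    samples are stationary band-limited noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_channels
    n_total = 2 * config.n_trials
    n_samp = int(np.floor(config.trial_seconds * config.fs + 0.5))
    pad = int(np.floor(config.fs + 0.5))

    G = rng.standard_normal((n, n))
    M = (G + G.T) / (2.0 * np.sqrt(n))
    A = np.eye(n) + config.mixing_strength * M

    noise = rng.standard_normal((n_total, n, n_samp + 2 * pad))
    sources = bandpass(noise, config.fs, 8.0, 30.0)[..., pad:pad + n_samp]

    labels = np.tile([0, 1], config.n_trials)
    scale = np.full((n_total, n), config.noise_sd)
    amp = np.sqrt(1.0 - config.erd_depth)
    for t, lab in enumerate(labels):
        suppressed = config.planted_right if lab == 0 else config.planted_left
        scale[t, list(suppressed)] *= amp

    data = np.einsum("cd,tds->tcs", A, sources * scale[:, :, None])
    return EpochedEEG(
        data=data, fs=config.fs, labels=labels,
        montage=default_montage(n),
    )


# -- fixture format -------------------------------------------------------

_META_REQUIRED = ("fs", "labels", "channel_labels", "n_trials")


def make_fixture(config: SimConfig, path) -> list[Path]:
    """Write a simulated dataset as ``data_trial<k>.csv`` files + ``meta.json``.

    The format is the canonical text fixture of the package: one CSV of
    shape channels x samples per trial (fixed ``%.10e`` formatting) and a
    JSON sidecar holding the sampling rate, per-trial class labels,
    channel labels, coordinates and the generating configuration.
    Regenerating from the same config is byte-identical.
    """
    epochs = simulate_mi(config)
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for t in range(epochs.n_trials):
        f = out / f"data_trial{t}.csv"
        np.savetxt(f, epochs.data[t], fmt="%.10e", delimiter=",")
        written.append(f)
    meta = {
        "fs": epochs.fs,
        "labels": epochs.labels.tolist(),
        "channel_labels": list(epochs.montage.labels),
        "coords": epochs.montage.coords.tolist(),
        "n_trials": epochs.n_trials,
        "sim_config": config.to_dict(),
    }
    meta_path = out / "meta.json"
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    written.append(meta_path)
    return written
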