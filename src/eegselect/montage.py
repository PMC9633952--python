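"""Electrode montages and symmetric channel-pair units.

The 10-20 naming convention encodes hemisphere in the trailing digit of a
channel label: odd numbers sit over the left hemisphere, even numbers over
the right, and a ``z`` suffix marks the midline (C3 and C4 flank Cz over the
motor strip).  Left/right mirror electrodes see mirrored versions of the
same physiology during hand motor imagery — ERD lateralizes contralateral
to the imagined hand — which is why a search over *channel pairs* instead
of single channels can halve the number of atomic moves without giving up
much selection quality.

This module represents montages (labels, optional 2-D scalp coordinates,
acquisition ordinals) and derives the unit partition used by the modified
floating search: left-right pairs where a mirror electrode exists, and
singleton units elsewhere (midline electrodes stay selectable one at a
time).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "ChannelUnit",
    "MontageError",
    "derive_units",
    "restrict",
]


class MontageError(ValueError):
    """Invalid montage (duplicate labels, bad coordinates, bad subset)."""


@dataclass(frozen=True, eq=False)
class Montage:
    """Ordered electrode layout.

    Parameters
    ----------
    labels
        Channel names in acquisition order, unique and non-empty.
    coords
        Optional ``(n, 2)`` scalp positions; ``x`` negative on the left,
        positive on the right, ``y`` positive anterior.  Units are arbitrary
        but must be consistent within a montage.
    ordinals
        Index of each channel in the original acquisition order.  A montage
        produced by :func:`restrict` keeps the *original* ordinals so that
        tie-breaking in the search stays anchored to file order.
    """

    labels: tuple[str, ...]
    coords: np.ndarray | None = None
    ordinals: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        if len(labels) == 0:
            raise MontageError("montage must contain at least one channel")
        if any(l == "" for l in labels):
            raise MontageError("empty channel label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise MontageError(f"duplicate channel labels: {dupes}")
        object.__setattr__(self, "labels", labels)
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (len(labels), 2):
                raise MontageError(
                    f"coords shape {coords.shape} does not match "
                    f"{len(labels)} labels"
                )
            if not np.all(np.isfinite(coords)):
                raise MontageError("non-finite montage coordinates")
            object.__setattr__(self, "coords", coords)
        if self.ordinals is None:
            object.__setattr__(self, "ordinals", tuple(range(len(labels))))
        else:
            ordinals = tuple(int(o) for o in self.ordinals)
            if len(ordinals) != len(labels) or len(set(ordinals)) != len(ordinals):
                raise MontageError("ordinals must be unique, one per label")
            object.__setattr__(self, "ordinals", ordinals)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def position_of(self, ordinal: int) -> int:
        """Row index of the channel whose acquisition ordinal is `ordinal`."""
        try:
            return self.ordinals.index(int(ordinal))
        except ValueError:
            raise MontageError(f"ordinal {ordinal} not in montage") from None

    def label_of(self, ordinal: int) -> str:
        return self.labels[self.position_of(ordinal)]

    def ordinal_of(self, label: str) -> int:
        """Acquisition ordinal for a label, matched case-insensitively."""
        lower = [l.lower() for l in self.labels]
        try:
            return self.ordinals[lower.index(label.lower())]
        except ValueError:
            raise MontageError(f"channel {label!r} not in montage") from None

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload: dict = {"labels": list(self.labels)}
        if self.coords is not None:
            payload["coords"] = self.coords.tolist()
        if self.ordinals != tuple(range(self.n_channels)):
            payload["ordinals"] = list(self.ordinals)
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "Montage":
        payload = json.loads(text)
        return cls(
            labels=tuple(payload["labels"]),
            coords=payload.get("coords"),
            ordinals=tuple(payload["ordinals"]) if "ordinals" in payload else None,
        )


@dataclass(frozen=True)
class ChannelUnit:
    """Atomic move of the modified search: one electrode or a mirror pair."""

    members: tuple[int, ...]

    def __post_init__(self) -> None:
        members = tuple(sorted(int(m) for m in self.members))
        if len(members) not in (1, 2) or len(set(members)) != len(members):
            raise MontageError(f"unit must have 1 or 2 distinct members: {members}")
        object.__setattr__(self, "members", members)

    @property
    def kind(self) -> str:
        return "pair" if len(self.members) == 2 else "singleton"

    @property
    def ordinal(self) -> int:
        """Tie-break ordinal of the unit = lowest member ordinal."""
        return self.members[0]

    def __len__(self) -> int:
        return len(self.members)


_TRAILING_NUM = re.compile(r"^(.*?)(\d+)$")


def _mirror_label(label: str) -> str | None:
    """10-20 mirror name: odd trailing number <-> the next even one."""
    m = _TRAILING_NUM.match(label)
    if m is None:
        return None
    prefix, num = m.group(1), int(m.group(2))
    if num == 0:  # some montages use 0 for midline (e.g. Fpz written FP0)
        return None
    mirror = num + 1 if num % 2 else num - 1
    return f"{prefix}{mirror}"


def derive_units(montage: Montage, coord_tol: float | None = None) -> list[ChannelUnit]:
    """Partition a montage into left-right pairs and singletons.

    Pairing runs in two stages.  First the 10-20 label rule: a channel whose
    label ends in an odd digit pairs with the same prefix ending in the next
    even digit (C3<->C4, FC1<->FC2, ...), matched case-insensitively.  When
    coordinates are available a label-rule pair is accepted only if the two
    channels actually mirror each other on the scalp (non-10-20 names such
    as L1/L2 would otherwise pair two left-hemisphere electrodes).
    Channels the label rule leaves unpaired (``z``-suffixed midline names,
    non-standard labels) fall back to coordinate mirroring when coordinates
    are available: a channel at (x, y) pairs with the mutual nearest
    unpaired channel near (-x, y), both axes within `coord_tol`.  Whatever
    remains becomes a singleton unit.

    Parameters
    ----------
    montage
        Layout to partition.
    coord_tol
        Absolute tolerance for the coordinate stage.  Default: 10% of the
        montage's largest coordinate range.

    Returns
    -------
    list of ChannelUnit
        A partition of all channels, sorted by unit ordinal.
    """
    n = montage.n_channels
    ords = montage.ordinals
    coords = montage.coords
    paired: dict[int, int] = {}  # position -> mirror position

    if coords is not None and coord_tol is None:
        span = float(np.max(coords.max(axis=0) - coords.min(axis=0)))
        coord_tol = 0.1 * span if span > 0 else 0.0

    def mirror_consistent(i: int, j: int) -> bool:
        if coords is None:
            return True
        return (
            abs(coords[j, 0] + coords[i, 0]) <= coord_tol
            and abs(coords[j, 1] - coords[i, 1]) <= coord_tol
        )

    by_lower = {l.lower(): i for i, l in enumerate(montage.labels)}
    for i, label in enumerate(montage.labels):
        if i in paired:
            continue
        if label.lower().endswith("z"):
            continue  # midline by name; never paired by the label rule
        mirror = _mirror_label(label)
        if mirror is None:
            continue
        j = by_lower.get(mirror.lower())
        if j is not None and j != i and j not in paired and mirror_consistent(i, j):
            paired[i] = j
            paired[j] = i

    if montage.coords is not None:
        leftovers = [i for i in range(n) if i not in paired]

        def mirror_match(i: int, pool: list[int]) -> int | None:
            target = np.array([-coords[i, 0], coords[i, 1]])
            best, best_d = None, np.inf
            for j in pool:
                if j == i:
                    continue  # a midline channel must not pair with itself
                d = float(np.hypot(*(coords[j] - target)))
                ok = (
                    abs(coords[j, 0] + coords[i, 0]) <= coord_tol
                    and abs(coords[j, 1] - coords[i, 1]) <= coord_tol
                )
                if ok and d < best_d:
                    best, best_d = j, d
            return best

        for i in leftovers:
            if i in paired:
                continue
            pool = [j for j in leftovers if j not in paired]
            j = mirror_match(i, pool)
            if j is not None and mirror_match(j, pool) == i:
                paired[i] = j
                paired[j] = i

    units: list[ChannelUnit] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        if i in paired:
            j = paired[i]
            units.append(ChannelUnit((ords[i], ords[j])))
            seen.update((i, j))
        else:
            units.append(ChannelUnit((ords[i],)))
            seen.add(i)
    units.sort(key=lambda u: u.ordinal)
    return units


def restrict(montage: Montage, subset: list[int] | tuple[int, ...]) -> Montage:
    """Montage containing only `subset` (acquisition ordinals), order kept.

    Original ordinals are preserved on the restricted montage, so repeated
    restriction commutes with restriction to the intersection.
    """
    subset = [int(s) for s in subset]
    if len(subset) == 0:
        raise MontageError("subset must be non-empty")
    if len(set(subset)) != len(subset):
        raise MontageError("duplicate ordinals in subset")
    positions = [montage.position_of(s) for s in subset]
    positions.sort()
    return Montage(
        labels=tuple(montage.labels[p] for p in positions),
        coords=None if montage.coords is None else montage.coords[positions],
        ordinals=tuple(montage.ordinals[p] for p in positions),
    )
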