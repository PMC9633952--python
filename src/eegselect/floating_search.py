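"""Sequential backward floating search over channels or channel-pair units.

The search starts from the full channel set and alternates two moves:

* **Exclusion** — remove the unit whose removal maximizes the criterion
  J on the remaining subset (ties: remove the lowest-ordinal unit, so
  later-acquired channels survive ties).
* **Conditional inclusion** — among excluded units, re-add the one that
  maximizes J, but only if the result *strictly* exceeds the best value
  already recorded at the resulting subset size; repeat while improvement
  continues, then go back to exclusion.

A per-size record (the "update strategy") keeps, for every visited
subset size k, the best criterion value and subset seen anywhere in the
run; the accuracy-vs-k curve and the final selection are read from this
record, so later floating passes can retroactively improve earlier
sizes.  The run terminates when an exclusion reaches ``k_min`` channels
(2 by default — the smallest subset CSP can handle) or no legal
exclusion remains.

In the modified search the atomic move is a :class:`~eegselect.montage.
ChannelUnit` — a left-right symmetric electrode pair or a singleton — so
one move can add or remove two channels at a time.  Sweeps then cost one
criterion call per *unit* rather than per channel, which is where the
speed-up over plain SBFS comes from; subset sizes skipped by pair moves
simply have no entry in the record.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .montage import ChannelUnit
from .preprocess import EpochedEEG

__all__ = [
    "SearchConfig",
    "SearchStep",
    "SizeRecord",
    "SelectionTrace",
    "SearchError",
    "sbfs",
    "modified_sbfs",
    "best_subset",
]

logger = logging.getLogger(__name__)


class SearchError(RuntimeError):
    """Search-level failure (criterion error mid-run, bad configuration)."""


@dataclass(frozen=True)
class SearchConfig:
    """Floating-search settings.

    k_min
        Smallest subset size the search may reach (>= 2: CSP needs two
        channels).
    max_steps
        Safety cap on accepted moves; ``None`` means ``50 * d``.  If the
        cap is hit the trace is returned flagged non-terminated.
    """

    k_min: int = 2
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise SearchError("k_min must be >= 2 (CSP constraint)")
        if self.max_steps is not None and self.max_steps <= 0:
            raise SearchError("max_steps must be positive")


@dataclass(frozen=True)
class SearchStep:
    """One accepted move of the search."""

    action: str  # "exclude" | "include"
    unit: tuple[int, ...]
    k_after: int
    J: float


@dataclass(frozen=True)
class SizeRecord:
    """Best subset and criterion value recorded at one subset size."""

    subset: tuple[int, ...]
    J: float


@dataclass
class SelectionTrace:
    """Full record of a selection run."""

    d: int
    unit_mode: str  # "channels" | "pairs"
    k_min: int
    best_per_size: dict[int, SizeRecord]
    steps: list[SearchStep]
    eval_count: int
    terminated: bool

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "d": self.d,
            "unit_mode": self.unit_mode,
            "k_min": self.k_min,
            "terminated": self.terminated,
            "eval_count": self.eval_count,
            "best_per_size": {
                str(k): {"subset": list(rec.subset), "J": rec.J}
                for k, rec in self.best_per_size.items()
            },
            "steps": [
                {
                    "action": s.action,
                    "unit": list(s.unit),
                    "k_after": s.k_after,
                    "J": s.J,
                }
                for s in self.steps
            ],
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "SelectionTrace":
        p = json.loads(text)
        return cls(
            d=int(p["d"]),
            unit_mode=p["unit_mode"],
            k_min=int(p["k_min"]),
            best_per_size={
                int(k): SizeRecord(tuple(v["subset"]), float(v["J"]))
                for k, v in p["best_per_size"].items()
            },
            steps=[
                SearchStep(s["action"], tuple(s["unit"]), int(s["k_after"]),
                           float(s["J"]))
                for s in p["steps"]
            ],
            eval_count=int(p["eval_count"]),
            terminated=bool(p["terminated"]),
        )


def _as_J(value) -> float:
    """Accept plain floats or CriterionValue-likes from the criterion."""
    return float(getattr(value, "accuracy", value))


def _float_search(
    units: list[ChannelUnit],
    criterion,
    config: SearchConfig,
    unit_mode: str,
) -> SelectionTrace:
    all_channels = sorted(c for u in units for c in u.members)
    d = len(all_channels)
    if len(set(all_channels)) != d:
        raise SearchError("units do not partition the channels")
    if d < config.k_min:
        raise SearchError(f"only {d} channels but k_min={config.k_min}")
    max_steps = config.max_steps if config.max_steps is not None else 50 * d
    units = sorted(units, key=lambda u: u.ordinal)

    evals = 0

    def J_of(subset: tuple[int, ...]) -> float:
        nonlocal evals
        evals += 1
        try:
            return _as_J(criterion(subset))
        except Exception as exc:
            raise SearchError(
                f"criterion failed on subset {subset}: {exc}"
            ) from exc

    best: dict[int, SizeRecord] = {}
    steps: list[SearchStep] = []

    def record(k: int, subset: tuple[int, ...], J: float) -> None:
        prev = best.get(k)
        if prev is None or J > prev.J:
            best[k] = SizeRecord(subset, J)

    def channels_of(unit_set: list[ChannelUnit]) -> tuple[int, ...]:
        return tuple(sorted(c for u in unit_set for c in u.members))

    current = list(units)
    k = d
    subset = channels_of(current)
    record(d, subset, J_of(subset))

    terminated = False
    while True:
        if k == config.k_min:
            terminated = True
            break
        # --- Exclusion -------------------------------------------------
        legal = [u for u in current if k - len(u) >= config.k_min]
        if not legal:
            terminated = True
            break
        best_u, best_J = None, -np.inf
        for u in legal:  # ordinal order: ties keep the first (lowest) seen
            trial_set = [v for v in current if v is not u]
            J = J_of(channels_of(trial_set))
            if J > best_J:
                best_u, best_J = u, J
        current = [v for v in current if v is not best_u]
        k -= len(best_u)
        subset = channels_of(current)
        record(k, subset, best_J)
        steps.append(SearchStep("exclude", best_u.members, k, best_J))
        if len(steps) >= max_steps:
            warnings.warn("floating search hit max_steps; trace incomplete",
                          RuntimeWarning, stacklevel=2)
            break
        if k == config.k_min:
            terminated = True
            break
        # --- Conditional inclusion -------------------------------------
        while True:
            excluded = [u for u in units if u not in current
                        and k + len(u) <= d]
            if not excluded:
                break
            inc_u, inc_J = None, -np.inf
            for u in excluded:  # ordinal order; ties add the lowest ordinal
                trial_set = current + [u]
                J = J_of(channels_of(trial_set))
                if J > inc_J:
                    inc_u, inc_J = u, J
            target = k + len(inc_u)
            prev = best.get(target)
            if prev is not None and not (inc_J > prev.J):
                break  # no strict improvement at the target size
            current = sorted(current + [inc_u], key=lambda u: u.ordinal)
            k = target
            subset = channels_of(current)
            record(k, subset, inc_J)
            steps.append(SearchStep("include", inc_u.members, k, inc_J))
            if len(steps) >= max_steps:
                break
        if len(steps) >= max_steps and not terminated:
            warnings.warn("floating search hit max_steps; trace incomplete",
                          RuntimeWarning, stacklevel=2)
            break

    return SelectionTrace(
        d=d,
        unit_mode=unit_mode,
        k_min=config.k_min,
        best_per_size=best,
        steps=steps,
        eval_count=evals,
        terminated=terminated,
    )


def sbfs(
    epochs: EpochedEEG,
    criterion,
    config: SearchConfig | None = None,
) -> SelectionTrace:
    """Channel-wise sequential backward floating search.

    ``criterion`` is called with a tuple of channel ordinals and must
    return a float (or an object with an ``accuracy`` attribute, such as
    :class:`~eegselect.criterion.CriterionValue`).
    """
    config = config or SearchConfig()
    units = [ChannelUnit((o,)) for o in epochs.ordinals]
    return _float_search(units, criterion, config, "channels")


def modified_sbfs(
    epochs: EpochedEEG,
    criterion,
    units: list[ChannelUnit],
    config: SearchConfig | None = None,
) -> SelectionTrace:
    """Floating search whose atomic move is a symmetric channel pair.

    ``units`` must partition the channels of `epochs` (see
    :func:`~eegselect.montage.derive_units`).  Subset sizes in the trace
    count channels, so a pair move changes k by 2; sizes the pair moves
    skip have no entry in the per-size record.
    """
    config = config or SearchConfig()
    unit_channels = sorted(c for u in units for c in u.members)
    if unit_channels != sorted(epochs.ordinals):
        raise SearchError("units do not partition the epochs' channels")
    return _float_search(units, criterion, config, "pairs")


def best_subset(trace: SelectionTrace) -> tuple[int, tuple[int, ...], float]:
    """Final selection: highest recorded J; ties go to the fewest channels."""
    if not trace.best_per_size:
        raise SearchError("empty selection trace")
    if not trace.terminated:
        warnings.warn("trace is non-terminated; best subset may be partial",
                      RuntimeWarning, stacklevel=2)
    k_star = min(
        trace.best_per_size,
        key=lambda k: (-trace.best_per_size[k].J, k),
    )
    rec = trace.best_per_size[k_star]
    return k_star, rec.subset, rec.J
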