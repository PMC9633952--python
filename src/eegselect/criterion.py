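"""Wrapper criterion J(X_k): cross-validated CSP + RBF-SVM accuracy.

The selection criterion for a channel subset is the mean accuracy of an
RBF-kernel SVM on CSP log-variance features, under stratified k-fold
cross-validation (10 folds by default).  CSP is fitted inside each
training fold only — the spatial filters never see test trials — so the
criterion is leakage-safe.

The evaluator is a pure function of (epochs, subset, config): fold
assignment is fixed once per evaluator from the seed and shared across
every subset evaluation, so criterion values for different subsets are
paired comparisons.  Results are memoized per subset, and every
evaluation is logged as one JSON line at DEBUG level for post-hoc audit
of the search's evaluation count.

A key computational shortcut: CSP fitting and log-variance features need
only the per-trial Gram matrices ``R_t = X_t X_tᵀ``.  The evaluator
computes the full-montage Gram matrix once per trial; any channel
subset's covariance is then a renormalized sub-block and a projected
variance is the quadratic form ``wᵀ R_t w``, so no evaluation ever
touches raw samples again.  This is exactly the naive computation,
reorganized.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .csp import _VAR_FLOOR, _csp_from_covs
from .preprocess import EpochedEEG

__all__ = [
    "CriterionConfig",
    "CriterionValue",
    "CriterionError",
    "CriterionEvaluator",
    "evaluate_subset",
]

logger = logging.getLogger(__name__)


class CriterionError(ValueError):
    """Invalid subset or fold configuration."""


@dataclass(frozen=True)
class CriterionConfig:
    """Settings of the wrapper criterion.

    folds
        Number of CV folds (10 by default, stratified).
    svm_c, svm_gamma
        RBF-SVM hyperparameters.  ``svm_gamma`` may be a float or
        ``"scale"`` = 1 / (n_features * feature_variance).
    m_pairs
        Requested CSP filter pairs (effective pairs shrink on small subsets).
    seed
        Seed for the fold shuffle; identical seeds give identical folds.
    stratified
        Keep class proportions per fold (plain KFold when False).
    """

    folds: int = 10
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    m_pairs: int = 2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise CriterionError("folds must be >= 2")


@dataclass(frozen=True)
class CriterionValue:
    """One criterion evaluation: mean CV accuracy of a channel subset."""

    accuracy: float
    fold_accuracies: tuple[float, ...]
    subset: tuple[int, ...]
    eval_id: int

    def __float__(self) -> float:
        return self.accuracy


class CriterionEvaluator:
    """Memoizing, fold-paired criterion over channel subsets.

    Calling the evaluator with a list of acquisition ordinals returns the
    :class:`CriterionValue` for that subset.  ``eval_count`` counts calls;
    ``unique_count`` counts cache misses (actual CV runs).
    """

    def __init__(self, epochs: EpochedEEG, config: CriterionConfig | None = None):
        self.config = config or CriterionConfig()
        self.epochs = epochs
        labels = epochs.labels
        counts = np.bincount(labels) if labels.size else np.array([])
        present = counts[counts > 0]
        if present.size != 2:
            raise CriterionError("criterion needs exactly two classes of trials")
        if int(present.min()) < self.config.folds:
            raise CriterionError(
                f"{self.config.folds} folds need >= {self.config.folds} trials "
                f"per class; smallest class has {int(present.min())}"
            )
        self._ordinals = epochs.ordinals
        self._pos = {o: i for i, o in enumerate(self._ordinals)}
        # full-montage Gram matrix per trial; every subset reuses sub-blocks
        self._gram = np.einsum("tcs,tds->tcd", epochs.data, epochs.data)
        self._n_samples = epochs.n_samples
        self._labels = labels
        if self.config.stratified:
            splitter = StratifiedKFold(
                n_splits=self.config.folds, shuffle=True,
                random_state=self.config.seed,
            )
        else:
            from sklearn.model_selection import KFold

            splitter = KFold(
                n_splits=self.config.folds, shuffle=True,
                random_state=self.config.seed,
            )
        self._folds = [
            (tr.copy(), te.copy())
            for tr, te in splitter.split(np.zeros(labels.size), labels)
        ]
        self._cache: dict[frozenset, CriterionValue] = {}
        self.eval_count = 0
        self.unique_count = 0

    # -- internals --------------------------------------------------------
    def _positions(self, subset) -> list[int]:
        try:
            positions = sorted(self._pos[int(s)] for s in subset)
        except KeyError as exc:
            raise CriterionError(f"unknown channel ordinal {exc}") from None
        if len(set(positions)) != len(list(subset)):
            raise CriterionError("duplicate ordinals in subset")
        return positions

    def _features(self, W: np.ndarray, cols, R_sub: np.ndarray) -> np.ndarray:
        Wsel = W[:, list(cols)]
        var = np.einsum("cf,tcd,df->tf", Wsel, R_sub, Wsel) / self._n_samples
        return np.log(np.maximum(var, _VAR_FLOOR))

    def __call__(self, subset) -> CriterionValue:
        subset_t = tuple(int(s) for s in subset)
        if len(subset_t) < 2:
            raise CriterionError(
                f"criterion needs >= 2 channels, got subset {subset_t}"
            )
        self.eval_count += 1
        key = frozenset(subset_t)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        positions = self._positions(subset_t)
        R_sub = self._gram[np.ix_(range(self._gram.shape[0]), positions, positions)]
        traces = np.trace(R_sub, axis1=1, axis2=2)
        if np.any(traces <= 0):
            raise CriterionError("degenerate trial (zero power) in subset")
        C_norm = R_sub / traces[:, None, None]
        y = self._labels
        classes = np.unique(y)
        fold_acc = []
        for tr_idx, te_idx in self._folds:
            y_tr = y[tr_idx]
            if np.unique(y_tr).size != 2:
                raise CriterionError("single-class training fold")
            Ca = C_norm[tr_idx][y_tr == classes[0]].mean(axis=0)
            Cb = C_norm[tr_idx][y_tr == classes[1]].mean(axis=0)
            model = _csp_from_covs(Ca, Cb, self.config.m_pairs)
            F_tr = self._features(model.W, model.selected_cols, R_sub[tr_idx])
            F_te = self._features(model.W, model.selected_cols, R_sub[te_idx])
            clf = SVC(
                C=self.config.svm_c, kernel="rbf", gamma=self.config.svm_gamma
            )
            clf.fit(F_tr, y_tr)
            fold_acc.append(float(np.mean(clf.predict(F_te) == y[te_idx])))
        value = CriterionValue(
            accuracy=float(np.mean(fold_acc)),
            fold_accuracies=tuple(fold_acc),
            subset=tuple(sorted(subset_t)),
            eval_id=self.unique_count,
        )
        self.unique_count += 1
        self._cache[key] = value
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                json.dumps(
                    {
                        "event": "criterion_eval",
                        "subset": sorted(subset_t),
                        "J": value.accuracy,
                        "eval_id": value.eval_id,
                        "time": time.time(),
                    },
                    sort_keys=True,
                )
            )
        return value


def evaluate_subset(
    epochs: EpochedEEG,
    subset,
    config: CriterionConfig | None = None,
) -> CriterionValue:
    """One-shot criterion evaluation (builds a fresh evaluator).

    For a selection run, construct a single :class:`CriterionEvaluator`
    instead so that fold pairing and memoization are shared.
    """
    return CriterionEvaluator(epochs, config)(subset)
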