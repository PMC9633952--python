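"""Common Spatial Patterns (CSP) feature extraction.

CSP finds spatial filters that maximize the variance of one class while
minimizing it for the other, by jointly diagonalizing the two class-mean
covariance matrices.  With ``X`` a band-passed trial (channels x samples),
the per-trial normalized covariance is

    C = X Xᵀ / trace(X Xᵀ)

and ``Ca``, ``Cb`` are the trial averages per class.  Writing the composite
``Cc = Ca + Cb = U diag(λ) Uᵀ``, the whitening transform is

    P = diag(λ)^(−1/2) Uᵀ          so that  P Cc Pᵀ = I.

The whitened class covariances ``Sa = P Ca Pᵀ`` and ``Sb = P Cb Pᵀ`` share
eigenvectors and their eigenvalues sum to one: ``Sa = V Λa Vᵀ``,
``Λa + Λb = I``.  The projection (weight) matrix is ``W = Pᵀ V`` with
columns ordered by descending Λa; the first columns maximize class-a
variance, the last maximize class-b variance.  Features are the
log-variances of the projected signal,

    f_j = log( var( w_jᵀ x(t) ) ),

taken for the first and last ``m_pairs`` columns of ``W``.

Variance here is the uncentered sample variance (mean square): band-passed
EEG is zero-mean, and using the same convention as the covariance step
keeps the fast Gram-matrix path of the criterion module bit-identical to
the naive one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochedEEG

__all__ = [
    "CSPModel",
    "CSPError",
    "normalized_covariance",
    "fit_csp",
    "transform",
]

#: floor for projected variances before the log (avoids -inf on degenerate data)
_VAR_FLOOR = np.finfo(float).tiny


class CSPError(ValueError):
    """Degenerate input to the CSP decomposition."""


@dataclass
class CSPModel:
    """Fitted CSP filters with all intermediate matrices kept for audit."""

    Ca: np.ndarray
    Cb: np.ndarray
    Cc: np.ndarray
    U: np.ndarray
    lam: np.ndarray
    P: np.ndarray
    Sa: np.ndarray
    Sb: np.ndarray
    V: np.ndarray
    LamA: np.ndarray
    LamB: np.ndarray
    W: np.ndarray
    m_pairs: int
    selected_cols: tuple[int, ...]

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    def save(self, path) -> None:
        np.savez(
            path,
            **{f: getattr(self, f) for f in (
                "Ca", "Cb", "Cc", "U", "lam", "P", "Sa", "Sb", "V",
                "LamA", "LamB", "W",
            )},
            m_pairs=self.m_pairs,
            selected_cols=np.asarray(self.selected_cols),
        )

    @classmethod
    def load(cls, path) -> "CSPModel":
        with np.load(path) as z:
            return cls(
                **{f: z[f] for f in (
                    "Ca", "Cb", "Cc", "U", "lam", "P", "Sa", "Sb", "V",
                    "LamA", "LamB", "W",
                )},
                m_pairs=int(z["m_pairs"]),
                selected_cols=tuple(int(c) for c in z["selected_cols"]),
            )


def normalized_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized covariance ``X Xᵀ / trace(X Xᵀ)`` of one trial."""
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise CSPError(f"trial must be >=2 channels x >=2 samples, got {X.shape}")
    R = X @ X.T
    tr = float(np.trace(R))
    if tr <= 0 or not np.isfinite(tr):
        raise CSPError("degenerate trial: zero or non-finite total power")
    return R / tr


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: first non-negligible entry positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        pivot = nz[0] if nz.size else 0
        if col[pivot] < 0:
            V[:, j] = -col
    return V


def _csp_from_covs(Ca: np.ndarray, Cb: np.ndarray, m_pairs: int) -> CSPModel:
    """Core decomposition shared by :func:`fit_csp` and the criterion module."""
    n = Ca.shape[0]
    Cc = Ca + Cb
    # small ridge keeps rank-deficient channel subsets decomposable
    ridge = 1e-10 * float(np.trace(Cc))
    Cc_r = Cc + ridge * np.eye(n)
    lam, U = np.linalg.eigh(Cc_r)
    lam = np.clip(lam, ridge if ridge > 0 else np.finfo(float).tiny, None)
    U = _fix_signs(U)
    P = (lam ** -0.5)[:, None] * U.T
    Sa = P @ Ca @ P.T
    Sb = P @ Cb @ P.T
    mu, V = np.linalg.eigh(Sa)
    order = np.argsort(mu)[::-1]  # descending Λa
    mu = mu[order]
    V = _fix_signs(V[:, order])
    W = P.T @ V
    m_eff = min(int(m_pairs), n // 2)
    selected = tuple(range(m_eff)) + tuple(range(n - m_eff, n))
    return CSPModel(
        Ca=Ca, Cb=Cb, Cc=Cc, U=U, lam=lam, P=P, Sa=Sa, Sb=Sb, V=V,
        LamA=np.diag(mu), LamB=np.eye(n) - np.diag(mu), W=W,
        m_pairs=m_eff, selected_cols=selected,
    )


def fit_csp(epochs: EpochedEEG, m_pairs: int = 2) -> CSPModel:
    """Fit CSP on two-class epochs.

    ``m_pairs`` is the requested number of filter pairs; the effective
    number shrinks to ``floor(channels / 2)`` on small channel subsets so
    the selection search can descend to two channels.
    """
    if epochs.n_channels < 2:
        raise CSPError("CSP needs at least 2 channels")
    classes = np.unique(epochs.labels)
    if classes.size != 2:
        raise CSPError(f"need exactly 2 classes, got {classes.tolist()}")
    if min(int(m_pairs), epochs.n_channels // 2) < 1:
        raise CSPError("m_pairs must allow at least one filter pair")
    covs = {c: [] for c in classes}
    for X, y in zip(epochs.data, epochs.labels):
        covs[y].append(normalized_covariance(X))
    Ca = np.mean(covs[classes[0]], axis=0)
    Cb = np.mean(covs[classes[1]], axis=0)
    return _csp_from_covs(Ca, Cb, m_pairs)


def transform(model: CSPModel, epochs: EpochedEEG) -> np.ndarray:
    """Log-variance CSP features, one row of ``2*m_pairs`` values per trial."""
    if epochs.n_channels != model.n_channels:
        raise CSPError(
            f"epochs have {epochs.n_channels} channels, model expects "
            f"{model.n_channels}"
        )
    Wsel = model.W[:, list(model.selected_cols)]
    Z = np.einsum("cf,tcs->tfs", Wsel, epochs.data)
    var = np.mean(Z**2, axis=2)  # uncentered variance per filter
    if np.any(var <= _VAR_FLOOR):
        warnings.warn(
            "zero-variance projected signal; clamping before log",
            RuntimeWarning,
            stacklevel=2,
        )
        var = np.maximum(var, _VAR_FLOOR)
    return np.log(var)
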