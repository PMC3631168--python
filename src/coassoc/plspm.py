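"""Two-block partial least squares path modeling (PLSPM).

Each gene is modeled as a latent variable reflected by its SNP dosages
(mode-A measurement); the two latents are linked by a single path whose
standardized coefficient equals the Pearson correlation of the latent
scores.  Estimation follows the classical alternating outer/inner scheme
with the centroid inner rule: the inner estimate of each latent is the
other latent's score times the sign ``e`` of their correlation, and mode-A
weights are updated as the correlations of the indicators with the inner
estimate.

For two blocks this iteration has a closed-form fixed point — the first
singular vectors of the cross-correlation matrix between the blocks — which
the test suite uses as an independent oracle.

The model is direction-free: fitting (X, Y) or (Y, X) yields the same path
coefficient, because the coefficient is a correlation of scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = ["PlspmConfig", "PlspmFit", "standardize_block", "fit_two_block", "path_symmetry_check"]


@dataclass(frozen=True)
class PlspmConfig:
    """Convergence settings for the alternating fit.

    tol
        Largest absolute weight change at which iteration stops.
    max_iter
        Iteration cap; the fit is returned with ``converged=False`` if hit.
    init
        ``"ones"`` starts each weight vector at (1,...,1)/sqrt(p);
        ``"dominant_eigvec"`` starts at the dominant eigenvector of the
        within-block correlation matrix (useful when the equal-weight start
        is orthogonal to the solution, which is a measure-zero degeneracy).
    """

    tol: float = 1e-6
    max_iter: int = 300
    init: str = "ones"

    def __post_init__(self) -> None:
        if not (0 < self.tol < 1):
            raise ValueError("tol must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("ones", "dominant_eigvec"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class PlspmFit:
    """Result of one two-block fit.

    ``weights_*`` are the unit-norm outer weight vectors (oriented so the
    largest-magnitude component is positive), ``loadings_*`` the correlations
    of each indicator with its own latent score, ``scores_*`` the latent
    scores (mean 0, unit variance), and ``path_coefficient`` their Pearson
    correlation.  ``inner_sign`` is the final centroid sign ``e``.
    """

    weights_a: np.ndarray
    weights_b: np.ndarray
    loadings_a: np.ndarray
    loadings_b: np.ndarray
    scores_a: np.ndarray
    scores_b: np.ndarray
    path_coefficient: float
    n_iterations: int
    converged: bool
    inner_sign: float


def standardize_block(raw: np.ndarray) -> np.ndarray:
    """Center each column and scale it to unit variance (divisor n-1).

    Raises if a column is (numerically) constant — such columns should have
    been removed by preprocessing — or if fewer than 3 rows are given.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D block")
    n = raw.shape[0]
    if n < 3:
        raise ValueError("standardization needs at least 3 samples")
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    bad = np.where(sd < 1e-12)[0]
    if bad.size:
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    return (raw - mu) / sd


def _initial_weights(R: np.ndarray, init: str) -> np.ndarray:
    p = R.shape[0]
    if init == "ones":
        return np.full(p, 1.0 / np.sqrt(p))
    vals, vecs = np.linalg.eigh(R)
    w = vecs[:, -1]
    i = int(np.argmax(np.abs(w)))
    return w if w[i] >= 0 else -w


def fit_two_block(X: np.ndarray, Y: np.ndarray, cfg: PlspmConfig | None = None) -> PlspmFit:
    """Fit the two-block path model on standardized blocks X (n x p), Y (n x q)."""
    cfg = cfg or PlspmConfig()
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = X.shape
    q = Y.shape[1]
    if n < 3 or p < 1 or q < 1:
        raise ValueError("need n >= 3 and at least one column per block")

    Z = np.hstack([X, Y])
    R, sd, mu, ok = _kernels.corr_from_raw(Z)
    if not ok:
        j = int(np.argmin(sd))
        raise ValueError(f"zero-variance column at joint index {j}")
    Rxx = np.ascontiguousarray(R[:p, :p])
    Ryy = np.ascontiguousarray(R[p:, p:])
    C = np.ascontiguousarray(R[:p, p:])

    init_a = _initial_weights(Rxx, cfg.init)
    init_b = _initial_weights(Ryy, cfg.init)
    wa, wb, beta, sa, sb, n_iter, converged, e = _kernels.plspm_weights(
        Rxx, Ryy, C, cfg.tol, cfg.max_iter, init_a, init_b
    )

    # scores on the standardized scale used by the weight formulas
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Ys = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    scores_a = Xs @ wa / sa
    scores_b = Ys @ wb / sb
    return PlspmFit(
        weights_a=wa,
        weights_b=wb,
        loadings_a=Rxx @ wa / sa,
        loadings_b=Ryy @ wb / sb,
        scores_a=scores_a,
        scores_b=scores_b,
        path_coefficient=float(beta),
        n_iterations=int(n_iter),
        converged=bool(converged),
        inner_sign=float(e),
    )


def path_symmetry_check(X: np.ndarray, Y: np.ndarray, cfg: PlspmConfig | None = None) -> bool:
    """True iff the path coefficient agrees (to 1e-8) in both fit directions."""
    f1 = fit_two_block(X, Y, cfg)
    f2 = fit_two_block(Y, X, cfg)
    return abs(f1.path_coefficient - f2.path_coefficient) < 1e-8
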