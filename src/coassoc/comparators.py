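"""Benchmark tests for gene-gene co-association.

Four established approaches against which the PLSPM statistic is compared:

* ``snp_logistic`` — every SNP pair across the two genes enters a logistic
  model with a product term; the smallest Wald p over pairs is adjusted for
  multiplicity by a min-p (max-T) label-permutation scheme.
* ``pca_logistic`` — the first principal component of each gene's pooled
  standardized dosage block enters a logistic model with a product term;
  the Wald p of the product term is the result.
* ``ccu`` — the case/control difference of the first canonical correlation
  between the two blocks, standardized by stratified-bootstrap variances and
  referred to a label-permutation null.
* ``covariance`` — the vectorized case/control difference ``d`` of the
  cross-gene covariance block in a quadratic form ``d' W^- d``, with ``W``
  the bootstrap sampling covariance of ``d`` and ``W^-`` its Moore-Penrose
  pseudo-inverse (the original statistic's ``W`` is frequently singular
  under strong LD; the pseudo-inverse keeps the test defined).  Permutation
  p is primary; the chi-square tail on the pseudo-rank is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _kernels
from .io_genotypes import GenotypeDataset
from .plspm import PlspmConfig
from .statistic import ResamplingPlan, derive_seed, _stratum_token

__all__ = [
    "LogisticFit",
    "ComparatorResult",
    "fit_logistic",
    "snp_logistic_minp",
    "pca_logistic_test",
    "ccu_test",
    "covariance_test",
]


@dataclass
class ComparatorResult:
    method: str
    statistic: float
    p_value: float
    detail: pd.DataFrame = field(default_factory=pd.DataFrame)
    converged: bool = True

    def to_frame(self, gene_a: str, gene_b: str) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_a": gene_a,
                    "gene_b": gene_b,
                    "method": self.method,
                    "statistic": self.statistic,
                    "p_value": self.p_value,
                }
            ]
        )


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (Newton/IRLS)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iterations: int
    message: str = ""


def fit_logistic(design: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8) -> LogisticFit:
    """Fit logit(P(y=1)) = design @ beta by Newton-Raphson.

    The design matrix is used as given (include an intercept column
    yourself).  A rank-deficient design raises, naming the collinear
    columns.  Separation or non-convergence is flagged via ``converged``
    rather than returning silently wrong numbers.
    """
    X = np.asarray(design, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than parameters")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("y must contain both classes")

    rank = np.linalg.matrix_rank(X)
    if rank < k:
        bad = []
        for j in range(k):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(j)
        raise ValueError(f"rank-deficient design; collinear column(s) {bad}")

    beta = np.zeros(k)
    converged = False
    message = "max iterations reached"
    H = np.eye(k)
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H + 1e-12 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving to keep the likelihood finite
        step = 1.0
        for _ in range(10):
            cand = beta + step * delta
            if np.abs(cand).max() < 1e3:
                break
            step /= 2
        beta = beta + step * delta
        if np.abs(step * delta).max() < tol:
            converged = True
            message = "converged"
            break
    if np.abs(beta).max() > 30:
        converged = False
        message = "coefficients diverging (possible complete separation)"

    with np.errstate(invalid="ignore"):
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        z = np.divide(beta, se, out=np.full(k, np.nan), where=se > 0)
        p = 2 * sps.norm.sf(np.abs(z))
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        z_values=z,
        p_values=p,
        converged=converged,
        n_iterations=it,
        message=message,
    )


def _gene_blocks(ds: GenotypeDataset, gene_a: str, gene_b: str):
    cols_a = ds.gene_block(gene_a).columns
    cols_b = ds.gene_block(gene_b).columns
    A = np.ascontiguousarray(ds.dosages[:, cols_a])
    B = np.ascontiguousarray(ds.dosages[:, cols_b])
    ids_a = [ds.snp_ids[i] for i in cols_a]
    ids_b = [ds.snp_ids[i] for i in cols_b]
    return A, B, ids_a, ids_b


def snp_logistic_minp(
    ds: GenotypeDataset, gene_a: str, gene_b: str, n_perm: int = 1000, seed: int = 0
) -> ComparatorResult:
    """Best single-SNP-pair interaction test with min-p permutation adjustment.

    For every pair (j in gene A, k in gene B) the Wald p of the product term
    in ``logit(y) ~ snp_j + snp_k + snp_j*snp_k`` is computed; the smallest p
    (equivalently the largest |z|) is the observed statistic, and its
    multiplicity-adjusted p-value is the add-one fraction of label
    permutations whose own max-|z| over all pairs reaches the observed one.
    Pairs whose fit fails (separation, collinearity) are skipped.
    """
    ds.require_both_classes()
    A, B, ids_a, ids_b = _gene_blocks(ds, gene_a, gene_b)
    y = np.ascontiguousarray(ds.phenotype.astype(np.float64))
    zabs = _kernels.minp_observed(A, B, y, 50, 1e-8)
    if np.isnan(zabs).all():
        raise RuntimeError("logistic fit failed for every SNP pair")
    obs_max = float(np.nanmax(zabs))
    jbest, kbest = np.unravel_index(int(np.nanargmax(zabs)), zabs.shape)
    p_unadj = 2 * sps.norm.sf(zabs)
    count = _kernels.minp_perm_count(
        A, B, y, obs_max, int(n_perm), derive_seed(seed, "minp"), 50, 1e-8
    )
    p_adj = (1 + int(count)) / (1 + n_perm)
    detail = pd.DataFrame(
        {
            "snp_a": np.repeat(ids_a, len(ids_b)),
            "snp_b": np.tile(ids_b, len(ids_a)),
            "abs_z": zabs.ravel(),
            "p_unadj": p_unadj.ravel(),
        }
    )
    detail["best"] = False
    detail.loc[jbest * len(ids_b) + kbest, "best"] = True
    return ComparatorResult(
        method="snp_logistic", statistic=obs_max, p_value=float(p_adj), detail=detail
    )


def pca_logistic_test(ds: GenotypeDataset, gene_a: str, gene_b: str) -> ComparatorResult:
    """Gene-level interaction test on first principal component scores.

    PC1 of each gene is taken from the pooled (cases + controls) standardized
    dosage block so both strata share one score definition; the PC sign is
    fixed by making the largest-|loading| entry positive.  The reported
    p-value is the Wald p of the PC1_A x PC1_B product term.
    """
    ds.require_both_classes()
    A, B, _, _ = _gene_blocks(ds, gene_a, gene_b)
    y = ds.phenotype.astype(np.float64)

    def pc1(block: np.ndarray) -> np.ndarray:
        Zs = (block - block.mean(axis=0)) / block.std(axis=0, ddof=1)
        _, _, vt = np.linalg.svd(Zs, full_matrices=False)
        v = vt[0]
        i = int(np.argmax(np.abs(v)))
        if v[i] < 0:
            v = -v
        return Zs @ v

    sa, sb = pc1(A), pc1(B)
    design = np.column_stack([np.ones_like(sa), sa, sb, sa * sb])
    fit = fit_logistic(design, y)
    detail = pd.DataFrame(
        {
            "term": ["intercept", "pc1_a", "pc1_b", "pc1_a:pc1_b"],
            "coef": fit.coefficients,
            "se": fit.standard_errors,
            "z": fit.z_values,
            "p": fit.p_values,
        }
    )
    return ComparatorResult(
        method="pca_logistic",
        statistic=float(fit.z_values[3]),
        p_value=float(fit.p_values[3]),
        detail=detail,
        converged=fit.converged,
    )


def ccu_test(
    ds: GenotypeDataset,
    gene_a: str,
    gene_b: str,
    plan: ResamplingPlan | None = None,
    cfg: PlspmConfig | None = None,
) -> ComparatorResult:
    """Case/control difference of the first canonical correlation.

    The statistic is (cc1_case - cc1_control) / sqrt of the summed stratified
    bootstrap variances, with significance from the same numerator-only label
    permutation scheme as the PLSPM statistic.  Canonical correlations are
    non-negative by construction, so a co-association that merely flips the
    sign of the between-gene correlation is invisible to this statistic.
    """
    plan = plan or ResamplingPlan()
    cfg = cfg or PlspmConfig()
    ds.require_both_classes()
    A, B, ids_a, ids_b = _gene_blocks(ds, gene_a, gene_b)
    p, q = A.shape[1], B.shape[1]
    case = ds.phenotype == 1
    Zc = np.ascontiguousarray(np.hstack([A, B])[case])
    Zk = np.ascontiguousarray(np.hstack([A, B])[~case])
    for name, Z in (("case", Zc), ("control", Zk)):
        if Z.shape[0] <= p + q:
            raise ValueError(f"{name} stratum must exceed p + q = {p + q} subjects")

    cc_case, _, ok1 = _kernels.stratum_stat(Zc, p, _kernels.STAT_CC1, cfg.tol, cfg.max_iter)
    cc_ctrl, _, ok2 = _kernels.stratum_stat(Zk, p, _kernels.STAT_CC1, cfg.tol, cfg.max_iter)
    if not (ok1 and ok2):
        raise ValueError("constant SNP column in a stratum; run preprocess first")

    case_rows = np.where(case)[0]
    ctrl_rows = np.where(~case)[0]
    max_fail = max(1, int(np.ceil(0.1 * plan.n_boot)))
    bc, _, _, okb1 = _kernels.bootstrap_stats(
        Zc, p, _kernels.STAT_CC1, plan.n_boot,
        derive_seed(plan.seed, "boot", _stratum_token(case_rows)),
        cfg.tol, cfg.max_iter, max_fail,
    )
    bk, _, _, okb2 = _kernels.bootstrap_stats(
        Zk, p, _kernels.STAT_CC1, plan.n_boot,
        derive_seed(plan.seed, "boot", _stratum_token(ctrl_rows)),
        cfg.tol, cfg.max_iter, max_fail,
    )
    if not (okb1 and okb2):
        raise RuntimeError("more than 10% of bootstrap replicates failed")
    var_case = float(np.var(bc, ddof=1))
    var_ctrl = float(np.var(bk, ddof=1))
    diff = float(cc_case - cc_ctrl)
    denom = float(np.sqrt(var_case + var_ctrl))
    stat = diff / denom if denom > 0 else (0.0 if diff == 0 else np.sign(diff) * np.inf)

    Zall = np.ascontiguousarray(ds.dosages[:, ds.gene_block(gene_a).columns + ds.gene_block(gene_b).columns])
    n_case = int(case.sum())
    diffs, _ = _kernels.perm_stat_diffs(
        Zall, p, n_case, _kernels.STAT_CC1, plan.n_perm,
        derive_seed(plan.seed, "perm", Zall.shape[0], n_case),
        cfg.tol, cfg.max_iter,
    )
    valid = diffs[~np.isnan(diffs)]
    p_perm = (1 + int(np.sum(np.abs(valid) >= abs(diff)))) / (1 + valid.size)
    detail = pd.DataFrame(
        [
            {
                "cc1_case": cc_case,
                "cc1_control": cc_ctrl,
                "var_case": var_case,
                "var_control": var_ctrl,
                "n_perm": valid.size,
                "n_boot": plan.n_boot,
            }
        ]
    )
    return ComparatorResult(method="ccu", statistic=float(stat), p_value=float(p_perm), detail=detail)


def covariance_test(
    ds: GenotypeDataset,
    gene_a: str,
    gene_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    n_boot: int = 200,
    scope: str = "cross_block",
    w_method: str = "perm_batch",
) -> ComparatorResult:
    """Covariance-difference quadratic-form test with pseudo-inverse fallback.

    ``d`` is the vectorized case-minus-control difference of the cross-gene
    covariance block (``scope='cross_block'``, the default: within-gene LD is
    a nuisance for a gene-pair test) or of the full joint covariance matrix
    (``scope='full_joint'``).  The statistic is ``d' pinv(W) d`` with ``W``
    an estimate of the sampling covariance of ``d`` and singular values below
    ``1e-10 * sigma_max`` dropped, so strong collinearity between SNPs never
    makes the test undefined.

    ``w_method`` controls how ``W`` (size ``n_boot`` ensemble) is estimated:
    ``"perm_batch"`` (default) uses an independent batch of label
    permutations, which makes ``W`` a label-invariant function of the pooled
    data and hence the permutation test exact under exchangeability;
    ``"bootstrap"`` uses the stratified bootstrap around the observed strata
    (closer to the original statistic's construction, but mildly
    anticonservative in high dimension because ``W`` then depends on the
    observed labels).

    The permutation p-value (labels permuted, ``W`` held fixed) is primary;
    the chi-square tail on the pseudo-rank is reported in the detail table.
    """
    ds.require_both_classes()
    A, B, _, _ = _gene_blocks(ds, gene_a, gene_b)
    p, q = A.shape[1], B.shape[1]
    case = ds.phenotype == 1
    Z = np.hstack([A, B])
    Zc = np.ascontiguousarray(Z[case])
    Zk = np.ascontiguousarray(Z[~case])
    for name, Zs in (("case", Zc), ("control", Zk)):
        if Zs.shape[0] <= p + q:
            raise ValueError(f"{name} stratum must exceed p + q = {p + q} subjects")

    if scope not in ("cross_block", "full_joint"):
        raise ValueError(f"unknown scope {scope!r}")
    if w_method not in ("perm_batch", "bootstrap"):
        raise ValueError(f"unknown w_method {w_method!r}")
    n_case = int(case.sum())
    Zall = np.ascontiguousarray(Z)

    if scope == "cross_block":
        def dvec(Zcase: np.ndarray, Zctrl: np.ndarray) -> np.ndarray:
            return (_kernels.cross_cov(Zcase, p) - _kernels.cross_cov(Zctrl, p)).ravel()

        def perm_ensemble(n_draws: int, stream: str) -> np.ndarray:
            return _kernels.perm_cov_d(
                Zall, p, n_case, int(n_draws), derive_seed(seed, stream, Z.shape[0], n_case)
            )
    else:
        iu = np.triu_indices(p + q)

        def dvec(Zcase: np.ndarray, Zctrl: np.ndarray) -> np.ndarray:
            return (np.cov(Zcase, rowvar=False) - np.cov(Zctrl, rowvar=False))[iu]

        def perm_ensemble(n_draws: int, stream: str) -> np.ndarray:
            rng = np.random.default_rng(derive_seed(seed, stream, Z.shape[0], n_case))
            out = np.empty((n_draws, len(iu[0])))
            for t in range(n_draws):
                idx = rng.permutation(Z.shape[0])
                out[t] = dvec(Z[idx[:n_case]], Z[idx[n_case:]])
            return out

    d = dvec(Zc, Zk)
    if w_method == "perm_batch":
        D = perm_ensemble(n_boot, "w_batch")
    elif scope == "cross_block":
        D = _kernels.bootstrap_cov_d(Zc, Zk, p, int(n_boot), derive_seed(seed, "boot_w"))
    else:
        rng = np.random.default_rng(derive_seed(seed, "boot_w"))
        D = np.empty((n_boot, d.size))
        for b in range(n_boot):
            ic = rng.integers(0, Zc.shape[0], Zc.shape[0])
            ik = rng.integers(0, Zk.shape[0], Zk.shape[0])
            D[b] = dvec(Zc[ic], Zk[ik])

    W = np.atleast_2d(np.cov(D, rowvar=False))
    Winv = np.linalg.pinv(W, rcond=1e-10, hermitian=True)
    rank = int(np.linalg.matrix_rank(W, tol=1e-10 * np.linalg.norm(W, 2)))
    stat = float(d @ Winv @ d)

    Dperm = perm_ensemble(n_perm, "perm")
    stats_perm = np.einsum("ti,ij,tj->t", Dperm, Winv, Dperm)
    p_perm = (1 + int(np.sum(stats_perm >= stat))) / (1 + n_perm)
    p_chi2 = float(sps.chi2.sf(stat, df=max(rank, 1)))
    detail = pd.DataFrame(
        [
            {
                "pseudo_rank": rank,
                "p_chi2": p_chi2,
                "n_boot": n_boot,
                "n_perm": n_perm,
                "scope": scope,
                "w_method": w_method,
            }
        ]
    )
    return ComparatorResult(
        method="covariance", statistic=stat, p_value=float(p_perm), detail=detail
    )
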