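"""The PLSPM-based gene-gene co-association statistic U.

The co-association of two genes with a binary disease is measured as the
difference between the case-group and control-group path coefficients of the
two-block PLS path model,

    U = (beta_case - beta_control) / sqrt(Var(beta_case) + Var(beta_control)),

with the two variances estimated by resampling subjects with replacement
within each stratum (stratified bootstrap).  Because the path coefficients
have no known asymptotic distribution, the p-value comes from a random
case/control label-permutation test: labels are reshuffled, the statistic is
recomputed, and the add-one estimator

    p = (1 + #{ |U*| >= |U| }) / (1 + n_perm)

is reported.  By default only the numerator is recomputed under permutation
(the bootstrap denominator is held at its observed value), which makes the
permuted statistic a fixed monotone transform of |beta_case* - beta_control*|
and keeps the test exact under exchangeability at a fraction of the cost;
full denominator recomputation is available for sensitivity analysis.

Randomness is split into independent streams (case bootstrap, control
bootstrap, permutations) derived from one master seed.  The bootstrap stream
of a stratum is keyed to the stratum's row set rather than to its label, so
relabeling cases as controls exactly negates U.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _kernels
from .io_genotypes import GenotypeDataset
from .plspm import PlspmConfig

__all__ = [
    "ResamplingPlan",
    "CoassocResult",
    "bootstrap_path_variance",
    "coassociation_test",
    "null_calibration",
]


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic child seed (< 2^31) for a named randomness stream."""
    h = zlib.crc32(repr(tokens).encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), int(h)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _stratum_token(rows: np.ndarray) -> int:
    """Content key for a stratum: CRC of its row indices in dataset order."""
    return int(zlib.crc32(np.asarray(rows, dtype=np.int64).tobytes()))


@dataclass(frozen=True)
class ResamplingPlan:
    """Bootstrap/permutation budgets and the master seed."""

    n_perm: int = 1000
    n_boot: int = 1000
    seed: int = 0
    perm_mode: str = "numerator_only"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.perm_mode not in ("numerator_only", "full_recompute"):
            raise ValueError(f"unknown perm_mode {self.perm_mode!r}")


@dataclass
class CoassocResult:
    """Case/control path coefficients, bootstrap variances, U, permutation p."""

    gene_a: str
    gene_b: str
    beta_case: float
    beta_control: float
    var_case: float
    var_control: float
    U: float
    p_perm: float
    n_perm: int
    n_boot: int
    seed: int
    perm_mode: str = "numerator_only"
    loadings: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_boot_redraws: int = 0
    n_perm_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        """One-row results table in the standard TSV schema."""
        return pd.DataFrame(
            [
                {
                    "gene_a": self.gene_a,
                    "gene_b": self.gene_b,
                    "beta_case": self.beta_case,
                    "beta_control": self.beta_control,
                    "var_case": self.var_case,
                    "var_control": self.var_control,
                    "U": self.U,
                    "p_perm": self.p_perm,
                    "n_perm": self.n_perm,
                    "n_boot": self.n_boot,
                    "seed": self.seed,
                }
            ]
        )


def bootstrap_path_variance(
    block_a: np.ndarray,
    block_b: np.ndarray,
    n_boot: int,
    seed: int,
    cfg: PlspmConfig | None = None,
    snp_ids: Sequence[str] | None = None,
    min_rows: int = 10,
) -> tuple[float, pd.DataFrame, int]:
    """Bootstrap variance of one stratum's path coefficient.

    Rows are resampled with replacement jointly across both blocks (so the
    SNP-SNP correlation structure travels with each subject), each replicate
    is re-standardized and refit, and the empirical variance of the replicate
    path coefficients (divisor ``n_boot - 1``) is returned together with a
    per-SNP table of loading means and bootstrap standard errors.

    Replicates whose resample leaves a column constant are redrawn; more than
    10% failed replicates raises (the stratum is too small or a SNP too rare
    for the bootstrap to be meaningful).
    """
    cfg = cfg or PlspmConfig()
    A = np.ascontiguousarray(np.asarray(block_a, dtype=np.float64))
    B = np.ascontiguousarray(np.asarray(block_b, dtype=np.float64))
    if A.shape[0] != B.shape[0]:
        raise ValueError("blocks must share rows")
    if A.shape[0] < max(min_rows, 3):
        raise ValueError(f"bootstrap needs at least {max(min_rows, 3)} subjects per stratum")
    Z = np.hstack([A, B])
    p = A.shape[1]
    max_fail = max(1, int(np.ceil(0.1 * n_boot)))
    if A.shape[0] < 10:
        # tiny-stratum mode (exact-enumeration toys): constant-column
        # resamples are common and harmless, so allow generous redraws
        max_fail = 50 * n_boot
    betas, loadings, fails, ok = _kernels.bootstrap_stats(
        Z, p, _kernels.STAT_PLSPM, int(n_boot), int(seed), cfg.tol, cfg.max_iter, max_fail
    )
    if not ok:
        raise RuntimeError(
            f"more than 10% of bootstrap replicates failed ({fails}); "
            "increase the stratum size or filter near-monomorphic SNPs"
        )
    var = float(np.var(betas, ddof=1))
    ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(Z.shape[1])]
    table = pd.DataFrame(
        {
            "snp": ids,
            "loading": loadings.mean(axis=0),
            "loading_se": loadings.std(axis=0, ddof=1),
        }
    )
    return var, table, int(fails)


def _observed_stat(Z: np.ndarray, p: int, cfg: PlspmConfig) -> float:
    stat, _, ok = _kernels.stratum_stat(
        np.ascontiguousarray(Z), p, _kernels.STAT_PLSPM, cfg.tol, cfg.max_iter
    )
    if not ok:
        raise ValueError("stratum contains a constant SNP column; run preprocess first")
    return float(stat)


def coassociation_test(
    ds: GenotypeDataset,
    gene_a: str,
    gene_b: str,
    plan: ResamplingPlan | None = None,
    cfg: PlspmConfig | None = None,
    min_stratum: int = 10,
) -> CoassocResult:
    """Test whether genes A and B are co-associated with the phenotype.

    Null hypothesis: the case and control path coefficients are equal.  See
    the module docstring for the statistic and the permutation scheme.
    """
    plan = plan or ResamplingPlan()
    cfg = cfg or PlspmConfig()
    for g in (gene_a, gene_b):
        if g not in ds.genes:
            raise ValueError(f"gene {g!r} not present in dataset (has {ds.genes})")
    ds.require_both_classes()

    cols_a = ds.gene_block(gene_a).columns
    cols_b = ds.gene_block(gene_b).columns
    p = len(cols_a)
    case_rows = np.where(ds.phenotype == 1)[0]
    ctrl_rows = np.where(ds.phenotype == 0)[0]
    if len(case_rows) < min_stratum or len(ctrl_rows) < min_stratum:
        raise ValueError(
            f"need at least {min_stratum} subjects per stratum "
            f"(got {len(case_rows)} cases, {len(ctrl_rows)} controls)"
        )

    cols = cols_a + cols_b
    Zc = np.ascontiguousarray(ds.dosages[np.ix_(case_rows, cols)])
    Zk = np.ascontiguousarray(ds.dosages[np.ix_(ctrl_rows, cols)])
    snp_ids = [ds.snp_ids[i] for i in cols]
    genes = [gene_a] * p + [gene_b] * len(cols_b)

    beta_case = _observed_stat(Zc, p, cfg)
    beta_control = _observed_stat(Zk, p, cfg)

    seed_case = derive_seed(plan.seed, "boot", _stratum_token(case_rows))
    seed_ctrl = derive_seed(plan.seed, "boot", _stratum_token(ctrl_rows))
    var_case, tab_case, redraw_c = bootstrap_path_variance(
        Zc[:, :p], Zc[:, p:], plan.n_boot, seed_case, cfg, snp_ids, min_rows=min_stratum
    )
    var_control, tab_ctrl, redraw_k = bootstrap_path_variance(
        Zk[:, :p], Zk[:, p:], plan.n_boot, seed_ctrl, cfg, snp_ids, min_rows=min_stratum
    )
    tab_case.insert(0, "gene", genes)
    tab_case.insert(0, "stratum", "case")
    tab_ctrl.insert(0, "gene", genes)
    tab_ctrl.insert(0, "stratum", "control")
    loadings = pd.concat([tab_case, tab_ctrl], ignore_index=True)

    diff = beta_case - beta_control
    denom = float(np.sqrt(var_case + var_control))
    if denom > 0:
        U = diff / denom
    else:
        U = 0.0 if diff == 0 else float(np.sign(diff)) * np.inf

    # pooled rows kept in dataset order (not case-first) so that relabeling
    # cases as controls leaves the permutation stream and its values intact
    Zall = np.ascontiguousarray(ds.dosages[:, cols])
    n_case = len(case_rows)
    seed_perm = derive_seed(plan.seed, "perm", Zall.shape[0], n_case)
    if plan.perm_mode == "numerator_only":
        diffs, _ = _kernels.perm_stat_diffs(
            Zall, p, n_case, _kernels.STAT_PLSPM, plan.n_perm, seed_perm, cfg.tol, cfg.max_iter
        )
        valid = diffs[~np.isnan(diffs)]
        exceed = int(np.sum(np.abs(valid) >= abs(diff)))
    else:
        n_boot_inner = min(plan.n_boot, 100)
        Ustars = _kernels.perm_full_U(
            Zall, p, n_case, _kernels.STAT_PLSPM, plan.n_perm, n_boot_inner,
            seed_perm, cfg.tol, cfg.max_iter,
        )
        valid = Ustars[~np.isnan(Ustars)]
        exceed = int(np.sum(np.abs(valid) >= abs(U)))
    n_valid = int(valid.size)
    p_perm = (1 + exceed) / (1 + n_valid)

    return CoassocResult(
        gene_a=gene_a,
        gene_b=gene_b,
        beta_case=beta_case,
        beta_control=beta_control,
        var_case=var_case,
        var_control=var_control,
        U=float(U),
        p_perm=float(p_perm),
        n_perm=n_valid,
        n_boot=plan.n_boot,
        seed=plan.seed,
        perm_mode=plan.perm_mode,
        loadings=loadings,
        n_boot_redraws=redraw_c + redraw_k,
        n_perm_dropped=plan.n_perm - n_valid,
    )


def null_calibration(
    dataset_factory: Callable[[int], GenotypeDataset],
    gene_a: str,
    gene_b: str,
    n_datasets: int,
    alpha_levels: Sequence[float],
    plan: ResamplingPlan | None = None,
    cfg: PlspmConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical type-I-error table for the permutation test.

    ``dataset_factory(seed)`` must yield an independent null dataset per call
    (phenotype exchangeable with respect to the genotypes).  For each nominal
    level the fraction of datasets with ``p_perm <= alpha`` is reported with
    an exact (Clopper-Pearson) binomial 95% interval.
    """
    plan = plan or ResamplingPlan()
    pvals = np.empty(n_datasets)
    for i in range(n_datasets):
        ds_seed = derive_seed(seed, "dataset", i)
        ds = dataset_factory(ds_seed)
        res = coassociation_test(
            ds, gene_a, gene_b,
            ResamplingPlan(plan.n_perm, plan.n_boot, derive_seed(seed, "test", i), plan.perm_mode),
            cfg,
        )
        pvals[i] = res.p_perm
    rows = []
    for alpha in alpha_levels:
        k = int(np.sum(pvals <= alpha))
        ci = sps.binomtest(k, n_datasets).proportion_ci(0.95)
        rows.append(
            {
                "alpha": alpha,
                "rejection_rate": k / n_datasets,
                "ci_low": ci.low,
                "ci_high": ci.high,
                "n_datasets": n_datasets,
            }
        )
    return pd.DataFrame(rows)
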