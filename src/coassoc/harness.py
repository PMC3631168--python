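"""Experiment runner: gene-pair testing, null calibration, power curves.

Replicate datasets are embarrassingly parallel; every dataset's seed is
derived from the master seed and the dataset index alone, so results are
byte-identical regardless of worker count or scheduling.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .comparators import ccu_test, covariance_test, pca_logistic_test, snp_logistic_minp
from .io_genotypes import GenotypeDataset
from .plspm import PlspmConfig
from .simulate import (
    DiseaseModel,
    Population,
    ScenarioPreset,
    build_population,
    paper_scenarios,
    remove_causal,
    sample_from_population,
)
from .statistic import CoassocResult, ResamplingPlan, coassociation_test, derive_seed

__all__ = [
    "METHODS",
    "ExperimentConfig",
    "run_method",
    "run_pair_tests",
    "run_calibration",
    "run_power",
    "write_table",
]

METHODS = ("plspm", "ccu", "pca_logistic", "snp_logistic", "covariance")


@dataclass
class ExperimentConfig:
    """Axes of a calibration or power experiment."""

    preset: str
    methods: tuple = ("plspm",)
    n_grid: tuple = (1000,)
    or_grid: tuple = ()
    n_datasets: int = 500
    alphas: tuple = (0.01, 0.05, 0.1)
    n_perm: int = 500
    n_boot: int = 200
    seed: int = 0
    n_workers: int = 1
    pool_cases: int = 20_000
    pool_controls: int = 20_000
    panel_haplotypes: int = 20_000
    remove_causal_snps: bool = True
    perm_mode: str = "numerator_only"

    def __post_init__(self) -> None:
        if not self.n_grid:
            raise ValueError("n_grid must be non-empty")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown method(s) {unknown}; valid: {list(METHODS)}")
        if any(not (0 < a < 1) for a in self.alphas if a != 1.0):
            raise ValueError("alphas must lie in (0, 1)")
        if self.preset not in paper_scenarios():
            raise ValueError(
                f"unknown preset {self.preset!r}; valid: {sorted(paper_scenarios())}"
            )

    def config_hash(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return f"{zlib.crc32(payload):08x}"


def run_method(
    method: str,
    ds: GenotypeDataset,
    gene_a: str,
    gene_b: str,
    plan: ResamplingPlan,
    cfg: PlspmConfig | None = None,
) -> dict:
    """Run one test and return a uniform result row (statistic + p-value)."""
    row = {
        "gene_a": gene_a, "gene_b": gene_b, "method": method,
        "statistic": np.nan, "p_value": np.nan,
        "beta_case": np.nan, "beta_control": np.nan,
        "var_case": np.nan, "var_control": np.nan,
        "n_perm": plan.n_perm, "n_boot": plan.n_boot, "seed": plan.seed,
    }
    if method == "plspm":
        res: CoassocResult = coassociation_test(ds, gene_a, gene_b, plan, cfg)
        row.update(
            statistic=res.U, p_value=res.p_perm,
            beta_case=res.beta_case, beta_control=res.beta_control,
            var_case=res.var_case, var_control=res.var_control,
        )
        row["_result"] = res
    elif method == "ccu":
        r = ccu_test(ds, gene_a, gene_b, plan, cfg)
        row.update(statistic=r.statistic, p_value=r.p_value)
        row["_result"] = r
    elif method == "pca_logistic":
        r = pca_logistic_test(ds, gene_a, gene_b)
        row.update(statistic=r.statistic, p_value=r.p_value)
        row["_result"] = r
    elif method == "snp_logistic":
        r = snp_logistic_minp(ds, gene_a, gene_b, n_perm=plan.n_perm, seed=plan.seed)
        row.update(statistic=r.statistic, p_value=r.p_value)
        row["_result"] = r
    elif method == "covariance":
        r = covariance_test(ds, gene_a, gene_b, n_perm=plan.n_perm, seed=plan.seed, n_boot=plan.n_boot)
        row.update(statistic=r.statistic, p_value=r.p_value)
        row["_result"] = r
    else:
        raise ValueError(f"unknown method {method!r}; valid: {list(METHODS)}")
    return row


def run_pair_tests(
    ds: GenotypeDataset,
    genes: Sequence[str],
    methods: Sequence[str],
    plan: ResamplingPlan,
    cfg: PlspmConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All unordered gene pairs x requested methods.

    Returns the main results table and a best-SNP-pair table (populated by
    the snp_logistic method, mirroring how single-SNP scans are reported).
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    rows, best_rows = [], []
    for gene_a, gene_b in combinations(genes, 2):
        for method in methods:
            row = run_method(method, ds, gene_a, gene_b, plan, cfg)
            res = row.pop("_result", None)
            rows.append(row)
            if method == "snp_logistic" and res is not None:
                best = res.detail[res.detail["best"]].iloc[0]
                best_rows.append(
                    {
                        "gene_a": gene_a, "gene_b": gene_b,
                        "snp_a": best["snp_a"], "snp_b": best["snp_b"],
                        "p_unadj": best["p_unadj"], "p_adj": row["p_value"],
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(best_rows)


# ---------------------------------------------------------------------------
# calibration / power machinery
# ---------------------------------------------------------------------------


def _replicate_pvalues(
    pop: Population,
    preset: ScenarioPreset,
    cfg_exp: ExperimentConfig,
    n: int,
    methods: Sequence[str],
    tag: str,
) -> pd.DataFrame:
    """p-values for ``n_datasets`` replicate draws of total size n."""

    def one(i: int) -> dict:
        ds_seed = derive_seed(cfg_exp.seed, tag, n, "dataset", i)
        sd = sample_from_population(pop, n, ds_seed)
        if cfg_exp.remove_causal_snps:
            sd = remove_causal(sd)
        out = {"dataset": i}
        for m in methods:
            plan = ResamplingPlan(
                n_perm=cfg_exp.n_perm,
                n_boot=cfg_exp.n_boot,
                seed=derive_seed(cfg_exp.seed, tag, n, "test", m, i),
                perm_mode=cfg_exp.perm_mode,
            )
            row = run_method(m, sd.dataset, preset.gene_a, preset.gene_b, plan)
            out[m] = row["p_value"]
        return out

    if cfg_exp.n_workers > 1:
        rows = Parallel(n_jobs=cfg_exp.n_workers)(
            delayed(one)(i) for i in range(cfg_exp.n_datasets)
        )
    else:
        rows = [one(i) for i in range(cfg_exp.n_datasets)]
    return pd.DataFrame(rows)


def _rate_rows(pvals: np.ndarray, alphas: Sequence[float]) -> list[dict]:
    from scipy.stats import binomtest

    out = []
    n = pvals.size
    for alpha in alphas:
        k = int(np.sum(pvals <= alpha))
        if n == 1:
            lo, hi = 0.0, 1.0
        else:
            ci = binomtest(k, n).proportion_ci(0.95)
            lo, hi = ci.low, ci.high
        out.append(
            {"alpha": alpha, "rejection_rate": k / n, "ci_low": lo, "ci_high": hi, "n_datasets": n}
        )
    return out


def run_calibration(cfg_exp: ExperimentConfig) -> pd.DataFrame:
    """Type-I-error table under the null preset (all odds ratios 1).

    One pool per preset is generated and each replicate dataset is an
    independent balanced subsample, analyzed with the causal SNPs removed.
    """
    preset = paper_scenarios()[cfg_exp.preset]
    model = preset.make_model()  # all ORs at their null defaults
    if not model.is_null:
        raise ValueError("calibration requires a null model (all ORs = 1)")
    panel = preset.make_panel(cfg_exp.panel_haplotypes, derive_seed(cfg_exp.seed, "panel"))
    pop = build_population(
        panel, model, cfg_exp.pool_cases, cfg_exp.pool_controls, derive_seed(cfg_exp.seed, "pool")
    )
    rows = []
    for n in cfg_exp.n_grid:
        pvals = _replicate_pvalues(pop, preset, cfg_exp, n, cfg_exp.methods, "calib")
        for m in cfg_exp.methods:
            for r in _rate_rows(pvals[m].to_numpy(), cfg_exp.alphas):
                rows.append({"scenario": cfg_exp.preset, "N": n, "method": m, **r})
    return pd.DataFrame(rows)


def _model_from_ors(preset: ScenarioPreset, ors: Sequence[float]) -> DiseaseModel:
    """Build the alternative model for one OR-grid entry.

    Entry layout by scenario: type1 ``(or_interaction,)``; type2
    ``(or_marginal_a, or_marginal_b)``; type3
    ``(or_interaction, or_marginal_a, or_marginal_b)``.
    """
    ors = tuple(float(v) for v in ors)
    if preset.scenario == "type1":
        if len(ors) != 1:
            raise ValueError("type1 OR entry must be a single interaction OR")
        return preset.make_model(or_interaction=ors[0])
    if preset.scenario == "type2":
        if len(ors) != 2:
            raise ValueError("type2 OR entry must be a marginal OR pair")
        return preset.make_model(or_marginal_a=ors[0], or_marginal_b=ors[1])
    if len(ors) != 3:
        raise ValueError("type3 OR entry must be (interaction, marginal_a, marginal_b)")
    return preset.make_model(or_interaction=ors[0], or_marginal_a=ors[1], or_marginal_b=ors[2])


def run_power(cfg_exp: ExperimentConfig, alpha: float = 0.05) -> pd.DataFrame:
    """Rejection rate per method x sample size x OR setting.

    For each OR-grid entry a fresh pool is generated under the alternative
    model; replicate datasets are balanced subsamples with the causal SNPs
    removed before testing.
    """
    if not cfg_exp.or_grid:
        raise ValueError("or_grid must be non-empty for a power run")
    preset = paper_scenarios()[cfg_exp.preset]
    panel = preset.make_panel(cfg_exp.panel_haplotypes, derive_seed(cfg_exp.seed, "panel"))
    rows = []
    for ors in cfg_exp.or_grid:
        ors = (ors,) if np.isscalar(ors) else tuple(ors)
        model = _model_from_ors(preset, ors)
        pop = build_population(
            panel, model, cfg_exp.pool_cases, cfg_exp.pool_controls,
            derive_seed(cfg_exp.seed, "pool", ors),
        )
        for n in cfg_exp.n_grid:
            pvals = _replicate_pvalues(pop, preset, cfg_exp, n, cfg_exp.methods, ("power",) + ors)
            for m in cfg_exp.methods:
                r = _rate_rows(pvals[m].to_numpy(), [alpha])[0]
                rows.append(
                    {
                        "scenario": cfg_exp.preset,
                        "N": n,
                        "ors": ":".join(f"{v:g}" for v in ors),
                        "method": m,
                        "alpha": alpha,
                        "power": r["rejection_rate"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "n_datasets": r["n_datasets"],
                    }
                )
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """TSV with a leading provenance comment block (version, config, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# coassoc {__version__}\n")
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
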