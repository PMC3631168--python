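"""Case-control genotype simulation with controllable LD structure.

The generator emulates the classical HapMap-panel + disease-model pipeline:
a phased haplotype panel fixes the allele frequencies and the within/cross
gene linkage disequilibrium; individuals are formed by drawing two panel
haplotypes with replacement and summing alleles (additive coding); disease
status follows a logistic model on one causal SNP per gene.  Three
co-association scenarios are supported:

* ``type1`` — the two genes are independent (no cross-gene LD) and the
  disease model carries a SNP x SNP interaction term,
* ``type2`` — the two genes are linked (cross-gene LD) and the disease model
  carries marginal effects only,
* ``type3`` — a 1:1 individual-level mixture of the two mechanisms on the
  same linked panel.

The synthetic panel uses a latent-Gaussian threshold model: a haplotype's
alleles are indicators of correlated standard normals falling below the
per-SNP quantile of its minor-allele frequency.  The *empirical* allelic
correlation of the panel — attenuated relative to the latent correlation —
is the quantity the downstream statistics see, and is what the panel
reports.

Analyses in the accompanying study design remove the causal SNPs before
testing, so that association is detected indirectly through LD; see
:func:`remove_causal`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special
from scipy.stats import norm

from .io_genotypes import GenotypeDataset, HaplotypePanel, ValidationError

__all__ = [
    "DiseaseModel",
    "SimulatedDataset",
    "Population",
    "ScenarioPreset",
    "make_synthetic_panel",
    "sample_population",
    "build_population",
    "sample_from_population",
    "remove_causal",
    "paper_scenarios",
]


@dataclass(frozen=True)
class DiseaseModel:
    """Scenario type, causal SNPs, and logistic effect sizes (as odds ratios).

    ``or_interaction`` is the interaction OR of the two causal dosages
    (type1/type3); ``or_marginal_*`` are the marginal ORs (type2/type3);
    ``or_main_*`` are optional main-effect ORs in the interaction model
    (default 1.0).  ``prevalence`` fixes the logistic intercept via a root
    find on the population disease frequency.
    """

    scenario: str
    causal_a: str
    causal_b: str
    or_interaction: float = 1.0
    or_marginal_a: float = 1.0
    or_marginal_b: float = 1.0
    or_main_a: float = 1.0
    or_main_b: float = 1.0
    prevalence: float = 0.1

    def __post_init__(self) -> None:
        if self.scenario not in ("type1", "type2", "type3"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("or_interaction", "or_marginal_a", "or_marginal_b"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")

    @property
    def is_null(self) -> bool:
        return all(
            getattr(self, f) == 1.0
            for f in ("or_interaction", "or_marginal_a", "or_marginal_b", "or_main_a", "or_main_b")
        )

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "causal_a": self.causal_a,
            "causal_b": self.causal_b,
            "or_interaction": self.or_interaction,
            "or_marginal_a": self.or_marginal_a,
            "or_marginal_b": self.or_marginal_b,
            "or_main_a": self.or_main_a,
            "or_main_b": self.or_main_b,
            "prevalence": self.prevalence,
        }


@dataclass
class SimulatedDataset:
    """A :class:`GenotypeDataset` plus generation provenance."""

    dataset: GenotypeDataset
    model: DiseaseModel
    causal_a: str
    causal_b: str
    provenance: dict = field(default_factory=dict)

    @property
    def causal_removed(self) -> bool:
        present = set(self.dataset.snp_ids)
        return self.causal_a not in present and self.causal_b not in present


@dataclass
class Population:
    """A pre-generated pool of case and control genotypes.

    Mirrors the study design of generating a large hypothetical population
    once and drawing each replicate dataset from it; sharing the pool across
    replicates makes large calibration runs affordable.
    """

    cases: np.ndarray
    controls: np.ndarray
    snp_ids: list[str]
    gene_of_snp: dict[str, str]
    model: DiseaseModel
    panel_hash: int
    seed: int
    beta0: float


# ---------------------------------------------------------------------------
# synthetic panel
# ---------------------------------------------------------------------------


def _ar1(m: int, rho: float) -> np.ndarray:
    i = np.arange(m)
    return rho ** np.abs(i[:, None] - i[None, :])


def make_synthetic_panel(
    mafs: Sequence[float],
    ld_target: np.ndarray | tuple[str, float] | float,
    n_haplotypes: int,
    seed: int,
    snp_ids: Sequence[str] | None = None,
    gene_of_snp: Mapping[str, str] | None = None,
) -> HaplotypePanel:
    """Latent-Gaussian threshold panel with target MAFs and LD.

    ``ld_target`` is either a full latent correlation matrix, a scalar rho,
    or ``("ar1", rho)`` for a first-order autoregressive latent structure.
    Allele j of a haplotype is 1 iff its latent normal falls below the
    maf_j-quantile, so the 1-allele is the minor allele by construction.
    The empirical (attenuated) allelic correlation, not the latent rho, is
    the panel's contract.
    """
    mafs = np.asarray(mafs, dtype=np.float64)
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("mafs must lie in (0, 0.5]")
    m = mafs.size
    if isinstance(ld_target, tuple):
        kind, rho = ld_target
        if kind != "ar1":
            raise ValueError(f"unknown ld_target kind {kind!r}")
        sigma = _ar1(m, float(rho))
    elif np.isscalar(ld_target):
        sigma = _ar1(m, float(ld_target))
    else:
        sigma = np.asarray(ld_target, dtype=np.float64)
        if sigma.shape != (m, m):
            raise ValueError("ld_target matrix shape does not match mafs")
    evals = np.linalg.eigvalsh(sigma)
    if evals[0] < -1e-10:
        raise ValueError(f"ld_target is not positive semi-definite (min eigenvalue {evals[0]:.3e})")
    # eigen square root tolerates the PSD-boundary case (duplicated latents)
    evecs = np.linalg.eigh(sigma)[1]
    L = evecs * np.sqrt(np.clip(evals, 0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_haplotypes, m)) @ L.T
    hap = (z < norm.ppf(mafs)).astype(np.int8)
    ids = list(snp_ids) if snp_ids is not None else [f"snp{i + 1}" for i in range(m)]
    return HaplotypePanel(
        haplotypes=hap,
        snp_ids=ids,
        mafs=mafs,
        gene_of_snp=dict(gene_of_snp) if gene_of_snp else {},
    )


# ---------------------------------------------------------------------------
# disease model
# ---------------------------------------------------------------------------


def _causal_columns(panel: HaplotypePanel, model: DiseaseModel) -> tuple[int, int]:
    try:
        ca = panel.snp_ids.index(model.causal_a)
        cb = panel.snp_ids.index(model.causal_b)
    except ValueError as exc:
        raise ValidationError(f"causal SNP not in panel: {exc}") from exc
    if panel.gene_of_snp:
        ga = panel.gene_of_snp.get(model.causal_a)
        gb = panel.gene_of_snp.get(model.causal_b)
        if ga == gb:
            raise ValidationError("causal SNPs must come from different genes")
    return ca, cb


def _linear_predictor(ga: np.ndarray, gb: np.ndarray, model: DiseaseModel, mechanism: str) -> np.ndarray:
    """Logistic linear predictor (without intercept) for one mechanism."""
    if mechanism == "type1":
        return (
            np.log(model.or_main_a) * ga
            + np.log(model.or_main_b) * gb
            + np.log(model.or_interaction) * ga * gb
        )
    if mechanism == "type2":
        return np.log(model.or_marginal_a) * ga + np.log(model.or_marginal_b) * gb
    raise ValueError(f"unknown mechanism {mechanism!r}")


def _draw_genotypes(panel: HaplotypePanel, n: int, rng: np.random.Generator) -> np.ndarray:
    H = panel.n_haplotypes
    i1 = rng.integers(0, H, n)
    i2 = rng.integers(0, H, n)
    return (panel.haplotypes[i1] + panel.haplotypes[i2]).astype(np.float64)


def _calibrate_beta0(
    panel: HaplotypePanel, model: DiseaseModel, mechanism: str, rng: np.random.Generator,
    n_calib: int = 50_000,
) -> float:
    """Intercept such that the population prevalence matches the model's.

    Monte-Carlo root find: P(D) = E[expit(b0 + eta(g))] over the panel's
    genotype distribution, solved for b0 by Brent's method.  Accurate to
    well within 0.005 on the prevalence scale at the default sample.
    """
    ca, cb = _causal_columns(panel, model)
    G = _draw_genotypes(panel, n_calib, rng)
    eta = _linear_predictor(G[:, ca], G[:, cb], model, mechanism)

    def f(b0: float) -> float:
        return float(np.mean(special.expit(b0 + eta))) - model.prevalence

    return float(optimize.brentq(f, -40.0, 40.0, xtol=1e-10))


def _fill_quotas(
    panel: HaplotypePanel,
    model: DiseaseModel,
    mechanism: str,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    max_batches: int = 400,
) -> tuple[np.ndarray, np.ndarray, float]:
    ca, cb = _causal_columns(panel, model)
    beta0 = _calibrate_beta0(panel, model, mechanism, rng)
    batch = max(20_000, 2 * (n_cases + n_controls))
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    got_c = got_k = 0
    for _ in range(max_batches):
        if got_c >= n_cases and got_k >= n_controls:
            break
        G = _draw_genotypes(panel, batch, rng)
        pr = special.expit(beta0 + _linear_predictor(G[:, ca], G[:, cb], model, mechanism))
        disease = rng.random(batch) < pr
        if got_c < n_cases:
            cases.append(G[disease][: n_cases - got_c])
            got_c += cases[-1].shape[0]
        if got_k < n_controls:
            controls.append(G[~disease][: n_controls - got_k])
            got_k += controls[-1].shape[0]
    if got_c < n_cases or got_k < n_controls:
        raise RuntimeError(
            f"could not fill case/control quotas (achieved {got_c}/{n_cases} cases, "
            f"{got_k}/{n_controls} controls); check prevalence/OR settings"
        )
    return np.vstack(cases), np.vstack(controls), beta0


def _panel_hash(panel: HaplotypePanel) -> int:
    return int(zlib.crc32(panel.haplotypes.tobytes()))


def sample_population(
    panel: HaplotypePanel,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int,
) -> SimulatedDataset:
    """Generate a case-control dataset directly from the panel + model.

    Individuals are drawn (two haplotypes with replacement, alleles summed)
    and assigned disease status from the scenario's logistic model until both
    quotas are filled.  ``type3`` fills half of each quota from the
    interaction mechanism and half from the marginal mechanism on the same
    panel, then concatenates at the individual level.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("quotas must be >= 1")
    if not panel.gene_of_snp:
        raise ValidationError("panel must carry a gene map to build datasets")
    rng = np.random.default_rng(seed)
    if model.scenario == "type3":
        h1c, h1k = n_cases // 2, n_controls // 2
        Gc1, Gk1, b01 = _fill_quotas(panel, model, "type1", h1c, h1k, rng)
        Gc2, Gk2, b02 = _fill_quotas(panel, model, "type2", n_cases - h1c, n_controls - h1k, rng)
        Gc = np.vstack([Gc1, Gc2])
        Gk = np.vstack([Gk1, Gk2])
        beta0 = (b01, b02)
    else:
        mechanism = "type1" if model.scenario == "type1" else "type2"
        Gc, Gk, beta0 = _fill_quotas(panel, model, mechanism, n_cases, n_controls, rng)

    dosages = np.vstack([Gc, Gk])
    phenotype = np.concatenate([np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)])
    order = rng.permutation(dosages.shape[0])
    dosages = dosages[order]
    phenotype = phenotype[order]
    ds = GenotypeDataset(
        dosages=dosages,
        snp_ids=list(panel.snp_ids),
        gene_of_snp=dict(panel.gene_of_snp),
        phenotype=phenotype,
        sample_ids=[f"ind{i + 1}" for i in range(dosages.shape[0])],
    )
    return SimulatedDataset(
        dataset=ds,
        model=model,
        causal_a=model.causal_a,
        causal_b=model.causal_b,
        provenance={
            "panel_hash": _panel_hash(panel),
            "model": model.as_dict(),
            "seed": int(seed),
            "n_cases": int(n_cases),
            "n_controls": int(n_controls),
            "beta0": beta0,
        },
    )


def build_population(
    panel: HaplotypePanel,
    model: DiseaseModel,
    pool_cases: int = 20_000,
    pool_controls: int = 20_000,
    seed: int = 0,
) -> Population:
    """Generate a reusable case/control pool for repeated subsampling.

    The default pool of 20k + 20k is a desk-scale stand-in for a very large
    hypothetical population; pool size affects only the (small) sampling
    dependence between replicate datasets, not the null distribution.
    """
    sd = sample_population(panel, model, pool_cases, pool_controls, seed)
    case = sd.dataset.phenotype == 1
    return Population(
        cases=sd.dataset.dosages[case],
        controls=sd.dataset.dosages[~case],
        snp_ids=list(panel.snp_ids),
        gene_of_snp=dict(panel.gene_of_snp),
        model=model,
        panel_hash=sd.provenance["panel_hash"],
        seed=seed,
        beta0=sd.provenance["beta0"],
    )


def sample_from_population(
    pop: Population, n: int, seed: int, balanced: bool = True, case_fraction: float = 0.5
) -> SimulatedDataset:
    """Draw a dataset of total size ``n`` from a pre-generated pool.

    The default is a balanced draw of n/2 cases and n/2 controls without
    replacement, matching the usual case-control sampling design; an
    arbitrary case fraction is available via ``case_fraction``.
    """
    if not balanced and not (0 < case_fraction < 1):
        raise ValueError("case_fraction must be in (0, 1)")
    n_case = n // 2 if balanced else int(round(n * case_fraction))
    n_ctrl = n - n_case
    if n_case > pop.cases.shape[0] or n_ctrl > pop.controls.shape[0]:
        raise ValueError("requested sample exceeds the pool size")
    rng = np.random.default_rng(seed)
    ic = rng.choice(pop.cases.shape[0], n_case, replace=False)
    ik = rng.choice(pop.controls.shape[0], n_ctrl, replace=False)
    dosages = np.vstack([pop.cases[ic], pop.controls[ik]])
    phenotype = np.concatenate([np.ones(n_case, dtype=np.int8), np.zeros(n_ctrl, dtype=np.int8)])
    order = rng.permutation(n)
    ds = GenotypeDataset(
        dosages=dosages[order],
        snp_ids=list(pop.snp_ids),
        gene_of_snp=dict(pop.gene_of_snp),
        phenotype=phenotype[order],
        sample_ids=[f"ind{i + 1}" for i in range(n)],
    )
    return SimulatedDataset(
        dataset=ds,
        model=pop.model,
        causal_a=pop.model.causal_a,
        causal_b=pop.model.causal_b,
        provenance={
            "panel_hash": pop.panel_hash,
            "model": pop.model.as_dict(),
            "pool_seed": pop.seed,
            "seed": int(seed),
            "n_cases": int(n_case),
            "n_controls": int(n_ctrl),
            "pool_sizes": [int(pop.cases.shape[0]), int(pop.controls.shape[0])],
        },
    )


def remove_causal(sd: SimulatedDataset) -> SimulatedDataset:
    """Drop the causal SNP columns so association must be detected via LD.

    The causal ids stay in the provenance.  Applying this twice is an error
    (the ids are already absent), as is removal that would empty a gene.
    """
    ds = sd.dataset
    present = set(ds.snp_ids)
    targets = [s for s in (sd.causal_a, sd.causal_b) if s in present]
    if not targets:
        raise ValueError("causal SNPs already removed from this dataset")
    keep = [s for s in ds.snp_ids if s not in targets]
    for gene in ds.genes:
        if not any(ds.gene_of_snp[s] == gene for s in keep):
            raise ValueError(f"removing causal SNPs would empty gene {gene!r}")
    idx = [ds.snp_ids.index(s) for s in keep]
    new_ds = GenotypeDataset(
        dosages=ds.dosages[:, idx],
        snp_ids=keep,
        gene_of_snp={s: ds.gene_of_snp[s] for s in keep},
        phenotype=ds.phenotype,
        sample_ids=list(ds.sample_ids),
    )
    prov = dict(sd.provenance)
    prov["causal_removed"] = [sd.causal_a, sd.causal_b]
    return replace(sd, dataset=new_ds, provenance=prov)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioPreset:
    """A named panel + disease-model configuration.

    Encodes the study conditions the simulations emulate: two common-variant
    gene blocks with strong local LD, one causal SNP per gene, cross-gene LD
    only in the linked-genes scenarios.
    """

    name: str
    scenario: str
    gene_a: str
    gene_b: str
    mafs: tuple
    sigma: np.ndarray
    snp_ids: tuple
    gene_of_snp: dict
    causal_a: str
    causal_b: str

    def make_panel(self, n_haplotypes: int = 20_000, seed: int = 0) -> HaplotypePanel:
        return make_synthetic_panel(
            np.asarray(self.mafs), self.sigma, n_haplotypes, seed,
            snp_ids=self.snp_ids, gene_of_snp=self.gene_of_snp,
        )

    def make_model(self, **or_kwargs) -> DiseaseModel:
        return DiseaseModel(
            scenario=self.scenario, causal_a=self.causal_a, causal_b=self.causal_b, **or_kwargs
        )


def _block_mafs(n: int, causal_idx: int, causal_maf: float) -> np.ndarray:
    # fixed spread of common-variant frequencies with the causal MAF injected
    base = np.linspace(0.22, 0.48, n)
    base[causal_idx] = causal_maf
    return base


def _preset(
    name: str,
    scenario: str,
    gene_a: str,
    n_a: int,
    causal_ia: int,
    maf_a: float,
    gene_b: str,
    n_b: int,
    causal_ib: int,
    maf_b: float,
    within_rho: float = 0.98,
    cross_rho: float = 0.0,
) -> ScenarioPreset:
    mafs = np.concatenate([_block_mafs(n_a, causal_ia, maf_a), _block_mafs(n_b, causal_ib, maf_b)])
    Sa = _ar1(n_a, within_rho)
    Sb = _ar1(n_b, within_rho)
    sigma = np.zeros((n_a + n_b, n_a + n_b))
    sigma[:n_a, :n_a] = Sa
    sigma[n_a:, n_a:] = Sb
    if cross_rho:
        # cross-gene dependence mediated by the causal pair: the cross block
        # is cross_rho * a b' with a, b the AR(1) LD profiles around the
        # causal positions (keeps the joint matrix positive semi-definite)
        a = Sa[:, causal_ia]
        b = Sb[causal_ib, :]
        sigma[:n_a, n_a:] = cross_rho * np.outer(a, b)
        sigma[n_a:, :n_a] = sigma[:n_a, n_a:].T
    ids_a = tuple(f"{gene_a}_s{i + 1}" for i in range(n_a))
    ids_b = tuple(f"{gene_b}_s{i + 1}" for i in range(n_b))
    gene_map = {s: gene_a for s in ids_a} | {s: gene_b for s in ids_b}
    return ScenarioPreset(
        name=name,
        scenario=scenario,
        gene_a=gene_a,
        gene_b=gene_b,
        mafs=tuple(mafs),
        sigma=sigma,
        snp_ids=ids_a + ids_b,
        gene_of_snp=gene_map,
        causal_a=ids_a[causal_ia],
        causal_b=ids_b[causal_ib],
    )


def paper_scenarios() -> dict[str, ScenarioPreset]:
    """Catalog of preset configurations for the three co-association scenarios.

    * ``scenario1_8x10`` — independent 8- and 10-SNP gene blocks (TNRC9/NEGR1
      style), causal MAFs 0.43 and 0.44, interaction disease model.
    * ``scenario2_7x7`` — two linked 7-SNP blocks (C6orf10/BTNL2 style),
      causal MAFs 0.46 and 0.45, cross-gene LD, marginal-effects model.
    * ``scenario3_7x7`` — the same linked panel with the 1:1 mixture of the
      interaction and marginal mechanisms.
    """
    return {
        "scenario1_8x10": _preset(
            "scenario1_8x10", "type1",
            "TNRC9", 8, 3, 0.43, "NEGR1", 10, 4, 0.44,
            within_rho=0.98, cross_rho=0.0,
        ),
        "scenario2_7x7": _preset(
            "scenario2_7x7", "type2",
            "C6orf10", 7, 3, 0.46, "BTNL2", 7, 3, 0.45,
            within_rho=0.98, cross_rho=0.9,
        ),
        "scenario3_7x7": _preset(
            "scenario3_7x7", "type3",
            "C6orf10", 7, 3, 0.46, "BTNL2", 7, 3, 0.45,
            within_rho=0.98, cross_rho=0.9,
        ),
    }
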