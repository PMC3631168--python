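"""Shared fixtures: small in-memory datasets and a reusable null population."""

from __future__ import annotations

import numpy as np
import pytest

from coassoc import GenotypeDataset, build_population, paper_scenarios


def make_dataset(
    rng: np.random.Generator,
    n_case: int = 60,
    n_ctrl: int = 60,
    p: int = 3,
    q: int = 4,
    rho: float = 0.4,
) -> GenotypeDataset:
    """Random two-gene dosage dataset with mild cross-gene correlation."""
    m = p + q
    sigma = np.full((m, m), rho)
    np.fill_diagonal(sigma, 1.0)
    n = n_case + n_ctrl
    L = np.linalg.cholesky(sigma)
    z = rng.standard_normal((2 * n, m)) @ L.T
    hap = (z < -0.5).astype(np.int8)  # common minor alleles (freq ~ 0.31)
    dos = (hap[:n] + hap[n:]).astype(np.float64)
    snp_ids = [f"a{i}" for i in range(p)] + [f"b{i}" for i in range(q)]
    gene_map = {s: ("GA" if s.startswith("a") else "GB") for s in snp_ids}
    pheno = np.concatenate([np.ones(n_case, dtype=np.int8), np.zeros(n_ctrl, dtype=np.int8)])
    return GenotypeDataset(
        dosages=dos,
        snp_ids=snp_ids,
        gene_of_snp=gene_map,
        phenotype=pheno,
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def small_dataset(rng) -> GenotypeDataset:
    return make_dataset(rng)


@pytest.fixture(scope="session")
def null_population_s1():
    """Shared null pool for the independent-genes preset (session-scoped)."""
    pre = paper_scenarios()["scenario1_8x10"]
    panel = pre.make_panel(20_000, seed=11)
    return pre, build_population(panel, pre.make_model(), 20_000, 20_000, seed=12)


@pytest.fixture(scope="session")
def null_population_s2():
    """Shared null pool for the linked-genes preset (session-scoped)."""
    pre = paper_scenarios()["scenario2_7x7"]
    panel = pre.make_panel(20_000, seed=13)
    return pre, build_population(panel, pre.make_model(), 20_000, 20_000, seed=14)
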