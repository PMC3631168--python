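"""Genotype, gene-map, phenotype and haplotype-panel I/O.

All numerical work downstream operates on additive-coded dosage matrices
(minor-allele counts in {0, 1, 2}).  This module reads the common text
representations of such data (PLINK ``--recode A`` style tables, VCF with GT
fields, plain TSV matrices, IMPUTE-style ``.hap``/``.legend`` panels), applies
a single pooled minor-allele coding across cases and controls, and performs
the light preprocessing (mean imputation, monomorphic-SNP removal) that the
co-association statistics require.

Coordinates play no role in the computation: SNP order is taken from the
file, and gene membership comes solely from a two-column gene-map TSV
(``snp_id<TAB>gene``).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeDataset",
    "GeneBlock",
    "HaplotypePanel",
    "PreprocessReport",
    "read_genotypes",
    "write_genotypes",
    "read_gene_map",
    "write_gene_map",
    "read_phenotype",
    "preprocess",
    "read_haplotype_panel",
    "write_haplotype_panel",
]


class ParseError(ValueError):
    """A malformed input file (reports the offending line/record)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a dataset contract."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """Samples x SNPs additive dosage matrix with gene labels and phenotype.

    ``dosages`` holds minor-allele counts as float64 (NaN marks a missing
    genotype; allowed only before :func:`preprocess`).  ``phenotype`` is
    coded 0 = control, 1 = case.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    gene_of_snp: dict[str, str]
    phenotype: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.snp_ids) != m:
            raise ValidationError(
                f"{len(self.snp_ids)} snp ids for {m} dosage columns"
            )
        if len(set(self.snp_ids)) != m:
            raise ValidationError("snp ids must be unique")
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match dosages")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids must be unique")
        if self.phenotype.shape != (n,):
            raise ValidationError("phenotype length does not match dosages")
        bad = set(np.unique(self.phenotype)) - {0, 1}
        if bad:
            raise ValidationError(f"phenotype values outside {{0,1}}: {sorted(bad)}")
        missing_map = [s for s in self.snp_ids if s not in self.gene_of_snp]
        if missing_map:
            raise ValidationError(f"snps without gene mapping: {missing_map[:5]}")

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.snp_ids:
            seen.setdefault(self.gene_of_snp[s], None)
        return list(seen)

    def gene_block(self, gene: str) -> "GeneBlock":
        cols = [i for i, s in enumerate(self.snp_ids) if self.gene_of_snp[s] == gene]
        if not cols:
            raise ValidationError(f"gene {gene!r} has no SNPs in this dataset")
        return GeneBlock(gene=gene, columns=cols)

    def block_matrix(self, gene: str) -> np.ndarray:
        return self.dosages[:, self.gene_block(gene).columns]

    def case_mask(self) -> np.ndarray:
        return self.phenotype == 1

    def require_both_classes(self) -> None:
        if not (self.phenotype == 1).any() or not (self.phenotype == 0).any():
            raise ValidationError("phenotype must contain at least one case and one control")


@dataclass(frozen=True)
class GeneBlock:
    """Column indices of one gene's SNPs inside a :class:`GenotypeDataset`."""

    gene: str
    columns: list[int]

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValidationError(f"gene block {self.gene!r} is empty")
        if any(b <= a for a, b in zip(self.columns, self.columns[1:])):
            raise ValidationError("gene block indices must be strictly increasing")


@dataclass
class HaplotypePanel:
    """Phased haplotypes (rows) x SNPs (columns) with allele frequencies.

    ``haplotypes`` entries are 0/1 (reference/alternate at each site, coded so
    that the declared frequency refers to the 1-allele).  ``mafs`` are the
    per-SNP frequencies of the 1-allele; for a panel built by the synthetic
    generator these equal the requested minor-allele frequencies, for a panel
    read from disk they are the empirical frequencies.
    """

    haplotypes: np.ndarray
    snp_ids: list[str]
    mafs: np.ndarray
    gene_of_snp: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValidationError("haplotypes must be a 2-D matrix")
        bad = set(np.unique(self.haplotypes)) - {0, 1}
        if bad:
            raise ParseError(f"non-binary haplotype entries: {sorted(bad)}")
        if len(self.snp_ids) != self.haplotypes.shape[1]:
            raise ValidationError("snp_ids length does not match haplotype columns")
        self.mafs = np.asarray(self.mafs, dtype=np.float64)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def empirical_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def ld_r(self) -> np.ndarray:
        """Pairwise allelic correlation r across haplotypes.

        Columns with zero variance (fixed alleles) yield NaN rows/columns and
        a logged warning rather than an error.
        """
        H = self.haplotypes.astype(np.float64)
        sd = H.std(axis=0, ddof=1)
        if (sd == 0).any():
            logger.warning(
                "panel has %d monomorphic columns; LD undefined there",
                int((sd == 0).sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(H, rowvar=False)
        r = np.atleast_2d(r)
        return r


@dataclass
class PreprocessReport:
    """What :func:`preprocess` changed."""

    n_imputed: int = 0
    dropped_samples: list[str] = field(default_factory=list)
    monomorphic_removed: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.n_imputed or self.dropped_samples or self.monomorphic_removed)


# ---------------------------------------------------------------------------
# gene map / phenotype
# ---------------------------------------------------------------------------


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``snp_id<TAB>gene`` TSV into a dict."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'snp_id<TAB>gene', got {line!r}")
            snp, gene = parts
            if snp in mapping and mapping[snp] != gene:
                raise ParseError(f"{path}:{lineno}: snp {snp!r} mapped to two genes")
            mapping[snp] = gene
    if not mapping:
        raise ParseError(f"{path}: empty gene map")
    return mapping


def write_gene_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for snp, gene in mapping.items():
            fh.write(f"{snp}\t{gene}\n")


def _recode_phenotype(values: np.ndarray, origin: str) -> np.ndarray:
    """Map 1/2 (PLINK) or 0/1 phenotype codings onto 0=control, 1=case."""
    uniq = set(np.unique(values).tolist())
    if uniq <= {0, 1}:
        coding = "0/1"
        out = values.astype(np.int8)
    elif uniq <= {1, 2}:
        coding = "1/2"
        out = (values - 1).astype(np.int8)
    else:
        raise ValidationError(
            f"{origin}: phenotype values {sorted(uniq)} outside recognized codings "
            "(0/1 or 1=control,2=case)"
        )
    logger.info("%s: phenotype coding auto-detected as %s", origin, coding)
    return out


def read_phenotype(path: str | Path) -> pd.Series:
    """Read a ``sample_id<TAB>status`` TSV; returns 0/1 status by sample id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "status"], comment="#")
    if df["status"].isna().any() or not np.issubdtype(df["status"].dtype, np.number):
        raise ParseError(f"{path}: non-numeric phenotype status")
    status = _recode_phenotype(df["status"].to_numpy(), str(path))
    return pd.Series(status, index=df["sample_id"].astype(str).to_list())


# ---------------------------------------------------------------------------
# genotype readers/writers
# ---------------------------------------------------------------------------

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _flip_to_minor(dosages: np.ndarray, snp_ids: Sequence[str]) -> np.ndarray:
    """Recode columns so dosages count the pooled-sample minor allele.

    The flip is decided on cases and controls together so both strata share a
    single coding (the co-association statistic compares path coefficients
    across strata, which is only meaningful under one coding).  Frequencies of
    exactly 0.5 are left as read.
    """
    freqs = np.nanmean(dosages, axis=0) / 2.0
    flip = freqs > 0.5
    if flip.any():
        flipped = [s for s, f in zip(snp_ids, flip) if f]
        logger.info("recoded %d SNP(s) to minor allele: %s", len(flipped), flipped[:8])
        dosages = dosages.copy()
        dosages[:, flip] = 2.0 - dosages[:, flip]
    return dosages


def _read_plink_raw(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    with _open_text(path) as fh:
        text = fh.read()
    try:
        df = pd.read_csv(io.StringIO(text), sep=r"\s+")
    except Exception as exc:  # pragma: no cover - pandas detail
        raise ParseError(f"{path}: cannot parse whitespace table: {exc}") from exc
    missing_meta = [c for c in _PLINK_META if c not in df.columns]
    if missing_meta:
        raise ParseError(f"{path}: missing PLINK-raw header columns {missing_meta}")
    snp_cols = [c for c in df.columns if c not in _PLINK_META]
    if not snp_cols:
        raise ParseError(f"{path}: no SNP columns after the six metadata columns")
    dos = df[snp_cols].to_numpy(dtype=np.float64)
    valid = np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ParseError(
            f"{path}: line {i + 2}: dosage {dos[i, j]!r} for {snp_cols[j]} not in {{0,1,2,NA}}"
        )
    pheno = _recode_phenotype(df["PHENOTYPE"].to_numpy(), str(path))
    sample_ids = df["IID"].astype(str).to_list()
    return dos, list(snp_cols), pheno, sample_ids


def _read_tsv_genotypes(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first TSV column must be 'sample_id'")
    snp_cols = list(df.columns[1:])
    if not snp_cols:
        raise ParseError(f"{path}: no SNP columns")
    dos = df[snp_cols].to_numpy(dtype=np.float64)
    valid = np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ParseError(f"{path}: row {i + 2}: dosage {dos[i, j]!r} not in {{0,1,2,NA}}")
    return dos, snp_cols, df["sample_id"].astype(str).to_list()


def _read_vcf(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"{path}: record {rec.CHROM}:{rec.POS} ({rec.ID or '.'}) is not biallelic "
                f"(ALT={','.join(rec.ALT)})"
            )
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=missing
        gt = rec.gt_types.astype(np.float64)
        gt[gt == 3] = np.nan
        cols.append(gt)
        snp_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    if not cols:
        raise ParseError(f"{path}: VCF contains no records")
    dos = np.column_stack(cols)
    return dos, snp_ids, sample_ids


def read_genotypes(
    path: str | Path,
    format: str,
    gene_map: str | Path | Mapping[str, str],
    phenotype: str | Path | pd.Series | None = None,
) -> GenotypeDataset:
    """Read an additive-coded genotype matrix into a :class:`GenotypeDataset`.

    Parameters
    ----------
    path
        Genotype file.  ``plink_raw`` is a whitespace table with header
        ``FID IID PAT MAT SEX PHENOTYPE snp...``; ``tsv`` is
        ``sample_id<TAB>snp...``; ``vcf`` is VCF v4.x with GT fields and
        biallelic records only.
    format
        One of ``plink_raw``, ``vcf``, ``tsv``.
    gene_map
        Path to (or mapping of) ``snp_id -> gene``.
    phenotype
        Companion phenotype TSV (or Series indexed by sample id); required for
        ``vcf`` and ``tsv``, ignored for ``plink_raw`` (which carries its own
        PHENOTYPE column).

    Dosages are recoded to pooled-sample minor-allele counts.
    """
    if isinstance(gene_map, (str, Path)):
        gene_map = read_gene_map(gene_map)
    gene_map = dict(gene_map)

    if format == "plink_raw":
        dos, snp_ids, pheno, sample_ids = _read_plink_raw(path)
    elif format == "tsv":
        dos, snp_ids, sample_ids = _read_tsv_genotypes(path)
        pheno = None
    elif format == "vcf":
        dos, snp_ids, sample_ids = _read_vcf(path)
        pheno = None
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    if pheno is None:
        if phenotype is None:
            raise ValidationError(f"format {format!r} requires a companion phenotype table")
        if isinstance(phenotype, (str, Path)):
            phenotype = read_phenotype(phenotype)
        try:
            pheno = phenotype.loc[sample_ids].to_numpy(dtype=np.int8)
        except KeyError as exc:
            raise ValidationError(f"phenotype table missing sample: {exc}") from exc

    dos = _flip_to_minor(dos, snp_ids)
    keep = {s: g for s, g in gene_map.items() if s in set(snp_ids)}
    unmapped = [s for s in snp_ids if s not in keep]
    if unmapped:
        raise ValidationError(f"gene map lacks entries for SNPs: {unmapped[:5]}")
    return GenotypeDataset(
        dosages=dos,
        snp_ids=snp_ids,
        gene_of_snp=keep,
        phenotype=pheno,
        sample_ids=sample_ids,
    )


def write_genotypes(ds: GenotypeDataset, path: str | Path, format: str = "plink_raw") -> None:
    """Write a complete dataset back out (plink_raw or tsv dialects)."""
    if np.isnan(ds.dosages).any():
        raise ValidationError("cannot write a dataset with missing dosages")
    dos = ds.dosages.astype(np.int64)
    if format == "plink_raw":
        with _open_text(path, "wt") as fh:
            fh.write(" ".join(_PLINK_META + list(ds.snp_ids)) + "\n")
            for sid, ph, row in zip(ds.sample_ids, ds.phenotype, dos):
                meta = [sid, sid, "0", "0", "0", str(int(ph) + 1)]
                fh.write(" ".join(meta + [str(int(v)) for v in row]) + "\n")
    elif format == "tsv":
        df = pd.DataFrame(dos, columns=ds.snp_ids)
        df.insert(0, "sample_id", ds.sample_ids)
        with _open_text(path, "wt") as fh:
            df.to_csv(fh, sep="\t", index=False)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess(ds: GenotypeDataset, impute: str = "mean") -> tuple[GenotypeDataset, PreprocessReport]:
    """Impute missing dosages and drop monomorphic SNPs.

    ``impute='mean'`` replaces each missing dosage with the per-SNP mean of
    the observed values; ``impute='drop_sample'`` removes any sample carrying
    a missing genotype.  SNP columns with zero variance afterwards are removed
    (standardization would divide by zero) and listed in the report; a gene
    losing all of its SNPs is a configuration error.
    """
    report = PreprocessReport()
    dos = ds.dosages.copy()
    sample_ids = list(ds.sample_ids)
    pheno = ds.phenotype.copy()

    miss = np.isnan(dos)
    if miss.any():
        if impute == "mean":
            col_means = np.nanmean(dos, axis=0)
            if np.isnan(col_means).any():
                j = int(np.argwhere(np.isnan(col_means))[0])
                raise ValidationError(f"SNP {ds.snp_ids[j]} has no observed genotypes")
            idx = np.where(miss)
            dos[idx] = col_means[idx[1]]
            report.n_imputed = int(miss.sum())
        elif impute == "drop_sample":
            bad = miss.any(axis=1)
            report.dropped_samples = [s for s, b in zip(sample_ids, bad) if b]
            dos = dos[~bad]
            pheno = pheno[~bad]
            sample_ids = [s for s, b in zip(sample_ids, bad) if not b]
        else:
            raise ValueError(f"unknown impute mode {impute!r}")

    sd = dos.std(axis=0, ddof=1) if dos.shape[0] > 1 else np.zeros(dos.shape[1])
    keep = sd > 0
    report.monomorphic_removed = [s for s, k in zip(ds.snp_ids, keep) if not k]
    if report.monomorphic_removed:
        logger.warning("removed monomorphic SNPs: %s", report.monomorphic_removed)
    snp_ids = [s for s, k in zip(ds.snp_ids, keep) if k]
    dos = dos[:, keep]

    for gene in ds.genes:
        if not any(ds.gene_of_snp[s] == gene for s in snp_ids):
            raise ValidationError(f"gene {gene!r} lost all SNPs during preprocessing")

    out = GenotypeDataset(
        dosages=dos,
        snp_ids=snp_ids,
        gene_of_snp={s: ds.gene_of_snp[s] for s in snp_ids},
        phenotype=pheno,
        sample_ids=sample_ids,
    )
    out.require_both_classes()
    return out, report


# ---------------------------------------------------------------------------
# haplotype panels
# ---------------------------------------------------------------------------


def read_haplotype_panel(
    path: str | Path,
    format: str = "tsv",
    legend: str | Path | None = None,
    gene_map: Mapping[str, str] | None = None,
) -> HaplotypePanel:
    """Read a phased haplotype panel.

    ``tsv``: haplotypes in rows, SNP ids in the header.  ``impute_hap_legend``:
    IMPUTE-style pair of files — ``path`` is the ``.hap`` matrix (one row per
    SNP, one column per haplotype) and ``legend`` (default: ``path`` with the
    ``.legend`` suffix) the ``id position allele0 allele1`` table.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        snp_ids = list(df.columns)
        hap = df.to_numpy()  # rows are haplotypes
        _check_binary(hap, path)
    elif format == "impute_hap_legend":
        if legend is None:
            legend = Path(str(path)).with_suffix(".legend")
        leg = pd.read_csv(legend, sep=r"\s+")
        if "id" not in leg.columns:
            raise ParseError(f"{legend}: legend file must have an 'id' column")
        snp_ids = leg["id"].astype(str).to_list()
        rows = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                rows.append(line.split())
        if len(rows) != len(snp_ids):
            raise ParseError(
                f"{path}: {len(rows)} hap rows but {len(snp_ids)} legend entries"
            )
        try:
            mat = np.asarray(rows, dtype=np.int64)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric haplotype entry ({exc})") from exc
        _check_binary(mat, path)
        hap = mat.T  # to haplotypes x SNPs
    else:
        raise ValueError(f"unknown panel format {format!r}")

    freqs = hap.mean(axis=0)
    return HaplotypePanel(
        haplotypes=hap,
        snp_ids=snp_ids,
        mafs=freqs,
        gene_of_snp=dict(gene_map) if gene_map else {},
    )


def _check_binary(mat: np.ndarray, path: str | Path) -> None:
    bad = ~np.isin(mat, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(f"{path}: non-binary entry {mat[i, j]!r} at row {i + 1}, column {j + 1}")


def write_haplotype_panel(
    panel: HaplotypePanel, path: str | Path, format: str = "tsv", legend: str | Path | None = None
) -> None:
    if format == "tsv":
        df = pd.DataFrame(panel.haplotypes, columns=panel.snp_ids)
        with _open_text(path, "wt") as fh:
            df.to_csv(fh, sep="\t", index=False)
    elif format == "impute_hap_legend":
        if legend is None:
            legend = Path(str(path)).with_suffix(".legend")
        with _open_text(legend, "wt") as fh:
            fh.write("id position allele0 allele1\n")
            for i, snp in enumerate(panel.snp_ids):
                fh.write(f"{snp} {i + 1} A B\n")
        with _open_text(path, "wt") as fh:
            for row in panel.haplotypes.T:  # one row per SNP
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown panel format {format!r}")


def subset_columns(ds: GenotypeDataset, keep_snps: Sequence[str]) -> GenotypeDataset:
    """Dataset restricted to ``keep_snps`` (order preserved from the dataset)."""
    keep = [s for s in ds.snp_ids if s in set(keep_snps)]
    idx = [ds.snp_ids.index(s) for s in keep]
    return replace(
        ds,
        dosages=ds.dosages[:, idx],
        snp_ids=keep,
        gene_of_snp={s: ds.gene_of_snp[s] for s in keep},
    )
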