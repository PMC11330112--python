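"""Readers, writers and the in-memory data model shared across the package.

Internal coordinates are 1-based inclusive (the VCF convention); BED input is
converted at the boundary.  Genotypes are stored as alternative-allele counts
in ``{0, 1, 2}`` with a distinct :data:`MISSING` sentinel that is never imputed
at I/O time — the feature-encoding layer decides how missing genotypes enter
the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an unobserved genotype in the alt-count matrix.
MISSING: int = -9

_VALID_COUNTS = frozenset({0, 1, 2, MISSING})

#: Strand-ambiguous allele pairs (palindromic SNPs).
_AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class DataValidationError(ValueError):
    """Raised when an input file or in-memory table violates the data model."""


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    """True for palindromic allele pairs (A/T, C/G) that cannot be strand-resolved."""
    return (ref.upper(), alt.upper()) in _AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class Variant:
    """A biallelic autosomal SNP.

    Positions are 1-based.  ``chrom`` is an integer 1-22; sex chromosomes and
    mitochondria are out of scope.
    """

    id: str
    chrom: int
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not 1 <= self.chrom <= 22:
            raise DataValidationError(
                f"variant {self.id}: chrom {self.chrom} outside autosomes 1-22"
            )
        if self.ref_allele == self.alt_allele:
            raise DataValidationError(f"variant {self.id}: ref == alt ({self.ref_allele})")


@dataclass
class GenotypeDataset:
    """Sample x variant alt-allele counts with optional phenotype and covariates.

    ``alt_counts`` has shape (n_samples, n_variants) with entries in
    {0, 1, 2, MISSING}.  Variants are kept sorted by (chrom, pos).
    """

    variants: list[Variant]
    sample_ids: list[str]
    alt_counts: np.ndarray
    phenotype: np.ndarray | None = None
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int16)
        n, m = self.alt_counts.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise DataValidationError(
                f"alt_counts shape {self.alt_counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.alt_counts, list(_VALID_COUNTS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataValidationError(
                f"alt_counts[{i},{j}] = {self.alt_counts[i, j]} not in {{0,1,2,MISSING}}"
            )
        if len(set(self.sample_ids)) != n:
            raise DataValidationError("duplicate sample ids")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != m:
            raise DataValidationError("duplicate variant ids")
        keys = [(v.chrom, v.pos) for v in self.variants]
        if keys != sorted(keys):
            order = sorted(range(m), key=lambda k: (keys[k][0], keys[k][1], self.variants[k].id))
            self.variants = [self.variants[k] for k in order]
            self.alt_counts = self.alt_counts[:, order]
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
            if self.phenotype.shape != (n,):
                raise DataValidationError("phenotype length does not match samples")
            if not np.isin(self.phenotype, [0, 1]).all():
                raise DataValidationError("phenotype must be binary 0/1")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim != 2 or self.covariates.shape[0] != n:
                raise DataValidationError("covariate matrix must be n_samples x n_covariates")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self) -> dict[str, int]:
        return {v.id: i for i, v in enumerate(self.variants)}

    def subset_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return GenotypeDataset(
            variants=list(self.variants),
            sample_ids=[self.sample_ids[i] for i in idx],
            alt_counts=self.alt_counts[idx],
            phenotype=None if self.phenotype is None else self.phenotype[idx],
            covariates=None if self.covariates is None else self.covariates[idx],
            covariate_names=list(self.covariate_names),
        )

    def subset_variants(self, ids: Iterable[str]) -> "GenotypeDataset":
        index = self.variant_index()
        cols = [index[i] for i in ids]
        return GenotypeDataset(
            variants=[self.variants[c] for c in cols],
            sample_ids=list(self.sample_ids),
            alt_counts=self.alt_counts[:, cols],
            phenotype=self.phenotype,
            covariates=self.covariates,
            covariate_names=list(self.covariate_names),
        )


@dataclass
class SummaryStatsTable:
    """Per-variant discovery-GWAS effect sizes (log-odds per alt allele) and p-values."""

    table: pd.DataFrame  # index: variant id; columns chrom,pos,ref_allele,alt_allele,beta,p_value

    REQUIRED = ("chrom", "pos", "ref_allele", "alt_allele", "beta", "p_value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"summary stats missing columns: {missing}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate variant ids in summary stats: {dups}")
        p = self.table["p_value"].to_numpy(float)
        if (p <= 0).any() or (p > 1).any():
            bad = self.table.index[(p <= 0) | (p > 1)].tolist()
            raise DataValidationError(f"p-values outside (0,1] for: {bad[:5]}")
        if not np.isfinite(self.table["beta"].to_numpy(float)).all():
            raise DataValidationError("non-finite beta in summary stats")

    @property
    def variant_ids(self) -> list[str]:
        return self.table.index.tolist()

    def beta(self, vid: str) -> float:
        return float(self.table.at[vid, "beta"])

    def p_value(self, vid: str) -> float:
        return float(self.table.at[vid, "p_value"])


@dataclass
class GeneAnnotationTable:
    """Gene intervals, 1-based inclusive, sorted by (chrom, start)."""

    table: pd.DataFrame  # columns gene_id, chrom, start, end

    def __post_init__(self) -> None:
        for c in ("gene_id", "chrom", "start", "end"):
            if c not in self.table.columns:
                raise DataValidationError(f"gene annotation missing column {c}")
        if self.table["gene_id"].duplicated().any():
            dups = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].tolist()
            raise DataValidationError(f"duplicate gene ids: {dups}")
        if (self.table["start"] > self.table["end"]).any():
            bad = self.table.loc[self.table["start"] > self.table["end"], "gene_id"].tolist()
            raise DataValidationError(f"gene start > end for: {bad}")
        self.table = (
            self.table.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)
        )

    def on_chrom(self, chrom: int) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _parse_chrom(token: str) -> int | None:
    """'chr7' / '7' -> 7; non-autosomes -> None."""
    tok = str(token)
    if tok.lower().startswith("chr"):
        tok = tok[3:]
    try:
        c = int(tok)
    except ValueError:
        return None
    return c if 1 <= c <= 22 else None


def read_vcf(
    path: str,
    phenotype_path: str | None = None,
    *,
    drop_strand_ambiguous: bool = False,
    on_multiallelic: str = "skip",
) -> GenotypeDataset:
    """Read a VCF into a :class:`GenotypeDataset`.

    Alt-allele counts come from the GT field; half-calls and ``./.`` become
    :data:`MISSING`.  Non-autosome contigs are skipped with a logged count.
    Multi-allelic records are skipped by default (``on_multiallelic='error'``
    raises instead); split them upstream with ``bcftools norm`` if needed.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("skip", "error"):
        raise ValueError("on_multiallelic must be 'skip' or 'error'")
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    n_non_autosome = 0
    n_multi = 0
    n_ambiguous = 0
    for rec in vcf:
        chrom = _parse_chrom(rec.CHROM)
        if chrom is None:
            n_non_autosome += 1
            continue
        if len(rec.ALT) != 1:
            if on_multiallelic == "error":
                raise DataValidationError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS} ({rec.REF}->{rec.ALT})"
                )
            n_multi += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if drop_strand_ambiguous and is_strand_ambiguous(ref, alt):
            n_ambiguous += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{chrom}:{rec.POS}:{ref}:{alt}"
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types
        col = np.full(len(sample_ids), MISSING, dtype=np.int16)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        variants.append(Variant(vid, chrom, rec.POS, ref, alt))
        columns.append(col)
    if n_non_autosome:
        logger.info("read_vcf: skipped %d non-autosome records", n_non_autosome)
    if n_multi:
        logger.info("read_vcf: skipped %d multi-allelic records", n_multi)
    if n_ambiguous:
        logger.info("read_vcf: dropped %d strand-ambiguous SNPs", n_ambiguous)
    alt_counts = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0), dtype=np.int16)
    )
    ds = GenotypeDataset(variants=variants, sample_ids=sample_ids, alt_counts=alt_counts)
    if phenotype_path is not None:
        attach_phenotype(ds, phenotype_path)
    return ds


def read_genotype_tsv(
    path: str,
    phenotype_path: str | None = None,
    variant_meta_path: str | None = None,
) -> GenotypeDataset:
    """Read the plain sample x variant allele-count TSV dialect.

    First column holds sample ids, the header names variants and cells are in
    {0, 1, 2, NA}.  Variant coordinates come from ``variant_meta_path`` (TSV:
    id, chrom, pos, ref_allele, alt_allele); without it, ids of the form
    ``chrom:pos:ref:alt`` are parsed directly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    mat = np.full(df.shape, MISSING, dtype=np.int16)
    values = df.to_numpy()
    for r in range(values.shape[0]):
        for c in range(values.shape[1]):
            cell = str(values[r, c]).strip()
            if cell in ("NA", "nan", "."):
                continue
            if cell not in ("0", "1", "2"):
                raise DataValidationError(
                    f"{path}: row {df.index[r]!r} column {df.columns[c]!r}: "
                    f"cell {cell!r} not in {{0,1,2,NA}}"
                )
            mat[r, c] = int(cell)
    meta: dict[str, tuple[int, int, str, str]] = {}
    if variant_meta_path is not None:
        mdf = pd.read_csv(variant_meta_path, sep="\t", dtype=str)
        for _, row in mdf.iterrows():
            meta[row["id"]] = (
                int(row["chrom"]), int(row["pos"]), row["ref_allele"], row["alt_allele"]
            )
    variants = []
    for vid in df.columns:
        if vid in meta:
            chrom, pos, ref, alt = meta[vid]
        else:
            try:
                c, p, ref, alt = vid.split(":")
                chrom, pos = int(c), int(p)
            except ValueError as exc:
                raise DataValidationError(
                    f"variant id {vid!r} is not chrom:pos:ref:alt and no metadata file given"
                ) from exc
        variants.append(Variant(vid, chrom, pos, ref, alt))
    ds = GenotypeDataset(variants=variants, sample_ids=df.index.astype(str).tolist(),
                         alt_counts=mat)
    if phenotype_path is not None:
        attach_phenotype(ds, phenotype_path)
    return ds


def attach_phenotype(ds: GenotypeDataset, path: str) -> None:
    """Attach phenotype (column ``phenotype``) and any extra covariate columns.

    The TSV must contain ``sample_id``; samples are matched by id and all
    dataset samples must be present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    missing = [s for s in ds.sample_ids if s not in df.index]
    if missing:
        raise DataValidationError(f"phenotype file lacks samples: {missing[:5]}")
    df = df.loc[ds.sample_ids]
    ds.phenotype = df["phenotype"].to_numpy(np.int8)
    cov_cols = [c for c in df.columns if c != "phenotype"]
    if cov_cols:
        ds.covariates = df[cov_cols].to_numpy(float)
        ds.covariate_names = cov_cols
    ds.__post_init__()


def write_genotype_tsv(ds: GenotypeDataset, path: str, variant_meta_path: str | None = None) -> None:
    """Write the allele-count TSV (MISSING -> NA); optionally a variant metadata TSV."""
    df = pd.DataFrame(
        ds.alt_counts.astype(object), index=ds.sample_ids, columns=ds.variant_ids
    )
    df[ds.alt_counts == MISSING] = "NA"
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    if variant_meta_path is not None:
        meta = pd.DataFrame(
            {
                "id": ds.variant_ids,
                "chrom": [v.chrom for v in ds.variants],
                "pos": [v.pos for v in ds.variants],
                "ref_allele": [v.ref_allele for v in ds.variants],
                "alt_allele": [v.alt_allele for v in ds.variants],
            }
        )
        meta.to_csv(variant_meta_path, sep="\t", index=False)


def write_phenotype_tsv(ds: GenotypeDataset, path: str) -> None:
    if ds.phenotype is None:
        raise DataValidationError("dataset has no phenotype to write")
    df = pd.DataFrame({"sample_id": ds.sample_ids, "phenotype": ds.phenotype})
    for k, name in enumerate(ds.covariate_names):
        df[name] = ds.covariates[:, k]
    df.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str) -> SummaryStatsTable:
    """Read GWAS summary statistics (TSV: id, chrom, pos, ref_allele, alt_allele, beta, p_value)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "ref_allele": str, "alt_allele": str})
    if "id" not in df.columns:
        raise DataValidationError(f"{path}: summary stats need an 'id' column")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise DataValidationError(f"{path}: duplicate variant ids: {dups}")
    df = df.set_index("id")
    return SummaryStatsTable(df)


def write_summary_stats(stats: SummaryStatsTable, path: str) -> None:
    stats.table.rename_axis("id").to_csv(path, sep="\t")


def read_gene_bed(path: str) -> GeneAnnotationTable:
    """Read gene intervals from BED4+ (0-based half-open), converting to 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise DataValidationError(f"{path}:{ln}: BED needs 4+ columns (chrom start end name)")
            chrom = _parse_chrom(parts[0])
            if chrom is None:
                continue
            start0, end0 = int(parts[1]), int(parts[2])
            start, end = start0 + 1, end0  # half-open 0-based -> inclusive 1-based
            if start > end:
                raise DataValidationError(f"{path}:{ln}: empty or inverted interval")
            rows.append({"gene_id": parts[3], "chrom": chrom, "start": start, "end": end})
    return GeneAnnotationTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]))


def write_gene_bed(genes: GeneAnnotationTable, path: str) -> None:
    with open(path, "w") as fh:
        for _, row in genes.table.iterrows():
            fh.write(f"chr{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\n")


def harmonize_alleles(ds: GenotypeDataset, stats: SummaryStatsTable) -> int:
    """Align dataset alt-counts to the summary-stats effect allele, in place.

    Variants are matched by id.  Where ref/alt are swapped relative to the
    summary stats, observed counts are flipped (2 - count, MISSING kept) and a
    count of flips is returned.  Mismatching allele pairs raise.
    """
    n_flipped = 0
    for j, v in enumerate(ds.variants):
        if v.id not in stats.table.index:
            continue
        row = stats.table.loc[v.id]
        if (v.ref_allele, v.alt_allele) == (row.ref_allele, row.alt_allele):
            continue
        if (v.ref_allele, v.alt_allele) == (row.alt_allele, row.ref_allele):
            col = ds.alt_counts[:, j]
            obs = col != MISSING
            col[obs] = 2 - col[obs]
            ds.variants[j] = Variant(v.id, v.chrom, v.pos, v.alt_allele, v.ref_allele)
            n_flipped += 1
        else:
            raise DataValidationError(
                f"variant {v.id}: alleles {v.ref_allele}/{v.alt_allele} do not match "
                f"summary stats {row.ref_allele}/{row.alt_allele}"
            )
    if n_flipped:
        logger.info("harmonize_alleles: flipped %d variants to the effect allele", n_flipped)
    return n_flipped
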