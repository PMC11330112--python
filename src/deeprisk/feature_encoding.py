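"""Two-dimensional ref/alt genotype encoding and the SNP-to-gene connectivity map.

Each observed genotype is encoded by its (ref-allele count, alt-allele count)
pair — (2,0), (1,1) or (0,2) — and a missing genotype by (0,0), so missingness
is a distinct input state rather than an imputed value.  The additive variant
keeps the traditional single alt-count dimension (missing -> 0).

The connectivity map links every selected SNP to each gene whose interval,
widened by 250 kb on both sides, contains the SNP; a SNP beyond 250 kb of all
genes is linked to its single nearest gene, so every SNP connects to at least
one gene.  Genes are grouped by chromosome and ordered by start position —
this ordering is the sequence the per-chromosome BiLSTM consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import MISSING, GeneAnnotationTable, Variant
from .snp_selection import SelectionResult

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 250_000


@dataclass
class EncodedGenotypes:
    """Tensor of shape (n_samples, n_snps, d): d=2 ref/alt counts, d=1 additive."""

    tensor: np.ndarray
    snp_ids: list[str]
    mode: str  # "two_dim" | "additive"


@dataclass
class GeneGroup:
    """Genes of one chromosome in BiLSTM order, with their SNP memberships."""

    chrom: int
    gene_ids: list[str]                 # ordered by (start, gene_id)
    gene_starts: list[int]
    snp_indices: list[list[int]]        # per gene: indices into the selected-SNP order


@dataclass
class ConnectivityMap:
    """Sparse SNP -> gene incidence, grouped per chromosome."""

    snp_ids: list[str]                  # selected SNPs, (chrom, pos) order
    groups: dict[int, GeneGroup]        # chrom -> group

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_genes(self) -> int:
        return sum(len(g.gene_ids) for g in self.groups.values())

    @property
    def n_edges(self) -> int:
        return sum(len(s) for g in self.groups.values() for s in g.snp_indices)

    def edges(self) -> list[tuple[str, str, int]]:
        """(snp_id, gene_id, chrom) triples in deterministic order."""
        out = []
        for c in sorted(self.groups):
            g = self.groups[c]
            for gene_id, snps in zip(g.gene_ids, g.snp_indices):
                for s in snps:
                    out.append((self.snp_ids[s], gene_id, c))
        return out

    def write_edge_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("snp_id\tgene_id\tchrom\n")
            for snp, gene, c in self.edges():
                fh.write(f"{snp}\t{gene}\t{c}\n")


def encode(
    geno_variants_or_dataset,
    selected: SelectionResult | list[str],
    mode: str = "two_dim",
) -> EncodedGenotypes:
    """Encode selected SNPs of a genotype dataset.

    two_dim: alt count k -> (2-k, k); MISSING -> (0, 0).
    additive: alt count k -> (k,); MISSING -> (0,).
    """
    if mode not in ("two_dim", "additive"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    ds = geno_variants_or_dataset
    ids = selected.selected_variant_ids if isinstance(selected, SelectionResult) else list(selected)
    index = ds.variant_index()
    missing_ids = [i for i in ids if i not in index]
    if missing_ids:
        raise KeyError(f"selected SNPs absent from dataset: {missing_ids[:5]}")
    counts = ds.alt_counts[:, [index[i] for i in ids]]
    observed = counts != MISSING
    k = np.where(observed, counts, 0).astype(np.float32)
    if mode == "two_dim":
        ref = np.where(observed, 2 - counts, 0).astype(np.float32)
        tensor = np.stack([ref, k], axis=2)
    else:
        tensor = np.where(observed, counts, 0).astype(np.float32)[:, :, None]
    return EncodedGenotypes(tensor=tensor, snp_ids=ids, mode=mode)


def build_connectivity(
    selected: SelectionResult | list[str],
    variants: list[Variant],
    genes: GeneAnnotationTable,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> ConnectivityMap:
    """Map each selected SNP to nearby genes; order genes per chromosome.

    A SNP-gene edge exists when the SNP position lies in
    [gene start - window, gene end + window]; a SNP with no such gene gets a
    single edge to its nearest gene (distance to the closer interval edge,
    equidistant ties broken by lexicographically smaller gene_id).  Genes that
    end with no SNPs are dropped, so the BiLSTM sequence covers only
    SNP-bearing genes.
    """
    ids = selected.selected_variant_ids if isinstance(selected, SelectionResult) else list(selected)
    by_id = {v.id: v for v in variants}
    snps = [by_id[i] for i in ids]
    snps_sorted = sorted(range(len(snps)), key=lambda k: (snps[k].chrom, snps[k].pos, snps[k].id))
    snp_order = [ids[k] for k in snps_sorted]
    snps = [snps[k] for k in snps_sorted]

    chroms_with_snps = sorted({v.chrom for v in snps})
    groups: dict[int, GeneGroup] = {}
    n_fallback = 0
    for c in chroms_with_snps:
        gdf = genes.on_chrom(c)
        if gdf.empty:
            raise ValueError(
                f"chromosome {c} has selected SNPs but no gene annotation; "
                "extend the gene annotation to cover it"
            )
        recs = sorted(gdf.itertuples(index=False), key=lambda r: (r.start, r.gene_id))
        gene_snps: dict[str, list[int]] = {r.gene_id: [] for r in recs}
        for s_idx, v in enumerate(snps):
            if v.chrom != c:
                continue
            hits = [
                r.gene_id
                for r in recs
                if r.start - window_bp <= v.pos <= r.end + window_bp
            ]
            if not hits:
                def dist(r):
                    if r.start <= v.pos <= r.end:
                        return 0
                    return min(abs(v.pos - r.start), abs(v.pos - r.end))
                best = min(recs, key=lambda r: (dist(r), r.gene_id))
                hits = [best.gene_id]
                n_fallback += 1
            for gid in hits:
                gene_snps[gid].append(s_idx)
        kept = [r for r in recs if gene_snps[r.gene_id]]
        groups[c] = GeneGroup(
            chrom=c,
            gene_ids=[r.gene_id for r in kept],
            gene_starts=[int(r.start) for r in kept],
            snp_indices=[gene_snps[r.gene_id] for r in kept],
        )
    if n_fallback:
        logger.info("build_connectivity: %d SNPs linked via nearest-gene fallback", n_fallback)
    cm = ConnectivityMap(snp_ids=snp_order, groups=groups)
    assert cm.n_edges >= cm.n_snps  # every SNP has at least one edge
    return cm
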