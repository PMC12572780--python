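"""Haplotype-diagnostic SNP extraction and candidate-gene ranking.

A diagnostic SNP is heterozygous in every AB individual and fixed for
opposite homozygous alleles between the AA and BB individuals (per-site
Weir-Cockerham theta of exactly 1). Counting such SNPs inside the coding
sequence of each gene (one longest isoform per gene) ranks candidate genes
for the trait the supergene controls.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GeneSet, GenotypeMatrix


def _classes_of(assignment) -> Mapping[str, str]:
    """Accept a GenotypeAssignment or a plain sample->class mapping."""
    return getattr(assignment, "classes", assignment)


def _class_rows(gm: GenotypeMatrix, assignment, label: str) -> list[int]:
    classes = _classes_of(assignment)
    return [gm.sample_index(s) for s, c in classes.items() if c == label]


def ab_het_sites(
    gm: GenotypeMatrix, assignment, region: tuple[str, int, int]
) -> np.ndarray:
    """Indices of region sites where every AB sample is called heterozygous.

    Strict "all": a site with any missing AB call is excluded.
    """
    rows = _class_rows(gm, assignment, "AB")
    if not rows:
        raise ValueError("no AB samples in assignment")
    mask = gm.site_mask(*region)
    sub = gm.calls[rows][:, mask]
    all_het = (sub == 1).all(axis=0)
    return np.flatnonzero(mask)[all_het]


def fixed_diff_sites(
    gm: GenotypeMatrix, assignment, candidate_sites: Sequence[int]
) -> np.ndarray:
    """Subset of candidate sites with opposing fixation between AA and BB.

    Keeps sites where all non-missing AA calls are one homozygote, all
    non-missing BB calls are the opposite homozygote, and each group has at
    least one non-missing call — equivalent to per-site theta = 1.
    """
    candidate_sites = np.asarray(candidate_sites, dtype=int)
    if candidate_sites.size == 0:
        raise ValueError("empty candidate site set")
    aa = gm.calls[_class_rows(gm, assignment, "AA")][:, candidate_sites]
    bb = gm.calls[_class_rows(gm, assignment, "BB")][:, candidate_sites]
    if aa.shape[0] == 0 or bb.shape[0] == 0:
        raise ValueError("need >= 1 AA and >= 1 BB sample")

    def fixed_for(group, value):
        called = group != MISSING
        return called.any(axis=0) & ((group == value) | ~called).all(axis=0)

    keep = (fixed_for(aa, 0) & fixed_for(bb, 2)) | (
        fixed_for(aa, 2) & fixed_for(bb, 0)
    )
    return candidate_sites[keep]


def cds_diagnostic_counts(
    gm: GenotypeMatrix, sites: Sequence[int], gene_set: GeneSet
) -> pd.DataFrame:
    """Per-gene counts of diagnostic SNPs inside the kept isoform's CDS.

    ``gene_set`` must already be reduced to one isoform per gene. A site is
    counted for every gene whose CDS contains its position (1-based
    inclusive boundaries). Genes are returned in genomic order with columns
    gene_id, chrom, start, n_diagnostic.
    """
    sites = np.asarray(sites, dtype=int)
    chroms = gm.sites["chrom"].to_numpy()[sites] if sites.size else np.array([])
    pos = gm.sites["pos"].to_numpy()[sites] if sites.size else np.array([])
    rows = []
    for gene in gene_set:
        if len(gene.transcripts) > 1:
            raise ValueError(
                f"gene {gene.gene_id} has multiple isoforms; reduce with "
                "longest_isoform first"
            )
        n = 0
        gene_start = None
        for tx in gene.transcripts:
            for s, e in tx.cds:
                gene_start = s if gene_start is None else min(gene_start, s)
                if sites.size:
                    n += int(
                        np.sum((chroms == gene.chrom) & (pos >= s) & (pos <= e))
                    )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "start": gene_start if gene_start is not None else -1,
                "n_diagnostic": n,
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["chrom", "start", "gene_id"], kind="stable"
    ).reset_index(drop=True)


def rank_candidate_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Order genes by descending diagnostic-SNP count; ties by genomic
    position, then gene id."""
    return counts.sort_values(
        ["n_diagnostic", "chrom", "start", "gene_id"],
        ascending=[False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)


def diagnostic_site_table(
    gm: GenotypeMatrix,
    ab_idx: np.ndarray,
    fixed_idx: np.ndarray,
    gene_set: GeneSet | None = None,
) -> pd.DataFrame:
    """Flat table of diagnostic sites with flags and (optionally) gene ids."""
    fixed = set(int(i) for i in fixed_idx)
    table = gm.sites.iloc[ab_idx][["chrom", "pos", "ref", "alt"]].copy()
    table["site_index"] = np.asarray(ab_idx, dtype=int)
    table["ab_all_het"] = True
    table["fixed_opposite"] = [int(i) in fixed for i in ab_idx]
    if gene_set is not None:
        gene_ids = []
        for _, row in table.iterrows():
            hits = [
                g.gene_id
                for g in gene_set
                for tx in g.transcripts
                for s, e in tx.cds
                if g.chrom == row["chrom"] and s <= row["pos"] <= e
            ]
            gene_ids.append(",".join(hits))
        table["gene_id"] = gene_ids
    return table.reset_index(drop=True)
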