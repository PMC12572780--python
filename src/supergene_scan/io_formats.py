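"""Readers, writers, and variant filters for the formats the pipeline touches.

All genomic coordinates are 1-based inclusive internally, matching VCF and
GFF3; half-open conversion happens only at analysis boundaries. Genotype
calls are stored as small integers: 0 = hom-ref (0/0), 1 = het (0/1),
2 = hom-alt (1/1), and :data:`MISSING` (-1) for anything unparseable.
Missingness is a first-class call state; nothing at the I/O layer imputes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled / unparseable genotype.
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]

_NUCLEOTIDES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed (malformed header, no samples)."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP-sites genotype calls.

    Attributes
    ----------
    sample_ids:
        Sample identifiers, in file order.
    sites:
        DataFrame with columns chrom, pos (1-based), ref, alt, qual;
        positions strictly increasing within each chromosome.
    calls:
        int8 array of shape (n_samples, n_sites) with values
        {0, 1, 2, MISSING}.
    depths:
        Optional int array of per-call read depths, same shape as calls;
        -1 where depth was not reported.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    depths: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.calls.shape:
                raise ValueError("depths shape does not match calls")
        for chrom, group in self.sites.groupby("chrom", sort=False):
            pos = group["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"site positions not strictly increasing on {chrom}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
            depths=None if self.depths is None else self.depths[:, index],
        )

    def site_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites on ``chrom`` with start <= pos <= end."""
        return (
            (self.sites["chrom"] == chrom)
            & (self.sites["pos"] >= start)
            & (self.sites["pos"] <= end)
        ).to_numpy()


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    cds: tuple[tuple[int, int], ...]  # 1-based closed intervals, sorted

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]


@dataclass
class GeneSet:
    """Genes with transcripts and their CDS intervals."""

    genes: list[Gene]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept (multi-allelic sites and indels are
    dropped, with a logged count). Unparseable genotypes become
    :data:`MISSING`. Record order is preserved.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise VcfFormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"VCF {path} declares zero samples")

    rows, call_rows, depth_rows = [], [], []
    n_dropped = 0
    any_depth = False
    for variant in vcf:
        if (
            len(variant.ALT) != 1
            or len(variant.REF) != 1
            or len(variant.ALT[0]) != 1
            or variant.REF.upper() not in _NUCLEOTIDES
            or variant.ALT[0].upper() not in _NUCLEOTIDES
        ):
            n_dropped += 1
            continue
        rows.append(
            (
                variant.CHROM,
                variant.POS,
                variant.REF.upper(),
                variant.ALT[0].upper(),
                np.nan if variant.QUAL is None else float(variant.QUAL),
            )
        )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types
        call = np.where(
            gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING))
        ).astype(np.int8)
        call_rows.append(call)
        try:
            dp = variant.format("DP")
        except KeyError:  # no DP in the FORMAT header
            dp = None
        if dp is not None:
            dp = dp.reshape(-1).astype(np.int64)
            dp[dp < 0] = -1  # htslib encodes missing as INT32_MIN
            any_depth = True
        depth_rows.append(dp if dp is not None else np.full(len(samples), -1))
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    n_sites = len(sites)
    calls = (
        np.stack(call_rows, axis=1)
        if n_sites
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    depths = None
    if any_depth and n_sites:
        depths = np.stack(depth_rows, axis=1).astype(np.int32)
    return GenotypeMatrix(sample_ids=samples, sites=sites, calls=calls, depths=depths)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=supergene-scan\n")
        for chrom, group in gm.sites.groupby("chrom", sort=False):
            length = int(group["pos"].max()) + 1 if len(group) else 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        fmt = "GT:DP" if gm.depths is not None else "GT"
        sites = gm.sites.itertuples(index=True)
        for row in sites:
            j = row.Index
            qual = "." if pd.isna(row.qual) else f"{row.qual:g}"
            fields = [row.chrom, str(row.pos), ".", row.ref, row.alt, qual, "PASS", ".", fmt]
            for i in range(gm.n_samples):
                gt = _GT_STRINGS[int(gm.calls[i, j])]
                if gm.depths is not None:
                    dp = int(gm.depths[i, j])
                    gt = f"{gt}:{dp if dp >= 0 else '.'}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def filter_variants(
    gm: GenotypeMatrix,
    min_site_quality: float = 20.0,
    min_depth: int = 3,
    max_missing_frac: float = 0.6,
) -> GenotypeMatrix:
    """Apply site-quality, per-call depth, and missingness filters.

    Semantics mirror vcftools ``--minQ/--minDP/--max-missing``: calls with
    depth below ``min_depth`` are masked to MISSING first, then sites with
    quality below ``min_site_quality`` are dropped, then sites whose called
    fraction falls below ``max_missing_frac`` are dropped (``0.6`` keeps
    sites with at least 60% of genotypes called). Idempotent.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError(f"max_missing_frac must be in [0,1], got {max_missing_frac}")
    if min_site_quality < 0 or min_depth < 0:
        raise ValueError("thresholds must be non-negative")

    calls = gm.calls.copy()
    depths = gm.depths
    if depths is not None and min_depth > 0:
        calls[(depths >= 0) & (depths < min_depth)] = MISSING

    qual = gm.sites["qual"].to_numpy(dtype=float)
    keep = ~(qual < min_site_quality)  # NaN quality passes (no annotation)
    called_frac = (calls != MISSING).mean(axis=0)
    keep &= called_frac >= max_missing_frac

    index = np.flatnonzero(keep)
    out = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        sites=gm.sites.iloc[index].reset_index(drop=True),
        calls=calls[:, index],
        depths=None if depths is None else depths[:, index],
    )
    logger.info(
        "filter_variants: kept %d/%d sites", out.n_sites, gm.n_sites
    )
    return out


class GffStructureError(ValueError):
    """Raised when CDS/transcript parent links are broken."""


def read_gff3(path: str | os.PathLike) -> GeneSet:
    """Read gene -> mRNA -> CDS structure from a GFF3 file."""
    import gffutils

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    tx_by_gene: dict[str, list] = {}
    gene_meta: dict[str, tuple[str, str]] = {}
    for gene in db.features_of_type("gene"):
        gene_meta[gene.id] = (gene.seqid, gene.strand)
        tx_by_gene[gene.id] = []
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in tx_by_gene:
            raise GffStructureError(f"transcript {mrna.id} has no parent gene")
        cds_intervals = sorted(
            (c.start, c.end) for c in db.children(mrna, featuretype="CDS")
        )
        tx_by_gene[parents[0]].append(
            Transcript(transcript_id=mrna.id, cds=tuple(cds_intervals))
        )
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents:
            raise GffStructureError(f"CDS at {cds.seqid}:{cds.start} has no parent")
    genes = [
        Gene(
            gene_id=gid,
            chrom=gene_meta[gid][0],
            strand=gene_meta[gid][1],
            transcripts=tuple(tx_by_gene[gid]),
        )
        for gid in gene_meta
    ]
    return GeneSet(genes=genes)


def longest_isoform(gs: GeneSet) -> GeneSet:
    """Keep exactly one transcript per gene: the one with the largest summed
    CDS length, ties broken by lexicographically smallest transcript id."""
    genes = []
    for gene in gs:
        if not gene.transcripts:
            genes.append(gene)
            continue
        best = min(
            gene.transcripts, key=lambda t: (-t.cds_length, t.transcript_id)
        )
        genes.append(replace(gene, transcripts=(best,)))
    return GeneSet(genes=genes)


REQUIRED_SAMPLE_COLUMNS = ["sample_id", "colony_id", "caste", "queen_count"]


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-sample phenotype/colony TSV.

    Required columns: sample_id, colony_id, caste, queen_count; optional:
    head_width_mm, genotype_class. Head widths must be positive numbers,
    sample ids unique, and queen_count consistent within a colony.
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "colony_id": str})
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sample table missing required column(s): {missing}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample id: {dup}")
    if "head_width_mm" in table.columns:
        widths = pd.to_numeric(table["head_width_mm"], errors="raise")
        if (widths.dropna() <= 0).any():
            raise ValueError("head_width_mm must be positive")
        table["head_width_mm"] = widths
    counts = table.groupby("colony_id")["queen_count"].nunique()
    if (counts > 1).any():
        bad = counts[counts > 1].index[0]
        raise ValueError(f"inconsistent queen_count within colony {bad}")
    return table


def write_samples(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_window_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a window-statistics table as TSV.

    Expects chrom, start, end (1-based inclusive) plus statistic columns;
    floats are written with 6 significant digits.
    """
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_window_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
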