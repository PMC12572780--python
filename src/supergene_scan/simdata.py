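"""Seeded synthetic datasets with a planted non-recombining supergene.

The generator emulates the downstream data of a queen-size-dimorphic ant
study at desk scale: a small diploid genome of founder-mosaic haplotypes,
one chromosome carrying a divergent haplotype block with two non-recombining
haplotype pools (A and B) and three genotype classes (AA/AB/BB), per-class
queen head-width distributions, monogyne/polygyne colony structure with
haplodiploid inheritance, and multi-locus microsatellite worker genotypes.
Every planted feature is recorded in a :class:`SimTruth` object so each
downstream pipeline stage has a ground-truth oracle.

Background haplotypes are mosaics of a founder pool with copy-switches at a
configurable per-bp rate, which produces linkage disequilibrium that decays
with distance. Inside the supergene interval haplotypes come from one of two
pools with no exchange between pools; a fraction ``fixed_diff_fraction`` of
interval SNPs is fixed 0-vs-1 between pools and the rest are shared
polymorphisms drawn from a common ancestral frequency per site. The
within-interval, within-pool switch rate defaults to 0 because suppressed
recombination is the defining property of such a region; it is exposed in
the config.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import MISSING, GeneSet, GenotypeMatrix, write_vcf

CLASSES = ("AA", "AB", "BB")


@dataclass
class SimConfig:
    """All knobs of the synthetic dataset; defaults are the study conditions.

    Distances are bp, widths mm. ``class_freqs`` are the cohort frequencies
    of the AA/AB/BB supergene genotypes; ``pheno_mean_mm`` are per-class
    head-width means with common sd ``pheno_sd_mm``, matching the reported
    per-class medians of 1.20/1.05/0.98 mm.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 10_000_000
    snp_density: float = 1.0 / 500.0
    supergene_chrom: int = 0  # index into chromosomes (name "chr1")
    supergene_start: int = 2_000_000
    supergene_end: int = 4_700_000
    fixed_diff_fraction: float = 0.5
    n_founders: int = 8  # founders per pool (background and each of A/B)
    switch_rate: float = 1e-6  # background copy-switch rate per bp
    supergene_switch_rate: float = 0.0  # within-pool rate inside the interval
    shared_freq_beta: float = 0.8  # Beta(a,a) base frequency of polymorphisms
    n_samples: int = 60
    class_freqs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    pheno_mean_mm: tuple[float, float, float] = (1.20, 1.05, 0.98)  # AA, AB, BB
    pheno_sd_mm: float = 0.03
    site_quality: float = 60.0
    # colony plan
    n_monogyne: int = 20
    n_polygyne: int = 10
    polygyne_extra_queens_mean: float = 1.2  # queens per colony = 2 + Poisson
    serial_polygyny_prob: float = 0.15
    workers_per_colony: int = 10
    male_b_haplotype_freq: float = 0.5  # supergene haplotype of haploid fathers
    # microsatellites
    n_microsat_loci: int = 5
    n_microsat_alleles: int = 8
    dropout_rate: float = 0.0
    false_allele_rate: float = 0.0
    # gene annotation
    gene_tile_bp: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fixed_diff_fraction <= 1.0):
            raise ValueError("fixed_diff_fraction must be in (0, 1]")
        if not (
            1 <= self.supergene_start < self.supergene_end <= self.chromosome_length
        ):
            raise ValueError("supergene interval must lie inside the chromosome")
        if not 0 <= self.supergene_chrom < self.n_chromosomes:
            raise ValueError("supergene_chrom out of range")
        if abs(sum(self.class_freqs) - 1.0) > 1e-9:
            raise ValueError("class_freqs must sum to 1")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def supergene_chrom_name(self) -> str:
        return self.chrom_names[self.supergene_chrom]


# site categories
BACKGROUND, FIXED_DIFF, SHARED_POLY = "background", "fixed-difference", "shared-polymorphic"


@dataclass
class HaplotypePool:
    """Founder haplotypes plus the site map they are defined on."""

    chrom_names: list[str]
    positions: dict[str, np.ndarray]  # 1-based, strictly increasing
    ref: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]
    category: dict[str, np.ndarray]  # per-site category strings
    founders_bg: dict[str, np.ndarray]  # (n_founders, n_sites) 0/1
    pool_a: np.ndarray  # (n_founders, n_interval_sites)
    pool_b: np.ndarray
    interval_index: np.ndarray  # site indices (on supergene chrom) in interval

    def n_sites(self, chrom: str) -> int:
        return len(self.positions[chrom])


def _draw_positions(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    n = int(round(cfg.chromosome_length * cfg.snp_density))
    pos = rng.choice(np.arange(1, cfg.chromosome_length + 1), size=n, replace=False)
    return np.sort(pos)


def _mosaic_indices(
    rng: np.random.Generator, positions: np.ndarray, rate: float, n_founders: int
) -> np.ndarray:
    """Founder index per site for one mosaic haplotype."""
    n = len(positions)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if rate <= 0:
        return np.full(n, rng.integers(n_founders))
    gaps = np.diff(positions)
    switch = rng.random(n - 1) < -np.expm1(-rate * gaps)
    seg = np.concatenate(([0], np.cumsum(switch)))
    choices = rng.integers(0, n_founders, size=seg[-1] + 1)
    return choices[seg]


def simulate_haplotypes(cfg: SimConfig, seed: Optional[int] = None) -> HaplotypePool:
    """Build the founder pools and the site map.

    Background sites: per-site ancestral frequency ~ Beta(a, a); founder
    alleles Bernoulli draws. Supergene interval: a fraction
    ``fixed_diff_fraction`` of sites is fixed ref-vs-alt between pools A and
    B (A carries the reference allele); the remainder are shared
    polymorphisms where both pools draw founders from a common frequency.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    a = cfg.shared_freq_beta
    positions, refs, alts, cats, founders = {}, {}, {}, {}, {}
    pool_a = pool_b = None
    interval_index = np.empty(0, dtype=np.int64)
    nt = np.array(list("ACGT"))
    for ci, chrom in enumerate(cfg.chrom_names):
        pos = _draw_positions(rng, cfg)
        n = len(pos)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        freq = rng.beta(a, a, size=n)
        fdr = rng.random((cfg.n_founders, n)) < freq
        cat = np.full(n, BACKGROUND, dtype=object)
        if ci == cfg.supergene_chrom:
            inside = (pos >= cfg.supergene_start) & (pos <= cfg.supergene_end)
            interval_index = np.flatnonzero(inside)
            n_in = len(interval_index)
            if n_in == 0:
                raise ValueError("supergene interval contains zero SNPs")
            is_fixed = rng.random(n_in) < cfg.fixed_diff_fraction
            cat[interval_index[is_fixed]] = FIXED_DIFF
            cat[interval_index[~is_fixed]] = SHARED_POLY
            pool_a = np.zeros((cfg.n_founders, n_in), dtype=bool)
            pool_b = np.zeros((cfg.n_founders, n_in), dtype=bool)
            pool_b[:, is_fixed] = True  # A = ref, B = alt at fixed sites
            shared = ~is_fixed
            base = rng.beta(a, a, size=int(shared.sum()))
            pool_a[:, shared] = rng.random((cfg.n_founders, len(base))) < base
            pool_b[:, shared] = rng.random((cfg.n_founders, len(base))) < base
        positions[chrom] = pos
        refs[chrom] = nt[ref_idx]
        alts[chrom] = nt[alt_idx]
        cats[chrom] = cat
        founders[chrom] = fdr
    return HaplotypePool(
        chrom_names=cfg.chrom_names,
        positions=positions,
        ref=refs,
        alt=alts,
        category=cats,
        founders_bg=founders,
        pool_a=pool_a,
        pool_b=pool_b,
        interval_index=interval_index,
    )


def _draw_haplotype(
    rng: np.random.Generator, cfg: SimConfig, pool: HaplotypePool, chrom: str,
    supergene_pool: Optional[str],
) -> np.ndarray:
    """One haploid chromosome: background mosaic, with the supergene interval
    (when this is the supergene chromosome) copied from pool A or B."""
    pos = pool.positions[chrom]
    idx = _mosaic_indices(rng, pos, cfg.switch_rate, cfg.n_founders)
    hap = pool.founders_bg[chrom][idx, np.arange(len(pos))].copy()
    if supergene_pool is not None and chrom == cfg.supergene_chrom_name:
        ii = pool.interval_index
        src = pool.pool_a if supergene_pool == "A" else pool.pool_b
        sub_idx = _mosaic_indices(
            rng, pos[ii], cfg.supergene_switch_rate, cfg.n_founders
        )
        hap[ii] = src[sub_idx, np.arange(len(ii))]
    return hap


@dataclass
class SimTruth:
    """Ground truth for every planted structure; the oracle for all stages."""

    supergene: tuple[str, int, int]  # chrom, start, end (1-based inclusive)
    classes: dict[str, str]  # sample id -> AA/AB/BB
    site_category: list[str]  # aligned with GenotypeMatrix.sites rows
    colonies: dict[str, dict] = field(default_factory=dict)
    workers: list[dict] = field(default_factory=list)
    gene_truth: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["supergene"] = tuple(d["supergene"])
        return cls(**d)


def _quota_classes(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Largest-remainder quota of class frequencies, then a seeded shuffle,
    so the default 1/3-1/3-1/3 cohort is exactly balanced."""
    n = cfg.n_samples
    raw = np.array(cfg.class_freqs) * n
    counts = np.floor(raw).astype(int)
    for k in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[k] += 1
    labels = np.repeat(np.array(CLASSES), counts)
    return rng.permutation(labels)


_POOLS_OF_CLASS = {"AA": ("A", "A"), "AB": ("A", "B"), "BB": ("B", "B")}


def simulate_cohort(
    cfg: SimConfig, seed: Optional[int] = None
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Simulate the sequenced queen/gyne cohort.

    Per sample: a genotype class drawn by quota from ``class_freqs``, two
    haplotypes per chromosome (the supergene interval copied from pool A
    and/or B according to class), and a head width ~ Normal(class mean, sd)
    truncated at 0 and reported to 0.01 mm.
    """
    base = np.random.SeedSequence(cfg.seed if seed is None else seed)
    hap_seed, cohort_seed = [s.generate_state(1)[0] % (2**31) for s in base.spawn(2)]
    pool = simulate_haplotypes(cfg, seed=int(hap_seed))
    rng = np.random.default_rng(int(cohort_seed))

    classes = _quota_classes(rng, cfg)
    width = len(str(cfg.n_samples))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(cfg.n_samples)]

    calls_per_chrom = []
    for chrom in cfg.chrom_names:
        n = pool.n_sites(chrom)
        dosage = np.zeros((cfg.n_samples, n), dtype=np.int8)
        for i, cls in enumerate(classes):
            for p in _POOLS_OF_CLASS[cls]:
                dosage[i] += _draw_haplotype(rng, cfg, pool, chrom, p)
        calls_per_chrom.append(dosage)
    calls = np.concatenate(calls_per_chrom, axis=1)

    sites = pd.DataFrame(
        {
            "chrom": np.concatenate(
                [[c] * pool.n_sites(c) for c in cfg.chrom_names]
            ),
            "pos": np.concatenate([pool.positions[c] for c in cfg.chrom_names]),
            "ref": np.concatenate([pool.ref[c] for c in cfg.chrom_names]),
            "alt": np.concatenate([pool.alt[c] for c in cfg.chrom_names]),
            "qual": cfg.site_quality,
        }
    )
    gm = GenotypeMatrix(sample_ids=sample_ids, sites=sites, calls=calls)

    means = dict(zip(CLASSES, cfg.pheno_mean_mm))
    widths = np.array(
        [max(rng.normal(means[c], cfg.pheno_sd_mm), 0.01) for c in classes]
    ).round(2)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "head_width_mm": widths,
            "colony_id": "",
            "caste": "queen",
            "queen_count": 1,
        }
    )
    truth = SimTruth(
        supergene=(cfg.supergene_chrom_name, cfg.supergene_start, cfg.supergene_end),
        classes=dict(zip(sample_ids, classes)),
        site_category=list(
            np.concatenate([pool.category[c] for c in cfg.chrom_names])
        ),
    )
    return gm, samples, truth


def _polygyne_queen_counts(
    rng: np.random.Generator, cfg: SimConfig, available: int
) -> np.ndarray:
    """Queens per polygyne colony: 2 + Poisson, truncated so the cohort's
    non-AA queens suffice (largest colonies shrunk first)."""
    if 2 * cfg.n_polygyne > available:
        raise ValueError(
            f"colony plan needs {2 * cfg.n_polygyne} non-AA queens, "
            f"only {available} simulated"
        )
    k = 2 + rng.poisson(cfg.polygyne_extra_queens_mean, size=cfg.n_polygyne)
    while k.sum() > available:
        k[np.argmax(k)] -= 1
    return k


def simulate_colonies(
    cfg: SimConfig,
    samples: pd.DataFrame,
    truth: SimTruth,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Assign cohort queens to colonies and simulate worker pedigrees.

    Monogyne colonies hold one AA queen; with probability
    ``serial_polygyny_prob`` an earlier (replaced) AA mother also contributed
    workers, giving a second matriline. Polygyne colonies hold k >= 2 AB/BB
    queens, each worker drawn from a uniformly chosen resident queen. All
    mothers are singly mated; fathers are haploid, their supergene haplotype
    drawn B with probability ``male_b_haplotype_freq``. Returns the updated
    sample table, a worker table, and the truth extended with colony and
    per-worker matriline records. Mutates ``samples``/``truth`` copies only.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    samples = samples.copy()
    truth = dataclasses.replace(
        truth, colonies=dict(truth.colonies), workers=list(truth.workers)
    )
    ids = samples["sample_id"].to_numpy()
    cls = np.array([truth.classes[s] for s in ids])
    aa_ids = rng.permutation(ids[cls == "AA"])
    non_aa_ids = list(rng.permutation(ids[cls != "AA"]))
    if cfg.n_monogyne > len(aa_ids):
        raise ValueError(
            f"colony plan requests {cfg.n_monogyne} AA queens, "
            f"only {len(aa_ids)} simulated"
        )
    k_poly = _polygyne_queen_counts(rng, cfg, len(non_aa_ids))

    colony_of = {}
    worker_rows = []

    def _add_workers(colony_id, mothers, mother_classes, shares):
        """mothers: matriline labels; shares: worker counts per mother."""
        fathers = {
            m: ("B" if rng.random() < cfg.male_b_haplotype_freq else "A")
            for m in mothers
        }
        w = 0
        for m, m_cls, n_w in zip(mothers, mother_classes, shares):
            m_haps = _POOLS_OF_CLASS[m_cls]
            for _ in range(n_w):
                w += 1
                maternal = m_haps[rng.integers(2)]
                worker_class = "".join(sorted(maternal + fathers[m]))
                worker_rows.append(
                    {
                        "worker_id": f"{colony_id}_W{w:02d}",
                        "colony_id": colony_id,
                        "matriline_id": m,
                        "mother_class": m_cls,
                        "father_haplotype": fathers[m],
                        "worker_class": worker_class,
                    }
                )

    for i in range(cfg.n_monogyne):
        colony_id = f"M{i + 1:02d}"
        queen = aa_ids[i]
        colony_of[queen] = colony_id
        serial = rng.random() < cfg.serial_polygyny_prob
        if serial:
            n_old = int(rng.integers(1, cfg.workers_per_colony // 2 + 1))
            mothers = [queen, f"{colony_id}_Qold"]
            mother_classes = ["AA", "AA"]
            shares = [cfg.workers_per_colony - n_old, n_old]
        else:
            mothers, mother_classes = [queen], ["AA"]
            shares = [cfg.workers_per_colony]
        _add_workers(colony_id, mothers, mother_classes, shares)
        truth.colonies[colony_id] = {
            "type": "monogyne",
            "queen_ids": [queen],
            "queen_count": 1,
            "n_matrilines": len(mothers),
        }

    for i, k in enumerate(k_poly):
        colony_id = f"P{i + 1:02d}"
        queens = [non_aa_ids.pop() for _ in range(k)]
        for q in queens:
            colony_of[q] = colony_id
        pick = rng.integers(0, k, size=cfg.workers_per_colony)
        shares = np.bincount(pick, minlength=k)
        contributing = [q for q, s in zip(queens, shares) if s > 0]
        _add_workers(
            colony_id,
            [q for q, s in zip(queens, shares) if s > 0],
            [truth.classes[q] for q, s in zip(queens, shares) if s > 0],
            [int(s) for s in shares if s > 0],
        )
        truth.colonies[colony_id] = {
            "type": "polygyne",
            "queen_ids": queens,
            "queen_count": int(k),
            "n_matrilines": len(contributing),
        }

    samples["colony_id"] = [colony_of.get(s, "") for s in samples["sample_id"]]
    samples["queen_count"] = [
        truth.colonies[c]["queen_count"] if c else 0 for c in samples["colony_id"]
    ]
    samples = samples[samples["colony_id"] != ""].reset_index(drop=True)
    truth.workers.extend(worker_rows)
    workers = pd.DataFrame(worker_rows)[
        ["worker_id", "colony_id", "matriline_id"]
    ]
    return samples, workers, truth


def microsat_allele_freqs(cfg: SimConfig) -> np.ndarray:
    """Configured allele-frequency spectrum per locus (uniform by default)."""
    return np.full(
        (cfg.n_microsat_loci, cfg.n_microsat_alleles), 1.0 / cfg.n_microsat_alleles
    )


def draw_mother_genotype(
    rng: np.random.Generator, freqs: np.ndarray
) -> np.ndarray:
    """Diploid mother genotype: (n_loci, 2) allele indices from the spectrum."""
    n_loci, n_alleles = freqs.shape
    out = np.empty((n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        out[l] = rng.choice(n_alleles, size=2, p=freqs[l])
    return out


def _allele_size(idx: int) -> int:
    return 100 + 2 * idx  # fragment-size-like labels


def simulate_microsatellites(
    cfg: SimConfig, truth: SimTruth, seed: Optional[int] = None
) -> pd.DataFrame:
    """Worker microsatellite genotypes under haplodiploid inheritance.

    Per matriline: a diploid mother and one haploid father drawn from the
    configured allele spectrum; each worker inherits one maternal allele and
    the paternal allele. Allelic dropout converts a heterozygous call to an
    apparent homozygote; a false allele substitutes one allele with a
    different random one.
    """
    if (cfg.dropout_rate > 0 or cfg.false_allele_rate > 0) and cfg.n_microsat_alleles < 2:
        raise ValueError("error rates > 0 require loci with >= 2 alleles")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    freqs = microsat_allele_freqs(cfg)
    n_loci, n_alleles = freqs.shape

    parents: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for w in truth.workers:
        m = w["matriline_id"]
        if m not in parents:
            mother = draw_mother_genotype(rng, freqs)
            father = np.array(
                [rng.choice(n_alleles, p=freqs[l]) for l in range(n_loci)]
            )
            parents[m] = (mother, father)
        mother, father = parents[m]
        row = {"worker_id": w["worker_id"], "colony_id": w["colony_id"]}
        for l in range(n_loci):
            maternal = mother[l, rng.integers(2)]
            pair = [int(maternal), int(father[l])]
            if pair[0] != pair[1] and rng.random() < cfg.dropout_rate:
                pair = [pair[rng.integers(2)]] * 2
            if rng.random() < cfg.false_allele_rate:
                k = rng.integers(2)
                pair[k] = int((pair[k] + rng.integers(1, n_alleles)) % n_alleles)
            a1, a2 = sorted(pair)
            row[f"L{l + 1}_a1"] = _allele_size(a1)
            row[f"L{l + 1}_a2"] = _allele_size(a2)
        rows.append(row)
    return pd.DataFrame(rows)


def _simulate_genes(
    cfg: SimConfig, rng: np.random.Generator
) -> list[dict]:
    """Genes tiled every ``gene_tile_bp``, 1-3 isoforms of 2-5 CDS each."""
    genes = []
    g = 0
    for chrom in cfg.chrom_names:
        for tile in range(0, cfg.chromosome_length - cfg.gene_tile_bp + 1, cfg.gene_tile_bp):
            g += 1
            span_start = tile + 5_000 + 1
            span_end = tile + cfg.gene_tile_bp - 5_000
            gene_id = f"g{g:04d}"
            n_iso = int(rng.integers(1, 4))
            transcripts = []
            for t in range(n_iso):
                n_cds = int(rng.integers(2, 6))
                cuts = np.sort(
                    rng.choice(
                        np.arange(span_start, span_end + 1),
                        size=2 * n_cds,
                        replace=False,
                    )
                )
                cds = [
                    (int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_cds)
                ]
                transcripts.append({"transcript_id": f"{gene_id}.t{t + 1}", "cds": cds})
            genes.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": span_start,
                    "end": span_end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "transcripts": transcripts,
                }
            )
    return genes


def _cds_len(tx: dict) -> int:
    return sum(e - s + 1 for s, e in tx["cds"])


def write_gff3(genes: list[dict], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write(
                f"{gene['chrom']}\tsim\tgene\t{gene['start']}\t{gene['end']}\t.\t"
                f"{gene['strand']}\t.\tID={gene['gene_id']}\n"
            )
            for tx in gene["transcripts"]:
                tid = tx["transcript_id"]
                fh.write(
                    f"{gene['chrom']}\tsim\tmRNA\t{gene['start']}\t{gene['end']}\t.\t"
                    f"{gene['strand']}\t.\tID={tid};Parent={gene['gene_id']}\n"
                )
                for k, (s, e) in enumerate(tx["cds"]):
                    fh.write(
                        f"{gene['chrom']}\tsim\tCDS\t{s}\t{e}\t.\t{gene['strand']}\t0\t"
                        f"ID=cds-{tid}-{k + 1};Parent={tid}\n"
                    )


@dataclass
class SimBundle:
    """One fully simulated dataset plus its ground truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    workers: pd.DataFrame
    microsats: pd.DataFrame
    genes: list[dict]
    truth: SimTruth


def simulate_dataset(cfg: SimConfig, seed: Optional[int] = None) -> SimBundle:
    """Run the full generator: cohort, colonies, microsatellites, annotation.

    All randomness flows from one seed through named substreams, so outputs
    are bit-identical for identical (cfg, seed).
    """
    base = np.random.SeedSequence(cfg.seed if seed is None else seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(4)]
    gm, samples, truth = simulate_cohort(cfg, seed=seeds[0])
    samples, workers, truth = simulate_colonies(cfg, samples, truth, seed=seeds[1])
    microsats = simulate_microsatellites(cfg, truth, seed=seeds[2])
    genes = _simulate_genes(cfg, np.random.default_rng(seeds[3]))
    truth.gene_truth = _gene_truth(cfg, gm, truth, genes)
    return SimBundle(cfg, gm, samples, workers, microsats, genes, truth)


def _gene_truth(cfg, gm, truth, genes) -> dict[str, dict]:
    """Independent per-gene tally of planted fixed differences inside the
    longest isoform's CDS (the oracle for the diagnostic-SNP stage)."""
    cat = np.array(truth.site_category)
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    fixed = cat == FIXED_DIFF
    out = {}
    for gene in genes:
        best = min(gene["transcripts"], key=lambda t: (-_cds_len(t), t["transcript_id"]))
        n = 0
        for s, e in best["cds"]:
            n += int(
                np.sum(fixed & (chrom == gene["chrom"]) & (pos >= s) & (pos <= e))
            )
        out[gene["gene_id"]] = {
            "longest_transcript": best["transcript_id"],
            "n_fixed_cds": n,
        }
    return out


def write_bundle(bundle: SimBundle, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the bundle as plain-text files (VCF, GFF3, TSVs, truth JSON)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "workers": os.path.join(outdir, "workers.tsv"),
        "microsats": os.path.join(outdir, "microsats.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(bundle.genotypes, paths["vcf"])
    write_gff3(bundle.genes, paths["gff3"])
    bundle.samples.to_csv(paths["samples"], sep="\t", index=False)
    bundle.workers.to_csv(paths["workers"], sep="\t", index=False)
    bundle.microsats.to_csv(paths["microsats"], sep="\t", index=False)
    bundle.truth.to_json(paths["truth"])
    return paths
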