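"""Core population-genetic statistics.

Weir & Cockerham (1984) variance-components FST (per site and in windows,
both ratio-of-sums and mean-of-ratios), per-sample observed heterozygosity,
composite (genotype-dosage) LD r-squared with distance-binned decay, and the
Kimura two-parameter nucleotide distance.

The FST estimator is the one the common VCF tooling computes: per-site
variance components a (among populations), b (among individuals within
populations) and c (within individuals), with theta = a / (a + b + c).
Negative estimates are reported, not clamped. The windowed "weighted" value
is the ratio of sums over sites, the scan statistic throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

Region = tuple[str, int, int]  # chrom, start, end; 1-based inclusive


class FstComponents(NamedTuple):
    a: float  # among-population variance component
    b: float  # among individuals within populations
    c: float  # within individuals
    theta: float  # a / (a + b + c); NaN when undefined


def _group_site_stats(calls: np.ndarray, group_rows: Sequence[np.ndarray]):
    """Per-population called counts, alt-allele and heterozygote frequencies.

    calls: (n_samples, n_sites); returns arrays of shape (r, n_sites).
    """
    n, p, h = [], [], []
    for rows in group_rows:
        sub = calls[rows]
        called = (sub != MISSING).sum(axis=0).astype(float)
        het = (sub == 1).sum(axis=0).astype(float)
        alt2 = (sub == 2).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p.append((het + 2.0 * alt2) / (2.0 * called))
            h.append(het / called)
        n.append(called)
    return np.array(n), np.array(p), np.array(h)


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Vectorized Weir-Cockerham components from per-pop (r, n_sites) arrays.

    Sites where any population has zero called genotypes, or where the total
    denominator is zero (monomorphic), come out NaN.
    """
    r = n.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / denom, np.nan)
    bad = (n == 0).any(axis=0)
    for arr in (a, b, c, theta):
        arr[bad] = np.nan
    return a, b, c, theta


def wc_fst_site(genotype_counts: Sequence[Sequence[int]]) -> FstComponents:
    """Weir-Cockerham components at one site from per-population genotype
    counts (n_hom_ref, n_het, n_hom_alt) per row.

    Raises if fewer than two populations or any population has zero called
    genotypes. A site monomorphic across all populations yields theta NaN.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("expected (r, 3) genotype counts")
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 populations")
    n = counts.sum(axis=1)
    if (n == 0).any():
        raise ValueError("a population has zero called genotypes")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n)
        h = counts[:, 1] / n
    a, b, c, theta = _wc_components(n[:, None], p[:, None], h[:, None])
    return FstComponents(float(a[0]), float(b[0]), float(c[0]), float(theta[0]))


@dataclass(frozen=True)
class WindowStat:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_sites: int
    fst_weighted: float  # ratio of sums (NaN when no informative site)
    fst_mean: float  # mean of per-site ratios


def windowed_fst(
    gm: GenotypeMatrix,
    groups: dict[str, str] | pd.Series,
    window_size: int = 10_000,
    step: Optional[int] = None,
) -> list[WindowStat]:
    """Weir-Cockerham FST in windows tiling each chromosome.

    ``groups`` maps sample id to population label; samples without a label
    are ignored. Windows are [start, start+window_size-1] from position 1 up
    to the last site; the weighted value is sum(a)/sum(a+b+c) over
    informative sites in the window (the vcftools "weighted" semantics).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    step = window_size if step is None else step
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    unknown = set(groups) - set(gm.sample_ids)
    if unknown:
        raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    group_rows = [
        np.array([gm.sample_index(s) for s, g in sorted(groups.items()) if g == lab])
        for lab in labels
    ]
    n, p, h = _group_site_stats(gm.calls, group_rows)
    a, b, c, theta = _wc_components(n, p, h)
    denom = a + b + c

    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    out: list[WindowStat] = []
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        cpos, ca, cd, ctheta = pos[on], a[on], denom[on], theta[on]
        last = int(cpos.max())
        for start in range(1, last + 1, step):
            end = start + window_size - 1
            sel = (cpos >= start) & (cpos <= end)
            ok = sel & np.isfinite(cd) & (cd != 0)
            n_sites = int(sel.sum())
            if ok.any():
                weighted = float(ca[ok].sum() / cd[ok].sum())
                mean = float(np.nanmean(ctheta[ok]))
            else:
                weighted = mean = float("nan")
            out.append(WindowStat(str(chrom), start, end, n_sites, weighted, mean))
    return out


def windows_to_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


def fst_percentile_threshold(stats: Sequence[WindowStat], pct: float = 95.0) -> float:
    """Empirical pct-quantile (linear interpolation between order statistics)
    of the finite windowed FST values, genome-wide."""
    if not 0.0 < pct < 100.0:
        raise ValueError("pct must be in (0, 100)")
    values = np.array([s.fst_weighted for s in stats], dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite window values")
    return float(np.percentile(values, pct))


def obs_het_fraction(gm: GenotypeMatrix, sample: str, region: Region) -> float:
    """Heterozygous / called genotypes of one sample within a region."""
    mask = gm.site_mask(*region)
    row = gm.calls[gm.sample_index(sample)][mask]
    called = row != MISSING
    if not called.any():
        raise ValueError(f"no called sites for {sample} in {region}")
    return float((row[called] == 1).mean())


def ld_r2(gm: GenotypeMatrix, i: int, j: int) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages over
    samples called at both sites. NaN when either site is monomorphic among
    the jointly called samples."""
    x = gm.calls[:, i].astype(float)
    y = gm.calls[:, j].astype(float)
    ok = (gm.calls[:, i] != MISSING) & (gm.calls[:, j] != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 jointly called samples")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class LDBin:
    lo: int  # bp, inclusive
    hi: int  # bp, exclusive
    mean_r2: float
    n_pairs: int


def _masked_r2_block(X, M, A, B):
    """r^2 between site-columns A of (X, M) and site-columns B, with
    pairwise-complete samples. X has zeros at missing cells, M is the
    called-mask; everything reduces to matrix products."""
    XA, MA = X[:, A], M[:, A]
    XB, MB = X[:, B], M[:, B]
    n = MA.T @ MB
    sx = XA.T @ MB
    sy = MA.T @ XB
    sxy = XA.T @ XB
    sxx = (XA**2).T @ MB
    syy = MA.T @ (XB**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx**2) * (n * syy - sy**2)
        r2 = np.where((den > 0) & (n >= 2), num**2 / den, np.nan)
    return r2


def ld_decay(
    gm: GenotypeMatrix,
    samples: Optional[Sequence[str]] = None,
    region: Optional[Region] = None,
    maf_min: float = 0.05,
    max_dist: int = 300_000,
    bin_width: int = 10_000,
    max_sites: Optional[int] = None,
) -> list[LDBin]:
    """Distance-binned mean r-squared over all site pairs within a region.

    Sites failing the minor-allele-frequency filter are excluded. With
    ``max_sites`` the region is thinned to evenly spaced sites (deterministic)
    to bound the pair count. Bins are [k*bin_width, (k+1)*bin_width).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rows = (
        np.arange(gm.n_samples)
        if samples is None
        else np.array([gm.sample_index(s) for s in samples])
    )
    mask = np.ones(gm.n_sites, bool) if region is None else gm.site_mask(*region)
    idx = np.flatnonzero(mask)
    calls = gm.calls[np.ix_(rows, idx)].astype(float)
    called = calls != MISSING
    calls[~called] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = calls.sum(axis=0) / (2.0 * called.sum(axis=0))
    maf = np.minimum(p, 1.0 - p)
    keep = np.isfinite(maf) & (maf >= maf_min)
    idx, calls, called = idx[keep], calls[:, keep], called[:, keep]
    if len(idx) < 2:
        raise ValueError("fewer than 2 sites pass the MAF filter")
    if max_sites is not None and len(idx) > max_sites:
        thin = np.linspace(0, len(idx) - 1, max_sites).round().astype(int)
        idx, calls, called = idx[thin], calls[:, thin], called[:, thin]
    pos = gm.sites["pos"].to_numpy()[idx]

    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    block = 512
    n_sites = len(idx)
    for a0 in range(0, n_sites, block):
        a1 = min(a0 + block, n_sites)
        b1 = int(np.searchsorted(pos, pos[a1 - 1] + max_dist, side="right"))
        A = np.arange(a0, a1)
        B = np.arange(a0, b1)
        r2 = _masked_r2_block(calls, called.astype(float), A, B)
        dist = np.abs(pos[B][None, :] - pos[A][:, None])
        upper = B[None, :] > A[:, None]  # each unordered pair once
        ok = upper & (dist <= max_dist) & (dist > 0) & np.isfinite(r2)
        bins = (dist[ok] - 1) // bin_width
        np.add.at(sums, bins, r2[ok])
        np.add.at(counts, bins, 1)
    out = []
    for k in range(n_bins):
        mean = float(sums[k] / counts[k]) if counts[k] else float("nan")
        out.append(LDBin(k * bin_width, (k + 1) * bin_width, mean, int(counts[k])))
    return out


def ld_decay_slope(bins: Sequence[LDBin]) -> float:
    """OLS slope of populated-bin mean r-squared against bin midpoint (per bp)."""
    x = np.array([(b.lo + b.hi) / 2.0 for b in bins if b.n_pairs > 0])
    y = np.array([b.mean_r2 for b in bins if b.n_pairs > 0])
    if len(x) < 2:
        raise ValueError("need >= 2 populated bins")
    return float(np.polyfit(x, y, 1)[0])


class K80Result(NamedTuple):
    distance: float  # substitutions per site; NaN when saturated
    p_transition: float
    q_transversion: float
    n_sites: int  # comparable (ACGT in both) sites
    saturated: bool


_PURINES = frozenset("AG")


def k80_distance(seq1: str, seq2: str) -> K80Result:
    """Kimura two-parameter distance between two aligned sequences.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P and Q the observed
    transition and transversion proportions over sites that are A/C/G/T in
    both sequences. A non-positive log argument is reported as saturation.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    s1, s2 = seq1.upper(), seq2.upper()
    n = ts = tv = 0
    for x, y in zip(s1, s2):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x != y:
            if (x in _PURINES) == (y in _PURINES):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K80Result(float("nan"), P, Q, n, True)
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return K80Result(float(d), P, Q, n, False)
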