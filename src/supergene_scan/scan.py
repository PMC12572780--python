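"""Rolling-window PCA, supergene interval detection, genotype assignment.

The three stages are scikit-learn style estimators (``get_params`` /
``set_params``, fitted attributes with a trailing underscore) so they can be
configured and composed programmatically; the module-level functions
``rolling_pca``, ``detect_supergene`` and ``assign_genotypes`` are thin
wrappers over them.

A non-recombining haplotype block shows up as a contiguous run of
high-differentiation FST windows, and within that region the first
principal component of the genotype-dosage matrix separates samples into
three clusters: the two opposite homozygotes at the extremes and the
heterozygotes in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .haplotype_snps import ab_het_sites
from .io_formats import MISSING, GenotypeMatrix
from .popgen import Region, WindowStat, fst_percentile_threshold, obs_het_fraction

CLASS_LABELS = ("AA", "AB", "BB")


class AssignmentValidationError(ValueError):
    """Raised when the heterozygosity sanity check on AB fails."""


@dataclass
class PCAWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_sites: int
    scores: Optional[np.ndarray]  # PC1 score per sample; None when degenerate
    var_frac: float

    @property
    def informative(self) -> bool:
        return self.scores is not None


@dataclass(frozen=True)
class SupergeneCall:
    chrom: str
    start: int
    end: int
    n_windows: int  # supporting (above-threshold) windows
    threshold: float


@dataclass
class GenotypeAssignment:
    """Per-sample supergene genotype classes with supporting evidence."""

    classes: dict[str, str]
    mean_pc1: dict[str, float]
    het_fraction: dict[str, float]
    n_clusters: int
    warnings: list[str] = field(default_factory=list)

    def samples_of(self, label: str) -> list[str]:
        return [s for s, c in self.classes.items() if c == label]


class RollingPCA(BaseEstimator):
    """PC1 of the standardized genotype-dosage matrix in windows along a
    chromosome.

    Per window, missing cells are imputed with the site mean dosage, sites
    are centered at 2p and (optionally) scaled by sqrt(2p(1-p)), and PC1
    comes from a singular decomposition. Because a PC sign is arbitrary,
    each window is oriented to correlate positively with the previous
    informative window; in the first window the lexicographically smallest
    sample id gets a non-negative score. Windows with fewer than two
    polymorphic sites (or no dosage variance) are emitted empty.
    """

    def __init__(self, window_size: int = 50_000, standardize: bool = True):
        self.window_size = window_size
        self.standardize = standardize

    def fit(self, gm: GenotypeMatrix, chromosome: str) -> "RollingPCA":
        if chromosome not in set(gm.sites["chrom"]):
            raise ValueError(f"unknown chromosome {chromosome!r}")
        on = (gm.sites["chrom"] == chromosome).to_numpy()
        pos = gm.sites["pos"].to_numpy()[on]
        calls = gm.calls[:, on]
        anchor = int(np.argmin(np.array(gm.sample_ids, dtype=object)))
        last = int(pos.max())
        windows: list[PCAWindow] = []
        prev_scores: Optional[np.ndarray] = None
        for start in range(1, last + 1, self.window_size):
            end = start + self.window_size - 1
            sel = (pos >= start) & (pos <= end)
            n_sites = int(sel.sum())
            scores, var_frac = None, float("nan")
            if n_sites >= 2:
                scores, var_frac = self._window_pc1(calls[:, sel])
            if scores is not None:
                if prev_scores is not None:
                    if float(scores @ prev_scores) < 0:
                        scores = -scores
                elif scores[anchor] < 0:
                    scores = -scores
                prev_scores = scores
            windows.append(
                PCAWindow(chromosome, start, end, n_sites, scores, var_frac)
            )
        self.windows_ = windows
        return self

    def _window_pc1(self, calls: np.ndarray):
        d = calls.astype(float)
        d[calls == MISSING] = np.nan
        col_mean = np.nanmean(d, axis=0)
        filled = np.where(np.isnan(d), col_mean, d)
        p = col_mean / 2.0
        poly = (p > 0) & (p < 1) & (filled.std(axis=0) > 0)
        if poly.sum() < 2:
            return None, float("nan")
        x = filled[:, poly] - 2.0 * p[poly]
        if self.standardize:
            x = x / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        if s[0] <= 1e-12:
            return None, float("nan")
        return u[:, 0] * s[0], float(s[0] ** 2 / np.sum(s**2))


def rolling_pca(
    gm: GenotypeMatrix, chromosome: str, window_size: int = 50_000,
    standardize: bool = True,
) -> list[PCAWindow]:
    return RollingPCA(window_size, standardize).fit(gm, chromosome).windows_


class SupergeneDetector(BaseEstimator):
    """Detect the longest run of above-threshold FST windows.

    A candidate is a maximal run of windows with weighted FST above the
    threshold, tolerating up to ``max_gap_windows`` below-threshold or empty
    windows inside; the call spans from the first to the last supporting
    window. Terminal supporting windows whose FST falls below
    ``edge_trim_frac`` times the candidate's median supporting FST are
    peeled off, so isolated background windows just above a permissive
    threshold cannot drag the bounds outward (set ``edge_trim_frac=0`` to
    disable). ``min_span`` defaults to 10x the window size. With no
    explicit ``threshold`` the ``percentile`` of the genome-wide finite
    window values is used.
    """

    def __init__(
        self,
        threshold: Optional[float] = None,
        percentile: float = 95.0,
        max_gap_windows: int = 2,
        min_span: Optional[int] = None,
        edge_trim_frac: float = 0.5,
    ):
        self.threshold = threshold
        self.percentile = percentile
        self.max_gap_windows = max_gap_windows
        self.min_span = min_span
        self.edge_trim_frac = edge_trim_frac

    def fit(self, windows: Sequence[WindowStat]) -> "SupergeneDetector":
        threshold = (
            self.threshold
            if self.threshold is not None
            else fst_percentile_threshold(windows, self.percentile)
        )
        win_size = windows[0].end - windows[0].start + 1
        min_span = 10 * win_size if self.min_span is None else self.min_span

        candidates: list[SupergeneCall] = []
        by_chrom: dict[str, list[WindowStat]] = {}
        for w in windows:
            by_chrom.setdefault(w.chrom, []).append(w)
        for chrom in sorted(by_chrom):
            ws = sorted(by_chrom[chrom], key=lambda w: w.start)
            above = [
                np.isfinite(w.fst_weighted) and w.fst_weighted > threshold
                for w in ws
            ]
            i = 0
            while i < len(ws):
                if not above[i]:
                    i += 1
                    continue
                support = [i]
                j = i + 1
                gap = 0
                while j < len(ws) and gap <= self.max_gap_windows:
                    if above[j]:
                        support.append(j)
                        gap = 0
                    else:
                        gap += 1
                    j += 1
                last = support[-1]
                support = self._trim(ws, support)
                if support:
                    candidates.append(
                        SupergeneCall(
                            chrom,
                            ws[support[0]].start,
                            ws[support[-1]].end,
                            len(support),
                            threshold,
                        )
                    )
                i = last + 1
        candidates = [
            c for c in candidates if c.end - c.start + 1 >= min_span
        ]
        candidates.sort(key=lambda c: (-(c.end - c.start + 1), c.chrom, c.start))
        self.threshold_ = float(threshold)
        self.call_ = candidates[0] if candidates else None
        return self

    def _trim(self, ws, support: list[int]) -> list[int]:
        if not support or self.edge_trim_frac <= 0:
            return support
        med = float(np.median([ws[k].fst_weighted for k in support]))
        cut = self.edge_trim_frac * med
        while support and ws[support[0]].fst_weighted < cut:
            support = support[1:]
        while support and ws[support[-1]].fst_weighted < cut:
            support = support[:-1]
        return support


def detect_supergene(
    windows: Sequence[WindowStat],
    threshold: float,
    max_gap_windows: int = 2,
    min_span: Optional[int] = None,
) -> Optional[SupergeneCall]:
    det = SupergeneDetector(
        threshold=threshold, max_gap_windows=max_gap_windows, min_span=min_span
    )
    return det.fit(windows).call_


def _kmeans_1d(scores: np.ndarray, centers: np.ndarray, max_iter: int = 200):
    """Deterministic Lloyd iterations in one dimension."""
    centers = centers.astype(float).copy()
    for _ in range(max_iter):
        labels = np.argmin(np.abs(scores[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [
                scores[labels == k].mean() if np.any(labels == k) else centers[k]
                for k in range(len(centers))
            ]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return labels, centers


class GenotypeAssigner(BaseEstimator):
    """Assign AA/AB/BB supergene genotypes from region PC1 scores.

    Samples are clustered on their mean PC1 over the region's informative
    windows by one-dimensional k-means seeded at the minimum, median and
    maximum score. The middle cluster is labeled AB; the outer clusters are
    oriented by their majority call at the AB-heterozygous site set (mostly
    hom-ref is AA, mostly hom-alt is BB). The assignment is validated by
    requiring AB to have the highest mean region heterozygosity. When the
    scores support only two clusters (center gap below
    ``min_center_gap_frac`` of the score range, or fewer than three distinct
    values) two clusters are reported with a warning instead of forcing a
    third.
    """

    def __init__(self, min_center_gap_frac: float = 0.1):
        self.min_center_gap_frac = min_center_gap_frac

    def fit(
        self,
        gm: GenotypeMatrix,
        region: Region,
        pca_windows: Sequence[PCAWindow],
    ) -> "GenotypeAssigner":
        chrom, start, end = region
        overlapping = [
            w
            for w in pca_windows
            if w.informative and w.chrom == chrom and w.start <= end and w.end >= start
        ]
        if not overlapping:
            raise ValueError("region overlaps no informative PCA window")
        scores = np.mean([w.scores for w in overlapping], axis=0)
        order = np.array(gm.sample_ids)
        het = {
            s: obs_het_fraction(gm, s, region) for s in gm.sample_ids
        }
        warnings: list[str] = []

        distinct = np.unique(scores)
        if len(distinct) < 2:
            raise ValueError("fewer than 2 distinct PC1 score values")
        k = 3 if len(distinct) >= 3 else 2
        init = (
            np.array([scores.min(), np.median(scores), scores.max()])
            if k == 3
            else np.array([scores.min(), scores.max()])
        )
        labels, centers = _kmeans_1d(scores, init)
        if k == 3:
            span = centers.max() - centers.min()
            csort = np.sort(centers)
            empty = len(np.unique(labels)) < 3
            if (
                empty
                or span == 0
                or np.min(np.diff(csort)) < self.min_center_gap_frac * span
            ):
                warnings.append(
                    "scores support only 2 clusters; not forcing a third"
                )
                labels, centers = _kmeans_1d(
                    scores, np.array([scores.min(), scores.max()])
                )
                k = 2
        rank_of = {c: r for r, c in enumerate(np.argsort(centers))}
        ranks = np.array([rank_of[l] for l in labels])  # 0 = lowest center

        classes: dict[str, str] = {}
        if k == 3:
            mid = ranks == 1
            for s in order[mid]:
                classes[s] = "AB"
            low_ids, high_ids = list(order[ranks == 0]), list(order[ranks == 2])
            ab_idx = ab_het_sites(gm, classes, region)
            low_is_aa = self._orient(gm, ab_idx, low_ids, high_ids, warnings)
            for s in low_ids:
                classes[s] = "AA" if low_is_aa else "BB"
            for s in high_ids:
                classes[s] = "BB" if low_is_aa else "AA"
            by_class = {
                lab: [het[s] for s in classes if classes[s] == lab]
                for lab in CLASS_LABELS
            }
            mean_het = {
                lab: float(np.mean(v)) for lab, v in by_class.items() if v
            }
            if mean_het.get("AB", 1.0) <= max(
                mean_het.get("AA", 0.0), mean_het.get("BB", 0.0)
            ):
                raise AssignmentValidationError(
                    "AB cluster does not have the highest mean heterozygosity; "
                    f"cluster het means: {mean_het}"
                )
        else:
            lows, highs = order[ranks == 0], order[ranks == 1]
            het_low = float(np.mean([het[s] for s in lows]))
            het_high = float(np.mean([het[s] for s in highs]))
            # one cluster is AB only if clearly heterozygote-like: well above
            # the other cluster and above what hom classes plausibly show
            if max(het_low, het_high) > max(
                0.35, 1.5 * max(min(het_low, het_high), 1e-9)
            ):
                ab_side = 0 if het_low > het_high else 1
                hom_side_ids = list(highs if ab_side == 0 else lows)
                hom_label = self._hom_label(gm, region, hom_side_ids)
                for s in order[ranks == ab_side]:
                    classes[s] = "AB"
                for s in hom_side_ids:
                    classes[s] = hom_label
            else:
                mask = gm.site_mask(*region)
                dose = np.where(gm.calls == MISSING, np.nan, gm.calls)[:, mask]
                mean_dose = np.nanmean(dose, axis=1)
                low_is_aa = (
                    np.nanmean(mean_dose[ranks == 0])
                    <= np.nanmean(mean_dose[ranks == 1])
                )
                for s in lows:
                    classes[s] = "AA" if low_is_aa else "BB"
                for s in highs:
                    classes[s] = "BB" if low_is_aa else "AA"

        self.assignment_ = GenotypeAssignment(
            classes=classes,
            mean_pc1={s: float(v) for s, v in zip(order, scores)},
            het_fraction=het,
            n_clusters=k,
            warnings=warnings,
        )
        self.labels_ = np.array([classes[s] for s in order])
        return self

    @staticmethod
    def _hom_label(gm, region, sample_ids) -> str:
        mask = gm.site_mask(*region)
        rows = [gm.sample_index(s) for s in sample_ids]
        sub = gm.calls[np.ix_(rows, np.flatnonzero(mask))]
        return "AA" if (sub == 0).sum() >= (sub == 2).sum() else "BB"

    @staticmethod
    def _orient(gm, ab_idx, low_ids, high_ids, warnings) -> bool:
        """True when the low-PC1 cluster is AA (majority hom-ref at the
        AB-heterozygous sites)."""
        if len(ab_idx) == 0:
            warnings.append(
                "no AB-diagnostic sites; orienting AA/BB by mean dosage"
            )
            return True
        low_rows = [gm.sample_index(s) for s in low_ids]
        sub = gm.calls[np.ix_(low_rows, ab_idx)]
        n_ref, n_alt = int((sub == 0).sum()), int((sub == 2).sum())
        if n_ref == n_alt:
            warnings.append("orientation tie; labeling low-PC1 cluster AA")
        return n_ref >= n_alt


def assign_genotypes(
    gm: GenotypeMatrix, region: Region, pca_windows: Sequence[PCAWindow]
) -> GenotypeAssignment:
    return GenotypeAssigner().fit(gm, region, pca_windows).assignment_


def genotype_count_profile(
    gm: GenotypeMatrix, region: Region, assignment: GenotypeAssignment
):
    """Counts of {hom-ref, het, hom-alt} per genotype class over all
    (sample, site) cells at the AB-heterozygous site set."""
    import pandas as pd

    ab_idx = ab_het_sites(gm, assignment.classes, region)
    if len(ab_idx) == 0:
        raise ValueError("empty AB-heterozygous site set")
    rows = {}
    for label in sorted(set(assignment.classes.values())):
        sample_rows = [
            gm.sample_index(s) for s, c in assignment.classes.items() if c == label
        ]
        sub = gm.calls[np.ix_(sample_rows, ab_idx)]
        rows[label] = {
            "hom_ref": int((sub == 0).sum()),
            "het": int((sub == 1).sum()),
            "hom_alt": int((sub == 2).sum()),
        }
    return pd.DataFrame(rows).T[["hom_ref", "het", "hom_alt"]]
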