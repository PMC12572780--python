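"""Morph classification and genotype-phenotype / genotype-colony statistics.

Queen morphs are called from head width with closed-interval cut-offs
(default: macrogyne > 1.08 mm, microgyne < 1.04 mm, intermediate in
[1.04, 1.08] mm). Group differences in head width use the tie-corrected
Kruskal-Wallis test with Dunn's rank-sum post hoc comparisons; associations
between genotype class and colony organisation use the two-sided Fisher
exact test (point-probability rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MORPHS = ("macrogyne", "intermediate", "microgyne")


def classify_morph(width_mm: float, lo: float = 1.04, hi: float = 1.08) -> str:
    """Queen morph from head width: > hi macrogyne, < lo microgyne,
    otherwise intermediate (both cut-offs inclusive in the middle class)."""
    if not width_mm > 0:
        raise ValueError(f"head width must be positive, got {width_mm}")
    if width_mm > hi:
        return "macrogyne"
    if width_mm < lo:
        return "microgyne"
    return "intermediate"


class KruskalResult(NamedTuple):
    H: float
    df: int
    p: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H over two or more groups."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):  # all values identical: no evidence
        return KruskalResult(0.0, df, 1.0)
    h, p = stats.kruskal(*groups)
    return KruskalResult(float(h), df, float(p))


@dataclass(frozen=True)
class DunnComparison:
    group_i: str
    group_j: str
    z: float
    p_raw: float
    p_adj: float


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "holm"
) -> list[DunnComparison]:
    """Dunn's post hoc z tests on pooled ranks for every pair of groups.

    z for pair (i, j) is the difference of mean ranks over the standard
    error sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j)) with
    the usual tie correction; two-sided normal p values are adjusted across
    all pairs by Holm (default) or Benjamini-Hochberg ("bh").
    """
    if adjust not in ("holm", "bh"):
        raise ValueError(f"unknown adjustment method {adjust!r}")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    values = [np.asarray(groups[g], float) for g in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for g, v in zip(names, values):
        mean_rank[g] = ranks[start : start + len(v)].mean()
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs, zs, ps = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            se = np.sqrt(base_var * (1.0 / len(groups[gi]) + 1.0 / len(groups[gj])))
            z = 0.0 if se == 0 else (mean_rank[gi] - mean_rank[gj]) / se
            pairs.append((gi, gj))
            zs.append(z)
            ps.append(2.0 * stats.norm.sf(abs(z)))
    method = "holm" if adjust == "holm" else "fdr_bh"
    p_adj = multipletests(ps, method=method)[1]
    return [
        DunnComparison(gi, gj, float(z), float(p), float(pa))
        for (gi, gj), z, p, pa in zip(pairs, zs, ps, p_adj)
    ]


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by the point-probability rule: the sum of
    probabilities of all tables with the observed margins whose probability
    does not exceed the observed table's (up to a 1 + 1e-7 tolerance)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def colony_genotype_association(
    samples: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Association between colony type (single- vs multiple-queen) and
    colony genotype class (AA if any resident queen is AA, else non-AA).

    ``samples`` needs columns colony_id, caste, queen_count, genotype_class;
    only queens are used. Returns the labeled 2x2 table and the two-sided
    Fisher p.
    """
    queens = samples[samples["caste"].isin(["queen", "gyne"])]
    if queens.empty:
        raise ValueError("no queens in sample table")
    cells = {("single", "AA"): 0, ("single", "non-AA"): 0,
             ("multiple", "AA"): 0, ("multiple", "non-AA"): 0}
    for colony, group in queens.groupby("colony_id"):
        n_queens = int(group["queen_count"].iloc[0])
        if n_queens < 1:
            raise ValueError(f"colony {colony} has zero queens")
        ctype = "single" if n_queens == 1 else "multiple"
        cls = "AA" if (group["genotype_class"] == "AA").any() else "non-AA"
        cells[(ctype, cls)] += 1
    table = pd.DataFrame(
        [
            [cells[("single", "AA")], cells[("single", "non-AA")]],
            [cells[("multiple", "AA")], cells[("multiple", "non-AA")]],
        ],
        index=["single-queen", "multiple-queen"],
        columns=["AA", "non-AA"],
    )
    return table, fisher_exact_2x2(table.to_numpy())


def matriline_genotype_association(
    matriline_counts: Mapping[str, int], colony_classes: Mapping[str, str]
) -> tuple[pd.DataFrame, float]:
    """Association between a single matriline (monogyny) and AA genotype.

    2x2 of (AA vs non-AA) x (1 matriline vs > 1) over the colonies present
    in both mappings, with the two-sided Fisher p.
    """
    colonies = sorted(set(matriline_counts) & set(colony_classes))
    if len(colonies) < 2:
        raise ValueError("need >= 2 colonies with matriline count and class")
    cells = np.zeros((2, 2), dtype=int)
    for c in colonies:
        n = matriline_counts[c]
        if n < 1:
            raise ValueError(f"colony {c} has matriline count < 1")
        row = 0 if colony_classes[c] == "AA" else 1
        col = 0 if n == 1 else 1
        cells[row, col] += 1
    table = pd.DataFrame(
        cells,
        index=["AA", "non-AA"],
        columns=["single-matriline", "multiple-matriline"],
    )
    return table, fisher_exact_2x2(cells)
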