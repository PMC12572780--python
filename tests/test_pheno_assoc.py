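"""Morph classification and association statistics against hand oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from supergene_scan.pheno_assoc import (
    classify_morph,
    colony_genotype_association,
    dunn_posthoc,
    fisher_exact_2x2,
    kruskal_wallis,
    matriline_genotype_association,
)


class TestClassifyMorph:
    @pytest.mark.parametrize(
        "width,expected",
        [
            (1.14, "macrogyne"),
            (0.92, "microgyne"),
            (1.04, "intermediate"),
            (1.08, "intermediate"),
            (1.09, "macrogyne"),
            (1.039, "microgyne"),
        ],
    )
    def test_cutoffs_closed_interval(self, width, expected):
        assert classify_morph(width) == expected

    def test_non_positive_width_rejected(self):
        with pytest.raises(ValueError):
            classify_morph(0.0)


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([(1, 2, 3), (1, 2, 3)])
        assert res.H == pytest.approx(0.0)
        assert res.df == 1
        assert res.p == pytest.approx(1.0)

    def test_all_values_equal_degenerate(self):
        res = kruskal_wallis([(5, 5), (5, 5, 5)])
        assert (res.H, res.p) == (0.0, 1.0)

    def test_matches_rank_sum_arithmetic(self):
        groups = [(1, 2), (3, 4), (5, 6)]
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        n_tot = 6
        mean_ranks = [1.5, 3.5, 5.5]
        h_hand = (
            12.0
            / (n_tot * (n_tot + 1))
            * sum(2 * (r - (n_tot + 1) / 2) ** 2 for r in mean_ranks)
        )
        res = kruskal_wallis(groups)
        assert res.H == pytest.approx(h_hand, abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(stats.chi2.sf(h_hand, 2), abs=1e-12)

    def test_shift_invariance(self):
        groups = [(1.0, 2.5, 2.5), (4.0, 0.5)]
        shifted = [tuple(v + 17.3 for v in g) for g in groups]
        assert kruskal_wallis(groups).H == pytest.approx(
            kruskal_wallis(shifted).H
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([(1, 2), ()])


def dunn_z_oracle(groups, gi, gj):
    """Independent scalar evaluation of the Dunn z formula with ties."""
    names = list(groups)
    pooled = [v for g in names for v in groups[g]]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    mean_rank = {}
    start = 0
    for g in names:
        n = len(groups[g])
        mean_rank[g] = sum(ranks[start : start + n]) / n
        start += n
    n_tot = len(pooled)
    from collections import Counter

    ties = Counter(pooled)
    tie_term = sum(t**3 - t for t in ties.values()) / (12.0 * (n_tot - 1))
    var = n_tot * (n_tot + 1) / 12.0 - tie_term
    se = math.sqrt(var * (1.0 / len(groups[gi]) + 1.0 / len(groups[gj])))
    return (mean_rank[gi] - mean_rank[gj]) / se


class TestDunn:
    def test_identical_groups_z_zero(self):
        res = dunn_posthoc({"a": (1, 2, 3), "b": (1, 2, 3)})
        assert res[0].z == pytest.approx(0.0)
        assert res[0].p_raw == pytest.approx(1.0)

    def test_pair_order_antisymmetry(self):
        g = {"a": (1.0, 2.0, 7.0), "b": (3.0, 9.0)}
        forward = dunn_posthoc(g)[0]
        backward = dunn_posthoc({"b": g["b"], "a": g["a"]})[0]
        assert forward.z == pytest.approx(-backward.z)
        assert forward.p_raw == pytest.approx(backward.p_raw)

    def test_matches_hand_arithmetic_with_ties(self):
        groups = {
            "x": (1.2, 1.2, 2.0),
            "y": (2.0, 3.5),
            "z": (0.5, 3.5, 3.5, 4.0),
        }
        results = {(r.group_i, r.group_j): r for r in dunn_posthoc(groups)}
        for gi, gj in [("x", "y"), ("x", "z"), ("y", "z")]:
            z = dunn_z_oracle(groups, gi, gj)
            assert results[(gi, gj)].z == pytest.approx(z, abs=1e-10)
            assert results[(gi, gj)].p_raw == pytest.approx(
                2 * stats.norm.sf(abs(z)), abs=1e-10
            )

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(6)
        groups = {f"g{i}": tuple(rng.normal(i * 0.3, 1, 6)) for i in range(4)}
        res = dunn_posthoc(groups, adjust="holm")
        by_raw = sorted(res, key=lambda r: r.p_raw)
        adj = [r.p_adj for r in by_raw]
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))
        assert all(r.p_adj >= r.p_raw - 1e-15 for r in res)

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc({"a": (1,), "b": (2,)}, adjust="bonferroni-ish")


class TestFisher:
    def test_single_concordant_pair_uninformative(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_transposition_and_double_swap_invariance(self):
        t = [[7, 2], [3, 9]]
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2(np.transpose(t)) == pytest.approx(p)
        swapped = [[9, 3], [2, 7]]  # simultaneous row + column swap
        assert fisher_exact_2x2(swapped) == pytest.approx(p)

    def test_two_sided_not_below_smaller_one_sided(self):
        t = np.array([[8, 1], [2, 6]])
        p_two = fisher_exact_2x2(t)
        p_one = min(
            stats.fisher_exact(t, alternative="less")[1],
            stats.fisher_exact(t, alternative="greater")[1],
        )
        assert p_one <= p_two <= 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


def sample_table(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "colony_id", "caste", "queen_count", "genotype_class"]
    )


class TestColonyAssociation:
    def test_degenerate_margin_gives_p_one(self):
        rows = [
            (f"q{i}", f"C{i}", "queen", 1, "AA") for i in range(5)
        ]
        table, p = colony_genotype_association(sample_table(rows))
        assert p == pytest.approx(1.0)
        assert table.loc["single-queen", "AA"] == 5

    def test_mixed_colony_counts_and_any_aa_rule(self):
        rows = [
            ("q1", "C1", "queen", 1, "AA"),
            ("q2", "C2", "queen", 1, "BB"),
            ("q3", "C3", "queen", 2, "AB"),
            ("q4", "C3", "queen", 2, "AA"),  # any-AA makes C3 an AA colony
        ]
        table, p = colony_genotype_association(sample_table(rows))
        assert table.loc["multiple-queen", "AA"] == 1
        assert table.loc["single-queen", "non-AA"] == 1

    def test_zero_queen_colony_rejected(self):
        rows = [("q1", "C1", "queen", 0, "AA")]
        with pytest.raises(ValueError, match="zero queens"):
            colony_genotype_association(sample_table(rows))


class TestMatrilineAssociation:
    def test_composition_identity_with_fisher(self):
        counts = {"C1": 1, "C2": 3, "C3": 1, "C4": 2}
        classes = {"C1": "AA", "C2": "BB", "C3": "AA", "C4": "AB"}
        table, p = matriline_genotype_association(counts, classes)
        assert p == pytest.approx(fisher_exact_2x2(table.to_numpy()))
        assert table.loc["AA", "single-matriline"] == 2
        assert table.loc["non-AA", "multiple-matriline"] == 2

    def test_single_colony_rejected(self):
        with pytest.raises(ValueError):
            matriline_genotype_association({"C1": 1}, {"C1": "AA"})

    def test_count_below_one_rejected(self):
        with pytest.raises(ValueError):
            matriline_genotype_association(
                {"C1": 0, "C2": 2}, {"C1": "AA", "C2": "BB"}
            )


@given(
    a=st.integers(0, 8), b=st.integers(0, 8), c=st.integers(0, 8), d=st.integers(0, 8)
)
def test_fisher_p_always_in_unit_interval(a, b, c, d):
    if a + b + c + d == 0:
        return
    p = fisher_exact_2x2([[a, b], [c, d]])
    assert 0.0 < p <= 1.0


def test_planted_association_detected_in_monte_carlo():
    """Colonies simulated with a perfect AA<->monogyny link give a strongly
    significant Fisher test in essentially every replicate."""
    from supergene_scan.simdata import SimConfig, SimTruth, simulate_colonies

    cfg = SimConfig(seed=0)
    n_sig = 0
    reps = 200
    for rep in range(reps):
        ids = [f"S{i:02d}" for i in range(60)]
        classes = dict(zip(ids, ["AA"] * 20 + ["AB"] * 20 + ["BB"] * 20))
        samples = pd.DataFrame(
            {
                "sample_id": ids,
                "head_width_mm": 1.0,
                "colony_id": "",
                "caste": "queen",
                "queen_count": 1,
            }
        )
        truth = SimTruth(supergene=("chr1", 1, 2), classes=classes, site_category=[])
        samples, workers, truth = simulate_colonies(
            cfg, samples, truth, seed=50_000 + rep
        )
        samples["genotype_class"] = samples["sample_id"].map(classes)
        _, p = colony_genotype_association(samples)
        n_sig += p < 0.001
    assert n_sig >= 0.95 * reps
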