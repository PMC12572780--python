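"""Population-genetic statistics against independent oracles and closed forms."""

import math

import numpy as np
import pytest
from helpers import make_gm, swap_ref_alt
from hypothesis import given
from hypothesis import strategies as st

from supergene_scan.io_formats import MISSING
from supergene_scan.popgen import (
    fst_percentile_threshold,
    k80_distance,
    ld_decay,
    ld_decay_slope,
    ld_r2,
    obs_het_fraction,
    wc_fst_site,
    windowed_fst,
)


def wc_oracle(counts):
    """Independent step-by-step evaluation of the 1984 variance components
    from per-population genotype counts, in plain scalar arithmetic."""
    r = len(counts)
    n = [c[0] + c[1] + c[2] for c in counts]
    p = [(c[1] + 2 * c[2]) / (2 * ni) for c, ni in zip(counts, n)]
    h = [c[1] / ni for c, ni in zip(counts, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return a, b, c, (a / denom if denom != 0 else float("nan"))


class TestWcFstSite:
    def test_fixed_difference_gives_theta_one(self):
        res = wc_fst_site([[5, 0, 0], [0, 0, 5]])
        assert res.theta == pytest.approx(1.0)

    def test_identical_populations_give_non_positive_theta(self):
        res = wc_fst_site([[2, 2, 2], [2, 2, 2]])
        assert res.theta <= 0.0

    def test_matches_hand_arithmetic_oracle(self):
        counts = [[1, 1, 1], [2, 1, 0]]
        res = wc_fst_site(counts)
        a, b, c, theta = wc_oracle(counts)
        assert res.a == pytest.approx(a, abs=1e-12)
        assert res.b == pytest.approx(b, abs=1e-12)
        assert res.c == pytest.approx(c, abs=1e-12)
        assert res.theta == pytest.approx(theta, abs=1e-12)

    def test_monomorphic_site_flagged_nan(self):
        assert math.isnan(wc_fst_site([[3, 0, 0], [4, 0, 0]]).theta)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            wc_fst_site([[0, 0, 0], [1, 1, 1]])


class TestWindowedFst:
    def _gm_two_pops(self):
        # samples 1-3 pop X, 4-6 pop Y; site 1 fixed-diff, site 2 shared
        calls = [[0, 1], [0, 0], [0, 1], [2, 1], [2, 0], [2, 1]]
        gm = make_gm(calls, positions=[100, 5000])
        groups = {s: ("X" if i < 3 else "Y") for i, s in enumerate(gm.sample_ids)}
        return gm, groups

    def test_single_site_window_equals_site_estimator(self):
        gm, groups = self._gm_two_pops()
        stats = windowed_fst(gm, groups, window_size=1000)
        site = wc_fst_site([[3, 0, 0], [0, 0, 3]])
        assert stats[0].fst_weighted == pytest.approx(site.theta)
        assert stats[0].fst_mean == pytest.approx(site.theta)

    def test_sample_order_invariance(self):
        gm, groups = self._gm_two_pops()
        perm = [3, 0, 5, 2, 4, 1]
        gm2 = make_gm(
            gm.calls[perm],
            positions=list(gm.sites["pos"]),
            sample_ids=[gm.sample_ids[i] for i in perm],
        )
        s1 = windowed_fst(gm, groups, window_size=1000)
        s2 = windowed_fst(gm2, groups, window_size=1000)
        for w1, w2 in zip(s1, s2):
            assert w1 == w2 or (
                math.isnan(w1.fst_weighted) and math.isnan(w2.fst_weighted)
            )

    def test_unknown_group_label_rejected(self):
        gm, groups = self._gm_two_pops()
        groups["ghost"] = "X"
        with pytest.raises(ValueError, match="unknown"):
            windowed_fst(gm, groups)

    def test_window_with_no_informative_sites_is_nan(self):
        gm, groups = self._gm_two_pops()
        stats = windowed_fst(gm, groups, window_size=1000)
        # windows between the two sites hold nothing
        empty = [s for s in stats if s.n_sites == 0]
        assert empty and all(math.isnan(s.fst_weighted) for s in empty)


def test_percentile_threshold_linear_interpolation():
    from supergene_scan.popgen import WindowStat

    stats = [
        WindowStat("chr1", 1 + i * 10, 10 + i * 10, 1, v, v)
        for i, v in enumerate(np.arange(0, 1.01, 0.1))
    ]
    assert fst_percentile_threshold(stats, 95) == pytest.approx(0.95)
    flat = [WindowStat("chr1", 1, 10, 1, 0.4, 0.4)] * 5
    assert fst_percentile_threshold(flat, 95) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        fst_percentile_threshold(stats, 100)


class TestObsHet:
    def test_all_het(self):
        gm = make_gm([[1, 1, 1]])
        assert obs_het_fraction(gm, "S01", ("chr1", 1, 1000)) == 1.0

    def test_missing_excluded_from_denominator(self):
        gm = make_gm([[0, 1, 2, MISSING]])
        assert obs_het_fraction(gm, "S01", ("chr1", 1, 1000)) == pytest.approx(1 / 3)

    def test_zero_called_sites_rejected(self):
        gm = make_gm([[MISSING, MISSING]])
        with pytest.raises(ValueError):
            obs_het_fraction(gm, "S01", ("chr1", 1, 1000))

    def test_site_order_invariance(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(-1, 3, size=(1, 30))
        gm = make_gm(calls)
        perm = rng.permutation(30)
        gm2 = make_gm(calls[:, perm])
        region = ("chr1", 1, 10_000)
        assert obs_het_fraction(gm, "S01", region) == obs_het_fraction(
            gm2, "S01", region
        )


class TestLdR2:
    def test_identical_and_opposite_dosages(self):
        gm = make_gm([[0, 0, 2], [1, 1, 1], [2, 2, 0], [0, 0, 2]])
        assert ld_r2(gm, 0, 1) == pytest.approx(1.0)
        assert ld_r2(gm, 0, 2) == pytest.approx(1.0)  # perfect negative corr

    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(12, 2))
        gm = make_gm(calls)
        x, y = calls[:, 0].astype(float), calls[:, 1].astype(float)
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        expected = cov**2 / (x.var() * y.var())
        assert ld_r2(gm, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_allele_relabel_invariance(self):
        rng = np.random.default_rng(4)
        gm = make_gm(rng.integers(0, 3, size=(10, 2)))
        assert ld_r2(gm, 0, 1) == pytest.approx(ld_r2(gm, 1, 0))
        assert ld_r2(swap_ref_alt(gm), 0, 1) == pytest.approx(ld_r2(gm, 0, 1))

    def test_monomorphic_is_nan_and_small_n_rejected(self):
        gm = make_gm([[0, 1], [0, 2], [0, 0]])
        assert math.isnan(ld_r2(gm, 0, 1))
        gm2 = make_gm([[0, 1], [MISSING, 2], [0, MISSING]])
        with pytest.raises(ValueError):
            ld_r2(gm2, 0, 1)


class TestLdDecay:
    def test_two_sites_single_populated_bin(self):
        gm = make_gm([[0, 0], [1, 1], [2, 2], [0, 1]], positions=[100, 4100])
        bins = ld_decay(gm, maf_min=0.0, max_dist=10_000, bin_width=5_000)
        populated = [b for b in bins if b.n_pairs > 0]
        assert len(populated) == 1
        assert populated[0].n_pairs == 1
        assert populated[0].mean_r2 == pytest.approx(ld_r2(gm, 0, 1))

    def test_duplicated_columns_give_unit_bins(self):
        col = np.array([0, 1, 2, 0, 2, 1])
        calls = np.tile(col[:, None], (1, 5))
        gm = make_gm(calls, positions=[100, 300, 900, 2000, 4000])
        bins = ld_decay(gm, maf_min=0.0, max_dist=5_000, bin_width=1_000)
        for b in bins:
            if b.n_pairs:
                assert b.mean_r2 == pytest.approx(1.0)

    def test_bins_contiguous_and_bad_width_rejected(self):
        gm = make_gm([[0, 1], [1, 0], [2, 2]], positions=[10, 500])
        bins = ld_decay(gm, maf_min=0.0, max_dist=3_000, bin_width=1_000)
        assert [b.lo for b in bins] == [0, 1000, 2000]
        assert [b.hi for b in bins] == [1000, 2000, 3000]
        with pytest.raises(ValueError):
            ld_decay(gm, bin_width=0)

    def test_slope_of_flat_profile_is_zero(self):
        col = np.array([0, 1, 2, 0, 2, 1])
        gm = make_gm(np.tile(col[:, None], (1, 4)), positions=[1, 800, 1600, 2400])
        bins = ld_decay(gm, maf_min=0.0, max_dist=3_000, bin_width=1_000)
        assert ld_decay_slope(bins) == pytest.approx(0.0, abs=1e-15)


class TestK80:
    def test_identical_sequences(self):
        assert k80_distance("ACGTACGT", "ACGTACGT").distance == 0.0

    def test_closed_form_value(self):
        # 100 sites: 10 transitions, 5 transversions -> P=0.10, Q=0.05
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        res = k80_distance(s1, s2)
        assert res.p_transition == pytest.approx(0.10)
        assert res.q_transversion == pytest.approx(0.05)
        assert res.distance == pytest.approx(0.1702, abs=5e-5)

    def test_counts_match_hand_tally_on_random_pairs(self):
        rng = np.random.default_rng(9)
        nts = "ACGT"
        for _ in range(10):
            s1 = "".join(rng.choice(list(nts), 60))
            s2 = "".join(rng.choice(list(nts + "N-"), 60))
            ts = tv = n = 0
            for x, y in zip(s1, s2):
                if y not in nts:
                    continue
                n += 1
                if x != y:
                    if {x, y} in ({"A", "G"}, {"C", "T"}):
                        ts += 1
                    else:
                        tv += 1
            res = k80_distance(s1, s2)
            assert (res.n_sites, res.p_transition, res.q_transversion) == (
                n,
                pytest.approx(ts / n),
                pytest.approx(tv / n),
            )
            if not res.saturated:
                expected = -0.5 * math.log(1 - 2 * ts / n - tv / n) - 0.25 * math.log(
                    1 - 2 * tv / n
                )
                assert res.distance == pytest.approx(expected, abs=1e-12)

    def test_saturation_flagged(self):
        res = k80_distance("A" * 10, "G" * 10)  # P = 1.0
        assert res.saturated and math.isnan(res.distance)

    def test_errors(self):
        with pytest.raises(ValueError):
            k80_distance("ACGT", "ACG")
        with pytest.raises(ValueError):
            k80_distance("NNNN", "ACGT")

    @given(
        ts=st.integers(0, 20),
        tv=st.integers(0, 10),
    )
    def test_monotone_in_transitions_at_fixed_transversions(self, ts, tv):
        n = 100
        base = "A" * n

        def seq(k_ts, k_tv):
            return "G" * k_ts + "C" * k_tv + "A" * (n - k_ts - k_tv)

        d1 = k80_distance(base, seq(ts, tv))
        d2 = k80_distance(base, seq(ts + 1, tv))
        if not d1.saturated and not d2.saturated:
            assert d2.distance > d1.distance
            assert d1.distance >= 0.0
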