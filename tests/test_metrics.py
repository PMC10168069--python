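import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcstruct import (
    TraitTable,
    community_metrics,
    cwm,
    gower_distance,
    mpd,
    standardize_traits,
)
from .oracles import brute_cwm, brute_gower, brute_mpd


class TestGower:
    def test_single_trait_range_normalization(self):
        tt = TraitTable(pd.DataFrame({"LT": [0.0, 1.0, 2.0]}, index=list("abc")),
                        standardized=True)
        d = gower_distance(tt).values
        assert d[0, 2] == pytest.approx(1.0)
        assert d[0, 1] == pytest.approx(0.5)
        assert d[1, 2] == pytest.approx(0.5)

    def test_identical_species_distance_zero(self):
        tt = TraitTable(pd.DataFrame({"LT": [1.0, 1.0, 3.0], "SLA": [5.0, 5.0, 9.0]},
                                     index=list("abc")), standardized=True)
        assert gower_distance(tt).values[0, 1] == 0.0

    def test_multi_trait_unweighted_mean(self):
        tt = TraitTable(
            pd.DataFrame({"A": [0.0, 0.2, 1.0], "B": [0.0, 0.6, 1.0]}, index=list("abc")),
            standardized=True,
        )
        d = gower_distance(tt).values
        assert d[0, 1] == pytest.approx(0.4)  # mean of 0.2 and 0.6

    def test_constant_trait_errors_by_name(self):
        tt = TraitTable(pd.DataFrame({"LT": [1.0, 1.0]}, index=list("ab")), standardized=True)
        with pytest.raises(ValueError, match="LT"):
            gower_distance(tt)

    def test_single_trait_invariant_to_standardization(self, small_traits):
        raw = gower_distance(small_traits, ["LT"]).values
        z = gower_distance(standardize_traits(small_traits), ["LT"]).values
        assert np.allclose(raw, z, atol=1e-12)

    def test_matches_brute_force(self, small_traits):
        cols = {t: small_traits.values[t].tolist() for t in small_traits.trait_names}
        expected = np.array(brute_gower(cols))
        got = gower_distance(small_traits).values
        assert np.allclose(got, expected, atol=1e-12)


class TestMPD:
    def _dm(self):
        tt = TraitTable(pd.DataFrame({"t": [0.0, 1.0, 2.0]}, index=list("abc")),
                        standardized=True)
        return gower_distance(tt)

    def test_three_species_mean_of_pairs(self):
        # pairs: d(ab)=0.5, d(ac)=1.0, d(bc)=0.5 -> mean 2/3
        assert mpd([1.0, 1.0, 1.0], self._dm()) == pytest.approx(2.0 / 3.0)

    def test_two_species_equals_their_distance(self):
        assert mpd([1.0, 0.0, 2.0], self._dm()) == pytest.approx(1.0)

    def test_single_species_undefined(self):
        with pytest.raises(ValueError, match="MPD undefined"):
            mpd([0.0, 3.0, 0.0], self._dm())

    def test_constant_distances_give_constant_mpd(self):
        from funcstruct.datatypes import DistanceMatrix

        c = 0.42
        d = np.full((4, 4), c)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(list("abcd"), d)
        for weights in ([1, 1, 1, 1], [5, 1, 2, 9]):
            assert mpd(weights, dm) == pytest.approx(c)
            assert mpd(weights, dm, abundance_weighted=True) == pytest.approx(c)

    def test_weighted_equals_unweighted_at_equal_abundance(self, small_traits):
        dm = gower_distance(small_traits)
        a = [2.0, 2.0, 2.0, 2.0, 2.0]
        assert mpd(a, dm, abundance_weighted=True) == pytest.approx(mpd(a, dm))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.booleans())
    def test_matches_brute_force(self, seed, weighted):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        traits = {"x": rng.uniform(0, 5, n).tolist(), "y": rng.uniform(0, 2, n).tolist()}
        # guard against zero trait range
        traits["x"][0] += 6.0
        traits["y"][0] += 3.0
        cover = np.where(rng.random(n) < 0.7, rng.uniform(0.5, 10, n), 0.0)
        if (cover > 0).sum() < 2:
            cover[:2] = 1.0
        tt = TraitTable(pd.DataFrame(traits, index=[f"s{i}" for i in range(n)]),
                        standardized=True)
        dm = gower_distance(tt)
        expected = brute_mpd(cover.tolist(), brute_gower(traits), weighted=weighted)
        assert mpd(cover, dm, abundance_weighted=weighted) == pytest.approx(expected, abs=1e-12)


class TestCWM:
    def test_weighted_mean_arithmetic(self):
        assert cwm([3.0, 1.0], [2.0, 4.0]) == pytest.approx(2.5)

    def test_single_species_returns_its_trait(self):
        assert cwm([0.0, 7.0], [1.0, 3.3]) == pytest.approx(3.3)

    def test_shared_trait_value_is_fixed_point(self):
        assert cwm([5.0, 1.0, 2.0], [4.2, 4.2, 4.2]) == pytest.approx(4.2)

    def test_zero_total_abundance_undefined(self):
        with pytest.raises(ValueError, match="CWM undefined"):
            cwm([0.0, 0.0], [1.0, 2.0])

    def test_rescaling_invariance(self):
        a = np.array([3.0, 1.0, 2.0])
        t = [1.0, 5.0, 2.0]
        assert cwm(a, t) == pytest.approx(cwm(17.3 * a, t))

    def test_bounded_by_present_trait_range(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.uniform(0, 4, 6) * (rng.random(6) < 0.8)
            if a.sum() == 0:
                a[0] = 1.0
            t = rng.uniform(-3, 3, 6)
            v = cwm(a, t)
            present = t[a > 0]
            assert present.min() - 1e-12 <= v <= present.max() + 1e-12


class TestCommunityMetrics:
    def test_row_counts(self, small_community, small_traits):
        table = community_metrics(small_community, standardize_traits(small_traits))
        # 3 traits x (5 CWM plots + 4 MPD plots with richness >= 2)
        assert len(table[table.metric == "CWM"]) == 15
        assert len(table[table.metric == "MPD"]) == 12
        assert not table[(table.metric == "MPD") & (table.n_species < 2)].shape[0]

    def test_species_order_invariance(self, small_community, small_traits):
        tt = standardize_traits(small_traits)
        base = community_metrics(small_community, tt)
        perm = ["sp3", "sp1", "sp5", "sp2", "sp4"]
        cm2 = type(small_community)(small_community.abundance[perm], small_community.site_of)
        other = community_metrics(cm2, tt)
        merged = base.merge(other, on=["plot", "trait", "metric"], suffixes=("_a", "_b"))
        assert np.allclose(merged["value_a"], merged["value_b"], atol=1e-12)

    def test_duplicating_a_plot_leaves_mpd_unchanged(self, small_community, small_traits):
        tt = standardize_traits(small_traits)
        ab = pd.concat([small_community.abundance,
                        small_community.abundance.loc[["P4"]].rename(index={"P4": "P4b"})])
        sites = pd.concat([small_community.site_of, pd.Series({"P4b": "B"})])
        cm2 = type(small_community)(ab, sites)
        a = community_metrics(small_community, tt)
        b = community_metrics(cm2, tt)
        for trait in tt.trait_names:
            v = a[(a["plot"] == "P4") & (a.trait == trait) & (a.metric == "MPD")]["value"].iloc[0]
            w = b[(b["plot"] == "P4b") & (b.trait == trait) & (b.metric == "MPD")]["value"].iloc[0]
            assert v == pytest.approx(w, abs=1e-12)

    def test_matches_brute_force_on_fixture(self, small_community, small_traits):
        tt = standardize_traits(small_traits)
        table = community_metrics(small_community, tt)
        for trait in tt.trait_names:
            dist = brute_gower({trait: tt.values[trait].tolist()})
            for k, plot in enumerate(small_community.plot_ids):
                cover = small_community.abundance.iloc[k].tolist()
                exp_mpd = brute_mpd(cover, dist)
                exp_cwm = brute_cwm(cover, tt.values[trait].tolist())
                sel = table[(table["plot"] == plot) & (table.trait == trait)]
                if exp_mpd is not None:
                    got = sel[sel["metric"] == "MPD"]["value"].iloc[0]
                    assert got == pytest.approx(exp_mpd, abs=1e-12)
                got = sel[sel["metric"] == "CWM"]["value"].iloc[0]
                assert got == pytest.approx(exp_cwm, abs=1e-12)
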