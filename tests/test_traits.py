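import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcstruct import (
    CorrelationPruner,
    TraitStandardizer,
    TraitTable,
    aggregate_species_traits,
    derive_leaf_traits,
    prune_correlated_traits,
    standardize_traits,
)


def leaf_frame(rows):
    cols = (
        "species plot leaf_index saturated_mass_mg dry_mass_mg area_mm2 "
        "perimeter_mm length_mm width_mm thickness_mm plant_height_mm"
    ).split()
    return pd.DataFrame(rows, columns=cols)


class TestDeriveLeafTraits:
    def test_ratio_definitions(self):
        df = leaf_frame([["sp1", "p1", 1, 100.0, 10.0, 200.0, 60.0, 30.0, 10.0, 0.5, 300.0]])
        out = derive_leaf_traits(df)
        row = out.iloc[0]
        assert row["SLA"] == pytest.approx(20.0)  # 200 mm2 / 10 mg
        assert row["LDMC"] == pytest.approx(0.1)  # 10 mg / 100 mg
        assert row["LS"] == pytest.approx(3.0)
        assert row["LT"] == 0.5 and row["PH"] == 300.0
        assert row["LA"] == 200.0 and row["LP"] == 60.0

    def test_half_saturated_mass_gives_ldmc_half(self):
        df = leaf_frame([["sp1", "p1", 1, 100.0, 50.0, 150.0, 50.0, 20.0, 20.0, 0.4, 200.0]])
        assert derive_leaf_traits(df)["LDMC"].iloc[0] == pytest.approx(0.5)

    def test_square_leaf_has_ls_one(self):
        df = leaf_frame([["sp1", "p1", 1, 80.0, 20.0, 150.0, 50.0, 12.0, 12.0, 0.4, 200.0]])
        assert derive_leaf_traits(df)["LS"].iloc[0] == pytest.approx(1.0)

    def test_bad_records_rejected(self, caplog):
        df = leaf_frame(
            [
                ["sp1", "p1", 1, 100.0, 10.0, 200.0, 60.0, 30.0, 10.0, 0.5, 300.0],
                ["sp1", "p1", 2, 100.0, 0.0, 200.0, 60.0, 30.0, 10.0, 0.5, 300.0],
                ["sp1", "p1", 3, 100.0, 10.0, 200.0, 60.0, 30.0, 0.0, 0.5, 300.0],
                ["sp1", "p1", 4, 40.0, 50.0, 200.0, 60.0, 30.0, 10.0, 0.5, 300.0],
            ]
        )
        with caplog.at_level("WARNING"):
            out = derive_leaf_traits(df)
        assert len(out) == 1
        assert sum("rejecting leaf record" in r.message for r in caplog.records) == 3


class TestAggregation:
    def test_species_plot_mean(self):
        rows = [
            ["sp1", "p1", i + 1, 100.0, 10.0, 200.0, 60.0, 30.0, 10.0, lt, 300.0]
            for i, lt in enumerate([1.0, 1.2, 1.4])
        ]
        by_plot = aggregate_species_traits(derive_leaf_traits(leaf_frame(rows)), "species_plot")
        assert by_plot.loc[("sp1", "p1"), "LT"] == pytest.approx(1.2)

    def test_species_level_is_mean_of_plot_means(self):
        rows = [
            ["sp1", "p1", 1, 100.0, 10.0, 200.0, 60.0, 30.0, 10.0, 2.0, 300.0],
            ["sp1", "p2", 1, 100.0, 10.0, 200.0, 60.0, 30.0, 10.0, 4.0, 300.0],
            ["sp1", "p2", 2, 100.0, 10.0, 200.0, 60.0, 30.0, 10.0, 4.0, 300.0],
        ]
        tt = aggregate_species_traits(derive_leaf_traits(leaf_frame(rows)), "species")
        # plot means 2 and 4 -> unweighted species mean 3, despite 2 leaves in p2
        assert tt.values.loc["sp1", "LT"] == pytest.approx(3.0)

    def test_single_leaf_identity(self):
        rows = [["sp1", "p1", 1, 100.0, 10.0, 200.0, 60.0, 30.0, 10.0, 0.7, 250.0]]
        tt = aggregate_species_traits(derive_leaf_traits(leaf_frame(rows)), "species")
        assert tt.values.loc["sp1", "LT"] == pytest.approx(0.7)
        assert tt.values.loc["sp1", "SLA"] == pytest.approx(20.0)

    @settings(deadline=None, max_examples=20)
    @given(st.randoms(use_true_random=False))
    def test_record_order_invariance(self, rnd):
        rows = [
            [f"sp{s}", f"p{p}", i, 100.0, 10.0 + i, 200.0, 60.0, 30.0, 10.0, 0.5 + 0.1 * i, 300.0]
            for s in (1, 2)
            for p in (1, 2)
            for i in (1, 2, 3)
        ]
        shuffled = rows[:]
        rnd.shuffle(shuffled)
        a = aggregate_species_traits(derive_leaf_traits(leaf_frame(rows)), "species")
        b = aggregate_species_traits(derive_leaf_traits(leaf_frame(shuffled)), "species")
        assert a.equals(b)


class TestPruning:
    def test_perfect_correlation_drops_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 2, 20)
        tt = TraitTable(pd.DataFrame({"LT": a, "PH": 2 * a, "SLA": rng.uniform(5, 20, 20)},
                                     index=[f"s{i}" for i in range(20)]))
        pruned = prune_correlated_traits(tt)
        assert len(pruned.trait_names) == 2
        assert "SLA" in pruned.trait_names
        assert {"LT", "PH"} & set(pruned.trait_names)

    def test_uncorrelated_unchanged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"),
                          index=[f"s{i}" for i in range(50)])
        pruned = CorrelationPruner().fit(df)
        assert pruned.kept_ == list("abcd")

    def test_victim_has_larger_mean_correlation(self):
        # x ~ y strongly; y also tracks z, x does not -> y is pruned
        rng = np.random.default_rng(2)
        z = rng.standard_normal(200)
        y = rng.standard_normal(200) + 0.8 * z
        x = y + 0.1 * rng.standard_normal(200)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        pruner = CorrelationPruner().fit(df)
        assert pruner.dropped_[0][0] == "y"

    def test_max_pairwise_r_below_threshold_property(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((60, 3))
        mixed = np.column_stack([base, base @ rng.uniform(-1, 1, (3, 4))])
        df = pd.DataFrame(mixed, columns=[f"v{i}" for i in range(7)])
        pruner = CorrelationPruner(threshold=0.7).fit(df)
        corr = df[pruner.kept_].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.7

    def test_constant_column_removed_first(self):
        df = pd.DataFrame({"c": np.ones(10), "a": np.arange(10.0), "b": np.arange(10.0) ** 2})
        pruner = CorrelationPruner().fit(df)
        assert pruner.dropped_[0][0] == "c"


class TestStandardize:
    def test_three_values_closed_form(self):
        tt = TraitTable(pd.DataFrame({"LT": [1.0, 2.0, 3.0]}, index=list("abc")))
        z = standardize_traits(tt)
        # sample-SD convention: SD of {1,2,3} is 1
        assert np.allclose(z.values["LT"].to_numpy(), [-1.0, 0.0, 1.0])
        assert z.standardized and z.meta["sd_convention"] == "sample (n-1)"

    def test_zero_mean_unit_sd(self, small_traits):
        z = standardize_traits(small_traits)
        assert np.all(np.abs(z.values.mean()) < 1e-12)
        assert np.all(np.abs(z.values.std(ddof=1) - 1) < 1e-12)

    def test_idempotence(self, small_traits):
        once = standardize_traits(small_traits)
        twice = standardize_traits(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_ranking_preserved(self, small_traits):
        z = standardize_traits(small_traits)
        for trait in small_traits.trait_names:
            assert (
                small_traits.values[trait].rank() == z.values[trait].rank()
            ).all()

    def test_constant_trait_errors_by_name(self):
        tt = TraitTable(pd.DataFrame({"LT": [1.0, 1.0, 1.0]}, index=list("abc")))
        with pytest.raises(ValueError, match="LT"):
            standardize_traits(tt)

    def test_sklearn_params_round_trip(self):
        s = TraitStandardizer(ddof=1)
        assert TraitStandardizer(**s.get_params()).get_params() == s.get_params()
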