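"""Filtering, rarefaction, Hill numbers, log-ratio, aggregation, biomes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilrich.community import (
    ASVTable,
    aggregate_sites,
    compare_biomes,
    compute_diversity,
    filter_taxa,
    grid_search_depth,
    hill_diversity,
    log_ratio,
    rare_common_split,
    rarefy,
    repeated_rarefaction,
)


class TestFilterTaxa:
    def test_toy_rules(self, toy_table):
        filtered, report = filter_taxa(toy_table)
        # one archaeon and one global singleton removed, three retained
        assert filtered.n_taxa == 3
        assert "t_arch" not in filtered.counts.index
        assert "t_single" not in filtered.counts.index
        assert report["retained"] == pytest.approx(3 / 5)

    def test_identity_when_nothing_to_remove(self, toy_table):
        once, _ = filter_taxa(toy_table)
        twice, report = filter_taxa(once)
        assert twice.counts.equals(once.counts)
        assert report["retained"] == 1.0

    def test_all_singletons_warns_and_empties(self):
        counts = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=["a", "b"])
        t = ASVTable(
            counts,
            pd.Series(["Bacteria", "Bacteria"], index=counts.index),
            pd.DataFrame({"site": ["A", "B"], "lat": [0.0, 0.0], "lon": [0.0, 0.0]},
                         index=counts.columns),
        )
        with pytest.warns(UserWarning):
            filtered, _ = filter_taxa(t)
        assert filtered.n_taxa == 0

    def test_unknown_kingdom_label_rejected(self, toy_table):
        toy_table.kingdom.iloc[0] = "Eukaryota"
        with pytest.raises(ValueError, match="kingdom"):
            filter_taxa(toy_table)


class TestRarefaction:
    def test_columns_sum_to_depth_and_exhaustive_draw(self, toy_table):
        depth = 20  # equals the shallowest sufficient totals below
        r = rarefy(toy_table, depth=20, seed=1)
        sums = r.counts.sum(axis=0)
        assert (sums == depth).all()

    def test_depth_equal_to_total_returns_sample_unchanged(self, toy_table):
        totals = toy_table.counts.sum(axis=0)
        r = rarefy(toy_table, depth=int(totals["s2"]), seed=0)
        assert (r.counts["s2"] == toy_table.counts["s2"]).all()

    def test_shallow_samples_dropped_with_warning(self, toy_table):
        with pytest.warns(UserWarning, match="shallower"):
            r = rarefy(toy_table, depth=30, seed=0)
        assert "s2" not in r.counts.columns  # s2 holds 26 reads

    def test_single_rep_matches_rarefy_distributionally(self, toy_table):
        one = repeated_rarefaction(toy_table, depth=20, reps=1, seed=3)
        assert (one.counts.sum(axis=0) == 20).all()

    def test_averaged_column_sums_exact(self, toy_table):
        avg = repeated_rarefaction(toy_table, depth=20, reps=25, seed=3)
        assert np.allclose(avg.counts.sum(axis=0), 20.0)

    def test_hypergeometric_expectation(self):
        # one deep sample: averaged count of taxon i ~ depth * c_i / C
        counts = pd.DataFrame({"s": [500, 300, 200]}, index=["a", "b", "c"])
        t = ASVTable(
            counts,
            pd.Series(["Bacteria"] * 3, index=counts.index),
            pd.DataFrame({"site": ["A"], "lat": [0.0], "lon": [0.0]}, index=["s"]),
        )
        depth, reps = 100, 100
        avg = repeated_rarefaction(t, depth=depth, reps=reps, seed=9)
        c = counts["s"].to_numpy()
        p = c / c.sum()
        expected = depth * p
        # SE of the mean of `reps` hypergeometric draws
        var = depth * p * (1 - p) * (c.sum() - depth) / (c.sum() - 1)
        se = np.sqrt(var / reps)
        assert np.all(np.abs(avg.counts["s"].to_numpy() - expected) < 3 * se + 1e-9)

    def test_taxon_reordering_equivariance(self, toy_table):
        avg = repeated_rarefaction(toy_table, depth=20, reps=60, seed=5)
        perm = toy_table.counts.index[::-1]
        t2 = ASVTable(
            toy_table.counts.loc[perm], toy_table.kingdom.loc[perm],
            toy_table.sample_meta,
        )
        avg2 = repeated_rarefaction(t2, depth=20, reps=60, seed=5)
        # same expected table up to Monte-Carlo noise of 60 repetitions
        diff = (avg2.counts.loc[avg.counts.index] - avg.counts).to_numpy()
        assert np.abs(diff).max() < 2.0

    def test_invalid_depth(self, toy_table):
        with pytest.raises(ValueError):
            rarefy(toy_table, depth=0)


class TestGridSearch:
    def test_all_samples_deep_selects_deepest(self):
        counts = pd.DataFrame(np.full((3, 4), 10000), columns=list("abcd"),
                              index=["t1", "t2", "t3"])
        t = ASVTable(
            counts, pd.Series(["Bacteria"] * 3, index=counts.index),
            pd.DataFrame({"site": list("ABCD"), "lat": [0.0] * 4, "lon": [0.0] * 4},
                         index=counts.columns),
        )
        res = grid_search_depth(t, depths=[2500, 10000, 15000])
        assert res.depth == 15000

    def test_toy_grid_score_enumerable_by_hand(self):
        # four samples: totals 3000, 9000, 9000, 9000
        tot = [3000, 9000, 9000, 9000]
        counts = pd.DataFrame({f"s{i}": [t] for i, t in enumerate(tot)},
                              index=["only"])
        t = ASVTable(
            counts, pd.Series(["Bacteria"], index=["only"]),
            pd.DataFrame({"site": list("ABCD"), "lat": [0.0] * 4, "lon": [0.0] * 4},
                         index=counts.columns),
        )
        depths = [2500, 5000, 7500]
        res = grid_search_depth(t, depths=depths)
        scores = {2500: 1.0 * np.log(2500), 5000: 0.75 * np.log(5000),
                  7500: 0.75 * np.log(7500)}
        assert res.depth == max(scores, key=scores.get)
        assert len(res.diagnostics) == len(depths)

    def test_empty_grid_rejected(self, toy_table):
        with pytest.raises(ValueError):
            grid_search_depth(toy_table, depths=[])


class TestHill:
    def test_equal_abundances_give_s_for_every_order(self):
        for q in [0, 0.5, 1, 2, 3]:
            assert hill_diversity(np.full(7, 0.3), q) == pytest.approx(7.0)

    def test_richness_order_counts_positives(self):
        assert hill_diversity([0.8, 0.2], 0) == 2.0
        assert hill_diversity([5, 0, 3, 0], 0) == 2.0

    def test_shannon_exponential_oracle(self):
        p = np.array([0.8, 0.2])
        h = -np.sum(p * np.log(p))
        assert hill_diversity(p, 1) == pytest.approx(np.exp(h), rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hill_diversity([0.0, 0.0], 1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1e3), min_size=2, max_size=30)
    )
    def test_profile_nonincreasing_in_q(self, abund):
        qs = [0, 0.5, 1, 1.5, 2, 3]
        vals = [hill_diversity(abund, q) for q in qs]
        assert all(a >= b - 1e-8 * abs(a) for a, b in zip(vals, vals[1:]))

    def test_continuity_at_shannon_limit(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = rng.dirichlet(np.ones(15))
            lo = hill_diversity(a, 1 - 1e-7)
            hi = hill_diversity(a, 1 + 1e-7)
            mid = hill_diversity(a, 1)
            assert lo == pytest.approx(mid, abs=1e-4)
            assert hi == pytest.approx(mid, abs=1e-4)


class TestRareCommon:
    def test_single_taxon_is_common(self):
        counts = pd.DataFrame({"s": [42]}, index=["a"])
        t = ASVTable(counts, pd.Series(["Bacteria"], index=["a"]),
                     pd.DataFrame({"site": ["A"], "lat": [0.0], "lon": [0.0]},
                                  index=["s"]))
        assert not rare_common_split(t).loc["a"]

    def test_threshold_arithmetic(self):
        # 1 read of 100,000 -> 1e-5 < 5e-5 -> rare
        counts = pd.DataFrame({"s": [1, 99_999]}, index=["r", "c"])
        t = ASVTable(counts, pd.Series(["Bacteria"] * 2, index=counts.index),
                     pd.DataFrame({"site": ["A"], "lat": [0.0], "lon": [0.0]},
                                  index=["s"]))
        flags = rare_common_split(t)
        assert flags.loc["r"] and not flags.loc["c"]

    def test_partition_of_grand_total(self, small_study):
        t = small_study.asv_table
        flags = rare_common_split(t)
        totals = t.counts.sum(axis=1)
        assert totals[flags].sum() + totals[~flags].sum() == totals.sum()

    def test_log_ratio_values(self):
        assert log_ratio(10, 10, correction=False) == 0.0
        assert log_ratio(20, 10, correction=False) == pytest.approx(np.log(2))
        assert log_ratio(5, 0) == pytest.approx(np.log(5.5 / 0.5))


class TestAggregation:
    def test_same_cell_by_floor_rule(self):
        df = pd.DataFrame({"lat": [10.01, 10.09], "lon": [20.01, 20.09],
                           "richness": [100.0, 200.0]})
        out = aggregate_sites(df)
        assert len(out) == 1
        assert out.loc[0, "n_samples"] == 2
        assert out.loc[0, "richness"] == pytest.approx(150.0)

    def test_cell_boundary_splits(self):
        df = pd.DataFrame({"lat": [10.09, 10.11], "lon": [20.09, 20.11],
                           "richness": [1.0, 2.0]})
        assert len(aggregate_sites(df)) == 2

    def test_partition_of_samples(self, small_study):
        meta = small_study.asv_table.sample_meta
        df = meta.assign(richness=1.0)
        out = aggregate_sites(df)
        assert out["n_samples"].sum() == len(meta)

    def test_bad_coordinates_rejected(self):
        df = pd.DataFrame({"lat": [95.0], "lon": [0.0], "m": [1.0]})
        with pytest.raises(ValueError):
            aggregate_sites(df)


class TestCompareBiomes:
    def test_identical_groups_give_p_one(self):
        vals = [1, 2, 3, 1, 2, 3]
        labels = ["x"] * 3 + ["y"] * 3
        out = compare_biomes(vals, labels)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_minimal_exact_two_sided_p(self):
        # complete separation of two triples: p = 2/C(6,3) = 0.1
        out = compare_biomes([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
        assert out.loc[0, "p_value"] == pytest.approx(0.1)

    def test_p_values_in_unit_interval(self, small_study):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=40)
        labels = rng.choice(["forest", "grassland", "desert"], size=40)
        out = compare_biomes(vals, labels)
        assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_biomes([1, 2, 3], ["a", "a", "a"])


class TestComputeDiversity:
    def test_fields_consistent(self, toy_table):
        div = compute_diversity(toy_table)
        assert (div["hill_0"] == div["richness"]).all()
        assert ((div["n_rare"] + div["n_common"]) == div["richness"]).all()

    def test_directional_rare_loss_with_wetness(self, small_study):
        # rare_sensitivity 2 by default: mean log-ratio above the CWC
        # peak is lower than around it
        div = compute_diversity(small_study.asv_table)
        meta = small_study.asv_table.sample_meta
        site_lr = div["log_ratio"].groupby(meta["site"]).mean()
        cwc = small_study.covariates["CWC"]
        near = site_lr[(cwc > 0.10) & (cwc < 0.25)]
        wet = site_lr[cwc > 0.30]
        assert wet.mean() < near.mean()
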