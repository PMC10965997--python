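import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset, triplicate_specs
from domchemo.chemodiversity import (
    build_dendrogram,
    chemodiversity_analysis,
    estimate_chemodiversity,
    gower_distance,
    pathlength_diversity,
    percent_change_vs_control,
    rao_q,
    rarefy_by_intensity,
)
from domchemo.descriptors import descriptor_table
from domchemo.simulate import generate_formula_universe
from oracles import gower_oracle, pathlength_oracle, rao_oracle


@pytest.fixture(scope="module")
def universe_desc():
    return descriptor_table(generate_formula_universe(40, seed=8))


class TestGower:
    def test_identical_rows_have_zero_distance(self, universe_desc):
        # duplicate row 0, keep a third distinct row so ranges stay nonzero
        desc = pd.concat([universe_desc.iloc[[0]], universe_desc.iloc[[0, 1]]])
        d = gower_distance(desc)
        assert d[0, 1] == 0.0 and d[0, 2] > 0

    def test_opposite_extremes_with_distinct_categories_hit_one(self):
        rows = pd.DataFrame(
            {
                "o_to_c": [0.0, 1.0],
                "h_to_c": [0.3, 2.2],
                "mass": [100.0, 900.0],
                "ai_mod": [0.0, 1.0],
                "dbe": [0.0, 20.0],
                "category8": ["polyphenols", "saturated fatty acids (CHO)"],
            },
            index=["a", "b"],
        )
        d = gower_distance(rows)
        assert d[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, universe_desc):
        desc = universe_desc.iloc[:10]
        d = gower_distance(desc)
        oracle = gower_oracle(
            [row.to_dict() for _, row in desc.iterrows()],
            ["o_to_c", "h_to_c", "mass", "ai_mod", "dbe"],
            "category8",
        )
        assert np.abs(d - oracle).max() <= 1e-12

    def test_symmetric_zero_diagonal_unit_range(self, universe_desc):
        d = gower_distance(universe_desc)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1

    def test_constant_variable_dropped_with_warning(self, universe_desc):
        desc = universe_desc.iloc[:5].copy()
        desc["mass"] = 250.0
        with pytest.warns(UserWarning, match="mass"):
            d = gower_distance(desc)
        assert np.isfinite(d).all()

    def test_nan_descriptor_names_formula(self, universe_desc):
        desc = universe_desc.iloc[:5].copy()
        desc.iloc[2, desc.columns.get_loc("dbe")] = np.nan
        with pytest.raises(ValueError, match=desc.index[2]):
            gower_distance(desc)

    def test_single_formula_rejected(self, universe_desc):
        with pytest.raises(ValueError):
            gower_distance(universe_desc.iloc[:1])


class TestDendrogram:
    def test_three_point_upgma_hand_heights(self):
        # d(A,B)=0.2, d(A,C)=d(B,C)=0.6: AB joins at 0.2, C at 0.6
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        tree = build_dendrogram(d, ["A", "B", "C"])
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.2)
        assert tree.linkage_matrix[1, 2] == pytest.approx(0.6)
        # total branch length: A,B pendants 0.2 each, AB->root 0.4, C pendant 0.6
        assert tree.total_branch_length() == pytest.approx(0.2 + 0.2 + 0.4 + 0.6)

    def test_equal_distances_merge_at_equal_heights(self):
        n = 6
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        tree = build_dendrogram(d, [f"t{i}" for i in range(n)])
        assert np.allclose(tree.linkage_matrix[:, 2], 0.5)

    def test_merge_heights_monotone_nondecreasing(self, universe_desc):
        tree = build_dendrogram(gower_distance(universe_desc), list(universe_desc.index))
        heights = tree.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_ultrametric_tips_equidistant_from_root(self, universe_desc):
        tree = build_dendrogram(gower_distance(universe_desc), list(universe_desc.index))
        root_h = tree.heights[-1]
        # every tip sits at height 0, so root-tip distance is the root height
        assert root_h > 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            build_dendrogram(d, ["a", "b"])

    def test_negative_entries_rejected(self):
        d = np.array([[0.0, -0.2], [-0.2, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            build_dendrogram(d, ["a", "b"])

    def test_newick_roundtrips_total_length(self, universe_desc):
        tree = build_dendrogram(gower_distance(universe_desc), list(universe_desc.index))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count(",") == tree.n_tips - 1


class TestPathlength:
    def test_all_tips_gives_total_branch_length(self, universe_desc):
        tree = build_dendrogram(gower_distance(universe_desc), list(universe_desc.index))
        assert pathlength_diversity(tree, tree.labels) == pytest.approx(
            tree.total_branch_length()
        )

    def test_single_tip_is_zero(self, universe_desc):
        tree = build_dendrogram(gower_distance(universe_desc), list(universe_desc.index))
        assert pathlength_diversity(tree, [tree.labels[3]]) == 0.0

    def test_star_tree_selected_k_tips_give_k_times_h(self):
        n, h = 8, 0.4
        d = np.full((n, n), h)
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(n)]
        tree = build_dendrogram(d, labels)
        for k in (2, 3, 5, 8):
            got = pathlength_diversity(tree, labels[:k])
            assert got == pytest.approx(k * h, abs=1e-12)

    def test_matches_edge_enumeration_oracle(self, universe_desc):
        desc = universe_desc.iloc[:20]
        tree = build_dendrogram(gower_distance(desc), list(desc.index))
        rng = np.random.default_rng(4)
        for _ in range(25):
            k = int(rng.integers(1, 20))
            tips = rng.choice(desc.index, size=k, replace=False).tolist()
            got = pathlength_diversity(tree, tips)
            want = pathlength_oracle(
                tree.linkage_matrix, tree.n_tips, set(tree.tip_indices(tips))
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_adding_a_tip_never_decreases_diversity(self, universe_desc):
        tree = build_dendrogram(gower_distance(universe_desc), list(universe_desc.index))
        rng = np.random.default_rng(5)
        for _ in range(20):
            base = rng.choice(tree.labels, size=10, replace=False).tolist()
            extra = rng.choice([t for t in tree.labels if t not in base])
            assert pathlength_diversity(tree, base + [extra]) >= pathlength_diversity(
                tree, base
            ) - 1e-12

    def test_unknown_tip_rejected(self, universe_desc):
        tree = build_dendrogram(gower_distance(universe_desc), list(universe_desc.index))
        with pytest.raises(KeyError):
            pathlength_diversity(tree, ["C1H1O1"])


class TestRarefaction:
    def _dataset(self, totals, rng):
        """6 samples with prescribed total intensities over 40 formulae."""
        names = [f"C{10 + i}H{14 + 2 * (i % 4)}O{3 + i % 5}" for i in range(40)]
        specs = triplicate_specs(treatment="control") + triplicate_specs(treatment="s_above")
        mat = {}
        base = rng.lognormal(3, 1, (40, 6))
        base = base / base.sum(axis=0) * np.asarray(totals)
        for i, n in enumerate(names):
            mat[n] = base[i].tolist()
        return make_dataset(mat, specs)

    def test_equal_totals_keep_everything(self):
        rng = np.random.default_rng(0)
        d = self._dataset([100.0] * 6, rng)
        # force exactly equal totals
        x = d.intensities / d.intensities.sum(axis=0) * 100.0
        d = d.with_intensities(x, "equalized")
        sets = rarefy_by_intensity(d, seed=1)
        for sid, pres in sets.items():
            assert pres == frozenset(d.intensities.index[d.intensities[sid] > 0])

    def test_stopping_rule_overshoots_by_at_most_one_compound(self):
        rng = np.random.default_rng(2)
        d = self._dataset([100, 100, 100, 200, 200, 200], rng)
        target = d.intensities.sum(axis=0).min()
        sets = rarefy_by_intensity(d, seed=3)
        for sid in ("alpine_s_above_t0_r1", "alpine_s_above_t0_r2"):
            kept = list(sets[sid])
            total_kept = d.intensities.loc[kept, sid].sum()
            largest = d.intensities.loc[kept, sid].max()
            assert total_kept >= target - 1e-9
            assert total_kept - largest < target

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(4)
        d = self._dataset([100, 120, 140, 160, 180, 200], rng)
        assert rarefy_by_intensity(d, seed=5) == rarefy_by_intensity(d, seed=5)

    def test_common_rescaling_leaves_presence_sets_unchanged(self):
        rng = np.random.default_rng(6)
        d = self._dataset([100, 120, 140, 160, 180, 200], rng)
        scaled = d.with_intensities(d.intensities * 37.5, "scaled")
        assert rarefy_by_intensity(d, seed=7) == rarefy_by_intensity(scaled, seed=7)

    def test_normalized_input_rejected(self):
        from domchemo.qc import normalize

        rng = np.random.default_rng(8)
        d = normalize(self._dataset([100] * 6, rng))
        with pytest.raises(ValueError):
            rarefy_by_intensity(d, seed=1)


@pytest.fixture(scope="module")
def tree(universe_desc):
    return build_dendrogram(gower_distance(universe_desc), list(universe_desc.index))


class TestEstimates:

    def test_identical_sets_and_seed_give_identical_estimates(self, tree):
        pres = frozenset(tree.labels[:25])
        a = estimate_chemodiversity(pres, tree, subsample_size=10, n_iterations=20, seed=9)
        b = estimate_chemodiversity(pres, tree, subsample_size=10, n_iterations=20, seed=9)
        assert (a.values == b.values).all()

    def test_small_set_gives_zero_variance(self, tree):
        pres = frozenset(tree.labels[:5])
        est = estimate_chemodiversity(pres, tree, subsample_size=10, n_iterations=15, seed=1)
        assert est.degenerate
        assert est.values.std() == 0.0
        assert est.values[0] == pytest.approx(pathlength_diversity(tree, pres))

    def test_nested_presence_sets_order_mean_diversity(self, tree):
        big = frozenset(tree.labels)
        small = frozenset(tree.labels[:25])
        e_big = estimate_chemodiversity(big, tree, subsample_size=15, n_iterations=400, seed=2)
        e_small = estimate_chemodiversity(small, tree, subsample_size=15, n_iterations=400, seed=2)
        assert e_small.mean <= e_big.mean * 1.05  # Monte Carlo slack

    def test_empty_presence_set_rejected(self, tree):
        with pytest.raises(ValueError):
            estimate_chemodiversity(frozenset(), tree, seed=1)

    def test_cophenetic_statistic_hand_values(self):
        from domchemo.chemodiversity import mean_cophenetic_distance

        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        t3 = build_dendrogram(d, ["A", "B", "C"])
        assert mean_cophenetic_distance(t3, ["A", "B"]) == pytest.approx(0.2)
        assert mean_cophenetic_distance(t3, ["A", "C"]) == pytest.approx(0.6)
        assert mean_cophenetic_distance(t3, ["A", "B", "C"]) == pytest.approx((0.2 + 0.6 + 0.6) / 3)
        assert mean_cophenetic_distance(t3, ["A"]) == 0.0

    def test_cophenetic_estimates_follow_same_sampling(self, tree):
        pres = frozenset(tree.labels[:5])
        est = estimate_chemodiversity(
            pres, tree, subsample_size=10, n_iterations=5, seed=1, statistic="cophenetic"
        )
        assert est.degenerate and est.values.std() == 0.0
        from domchemo.chemodiversity import mean_cophenetic_distance

        assert est.values[0] == pytest.approx(mean_cophenetic_distance(tree, pres))


class TestRao:
    def test_single_compound_is_zero(self):
        assert rao_q([1.0], np.zeros((1, 1))) == 0.0

    def test_two_compound_hand_value(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert rao_q([0.5, 0.5], d) == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self, universe_desc):
        desc = universe_desc.iloc[:5]
        d = gower_distance(desc)
        p = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        assert rao_q(p, d) == pytest.approx(rao_oracle(p.tolist(), d), abs=1e-12)

    def test_unnormalized_p_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            rao_q([0.5, 0.6], np.zeros((2, 2)))


class TestPercentChange:
    def _estimates(self, mean_by_sample):
        rows = []
        for sid, mean in mean_by_sample.items():
            for it in range(10):
                rows.append({"sample_id": sid, "iteration": it, "diversity": mean})
        return pd.DataFrame(rows)

    def test_identical_treatment_and_control_give_zero(self):
        specs = triplicate_specs(treatment="control") + triplicate_specs(treatment="s_above")
        est = self._estimates({s.sample_id: 5.0 for s in specs})
        out = percent_change_vs_control(est, specs)
        assert np.allclose(out["pct_change"], 0.0)

    def test_ninety_percent_of_control_is_minus_ten(self):
        specs = triplicate_specs(treatment="control") + triplicate_specs(treatment="s_above")
        means = {s.sample_id: (4.5 if s.treatment == "s_above" else 5.0) for s in specs}
        out = percent_change_vs_control(self._estimates(means), specs)
        assert np.allclose(out["pct_change"], -10.0)

    def test_missing_control_raises(self):
        specs = triplicate_specs(treatment="s_above")
        with pytest.raises(ValueError, match="control"):
            percent_change_vs_control(self._estimates({s.sample_id: 1.0 for s in specs}), specs)


class TestFullStage:
    def test_bit_reproducible_under_fixed_seed(self, sim_filtered):
        desc = descriptor_table(sim_filtered.formulae)
        a, _ = chemodiversity_analysis(sim_filtered, desc, subsample_size=200, n_iterations=10, seed=13)
        b, _ = chemodiversity_analysis(sim_filtered, desc, subsample_size=200, n_iterations=10, seed=13)
        pd.testing.assert_frame_equal(a, b)

    def test_correlates_positively_with_rao(self, sim_filtered):
        from domchemo.qc import normalize

        desc = descriptor_table(sim_filtered.formulae)
        est, tree = chemodiversity_analysis(
            sim_filtered, desc, subsample_size=200, n_iterations=10, seed=13
        )
        mean_div = est.groupby("sample_id")["diversity"].mean()
        dist = gower_distance(desc.loc[sim_filtered.intensities.index])
        norm = normalize(sim_filtered)
        raos = {}
        for sid in mean_div.index:
            p = norm.intensities[sid].to_numpy()
            raos[sid] = rao_q(p / p.sum(), dist)
        rao_series = pd.Series(raos)
        r = np.corrcoef(mean_div, rao_series[mean_div.index])[0, 1]
        assert r > 0
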