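import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treekor.clustering import use_precomputed_labels
from treekor.io import SampleMetadata
from treekor.proportions import compute_proportions
from treekor.synthetic import default_spec, generate_dataset
from treekor.testing import adjust_fdr, ttest_two_sample, wilcoxon_rank_sum
from treekor.testing import test_all_nodes as _test_all_nodes

from oracles import bh_adjust_reference, welch_t_reference, wilcoxon_exact_reference


class TestTTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        stat, p = ttest_two_sample(x, x.copy())
        assert stat == 0.0
        assert p == 1.0

    def test_matches_reference_implementation(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 15))
            y = rng.normal(loc=rng.normal(), size=rng.integers(2, 15))
            stat, p = ttest_two_sample(x, y)
            ref_stat, ref_p = welch_t_reference(x, y)
            assert stat == pytest.approx(ref_stat, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)

    def test_antisymmetric_in_group_order(self, rng):
        x, y = rng.normal(size=6), rng.normal(1.0, size=8)
        s1, p1 = ttest_two_sample(x, y)
        s2, p2 = ttest_two_sample(y, x)
        assert s1 == pytest.approx(-s2)
        assert p1 == pytest.approx(p2)

    def test_insufficient_data_is_missing_not_fatal(self):
        stat, p = ttest_two_sample([1.0], [2.0, 3.0])
        assert np.isnan(stat) and np.isnan(p)

    def test_pooled_variant(self, rng):
        from scipy import stats
        x, y = rng.normal(size=7), rng.normal(size=5)
        stat, p = ttest_two_sample(x, y, equal_var=True)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert stat == pytest.approx(float(ref.statistic), abs=1e-10)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-10)


class TestWilcoxon:
    def test_most_extreme_ranking_exact_p(self):
        stat, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)  # 2 / C(4,2)
        assert stat < 0

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 5.0]
        stat, p = wilcoxon_rank_sum(x, list(x))
        assert p == pytest.approx(1.0)
        assert stat == 0.0

    def test_exact_untied_matches_enumeration(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 6, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            stat, p = wilcoxon_rank_sum(x, y)
            ref_stat, ref_p = wilcoxon_exact_reference(x, y)
            assert stat == pytest.approx(ref_stat, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)

    def test_tied_fixture_close_to_permutation_enumeration(self, rng):
        # ties switch to the corrected normal approximation, which should
        # track the exact permutation p closely on small fixtures
        for _ in range(8):
            x = rng.integers(0, 6, size=8).astype(float)
            y = rng.integers(1, 7, size=8).astype(float)
            if len(np.unique(np.concatenate([x, y]))) == 16:
                continue  # untied draws take the exact path instead
            _, p = wilcoxon_rank_sum(x, y)
            _, p_ref = wilcoxon_exact_reference(x, y)
            assert p == pytest.approx(p_ref, abs=0.1)


class TestFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.123]), [0.123])

    def test_matches_from_definition_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            got = adjust_fdr(p)
            np.testing.assert_allclose(got, bh_adjust_reference(p), atol=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(got, sm, atol=1e-12)

    def test_nan_passthrough(self):
        out = adjust_fdr([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust_reference([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_and_order_consistent(self, ps):
        adj = adjust_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestTestAllNodes:
    def _run(self, scenario, seed, **kw):
        spec = default_spec(scenario, seed=seed, **kw)
        events, meta, truth = generate_dataset(spec)
        asg = use_precomputed_labels(events, truth.labels)
        props = compute_proportions(asg, truth.tree, events)
        return props, meta, truth

    def test_parent_effect_detected_on_parent_scale(self):
        wins = 0
        for seed in range(10):
            props, meta, _ = self._run("parent_effect", seed, cells_per_sample=1000)
            res = _test_all_nodes(props, meta).set_index("node_id")
            wins += res.loc["A1a", "p_parent"] < res.loc["A1a", "p_total"]
        assert wins >= 9

    def test_results_structure_and_fdr_families(self):
        props, meta, truth = self._run("null", 0, cells_per_sample=500)
        res = _test_all_nodes(props, meta, fdr=True)
        assert truth.tree.root not in set(res["node_id"])
        assert len(res) == len(truth.tree.nodes) - 1
        assert (res["fdr_total"] >= res["p_total"] - 1e-15).all()
        assert (res["fdr_parent"] >= res["p_parent"] - 1e-15).all()
        np.testing.assert_allclose(
            res["fdr_total"], adjust_fdr(res["p_total"]), atol=1e-15)

    def test_wilcoxon_method(self):
        props, meta, _ = self._run("parent_effect", 1, cells_per_sample=500)
        res = _test_all_nodes(props, meta, method="wilcoxon").set_index("node_id")
        assert (res["method"] == "wilcoxon").all()
        assert res.loc["A1a", "p_parent"] < 0.05

    def test_constant_rows_do_not_crash(self):
        props, meta, _ = self._run("null", 2, cells_per_sample=500)
        props.pct_total.iloc[:, :] = 0.5  # degenerate: all-constant rows
        res = _test_all_nodes(props, meta)
        assert (res["stat_total"] == 0).all()
        assert (res["p_total"] == 1).all()

    def test_three_condition_levels_rejected(self):
        props, meta, _ = self._run("null", 3, cells_per_sample=500)
        meta3 = SampleMetadata(table=pd.DataFrame({
            "sample_id": meta.sample_ids,
            "condition": (["X", "Y", "Z"] * 7)[: len(meta.sample_ids)]}))
        with pytest.raises(ValueError, match="two condition levels"):
            _test_all_nodes(props, meta3)

    def test_invariant_to_sample_order_in_metadata(self):
        props, meta, _ = self._run("parent_effect", 4, cells_per_sample=500)
        res1 = _test_all_nodes(props, meta)
        meta_rev = SampleMetadata(table=meta.table.iloc[::-1].reset_index(drop=True),
                                  condition_levels=list(meta.condition_levels))
        res2 = _test_all_nodes(props, meta_rev)
        pd.testing.assert_frame_equal(res1, res2)

    def test_logit_transform_preserves_conclusions_on_clear_effect(self):
        props, meta, _ = self._run("parent_effect", 6, cells_per_sample=4000)
        raw = _test_all_nodes(props, meta).set_index("node_id")
        lg = _test_all_nodes(props, meta, logit=True).set_index("node_id")
        assert lg.loc["A1a", "p_parent"] < lg.loc["A1a", "p_total"]
        assert lg.loc["A1a", "p_parent"] < 0.05
        # monotone transform: statistic signs agree where both defined
        both = raw["stat_parent"].notna() & lg["stat_parent"].notna()
        agree = np.sign(raw.loc[both, "stat_parent"]) == np.sign(lg.loc[both, "stat_parent"])
        assert agree.mean() > 0.9

    def test_permuted_labels_type_i_error(self, rng):
        props, meta, truth = self._run("null", 5, cells_per_sample=500)
        node = "A1"
        vals = props.pct_total.loc[node].to_numpy()
        hits = 0
        n_perm = 500
        for _ in range(n_perm):
            perm = rng.permutation(len(vals))
            _, p = ttest_two_sample(vals[perm[:10]], vals[perm[10:]])
            hits += p < 0.05
        assert 0.03 <= hits / n_perm <= 0.07
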