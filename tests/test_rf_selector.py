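import numpy as np
import pandas as pd
import pytest

from markerforest.rf_selector import (
    RFConfig,
    RepeatResults,
    aggregate_confusion,
    aggregate_importance,
    augment_features,
    stability_check,
    take_top_out_selection,
    train_rf_repeats,
)

from conftest import build_matrix


def separable_matrix(rng, n_noise=5, per_class=10):
    """One feature cleanly separates three classes; the rest is noise."""
    ns = 3 * per_class
    classes = ["A"] * per_class + ["B"] * per_class + ["C"] * per_class
    sep = np.concatenate([
        rng.uniform(1, 2, per_class),
        rng.uniform(10, 12, per_class),
        rng.uniform(50, 60, per_class),
    ])
    noise = rng.uniform(1, 60, size=(n_noise, ns))
    return build_matrix(np.vstack([sep, noise]), classes=classes)


class TestTrainRepeats:
    def test_separable_case(self, rng):
        m = separable_matrix(rng)
        cfg = RFConfig(n_trees=100, n_repeats=10, base_seed=5, mda_permutations=3)
        res = train_rf_repeats(m, config=cfg)
        sep_id = m.feature_ids[0]
        # the separating feature has top MDA in every repeat
        assert (res.mda.idxmax(axis=1) == sep_id).all()
        # every held-out confusion matrix is diagonal
        for cm in res.confusions:
            assert np.trace(cm.to_numpy()) == cm.to_numpy().sum()
        assert res.errors == [0.0] * 10

    def test_deterministic_under_fixed_seed(self, rng):
        m = separable_matrix(rng)
        cfg = RFConfig(n_trees=60, n_repeats=3, base_seed=17)
        r1 = train_rf_repeats(m, config=cfg)
        r2 = train_rf_repeats(m, config=cfg)
        pd.testing.assert_frame_equal(r1.mda, r2.mda)
        pd.testing.assert_frame_equal(r1.mdg, r2.mdg)
        for a, b in zip(r1.confusions, r2.confusions):
            pd.testing.assert_frame_equal(a, b)

    def test_pure_noise_near_chance(self, rng):
        """Monte-Carlo: held-out accuracy of a pure-noise model is ~0.5."""
        vals = rng.uniform(1, 10, size=(20, 40))
        m = build_matrix(vals, classes=["A"] * 20 + ["B"] * 20)
        cfg = RFConfig(n_trees=40, n_repeats=60, base_seed=3, mda_permutations=1)
        res = train_rf_repeats(m, config=cfg)
        acc = 1.0 - float(np.mean(res.errors))
        # sampling error of 60 repeats × 20 held-out samples
        assert abs(acc - 0.5) < 0.1

    def test_unstratified_exhausts_retries(self, rng):
        vals = rng.uniform(1, 5, size=(3, 10))
        classes = ["A"] * 9 + ["B"]  # B almost never lands in a 2-sample draw
        m = build_matrix(vals, classes=classes)
        cfg = RFConfig(n_trees=10, n_repeats=2, train_count=2, stratified=False,
                       max_split_retries=3, base_seed=1)
        with pytest.raises(ValueError, match="stratified"):
            train_rf_repeats(m, config=cfg)


def _results_from(mda_rows, mdg_rows, fids):
    return RepeatResults(
        mda=pd.DataFrame(mda_rows, columns=fids),
        mdg=pd.DataFrame(mdg_rows, columns=fids),
        confusions=[],
        errors=[0.0] * len(mda_rows),
        classes=["A", "B"],
    )


class TestAggregateImportance:
    def test_two_point_mean_and_se(self):
        res = _results_from([[1.0], [3.0]], [[0.5], [0.5]], ["f1"])
        table = aggregate_importance(res).table
        assert table.loc["f1", "mda_mean"] == 2.0
        assert table.loc["f1", "mda_se"] == pytest.approx(1.0)

    def test_perfect_linearity_r2(self):
        mda = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]
        mdg = [[2.0, 4.0, 6.0], [2.0, 4.0, 6.0]]
        agg = aggregate_importance(_results_from(mda, mdg, ["a", "b", "c"]))
        assert agg.r_squared == pytest.approx(1.0)

    def test_constant_mda_degenerate(self):
        mda = [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]
        mdg = [[3.0, 2.0, 1.0], [3.0, 2.0, 1.0]]
        agg = aggregate_importance(_results_from(mda, mdg, ["b", "c", "a"]))
        assert agg.r_squared is None
        # ties broken lexicographically
        ranked = agg.table.sort_values("rank").index.tolist()
        assert ranked == ["a", "b", "c"]

    def test_ranks_are_permutation(self, rng):
        mda = rng.uniform(0, 1, size=(4, 7))
        mdg = rng.uniform(0, 1, size=(4, 7))
        agg = aggregate_importance(_results_from(mda, mdg, [f"f{i}" for i in range(7)]))
        assert sorted(agg.table["rank"]) == list(range(1, 8))


class TestStabilityCheck:
    def _table(self, mda, r2_pair):
        res = _results_from([mda, mda], [r2_pair, r2_pair], [f"f{i}" for i in range(len(mda))])
        return aggregate_importance(res)

    def test_fixed_point_is_stable(self):
        t = self._table([3.0, 2.0, 1.0], [3.0, 2.0, 1.0])
        assert stability_check([t, t], k=2, eps=0.01)

    def test_r2_jump_fails(self):
        a = self._table([3.0, 2.0, 1.0], [3.0, 2.0, 1.0])  # r2 = 1
        b = self._table([3.0, 2.0, 1.0], [1.0, 3.0, 1.9])  # lower r2
        assert a.r_squared == pytest.approx(1.0)
        assert b.r_squared < 0.99
        assert not stability_check([a, b], k=2, eps=0.01)

    def test_top_set_change_fails(self):
        a = self._table([3.0, 2.0, 1.0], [3.0, 2.0, 1.0])
        b = self._table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # reversed ranks, same r2
        assert not stability_check([a, b], k=1, eps=0.5)


class TestAggregateConfusion:
    def test_all_diagonal(self):
        cm = pd.DataFrame([[5, 0], [0, 7]], index=["A", "B"], columns=["A", "B"])
        summ = aggregate_confusion([cm, cm])
        assert (summ.per_class[["fnr_avg", "fdr_avg", "fnr_max", "fdr_max"]].to_numpy() == 0).all()
        assert summ.overall_error_mean_pct == 0.0

    def test_hand_computed_rates(self):
        # true A: TP=8, FN=2; true B: 1 predicted A (FP for A), 9 correct
        cm = pd.DataFrame([[8, 2], [1, 9]], index=["A", "B"], columns=["A", "B"])
        summ = aggregate_confusion([cm])
        assert summ.per_class.loc["A", "fnr_avg"] == pytest.approx(0.2)
        assert summ.per_class.loc["A", "fdr_avg"] == pytest.approx(1 / 9)

    def test_two_model_overall_stats(self):
        # errors 4 % and 10 % of 50 predictions
        a = pd.DataFrame([[48, 2], [0, 0]], index=["A", "B"], columns=["A", "B"])
        b = pd.DataFrame([[45, 5], [0, 0]], index=["A", "B"], columns=["A", "B"])
        summ = aggregate_confusion([a, b])
        assert summ.overall_error_mean_pct == pytest.approx(7.0)
        assert summ.overall_error_sd_pct == pytest.approx(np.std([4.0, 10.0], ddof=1))

    def test_never_predicted_class_excluded_from_fdr(self):
        cm = pd.DataFrame([[10, 0], [3, 0]], index=["A", "B"], columns=["A", "B"])
        summ = aggregate_confusion([cm])
        assert summ.per_class.loc["B", "n_fdr_defined"] == 0
        assert np.isnan(summ.per_class.loc["B", "fdr_avg"])

    def test_counting_oracle_on_random_matrices(self, rng):
        """Rates recomputed from raw matrices by explicit counting match."""
        classes = ["A", "B", "C"]
        cms = []
        for _ in range(6):
            cms.append(pd.DataFrame(rng.integers(1, 20, size=(3, 3)),
                                    index=classes, columns=classes))
        summ = aggregate_confusion(cms)
        for c in classes:
            fnrs, fdrs = [], []
            for cm in cms:
                tp = cm.loc[c, c]
                fn = sum(cm.loc[c, q] for q in classes if q != c)
                fp = sum(cm.loc[t, c] for t in classes if t != c)
                fnrs.append(fn / (fn + tp))
                fdrs.append(fp / (fp + tp))
            assert summ.per_class.loc[c, "fnr_avg"] == pytest.approx(np.mean(fnrs))
            assert summ.per_class.loc[c, "fnr_max"] == pytest.approx(np.max(fnrs))
            assert summ.per_class.loc[c, "fdr_avg"] == pytest.approx(np.mean(fdrs))
            assert summ.per_class.loc[c, "fdr_max"] == pytest.approx(np.max(fdrs))
        errs = [100 * (1 - np.trace(cm.to_numpy()) / cm.to_numpy().sum()) for cm in cms]
        assert summ.overall_error_mean_pct == pytest.approx(np.mean(errs))


class TestTakeTopOut:
    def test_zero_ceiling_stops_immediately(self, rng):
        m = separable_matrix(rng)
        cfg = RFConfig(n_trees=40, n_repeats=2, base_seed=2, error_ceiling=0.0)
        trace = take_top_out_selection(m, config=cfg)
        assert len(trace.steps) == 1
        assert trace.stop_reason == "error_ceiling"

    def test_pure_noise_stops_at_first_iteration(self, rng):
        vals = rng.uniform(1, 10, size=(12, 24))
        classes = [c for c in "ABCD" for _ in range(6)]
        m = build_matrix(vals, classes=classes)
        cfg = RFConfig(n_trees=60, n_repeats=4, base_seed=9, error_ceiling=0.33)
        trace = take_top_out_selection(m, config=cfg)
        assert trace.steps[0].overall_error > 0.33
        assert len(trace.steps) == 1
        assert trace.stop_reason == "error_ceiling"

    def test_informative_compounds_selected_then_ceiling(self, rng):
        """Three planted compounds (2 redundant features each) are extracted
        before the error rises above the ceiling."""
        per_class = 10
        ns = 3 * per_class
        classes = ["A"] * per_class + ["B"] * per_class + ["C"] * per_class
        rows, groups = [], {}
        for k, cls in enumerate("ABC"):
            sig = np.where(np.array(classes) == cls,
                           rng.uniform(40, 50, ns), rng.uniform(1, 2, ns))
            rows.append(sig)
            rows.append(sig * 0.6 * np.exp(rng.normal(0, 0.02, ns)))
        noise = [rng.uniform(1, 50, ns) for _ in range(6)]
        vals = np.vstack(rows + noise)
        m = build_matrix(vals)
        # rebuild classes: build_matrix used default single class
        m = build_matrix(vals, classes=classes)
        for k in range(3):
            groups[m.feature_ids[2 * k]] = f"cmp{k}"
            groups[m.feature_ids[2 * k + 1]] = f"cmp{k}"
        cfg = RFConfig(n_trees=80, n_repeats=4, base_seed=21, error_ceiling=0.33,
                       max_vars_per_node=4, max_iterations=8)
        trace = take_top_out_selection(m, groups=groups, config=cfg)
        assert trace.stop_reason == "error_ceiling"
        assert len(trace.steps) == 3
        # every iteration picks a planted compound (with its redundant twin);
        # the error stays at 0 while two markers remain and rises above the
        # ceiling once only one class is still identifiable
        picked = [groups.get(s.selected_feature) for s in trace.steps]
        assert sorted(picked) == ["cmp0", "cmp1", "cmp2"]
        assert all(s.overall_error == 0.0 for s in trace.steps[:-1])
        selected = trace.selected_features()
        assert {groups.get(f) for f in selected} == {"cmp0", "cmp1", "cmp2"}
        assert len(selected) == 6  # redundant partners co-removed

    def test_trace_features_disjoint(self, rng):
        m = separable_matrix(rng, n_noise=8)
        cfg = RFConfig(n_trees=40, n_repeats=3, base_seed=4, error_ceiling=0.9,
                       max_iterations=4)
        trace = take_top_out_selection(m, config=cfg)
        sel = trace.selected_features()
        assert len(sel) == len(set(sel))


class TestAugmentFeatures:
    def test_union_counts(self, rng):
        parent = build_matrix(rng.uniform(1, 5, size=(92, 6)))
        selected = parent.subset_features(parent.feature_ids[:84])
        extra = parent.feature_ids[84:]
        out = augment_features(selected, parent, extra)
        assert out.n_features == 92
        assert out.feature_ids == parent.feature_ids

    def test_duplicate_id_warns_not_duplicated(self, rng):
        parent = build_matrix(rng.uniform(1, 5, size=(4, 4)))
        selected = parent.subset_features(parent.feature_ids[:3])
        with pytest.warns(UserWarning, match="already present"):
            out = augment_features(selected, parent, [parent.feature_ids[0]])
        assert out.n_features == 3

    def test_empty_extra_is_identity(self, rng):
        parent = build_matrix(rng.uniform(1, 5, size=(4, 4)))
        out = augment_features(parent, parent, [])
        assert out.feature_ids == parent.feature_ids

    def test_unknown_id_is_error(self, rng):
        parent = build_matrix(rng.uniform(1, 5, size=(4, 4)))
        with pytest.raises(KeyError, match="nope"):
            augment_features(parent, parent, ["nope"])
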