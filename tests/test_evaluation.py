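"""ROC/AUC machinery, balanced thresholds and report-table reproduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from auscult import evaluation as ev
from auscult import synthesis as syn
from auscult.types import DataError, INDEX_NAMES


def brute_force_auc(pos, neg) -> float:
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestGroups:
    def test_flag_combinations_map_to_four_distinct_groups(self):
        groups = {ev.assign_group(a, b).group for a in (True, False) for b in (True, False)}
        assert groups == {"AA", "AN", "NA", "NN"}
        assert ev.assign_group(True, True).group == "AA"
        assert ev.assign_group(False, False).group == "NN"

    def test_missing_flag_rejected(self):
        with pytest.raises(DataError):
            ev.assign_group(None, True)


class TestAUC:
    def test_disjoint_ranges(self):
        assert ev.compute_auc([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_identical_multisets_give_half(self):
        assert ev.compute_auc([0.3, 0.7, 0.7], [0.3, 0.7, 0.7]) == pytest.approx(0.5)

    def test_hand_enumerated_example(self):
        assert ev.compute_auc([0.9, 0.7], [0.8, 0.1]) == pytest.approx(0.75)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            ev.compute_auc([], [0.1])

    @settings(max_examples=200, deadline=None)
    @given(data=st.data())
    def test_equals_bruteforce_with_ties(self, data):
        grid = st.integers(0, 10)  # coarse grid forces ties
        pos = data.draw(st.lists(grid, min_size=1, max_size=30))
        neg = data.draw(st.lists(grid, min_size=1, max_size=30))
        auc = ev.compute_auc(pos, neg)
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
        # antisymmetry and monotone-transform invariance
        assert ev.compute_auc(neg, pos) == pytest.approx(1.0 - auc, abs=1e-12)
        f = lambda xs: [np.expm1(x) + 2.0 * x for x in xs]  # strictly increasing
        assert ev.compute_auc(f(pos), f(neg)) == pytest.approx(auc, abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(42)
        pos, neg = rng.normal(0.6, 0.2, 40), rng.normal(0.4, 0.2, 55)
        labels = np.r_[np.ones(40), np.zeros(55)]
        assert ev.compute_auc(pos, neg) == pytest.approx(
            roc_auc_score(labels, np.r_[pos, neg]), abs=1e-12
        )


class TestThresholds:
    def test_separable_threshold_sits_in_gap(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([True, True, False, False])
        thr = ev.select_balanced_threshold(scores, labels)
        assert 0.2 < thr < 0.8
        assert ev.classification_metrics(scores, labels, thr) == (1.0, 1.0, 1.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.random(24).round(2)
            labels = np.r_[np.ones(10, bool), np.zeros(14, bool)]
            thr = ev.select_balanced_threshold(scores, labels)
            uniq = np.unique(scores)
            cands = (uniq[:-1] + uniq[1:]) / 2
            best = min(
                (
                    (abs(s - p), -(s + p - 1), t)
                    for t in cands
                    for s, p, _ in [ev.classification_metrics(scores, labels, t)]
                ),
            )
            assert thr == pytest.approx(best[2])

    def test_all_equal_scores_returns_the_single_candidate(self):
        thr = ev.select_balanced_threshold([0.5, 0.5, 0.5], [True, False, True])
        assert thr == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(DataError):
            ev.select_balanced_threshold([0.1, 0.2], [True, True])

    def test_metrics_hand_counts(self):
        sens, spec, acc = ev.classification_metrics(
            [0.9, 0.4, 0.6, 0.2], [True, True, False, False], 0.5
        )
        assert (sens, spec, acc) == (0.5, 0.5, 0.5)

    def test_all_predicted_positive(self):
        sens, spec, _ = ev.classification_metrics([0.9, 0.8], [True, False], 0.0)
        assert (sens, spec) == (1.0, 0.0)

    def test_reported_operating_point_is_consistent(self):
        rng = np.random.default_rng(11)
        analysis = ev.roc_analysis(rng.normal(0.7, 0.2, 30), rng.normal(0.3, 0.2, 30))
        sens, spec, acc = analysis.sensitivity, analysis.specificity, analysis.accuracy
        assert 0.0 <= analysis.auc <= 1.0
        assert all(0.0 <= m <= 1.0 for m in (sens, spec, acc))
        assert np.all(np.diff(analysis.fpr) >= 0)


class TestTables:
    def test_single_examination_group_has_zero_sd(self):
        rows = []
        for g, v in [("AA", 0.4), ("AN", 0.1), ("NA", 0.3), ("NN", 0.0)]:
            rows.append({"exam_id": g, "group": g, **{n: v for n in INDEX_NAMES}})
        stats = ev.group_statistics(pd.DataFrame(rows))
        assert np.allclose(stats["AA_sd"], 0.0)
        assert np.allclose(stats["AA_mean"], 0.4)

    def test_constant_column_mean_is_constant(self):
        df = syn.simulate_index_dataset(n_per_group=5, seed=0)
        df[list(INDEX_NAMES)] = 0.2
        stats = ev.group_statistics(df)
        assert np.allclose(stats.filter(like="_mean"), 0.2)
        assert np.allclose(stats.filter(like="_sd"), 0.0)

    def test_missing_group_warns_and_flags_nan(self):
        df = syn.simulate_index_dataset(n_per_group=5, seed=0)
        df = df[df["group"] != "NA"]
        with pytest.warns(UserWarning):
            stats = ev.group_statistics(df)
        assert stats["NA_mean"].isna().all()

    def test_null_case_aucs_near_half(self):
        arch = [
            syn.GroupArchetype(
                g, {n: 0.3 for n in INDEX_NAMES}, {n: 0.2 for n in INDEX_NAMES}
            )
            for g in ("AA", "AN", "NA", "NN")
        ]
        df = syn.simulate_index_dataset(tuple(arch), n_per_group=500, seed=2)
        aucs = ev.pairwise_auc_table(df)
        assert aucs.shape == (7, 4)  # cross comparisons excluded
        assert np.all(np.abs(aucs.to_numpy() - 0.5) < 0.05)

    def test_archetype_simulation_recovers_headline_separation(self):
        df = syn.simulate_index_dataset(n_per_group=500, seed=0)
        aucs = ev.pairwise_auc_table(df)
        assert aucs.loc["continuous_phenomena_index", "AA_vs_AN"] > 0.9

    def test_reproduce_tables_bundle(self):
        df = syn.simulate_index_dataset(n_per_group=30, seed=1)
        reports = ev.reproduce_tables(df)
        assert set(reports) == {"group_statistics", "pairwise_auc", "balanced_metrics"}
        assert len(reports["balanced_metrics"]) == 4 * 7
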