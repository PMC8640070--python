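import numpy as np
import pytest

from stratifs.evaluation import (
    EvalRecord,
    ModelSpec,
    compute_metrics,
    default_thresholds,
    mean_metrics,
    nested_cv,
    net_benefit,
    run_grid,
    split_holdout,
    tune_final,
)
from stratifs.simulate import SyntheticConfig, generate_cohort

from conftest import toy_matrix


def separable_matrix(n=200, seed=0):
    """Dosage pattern that linearly separates the classes."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    m = toy_matrix(n=n, p=4, seed=seed, labels=labels)
    m.dosages[:, 0] = np.where(labels == 1, 1.8, 0.2) + rng.uniform(-0.1, 0.1, n)
    return m


class TestSplitHoldout:
    def test_80_20_with_class_ratio_preserved(self):
        m = toy_matrix(n=100, p=2, seed=1, labels=np.array([1] * 40 + [0] * 60))
        train, hold = split_holdout(m, 0.2, seed=0)
        assert train.n == 80 and hold.n == 20
        assert abs(int(hold.label.sum()) - 8) <= 1

    def test_deterministic(self):
        m = toy_matrix(n=60, p=2, seed=2)
        a1, b1 = split_holdout(m, 0.25, seed=5)
        a2, b2 = split_holdout(m, 0.25, seed=5)
        assert a1.sample_ids == a2.sample_ids and b1.sample_ids == b2.sample_ids

    def test_union_and_disjointness(self):
        for seed in range(5):
            m = toy_matrix(n=83, p=2, seed=seed)
            train, hold = split_holdout(m, 0.3, seed=seed)
            ids = set(train.sample_ids) | set(hold.sample_ids)
            assert len(ids) == 83
            assert not (set(train.sample_ids) & set(hold.sample_ids))

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_holdout(toy_matrix(), 1.2, seed=0)


class TestComputeMetrics:
    def test_perfect_scores(self):
        labels = np.array([0, 1, 0, 1])
        got = compute_metrics(labels.astype(float), labels)
        assert all(v == 1.0 for v in got.values())

    def test_all_negative_predictions_use_zero_convention(self):
        labels = np.array([0, 1, 0, 1])
        got = compute_metrics(np.full(4, 0.1), labels)
        assert got["precision"] == 0.0 and got["recall"] == 0.0 and got["f1"] == 0.0

    def test_six_sample_confusion_matrix_by_hand(self):
        # scores: predictions at 0.5 -> [1, 0, 1, 1, 0, 0]; labels [1, 1, 0, 1, 0, 0]
        scores = np.array([0.9, 0.4, 0.7, 0.6, 0.2, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0])
        got = compute_metrics(scores, labels)
        # by hand: TP=2, FP=1, FN=1, TN=2 -> precision 2/3, recall 2/3, acc 4/6
        assert got["precision"] == pytest.approx(2 / 3)
        assert got["recall"] == pytest.approx(2 / 3)
        assert got["accuracy"] == pytest.approx(4 / 6)
        assert got["f1"] == pytest.approx(2 / 3)
        # AUC by pair count: 0.9 beats all 3 negatives, 0.6 and 0.4 beat 0.2 and 0.1 -> 7/9
        assert got["auc"] == pytest.approx(7 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0.2, 0.6]), np.array([1, 1]))


class TestNetBenefit:
    def test_treat_none_is_zero(self):
        labels = np.array([0, 1] * 10)
        curve = net_benefit(np.zeros(20), labels, default_thresholds())
        np.testing.assert_array_equal(curve.treat_none, 0.0)

    def test_treat_all_closed_form(self):
        labels = np.array([1] * 3 + [0] * 7)
        t = np.array([0.25, 0.5, 0.75])
        curve = net_benefit(np.linspace(0, 1, 10), labels, t)
        pi = 0.3
        np.testing.assert_allclose(curve.treat_all, pi - (1 - pi) * t / (1 - t), atol=1e-12)

    def test_direct_arithmetic(self):
        # TP=30, FP=20, N=100 at p_t = 0.25 -> 0.30 - 0.20/3
        labels = np.array([1] * 30 + [0] * 20 + [0] * 40 + [1] * 10)
        scores = np.array([0.9] * 50 + [0.1] * 50)
        curve = net_benefit(scores, labels, [0.25])
        assert curve.net_benefit[0] == pytest.approx(0.30 - 0.20 * (0.25 / 0.75))

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            net_benefit(np.array([0.5]), np.array([0, 1]), [1.0])


class TestNestedCV:
    def test_separable_data_reaches_near_perfect_auc(self):
        m = separable_matrix()
        per_fold = nested_cv(ModelSpec("LR", {"C": [1.0]}), [m.feature_names[0]], m, seed=1)
        assert mean_metrics(per_fold)["auc"] >= 0.99

    def test_deterministic_under_fixed_seed(self):
        m = toy_matrix(n=120, p=4, seed=3)
        spec = ModelSpec("DT", {"max_depth": [1, 2]})
        a = nested_cv(spec, m.feature_names[:2], m, seed=7)
        b = nested_cv(spec, m.feature_names[:2], m, seed=7)
        assert a == b

    def test_permuted_labels_sit_at_chance(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = separable_matrix(seed=seed)
            permuted = toy_matrix(n=m.n, p=4, seed=seed, labels=rng.permutation(m.label))
            permuted.dosages = m.dosages
            per_fold = nested_cv(ModelSpec("LR", {"C": [1.0]}), m.feature_names[:2], permuted, seed=seed)
            aucs.append(mean_metrics(per_fold)["auc"])
        assert 0.45 <= np.mean(aucs) <= 0.55


class TestTuneFinal:
    def test_single_point_grid_chosen(self):
        m = separable_matrix()
        est, params = tune_final(ModelSpec("LR", {"C": [0.1]}), m.feature_names[:1], m, seed=0)
        assert params == {"C": 0.1}

    def test_empty_grid_is_plain_fit(self):
        m = separable_matrix()
        est, params = tune_final(ModelSpec.default("NB"), m.feature_names[:1], m, seed=0)
        assert params == {}
        assert hasattr(est, "predict_proba")

    def test_tuning_beats_or_matches_fixed_default(self):
        """With the generating complexity in the grid, tuning cannot lose on average."""
        diffs = []
        for seed in range(5):
            m = separable_matrix(n=300, seed=seed)
            train, val = split_holdout(m, 0.3, seed=seed)
            tuned, _ = tune_final(ModelSpec("LR", {"C": [0.001, 1.0]}), m.feature_names[:1], train, seed=seed)
            fixed = ModelSpec("LR", {}).build(seed)
            fixed.set_params(C=0.001)
            fixed.fit(train.select_features(m.feature_names[:1]), train.label)
            X = val.select_features(m.feature_names[:1])
            t = compute_metrics(tuned.predict_proba(X)[:, 1], val.label)["auc"]
            f = compute_metrics(fixed.predict_proba(X)[:, 1], val.label)["auc"]
            diffs.append(t - f)
        assert np.mean(diffs) >= 0


class TestRunGrid:
    def make_inputs(self, seed=0):
        m = separable_matrix(n=260, seed=seed)
        train, hold = split_holdout(m, 0.2, seed=seed)
        rankings = {"MIM": list(m.feature_names)}
        return train, hold, rankings

    def test_single_cell_grid_is_best(self):
        train, hold, rankings = self.make_inputs()
        records, best_per_model, best = run_grid(
            train, hold, None, rankings, [1], models=["NB"], seed=1
        )
        assert len(records) == 1
        assert best.model == "NB" and best.n_features == 1
        assert "holdout" in best.metrics

    def test_grid_cell_count(self):
        train, hold, rankings = self.make_inputs()
        rankings["mRMR"] = rankings["MIM"][::-1]
        records, _, _ = run_grid(
            train,
            hold,
            None,
            rankings,
            [1, 2],
            models=["NB", "LR"],
            grids={"LR": {"C": [1.0]}},
            seed=1,
        )
        assert len(records) == 2 * 2 * 2  # criteria x feature counts x models

    def test_best_breaks_ties_toward_fewer_features(self):
        train, hold, rankings = self.make_inputs()
        # feature 0 separates alone; adding more features cannot raise a full AUC of 1
        records, best_per_model, best = run_grid(
            train, hold, None, rankings, [1, 3], models=["LR"], grids={"LR": {"C": [1.0]}}, seed=1
        )
        by_cells = {r.n_features: r.cv_auc for r in records}
        if by_cells[1] == by_cells[3]:
            assert best.n_features == 1

    def test_external_missing_features_rejected(self):
        train, hold, rankings = self.make_inputs()
        external = toy_matrix(n=60, p=2, seed=9)  # lacks the training features? same names p=2
        external.feature_names[0] = "OTHER"
        with pytest.raises(Exception, match="lacks|not in matrix"):
            run_grid(train, hold, external, {"MIM": train.feature_names[:1]}, [1], models=["NB"], seed=1)

    def test_external_phase_scored_when_compatible(self):
        train, hold, rankings = self.make_inputs()
        external = separable_matrix(n=100, seed=33)
        _, best_per_model, best = run_grid(
            train, hold, external, rankings, [1], models=["NB"], seed=1
        )
        assert "external" in best.metrics
        assert best.metrics["external"]["auc"] > 0.95

    def test_monotone_information_with_more_features(self, default_cohort):
        """CV AUC with all features is not materially below the 1-feature cell.

        Needs the full-size cohort: at a few hundred samples the 70-feature
        fit is noise-dominated and the comparison is uninformative.
        """
        m, truth = default_cohort
        rankings = {"MIM": [truth.causal_feature] + [f for f in m.feature_names if f != truth.causal_feature]}
        records, _, _ = run_grid(m, m, None, rankings, [1, m.p], models=["LR"], seed=2)
        by_cells = {r.n_features: r.cv_auc for r in records}
        assert by_cells[m.p] >= by_cells[1] - 0.02

    def test_empty_grid_rejected(self):
        train, hold, rankings = self.make_inputs()
        with pytest.raises(ValueError):
            run_grid(train, hold, None, {}, [1], models=["NB"], seed=1)
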