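"""Fold construction, learning-rate schedule, metrics, aggregation, baseline."""

import numpy as np
import pytest

from slidemil.synthetic import SynthBagConfig, generate_bags
from slidemil.train import (
    FoldSplit,
    TrainConfig,
    aggregate_folds,
    build_model,
    default_train_config,
    evaluate,
    fold_results_frame,
    lr_at_epoch,
    majority_vote_baseline,
    make_folds,
    metrics_from_precision_recall,
    predict_probs,
    train_model,
)

# per-fold validation metrics reported for the tuned CLAM and custom ABMIL runs
CLAM_FOLD_AUCS = [0.774, 0.939, 0.679, 0.929, 0.952]
CLAM_FOLD_ACCS = [0.714, 0.810, 0.667, 0.810, 0.810]
ABMIL_FOLD_AUCS = [0.755, 0.799, 0.720, 0.728, 0.832]
ABMIL_FOLD_ACCS = [0.727, 0.773, 0.727, 0.636, 0.682]


class TestMakeFolds:
    def test_fifteen_cases_five_folds(self):
        cases = [(f"c{i}", i % 3) for i in range(15)]
        folds = make_folds(cases, k=5, seed=0)
        val_sets = [set(f.val_ids) for f in folds]
        assert all(len(f.train_ids) + len(f.val_ids) == 15 for f in folds)
        assert set.union(*val_sets) == {c for c, _ in cases}
        for f in folds:
            assert not set(f.train_ids) & set(f.val_ids)

    def test_deterministic_per_seed(self):
        cases = [(f"c{i}", i % 3) for i in range(30)]
        assert make_folds(cases, seed=5) == make_folds(cases, seed=5)
        assert make_folds(cases, seed=5) != make_folds(cases, seed=6)

    def test_stratified_medium_counts_on_imbalanced_cohort(self):
        """210 cases with priors (0.45, 0.10, 0.45): 21 medium cases spread 4-5
        per validation fold."""
        bags, truth = generate_bags(SynthBagConfig(n_cases=210, dim=4, bag_size_range=(1, 2), seed=0))
        cases = list(zip(truth["case_id"], truth["tier"]))
        folds = make_folds(cases, k=5, seed=1)
        tier_of = dict(cases)
        for f in folds:
            medium = sum(tier_of[c] == 1 for c in f.val_ids)
            assert medium in (4, 5)

    def test_empty_class_rejected(self):
        cases = [(f"c{i}", 0) for i in range(10)]
        with pytest.raises(ValueError):
            make_folds(cases, k=2, seed=0)

    def test_overlap_rejected_in_split_type(self):
        with pytest.raises(ValueError):
            FoldSplit(0, ["a", "b"], ["b"])


class TestLrSchedule:
    def test_after_warmup_constant(self):
        cfg = TrainConfig(lr=3e-5, warmup_epochs=5)
        for epoch in (5, 6, 50):
            assert lr_at_epoch(epoch, cfg) == 3e-5

    def test_linear_ramp(self):
        cfg = TrainConfig(lr=3e-5, warmup_epochs=5)
        assert lr_at_epoch(0, cfg) == pytest.approx(3e-5 / 5)
        assert lr_at_epoch(4, cfg) == pytest.approx(3e-5)

    def test_zero_warmup(self):
        cfg = TrainConfig(lr=1e-3, warmup_epochs=0)
        assert lr_at_epoch(0, cfg) == 1e-3


class TestEvaluate:
    def test_per_class_f1_from_printed_precision_recall(self):
        """The reported per-class precision/recall imply F1 0.889/0.267/0.750
        and macro F1 0.635."""
        precision = [0.857, 0.400, 0.750]
        recall = [0.923, 0.200, 0.750]
        f1, macro = metrics_from_precision_recall(precision, recall)
        np.testing.assert_allclose(f1, [0.889, 0.267, 0.750], atol=5e-4)
        assert macro == pytest.approx(0.635, abs=5e-4)

    def test_perfect_predictions(self):
        tiers = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[tiers]
        r = evaluate(probs, tiers)
        assert r.accuracy == 1.0
        np.testing.assert_allclose(r.f1, 1.0)
        assert r.auc == 1.0
        assert np.trace(r.confusion) == 6

    def test_matches_counting_oracle_on_random_predictions(self, rng):
        tiers = rng.integers(0, 3, size=60)
        probs = rng.dirichlet(np.ones(3), size=60)
        r = evaluate(probs, tiers)
        preds = probs.argmax(axis=1)
        for c in range(3):
            tp = np.sum((preds == c) & (tiers == c))
            fp = np.sum((preds == c) & (tiers != c))
            fn = np.sum((preds != c) & (tiers == c))
            p = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert r.precision[c] == pytest.approx(p)
            assert r.recall[c] == pytest.approx(rec)
            assert r.confusion[c].sum() == np.sum(tiers == c)
        assert r.accuracy == pytest.approx((preds == tiers).mean())
        assert r.macro_f1 == pytest.approx(r.f1.mean())

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(123)
        tiers = rng.integers(0, 3, size=600)
        probs = rng.dirichlet(np.ones(3), size=600)
        r = evaluate(probs, tiers)
        assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_absent_class_warns_and_excludes(self):
        tiers = np.array([0, 0, 2, 2])
        probs = np.array([[0.8, 0.1, 0.1]] * 2 + [[0.1, 0.1, 0.8]] * 2)
        with pytest.warns(UserWarning, match="absent"):
            r = evaluate(probs, tiers)
        assert np.isfinite(r.auc)

    def test_tie_goes_to_lowest_class(self):
        probs = np.array([[0.4, 0.4, 0.2]])
        with pytest.warns(UserWarning):  # single-class truth: AUC classes excluded
            r = evaluate(probs, np.array([0]))
        assert r.accuracy == 1.0


class TestAggregateFolds:
    def test_reported_fold_means(self):
        reports = [
            {"auc": a, "accuracy": acc} for a, acc in zip(CLAM_FOLD_AUCS, CLAM_FOLD_ACCS)
        ]
        agg = aggregate_folds(reports)
        assert agg["auc"][0] == pytest.approx(0.855, abs=5e-4)
        assert agg["accuracy"][0] == pytest.approx(0.762, abs=5e-4)
        reports = [
            {"auc": a, "accuracy": acc} for a, acc in zip(ABMIL_FOLD_AUCS, ABMIL_FOLD_ACCS)
        ]
        agg = aggregate_folds(reports)
        assert agg["auc"][0] == pytest.approx(0.767, abs=5e-4)
        assert agg["accuracy"][0] == pytest.approx(0.709, abs=5e-4)

    def test_identical_reports_zero_sd(self):
        agg = aggregate_folds([{"auc": 0.8}] * 4)
        assert agg["auc"] == (pytest.approx(0.8), pytest.approx(0.0))

    def test_single_report_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([{"auc": 0.8}])


class TestMajorityVote:
    @pytest.mark.parametrize("patches,expected", [
        ([0, 0, 1], 0), ([0, 1], 0), ([2, 2, 2], 2), ([1, 2, 2, 1], 1)])
    def test_votes(self, patches, expected):
        assert majority_vote_baseline([np.array(patches)])[0] == expected

    def test_empty_slide_rejected(self):
        with pytest.raises(ValueError):
            majority_vote_baseline([np.array([], dtype=int)])


class TestTraining:
    def _split(self, bags, n_val=6):
        ids = [b.case_id for b in bags]
        return FoldSplit(0, ids[:-n_val], ids[-n_val:]), {b.case_id: b for b in bags}

    def test_history_and_determinism(self, small_cohort):
        bags, _ = small_cohort
        split, by_id = self._split(bags)
        cfg = default_train_config("abmil", max_epochs=3, early_stop_patience=3)
        m1, h1 = train_model(build_model("abmil", 16, seed=1), by_id, split, cfg)
        m2, h2 = train_model(build_model("abmil", 16, seed=1), by_id, split, cfg)
        assert len(h1) == 3
        assert np.isfinite(h1["train_loss"]).all()
        assert "gate_mean" in h1.columns  # gate-openness telemetry
        assert h1.equals(h2)

    def test_single_step_decreases_loss_on_one_bag(self, small_cohort):
        """Gradient-flow smoke: one small-lr step on a one-bag dataset."""
        bags, _ = small_cohort
        bag = bags[0]
        from slidemil.autodiff import Adam
        from slidemil.losses import FocalParams, make_bag_loss

        model = build_model("clam_sb", 16, seed=0)
        loss_fn = make_bag_loss("focal", FocalParams(np.array([1.0, 3.0, 1.0]), 2.0), None)
        opt = Adam(model.parameters(), lr=1e-3)
        before = float(loss_fn(model.forward(bag)[0], bag.tier).data)
        loss = loss_fn(model.forward(bag)[0], bag.tier)
        opt.zero_grad()
        loss.backward()
        opt.step()
        after = float(loss_fn(model.forward(bag)[0], bag.tier).data)
        assert after < before

    def test_capacity_on_separable_bags(self):
        """Strong effect size and a moderate lr: training accuracy >= 0.95."""
        bags, _ = generate_bags(SynthBagConfig(
            n_cases=24, dim=16, bag_size_range=(8, 16), effect_size=3.0,
            signal_fraction=0.5, seed=3))
        split, by_id = self._split(bags, n_val=4)
        cfg = default_train_config("clam_sb", lr=1e-3, max_epochs=25, early_stop_patience=25)
        model, hist = train_model(build_model("clam_sb", 16, seed=2), by_id, split, cfg)
        train_bags = [by_id[c] for c in split.train_ids]
        probs = predict_probs(model, train_bags)
        acc = (probs.argmax(axis=1) == [b.tier for b in train_bags]).mean()
        assert acc >= 0.95

    def test_fold_results_frame_shape(self, rng):
        tiers = rng.integers(0, 3, 30)
        probs = rng.dirichlet(np.ones(3), 30)
        frame = fold_results_frame([evaluate(probs, tiers)] * 2)
        assert list(frame["fold"]) == [0, 1]
        assert "macro_f1" in frame.columns
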