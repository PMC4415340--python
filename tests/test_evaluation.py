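"""ROC curves, cut-offs, indices, progressive exactness and the pipeline."""

import math
import warnings

import numpy as np
import pytest

from medkb import synthetic_data, transactions
from medkb.evaluation import (
    PipelineConfig,
    best_cutoff,
    classification_indices,
    evaluate_pipeline,
    progressive_exactness,
    roc_curve,
    scale_chi2_cutoff,
)
from medkb.scoring import GoldStandard


def auc_by_pair_counting(scores, labels):
    """Mann-Whitney with half credit for ties — the independent AUC oracle."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_ranking(self):
        assert roc_curve([0.9, 0.8, 0.1], [True, True, False]).auc == 1.0

    def test_all_ties(self):
        assert roc_curve([1.0, 1.0, 1.0, 1.0], [True, False, True, False]).auc == 0.5

    def test_interleaved(self):
        assert roc_curve([3, 2, 1, 0], [True, False, True, False]).auc == 0.75

    def test_endpoints(self):
        c = roc_curve([3, 2, 1, 0], [True, False, True, False])
        assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
        assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])

    @pytest.mark.parametrize("seed", range(25))
    def test_auc_equals_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.choice([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], size=n).tolist()
        labels = (rng.random(n) < 0.5).tolist()
        if all(labels) or not any(labels):
            labels[0] = not labels[0]
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(
            auc_by_pair_counting(scores, labels), abs=1e-12
        )


class TestBestCutoff:
    def test_perfect_separation_threshold(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert best_cutoff(curve) == pytest.approx(0.8)

    def test_tie_breaks_toward_lower_threshold(self):
        curve = roc_curve([3, 2, 1, 0], [True, False, True, False])
        assert best_cutoff(curve) == pytest.approx(1.0)

    def test_lower_cutoff_trades_specificity_for_recall(self):
        scores = [5, 4, 3, 2, 1, 0]
        labels = [True, True, False, True, False, False]
        cuts = sorted(set(scores))
        prev = None
        for cut in cuts[::-1]:  # decreasing cut-off
            rep = classification_indices([s >= cut for s in scores], labels)
            if prev is not None:
                assert rep.recall >= prev.recall
                assert rep.specificity <= prev.specificity
            prev = rep


class TestScaleChi2Cutoff:
    def test_paper_split_sizes(self):
        assert scale_chi2_cutoff(9.0, 1080, 360) == pytest.approx(3.0)

    def test_identity_and_zero(self):
        assert scale_chi2_cutoff(7.7, 500, 500) == 7.7
        assert scale_chi2_cutoff(0.0, 1080, 360) == 0.0

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            scale_chi2_cutoff(1.0, 0, 10)


class TestClassificationIndices:
    def test_definitional_arithmetic(self):
        pred = [True] * 3 + [True] + [False] + [False] * 15
        label = [True] * 3 + [False] + [True] + [False] * 15
        rep = classification_indices(pred, label)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 1, 15)
        assert rep.recall == pytest.approx(0.75)
        assert rep.precision == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(0.9375)
        assert rep.npv == pytest.approx(0.9375)
        assert rep.exactness == pytest.approx(0.9)

    def test_all_correct(self):
        rep = classification_indices([True, False], [True, False])
        assert (rep.recall, rep.specificity, rep.precision, rep.npv, rep.exactness) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_no_predicted_positive_flags_precision(self):
        rep = classification_indices([False, False], [True, False])
        assert math.isnan(rep.precision)
        assert rep.undefined == ("precision",)
        assert rep.recall == 0.0

    def test_counts_sum_to_size(self):
        rng = np.random.default_rng(3)
        pred = (rng.random(50) < 0.4).tolist()
        label = (rng.random(50) < 0.3).tolist()
        rep = classification_indices(pred, label)
        assert rep.tp + rep.fp + rep.fn + rep.tn == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classification_indices([True], [True, False])


class TestProgressiveExactness:
    def test_running_precision(self):
        assert progressive_exactness([True, False, True], 3) == pytest.approx(
            [1.0, 0.5, 2 / 3]
        )

    def test_constant_lists(self):
        assert progressive_exactness([True] * 4, 4) == [1.0] * 4
        assert progressive_exactness([False] * 4, 4) == [0.0] * 4

    def test_final_value_is_overall_precision(self):
        labels = [True, False, False, True, True, False]
        assert progressive_exactness(labels, 6)[-1] == pytest.approx(0.5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            progressive_exactness([True], 2)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = synthetic_data.default_cardiology_scenario(n_stays=800, seed=3)
    stays, truth = synthetic_data.generate_cohort(cfg)
    db = transactions.stays_to_db(transactions.parse_stay_objects(stays))
    train, test = transactions.split_train_test(db, 0.75, seed=30)
    return train, test, synthetic_data.emit_gold_standard(truth)


class TestEvaluatePipeline:
    def test_deterministic(self, small_cohort):
        train, test, gold = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = evaluate_pipeline(train, test, gold)
            b = evaluate_pipeline(train, test, gold)
        assert a.reports == b.reports
        assert a.thresholds == b.thresholds

    def test_single_class_gold_rejected(self, small_cohort):
        train, test, _ = small_cohort
        # a gold standard blessing every mined pair leaves no negatives
        from medkb.evaluation import _one_to_one_pairs
        from medkb.scoring import rule_atc, rule_dx

        pairs, _ = _one_to_one_pairs(train, PipelineConfig())
        gold_all = GoldStandard.from_pairs(
            [(rule_atc(r), rule_dx(r)) for r, _ in pairs]
        )
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                evaluate_pipeline(train, test, gold_all)

    def test_report_structure(self, small_cohort):
        train, test, gold = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = evaluate_pipeline(train, test, gold)
        assert set(res.reports) == {
            "lift", "conviction", "chi_square", "dependency", "novelty",
            "satisfaction", "score",
        }
        n_test_rules = res.counts["test_rules_one_to_one"]
        for rep in res.reports.values():
            assert rep.tp + rep.fp + rep.fn + rep.tn == n_test_rules
            for v in (rep.recall, rep.specificity, rep.precision, rep.npv, rep.exactness):
                assert math.isnan(v) or 0.0 <= v <= 1.0

    def test_chi2_cutoff_rescaled(self, small_cohort):
        train, test, gold = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = evaluate_pipeline(train, test, gold)
        assert res.thresholds.n_train == train.n
        assert "chi_square" in res.thresholds.cutoffs
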