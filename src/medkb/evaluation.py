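"""ROC calibration, cut-off transfer and confusion-matrix evaluation.

The validation protocol: mine and measure one-to-one drug -> diagnosis
rules on a training split, label them against the gold standard, fit the
composite score, choose one cut-off per measure (and for the score) on the
training split by maximising Youden's J on the ROC curve, transfer the
cut-offs to the test split — rescaling only the chi-square cut-off by the
sample-size ratio n_test/n_train, since the statistic grows linearly with
the database size — and report recall, specificity, precision, NPV and
exactness (accuracy) per measure on the test split. The
progressive-exactness curve (precision among the k best-ranked rules)
summarises ranking quality independently of any cut-off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn.metrics

from . import scoring
from .measures import MEASURE_NAMES, MeasureVector, compute_all
from .mining import Rule, derive_mnr_rules
from .scoring import (
    GoldStandard,
    LabeledRule,
    ScoreModel,
    cap_measure_matrix,
    filter_med_to_dx,
    fit_score_model,
    label_rules,
    select_one_to_one,
)
from .transactions import TransactionDB

__all__ = [
    "RocCurve",
    "Thresholds",
    "EvalReport",
    "PipelineConfig",
    "PipelineResult",
    "roc_curve",
    "best_cutoff",
    "scale_chi2_cutoff",
    "classification_indices",
    "progressive_exactness",
    "evaluate_pipeline",
    "report_table",
]


@dataclass(frozen=True)
class RocCurve:
    """ROC points over all distinct thresholds, plus the trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class Thresholds:
    """Calibrated cut-offs (per measure and for the score) and their provenance."""

    cutoffs: dict[str, float]
    n_train: int


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and the five derived indices.

    Indices with a zero denominator are NaN and listed in ``undefined``.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    recall: float
    specificity: float
    precision: float
    npv: float
    exactness: float
    undefined: tuple[str, ...] = ()
    auc: float = math.nan


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC curve of ``scores`` against boolean ``labels``.

    AUC is the trapezoid area, which with the full threshold set equals the
    tie-corrected Mann-Whitney rank statistic (ties count one half).
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("ROC analysis needs both classes")
    fpr, tpr, thr = sklearn.metrics.roc_curve(y, s, drop_intermediate=False)
    return RocCurve(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=float(sklearn.metrics.auc(fpr, tpr))
    )


def best_cutoff(curve: RocCurve) -> float:
    """Threshold maximising Youden's J = TPR - FPR; ties break toward the
    lower threshold (the higher-recall operating point)."""
    j = curve.tpr - curve.fpr
    best = np.flatnonzero(j == j.max())[-1]  # thresholds are descending
    return float(curve.thresholds[best])


def scale_chi2_cutoff(threshold_train: float, n_train: int, n_test: int) -> float:
    """Rescale a chi-square cut-off across sample sizes:
    ``threshold_test = n_test / n_train * threshold_train``."""
    if n_train <= 0 or n_test <= 0:
        raise ValueError("sample sizes must be positive")
    return threshold_train * n_test / n_train


def classification_indices(
    predicted: Sequence[bool], labels: Sequence[bool], auc: float = math.nan
) -> EvalReport:
    """Confusion counts plus recall, specificity, precision, NPV, exactness."""
    pred = np.asarray(predicted, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if len(pred) != len(y):
        raise ValueError("predicted and labels must have equal length")
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        recall=ratio(tp, tp + fn, "recall"),
        specificity=ratio(tn, tn + fp, "specificity"),
        precision=ratio(tp, tp + fp, "precision"),
        npv=ratio(tn, tn + fn, "npv"),
        exactness=(tp + tn) / len(y),
        undefined=tuple(undefined),
        auc=auc,
    )


def progressive_exactness(
    ranked_labels: Sequence[bool], n_max: int
) -> list[float]:
    """Proportion of correct rules among the k best, for k = 1..n_max."""
    if not 1 <= n_max <= len(ranked_labels):
        raise ValueError("n_max must be in 1..len(ranked_labels)")
    y = np.asarray(ranked_labels[:n_max], dtype=float)
    return (np.cumsum(y) / np.arange(1, n_max + 1)).tolist()


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and options of the end-to-end evaluation.

    ``min_supp`` >= 1 is an absolute stay count (converted per split);
    below 1 it is a support proportion.
    """

    min_supp: float = 5.0
    min_conf: float = 0.2
    match_level: int = scoring.DEFAULT_MATCH_LEVEL
    ridge_penalty: float = scoring.DEFAULT_RIDGE

    def min_supp_proportion(self, db: TransactionDB) -> float:
        if self.min_supp >= 1.0:
            return self.min_supp / db.n
        return self.min_supp


@dataclass
class PipelineResult:
    reports: dict[str, EvalReport]
    model: ScoreModel
    thresholds: Thresholds
    train_labeled: list[LabeledRule]
    test_labeled: list[LabeledRule]  # scored, sorted best-first
    counts: dict[str, int]


def _one_to_one_pairs(
    db: TransactionDB, config: PipelineConfig
) -> tuple[list[tuple[Rule, MeasureVector]], dict[str, int]]:
    rules = derive_mnr_rules(
        db, config.min_supp_proportion(db), config.min_conf
    )
    med_dx = filter_med_to_dx(rules)
    one_one = select_one_to_one(med_dx)
    pairs = [(r, compute_all(r, db)) for r in one_one]
    return pairs, {
        "rules_mined": len(rules),
        "rules_med_to_dx": len(med_dx),
        "rules_one_to_one": len(one_one),
    }


def evaluate_pipeline(
    train_db: TransactionDB,
    test_db: TransactionDB,
    gold: GoldStandard,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Calibrate on the training split, evaluate on the test split.

    Returns one :class:`EvalReport` per interestingness measure plus one for
    the composite score (key ``"score"``). All calibration — the score model
    and every cut-off — uses the training split only; the chi-square cut-off
    is rescaled by n_test/n_train before application.
    """
    if not gold.entries:
        raise ValueError("empty gold standard")
    train_pairs, train_counts = _one_to_one_pairs(train_db, config)
    test_pairs, test_counts = _one_to_one_pairs(test_db, config)

    train_labeled = label_rules(train_pairs, gold, config.match_level)
    test_labeled = label_rules(test_pairs, gold, config.match_level)
    y_train = np.array([lr.label for lr in train_labeled], dtype=bool)
    y_test = np.array([lr.label for lr in test_labeled], dtype=bool)
    if len(y_train) == 0 or not y_train.any():
        raise ValueError("no labelled positives among training rules")
    if y_train.all():
        raise ValueError("training labels are single-class (all positive)")

    model = fit_score_model(train_labeled, ridge_penalty=config.ridge_penalty)

    raw_train = np.array([lr.measures.as_array() for lr in train_labeled])
    raw_test = np.array([lr.measures.as_array() for lr in test_labeled])
    X_train = cap_measure_matrix(raw_train, model.conviction_cap)
    X_test = cap_measure_matrix(raw_test, model.conviction_cap)
    score_train = scoring.score_measures(model, [lr.measures for lr in train_labeled])
    score_test = scoring.score_measures(model, [lr.measures for lr in test_labeled])
    for lr, s in zip(train_labeled, score_train):
        lr.score = float(s)

    cutoffs: dict[str, float] = {}
    for k, name in enumerate(MEASURE_NAMES):
        cutoffs[name] = best_cutoff(roc_curve(X_train[:, k], y_train))
    cutoffs["score"] = best_cutoff(roc_curve(score_train, y_train))
    thresholds = Thresholds(cutoffs=cutoffs, n_train=train_db.n)

    reports: dict[str, EvalReport] = {}
    both_test_classes = bool(y_test.any() and not y_test.all())
    for k, name in enumerate(MEASURE_NAMES):
        cut = cutoffs[name]
        if name == "chi_square":
            cut = scale_chi2_cutoff(cut, train_db.n, test_db.n)
        auc = (
            roc_curve(X_test[:, k], y_test).auc if both_test_classes else math.nan
        )
        reports[name] = classification_indices(X_test[:, k] >= cut, y_test, auc=auc)
    auc = roc_curve(score_test, y_test).auc if both_test_classes else math.nan
    reports["score"] = classification_indices(
        score_test >= cutoffs["score"], y_test, auc=auc
    )

    scored_test = [
        LabeledRule(rule=lr.rule, measures=lr.measures, label=lr.label, score=float(s))
        for lr, s in zip(test_labeled, score_test)
    ]
    scored_test.sort(key=lambda lr: (-lr.score,) + lr.rule.key())

    counts = {f"train_{k}": v for k, v in train_counts.items()}
    counts.update({f"test_{k}": v for k, v in test_counts.items()})
    counts["train_valid_rules"] = int(y_train.sum())
    counts["test_valid_rules"] = int(y_test.sum())
    return PipelineResult(
        reports=reports,
        model=model,
        thresholds=thresholds,
        train_labeled=train_labeled,
        test_labeled=scored_test,
        counts=counts,
    )


def report_table(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Evaluation table: one row per measure (and the score), the five indices."""
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "measure": name,
                "recall": rep.recall,
                "specificity": rep.specificity,
                "precision": rep.precision,
                "npv": rep.npv,
                "exactness": rep.exactness,
                "auc": rep.auc,
            }
        )
    return pd.DataFrame(rows).set_index("measure")


def report_to_json(result: PipelineResult, path: str | Path) -> None:
    obj = {
        "reports": {
            name: {
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "tn": r.tn,
                "recall": r.recall,
                "specificity": r.specificity,
                "precision": r.precision,
                "npv": r.npv,
                "exactness": r.exactness,
                "auc": r.auc,
                "undefined": list(r.undefined),
            }
            for name, r in result.reports.items()
        },
        "thresholds": result.thresholds.cutoffs,
        "n_train": result.thresholds.n_train,
        "counts": result.counts,
    }
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=True) + "\n")
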