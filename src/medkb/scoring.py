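"""Rule post-filtering, gold-standard labelling and the logistic composite score.

After mining, rules are narrowed to the drug -> diagnosis direction
(at least one medication in the antecedent, at least one ICD-10 code in the
consequent) and, for validation, to one-to-one rules
({one medication} -> {one diagnosis}). One-to-one rules can be labelled
correct/incorrect against a gold standard mapping each ATC code to its
indicated ICD-10 prefixes (the role the Summary of Product Characteristics
plays for real drugs).

The composite score is a logistic regression of the correctness label on
the six interestingness measures: infinite conviction/satisfaction values
are capped, the measures are z-standardised, and a small ridge penalty
keeps separable training sets finite. Scores are reported on the log-odds
scale, so they span negative and positive reals and order rules from least
to most indication-like.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .measures import MEASURE_NAMES, MeasureVector
from .mining import Rule
from .transactions import is_dx, is_med, item_code

__all__ = [
    "GoldStandard",
    "LabeledRule",
    "ScoreModel",
    "filter_med_to_dx",
    "select_one_to_one",
    "label_rules",
    "fit_score_model",
    "apply_score",
    "rule_atc",
    "rule_dx",
]

#: default gold-standard matching granularity: 3 characters = ICD-10 category
DEFAULT_MATCH_LEVEL = 3
#: default ridge penalty on standardised covariates (intercept unpenalised)
DEFAULT_RIDGE = 1e-6
#: minimum number of labelled rules the fit will accept
MIN_TRAINING_RULES = 20


@dataclass(frozen=True)
class GoldStandard:
    """ATC code -> set of indicated ICD-10 prefixes."""

    entries: dict[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GoldStandard":
        entries: dict[str, set[str]] = {}
        for atc, prefix in pairs:
            entries.setdefault(atc, set()).add(prefix)
        return cls(entries={k: frozenset(v) for k, v in entries.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "GoldStandard":
        df = pd.read_csv(path)
        return cls.from_pairs(
            (str(r.atc_code), str(r.icd10_prefix)) for r in df.itertuples()
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"atc_code": atc, "icd10_prefix": p}
            for atc in sorted(self.entries)
            for p in sorted(self.entries[atc])
        ]
        pd.DataFrame(rows, columns=["atc_code", "icd10_prefix"]).to_csv(
            path, index=False
        )


@dataclass
class LabeledRule:
    """A one-to-one rule with its measures and gold-standard label."""

    rule: Rule
    measures: MeasureVector
    label: bool
    score: float | None = None


@dataclass
class ScoreModel:
    """Fitted composite-score model: logistic coefficients plus preprocessing."""

    intercept: float
    coefficients: np.ndarray  # one per measure, MEASURE_NAMES order
    means: np.ndarray
    scales: np.ndarray
    ridge_penalty: float
    conviction_cap: float
    coef_se: np.ndarray | None = None
    intercept_se: float | None = None

    def to_json(self, path: str | Path) -> None:
        obj = {
            "intercept": self.intercept,
            "coefficients": dict(zip(MEASURE_NAMES, self.coefficients.tolist())),
            "means": dict(zip(MEASURE_NAMES, self.means.tolist())),
            "scales": dict(zip(MEASURE_NAMES, self.scales.tolist())),
            "ridge_penalty": self.ridge_penalty,
            "conviction_cap": self.conviction_cap,
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreModel":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            intercept=float(obj["intercept"]),
            coefficients=np.array([obj["coefficients"][m] for m in MEASURE_NAMES]),
            means=np.array([obj["means"][m] for m in MEASURE_NAMES]),
            scales=np.array([obj["scales"][m] for m in MEASURE_NAMES]),
            ridge_penalty=float(obj["ridge_penalty"]),
            conviction_cap=float(obj["conviction_cap"]),
        )


def filter_med_to_dx(rules: Sequence[Rule]) -> list[Rule]:
    """Keep rules with >= 1 medication in the antecedent and >= 1 diagnosis
    in the consequent (the drug -> condition direction)."""
    return [
        r
        for r in rules
        if any(is_med(i) for i in r.antecedent)
        and any(is_dx(i) for i in r.consequent)
    ]


def select_one_to_one(rules: Sequence[Rule]) -> list[Rule]:
    """Keep {one medication} -> {one diagnosis} rules only."""
    return [
        r
        for r in rules
        if len(r.antecedent) == 1
        and len(r.consequent) == 1
        and is_med(next(iter(r.antecedent)))
        and is_dx(next(iter(r.consequent)))
    ]


def rule_atc(rule: Rule) -> str:
    """ATC code of a one-to-one rule's antecedent."""
    return item_code(next(iter(rule.antecedent)))


def rule_dx(rule: Rule) -> str:
    """ICD-10 code of a one-to-one rule's consequent."""
    return item_code(next(iter(rule.consequent)))


def _truncate(code: str, level: int) -> str:
    return code.replace(".", "")[:level]


def label_rules(
    rules: Sequence[Rule | tuple[Rule, MeasureVector]],
    gs: GoldStandard,
    match_level: int = DEFAULT_MATCH_LEVEL,
) -> list[LabeledRule]:
    """Label one-to-one rules correct/incorrect against the gold standard.

    A rule is correct iff its diagnosis code, truncated to ``match_level``
    characters with the dot removed, equals some gold prefix of its ATC code
    truncated the same way. ATC codes absent from the gold standard label
    false (with a warning). Accepts bare rules or (rule, measures) pairs.
    """
    if match_level not in range(3, 8):
        raise ValueError("match_level must be in 3..7")
    out: list[LabeledRule] = []
    unknown: set[str] = set()
    for entry in rules:
        rule, mv = entry if isinstance(entry, tuple) else (entry, None)
        if len(rule.antecedent) != 1 or len(rule.consequent) != 1:
            raise ValueError(f"not a one-to-one rule: {rule.key()}")
        atc = rule_atc(rule)
        dx = _truncate(rule_dx(rule), match_level)
        prefixes = gs.entries.get(atc)
        if prefixes is None:
            unknown.add(atc)
            label = False
        else:
            label = any(_truncate(p, match_level) == dx for p in prefixes)
        out.append(LabeledRule(rule=rule, measures=mv, label=label))
    if unknown:
        warnings.warn(
            f"{len(unknown)} ATC codes absent from the gold standard labelled "
            f"false: {', '.join(sorted(unknown)[:5])}"
            + ("..." if len(unknown) > 5 else ""),
            stacklevel=2,
        )
    return out


def _raw_matrix(measures: Sequence[MeasureVector]) -> np.ndarray:
    return np.array([mv.as_array() for mv in measures], dtype=float)


def cap_measure_matrix(raw: np.ndarray, cap: float) -> np.ndarray:
    """Replace infinite conviction/satisfaction sentinels by +-``cap``."""
    capped = raw.copy()
    capped[np.isposinf(capped)] = cap
    capped[np.isneginf(capped)] = -cap
    return capped


def _auto_cap(raw: np.ndarray) -> float:
    """Cap policy: 10x the largest finite magnitude seen in the conviction
    and satisfaction columns (fallback 10 when none is finite)."""
    cols = raw[:, [MEASURE_NAMES.index("conviction"), MEASURE_NAMES.index("satisfaction")]]
    finite = np.abs(cols[np.isfinite(cols)])
    if finite.size == 0 or finite.max() == 0.0:
        return 10.0
    return float(finite.max() * 10.0)


def fit_score_model(
    training: Sequence[LabeledRule],
    ridge_penalty: float = DEFAULT_RIDGE,
    conviction_cap: float | None = None,
) -> ScoreModel:
    """Maximum-likelihood logistic fit of the correctness label on the six measures.

    Sentinel (infinite) conviction/satisfaction values are capped, measures
    are z-standardised, and an L2 (ridge) penalty of ``ridge_penalty`` on the
    standardised coefficients (intercept unpenalised) stabilises separable
    data. Standard errors come from the observed information at the fit.
    Deterministic given its inputs.
    """
    if len(training) < MIN_TRAINING_RULES:
        raise ValueError(
            f"need at least {MIN_TRAINING_RULES} labelled rules, got {len(training)}"
        )
    if ridge_penalty < 0:
        raise ValueError("ridge_penalty must be non-negative")
    y = np.array([lr.label for lr in training], dtype=float)
    if y.min() == y.max():
        raise ValueError("training labels are single-class; cannot fit the score")
    raw = _raw_matrix([lr.measures for lr in training])
    cap = _auto_cap(raw) if conviction_cap is None else float(conviction_cap)
    X = cap_measure_matrix(raw, cap)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0.0] = 1.0
    Z = (X - means) / scales

    # sklearn minimises sum(logloss) + (1/(2C))||w||^2 with the intercept
    # unpenalised, i.e. an L2 penalty of 1/C on the slopes
    C = np.inf if ridge_penalty == 0 else 1.0 / ridge_penalty
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(Z, y)
    n_iter = int(np.max(clf.n_iter_))
    if n_iter >= 5000:
        raise RuntimeError(
            f"logistic fit did not converge ({n_iter} iterations); "
            "consider a larger ridge penalty"
        )
    coef = clf.coef_.ravel().astype(float)
    intercept = float(clf.intercept_[0])

    # observed information of the penalised log-likelihood at the optimum
    design = np.column_stack([np.ones(len(Z)), Z])
    eta = design @ np.concatenate([[intercept], coef])
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = design.T @ (design * w[:, None])
    info += np.diag([0.0] + [ridge_penalty] * len(MEASURE_NAMES))
    cov = np.linalg.inv(info)
    ses = np.sqrt(np.diag(cov))

    return ScoreModel(
        intercept=intercept,
        coefficients=coef,
        means=means,
        scales=scales,
        ridge_penalty=ridge_penalty,
        conviction_cap=cap,
        coef_se=ses[1:],
        intercept_se=float(ses[0]),
    )


def score_measures(model: ScoreModel, measures: Sequence[MeasureVector]) -> np.ndarray:
    """Linear predictor (log-odds) of the model for each measure vector."""
    raw = _raw_matrix(measures)
    Z = (cap_measure_matrix(raw, model.conviction_cap) - model.means) / model.scales
    return model.intercept + Z @ model.coefficients


def apply_score(
    model: ScoreModel, rules: Sequence[tuple[Rule, MeasureVector]]
) -> list[tuple[Rule, MeasureVector, float]]:
    """Score measured rules and sort best-first.

    Output is ordered by score descending with a deterministic tie-break on
    the lexicographic rule key.
    """
    if not rules:
        return []
    scores = score_measures(model, [mv for _, mv in rules])
    scored = [
        (rule, mv, float(s)) for (rule, mv), s in zip(rules, scores)
    ]
    scored.sort(key=lambda t: (-t[2],) + t[0].key())
    return scored
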