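"""The six rule-interestingness measures, with a contingency-table chi-square oracle.

For a rule L -> R over a database of n stays, with supp(L), supp(R) the
marginal supports, supp(L->R) = supp(L u R) and conf = supp(L->R)/supp(L):

* ``lift``        = conf / supp(R)                     (1 under independence)
* ``conviction``  = supp(L)(1 - supp(R)) / (supp(L) - supp(L->R)); +inf at conf = 1
* ``chi_square``  = n (lift - 1)^2 * conf * supp(L->R)
                    / ((conf - supp(L->R)) (lift - conf))
                    — the Pearson statistic of the 2x2 stay table, rewritten
                    in rule quantities
* ``dependency``  = |conf - supp(R)|
* ``novelty``     = supp(L->R) - supp(L) supp(R)       (leverage)
* ``satisfaction``= (conviction - 1) / conviction; 1 at conviction = +inf,
                    -inf at conviction = 0

Degenerate cases: conviction and satisfaction return infinite sentinels
rather than raising (downstream score fitting caps them); a chi-square with
a marginal support of 0 or 1 is undefined and reported as 0 with a warning
so that pipelines over many rules do not abort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from . import mining
from .mining import Rule
from .transactions import TransactionDB

__all__ = [
    "MeasureVector",
    "ContingencyTable",
    "MEASURE_NAMES",
    "lift",
    "conviction",
    "chi_square",
    "dependency",
    "novelty",
    "satisfaction",
    "chi_square_contingency",
    "compute_all",
]

MEASURE_NAMES = (
    "lift",
    "conviction",
    "chi_square",
    "dependency",
    "novelty",
    "satisfaction",
)


@dataclass(frozen=True)
class MeasureVector:
    """The six interestingness measures of one rule."""

    lift: float
    conviction: float
    chi_square: float
    dependency: float
    novelty: float
    satisfaction: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in MEASURE_NAMES])


@dataclass(frozen=True)
class ContingencyTable:
    """Stay counts of the 2x2 table behind a rule: (L&R, L&-R, -L&R, -L&-R)."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def lift(rule: Rule, supp_R: float) -> float:
    """conf / supp(R); equals 1 when the two sides are independent."""
    if supp_R <= 0.0:
        raise ValueError("lift undefined for supp(R) = 0")
    return rule.confidence / supp_R


def conviction(rule: Rule, supp_L: float, supp_R: float) -> float:
    """supp(L)(1 - supp(R)) / (supp(L) - supp(L->R)); +inf at confidence 1."""
    denom = supp_L - rule.support
    if denom <= 1e-15:
        return math.inf
    return supp_L * (1.0 - supp_R) / denom


def chi_square(rule: Rule, supp_L: float, supp_R: float, n: int) -> float:
    """Pearson chi-square of the rule's 2x2 table, from rule quantities.

    Computed as ``n (lift-1)^2 conf supp / ((conf - supp)(lift - conf))``,
    which for non-degenerate marginals equals
    ``n (supp - supp_L supp_R)^2 / (supp_L supp_R (1-supp_L)(1-supp_R))``.
    Degenerate marginals (support 0 or 1 on either side) make the statistic
    undefined; those return 0 with a warning.
    """
    if not (0.0 < supp_L < 1.0) or not (0.0 < supp_R < 1.0):
        warnings.warn(
            "chi-square undefined for degenerate marginal support; reporting 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    supp = rule.support
    conf = rule.confidence
    if supp <= 0.0:
        # conf = lift = 0 makes the rewritten form 0/0; use the algebraic
        # equivalent, which stays defined
        return (
            n
            * (supp - supp_L * supp_R) ** 2
            / (supp_L * supp_R * (1.0 - supp_L) * (1.0 - supp_R))
        )
    lft = conf / supp_R
    return (
        n
        * (lft - 1.0) ** 2
        * conf
        * supp
        / ((conf - supp) * (lft - conf))
    )


def dependency(rule: Rule, supp_R: float) -> float:
    """|conf - supp(R)|: how far the consequent moves given the antecedent."""
    return abs(rule.confidence - supp_R)


def novelty(rule: Rule, supp_L: float, supp_R: float) -> float:
    """supp(L->R) - supp(L) supp(R): signed deviation from independence."""
    return rule.support - supp_L * supp_R


def satisfaction(conviction_value: float) -> float:
    """(conviction - 1)/conviction; 1 in the infinite-conviction limit."""
    if math.isinf(conviction_value):
        return 1.0
    if conviction_value == 0.0:
        return -math.inf
    return (conviction_value - 1.0) / conviction_value


def chi_square_contingency(table: ContingencyTable) -> float:
    """Pearson chi-square (no continuity correction) — the oracle form."""
    row1 = table.n11 + table.n10
    row0 = table.n01 + table.n00
    col1 = table.n11 + table.n01
    col0 = table.n10 + table.n00
    if min(row1, row0, col1, col0) <= 0:
        raise ValueError("chi-square undefined for a zero marginal")
    result = chi2_contingency(
        [[table.n11, table.n10], [table.n01, table.n00]], correction=False
    )
    return float(result.statistic)


def compute_all(rule: Rule, db: TransactionDB) -> MeasureVector:
    """All six measures of a rule, with supports recomputed on ``db``."""
    supp_L = mining.support(db, rule.antecedent)
    supp_R = mining.support(db, rule.consequent)
    supp_LR = mining.support(db, rule.items)
    if supp_L <= 0.0:
        raise ValueError("rule antecedent has zero support in the database")
    if supp_R <= 0.0:
        raise ValueError("rule consequent has zero support in the database")
    r = Rule(
        antecedent=rule.antecedent,
        consequent=rule.consequent,
        support=supp_LR,
        confidence=supp_LR / supp_L,
    )
    conv = conviction(r, supp_L, supp_R)
    return MeasureVector(
        lift=lift(r, supp_R),
        conviction=conv,
        chi_square=chi_square(r, supp_L, supp_R, db.n),
        dependency=dependency(r, supp_R),
        novelty=novelty(r, supp_L, supp_R),
        satisfaction=satisfaction(conv),
    )


def measures_frame(
    pairs: Sequence[tuple[Rule, MeasureVector]],
) -> "pd.DataFrame":
    """Rules-with-measures table (rule columns + the six measure columns)."""
    import pandas as pd

    rows = []
    for rule, mv in pairs:
        ant, cons = rule.key()
        row = {
            "antecedent": ant,
            "consequent": cons,
            "support": rule.support,
            "confidence": rule.confidence,
        }
        row.update(mv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
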