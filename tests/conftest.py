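"""Shared fixtures: the two hand-checkable databases used throughout.

``fix10``: ten stays — four containing {digoxin, AF}, one {digoxin} alone,
five {a neutral screening code}. All supports and measures on this database
are computable by hand.

``fixind``: four stays {a,b}, {a}, {b}, {} — the two items are exactly
independent (supp(a) = supp(b) = 1/2, supp(ab) = 1/4).
"""

import pytest

from medkb.mining import Rule
from medkb.transactions import TransactionDB, build_transaction_db

D = "MED:C01AA05"  # digoxin
X = "DX:I48"       # atrial fibrillation
Z = "DX:Z00"       # neutral code carried by the other half of the stays


@pytest.fixture
def fix10() -> TransactionDB:
    rows = [(f"s{i}", ["I48"], ["C01AA05"]) for i in range(4)]
    rows.append(("s4", [], ["C01AA05"]))
    rows += [(f"s{5 + i}", ["Z00"], []) for i in range(5)]
    return build_transaction_db(rows)


@pytest.fixture
def fixind() -> TransactionDB:
    return build_transaction_db(
        [
            ("s0", ["A00", "B00"], []),
            ("s1", ["A00"], []),
            ("s2", ["B00"], []),
            ("s3", [], []),
        ]
    )


@pytest.fixture
def rule_d_to_x() -> Rule:
    return Rule(
        antecedent=frozenset({D}), consequent=frozenset({X}),
        support=0.4, confidence=0.8,
    )


@pytest.fixture
def rule_x_to_d() -> Rule:
    return Rule(
        antecedent=frozenset({X}), consequent=frozenset({D}),
        support=0.4, confidence=1.0,
    )
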