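"""Closed frequent itemsets, minimal generators and non-redundant rule mining.

The miner follows the Eclat family: a vertical representation maps every
item to its *tidset* (the set of stays containing it, stored as a bitmask),
and supports are obtained by tidset intersection. On top of that it mines
the *minimal non-redundant* (MNR) rule family:

* a **closed itemset** is an itemset no strict superset of which has the
  same support (equivalently, the intersection of all stays containing it);
* a **generator** (free set) of a closed itemset ``c`` is a minimal itemset
  with the same support / closure as ``c``;
* MNR rules are ``g -> c \\ g`` for every generator ``g`` and every frequent
  closed itemset ``c`` containing ``closure(g)``, with ``g`` a strict subset
  of ``c``. Rules with ``c == closure(g)`` are exact (confidence 1); larger
  closed supersets give approximate rules. Every confident association rule
  of the database is derivable from this family (same support and
  confidence through closures), which is what makes it non-redundant.

Generators are mined level-wise (freeness is anti-monotone), closures come
from tidset intersections, and an exhaustive :func:`brute_force_rules`
enumerator serves as an independent oracle on small databases.

Supports are exact: integer stay counts divided once by the database size.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .transactions import TransactionDB

__all__ = [
    "Rule",
    "ClosedItemset",
    "support",
    "closure",
    "mine_closed_itemsets",
    "compute_generators",
    "derive_mnr_rules",
    "brute_force_rules",
    "rule_sort_key",
    "write_rules_csv",
    "read_rules_csv",
]

#: brute-force enumeration guard: 3**12 (antecedent, consequent, neither) cases
MAX_BRUTE_FORCE_ITEMS = 12


@dataclass(frozen=True)
class Rule:
    """An association rule ``antecedent -> consequent`` between disjoint itemsets."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def items(self) -> frozenset[str]:
        return self.antecedent | self.consequent

    def key(self) -> tuple[str, str]:
        """Canonical serialisation used for ordering and deduplication."""
        return (
            ";".join(sorted(self.antecedent)),
            ";".join(sorted(self.consequent)),
        )


def rule_sort_key(rule: Rule) -> tuple[float, str, str]:
    """Canonical order: support descending, then lexicographic rule key."""
    ant, cons = rule.key()
    return (-rule.support, ant, cons)


@dataclass(frozen=True)
class ClosedItemset:
    items: frozenset[str]
    support: float
    generators: tuple[frozenset[str], ...] = ()


class _Context:
    """Vertical (bitmask) view of a TransactionDB.

    Items are indexed 0..m-1 in sorted serialisation order; each item carries
    a stay bitmask (tidset) and each stay an item bitmask, so closures and
    subset tests are single integer operations.
    """

    def __init__(self, db: TransactionDB):
        if db.n == 0:
            raise ValueError("empty transaction database")
        self.n = db.n
        self.items: list[str] = db.vocabulary()
        self.index = {it: k for k, it in enumerate(self.items)}
        self.tids = [0] * len(self.items)
        self.stay_masks: list[int] = []
        for t, stay in enumerate(db.stays):
            m = 0
            bit = 1 << t
            for it in stay.items:
                k = self.index[it]
                self.tids[k] |= bit
                m |= 1 << k
            self.stay_masks.append(m)
        self.full_tid = (1 << self.n) - 1
        self.all_items_mask = (1 << len(self.items)) - 1
        self._closure_cache: dict[int, int] = {}

    def tid_of_indices(self, indices: Iterable[int]) -> int:
        tid = self.full_tid
        for k in indices:
            tid &= self.tids[k]
        return tid

    def closure_of_tid(self, tid: int) -> int:
        """Item mask common to all stays in ``tid`` (all items if ``tid`` empty)."""
        cached = self._closure_cache.get(tid)
        if cached is not None:
            return cached
        mask = self.all_items_mask
        t = tid
        while t and mask:
            low = t & -t
            mask &= self.stay_masks[low.bit_length() - 1]
            t ^= low
        self._closure_cache[tid] = mask
        return mask

    def itemset_of_mask(self, mask: int) -> frozenset[str]:
        out = []
        while mask:
            low = mask & -mask
            out.append(self.items[low.bit_length() - 1])
            mask ^= low
        return frozenset(out)

    def mask_of_items(self, items: Iterable[str]) -> int:
        mask = 0
        for it in items:
            mask |= 1 << self.index[it]
        return mask


def support(db: TransactionDB, items: Iterable[str]) -> float:
    """Exact support of an itemset: stays containing all items, over n.

    The empty itemset has support 1. Items outside the vocabulary simply
    never match (support 0).
    """
    if db.n == 0:
        raise ValueError("empty transaction database")
    iset = frozenset(items)
    if not iset:
        return 1.0
    count = sum(1 for stay in db.stays if iset <= stay.items)
    return count / db.n


def closure(db: TransactionDB, items: Iterable[str]) -> frozenset[str]:
    """Closure of an itemset: intersection of all stays containing it.

    For an itemset contained in no stay the closure is conventionally the
    full vocabulary; the empty itemset closes to the items present in every
    stay.
    """
    ctx = _Context(db)
    tid = ctx.tid_of_indices(ctx.index[it] for it in frozenset(items))
    return ctx.itemset_of_mask(ctx.closure_of_tid(tid))


def _min_count(min_supp: float, n: int) -> int:
    """Smallest stay count whose support reaches ``min_supp`` (at least 1)."""
    return max(1, math.ceil(min_supp * n - 1e-9))


def _mine_generators(
    ctx: _Context, min_count: int
) -> dict[tuple[int, ...], tuple[int, int]]:
    """Level-wise mining of frequent generators (free itemsets).

    Returns ``{sorted item-index tuple: (count, tidset)}`` including the
    empty generator. A candidate of size k is free iff all its (k-1)-subsets
    are free and its count is strictly below each subset's count; freeness is
    anti-monotone, so the Apriori-style join is sound and complete.
    """
    n = ctx.n
    out: dict[tuple[int, ...], tuple[int, int]] = {(): (n, ctx.full_tid)}
    level: dict[tuple[int, ...], tuple[int, int]] = {}
    for k, tid in enumerate(ctx.tids):
        c = tid.bit_count()
        # items present in every stay belong to closures, never to generators
        if min_count <= c < n:
            level[(k,)] = (c, tid)
    out.update(level)
    while level:
        groups: dict[tuple[int, ...], list[int]] = defaultdict(list)
        for key in sorted(level):
            groups[key[:-1]].append(key[-1])
        next_level: dict[tuple[int, ...], tuple[int, int]] = {}
        for prefix, lasts in groups.items():
            for i in range(len(lasts)):
                for j in range(i + 1, len(lasts)):
                    cand = prefix + (lasts[i], lasts[j])
                    min_sub = n + 1
                    ok = True
                    for drop in range(len(cand)):
                        sub = cand[:drop] + cand[drop + 1 :]
                        info = level.get(sub)
                        if info is None:
                            ok = False
                            break
                        if info[0] < min_sub:
                            min_sub = info[0]
                    if not ok:
                        continue
                    tid = level[cand[:-1]][1] & ctx.tids[cand[-1]]
                    c = tid.bit_count()
                    if min_count <= c < min_sub:
                        next_level[cand] = (c, tid)
        out.update(next_level)
        level = next_level
    return out


def _closed_map(
    ctx: _Context, gens: dict[tuple[int, ...], tuple[int, int]]
) -> dict[int, tuple[int, list[tuple[int, ...]]]]:
    """Group generators by closure: ``{closure item-mask: (count, [gen tuples])}``."""
    closed: dict[int, tuple[int, list[tuple[int, ...]]]] = {}
    for g, (count, tid) in gens.items():
        clo = ctx.closure_of_tid(tid)
        entry = closed.get(clo)
        if entry is None:
            closed[clo] = (count, [g])
        else:
            entry[1].append(g)
    return closed


def _itemset_key(items: frozenset[str]) -> str:
    return ";".join(sorted(items))


def mine_closed_itemsets(db: TransactionDB, min_supp: float) -> list[ClosedItemset]:
    """All non-empty closed itemsets with support >= ``min_supp``.

    Output is canonically ordered: support descending, then lexicographic
    item serialisation. Each closed itemset carries its minimal generators
    (ordered by size, then lexicographically).
    """
    if not 0.0 < min_supp <= 1.0:
        raise ValueError("min_supp must be in (0, 1]")
    ctx = _Context(db)
    gens = _mine_generators(ctx, _min_count(min_supp, ctx.n))
    out: list[ClosedItemset] = []
    for clo_mask, (count, gen_tuples) in _closed_map(ctx, gens).items():
        if clo_mask == 0:  # the empty itemset is not reported
            continue
        gen_sets = [
            frozenset(ctx.items[k] for k in g) for g in gen_tuples
        ]
        gen_sets.sort(key=lambda s: (len(s), _itemset_key(s)))
        out.append(
            ClosedItemset(
                items=ctx.itemset_of_mask(clo_mask),
                support=count / ctx.n,
                generators=tuple(gen_sets),
            )
        )
    out.sort(key=lambda c: (-c.support, _itemset_key(c.items)))
    return out


def compute_generators(db: TransactionDB, closed: ClosedItemset) -> list[frozenset[str]]:
    """Minimal subsets of ``closed.items`` with the same support (independent search).

    Enumerates subsets by increasing size and keeps those matching the closed
    set's stay count whose proper subsets all have strictly larger counts.
    Intended for verification on small closed sets; the miner derives
    generators as a by-product instead.
    """
    if db.n == 0:
        raise ValueError("empty transaction database")
    items = sorted(closed.items)
    target = round(closed.support * db.n)
    kept: list[frozenset[str]] = []
    for size in range(len(items) + 1):
        for combo in combinations(items, size):
            cand = frozenset(combo)
            if any(k <= cand for k in kept):
                continue
            count = round(support(db, cand) * db.n)
            if count == target:
                kept.append(cand)
    kept.sort(key=lambda s: (len(s), _itemset_key(s)))
    return kept


def derive_mnr_rules(
    db: TransactionDB, min_supp: float, min_conf: float
) -> list[Rule]:
    """Minimal non-redundant rules above the support and confidence thresholds.

    For every non-empty generator ``g`` and every frequent closed itemset
    ``c`` with ``closure(g) <= c`` and ``g`` strictly inside ``c``, emits
    ``g -> c \\ g`` with support ``supp(c)`` and confidence
    ``supp(c)/supp(g)``. Canonically ordered (support descending, then
    lexicographic).
    """
    if not 0.0 < min_supp <= 1.0 or not 0.0 < min_conf <= 1.0:
        raise ValueError("min_supp and min_conf must be in (0, 1]")
    ctx = _Context(db)
    min_count = _min_count(min_supp, ctx.n)
    gens = _mine_generators(ctx, min_count)
    closed = _closed_map(ctx, gens)

    # frequent closed sets, indexed per item by the closed supersets
    # containing it; superset candidates are scanned from the rarest item
    closed_masks: list[int] = []
    closed_counts: list[int] = []
    by_item: dict[int, list[int]] = defaultdict(list)
    for mask, (count, _) in closed.items():
        if count < min_count:
            continue
        cid = len(closed_masks)
        closed_masks.append(mask)
        closed_counts.append(count)
        m = mask
        while m:
            low = m & -m
            by_item[low.bit_length() - 1].append(cid)
            m ^= low

    rules: dict[tuple[str, str], Rule] = {}
    for g, (count_g, tid_g) in gens.items():
        if not g:
            continue  # rules need a non-empty antecedent
        g_mask = 0
        for k in g:
            g_mask |= 1 << k
        clo = ctx.closure_of_tid(tid_g)
        min_count_c = max(min_count, int(math.ceil(min_conf * count_g - 1e-9)))
        # scan candidates via the closure item with the fewest closed supersets
        best_list: list[int] | None = None
        m = clo
        while m:
            low = m & -m
            ids = by_item.get(low.bit_length() - 1)
            if not ids:
                best_list = []
                break
            if best_list is None or len(ids) < len(best_list):
                best_list = ids
            m ^= low
        for cid in best_list or ():
            c_mask = closed_masks[cid]
            if c_mask & clo != clo or c_mask == g_mask:
                continue
            count_c = closed_counts[cid]
            if count_c < min_count_c:
                continue
            rule = Rule(
                antecedent=frozenset(ctx.items[k] for k in g),
                consequent=ctx.itemset_of_mask(c_mask & ~g_mask),
                support=count_c / ctx.n,
                confidence=count_c / count_g,
            )
            rules[rule.key()] = rule
    out = list(rules.values())
    out.sort(key=rule_sort_key)
    return out


def brute_force_rules(
    db: TransactionDB, min_supp: float, min_conf: float
) -> list[Rule]:
    """Exhaustive rule enumeration — the testing oracle for the MNR miner.

    Emits every rule with non-empty disjoint sides passing both thresholds.
    Guarded to small vocabularies (the enumeration is 3^m in the number of
    distinct items m).
    """
    if not 0.0 < min_supp <= 1.0 or not 0.0 < min_conf <= 1.0:
        raise ValueError("min_supp and min_conf must be in (0, 1]")
    ctx = _Context(db)
    m = len(ctx.items)
    if m > MAX_BRUTE_FORCE_ITEMS:
        raise ValueError(
            f"{m} distinct items exceed the brute-force guard of "
            f"{MAX_BRUTE_FORCE_ITEMS}"
        )
    min_count = _min_count(min_supp, ctx.n)

    counts = [0] * (1 << m)
    tids = [0] * (1 << m)
    tids[0] = ctx.full_tid
    counts[0] = ctx.n
    for mask in range(1, 1 << m):
        low = mask & -mask
        tids[mask] = tids[mask ^ low] & ctx.tids[low.bit_length() - 1]
        counts[mask] = tids[mask].bit_count()

    out: list[Rule] = []
    for left in range(1, 1 << m):
        count_l = counts[left]
        if count_l == 0:
            continue
        rest = ctx.all_items_mask & ~left
        right = rest
        while right:
            both = counts[left | right]
            if both >= min_count:
                conf = both / count_l
                if conf >= min_conf - 1e-12:
                    out.append(
                        Rule(
                            antecedent=ctx.itemset_of_mask(left),
                            consequent=ctx.itemset_of_mask(right),
                            support=both / ctx.n,
                            confidence=conf,
                        )
                    )
            right = (right - 1) & rest
    out.sort(key=rule_sort_key)
    return out


# ---------------------------------------------------------------------------
# Rule CSV I/O
# ---------------------------------------------------------------------------

def write_rules_csv(rules: Sequence[Rule], path: str | Path) -> None:
    """One rule per row: semicolon-joined sides, support, confidence."""
    df = pd.DataFrame(
        {
            "antecedent": [r.key()[0] for r in rules],
            "consequent": [r.key()[1] for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
        }
    )
    df.to_csv(path, index=False)


def read_rules_csv(path: str | Path) -> list[Rule]:
    df = pd.read_csv(path)
    return [
        Rule(
            antecedent=frozenset(str(row.antecedent).split(";")),
            consequent=frozenset(str(row.consequent).split(";")),
            support=float(row.support),
            confidence=float(row.confidence),
        )
        for row in df.itertuples()
    ]
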