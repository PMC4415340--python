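"""Stay-level transaction building: mention cleaning, medication filtering, basket I/O.

The pipeline starts from coded hospital-stay data. Each stay carries the
medications administered during the stay (ATC level-5 codes) and the
diagnosis mentions extracted upstream from the discharge documents (ICD-10
codes, each flagged for negation, document section and acuity). This module
applies the cleaning rules that turn raw mentions into a transaction
database over namespaced items (``MED:<atc>`` / ``DX:<icd10>``), the input
of the rule miner.

Cleaning drops, in order: codes from chapters that do not describe medical
management (external-cause chapters by default), negated mentions, acute
pathologies reported in the patient-history ("antecedents") section, and
known homonym artefacts of the upstream code extraction. Medication lists
lose drug classes that carry no indication signal (radio contrast agents
and electrolyte solutions by default).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Section",
    "Acuity",
    "CodedMention",
    "MedicationEntry",
    "StayRecord",
    "TransactionDB",
    "MED_PREFIX",
    "DX_PREFIX",
    "med_item",
    "dx_item",
    "is_med",
    "is_dx",
    "item_code",
    "DEFAULT_DROP_PREFIXES",
    "DEFAULT_EXCLUDED_ATC_PREFIXES",
    "clean_mentions",
    "filter_medications",
    "build_transaction_db",
    "split_train_test",
    "read_stays_jsonl",
    "write_stays_jsonl",
    "read_basket",
    "write_basket",
]

#: ICD-10 code: one letter, two digits, optional dot plus up to four more digits.
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(?:\.[0-9]{1,4})?$")
#: ATC level-5 code: letter, 2 digits, 2 letters, 2 digits (e.g. C01AA05 = digoxin).
ATC5_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}[0-9]{2}$")

#: ICD-10 chapter letters treated as "not medical management" (external causes).
DEFAULT_DROP_PREFIXES = frozenset({"V", "W", "X", "Y"})
#: ATC prefixes excluded from the medication lists: V08 radio contrast agents,
#: B05 electrolyte/irrigating solutions.
DEFAULT_EXCLUDED_ATC_PREFIXES = frozenset({"V08", "B05"})

MED_PREFIX = "MED:"
DX_PREFIX = "DX:"


class Section(str, Enum):
    """Document section a mention was extracted from."""

    BODY = "BODY"
    ANTECEDENTS = "ANTECEDENTS"


class Acuity(str, Enum):
    """Acute/chronic class of the condition behind a mention."""

    ACUTE = "ACUTE"
    CHRONIC = "CHRONIC"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class CodedMention:
    """One extracted ICD-10 mention with its cleaning flags."""

    code: str
    negated: bool = False
    section: Section = Section.BODY
    acuity: Acuity = Acuity.UNKNOWN
    source_stay: str | None = None

    def __post_init__(self) -> None:
        if not ICD10_RE.match(self.code):
            raise ValueError(f"malformed ICD-10 code: {self.code!r}")


@dataclass(frozen=True)
class MedicationEntry:
    """One administered medication, identified by its ATC level-5 code."""

    atc_code: str
    inn_name: str | None = None
    source_stay: str | None = None

    def __post_init__(self) -> None:
        if not ATC5_RE.match(self.atc_code):
            raise ValueError(f"malformed ATC level-5 code: {self.atc_code!r}")


def med_item(atc_code: str) -> str:
    return MED_PREFIX + atc_code


def dx_item(icd10_code: str) -> str:
    return DX_PREFIX + icd10_code


def is_med(item: str) -> bool:
    return item.startswith(MED_PREFIX)


def is_dx(item: str) -> bool:
    return item.startswith(DX_PREFIX)


def item_code(item: str) -> str:
    """Strip the namespace prefix off an item."""
    return item.split(":", 1)[1]


@dataclass(frozen=True)
class StayRecord:
    """One hospital stay as a set of namespaced items."""

    stay_id: str
    items: frozenset[str]


@dataclass
class TransactionDB:
    """A set of stays over which itemset supports are defined."""

    stays: list[StayRecord]

    @property
    def n(self) -> int:
        return len(self.stays)

    def vocabulary(self) -> list[str]:
        """Sorted list of distinct items appearing in any stay."""
        return sorted({it for s in self.stays for it in s.items})

    def stay_ids(self) -> list[str]:
        return [s.stay_id for s in self.stays]


def clean_mentions(
    mentions: Sequence[CodedMention],
    homonym_blocklist: Iterable[str] = (),
    drop_prefixes: Iterable[str] = DEFAULT_DROP_PREFIXES,
) -> list[str]:
    """Apply the four mention-deletion rules; return surviving codes, deduplicated.

    Deletions: (1) codes whose chapter letter is in ``drop_prefixes``
    (non-medical-management chapters); (2) negated mentions; (3) acute
    pathologies mentioned in the antecedents section; (4) codes on the
    homonym blocklist. Order of first appearance is preserved.
    """
    blocked = set(homonym_blocklist)
    prefixes = tuple(drop_prefixes)
    out: list[str] = []
    seen: set[str] = set()
    for m in mentions:
        if prefixes and m.code.startswith(prefixes):
            continue
        if m.negated:
            continue
        if m.section is Section.ANTECEDENTS and m.acuity is Acuity.ACUTE:
            continue
        if m.code in blocked:
            continue
        if m.code not in seen:
            seen.add(m.code)
            out.append(m.code)
    return out


def filter_medications(
    meds: Sequence[MedicationEntry],
    excluded_atc_prefixes: Iterable[str] = DEFAULT_EXCLUDED_ATC_PREFIXES,
) -> list[str]:
    """Drop medications whose ATC code starts with an excluded prefix; deduplicate."""
    prefixes = tuple(excluded_atc_prefixes)
    out: list[str] = []
    seen: set[str] = set()
    for m in meds:
        if prefixes and m.atc_code.startswith(prefixes):
            continue
        if m.atc_code not in seen:
            seen.add(m.atc_code)
            out.append(m.atc_code)
    return out


def build_transaction_db(
    stay_inputs: Iterable[tuple[str, Iterable[str], Iterable[str]]],
) -> TransactionDB:
    """Assemble stays from (stay_id, cleaned DX codes, filtered ATC codes) triples.

    Items are the union of ``DX:*`` and ``MED:*`` codes; repeated codes within
    a stay collapse by set semantics. Duplicate stay ids are an error.
    """
    stays: list[StayRecord] = []
    seen_ids: set[str] = set()
    for stay_id, dx_codes, atc_codes in stay_inputs:
        if stay_id in seen_ids:
            raise ValueError(f"duplicate stay id: {stay_id!r}")
        seen_ids.add(stay_id)
        items = frozenset(dx_item(c) for c in dx_codes) | frozenset(
            med_item(a) for a in atc_codes
        )
        stays.append(StayRecord(stay_id=stay_id, items=items))
    return TransactionDB(stays=stays)


def split_train_test(
    db: TransactionDB, train_fraction: float, seed: int
) -> tuple[TransactionDB, TransactionDB]:
    """Randomly partition stays into train/test sets.

    The train size is ``round(train_fraction * n)`` (half away from zero).
    Both parts must be non-empty. The same seed yields the same partition;
    stay order within each part follows the original database order.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = db.n
    if n < 2:
        raise ValueError("need at least 2 stays to split")
    n_train = int(math.floor(train_fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"split of {n} stays at fraction {train_fraction} leaves an empty part"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = sorted(perm[:n_train].tolist())
    test_idx = sorted(perm[n_train:].tolist())
    return (
        TransactionDB(stays=[db.stays[i] for i in train_idx]),
        TransactionDB(stays=[db.stays[i] for i in test_idx]),
    )


# ---------------------------------------------------------------------------
# I/O: JSON-lines stay files and TSV basket files
# ---------------------------------------------------------------------------

def parse_stay_objects(
    objs: Iterable[dict],
) -> list[tuple[str, list[CodedMention], list[MedicationEntry]]]:
    """Convert raw stay dicts (the JSON-lines schema) into typed records."""
    out = []
    for obj in objs:
        stay_id = obj["stay_id"]
        mentions = [
            CodedMention(
                code=m["code"],
                negated=bool(m.get("negated", False)),
                section=Section(m.get("section", "BODY")),
                acuity=Acuity(m.get("acuity", "UNKNOWN")),
                source_stay=stay_id,
            )
            for m in obj.get("mentions", [])
        ]
        meds = [
            MedicationEntry(atc_code=d["atc"], inn_name=d.get("inn"), source_stay=stay_id)
            for d in obj.get("medications", [])
        ]
        out.append((stay_id, mentions, meds))
    return out


def stays_to_db(
    stays: Iterable[tuple[str, Sequence[CodedMention], Sequence[MedicationEntry]]],
    homonym_blocklist: Iterable[str] = (),
    drop_prefixes: Iterable[str] = DEFAULT_DROP_PREFIXES,
    excluded_atc_prefixes: Iterable[str] = DEFAULT_EXCLUDED_ATC_PREFIXES,
) -> TransactionDB:
    """Clean every stay's mentions and medications, then build the database."""
    blocked = set(homonym_blocklist)
    return build_transaction_db(
        (
            stay_id,
            clean_mentions(mentions, blocked, drop_prefixes),
            filter_medications(meds, excluded_atc_prefixes),
        )
        for stay_id, mentions, meds in stays
    )


def read_stays_jsonl(
    path: str | Path,
) -> list[tuple[str, list[CodedMention], list[MedicationEntry]]]:
    """Read per-stay coded data from a JSON-lines file.

    One object per line: ``{"stay_id", "medications": [{"atc", "inn"}...],
    "mentions": [{"code", "negated", "section", "acuity"}...]}``.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            stay_id = obj["stay_id"]
            mentions = [
                CodedMention(
                    code=m["code"],
                    negated=bool(m.get("negated", False)),
                    section=Section(m.get("section", "BODY")),
                    acuity=Acuity(m.get("acuity", "UNKNOWN")),
                    source_stay=stay_id,
                )
                for m in obj.get("mentions", [])
            ]
            meds = [
                MedicationEntry(
                    atc_code=d["atc"], inn_name=d.get("inn"), source_stay=stay_id
                )
                for d in obj.get("medications", [])
            ]
            out.append((stay_id, mentions, meds))
    return out


def write_stays_jsonl(stays: Iterable[dict], path: str | Path) -> None:
    """Write raw stay objects (the JSON-lines schema above) to ``path``."""
    with open(path, "w", encoding="utf-8") as fh:
        for obj in stays:
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def write_basket(db: TransactionDB, path: str | Path) -> None:
    """Write a transaction basket: one line per stay, ``stay_id TAB item item ...``."""
    with open(path, "w", encoding="utf-8") as fh:
        for stay in db.stays:
            fh.write(stay.stay_id + "\t" + " ".join(sorted(stay.items)) + "\n")


def read_basket(path: str | Path) -> TransactionDB:
    """Read a transaction basket written by :func:`write_basket`."""
    stays: list[StayRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            stay_id, _, items_field = line.partition("\t")
            if stay_id in seen:
                raise ValueError(f"duplicate stay id: {stay_id!r}")
            seen.add(stay_id)
            items = frozenset(items_field.split()) if items_field else frozenset()
            stays.append(StayRecord(stay_id=stay_id, items=items))
    return TransactionDB(stays=stays)
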