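"""Synthetic coded cohorts with planted ground truth.

Real per-stay coded data of this kind (hospital stays with administered
drugs and NLP-extracted diagnosis mentions) is not publicly shareable, so
the generator emulates its structure with a known answer key:

* **conditions** are sampled per stay from configured prevalences, with
  pairwise comorbidity expressed as odds multipliers applied in a fixed
  condition order — enough dependence to manufacture the transitive
  drug -> comorbid-disease associations that plague real mining;
* **indicated drugs** are prescribed with a configured probability given
  their condition (the planted true indications);
* **adverse-event mentions** depend on an administered drug, not on any
  condition — planted rules that are real associations but not indications;
* **documentation noise**: background (non-indicated) drug administrations,
  negated mentions, mentions filed under the antecedents section, and
  spurious homonym codes, all at configurable rates.

Everything derives from one seeded generator stream iterated stay by stay,
so a configuration plus a seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from .scoring import GoldStandard
from .transactions import Acuity

__all__ = [
    "Condition",
    "ComorbidityLink",
    "Indication",
    "AdverseEvent",
    "SynthConfig",
    "GroundTruth",
    "generate_cohort",
    "emit_gold_standard",
    "default_cardiology_scenario",
    "load_scenario",
    "save_scenario",
]


@dataclass(frozen=True)
class Condition:
    code: str  # ICD-10
    prevalence: float
    acuity: Acuity = Acuity.UNKNOWN


@dataclass(frozen=True)
class ComorbidityLink:
    """When ``a`` is present, the odds of ``b`` are multiplied by ``odds_multiplier``.

    Applied while sampling conditions in configuration order, so ``a`` should
    precede ``b`` in the condition list for the link to act.
    """

    a: str
    b: str
    odds_multiplier: float


@dataclass(frozen=True)
class Indication:
    atc: str
    icd10: str
    p_prescription: float  # probability the drug is given when the condition is present


@dataclass(frozen=True)
class AdverseEvent:
    atc: str
    icd10: str
    p_mention: float  # probability the event code is mentioned given the drug


@dataclass
class SynthConfig:
    n_stays: int
    seed: int
    conditions: list[Condition]
    comorbidity_links: list[ComorbidityLink] = field(default_factory=list)
    indications: list[Indication] = field(default_factory=list)
    adverse_events: list[AdverseEvent] = field(default_factory=list)
    background_meds: list[str] = field(default_factory=list)
    background_med_rate: float = 0.0
    negation_rate: float = 0.0
    antecedent_rate: float = 0.0
    homonym_noise: list[tuple[str, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_stays < 1:
            raise ValueError("n_stays must be positive")
        if not self.conditions:
            raise ValueError("need at least one condition")
        if not self.indications:
            raise ValueError("need at least one indication")
        codes = [c.code for c in self.conditions]
        if len(set(codes)) != len(codes):
            raise ValueError("condition codes must be unique")
        probs = (
            [c.prevalence for c in self.conditions]
            + [i.p_prescription for i in self.indications]
            + [a.p_mention for a in self.adverse_events]
            + [p for _, p in self.homonym_noise]
            + [self.background_med_rate, self.negation_rate, self.antecedent_rate]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if any(l.odds_multiplier <= 0 for l in self.comorbidity_links):
            raise ValueError("odds multipliers must be positive")

    def drug_vocabulary(self) -> list[str]:
        return sorted(
            {i.atc for i in self.indications}
            | {a.atc for a in self.adverse_events}
            | set(self.background_meds)
        )


@dataclass(frozen=True)
class GroundTruth:
    """The answer key: which drug-diagnosis pairs were planted, and why."""

    true_indication_pairs: frozenset[tuple[str, str]]
    planted_adverse_pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.true_indication_pairs & self.planted_adverse_pairs:
            raise ValueError("indication and adverse pairs must be disjoint")


def generate_cohort(config: SynthConfig) -> tuple[list[dict], GroundTruth]:
    """Sample stays per the configuration; return raw stay objects + answer key.

    Stay objects follow the JSON-lines schema of :mod:`medkb.transactions`.
    Deterministic given the configuration (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cond_acuity = {c.code: c.acuity for c in config.conditions}
    drugs = config.drug_vocabulary()
    by_condition: dict[str, list[Indication]] = {}
    for ind in config.indications:
        by_condition.setdefault(ind.icd10, []).append(ind)

    stays: list[dict] = []
    for i in range(config.n_stays):
        present: list[str] = []
        present_set: set[str] = set()
        for cond in config.conditions:
            p = cond.prevalence
            if p >= 1.0:
                p_eff = 1.0
            elif p <= 0.0:
                p_eff = 0.0
            else:
                odds = p / (1.0 - p)
                for link in config.comorbidity_links:
                    if link.b == cond.code and link.a in present_set:
                        odds *= link.odds_multiplier
                p_eff = odds / (1.0 + odds)
            if rng.random() < p_eff:
                present.append(cond.code)
                present_set.add(cond.code)

        meds: set[str] = set()
        for cond_code in present:
            for ind in by_condition.get(cond_code, []):
                if rng.random() < ind.p_prescription:
                    meds.add(ind.atc)
        for drug in drugs:
            if rng.random() < config.background_med_rate:
                meds.add(drug)

        mention_codes: list[tuple[str, Acuity]] = [
            (c, cond_acuity[c]) for c in present
        ]
        for ae in config.adverse_events:
            if ae.atc in meds and rng.random() < ae.p_mention:
                mention_codes.append((ae.icd10, Acuity.UNKNOWN))
        for code, p_inject in config.homonym_noise:
            if rng.random() < p_inject:
                mention_codes.append((code, Acuity.UNKNOWN))

        mentions = []
        for code, acuity in mention_codes:
            negated = bool(rng.random() < config.negation_rate)
            antecedent = bool(rng.random() < config.antecedent_rate)
            mentions.append(
                {
                    "code": code,
                    "negated": negated,
                    "section": "ANTECEDENTS" if antecedent else "BODY",
                    "acuity": acuity.value,
                }
            )
        stays.append(
            {
                "stay_id": f"S{i:06d}",
                "medications": [{"atc": a, "inn": None} for a in sorted(meds)],
                "mentions": mentions,
            }
        )

    truth = GroundTruth(
        true_indication_pairs=frozenset(
            (ind.atc, ind.icd10) for ind in config.indications
        ),
        planted_adverse_pairs=frozenset(
            (ae.atc, ae.icd10)
            for ae in config.adverse_events
            if (ae.atc, ae.icd10)
            not in {(i.atc, i.icd10) for i in config.indications}
        ),
    )
    return stays, truth


def emit_gold_standard(truth: GroundTruth) -> GoldStandard:
    """The planted indications as an ATC -> ICD-10-prefix gold standard.

    Adverse-event pairs are deliberately excluded: they are real planted
    associations but not indications, exactly the confound the evaluation
    must penalise.
    """
    return GoldStandard.from_pairs(sorted(truth.true_indication_pairs))


def default_cardiology_scenario(n_stays: int = 2000, seed: int = 0) -> SynthConfig:
    """A cardiology-ward-flavoured scenario with known ground truth.

    Fifteen conditions at ward-realistic prevalences, twenty-five drugs
    (twenty-three with a planted indication, two pure-background), a strong
    diabetes-hypertension comorbidity (the source of the classic
    metformin -> hypertension transitive artefact), one planted adverse
    event (a beta-blocker mentioned with nausea/vomiting), and modest
    documentation noise.
    """
    conditions = [
        Condition("I48", 0.50, Acuity.CHRONIC),    # atrial fibrillation
        Condition("E11", 0.25, Acuity.CHRONIC),    # type 2 diabetes
        Condition("I10", 0.75, Acuity.CHRONIC),    # essential hypertension
        Condition("E78.0", 0.50, Acuity.CHRONIC),  # hypercholesterolaemia
        Condition("I50", 0.30, Acuity.CHRONIC),    # heart failure
        Condition("I25", 0.40, Acuity.CHRONIC),    # chronic ischaemic heart disease
        Condition("I21", 0.12, Acuity.ACUTE),      # acute myocardial infarction
        Condition("E03.9", 0.08, Acuity.CHRONIC),  # hypothyroidism
        Condition("J18", 0.06, Acuity.ACUTE),      # pneumonia
        Condition("N39.0", 0.05, Acuity.ACUTE),    # urinary tract infection
        Condition("N18", 0.10, Acuity.CHRONIC),    # chronic kidney disease
        Condition("J44", 0.08, Acuity.CHRONIC),    # COPD
        Condition("D64.9", 0.10, Acuity.CHRONIC),  # anaemia
        Condition("I63", 0.05, Acuity.ACUTE),      # cerebral infarction
        Condition("G47.3", 0.06, Acuity.CHRONIC),  # sleep apnoea
    ]
    comorbidity = [
        ComorbidityLink("E11", "I10", 4.0),   # diabetes -> hypertension
        ComorbidityLink("I10", "E78.0", 2.0),
        ComorbidityLink("I10", "I25", 2.5),
        ComorbidityLink("I48", "I50", 2.0),
        ComorbidityLink("E11", "N18", 2.0),
    ]
    indications = [
        Indication("C01AA05", "I48", 0.30),   # digoxin
        Indication("C01BD01", "I48", 0.35),   # amiodarone
        Indication("B01AA12", "I48", 0.30),   # fluindione
        Indication("B01AE07", "I48", 0.25),   # dabigatran etexilate
        Indication("B01AA03", "I48", 0.20),   # warfarin
        Indication("C07AB07", "I10", 0.40),   # bisoprolol
        Indication("C08CA04", "I10", 0.30),   # nicardipine
        Indication("C08CA01", "I10", 0.35),   # amlodipine
        Indication("C09AA05", "I10", 0.45),   # ramipril
        Indication("C03CA01", "I50", 0.70),   # furosemide
        Indication("C03DA01", "I50", 0.30),   # spironolactone
        Indication("B01AC06", "I25", 0.60),   # aspirin
        Indication("C01DA14", "I25", 0.30),   # isosorbide mononitrate
        Indication("B01AC04", "I21", 0.60),   # clopidogrel
        Indication("C10AA05", "E78.0", 0.60), # atorvastatin
        Indication("C10AA01", "E78.0", 0.25), # simvastatin
        Indication("A10BA02", "E11", 0.60),   # metformin
        Indication("A10AB01", "E11", 0.35),   # human insulin
        Indication("A10AE04", "E11", 0.30),   # insulin glargine
        Indication("H03AA01", "E03.9", 0.85), # levothyroxine sodium
        Indication("J01CA04", "J18", 0.60),   # amoxicillin
        Indication("J01MA02", "N39.0", 0.50), # ciprofloxacin
        Indication("R03AC02", "J44", 0.50),   # salbutamol
        Indication("B03XA01", "D64.9", 0.30), # erythropoietin
    ]
    adverse = [AdverseEvent("C07AB07", "R11", 0.08)]  # bisoprolol -> nausea/vomiting
    return SynthConfig(
        n_stays=n_stays,
        seed=seed,
        conditions=conditions,
        comorbidity_links=comorbidity,
        indications=indications,
        adverse_events=adverse,
        background_meds=["N02BE01", "A06AD11"],  # paracetamol, lactulose
        background_med_rate=0.02,
        negation_rate=0.25,
        antecedent_rate=0.30,
        homonym_noise=[("K59.0", 0.05), ("M54.5", 0.04)],
    )


# ---------------------------------------------------------------------------
# Scenario YAML I/O
# ---------------------------------------------------------------------------

def save_scenario(config: SynthConfig, path: str | Path) -> None:
    obj = {
        "n_stays": config.n_stays,
        "seed": config.seed,
        "conditions": [
            {"code": c.code, "prevalence": c.prevalence, "acuity": c.acuity.value}
            for c in config.conditions
        ],
        "comorbidity_links": [
            {"a": l.a, "b": l.b, "odds_multiplier": l.odds_multiplier}
            for l in config.comorbidity_links
        ],
        "indications": [
            {"atc": i.atc, "icd10": i.icd10, "p_prescription": i.p_prescription}
            for i in config.indications
        ],
        "adverse_events": [
            {"atc": a.atc, "icd10": a.icd10, "p_mention": a.p_mention}
            for a in config.adverse_events
        ],
        "background_meds": list(config.background_meds),
        "background_med_rate": config.background_med_rate,
        "negation_rate": config.negation_rate,
        "antecedent_rate": config.antecedent_rate,
        "homonym_noise": [{"code": c, "p": p} for c, p in config.homonym_noise],
    }
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False), encoding="utf-8")


def load_scenario(path: str | Path) -> SynthConfig:
    obj = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return SynthConfig(
        n_stays=int(obj["n_stays"]),
        seed=int(obj["seed"]),
        conditions=[
            Condition(c["code"], float(c["prevalence"]), Acuity(c.get("acuity", "UNKNOWN")))
            for c in obj["conditions"]
        ],
        comorbidity_links=[
            ComorbidityLink(l["a"], l["b"], float(l["odds_multiplier"]))
            for l in obj.get("comorbidity_links", [])
        ],
        indications=[
            Indication(i["atc"], i["icd10"], float(i["p_prescription"]))
            for i in obj.get("indications", [])
        ],
        adverse_events=[
            AdverseEvent(a["atc"], a["icd10"], float(a["p_mention"]))
            for a in obj.get("adverse_events", [])
        ],
        background_meds=list(obj.get("background_meds", [])),
        background_med_rate=float(obj.get("background_med_rate", 0.0)),
        negation_rate=float(obj.get("negation_rate", 0.0)),
        antecedent_rate=float(obj.get("antecedent_rate", 0.0)),
        homonym_noise=[
            (h["code"], float(h["p"])) for h in obj.get("homonym_noise", [])
        ],
    )
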