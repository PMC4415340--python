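"""The cohort generator: determinism, planted statistics, noise plumbing."""

import json

import numpy as np
import pytest

from medkb import mining, transactions
from medkb.measures import compute_all
from medkb.scoring import select_one_to_one, filter_med_to_dx, rule_atc, rule_dx
from medkb.synthetic_data import (
    ComorbidityLink,
    Condition,
    Indication,
    SynthConfig,
    GroundTruth,
    default_cardiology_scenario,
    emit_gold_standard,
    generate_cohort,
    load_scenario,
    save_scenario,
)
from medkb.transactions import Acuity, parse_stay_objects, stays_to_db


def one_condition_config(**overrides):
    base = dict(
        n_stays=100,
        seed=0,
        conditions=[Condition("I48", 0.3, Acuity.CHRONIC)],
        indications=[Indication("C01AA05", "I48", 0.9)],
    )
    base.update(overrides)
    return SynthConfig(**base)


class TestGenerateCohort:
    def test_deterministic(self):
        cfg = default_cardiology_scenario(n_stays=200, seed=9)
        a, truth_a = generate_cohort(cfg)
        b, truth_b = generate_cohort(cfg)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)
        assert truth_a == truth_b

    def test_planted_joint_support_matches_binomial_expectation(self):
        cfg = one_condition_config(n_stays=10000, seed=4)
        stays, _ = generate_cohort(cfg)
        db = stays_to_db(parse_stay_objects(stays))
        supp = mining.support(db, {"MED:C01AA05", "DX:I48"})
        expected = 0.3 * 0.9
        se = np.sqrt(expected * (1 - expected) / cfg.n_stays)
        assert abs(supp - expected) < 3 * se

    def test_full_negation_cleans_every_mention(self):
        cfg = one_condition_config(negation_rate=1.0, seed=2)
        stays, _ = generate_cohort(cfg)
        db = stays_to_db(parse_stay_objects(stays))
        assert all(
            not any(transactions.is_dx(i) for i in s.items) for s in db.stays
        )

    def test_prevalence_recovery(self):
        cfg = default_cardiology_scenario(n_stays=20000, seed=6)
        cfg.comorbidity_links = []  # isolate the marginal prevalences
        stays, _ = generate_cohort(cfg)
        present = {c.code: 0 for c in cfg.conditions}
        for stay in stays:
            seen = {m["code"] for m in stay["mentions"]}
            for code in present:
                present[code] += code in seen
        for cond in cfg.conditions:
            observed = present[cond.code] / cfg.n_stays
            se = np.sqrt(cond.prevalence * (1 - cond.prevalence) / cfg.n_stays)
            # mentions include noise codes but each condition emits one mention
            assert abs(observed - cond.prevalence) < 3 * se + 1e-9

    def test_comorbidity_link_raises_joint_prevalence(self):
        conds = [Condition("E11", 0.2, Acuity.CHRONIC), Condition("I10", 0.4, Acuity.CHRONIC)]
        linked = SynthConfig(
            n_stays=8000, seed=5, conditions=conds,
            comorbidity_links=[ComorbidityLink("E11", "I10", 4.0)],
            indications=[Indication("A10BA02", "E11", 0.5)],
        )
        free = SynthConfig(
            n_stays=8000, seed=5, conditions=conds,
            indications=[Indication("A10BA02", "E11", 0.5)],
        )
        def joint(cfg):
            stays, _ = generate_cohort(cfg)
            both = sum(
                1 for s in stays
                if {"E11", "I10"} <= {m["code"] for m in s["mentions"]}
            )
            return both / cfg.n_stays
        assert joint(linked) > joint(free) + 0.02

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(one_condition_config(negation_rate=1.5))


class TestGoldStandard:
    def test_single_indication(self):
        truth = GroundTruth(
            true_indication_pairs=frozenset({("C01AA05", "I48")}),
            planted_adverse_pairs=frozenset(),
        )
        gs = emit_gold_standard(truth)
        assert gs.entries == {"C01AA05": frozenset({"I48"})}

    def test_empty_truth(self):
        truth = GroundTruth(frozenset(), frozenset())
        assert emit_gold_standard(truth).entries == {}

    def test_adverse_pairs_excluded(self):
        truth = GroundTruth(
            true_indication_pairs=frozenset(),
            planted_adverse_pairs=frozenset({("C07AB07", "R11")}),
        )
        assert emit_gold_standard(truth).entries == {}

    def test_overlapping_pairs_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(
                true_indication_pairs=frozenset({("C07AB07", "R11")}),
                planted_adverse_pairs=frozenset({("C07AB07", "R11")}),
            )


class TestDefaultScenario:
    def test_validates(self):
        default_cardiology_scenario().validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = default_cardiology_scenario(n_stays=300, seed=12)
        path = tmp_path / "scenario.yaml"
        save_scenario(cfg, path)
        assert load_scenario(path) == cfg

    def test_digoxin_af_rule_emerges_with_lift(self):
        cfg = default_cardiology_scenario(n_stays=2000, seed=21)
        stays, _ = generate_cohort(cfg)
        db = stays_to_db(parse_stay_objects(stays))
        rules = mining.derive_mnr_rules(db, 5 / db.n, 0.2)
        one_one = select_one_to_one(filter_med_to_dx(rules))
        digoxin = [
            r for r in one_one if rule_atc(r) == "C01AA05" and rule_dx(r) == "I48"
        ]
        assert digoxin, "digoxin -> atrial fibrillation rule missing"
        assert compute_all(digoxin[0], db).lift > 1.0

    def test_disabling_comorbidity_shrinks_transitive_novelty(self):
        # metformin -> hypertension exists only through the diabetes comorbidity
        def transitive_novelty(cfg):
            stays, _ = generate_cohort(cfg)
            db = stays_to_db(parse_stay_objects(stays))
            rule = mining.Rule(
                antecedent=frozenset({"MED:A10BA02"}),
                consequent=frozenset({"DX:I10"}),
                support=mining.support(db, {"MED:A10BA02", "DX:I10"}),
                confidence=0.0,
            )
            supp_l = mining.support(db, {"MED:A10BA02"})
            supp_r = mining.support(db, {"DX:I10"})
            return rule.support - supp_l * supp_r

        linked = default_cardiology_scenario(n_stays=6000, seed=8)
        unlinked = default_cardiology_scenario(n_stays=6000, seed=8)
        unlinked.comorbidity_links = [
            ComorbidityLink(l.a, l.b, 1.0) for l in unlinked.comorbidity_links
        ]
        assert abs(transitive_novelty(unlinked)) < transitive_novelty(linked)


def test_noise_free_significant_rules_are_planted():
    """Without documentation noise or comorbidity, every one-to-one rule that
    is significantly lifted (chi-square above 3.84) is a planted pair in
    nearly all seeds."""
    hits = 0
    n_seeds = 5
    for seed in range(n_seeds):
        cfg = default_cardiology_scenario(n_stays=5000, seed=seed)
        cfg.comorbidity_links = []
        cfg.background_med_rate = 0.0
        cfg.negation_rate = 0.0
        cfg.antecedent_rate = 0.0
        cfg.homonym_noise = []
        cfg.adverse_events = []
        # moderate prevalences so independent pairs cannot reach the
        # confidence floor by prevalence alone
        cfg.conditions = [
            Condition(c.code, min(c.prevalence, 0.35), c.acuity)
            for c in cfg.conditions
        ]
        stays, truth = generate_cohort(cfg)
        db = stays_to_db(parse_stay_objects(stays))
        rules = mining.derive_mnr_rules(db, 5 / db.n, 0.5)
        one_one = select_one_to_one(filter_med_to_dx(rules))
        planted = truth.true_indication_pairs | truth.planted_adverse_pairs
        ok = True
        for r in one_one:
            mv = compute_all(r, db)
            if mv.lift > 1.0 and mv.chi_square > 3.84:
                ok &= (rule_atc(r), rule_dx(r)) in planted
        hits += ok
    assert hits >= n_seeds - 1
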