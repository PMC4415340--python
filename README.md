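# medkb

Automated construction of a drug → indication knowledge base from coded
hospital-stay data, by association rule mining.

## The problem

Hospital information systems know which medications a patient received, and
natural-language processing of discharge documents yields the ICD-10 codes
of the conditions discussed — but the link between the two (what each drug
was given *for*) is not recorded anywhere. A table mapping ATC drug codes to
the ICD-10 codes of their indications supports problem-list completion,
billing audit and off-label-use surveillance, yet building one by hand is
slow and goes stale. `medkb` builds such a table from the data itself: it
mines association rules between administered drugs and documented
diagnoses across hospital stays, ranks them by how far they depart from
chance co-occurrence, and calibrates the ranking against a reference of
known indications.

It is aimed at medical informatics teams with access to per-stay coded
data; the input is coded mentions with flags (negation, document section,
acute/chronic), not free text — NLP extraction happens upstream.

## Method

Each stay is a transaction over namespaced items (`MED:C01AA05`,
`DX:I48`). After cleaning (drop external-cause chapter codes, negated
mentions, acute conditions mentioned only in the patient-history section,
and known homonym artefacts; drop contrast agents and electrolyte
solutions from the drug lists), the pipeline:

1. **Mines minimal non-redundant rules** (Eclat-style, tidset
   intersection): closed itemsets with their minimal generators, and rules
   `g → c \ g` for each generator `g` and frequent closed superset `c`,
   from which every confident rule of the database is derivable without
   information loss.
2. **Scores each rule L → R** with six interestingness measures, writing
   `supp` for support and `conf = supp(L∪R)/supp(L)`:
   lift `conf/supp(R)`; conviction `supp(L)(1−supp(R))/(supp(L)−supp(L→R))`;
   the Pearson χ² of the 2×2 stay table; dependency `|conf − supp(R)|`;
   novelty `supp(L→R) − supp(L)·supp(R)`; satisfaction `(conv−1)/conv`.
3. **Learns a composite score**: one-to-one rules
   ({one drug} → {one diagnosis}) are labelled correct/incorrect against a
   gold standard of known indications (the role a Summary of Product
   Characteristics plays), and a ridge-stabilised logistic regression of
   the label on the six standardised measures yields a log-odds score.
4. **Validates on held-out stays**: cut-offs for every measure and for the
   score are chosen on the training split by maximising Youden's J on the
   ROC curve, transferred to the test split (only the χ² cut-off is
   rescaled, by `n_test/n_train`, since χ² grows with the database size),
   and reported as recall, specificity, precision, NPV and exactness
   (accuracy), plus the progressive exactness of the ranked list.

Because real per-stay data cannot be shipped, `medkb.synthetic_data`
generates cohorts with planted ground truth — indications, comorbidity
links that manufacture transitive drug→disease artefacts, an adverse-event
link, and documentation noise — so the whole pipeline is testable.

## Worked example

```
medkb simulate --n 2000 --seed 42 --out stays.jsonl --gold gold.csv
medkb clean    --in stays.jsonl --out basket.tsv
medkb split    --in basket.tsv --train-out train.tsv --test-out test.tsv --seed 42
medkb evaluate --train train.tsv --test test.tsv --gold gold.csv --out report.json
```

prints (seed 42):

```
              recall  specificity  precision    npv  exactness    auc
measure
lift           0.957        0.860      0.579  0.990      0.876  0.973
conviction     1.000        0.965      0.852  1.000      0.971  0.988
chi_square     0.957        1.000      1.000  0.991      0.993  0.999
dependency     0.957        0.947      0.786  0.991      0.949  0.984
novelty        0.913        0.956      0.808  0.982      0.949  0.993
satisfaction   1.000        0.965      0.852  1.000      0.971  0.988
score          0.783        1.000      1.000  0.958      0.964  1.000
```

One row per interestingness measure plus the learned score, each evaluated
on the held-out split at its train-calibrated cut-off. On this cohort the
test split yields 137 one-to-one drug→diagnosis candidates of which 23 are
true planted indications. The score ranks perfectly (AUC 1.0) and its
cut-off admits no false positive (precision 1.0) at the cost of recall;
lift alone, by contrast, lets through a false positive for every true one
it keeps (precision 0.58). Which operating point matters depends on how
much human review time each false candidate costs.

The same steps run in-process:

```python
from medkb import synthetic_data, transactions, evaluation

cfg = synthetic_data.default_cardiology_scenario(n_stays=2000, seed=42)
stays, truth = synthetic_data.generate_cohort(cfg)
db = transactions.stays_to_db(transactions.parse_stay_objects(stays))
train, test = transactions.split_train_test(db, 0.75, seed=42)
result = evaluation.evaluate_pipeline(train, test,
                                      synthetic_data.emit_gold_standard(truth))
print(evaluation.report_table(result.reports).round(3))
```

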