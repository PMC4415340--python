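# Methods

## Data model and cleaning

The unit of analysis is the hospital stay. A stay carries two coded lists:
medications administered (ATC level-5 codes) and diagnosis mentions
extracted from discharge documents (ICD-10 codes, each flagged by the
upstream NLP step as negated or not, by document section, and by
acute/chronic class). Cleaning turns mentions into diagnosis items by four
deletions, in order:

1. codes whose chapter letter is in a configurable set, default
   `{V, W, X, Y}` — the ICD-10 external-cause chapters, which describe
   circumstances (traffic accidents, falls) rather than managed disease.
   The rule is driven by a prefix list because "not medical management"
   is a judgement, not an enumerable code set;
2. negated mentions ("no evidence of heart failure");
3. mentions filed in the patient-history ("antecedents") section whose
   condition is *acute*: a past pneumonia is not treated during this stay,
   but a chronic condition in the history section still is, so chronic and
   unknown acuity are retained;
4. codes on a user-supplied homonym blocklist (abbreviation artefacts of
   the extraction; default empty, since any list is site-specific).

Medication lists drop ATC prefixes `V08` (radio contrast agents — given
for imaging, not for a condition) and `B05` (electrolyte and irrigating
solutions — near-universal and therefore pure noise), both configurable.
Items are namespaced (`MED:`/`DX:`) and each stay becomes a set, so
repeated administrations or mentions count once.

Stays are split at random into training and test sets (default 75/25,
train size rounded half away from zero; the split is seeded and by stay).

## Rule mining

The miner works on the vertical representation: each item maps to the
bitmask of stays containing it, so the support of an itemset is one chain
of integer intersections, and supports are exact (integer counts divided
once by n).

Redundancy is handled through the closure operator. The closure of an
itemset is the intersection of all stays containing it; closed itemsets
are the fixed points, and a *generator* (free set) is a minimal itemset
with the same closure. Freeness is anti-monotone, so frequent generators
are mined level-wise with an Apriori-style join (a candidate is free iff
all its immediate subsets are free and its support is strictly below each
of theirs); closures then come from one tidset intersection each, cached
by tidset. The minimal non-redundant rule family is

    g  →  c \ g      for every frequent generator g and every frequent
                     closed itemset c ⊇ closure(g), with g ⊂ c,

with support supp(c) and confidence supp(c)/supp(g); c = closure(g) gives
the exact (confidence-1) rules. Every confident rule of the database is
derivable from this family: for any rule L → R, supp and conf are read
off closure(L) and closure(L ∪ R). Rules with an empty antecedent are not
emitted — a corner reachable only when an item occurs in every stay, in
which case conf = supp and the closed itemset alone carries the
information (the property tests special-case it). Output ordering is
canonical (support descending, then lexicographic serialisation), so runs
are byte-stable.

Thresholds must be explicit to be reproducible. Defaults: minimum support
**5 stays** (converted to a proportion per database) — below that, a 2×2
table is too sparse for any of the measures to mean much — and minimum
confidence **0.2**. The confidence floor is deliberately low: the tool's
output is a ranked candidate list for human review, and the published
experience with this design is that the valid rules are a small minority
of a large candidate set (hundreds of drug→diagnosis candidates, ~5–15%
correct); a floor of 0.5 would pre-filter the list down to mostly-valid
rules and leave both the measure cut-offs and the composite score nothing
to learn from. Both thresholds are exposed on the CLI and in
`PipelineConfig`.

An exhaustive enumerator (`brute_force_rules`, guarded to ≤ 12 distinct
items) serves as the independent oracle: on random small databases the
MNR family must expand to exactly the enumerated rule set, and is never
larger.

## Interestingness measures

For a rule L → R (conf = supp(L∪R)/supp(L)):

| measure      | formula                                             | independence value |
|--------------|-----------------------------------------------------|--------------------|
| lift         | conf / supp(R)                                      | 1                  |
| conviction   | supp(L)(1−supp(R)) / (supp(L) − supp(L→R))          | 1                  |
| χ²           | n(lift−1)²·conf·supp(L→R) / ((conf−supp(L→R))(lift−conf)) | 0            |
| dependency   | \|conf − supp(R)\|                                  | 0                  |
| novelty      | supp(L→R) − supp(L)·supp(R)                         | 0                  |
| satisfaction | (conviction − 1)/conviction                         | 0                  |

The χ² expression is an algebraic rewrite of the Pearson statistic of the
2×2 stay-count table; the package carries both forms and a property test
holds them equal to 1e−9 on random tables. The rewrite is 0/0 when
supp(L→R) = 0, where the Pearson form is used directly; a marginal
support of 0 or 1 makes the statistic undefined and is reported as 0 with
a `RuntimeWarning` so batch pipelines survive. Degenerate conviction is
kept as a sentinel: +∞ at confidence 1 (satisfaction 1, the limit), 0
when supp(R) = 1 (satisfaction −∞). Dependency keeps the absolute value,
losing direction; the sign of novelty recovers it.

## Composite score

One-to-one rules ({one drug} → {one diagnosis}) are labelled against the
gold standard by prefix match: rule diagnosis and gold prefixes are
truncated to a common granularity (default 3 characters, the ICD-10
category; configurable 3–7) with dots removed. Drugs absent from the gold
standard label *incorrect* with a warning — the honest default for an
incomplete reference.

The score is the linear predictor of a logistic regression of the label
on the six measures. Preprocessing: infinite conviction/satisfaction are
capped at 10× the largest finite magnitude observed in training (the cap
is stored in the model and reused at application time), then all six
measures are z-standardised. The fit is by maximum likelihood with an L2
penalty of 1e−6 on the standardised coefficients (intercept unpenalised)
— negligible bias, but it keeps perfectly separable training sets finite.
Standard errors come from the observed information at the optimum.
Scores are reported on the log-odds scale rather than as probabilities:
ranking is invariant to the choice, and the scale makes the
negative/positive spread of good and bad rules visible. Sorting is by
score descending with a lexicographic tie-break, so output order is
deterministic.

## Validation protocol

All calibration happens on the training split: the score model, and one
cut-off per measure and for the score, chosen on the ROC curve by
maximising Youden's J = TPR − FPR (ties resolved toward the lower
threshold, i.e. the higher-recall operating point). Cut-offs transfer to
the test split unchanged except χ², which scales linearly with the
database size and is therefore multiplied by n_test/n_train. Test-split
rules are then classified (value ≥ cut-off) and summarised as recall,
specificity, precision, NPV and exactness ((TP+TN)/total), with
zero-denominator indices flagged rather than silently dropped. AUC is the
trapezoid area over all distinct thresholds, which equals the
Mann-Whitney rank statistic with half credit for ties; a hand pair-counting
oracle checks this in the tests. The ranked list is also summarised by
progressive exactness (precision among the k best rules).

The sources say both "calibrate on train" and "calibrate on test" in
different places; this package calibrates on train and applies to test —
the only protocol that measures transferable performance.

## Synthetic cohorts

`synthetic_data` emulates a cardiology-ward cohort with a known answer
key. Per stay, conditions are sampled from configured prevalences;
comorbidity is expressed as pairwise odds multipliers applied in the
fixed condition order (simple, seedable, and sufficient to create
transitive drug→comorbid-disease associations — not a full graphical
model). Drugs are prescribed with a configured probability given their
condition; background drugs appear at a small unconditional rate;
adverse-event codes are emitted conditional on a drug, not on any
condition; homonym noise codes are injected independently. Mentions carry
negation and section flags at configurable rates, so the cleaning stage
has real work to do. One seeded generator stream drives everything; a
configuration plus a seed reproduces the cohort byte for byte.

The default scenario (15 conditions, 24 indicated drugs + 2
pure-background drugs) encodes ward realities that matter for mining:
hypertension at prevalence 0.75, atrial fibrillation 0.50 and
dyslipidaemia 0.50 (anchor conditions of a cardiology service, documented
in most letters), a strong diabetes→hypertension comorbidity (odds ×4)
that manufactures the classic metformin→hypertension transitive artefact,
one adverse-event link (a beta-blocker with nausea/vomiting), and
documentation-noise rates (negation 0.25, history-section 0.30) chosen so
that cleaning removes a share of mentions of the order reported for
real NLP extraction pipelines, where most raw codes do not survive.

What the generator does **not** emulate: correlated extraction noise
(section bleed, template boilerplate shared across letters), dose/route
structure, time (admission order, drug changes mid-stay), and coding-habit
clusters by author. Its false rules are therefore cleaner — closer to
exact independence — than real false rules, and single-measure cut-offs
classify them more easily than published experience suggests. Passing
tests on this generator show the pipeline is correct and that the score
learns to integrate the measures; they do not show field performance.

## Numerical choices and degenerate inputs

- Support/confidence thresholds compare integer counts (ceil of
  proportion × n, with a 1e−9 guard against float dust).
- Empty database, single-class labels, fewer than 20 labelled training
  rules, non-convergent fits, zero marginals in the oracle χ², and
  out-of-range split fractions all raise with specific messages.
- The brute-force enumerator refuses more than 12 distinct items (3^m
  growth).
- All randomness (splits, cohorts, simulations) flows through
  `numpy.random.default_rng` seeds passed explicitly.

Problem sizes used in the shipped tests and acceptance script — 2000-stay
cohorts, 10–20 seeds, 200 random oracle databases, 100 fit replications —
were chosen as the smallest sizes at which the binomial noise of the
checked properties is well below the asserted margins.

## Known limitations

- Generalised rules over the ICD-10/ATC hierarchies (mining at category
  level) are out of scope, as is any free-text processing.
- The gold standard is user-supplied and treated as complete; drugs
  missing from it are labelled incorrect, which deflates precision when
  the reference is partial.
- On small, clean cohorts the training set can be nearly separable; the
  score then concentrates at extreme log-odds and its Youden cut-off
  (an observed training score) transfers conservatively. The ranking is
  unaffected; only the single operating point is.
- The composite score's advantage over the *best* single measure is a
  property of noisy regimes; on cohorts where one measure already
  classifies nearly perfectly, the score matches it rather than beating
  it (see the acceptance test's seed-fraction assertion).
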