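# Methods

This note documents the statistical model, the synthetic study design,
the numerical conventions, and the open design choices made in this
package, in the order the pipeline runs them.

## Inputs and normalization

All inputs are tab-separated tables with headers (see `offlabel.io`
for schemas): patient mention records, one or more known-usage tables,
concept-hierarchy edges, a product→ingredient map, drug attribute
sets, spontaneous-report and literature evidence, side-effect pairs,
adverse-event associations and unit costs. Mention records are assumed
to be post-NLP: concept extraction, negation and experiencer filtering
happen upstream; this package starts from `(patient, note, date,
concept, type)` rows.

Normalization rewrites drug mentions to active ingredients (a
combination product yields one record per ingredient) and rolls
out-of-vocabulary indications up the hierarchy to their **minimal
in-target ancestors**: every in-target ancestor reachable by a parent
path containing no other in-target node. A multi-parent concept can
therefore map to several target indications; all are kept, because
discarding branches would silently lose signal, and downstream
counting treats each as a mention. Records are deduplicated on
(patient, date, concept); an accounting identity (expanded = accepted
+ rejected, dedup counted separately) guarantees nothing is dropped
silently.

## Empirical features

A drug or indication is *present* for a patient if it appears in any
record of that patient; dates enter only through per-patient first
mention dates. The 2×2 table for pair (d, i) over N patients is

    a = conditioned co-mention count     b = n_d − a
    c = n_i − a                          d = N − a − b − c

where the **conditioned co-mention rule** counts a patient toward `a`
only if (d, i) is itself a known usage (known co-occurrences always
count) or no other known indication of d is present in the record.
"Known" here is the union of all configured usage knowledge bases.
With conditioning, `d` can in principle go negative; it is clipped at
0 with a warning (never observed in practice). Note that for a truly
confounded pair conditioning does not merely shrink χ² — it flips the
association's direction (odds ratio from > 1 to < 1), which is what
removes the false positive.

Derived statistics: Pearson χ² without continuity correction, defined
as 0 when any margin is zero; odds ratio `ad/bc` with the
Haldane–Anscombe +0.5 applied to all four cells when any cell is zero;
and P(drug | indication) = a / n_i (0 when n_i = 0).

The drug-first fraction (dff) is computed over the conditioned
co-occurring patients: strictly earlier drug counts 1, equal dates
count 0.5 (dates are day-resolution; the data cannot order same-day
mentions), no co-occurring patients defaults to the uninformative 0.5.
The frequency-adjusted variants subtract the drug's mean dff across
all indications with at least one co-mention, and the indication's
mean dff analogously; the published adjustment this mirrors is not
specified in formula form, so mean-baseline centering is used as the
simplest adjustment with the right invariance.

The unconditioned ("naive") variants of the co-count-derived features
are also computed, solely for the ablation contrast; they are never
part of the 25-feature vector.

## Knowledge features

Usage-profile similarity follows the known-usage matrix: the profile
of drug d is its binary indication vector, with the query indication's
column removed from **all** profiles before comparison (otherwise a
shared check on the query itself would be a trivial self-signal); the
feature is the maximum cosine and Jaccard similarity of d against the
drugs known to treat the query indication (excluding d). The
indication–indication features are the transposed construction with
the query drug's row removed. The same four features are computed from
the second knowledge base, whose own usage relation also supplies the
treater sets for the attribute features: maxima over treaters of
cosine/Jaccard overlap of target, pathway and category sets, with
empty or absent attribute sets contributing 0. A count of known
treaters and their approved fraction complete the sixteen.

Leakage control: when features are computed for a train/test
evaluation, the held-out test positives are removed from both usage
matrices before any profile or treater set is formed. The conditioning
of co-mention counts always uses the full known-usage union — it
defines the counting scheme, not the learned signal. The final model
applied to all pairs is trained on full-knowledge-base features, since
its predictions are also made with the full knowledge bases.

## Gold standard and classifier

Positives are the known-usage pairs whose drug and indication each
occur at least once in the corpus. Negatives are built by sampling
positives with replacement and replacing *both* members with concepts
drawn uniformly from the ±10 ranks flanking the original in a
frequency-sorted list (ties broken lexicographically; windows truncate
at list bounds); sampled pairs colliding with a known usage are
discarded without replacement, so the negative count can fall slightly
below the nominal 4:1 ratio. The split into 80% train / 20% test is
stratified by label (plain random splitting destabilizes class balance
at synthetic sizes) and seeded.

The classifier is an RBF-kernel SVM. Count-like features are
log1p-transformed and all features standardized on training data only
(inside every CV fold), because heavy-tailed counts otherwise dominate
the RBF metric. The cost parameter is selected over the grid
2⁻⁵, 2⁻³, …, 2¹⁵ by ten-fold stratified CV with the **1-se rule**
(smallest cost whose mean error is within one standard error of the
minimum); kernel width is the scikit-learn `scale` default, recorded
in the results object. Platt calibration is an unpenalized logistic
regression fitted on **out-of-fold** decision values — in-sample
decision values give an optimistically steep map. Prediction flags
pairs with calibrated probability ≥ 0.99; this hard, untuned threshold
deliberately trades sensitivity for precision. Ablation tables
evaluate at 0.5 (raw discrimination) so feature sets are compared on
ranking quality rather than on how they interact with the extreme
flag threshold.

## Filter cascade

Flagged pairs pass through, in fixed canonical order (the filters do
not commute): (1) removal of pairs in the known-usage union; (2)
near-miss removal — the predicted indication is a transitive
descendant of a known indication of the drug, or its *direct* parent
(distance 1 exactly; a grandparent passes); (3) at least 10 distinct
supporting case reports (default; configurable); (4) at least 3
distinct supporting articles (the stricter of the two stated
thresholds, configurable); (5) side-effect veto, with every match
flagged in the ledger and a whitelist representing manual review of
matches (uncurated side-effect resources list many indications as
adverse events); (6) an explicit manual removal list. The ledger
records n_in = n_pass + n_removed at every stage and exactly one
primary removal reason per removed pair.

## Risk and cost indices

A drug's expected disutility is Σ severity_weight × frequency_prob
over its adverse-event associations. The shipped weights (mild 0.05,
moderate 0.2, severe 0.5, life-threatening 1.0) and frequency-class
probabilities (rare 0.0005, infrequent 0.005, common 0.05) are
reconstructions — reasonable relative disutilities and labeling-band
midpoints — and are configuration, not code, as is the class
vocabulary itself. The risk index is the rank-normalized disutility
with a zero floor: drugs with no adverse-event associations sit at
exactly 0 and are excluded from the rank denominator. The cost index
rank-normalizes mean unit cost; drugs without cost data are excluded
(flagged downstream, not zeroed). Ranks use average ties and divide by
the maximum rank, so the riskiest/most expensive drug scores exactly 1
and indices are invariant to rescaling all costs. Binning thresholds
are type-7 (linear-interpolation) quartiles of the index values **over
the surviving usage set**, with inclusive comparisons so threshold
ties fall into the extreme bins; with all indices identical this
degenerates to everything in the high–high bin, which is asserted
rather than hidden.

## The synthetic study

The generator emulates the full input suite with planted ground truth;
everything is deterministic under (config, seed).

* **Known usage with drug-class structure.** Drugs and indications are
  dealt into classes; each member is labeled for each class indication
  with probability 0.7, plus occasional off-class usages. This gives
  treaters of an indication overlapping usage profiles — the premise
  of the similarity features; under a purely random usage matrix those
  features carry no signal for positives and the model would learn the
  wrong thing. A second, noisier usage KB echoes 70% of the primary
  relation plus a few spurious pairs.
* **Planted off-label pairs** are class-consistent holes: a drug whose
  class treats an indication it is not itself labeled for, with an
  approved treater sharing a known indication, plus the indication's
  attribute signature — the archetypal off-label pattern (a drug used
  like its class siblings). Prevalent indications are preferred so the
  signal is observable; pairs hierarchically adjacent to the drug's
  known indications are never planted (they would be near-miss
  filtered by design). Cross-class planting by explicit profile
  copying is the fallback when holes run out.
* **Corpus.** Indications per patient follow a Zipf-shaped prevalence
  profile (dense frequency ordering is what makes ±10-rank negative
  sampling meaningful) with comorbidity odds multipliers; each drug
  treating a present indication is prescribed with probability 0.85
  and dated 1–30 days after the earliest treated indication;
  adverse-event links add indication mentions 1–60 days after drug
  exposure; noise mentions arrive at low Poisson rates; 10% of drug
  mentions are recorded as combination products and 20% of indication
  mentions as out-of-vocabulary subtypes, exercising normalization.
  One record per (patient, date, concept) — counting is presence-based
  at patient level, so note multiplicity is not modeled.
* **Evidence.** Treated pairs receive distinct report and article
  links (planted pairs always — the study targets *well-supported*
  novel usages; known usages with 70% coverage). Side effects are the
  true adverse-event links plus a 30% spurious fraction drawn from
  non-treatment pairs (excluding planted pairs, whose rescue by manual
  review is modeled as data, not simulated).
* **Defaults** are the shipped study conditions: 2,000 patients, 60
  drugs × 50 indications, 12 planted pairs.

What passing tests on this world do **not** show about real data:
mention extraction noise (negation, misattribution), vocabulary
mismatch between sources (the hardest practical problem in
recognizing *known* usage), dosage/duration effects, temporal drift,
and realistic reporting biases in evidence sources are all absent.
The synthetic study validates the machinery — conditioning,
similarity, calibration, filtering, accounting — not clinical
performance.

## Problem sizes and determinism

The default study (2,000 patients, 3,000 candidate pairs, ~600-pair
gold standard) runs end to end in seconds on one CPU; the test suite
uses smaller worlds (≈ 250–1,500 patients) chosen so each property is
cleanly observable. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; two runs with identical config and
seed produce byte-identical TSV outputs.

## Known limitations

Only indication-type off-label use is modeled (not age, dose, or
contraindication deviations). Conditioning reduces but cannot
eliminate comorbidity and adverse-event confounding. Requiring
external report support sacrifices sensitivity for precision — the
0.99 cut already flags fewer than half of weakly-observed true
usages, and this is by design. The risk index ignores dose,
polypharmacy and comorbidity dependence; the cost index uses unit
price, not treatment cost.
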