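# Methods

## Study design

`pvlabel` treats the addition of a clinically significant adverse reaction
(CSAR) to a drug's package insert as a binary prediction target over
drug–disease pairs in a spontaneous-reporting database.  A pair is
**positive** when the revision log attributes the addition to accumulated
domestic case reports; its feature cut-off ("as-of" quarter) is placed two
calendar quarters before the announcement quarter, because revisions are
announced weeks to months after the underlying risk investigation begins.
The lag is configurable (`lag_quarters`, default 2); a fixed integer lag is
used because report data are aggregated quarterly.  A pair is **negative**
when the disease was reported for the drug during the analysis period but
was still absent from the drug's label at the period end.  Pairs revised
for a non-domestic reason belong to neither class, and revisions whose
disease name cannot be matched to the packaged preferred-term grouping are
excluded with a logged warning.

A drug revised for one disease may still contribute negative pairs for its
other diseases: each pair is an independent unit of analysis.

### Negative cut-off quarters

By default negatives take the final quarter of the analysis period as their
as-of quarter (the period end is the natural "still unlisted" reference
point).  The end-to-end benchmark instead uses a *matched* mode that
recycles the positives' as-of quarters over the negatives in rank order.
The reason is a confound we measured, not guessed: with staggered revision
announcements, positives systematically see shorter observation windows
than period-end negatives, so cumulative counts encode the label even when
the underlying report rates are identical (a no-signal database yields test
MCC ≈ 0.8 under the default, ≈ 0.0 under matching).  Matching equalises the
window distribution between classes, so a benchmark score reflects planted
reporting elevation rather than calendar arithmetic.  Analyses of real data
should consider the same artifact.

## Pre-processing

Three exclusion rules run before any tabulation, at the case × reaction
record level, in order:

1. **Onset before first dose** — the record's onset date precedes the
   earliest start date among the case's suspected drugs.  Both dates must
   be present; a missing date retains the record, since exclusion requires
   positive evidence of precedence.
2. **Duplicates** — records sharing (case id, preferred term, onset date)
   keep a single representative: the highest follow-up version (the latest
   report is the most complete), with ties broken by outcome string so the
   result is independent of input order.
3. **OTC** — every record of a case whose suspected drugs include an
   over-the-counter product is removed.

Each removed record is counted once under the first rule that removes it;
counts plus retained records always equal the input record count.  All
tabulation afterwards uses suspected-role drug entries only.  Dates are ISO
calendar dates; the quarter of a date is its calendar quarter, and quarter
ids are `YYYYQn` strings ordered through a linear index, never
lexicographically.

## Preferred-term grouping

Reactions are recorded as MedDRA preferred terms (PTs) but labels name
diseases, so tabulation first maps PTs to 75 target diseases via a packaged
two-column CSV (`disease,pt`, 144 PT rows).  Matching is exact-string after
case-folding, whitespace collapsing and unicode-dash normalisation — no
fuzzy matching, because label wording is matched to PT names verbatim in
practice.  A PT may belong to at most one disease; loading fails loudly on
duplicates.  Standardised MedDRA query expansion is out of scope (SMQ data
is licensed); the CSV is editable for users who need broader groupings.

## Disproportionality statistics

For a pair's 2×2 table (a, b, c, d as in the README): ROR = ad/bc,
PRR = a(b+d)/(b(a+c)), Yates-corrected χ² = N(|ad−bc| − N/2)²/
((a+b)(c+d)(a+c)(b+d)) floored at 0 when the correction exceeds |ad−bc|,
Index A = 100a/(a+c), Index B = 100a/(a+b).  Confidence intervals are the
standard log-scale Wald forms — ROR: exp(ln ROR ± z·√(1/a+1/b+1/c+1/d));
PRR: exp(ln PRR ± z·√(1/a − 1/(a+c) + 1/b − 1/(b+d))) with z = 1.959964 at
the default 0.95 level.  Logarithms are natural.  Zero denominators yield
NaN ("undefined") rather than exceptions; no Haldane +0.5 correction is
applied by default (the plain ratio definitions carry none), but every
statistic accepts `haldane=True`.  The conventional screening rule flags a
pair when a ≥ 3, χ² ≥ 4 and PRR ≥ 2; an undefined statistic fails its
threshold.  The "cumulative number of reports" in the rule is cell *a*
(unique patients), consistent with the patient-level tabulation used
everywhere else — a choice worth a sensitivity analysis where report-level
counting is plausible.

## The 34 features

Per pair, using only reports received on or before the as-of quarter:
cumulative unique patients, deaths, rechallenge patients (suspected entry
re-administered), discontinuations; mean and median days from the suspected
drug's first dose to the earliest matching onset, and patients with onset
within 15/30/90 days; mean missing values per case over seven fields (sex,
age band, weight band, onset date, drug start date, outcome, medical
history — the field list is configurable in code since no canonical list
exists); mean follow-up reports per case (the case's version count);
Index A and B; quarters elapsed since the first report, counted inclusively
of both endpoints; newly reported patients in each of the four single
quarters ending at the as-of quarter (window *k* means the one quarter
as_of − k + 1, since the four windows are listed as separate features);
new deaths/rechallenges/discontinuations/short-onset patients among the
last quarter's new patients; mean patients per quarter = cumulative
patients ÷ quarters since first; and the disproportionality block at the
as-of cut-off.

Features are a pure function of (pair, reports ≤ as-of); this no-leakage
contract is property-tested by mutating future reports and asserting
bit-identical vectors.

**Imputation.** Missing onset summaries (both dates absent on every
matching record) are replaced by the median onset days of the same disease
under *other* drugs — the donor median; pairs with no donor anywhere keep
the missing marker and are logged, then filled with 0 at finalisation.
Undefined disproportionality values at small counts are filled neutrally
(ratio 1, log 0, χ² and coverage percentages 0).  Both imputations set flag
columns (`onset_imputed`, `dispro_imputed`) that are never model inputs.

**Transforms.** Standardization ((x − mean)/sd, constant features map to 0)
or a quantile transform (monotone map of training ranks onto [0, 1] applied
to held-out data by linear interpolation; constant features map to 0.5).
Transforms are fitted on training data only — refitted inside every
cross-validation fold — and frozen thereafter.  Default pairing:
standardization for the RBF SVM, none for the boosting backends.

## Modelling

Stratified 7:3 train/test split; stratified k-fold cross-validation
(default k = 5; the end-to-end benchmark uses k = 3 against its ~21
training positives).  The headline metric is the MCC, with precision,
recall and ROC AUC reported alongside; a zero factor under the MCC root
gives 0.  Class imbalance is handled by moving the decision threshold
(default 0.5, with a sweep that always includes 0.1), not by weighting or
resampling.

**Exhaustive feature selection** evaluates every subset of the requested
sizes by cross-validated mean MCC under an explicit subset budget
(default 100,000); ties break toward the smaller subset, then lexicographic
feature order.  A greedy forward fallback covers sizes where 2³⁴-style
enumeration is infeasible.  **Hyperparameter search** is a seeded random
search, log-uniform over the standard box C ∈ [0.01, 3000],
γ ∈ [0.001, 1000], scored by cross-validated MCC and deterministic for a
fixed seed.  **Permutation importance** is the mean MCC drop over seeded
shuffles of one feature column on held-out data.  Estimator internals are
delegated: scikit-learn's SVC for the RBF SVM, XGBoost/LightGBM behind the
two gradient-boosting kinds; this module owns selection, validation,
scoring and importance logic.

## The synthetic generator

Report arrival per drug–disease pair per quarter is Poisson — the simplest
count process consistent with gradual accumulation.  Planted pairs multiply
the baseline rate by `rate_multiplier` during the `ramp_quarters` quarters
immediately before their logged revision; the multiplier may be exactly 1
so that *label-only null* databases (revisions with no underlying signal)
can be generated.  Each report is one case with one suspected drug and one
reaction whose PT is drawn from the disease's grouping.  Onset days follow
a configurable distribution (default exponential, mean 20 days); the onset
date is uniform within the receipt quarter and the start date is derived
backwards.  Anomalies are injected at configured probabilities: missing
dates and demographics (default 0.15, in line with the ~20% missingness of
real onset intervals), deaths 0.05, rechallenge 0.02, discontinuation 0.25,
duplicate reaction rows 0.03, onset 1–30 days before the first dose 0.01,
follow-up versions 1 + Poisson(0.3), and 2% of non-planted drugs flagged
OTC.  Output is deterministic for a fixed (config, seed): one numpy
generator, fixed iteration order.

The benchmark database (`study_config`) is 60 drugs × 40 diseases over 24
quarters at baseline 0.25 reports/pair-quarter — ~2,400 pairs and ~15,000
cases, sized so the full pipeline runs in well under a minute on one CPU —
with 30 planted pairs (multiplier 10, ramp 8 quarters, revisions staggered
over the last three years).  The positive:negative ratio (30:~2,330) keeps
the realistic two-orders-of-magnitude imbalance of label-change data.

**What the generator does not emulate**, hence what passing tests do not
show about real data: reporting-behaviour dynamics (stimulated reporting,
secular trends, the Weber effect), correlated multi-drug/multi-reaction
cases, drug-class effects, real PT misspelling or encoding dialects, and
revisions triggered by anything other than the planted accumulation.  A
perfect benchmark MCC therefore demonstrates correct plumbing and a
recoverable planted effect, not real-world performance, where published
models reach high but imperfect scores.

## Numerical and degenerate-input conventions

Undefined statistics are NaN and always fail thresholds; empty inputs give
empty outputs rather than errors; a pair with zero reports at its as-of
quarter gets all-zero counts and missing onset/coverage values routed
through imputation; cross-validation refuses fold counts that would leave a
fold without positives (advising a smaller k); splits, folds, searches,
permutations and the generator all take explicit integer seeds.
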