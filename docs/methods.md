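# Methods

## Cohort model

The unit of observation is a hospital diagnosis event: an ICD-10 level-3
code (letter + two digits) with admission and discharge dates, a
diagnosis-type letter, and an encounter identifier.  Preprocessing keeps
only residents with status codes 01 (active) and 90 (deceased), and drops
diagnosis types H and M (referral and temporary codes), so analyses rest
on confirmed diagnoses.  Cases are patients carrying the pancreatic-cancer
code C25 *and* present in an external cancer-registry confirmation set;
the index date is the first C25 admission.  Symptom history is the
half-open window `[index − L years, index)` with L = 5 by default and one
year = 365.25 days; events on the index day belong to the diagnosis
itself, not the history, which keeps the cancer admission's own codes out
of the "prior symptom" record.  Within the window, a symptom is counted at
most once per (encounter, code), earliest admission kept.

Each case receives `ratio` (default 10) controls matched exactly on sex,
birth year and index year, the control's index date being its earliest
hospital contact in the matched year.  Controls may be reused across cases
but not within a case; matching on diagnosis *year* rather than date
follows the design it emulates (a date would starve the strata).  When a
reused control has been matched under two different index years, the
comparison pool uses its first assignment (sorted case order).

## Pair statistics

**Relative risk (registry).**  For pair (D1, D2), the exposed group is all
cases with ≥1 D1 event, anchored at the first D1 discharge.  N comparison
groups (default 10) are sampled from the matched control pool; member *i*
of each group shares sex and 10-year age band with exposed member *i* and
has some discharge in the same ISO week-of-year as that member's anchor
(week 53 is folded into week 52 — the annual cycle is what matters, and
calendar week-53 strata are too thin to match against).  Sampling is
without replacement within a group, with reuse across groups.  The
estimator is `RR = C_exposed / mean_i(C_i)` with C counting patients
carrying D2 anywhere in their window.  Significance is the one-sided exact
binomial tail `P(X ≥ C_exposed | n_exposed, p0)` with
`p0 = mean_i(C_i)/n_exposed`; one-sided because trajectory construction
only ever consumes enrichment (effect > 1).  D2-after-D1 ordering is
deliberately *not* built into C_exposed: temporal order is handled
entirely by the directionality test, keeping the two stages orthogonal.
A pair whose comparison counts are all zero is reported incalculable, not
infinite; `p0 = 0` with a positive exposed count yields p = 0 by
convention, logged.

**Odds ratio (notes).**  Exposure is the per-patient indicator "carries D1
and D2 with D1 strictly first".  Case/control status is regressed on
exposure by conditional logistic regression with the 1:10 matched sets as
strata; sets missing cases or controls, or with constant exposure, carry
no information and are dropped (counted and logged).  With a single
stratum the estimate reduces analytically to the 2×2 cross-product OR with
a Wald p-value, and the code takes that path exactly.  The fit is
cross-checked against the Mantel–Haenszel pooled OR; on separation or
non-convergence the Mantel–Haenszel estimate (with its null test) is the
fallback.  The same machinery with single-symptom exposure provides the
per-symptom enrichment screen.

**Directionality.**  Among patients with both codes, the first occurrences
are compared at day resolution: n_forward (D1 strictly first), n_backward,
n_same (same day).  The test is two-sided exact binomial,
`min(1, 2·min(P(X ≤ k), P(X ≥ k)))` at p = ½ with k = n_forward over
n_forward + n_backward + n_same trials — same-day patients enter the trial
count but are never forward successes.  At p = ½ this equals the
minimum-likelihood exact two-sided test.

**Multiplicity.**  Effect tests and direction tests are corrected as two
separate Bonferroni families: all ordered pairs with a computable effect
p-value, and all pairs eligible for direction testing (effect > 1,
corrected effect p < α).  Both family sizes are recorded in the run
manifest, because the correction is meaningless if m is not auditable.

## Trajectories and survival

Edges are pairs with effect > 1, corrected effect and direction p < α
(default 0.05), and n_forward > n_backward.  Trajectories are all simple
3- or 4-code paths whose *consecutive* pairs are edges; non-consecutive
pairs are not required (chaining joins significant directed pairs, it does
not test triples).  A patient follows a path when the first occurrences of
its codes are strictly increasing — same-day occurrences break the chain,
consistent with the n_same convention — and, in the default `pre_only`
mode, all precede the index date; a `straddle` switch admits post-index
codes for layouts that span the diagnosis.  Support thresholds default to
100 followers (registry) and 20 (notes).

Survival per trajectory group is death minus index in days, censored at
end of data, summarised by the Kaplan–Meier median (the estimator is not
dictated by the design, so the naive median over observed deaths is also
emitted for comparison); a group is "short" iff the KM median is ≤ 90
days, and a median the curve never reaches is reported as infinity and
classed "long".

## Text mining

The dictionary maps lowercase surface forms (multiword allowed) to level-3
codes, each entry carrying a provenance tag.  Base terms are expanded with
suffixes; spelling variants are corpus tokens of length ≥ 5 at Levenshtein
distance exactly 1 (unit costs, no transposition — one substitution,
deletion or insertion, computed with edlib) from a dictionary token,
mapped to the nearest token with lexicographic tie-breaking.  Note that an
adjacent transposition is two unit edits and is therefore *not* harvested.
Tagging is a case-insensitive, longest-match-wins scan over whole-token
n-grams (no intra-word matches); mentions never overlap.  Sentences are
delimited by `.!?;` followed by whitespace or end of text, and by
newlines, since clinical notes are newline-heavy; a mention is flagged
negated (or other-person) when its sentence contains a lexicon word, and
flags only ever go from False to True, making filtering monotone in the
lexicon.  Evaluation against gold spans counts a true positive when an
unflagged prediction shares the code and overlaps the span (suffix
variants shift boundaries by design, so exact-boundary matching would be
wrong); TN is the remaining token mass, `n_tokens − (TP+FP+FN)` — TN is
not observable directly in a token-classification view of a dictionary
tagger, so this denominator convention is part of the package's
definition of specificity.  The worked validation example uses a 200-note
test corpus with 807 manually annotated symptoms, of which 675 are found:
the sensitivity formula gives 675/807 = 83.6 %.  A figure of 83.4 % is
sometimes quoted for these counts; the package always reports the formula
value and treats such differences as rounding.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed, not tuned:

* `n_cases` cancer patients aged 55–84 at diagnosis, index dates spread
  over `years_span` (3 y) starting five years after the data start, all
  confirmed; a control pool of `control_pool_multiplier` (≥ 10, enforced)
  × n_cases patients whose matching strata copy the cases', so every
  stratum can supply 10 controls per case by construction.
* Hospital contacts follow a homogeneous Poisson process (2 per
  patient-year over the 5-year window) modulated by an annual sinusoid of
  amplitude `seasonal_amplitude` (0.2) peaking mid-January — the simplest
  process that actually exercises same-week seasonal matching.
* Baseline symptom presence per code is Bernoulli with window probability
  `1 − exp(−rate·L)` (default rates 0.02/patient-year ≈ 9.5 % per window);
  occurrences number 1 + Poisson(0.3).  Control symptom events are
  attached to existing contact encounters (same admission and discharge):
  diagnoses are coded at encounters, and this keeps a control's
  week-coverage — hence its chance of entering a comparison group —
  independent of which symptoms it carries.  Without this, comparison
  members are activity-biased toward carrying D2 and the RR estimator
  runs ~10 % low.
* A planted pair (a, b, RR, d) overrides b's presence among a-carriers to
  `min(1, RR·q_b)` — a closed-form calibration that makes the expected
  matched-comparison RR equal the target without iterative tuning — and
  places b after a's first occurrence with probability d (before it
  otherwise), always inside the window with ≥1 day separation.  Chained
  plants are processed sequentially so a→b→c produces strictly ordered
  triples.
* Survival is a two-component exponential mixture (default 35 % with
  45-day median, 65 % with 250-day median), giving analytic medians
  (ln 2/λ) for exact test oracles and both ≤90-day and >90-day groups;
  deaths after end of data (3 y past the last index) are censored and the
  patient stays status 01.  A small residue of status-30 patients and of
  H/M-type duplicate rows exercises the preprocessing filters without
  affecting calibrated quantities (they are additions, and the filters
  remove them).
* Notes are templated English sentences, one mention per deduplicated
  symptom event, dated at the admission day (which is also the symptom
  timestamp convention on the notes side).  Per mention, independently:
  one random edit at rate `spelling_error_rate`, a negated template at
  `negation_rate`, an other-person template at `other_person_rate` (both
  flags can co-occur; the template then contains both lexica).  Gold
  annotations record exact character offsets and both flags.  Filler
  sentences and filler-only notes (up to `note_rate` notes per
  patient-year) contain no dictionary, negation or relation tokens.

What the generator does **not** emulate: Danish morphology or any real
note structure (section headers, abbreviations, telegraphic style),
coding-practice drift over calendar time, comorbidity confounding,
medication, geography, emigration dynamics.  Passing tests therefore show
that the statistical machinery is correct and calibrated under a
plausible event-stream model — not that the tagger would reach the same
sensitivity on real clinical prose, nor that real symptom trajectories
are causal.

## Numerical and design choices

* Dates are compared at day resolution throughout; 1 year = 365.25 days.
* Determinism: every public entry point takes a seed; the model derives
  per-stage substreams (control sampling, comparison sampling) from it, so
  stages rerun identically in isolation.  Identical configs give
  byte-identical generator output.
* Comparison-group age bands are 10-year bands at the anchor discharge —
  wide enough that desk-scale pools do not exhaust, matching the
  "same age group" design rather than exact-age matching.
* Variant-harvest ties break lexicographically; dictionary collisions
  resolve first-entry-wins with a logged warning.
* Zero-denominator cases raise typed errors (`IncalculablePairError`,
  `StratumExhaustedError` naming the stratum, `ZeroDivisionError` for
  undefined sensitivity/specificity) rather than returning sentinels.

## Validation experiments (symtraj.experiments)

The experiment module reruns the study conditions at desk scale: 550-case
cohorts (≈ 520 exposed) for RR recovery over 20 replicates per target;
250-case null cohorts for 20 no-plant replicates at the 20-follower /
corrected-0.05 thresholds; 10 000 fair-coin simulations for the
directionality test's type-I rate; 200 matched 1:10 sets for the
conditional-logit vs Mantel–Haenszel comparison; 80–150-case corpora for
tagger scoring; n = 200 exponential survival draws for the KM median.
These sizes keep each experiment between seconds and ~1 minute on one CPU
with Monte-Carlo error far inside the tolerances being checked
(e.g. the mean RR estimate has ≈1.5 % standard error over 20 replicates,
against a 15 % acceptance band).

## Known limitations

* The week-matching candidate index treats every patient-discharge-week
  as eligible regardless of how many discharges fall in that week; very
  small pools can still exhaust a (sex, band, week) stratum, which raises
  rather than silently relaxing the match.
* Conditional logistic estimates are finite-sample biased away from the
  Mantel–Haenszel value in sparse sets; the internal cross-check tolerates
  10 %.
* The tagger is dictionary-bound: it cannot find symptoms phrased without
  a dictionary surface form, and harvested variants are limited to one
  edit on tokens of length ≥ 5 (so transpositions and short-word typos
  stay unmatched).
* Trajectory follower counting uses first occurrences only; recurrent
  episodes do not re-enter the ordering.
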