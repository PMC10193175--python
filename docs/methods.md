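# Methods

## Surveillance model

The unit of analysis is a CIED **procedure**. A procedure enters the
cohort when at least one antibiotic exposure is dated within one day of
it (day offsets −1, 0, +1; every interval in the package is closed on the
integer day axis, with day 0 the procedure date). Exposure duration is
the count of distinct covered calendar days — an inpatient administration
covers its own day, an outpatient fill covers `[fill, fill + supply − 1]`
— capped at day +45. Each included case carries two windows:

* **extraction window** `[0, 45]`: the span detection variables may come
  from;
* **attribution window** `[0, min(last exposure + 10, 45)]`: the span in
  which an event is attributable to the periprocedural antibiotics.

Detection variables are binary flags (allergy-module entries, eight
PheCode groups mapped from ICD-10 by longest-prefix match, a new-allergy
code with a 365-day carried-forward-history suppressor, note
keyword–medication co-occurrence, rescue medications, consults, three
prespecified AND-composites). The detection score is a logistic
regression on these flags, with variables chosen by L1-penalized
logistic regression (10-fold cross-validated deviance, 1-SE rule) and
then refit unpenalized so the reported odds ratios are unshrunken.
Probabilities estimated on the outcome-enriched review sample are applied
to the cohort **without recalibration**, as in the original deployment;
`predict_probability(..., recalibrate_to=p)` offers an intercept shift by
the log prevalence ratio for users who want calibrated absolute risks.

Review sampling is two-armed: coverage sampling for training (every
candidate variable represented at least `per_variable_target` times plus
a block of flag-free negatives) and stratified outcome-enriched sampling
for testing (simple random samples within probability strata `(0, .1],
(.1, .2], …, (.9, 1]`, oversampling high strata). PPV, sensitivity and
specificity are computed from the adjudicated strata at a cutoff aligned
with a stratum edge; because the review sample is enriched, sensitivity
and specificity are *sample-conditional* — they describe the reviewed
charts, not the source population, and are reported as such.

Severity of a confirmed allergic-type reaction: **mild** = no treatment
and no care escalation; **moderate** = treated (antihistamine,
corticosteroid, IV epinephrine) without escalation; **severe** = treated
with escalation, or any intubation/ICU admission. Intubation forces the
severe grade even with no recorded premedication: a literal reading of
the treated-AND-escalated definition would let an intubated patient with
a documentation gap grade mild, which is clinically indefensible.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| inclusion window | ±1 | days | periprocedural exposure rule |
| extraction window | 45 | days | post-procedure surveillance span |
| attribution lag | 10 | days after last exposure | event attributability |
| new-allergy lookback | 365 | days | carried-forward history suppressor |
| probability cutoff | 0.30 | — | development-cohort operating point |
| CV folds / rule | 10 / 1-SE | — | sparse, stable selection |
| negation scope | 5 | tokens | conservative pre-window |
| frozen-model baseline | 0.005 | probability | ≈ cohort event rate |

## Synthetic-data generator

The generator emulates the development cohort's study conditions: ~96 %
of procedures antibiotic-exposed; prophylaxis duration `round(lognormal)`
with ln-median 4 d and σ = 0.83, clipped to [1, 45], giving median 4 and
IQR 2–7; latent allergic events in 0.6 % of exposed procedures (adverse
1 %, other 0.2 %); the event day uniform on the attribution window;
culprit-class weights proportional to the adjudicated reaction mix
(cephalosporins 40 %, vancomycin 23 %, …) and severity weights to the
adjudicated grade totals.

Each detection channel fires with `P(flag | allergic)` taken from the
adjudicated review sample (e.g. 60/96 = 62.5 % for an observed
allergy-module entry) and a background rate `p0` solved from
`r_cohort = p_a·p1 + (1 − p_a)·p0` so the simulated cohort marginal
reproduces the cohort-level detection rate (0.3 % observed ART, 8.7 %
keyword notes, …). Three consequences are deliberate:

* the *negative* column of the enriched review sample (e.g. 5.7 %
  observed ART among reviewed non-allergic charts) is **not** matched —
  those negatives were coverage-selected, not representative;
* for the observed-ART channel the solved background rate floors at 0,
  because `p_a · p1` alone slightly exceeds the cohort marginal — a small
  internal inconsistency of the source tables (the implied marginal,
  0.375 %, is still within 3 binomial SEs of the printed 0.3 %);
* channels are kept disjoint in code space (the new-allergy channel
  emits only Z88\* status codes, which no PheCode group maps) so each
  extracted flag stays calibrated to its own configured rate. Composite
  flags consequently follow independence products and sit below the
  published composite rates, which encode real within-case correlation.

Notes are templated sentences (symptom–linker–medication triplets),
negated mentions ("denies hives … tolerated vancomycin") at a
configurable noise rate, GI-symptom notes for adverse events, and
distractor notes; this exercises the matcher's word-boundary, phrase,
per-note co-occurrence and negation-scope logic but is *not* clinical
language — template-external phrasing, abbreviations, sections and
copy-forward text are absent, so passing tests demonstrate correctness of
the extraction rules, not NLP performance on real notes. Likewise the
generator draws channels independently given the latent event, so it
cannot demonstrate performance under correlated documentation behaviour.

## Numerical choices

* **Penalized solver**: IRLS with cyclic coordinate descent, intercept
  unpenalized, binary flags not standardized (they share a scale;
  standardizing would silently reweight rare flags). Every returned path
  point satisfies the exact stationarity (KKT) conditions to below 1e−9
  (certified in tests at 1e−6); cross-validation fold fits relax the
  inner tolerance since only held-out deviance is consumed. λ grid:
  40 log-spaced points from the closed-form λ_max down to λ_max/100.
* **Refit**: statsmodels ML with Wald CIs; on detected separation (fitted
  probability within 1e−8 of 0/1 with a diverging coefficient, or a
  non-converged fit with |β| > 15) it falls back to Firth's bias-reduced
  likelihood and flags the result. Quasi-separation is expected — the
  strongest published OR is ≈175 with a wide CI.
* **Confidence intervals**: Clopper–Pearson via beta quantiles, chosen
  because it reproduces the development cohort's printed intervals
  (54/70 → 66–86 %, 27/31 → 70–96 %); the source does not name its
  method. Percentages are displayed rounded half-up to whole percent;
  underlying values keep full precision.
* **C statistic**: rank-based with half-credit for ties; equals
  brute-force pairwise concordance (tested exactly).
* **Cutoff selection**: grid 0.1–0.9; recommendation maximizes Youden's
  J with PPV reported alongside; an override (default 0.30 in the
  pipeline) is supported and logged; a degenerate single-cell score
  distribution flags the recommendation unstable.
* **Strata** are left-open/right-closed, so a score of exactly 0.10 sits
  in the lowest stratum and "above the cutoff" means strata whose lower
  edge ≥ cutoff.
* **Ties/degeneracies**: constant feature columns are dropped from
  refits with a warning; a stratum with zero reviewed charts above the
  cutoff yields a *not-estimable* PPV (never 0); exhausted sampling
  strata are taken whole with a warning.

## Design decisions on genuinely open points

* **Train/test split** mechanism is unstated in the source; implemented
  as a seeded patient-level randomized split (greedy balancing after a
  shuffle), so multi-procedure patients never straddle arms. Exact ±1
  balance is achieved whenever per-patient counts permit; pathological
  inputs (every patient contributing 2 procedures, odd patient count)
  settle at the closest feasible difference.
* **Keyword co-occurrence scope**: one *note* (not one sentence, not the
  whole window), matching the variable's "symptom and medication"
  phrasing; negation is simple trigger-within-5-tokens, configurable,
  default on even though the source never mentions negation — without it
  templated denials flag absurdly often.
* **Prior-year antibiotic allergy** is derived from allergy-module
  entries (365-day lookback) rather than codes.
* **Published-model discrepancies**: the frozen model follows the
  tabulated coefficients where the narrative and table disagree (6.51
  attributed to corticosteroid receipt), and both skin-related PheCode
  flags are implemented since selection narratives name each.
* **Consult flags** are extracted but excluded from the final model,
  reproducing the rejected-variable analysis.
* **Reference severity table** rows are stored exactly as printed even
  though the severity columns over-count the class totals (115 vs 104);
  a consistency report surfaces the discrepancy, and the record-level
  reconstruction used in tests relies only on the internally consistent
  marginals (class counts, allergy-module flags, >24 h attribution),
  trimming severity overflow from the largest grade.

## Problem sizes

Tests run the generator at up to 10 500 patients (calibration checks use
3 binomial SEs at that scale), the selection-consistency experiment at
n = 2000 × 50 seeded replicates, and the acceptance script simulates
4000 patients; these sizes give stable Monte-Carlo verdicts for every
checked property while keeping a full run in the low minutes on one core.

## Known limitations

* Sensitivity/specificity from enriched review samples are not
  population-weighted; inverse-probability-of-sampling estimates are an
  explicit extension, not implemented.
* The generator has no comorbidity structure, facility effects, or
  inter-channel documentation correlation; calibration tests validate
  marginals and conditionals, not joint behaviour.
* Culprit-drug attribution from timing alone is out of scope (the
  source found it infeasible without manual adjudication); severity and
  class summaries consume adjudicated records.
* The fitted odds ratios, training C statistic and comparator PPV of the
  original cohort depend on non-public data; the package checks them
  only through the property suite (parameter recovery, KKT certificates,
  concordance identities) and generator calibration, not as numeric
  reproduction targets.
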