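# Methods

This note documents the statistical procedures, the synthetic-data
generator, numerical choices, and the limits of what the test suite shows.

## Instrument and data model

The long-form instrument has 17 items: 16 ordinal items scored 0–4
(0 = none, 4 = "all of the time") across four ordinal subscales
(symptom intensity, impact, symptom frequency, coping) plus one binary
(0/1) help-seeking item. The source publication never states the response
range explicitly; the 0–4 scale is inferred from the description of a
response of "4 (All of the time)" as the top category, and is a documented
assumption, not a reported fact. Responses live in a person × item table
(`ResponseMatrix`); missing cells are allowed and excluded pairwise from
all item statistics and likelihood sums. Persons missing more than half
their items are dropped with a logged warning (the source is silent on
missingness handling). Files are comma-separated UTF-8 with `NA` as the
missing marker.

## Classical item screening

- **Floor/ceiling**: percent of non-missing responses at category 0 / at
  the maximum. Inclusion requires floor **strictly below 50%** (a floor of
  exactly 50.0 fails).
- **Item-rest correlation**: Pearson correlation between an item and the
  sum of the *other* ordinal items (the corrected form — the criterion
  wording names the correlation "with the remaining items"); inclusion at
  r ≥ 0.80. The uncorrected item-total correlation is reported alongside.
  Pearson on the raw ordinal categories matches the era-standard practice;
  polychoric correlation is out of scope. Zero-variance items yield an
  undefined (NaN) correlation, which fails the criterion.
- **KR-20** for dichotomous matrices (for example the pivot flag matrix):
  (k/(k−1))(1 − Σp_i q_i / σ²_total) with population variances. This is
  algebraically identical to coefficient alpha on the same 0/1 matrix, a
  fact the test suite checks against an independent implementation.

## Partial Credit Model

Category probabilities follow the Partial Credit Model (PCM), the
polytomous extension of the dichotomous Rasch model, with item-specific
step difficulties δ_i1..δ_im and person severities θ_n on a common logit
scale. The cumulative-logit form is evaluated with a log-sum-exp shift, so
probabilities are stable for |θ − δ| of several hundred logits.

**Estimation** is joint maximum likelihood (JMLE): alternating
Newton–Raphson updates — a full multivariate Newton step per item on its
step vector (gradient Σ_n[P(X≥k) − 1(x≥k)], Hessian from the cumulative
probabilities) and a scalar Newton step per person on θ (score r_n − E_n,
information Σ_i W_ni) — with updates clipped to ±1 logit per cycle for
stability. Identification fixes the grand mean of per-item step means at
zero. Convergence is declared when the largest parameter change falls
below `jmle_tol` (default 1e−4 logits, cap 200 cycles); non-convergence is
flagged on the results object, never raised. JMLE was chosen over CMLE/MML
because the reported statistics (person/item separation, extreme-score
conventions, mean-square fit) are the native reporting family of JMLE
software.

- **Extreme scores**: persons with zero or perfect totals carry no
  likelihood information and are excluded from estimation; they receive
  extrapolated measures at pseudo-scores 0.3 and max−0.3 (solved by
  bisection on the expected-score curve), a conventional reporting device.
- **Unobserved categories**: an item category never observed cannot have
  its step estimated; the category is collapsed into its lower neighbour
  and the item reported as re-scored. This keeps small data sets estimable
  at the cost of a changed step count for that item.
- **Bias correction**: JMLE inflates item parameters away from zero by
  roughly K/(K−1) for K items because person parameters are estimated
  jointly. The default fit is uncorrected; `step_correction=True` applies
  the multiplicative (K−1)/K shrinkage. The recovery simulations in the
  acceptance script use the corrected fit: at n=500 persons and 8
  five-category items the uncorrected step RMSE is ≈0.3 logits (almost all
  of it bias), the corrected RMSE ≈0.15.
- **Fit statistics**: infit_i = Σ_n(x−E)²/Σ_n W (information-weighted),
  outfit_i = mean_n (x−E)²/W, over non-extreme persons with observed
  responses; pairs with W ≈ 0 are excluded. Misfit is flagged outside the
  0.60–1.40 band on either statistic; the stricter 0.80–1.20 band used in
  the published criteria table is available as
  `RunConfig.STRICT_INFIT_BAND`. (A "1.6 – 2.4" range appearing once in
  the source text contradicts both stated bands and is treated as a
  typographical error; it is documented here, not implemented.)
- **Separation/reliability**: R = (var(estimates) − mean(SE²))/var,
  truncated at 0, with G = sqrt(R/(1−R)); person statistics over
  non-extreme person measures, item statistics over all step estimates
  pooled. The identity R = G²/(1+G²) holds exactly by construction and
  reproduces the published subscale reliabilities from their printed
  separation indices.
- **Subscale fits**: the published per-item fit values are grouped by
  domain, but whether estimation was per-subscale or whole-scale is not
  stated. Default here: separate unidimensional fits per subscale
  (`fit_by_subscale`), with a whole-scale fit available via the CLI flag
  `--whole-scale`.

## Pivot-anchored scoring

Each responding clinician marks the items relevant to referral and the
lowest category that indicates a clinically meaningful problem. The
per-item rule takes the **modal** threshold among endorsers, resolving ties
toward the **lower** category (the elicitation asked for the *lowest*
meaningful rating, and the lower tie is the more sensitive screen); the
endorsement percentage is computed over all responders, and the clinician
criterion requires a strict majority (>50%). Patient responses at or above
the threshold flag 1. Two scores are produced: the flag score (number of
flagged items, 0–8 on the short form) and the **raw total score** — the sum
of ordinal responses over the retained items (0–32 on the 8-item short
form), the score the published cut-point table uses. The printed cut of
">= 21" exceeds any possible flag score, which forces the raw-sum reading;
the binary help item is excluded from the total (its threshold of 1 marks
it as a flag, not a severity rating). Missing responses contribute 0 to
totals and flags, biasing toward non-referral; the count of cells so
treated is recorded on the result so the bias is auditable. Referral is
recommended at raw total ≥ cut, inclusive (default cut 6).

## Item reduction

`evaluate_criteria` combines the four criteria into per-item booleans;
`select_items` applies a named policy. The published 8-item short form is
consistent with the `any_criterion` policy (retain an item meeting at least
one criterion), which is the default; stricter policies
(`all_statistical_or_clinician`, `k_of_n`) are provided because the exact
published combination rule is not recoverable: the published criteria
table marks the infit criterion as met for two items whose printed infit
values (0.43, 0.52) fall outside both stated bands, and no single boolean
rule explains every inclusion. The published marks are therefore shipped
verbatim as a fixture (`published_criteria_marks`) rather than recomputed,
and the engine is validated against policies on that fixture. The binary
help item is retained through the clinician criterion.

## Predictive validity

Confusion tables count (score ≥ cut) × referral label. Reported per cut:
diagnostic odds ratio (TP·TN)/(FN·FP), sensitivity, specificity, PPV, NPV,
percent correctly classified, and a per-cut c-statistic computed as the
AUC of the *dichotomised* predictor — equal to (Se+Sp)/2, which is the
only reading that reproduces the published per-row c values. A zero
off-diagonal cell makes the odds ratio undefined; the default policy
reports it as missing (displayed "."), with the Haldane–Anscombe +0.5
correction opt-in. Display rounding follows the published table (2 dp for
OR/Se/Sp, 1 dp for PPV/NPV/percent, 3 dp for c); machine-readable outputs
keep full precision. The overall AUC uses the Mann–Whitney rank formula
with ties counted one half, which equals the trapezoidal area under the
empirical ROC. Logistic regression (single predictor, Newton–Raphson via
statsmodels) backs the odds-ratio cross-check exp(slope) = cross-product
OR; separation is reported as `converged=False` with a diagnostic rather
than an exception. The Hosmer–Lemeshow test uses deciles of risk with ties
kept together, X² over G groups against χ²(G−2); degenerate groups (mean
probability exactly 0 or 1) are merged with a neighbour with the degrees
of freedom adjusted.

## Synthetic data

The generator emulates the validation study's conditions: 151 patients,
28 clinicians with a 23/28 survey response rate, 16 ordinal + 1 binary
items. Defaults chosen where the source is silent:

- θ ~ N(−1.0, 1.5²): concentrates responses toward the floor, as expected
  when many screened patients have mild or no symptoms (≈41% reported
  urinary symptoms in the study population).
- Item step difficulties: item locations spread over −1..+2 logits
  (symptoms common, severe impact rarer) with step offsets −1.5..+1.5.
- Referral link: referred ~ Bernoulli(logistic(−5.5 + 0.25·raw total)),
  giving ≈1/3 referral prevalence at the default severity distribution,
  matching the study's 49/151. Labels are generated from the raw total
  score by default — the clinicians judged the completed questionnaire —
  with a latent-θ link available in the config.
- Clinician surveys: responders endorse each item with probability 0.7 and
  report the true threshold, off by one category with probability 0.1.
- Randomness: one seed per run; each stage draws from a sub-stream keyed
  by the stage name, so adding a stage never shifts another stage's draws,
  and all outputs are bit-reproducible under a fixed seed.

The generator draws independent responses from a unidimensional PCM: it
does **not** emulate local dependence between items, multidimensionality,
response styles, informative missingness, or clinician-specific referral
thresholds. Passing recovery tests therefore show the estimator is correct
under the model, not that real questionnaire data satisfy the model.

The deterministic fixture encodes the unique integer allocation of 151
(score, label) pairs — 49 referred, 102 not — consistent with the published
sensitivity and specificity at all five printed cut-points. Scores are
placed at bin lower edges (21, 9, 6, 4, 1, 0); any placement within bins
yields the same table. The fixture constrains only these bin counts, not
the full score distribution, so the published overall c-statistic (0.928)
and Hosmer–Lemeshow p (0.5180) are **not** reproducible from it — nor are
the published per-item infit/outfit values or the specific 8-item
selection, all of which require the unpublished raw data. These are
covered instead by oracle-equivalence and calibration property tests
(all-pairs AUC, direct-sum infit, logistic-vs-cross-product OR, cut
monotonicity, Hosmer–Lemeshow null rejection rate, byte-identical
pipeline reruns).

## Problem sizes

Simulation-based checks use n=500 persons × 8 items for parameter
recovery, n=2000 for null-model infit calibration, 300 observations ×
1000 replicates for the Hosmer–Lemeshow null, and n=100–151 for pipeline
runs — sizes at which the checked effects are comfortably resolved while
the whole suite runs in well under a minute of compute.

## Known limitations

- JMLE estimates are finite-sample biased; the optional (K−1)/K step
  correction removes most but not all bias for small item counts.
- Person measures are step functions of the raw total (given a complete
  response pattern), so person-level inference at 8 items is coarse.
- The pivot rule aggregates thresholds by unweighted mode; clinician
  expertise weighting is deliberately out of scope.
- No differential item functioning, rating-scale-constrained, or
  multidimensional models; subscales are treated as separate
  unidimensional scales.
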