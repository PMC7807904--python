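# Methods

## The model

`dmardseq` treats a patient's DMARD therapy as a discrete-state,
discrete-time stochastic process. The state space has six levels —
tocilizumab monotherapy (`TCZ_MONO`), tocilizumab with a csDMARD
(`TCZ_COMBO`), TNF inhibitors with or without csDMARDs (`TNFI`), all other
biologics and JAK inhibitors (`OTHER_BDMARD`), conventional synthetic DMARDs
without a biologic (`CSDMARD_ONLY`), and no DMARD (`NO_DMARD`) — and time
advances in six-month steps from the first biologic report, for up to ten
steps (five years). The analysis makes the usual first-order Markov reading
of the transition tables: the estimated matrix describes one-step
probabilities conditional on the current state, estimated by row-normalised
transition counts over adjacent grid months. No time-homogeneity is assumed
in the per-interval variant; the pooled variant averages over follow-up.

Assumptions worth keeping in mind:

- **State at nearest visit.** A grid month takes the state of the nearest
  visit within ±3 months (ties to the earlier visit). A drug started and
  stopped entirely between two forms is invisible; "any use in interval"
  would be an alternative convention and would count more switching.
- **Censoring, not missingness.** A grid month with no visit in window but
  later visits is filled by LOCF (flagged, and reruns can exclude the filled
  cells); when no later visits exist the grid censors. Censoring is treated
  as non-informative.
- **Glucocorticoids never classify.** They enter only as covariates.
- **Concurrent TCZ + TNFi** (not expected on real forms) classifies as
  `TCZ_COMBO`, because the TNFi class is defined as TNF inhibitors *without*
  TCZ.

## Trajectory mining

Trajectory steps are **episodes** — maximal runs of identical grid states —
not raw six-month cells, so duration in a state does not multiply sequence
variants. For each patient whose grid contains the target state, the at-most
four episodes preceding the first target episode (plus the target itself)
form the trajectory; identical trajectories are counted and those below a
count threshold (4 by default; 5 in the TNFi comparison figure) are pooled
into a gray below-threshold bucket. Conservation (kept counts + bucket =
reachers) is asserted in tests against a brute-force enumerator.

Time-to-target uses the grid clock: months from the first biologic (grid
month 0) to the first target grid month, among reachers; never-reachers are
reported as a count. Quantiles use midpoint interpolation (mean of the two
central order statistics for even n); the convention is recorded in the
summary output. The count of biologics tried before the target counts
bDMARD-category episodes (`TNFI`, `OTHER_BDMARD`, `TCZ_COMBO`) strictly
between the first episode and the first target episode, with repeated
categories counting as distinct episodes; since agent identity is out of
scope this undercounts within-class switches (adalimumab → etanercept is one
episode here).

## Predictor models

- **Screen.** One-covariate logistic fits; a covariate advances if any
  non-reference level has Wald p < 0.2. Constant covariates are excluded
  with a warning. Under the null the p-value is near-uniform, so the screen
  excludes an irrelevant covariate with probability ≈ 0.8 — verified over
  500 null simulations.
- **Baseline model.** Maximum-likelihood logistic regression of ever
  reaching the target on the advanced baseline covariates; Wald 95%
  intervals; odds ratios per year for age and disease duration. Reference
  levels: serostatus = negative, CDAI category = high (severe), DMARD use =
  non-use. CDAI categories: remission < 2.8, low 2.9–10.0, moderate
  10.1–22.0, high > 22.1.
- **Longitudinal model.** The repeated-measures model is implemented as a
  *marginal* pooled logistic over person-intervals — predictors at month t,
  outcome = initiation of the target state at t + 6 — with a cluster-robust
  (sandwich) covariance on patient. A generalized linear mixed model with
  robust covariance is the obvious alternative; the marginal model makes the
  same point estimates as the stacked logistic by construction, needs no
  random-effect structure to be guessed, and is reproducible across
  ecosystems. The strict one-step lag prevents outcome–predictor
  circularity.
- **Incident framing.** Person-intervals in which the patient already
  occupies an outcome state are excluded by default (`incident_only`): the
  model predicts initiation among those at risk of initiating. Besides being
  the standard epidemiological framing, this removes cells with
  probabilities near 1 (patients staying on the target), whose near-complete
  separation at cohort-scale sample sizes otherwise skews the MLE and its
  robust standard errors.
- **Separation.** A term with a runaway estimate (|coef| > 15 or exploded
  SE) is withheld and the model refit, worst offender first; a separated
  factor *level* folds into the reference rather than discarding the whole
  factor, since discarding a state indicator would bias every other
  coefficient. Withheld terms are recorded on the fit object.
- **Stratified fits.** Independent fits per stratum of prior
  TCZ-combination use; empty or degenerate strata are skipped with a
  warning and reported as such.

## The synthetic registry

The generator is the package's ground truth; its defaults emulate the
structure of a large US RA registry cohort of biologic initiators:

| Parameter | Default | Why |
| --- | --- | --- |
| `n_patients` | 7,300 | cohort scale of interest |
| `seed` | 20210114 | fixed default; all draws flow from one generator |
| `visit_gap_months` | U(4, 6) | case report form cadence |
| `horizon_months` | 60 | five-year follow-up |
| initial state mix | 0.9% TCZm, 3% TCZc, 79.3% TNFi, 16.8% other | first-biologic mix dominated by TNFi |
| `dropout_hazard` | 0.093/interval | matches at-risk denominators shrinking ~9% per interval |
| `sero_missing_rate` | 0.089 | share of patients with unresolvable serostatus |
| `prevalent_fraction` | 0.10 | registries are left-censored; some patients enter already on a biologic |
| `score_missing_rate` | 0.12/visit | exercises CDAI/HAQ carry-forward |

Latent states evolve on the exact six-month grid; a visit at time t reports
the state of the nearest grid point, so visits within three months of a grid
point reproduce it exactly and the discretizer's round-trip is exact by
construction (tested). Covariate distributions mimic published cohort
marginals (age ≈ N(57, 12.5²), 77.6% female, log-normal disease duration
with median 5 years, 15 comorbidity indicators at their cohort prevalences);
the joint distribution is independent, which no real cohort satisfies.

**Covariate effects** enter as additive log-odds shifts on destination
states in a multinomial-logit parameterisation of each kernel row. Shifting
a single destination's log-odds by s multiplies the binary odds of that
destination by exp(s) exactly, so a pooled logistic model of "next state is
the target" with current-state indicators is *exactly specified* with
coefficient s — this is what makes the generating coefficients recoverable
rather than merely approximate. Default shifts (all toward `TCZ_MONO`):
prior TCZ-combination +2.0, age +0.03/year, disease duration +0.03/year,
seropositive −0.4. Continuous features are centred at the cohort medians so
the kernel remains the typical patient's transition law.

**Calibration.** The kernel was chosen, once, to satisfy jointly: (a)
cumulative observed TCZm incidence ≈ 3.9% of the cohort within 60 months at
n = 10,000; (b) TCZm entered predominantly from TCZ combination, TNFi, or
another biologic, via a TCZ-combination funnel (3% initial occupancy,
~3%/step inflow from TNFi and other biologics, fast exit) that leaves
enough prior-combination patients in non-combination states for the
prior-TCZc coefficient to be identified at a 2,000-patient sample; and (c)
TCZm sticky once reached (0.78 stay). Constraint (a) caps the number of
incident target events (~78 per 2,000 patients), which is what makes (b) a
real design constraint rather than a free choice.

**What the generator does not emulate** — and hence what passing tests do
not establish about real registries: confounding by indication and
insurance/formulary effects on drug choice; informative dropout; within-class
agent identity; serostatus that correlates with other covariates;
measurement error in medication flags. The recovery experiments validate the
estimation machinery, not the clinical conclusions.

## Numerical conventions

- Percentages print with half-up rounding (via `decimal`), two decimals in
  occupancy tables, one in prose-style outputs.
- Quantiles: midpoint interpolation throughout.
- Transition rows with zero counts are reported as undefined (NaN) and
  flagged, never zero-filled.
- Ties in visit-to-grid matching break to the earlier visit; distances are
  rounded at 1e-9 before comparison to keep the tie-break deterministic in
  floating point.
- Trajectory figures: sequences sorted by count descending then
  lexicographically; widths linear in count with a cap; fixed SVG hash salt
  and no embedded date, so reruns are byte-identical.

## Problem sizes used in validation

Transition-matrix recovery runs 8,000 patients started from a uniform state
distribution (≈38,000 person-intervals; every origin row receives ≥2,000
intervals), recovering each kernel entry to within 0.02 (observed ≈ 0.01).
Coefficient recovery runs 50 replicates of 2,000 patients with only the
prior-combination effect active, so the fitted model matches the generating
model exactly; coverage of the 2-robust-SE interval is ≥ 90% (observed
92–96% across base seeds). Incidence calibration uses n = 10,000; the screen
null uses 500 simulations of n = 400.

## Known limitations

- The Markov matrices are descriptive; no intensity-based multistate model
  or hypothesis testing on matrices is provided.
- The six-state taxonomy pools subcutaneous and intravenous routes and all
  agents within a class.
- The baseline fallback for prevalent initiators (baseline = enrollment
  visit) makes their "baseline" covariates contemporaneous with, not prior
  to, the first biologic.
- The longitudinal model is marginal; subject-specific (conditional) odds
  ratios would differ under strong unobserved heterogeneity.
- With `gap_rule="censor"` a single missed window discards all later
  follow-up, which is conservative.
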