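# dmardseq

Quantifying sequences of disease-modifying anti-rheumatic drug (DMARD)
treatment in rheumatoid-arthritis registries: which paths lead patients to a
target therapy, how long they take, and which patient characteristics predict
arriving there.

Patients with RA who fail conventional synthetic DMARDs (csDMARDs) move
through biologic DMARDs — TNF inhibitors, IL-6 antagonists such as
tocilizumab (TCZ), other biologics and JAK inhibitors — in sequences that are
poorly characterised. `dmardseq` implements a discrete-state analysis of such
sequences, with tocilizumab **monotherapy** (TCZm, TCZ with no concurrent
DMARD) as the worked target therapy:

1. **Six-state classification.** Every clinic visit's medication flags map to
   one of `TCZ_MONO`, `TCZ_COMBO` (TCZ + csDMARD), `TNFI`, `OTHER_BDMARD`
   (other biologics and JAK inhibitors), `CSDMARD_ONLY`, `NO_DMARD`, with
   precedence TCZ > TNFi > other bDMARD > csDMARD.
2. **Six-month Markov discretization.** Each patient's clock starts at the
   first biologic report (the visit before it is baseline). States are read
   at months 0, 6, …, 60 from the nearest visit within ±3 months; interior
   gaps are filled by last observation carried forward, terminal gaps censor.
   From the grids: per-interval state occupancy tables with declining at-risk
   denominators, and row-stochastic transition matrices
   P[s→s′] = N[s→s′] / Σ_{s′} N[s→s′], pooled or per interval.
3. **Trajectory mining.** Consecutive identical grid states collapse into
   episodes; for each patient who reaches the target, the at-most-4 episodes
   preceding the first target episode form a trajectory. Identical
   trajectories are counted; rare ones pool into a below-threshold bucket.
   Time to target is summarised by midpoint-interpolated median/IQR.
4. **Predictor models.** A univariable logistic screen advances covariates
   with Wald p < 0.2; a baseline-only logistic model predicts ever reaching
   the target; a longitudinal pooled logistic model over person-intervals
   (predictors at month t, initiation at t + 6) uses a patient-clustered
   sandwich covariance for within-person correlation, with fits stratified
   on prior TCZ-combination use.

Real registries of this kind are proprietary, so the package ships a
synthetic registry generator that emulates their structure — case report
forms every 4–6 months, covariate-dependent switching on the
multinomial-logit scale, ~8.9% missing serostatus, per-interval dropout, and
a cumulative TCZm incidence near 3.9% — and every stage is validated against
that generator's known ground truth.

## Worked example

```python
from dmardseq import SimConfig, run_pipeline
manifest = run_pipeline(SimConfig(), "results/demo")
```

or step by step via the numbered drivers:

```sh
python analysis/01_simulate_registry.py
python analysis/02_build_state_grids.py
python analysis/03_markov_tables.py
python analysis/04_mine_trajectories.py
python analysis/05_predictor_models.py
python analysis/06_validation.py
```

With the default configuration (7,300 patients, seed 20210114) this prints,
among other things:

```
cohort: 7300 patients, 67147 visits
serostatus missing: 650 (8.9%)
at risk by month: {0: 7300, 6: 6571, 12: 5954, ..., 60: 2719}

--- TCZ_MONO ---
reachers: 275; median 18.0 months (IQR (0.0, 36.0))
within 36 months: 80.4%
                sequence  count  share
                TCZ_MONO     79  0.287
 TNFI>TCZ_COMBO>TCZ_MONO     50  0.182
           TNFI>TCZ_MONO     37  0.135
      TCZ_COMBO>TCZ_MONO     24  0.087
```

(your exact counts depend on the seed): about 3.8% of the synthetic cohort
reaches TCZ monotherapy within five years, most arriving from TCZ
combination therapy or a TNF inhibitor, and the dominant mined trajectories
are TNFi → TCZ combination → TCZm and TNFi → TCZm. The validation driver
then reports that the pooled transition-matrix estimate recovers the
generating kernel to within 0.01, and that the longitudinal model recovers
the generating prior-TCZ-combination log-odds shift (2.0) within two robust
standard errors in 96% of 50 replicates.

A CLI wraps the same stages:

```sh
dmardseq run --out results/demo --seed 1 --n 2000
dmardseq simulate --out data/ --n 500
dmardseq mine --grids data/grids.csv --target TCZ_MONO --lookback 4 --min-count 4 --out mined/
```

## Layout

- `src/dmardseq/` — library: `states`, `simulate`, `grids`, `markov`,
  `mining`, `models`, `reporting`, `experiments`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables/figures under
  `results/analysis/`.
- `tests/` — pytest suite, including property-based checks (hypothesis) and
  end-to-end acceptance tests.
- `docs/methods.md` — modelling assumptions, generator design, numerical
  conventions and limitations.
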