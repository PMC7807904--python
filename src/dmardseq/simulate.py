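"""Synthetic rheumatoid-arthritis registry generator.

Emulates the data structure of a large observational RA registry in which
patients starting a biologic DMARD are followed with case report forms every
4-6 months for up to five years: a patients table (one row per patient,
baseline covariates) and a visits table (one row per clinic visit, medication
indicator flags plus CDAI and HAQ scores).

The generating process is an explicit discrete-time Markov chain on the
six-state treatment taxonomy with one step per six months.  Patient covariates
shift the chain's rows on the multinomial-logit scale, so the generating
coefficients are known exactly and the downstream predictor models can be
checked against ground truth.  Shifting a single destination state's log-odds
by ``s`` multiplies the binary odds of that destination by ``exp(s)`` within
every row, so a pooled logistic model of "next state is the target" with
current-state indicators is exactly specified with coefficient ``s``.

Default magnitudes are chosen to mimic the published cohort: ~81% of first
biologics are TNF inhibitors, serostatus is missing for 8.9% of patients,
denominators decline by roughly 9% per interval, and about 3.9% of patients
ever reach tocilizumab monotherapy within 60 months, predominantly arriving
from TCZ combination therapy, a TNF inhibitor, or another bDMARD.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .states import STATE_INDEX, STATE_ORDER, TreatmentState, state_flags

N_STATES = 6
STEP_MONTHS = 6

#: Baseline six-month transition kernel (rows/cols in STATE_ORDER:
#: TCZ_MONO, TCZ_COMBO, TNFI, OTHER_BDMARD, CSDMARD_ONLY, NO_DMARD).
#: Tocilizumab monotherapy is sticky once reached and is entered mostly from
#: TCZ combination (whose row, together with the prior-combination covariate
#: shift, forms the dominant funnel), with smaller direct hazards from the
#: TNFi and other-bDMARD states; re-entry from csDMARD-only or no-DMARD is
#: rare.  Calibrated so the cohort's cumulative observed incidence of the
#: target state over ten intervals sits near 3.9%.
DEFAULT_KERNEL = np.array(
    [
        # T       C       N       O       S       X
        [0.7800, 0.0600, 0.0500, 0.0400, 0.0450, 0.0250],  # TCZ_MONO
        [0.0075, 0.6170, 0.1700, 0.0900, 0.0800, 0.0355],  # TCZ_COMBO
        [0.0020, 0.0300, 0.8368, 0.0550, 0.0510, 0.0252],  # TNFI
        [0.0026, 0.0300, 0.0500, 0.7999, 0.0700, 0.0475],  # OTHER_BDMARD
        [0.0008, 0.0100, 0.0800, 0.0500, 0.8142, 0.0450],  # CSDMARD_ONLY
        [0.0005, 0.0070, 0.0600, 0.0400, 0.1000, 0.7925],  # NO_DMARD
    ]
)

#: Distribution of the first-biologic state (grid month 0).  Mirrors the
#: observed first-bDMARD mix: ~80% TNFi, ~17% other bDMARD, ~1% TCZ mono,
#: with TCZ combination the remainder.
DEFAULT_INITIAL_DISTRIBUTION = np.array([0.009, 0.030, 0.793, 0.168, 0.0, 0.0])

#: Additive log-odds shifts on destination states (multinomial-logit scale),
#: keyed by feature name then destination state.  Defaults shift only the
#: target destination, which keeps the implied binary logistic model for the
#: target outcome exactly specified (see module docstring).
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[TreatmentState, float]] = {
    "ever_tcz_combo": {TreatmentState.TCZ_MONO: 2.0},
    "age_c": {TreatmentState.TCZ_MONO: 0.03},
    "duration_c": {TreatmentState.TCZ_MONO: 0.03},
    "seropositive": {TreatmentState.TCZ_MONO: -0.4},
}

#: Centering constants for continuous features (cohort medians), so that the
#: covariate shifts average out near zero and the kernel stays interpretable
#: as the typical patient's transition law.
AGE_CENTER = 57.0
DURATION_CENTER = 5.0

#: Baseline comorbidity prevalences (15 conditions of the published cohort).
COMORBIDITY_PREVALENCE: dict[str, float] = {
    "anemia": 0.0144,
    "asthma": 0.0155,
    "depression": 0.0434,
    "diabetes": 0.0382,
    "diarrhea": 0.0104,
    "dyspepsia": 0.0132,
    "fibromyalgia": 0.0152,
    "hepatic_event": 0.0014,
    "hyperlipidemia": 0.0349,
    "hypertension": 0.1290,
    "nausea": 0.0118,
    "cancer": 0.0190,
    "stroke": 0.0084,
    "ulcer": 0.0258,
    "misc": 0.1799,
}

COMORBIDITY_COLUMNS = tuple(f"como_{name}" for name in COMORBIDITY_PREVALENCE)


@dataclasses.dataclass
class SimConfig:
    """Configuration of the synthetic registry generator.

    Parameters
    ----------
    n_patients
        Cohort size (number of biologic initiators).
    seed
        Seed for the single pseudo-random generator all draws flow from.
    visit_gap_months
        Uniform range for the gap between consecutive case report forms.
    horizon_months
        Follow-up horizon after the first-biologic baseline; must be a
        multiple of the six-month step.
    kernel
        Baseline 6x6 row-stochastic transition matrix per six-month step.
    initial_distribution
        Distribution of the state at grid month 0 (the first biologic).
    covariate_effects
        Mapping feature name -> {destination state: additive log-odds shift}.
    dropout_hazard
        Per-interval probability that follow-up ends (simple censoring,
        independent of state).
    sero_missing_rate
        Fraction of patients whose recorded serostatus is set to missing.
    prevalent_fraction
        Fraction of patients already on a biologic at their enrollment visit
        (registries are left-censored; such patients have no pre-biologic
        visit and their baseline falls back to the enrollment visit).
    score_missing_rate
        Per-visit probability that CDAI (and, independently, HAQ) is left
        blank on the form.
    target_state
        The therapy whose pathways are under study.
    """

    n_patients: int = 7300
    seed: int = 20210114
    visit_gap_months: tuple[float, float] = (4.0, 6.0)
    horizon_months: int = 60
    kernel: np.ndarray = dataclasses.field(default_factory=lambda: DEFAULT_KERNEL.copy())
    initial_distribution: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_INITIAL_DISTRIBUTION.copy()
    )
    covariate_effects: Mapping[str, Mapping[TreatmentState, float]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    dropout_hazard: float = 0.093
    sero_missing_rate: float = 0.089
    prevalent_fraction: float = 0.10
    score_missing_rate: float = 0.12
    target_state: TreatmentState = TreatmentState.TCZ_MONO

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.kernel.shape != (N_STATES, N_STATES):
            raise ValueError(f"kernel must be {N_STATES}x{N_STATES}")
        if np.any(self.kernel < 0) or np.any(self.kernel > 1):
            raise ValueError("kernel entries must be probabilities in [0, 1]")
        row_sums = self.kernel.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-12):
            bad = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"kernel row {bad} ({STATE_ORDER[bad]}) sums to {row_sums[bad]!r}, not 1"
            )
        if not np.isclose(self.initial_distribution.sum(), 1.0, atol=1e-12):
            raise ValueError("initial_distribution must sum to 1")
        if self.horizon_months % STEP_MONTHS != 0 or self.horizon_months <= 0:
            raise ValueError("horizon_months must be a positive multiple of 6")
        lo, hi = self.visit_gap_months
        if not (0 < lo <= hi):
            raise ValueError("visit_gap_months must satisfy 0 < lo <= hi")
        for name, rate in [
            ("dropout_hazard", self.dropout_hazard),
            ("sero_missing_rate", self.sero_missing_rate),
            ("prevalent_fraction", self.prevalent_fraction),
            ("score_missing_rate", self.score_missing_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_intervals(self) -> int:
        """Number of six-month steps from baseline to the horizon."""
        return self.horizon_months // STEP_MONTHS

    def effects_matrix(self) -> tuple[list[str], np.ndarray]:
        """Covariate effects as (feature names, len(features) x 6 shift matrix)."""
        names = list(self.covariate_effects)
        mat = np.zeros((len(names), N_STATES))
        for i, name in enumerate(names):
            for state, shift in self.covariate_effects[name].items():
                mat[i, STATE_INDEX[TreatmentState(state)]] = float(shift)
        return names, mat


def _shift_rows(base_rows: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Apply additive log-odds shifts to stochastic rows (softmax renormalise).

    Zero-probability destinations stay at zero regardless of shifts.
    """
    with np.errstate(divide="ignore"):
        logits = np.log(base_rows) + shifts
    out = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return out / out.sum(axis=-1, keepdims=True)


def patient_features(patients: pd.DataFrame, ever_tcz_combo: np.ndarray | int = 0) -> pd.DataFrame:
    """Derive the model features the covariate effects are defined on.

    ``seropositive`` uses the *latent* serostatus when present (column
    ``serostatus_true``) so that injected missingness does not alter the
    generating process; missing counts as not-positive.
    """
    sero_col = "serostatus_true" if "serostatus_true" in patients.columns else "serostatus"
    n = len(patients)
    return pd.DataFrame(
        {
            "age_c": patients["age_years"].to_numpy(float) - AGE_CENTER,
            "duration_c": patients["disease_duration_years"].to_numpy(float) - DURATION_CENTER,
            "seropositive": (patients[sero_col] == "positive").to_numpy(float),
            "ever_tcz_combo": np.broadcast_to(np.asarray(ever_tcz_combo, float), (n,)).copy(),
        },
        index=patients.index,
    )


def true_transition_row(
    config: SimConfig,
    state: TreatmentState,
    covariates: Mapping[str, float] | pd.Series | None = None,
) -> np.ndarray:
    """Exact generating transition row for ``state`` under covariate shifts.

    ``covariates`` maps feature names (as used in ``config.covariate_effects``)
    to values; absent features count as zero.  Serves as the oracle for
    transition-matrix and coefficient recovery checks.
    """
    if state not in STATE_INDEX:
        raise ValueError(f"unknown state {state!r}")
    names, effect_mat = config.effects_matrix()
    shift = np.zeros(N_STATES)
    if covariates is not None:
        for i, name in enumerate(names):
            shift += float(covariates.get(name, 0.0)) * effect_mat[i]
    return _shift_rows(config.kernel[STATE_INDEX[state]], shift)


def inject_missingness(
    patients: pd.DataFrame,
    rate: float,
    field: str,
    rng: np.random.Generator,
    missing_value: object = "missing",
) -> pd.DataFrame:
    """Set exactly ``round(rate * n)`` values of ``field`` to missing.

    Records are chosen by a seeded draw without replacement; returns a copy.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if field not in patients.columns:
        raise KeyError(f"unknown field {field!r}")
    out = patients.copy()
    n_missing = int(round(rate * len(out)))
    if n_missing:
        rows = rng.choice(len(out), size=n_missing, replace=False)
        out.iloc[rows, out.columns.get_loc(field)] = missing_value
    return out


def _draw_patients(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline covariate table, marginals mimicking the published cohort."""
    n = config.n_patients
    age = np.clip(rng.normal(57.0, 12.5, n).round(0), 18, 90)
    duration = np.clip(np.exp(rng.normal(np.log(5.0), 1.15, n)), 0.1, 50.0).round(1)
    sero = np.where(rng.random(n) < 0.60, "positive", "negative")
    cdai = np.clip(rng.gamma(1.7, 10.5, n), 0.0, 76.0).round(1)
    haq = np.clip(rng.normal(0.86, 0.65, n), 0.0, 3.0).round(2)
    patients = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age_years": age,
            "sex": np.where(rng.random(n) < 0.776, "female", "male"),
            "disease_duration_years": duration,
            "serostatus": sero,
            "erosion_flag": (rng.random(n) < 0.30).astype(int),
            "csdmard_baseline": (rng.random(n) < 0.821).astype(int),
            "glucocorticoid_baseline": (rng.random(n) < 0.34).astype(int),
            "cdai_baseline": cdai,
            "haq_baseline": haq,
        }
    )
    for name, prev in COMORBIDITY_PREVALENCE.items():
        patients[f"como_{name}"] = (rng.random(n) < prev).astype(int)
    # keep the latent serostatus for the generating process; the recorded
    # column gets missingness injected afterwards
    patients["serostatus_true"] = patients["serostatus"]
    return patients


def _simulate_chains(
    config: SimConfig, patients: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Run the covariate-shifted Markov chain for every patient.

    Returns ``(states, n_observed)`` where ``states`` is an
    ``(n, n_intervals + 1)`` integer array of state indices on the six-month
    grid and ``n_observed[i]`` is the number of grid points observed before
    dropout (at least 1; the baseline interval is always observed).
    """
    n = config.n_patients
    k_steps = config.n_intervals
    states = np.empty((n, k_steps + 1), dtype=np.int64)
    if n == 0:
        return states, np.zeros(0, dtype=np.int64)
    names, effect_mat = config.effects_matrix()
    feats = patient_features(patients)
    static = np.zeros((n, N_STATES))
    dyn_idx = None
    for i, name in enumerate(names):
        if name == "ever_tcz_combo":
            dyn_idx = i
            continue
        static += np.outer(feats[name].to_numpy(float), effect_mat[i])

    states[:, 0] = rng.choice(N_STATES, size=n, p=config.initial_distribution)
    ever_combo = states[:, 0] == STATE_INDEX[TreatmentState.TCZ_COMBO]
    for k in range(k_steps):
        rows = config.kernel[states[:, k]]
        shifts = static.copy()
        if dyn_idx is not None:
            shifts += np.outer(ever_combo.astype(float), effect_mat[dyn_idx])
        probs = _shift_rows(rows, shifts)
        u = rng.random(n)
        states[:, k + 1] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        ever_combo |= states[:, k + 1] == STATE_INDEX[TreatmentState.TCZ_COMBO]

    # dropout: geometric number of observed grid points, baseline always seen
    if config.dropout_hazard > 0:
        drop = rng.random((n, k_steps)) < config.dropout_hazard
        first = np.argmax(drop, axis=1)
        any_drop = drop.any(axis=1)
        n_observed = np.where(any_drop, first + 1, k_steps + 1)
    else:
        n_observed = np.full(n, k_steps + 1)
    return states, n_observed.astype(np.int64)


def generate_registry(
    config: SimConfig, return_latent: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the synthetic (patients, visits) tables.

    Each patient contributes an enrollment visit, a first-biologic visit and
    subsequent visits at gaps drawn uniformly from ``visit_gap_months`` until
    dropout or the horizon.  Medication flags at each visit reflect the latent
    six-month-grid state nearest in time, so visits within three months of a
    grid point report that grid point's state exactly.  Deterministic given
    the seed.

    With ``return_latent=True`` a third tidy frame of the latent grid states
    (patient_id, interval, grid_month_abs, state, observed flag) is returned
    for use as ground truth in recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    patients = _draw_patients(config, rng)
    states, n_observed = _simulate_chains(config, patients, rng)
    n = config.n_patients
    k_grid = config.n_intervals + 1

    if n > 0:
        prevalent = rng.random(n) < config.prevalent_fraction
        lo, hi = config.visit_gap_months
        # months from enrollment to the first-biologic visit (0 if prevalent)
        first_bio = np.where(prevalent, 0.0, rng.uniform(lo, hi, n))

        # enrollment visit for non-prevalent patients: pre-biologic state
        pre_state = np.where(
            patients["csdmard_baseline"].to_numpy(bool),
            STATE_INDEX[TreatmentState.CSDMARD_ONLY],
            STATE_INDEX[TreatmentState.NO_DMARD],
        )

        # post-baseline visit times: first-bio visit plus uniform gaps; enough
        # gaps to overrun the horizon even at the shortest gap
        max_visits = int(np.ceil(config.horizon_months / lo)) + 2
        gaps = rng.uniform(lo, hi, (n, max_visits))
        offsets = np.concatenate([np.zeros((n, 1)), gaps.cumsum(axis=1)], axis=1)
        interval = np.rint(offsets / STEP_MONTHS).astype(np.int64)
        keep = (interval < n_observed[:, None]) & (interval <= config.n_intervals)

        pid_grid = np.broadcast_to(patients["patient_id"].to_numpy()[:, None], offsets.shape)
        times = first_bio[:, None] + offsets
        vis_state = np.take_along_axis(states, np.clip(interval, 0, k_grid - 1), axis=1)

        concurrent_cs = rng.random(offsets.shape) < 0.60
        core = pd.DataFrame(
            {
                "patient_id": pid_grid[keep],
                "months_since_enrollment": times[keep],
                "state_idx": vis_state[keep],
                "concurrent_cs": concurrent_cs[keep],
            }
        )
        enroll = pd.DataFrame(
            {
                "patient_id": patients["patient_id"].to_numpy()[~prevalent],
                "months_since_enrollment": 0.0,
                "state_idx": pre_state[~prevalent],
                "concurrent_cs": False,
            }
        )
        core = pd.concat([enroll, core], ignore_index=True)
        core.sort_values(["patient_id", "months_since_enrollment"], inplace=True, kind="stable")
        core.reset_index(drop=True, inplace=True)

        # medication flags from the latent state
        sidx = core["state_idx"].to_numpy()
        cs = core["concurrent_cs"].to_numpy()
        flag_tbl = np.empty((len(core), 4), dtype=np.int64)
        for j in range(N_STATES):
            for conc in (False, True):
                mask = (sidx == j) & (cs == conc)
                if mask.any():
                    f = state_flags(STATE_ORDER[j], csdmard_concurrent=conc)
                    flag_tbl[mask] = [f["tcz"], f["tnfi"], f["other_bdmard_or_jak"], f["csdmard"]]
        m = len(core)
        base = patients.set_index("patient_id")
        cdai0 = base["cdai_baseline"].reindex(core["patient_id"]).to_numpy(float)
        haq0 = base["haq_baseline"].reindex(core["patient_id"]).to_numpy(float)
        cdai = np.clip(cdai0 + rng.normal(0.0, 3.0, m), 0.0, 76.0).round(1)
        haq = np.clip(haq0 + rng.normal(0.0, 0.2, m), 0.0, 3.0).round(2)
        cdai[rng.random(m) < config.score_missing_rate] = np.nan
        haq[rng.random(m) < config.score_missing_rate] = np.nan
        visits = pd.DataFrame(
            {
                "patient_id": core["patient_id"].to_numpy(),
                "months_since_enrollment": core["months_since_enrollment"].round(2),
                "tcz": flag_tbl[:, 0],
                "tnfi": flag_tbl[:, 1],
                "other_bdmard_or_jak": flag_tbl[:, 2],
                "csdmard": flag_tbl[:, 3],
                "glucocorticoid": (rng.random(m) < 0.34).astype(int),
                "cdai": cdai,
                "haq": haq,
            }
        )
    else:
        first_bio = np.zeros(0)
        visits = pd.DataFrame(
            columns=[
                "patient_id",
                "months_since_enrollment",
                "tcz",
                "tnfi",
                "other_bdmard_or_jak",
                "csdmard",
                "glucocorticoid",
                "cdai",
                "haq",
            ]
        )

    patients = inject_missingness(patients, config.sero_missing_rate, "serostatus", rng)

    if not return_latent:
        return patients.drop(columns=["serostatus_true"]), visits

    latent = pd.DataFrame(
        {
            "patient_id": np.repeat(patients["patient_id"].to_numpy(), k_grid),
            "interval": np.tile(np.arange(k_grid), n),
            "grid_month_abs": np.repeat(first_bio, k_grid) + np.tile(np.arange(k_grid), n) * 6.0,
            "state": np.array([s.value for s in STATE_ORDER])[states.ravel()],
            "observed": (np.tile(np.arange(k_grid), n) < np.repeat(n_observed, k_grid)).astype(int),
        }
    )
    return patients.drop(columns=["serostatus_true"]), visits, latent


def ever_target_fraction(config: SimConfig) -> float:
    """Fraction of patients observed in the target state within the horizon.

    Convenience wrapper used for calibration checks; runs the full generator
    and inspects the latent grid restricted to observed intervals.
    """
    _, _, latent = generate_registry(config, return_latent=True)
    hit = latent[(latent["observed"] == 1) & (latent["state"] == config.target_state.value)]
    return hit["patient_id"].nunique() / max(config.n_patients, 1)
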