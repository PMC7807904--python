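"""Anchor patients at their first-biologic baseline and discretize visits
onto the six-month state grid.

The cohort clock starts at the first visit reporting a biologic DMARD; the
visit before it is the baseline.  States are then read off at months
0, 6, ..., 60: each grid month takes the classified state of the nearest
visit within a +/-3-month window (ties broken to the earlier visit).  An
interior month with no visit in the window is filled by last observation
carried forward (LOCF) while later visits exist; once no later visits
remain the grid is censored.  With forms arriving every 4-6 months the
windows tile follow-up, so LOCF only fires on unusually long gaps.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .states import BDMARD_STATES, TreatmentState, classify_visit

GRID_STEP = 6


@dataclasses.dataclass(frozen=True)
class GridPolicy:
    """Visit-to-grid mapping policy.

    window_halfwidth_months
        Half-width of the matching window around each grid month.
    gap_rule
        ``"locf"`` fills interior gaps with the last observed state;
        ``"censor"`` truncates the grid at the first gap.
    """

    window_halfwidth_months: float = 3.0
    gap_rule: str = "locf"

    def __post_init__(self) -> None:
        if self.gap_rule not in ("locf", "censor"):
            raise ValueError("gap_rule must be 'locf' or 'censor'")
        if not 0 < self.window_halfwidth_months <= GRID_STEP / 2 + 1e-9:
            raise ValueError("window_halfwidth_months must lie in (0, 3]")


@dataclasses.dataclass
class StateGrid:
    """One patient's treatment states on the six-month grid.

    ``states`` holds entries for months ``0, 6, ...`` up to (excluding) the
    censoring month; entries beyond the censor index are absent by
    construction.  ``filled`` marks LOCF-filled cells.  ``prevalent`` flags
    patients whose first recorded visit was already a biologic, for whom
    baseline falls back to the enrollment visit.
    """

    patient_id: object
    baseline_month: float
    states: list[TreatmentState]
    filled: list[bool]
    prevalent: bool = False

    @property
    def censor_index(self) -> int:
        return len(self.states)

    def grid_months(self) -> list[int]:
        return [GRID_STEP * i for i in range(len(self.states))]


class NoBiologicError(ValueError):
    """Raised when a patient never reports a biologic DMARD (not in cohort)."""


def classify_visits(visits: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`~dmardseq.states.classify_visit` over a visits table."""
    tcz = visits["tcz"].to_numpy(bool)
    tnfi = visits["tnfi"].to_numpy(bool)
    other = visits["other_bdmard_or_jak"].to_numpy(bool)
    cs = visits["csdmard"].to_numpy(bool)
    out = np.where(
        tcz,
        np.where(tnfi | other | cs, TreatmentState.TCZ_COMBO.value, TreatmentState.TCZ_MONO.value),
        np.where(
            tnfi,
            TreatmentState.TNFI.value,
            np.where(
                other,
                TreatmentState.OTHER_BDMARD.value,
                np.where(cs, TreatmentState.CSDMARD_ONLY.value, TreatmentState.NO_DMARD.value),
            ),
        ),
    )
    return pd.Series(out, index=visits.index, name="state")


def find_baseline(visits: pd.DataFrame) -> tuple[int, float, bool]:
    """Locate the baseline visit for one patient's time-sorted visits.

    Returns ``(baseline_index, time_zero_month, prevalent_flag)`` where
    ``baseline_index`` is the positional index of the last visit strictly
    before the first biologic report and ``time_zero_month`` is the month of
    that first biologic visit (the cohort clock's zero).  If the very first
    visit is already a biologic, the baseline falls back to that visit and
    the patient is flagged as a prevalent initiator.

    Raises :class:`NoBiologicError` if no visit ever reports a biologic.
    """
    t = visits["months_since_enrollment"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ValueError("visits must be sorted by months_since_enrollment")
    states = classify_visits(visits)
    is_bio = states.isin([s.value for s in BDMARD_STATES]).to_numpy()
    if not is_bio.any():
        raise NoBiologicError(f"patient {visits['patient_id'].iloc[0]!r} never on a biologic")
    first = int(np.argmax(is_bio))
    if first == 0:
        return 0, float(t[0]), True
    return first - 1, float(t[first]), False


def build_state_grid(
    visits: pd.DataFrame,
    baseline: tuple[int, float, bool] | None = None,
    policy: GridPolicy = GridPolicy(),
    horizon_months: int = 60,
) -> StateGrid:
    """Discretize one patient's visits onto the grid (reference implementation).

    Per grid month ``m``: the state of the visit nearest ``time_zero + m``
    within the policy window (ties to the earlier visit); otherwise LOCF if
    later visits exist and the policy allows, else censoring.  The batch
    routine :func:`build_state_grids` is the vectorised equivalent.
    """
    if baseline is None:
        baseline = find_baseline(visits)
    _, t0, prevalent = baseline
    t = visits["months_since_enrollment"].to_numpy(float)
    states = classify_visits(visits).to_numpy()
    post = t >= t0 - 1e-9
    t_post, s_post = t[post] - t0, states[post]
    last_time = t_post.max() if len(t_post) else -np.inf

    out_states: list[TreatmentState] = []
    filled: list[bool] = []
    for m in range(0, horizon_months + 1, GRID_STEP):
        dist = np.abs(t_post - m)
        in_win = dist <= policy.window_halfwidth_months + 1e-9
        if in_win.any():
            cand = np.flatnonzero(in_win)
            best = cand[np.lexsort((t_post[cand], np.round(dist[cand], 9)))][0]
            out_states.append(TreatmentState(s_post[best]))
            filled.append(False)
        elif last_time > m and policy.gap_rule == "locf" and out_states:
            out_states.append(out_states[-1])
            filled.append(True)
        else:
            break  # terminal gap or censor policy: censored from here on
    pid = visits["patient_id"].iloc[0]
    return StateGrid(pid, t0, out_states, filled, prevalent)


def build_state_grids(
    visits: pd.DataFrame,
    policy: GridPolicy = GridPolicy(),
    horizon_months: int = 60,
) -> pd.DataFrame:
    """Vectorised grid construction for a whole visits table.

    Returns a tidy frame with one row per observed patient-gridmonth:
    ``patient_id, grid_month, state, filled, prevalent, cdai, haq`` where
    ``cdai``/``haq`` come from the matched visit (NaN for LOCF-filled cells;
    apply :func:`carry_forward_covariates` to the visits first if carried
    scores are wanted).  Patients never on a biologic are dropped.
    """
    visits = visits.sort_values(["patient_id", "months_since_enrollment"], kind="stable")
    v = visits.copy()
    v["state"] = classify_visits(v)
    v["is_bio"] = v["state"].isin([s.value for s in BDMARD_STATES])

    # time zero: first biologic visit per patient
    bio = v[v["is_bio"]]
    t0 = bio.groupby("patient_id")["months_since_enrollment"].first().rename("t0")
    first_visit = v.groupby("patient_id")["months_since_enrollment"].first()
    prevalent = (t0 <= first_visit.reindex(t0.index) + 1e-9).rename("prevalent")

    v = v.join(t0, on="patient_id", how="inner")
    v["rel"] = v["months_since_enrollment"] - v["t0"]
    v = v[v["rel"] >= -1e-9]

    # candidate (grid month, visit) pairs within the window
    w = policy.window_halfwidth_months
    rel = v["rel"].to_numpy(float)
    lo_k = np.ceil((rel - w - 1e-9) / GRID_STEP).astype(int)
    hi_k = np.floor((rel + w + 1e-9) / GRID_STEP).astype(int)
    lo_k = np.clip(lo_k, 0, horizon_months // GRID_STEP)
    hi_k = np.clip(hi_k, -1, horizon_months // GRID_STEP)
    counts = np.maximum(hi_k - lo_k + 1, 0)
    ridx = np.repeat(np.arange(len(v)), counts)
    k = np.concatenate([np.arange(a, b + 1) for a, b in zip(lo_k, hi_k) if b >= a]) if len(v) else np.array([], int)
    cand = pd.DataFrame(
        {
            "patient_id": v["patient_id"].to_numpy()[ridx],
            "grid_month": k * GRID_STEP,
            "state": v["state"].to_numpy()[ridx],
            "rel": rel[ridx],
            "cdai": v["cdai"].to_numpy(float)[ridx] if "cdai" in v else np.nan,
            "haq": v["haq"].to_numpy(float)[ridx] if "haq" in v else np.nan,
        }
    )
    cand["dist"] = np.round(np.abs(cand["rel"] - cand["grid_month"]), 9)
    cand = cand[cand["dist"] <= w + 1e-9]
    # nearest visit wins; tie -> earlier visit (rel ascending after dist)
    cand.sort_values(["patient_id", "grid_month", "dist", "rel"], inplace=True, kind="stable")
    matched = cand.drop_duplicates(["patient_id", "grid_month"]).copy()
    matched["filled"] = False

    # LOCF fill: interior grid months with no visit in window but later visits
    last_rel = v.groupby("patient_id")["rel"].max().rename("last_rel")
    pids = t0.index.to_numpy()
    n_k = horizon_months // GRID_STEP + 1
    full = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, n_k),
            "grid_month": np.tile(np.arange(n_k) * GRID_STEP, len(pids)),
        }
    )
    full = full.join(last_rel, on="patient_id")
    full = full.merge(matched[["patient_id", "grid_month", "state", "filled", "cdai", "haq"]],
                      on=["patient_id", "grid_month"], how="left")
    observable = full["grid_month"] < full["last_rel"] - 1e-9
    keep = full["state"].notna() | observable
    full = full[keep].copy()
    if policy.gap_rule == "locf":
        full["filled"] = full["state"].isna()
        full["state"] = full.groupby("patient_id")["state"].ffill()
    else:
        # censor at first gap: drop everything from the first unmatched month on
        gap = full["state"].isna()
        bad = gap.groupby(full["patient_id"]).cummax()
        full = full[~bad].copy()
        full["filled"] = False
    # a leading unmatched month cannot happen (month 0 is the first-bio visit)
    full = full[full["state"].notna()].copy()
    full = full.join(prevalent, on="patient_id")
    full = full.join(t0.rename("baseline_month"), on="patient_id")
    full["filled"] = full["filled"].astype(bool)
    return full[
        ["patient_id", "grid_month", "state", "filled", "prevalent", "baseline_month", "cdai", "haq"]
    ].reset_index(drop=True)


def carry_forward_covariates(visits: pd.DataFrame, columns: tuple[str, ...] = ("cdai", "haq")) -> pd.DataFrame:
    """Fill missing scores with the most recent prior non-missing value.

    Within-patient forward fill on time-sorted visits; leading missing values
    stay missing.  Returns a copy.
    """
    out = visits.sort_values(["patient_id", "months_since_enrollment"], kind="stable").copy()
    for col in columns:
        if col in out.columns:
            out[col] = out.groupby("patient_id")[col].ffill()
    return out
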