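"""Mining of treatment trajectories that end in a target therapy.

Trajectory steps are *episodes* — maximal runs of consecutive grid intervals
in the same state — not raw six-month cells, so a patient holding a TNF
inhibitor for two years contributes one step.  For every patient who ever
reaches the target state, the episode sequence up to and including the first
target episode is truncated to the last ``lookback`` pre-target steps and
identical sequences are counted; rare sequences below a count threshold are
pooled into a below-threshold bucket (the faint gray lines of the published
pathway figures).
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
import pandas as pd

from .states import BDMARD_STATES, TreatmentState

GRID_STEP = 6

#: Category label for target episodes with no preceding episode.
FIRST_RECORDED = "none (first recorded)"


@dataclasses.dataclass
class Episode:
    state: TreatmentState
    start_month: int
    duration_months: int


@dataclasses.dataclass
class EpisodeSequence:
    patient_id: object
    episodes: list[Episode]

    def states(self) -> tuple[str, ...]:
        return tuple(e.state.value for e in self.episodes)


@dataclasses.dataclass
class TrajectoryCatalog:
    """Counted pre-target sequences ending in the target state.

    ``sequences`` maps a tuple of state names (ending in the target) to its
    patient count, keeping only sequences with count >= ``min_count``;
    ``below_threshold`` is the pooled patient count of the rarer sequences.
    ``n_reachers`` = sum of counts + bucket (conservation).
    """

    target: TreatmentState
    sequences: dict[tuple[str, ...], int]
    below_threshold: int
    n_reachers: int
    lookback: int
    min_count: int

    def shares(self) -> dict[tuple[str, ...], float]:
        if self.n_reachers == 0:
            return {}
        return {k: v / self.n_reachers for k, v in self.sequences.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sequence": ">".join(k), "count": v, "share": v / self.n_reachers}
            for k, v in sorted(self.sequences.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        if self.below_threshold:
            rows.append(
                {
                    "sequence": f"<other, fewer than {self.min_count} occurrences>",
                    "count": self.below_threshold,
                    "share": self.below_threshold / self.n_reachers,
                }
            )
        return pd.DataFrame(rows, columns=["sequence", "count", "share"])


@dataclasses.dataclass
class TimeToTargetSummary:
    """Months from the first biologic to first target use, among reachers."""

    n_reachers: int
    n_never: int
    median_months: float | None
    iqr_months: tuple[float, float] | None
    fraction_within_36: float | None
    prior_bdmard_counts: list[int]
    median_prior_bdmards: float | None
    range_prior_bdmards: tuple[int, int] | None


def midpoint_quantile(values, q: float) -> float:
    """Quantile by midpoint interpolation (mean of the two bracketing order
    statistics when the index falls between them)."""
    return float(np.percentile(np.asarray(values, float), 100 * q, method="midpoint"))


def collapse_episodes(grid_states: pd.Series | list, patient_id: object = None) -> EpisodeSequence:
    """Run-length collapse of one patient's grid states into episodes.

    Input is the state sequence at months 0, 6, ... (censored tail absent).
    """
    states = [TreatmentState(s) for s in list(grid_states)]
    episodes: list[Episode] = []
    for i, s in enumerate(states):
        if episodes and episodes[-1].state is s:
            episodes[-1].duration_months += GRID_STEP
        else:
            episodes.append(Episode(s, i * GRID_STEP, GRID_STEP))
    return EpisodeSequence(patient_id, episodes)


def episodes_from_grids(grids: pd.DataFrame) -> list[EpisodeSequence]:
    """Collapse a tidy grid frame (``build_state_grids`` output) per patient."""
    g = grids.sort_values(["patient_id", "grid_month"], kind="stable")
    return [
        collapse_episodes(chunk["state"], patient_id=pid)
        for pid, chunk in g.groupby("patient_id", sort=True)
    ]


def _pre_target(seq: EpisodeSequence, target: TreatmentState, lookback: int) -> tuple[str, ...] | None:
    """Sequence of <=lookback episodes before the first target episode, plus
    the target itself; None if the patient never reaches the target."""
    for i, ep in enumerate(seq.episodes):
        if ep.state is target:
            start = max(0, i - lookback)
            return tuple(e.state.value for e in seq.episodes[start : i + 1])
    return None


def mine_target_trajectories(
    episodes: list[EpisodeSequence],
    target: TreatmentState = TreatmentState.TCZ_MONO,
    lookback: int = 4,
    min_count: int = 4,
) -> TrajectoryCatalog:
    """Count collapsed trajectories ending in the first target episode.

    Lookback of 4 and a visibility threshold of 4 mirror the published
    pathway-figure conventions (the companion figure for TNFi monotherapy
    uses a threshold of 5).
    """
    if target not in TreatmentState:
        raise ValueError(f"target {target!r} not in state space")
    counter: Counter[tuple[str, ...]] = Counter()
    for seq in episodes:
        key = _pre_target(seq, target, lookback)
        if key is not None:
            counter[key] += 1
    kept = {k: c for k, c in counter.items() if c >= min_count}
    bucket = sum(c for k, c in counter.items() if c < min_count)
    return TrajectoryCatalog(
        target=target,
        sequences=kept,
        below_threshold=bucket,
        n_reachers=sum(counter.values()),
        lookback=lookback,
        min_count=min_count,
    )


def prior_state_distribution(
    episodes: list[EpisodeSequence], target: TreatmentState = TreatmentState.TCZ_MONO
) -> dict[str, float]:
    """Share of each immediately-preceding state among target reachers.

    Patients whose first episode is already the target fall into the
    ``"none (first recorded)"`` category.
    """
    counter: Counter[str] = Counter()
    for seq in episodes:
        for i, ep in enumerate(seq.episodes):
            if ep.state is target:
                counter[seq.episodes[i - 1].state.value if i > 0 else FIRST_RECORDED] += 1
                break
    total = sum(counter.values())
    return {k: v / total for k, v in counter.items()} if total else {}


def bdmard_preceded_share(shares: dict[str, float], target: TreatmentState) -> float:
    """Share of reachers arriving from a biologic state (incl. TCZ combo)."""
    bio = {s.value for s in BDMARD_STATES if s is not target}
    return sum(v for k, v in shares.items() if k in bio)


def count_bdmards_before(
    seq: EpisodeSequence, target: TreatmentState = TreatmentState.TCZ_MONO
) -> int | None:
    """Number of biologic-category episodes strictly between the first episode
    and the first target episode (repeat categories count as new episodes).

    None if the patient never reaches the target.
    """
    bio = {s for s in BDMARD_STATES if s is not target}
    for i, ep in enumerate(seq.episodes):
        if ep.state is target:
            return sum(1 for e in seq.episodes[1:i] if e.state in bio)
    return None


def time_to_target(
    grids: pd.DataFrame, target: TreatmentState = TreatmentState.TCZ_MONO
) -> TimeToTargetSummary:
    """Time from grid month 0 (first biologic) to first target grid month.

    Median and IQR use midpoint-interpolated quantiles; patients never
    observed in the target state are excluded from the statistics and
    reported as a count.  Appending post-target intervals leaves the summary
    unchanged.
    """
    hit = grids[grids["state"] == target.value]
    first = hit.groupby("patient_id")["grid_month"].min()
    n_patients = grids["patient_id"].nunique()
    times = first.to_numpy(float)
    if len(times) == 0:
        return TimeToTargetSummary(0, n_patients, None, None, None, [], None, None)

    episodes = episodes_from_grids(grids[grids["patient_id"].isin(first.index)])
    prior_counts = [c for c in (count_bdmards_before(s, target) for s in episodes) if c is not None]
    return TimeToTargetSummary(
        n_reachers=len(times),
        n_never=n_patients - len(times),
        median_months=midpoint_quantile(times, 0.5),
        iqr_months=(midpoint_quantile(times, 0.25), midpoint_quantile(times, 0.75)),
        fraction_within_36=float(np.mean(times <= 36)),
        prior_bdmard_counts=prior_counts,
        median_prior_bdmards=midpoint_quantile(prior_counts, 0.5) if prior_counts else None,
        range_prior_bdmards=(int(min(prior_counts)), int(max(prior_counts))) if prior_counts else None,
    )
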