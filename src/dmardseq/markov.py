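"""Per-interval state occupancy and Markov transition estimation.

Occupancy reproduces the registry-table convention: at each six-month grid
point, the count of uncensored patients in each treatment state and its
percentage of the at-risk denominator, printed with half-up rounding.  The
transition table counts moves between adjacent grid months and normalises
each row to a row-stochastic probability matrix, either pooled over all
intervals (time-homogeneous estimate) or kept per interval.
"""

from __future__ import annotations

import dataclasses
import decimal

import numpy as np
import pandas as pd

from .states import STATE_ORDER

GRID_STEP = 6


def format_pct(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage ``100*num/den`` rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches clinical-table typesetting.
    """
    if denominator == 0:
        raise ZeroDivisionError("format_pct denominator is zero")
    q = decimal.Decimal(1).scaleb(-decimals)
    val = decimal.Decimal(100) * decimal.Decimal(numerator) / decimal.Decimal(denominator)
    return float(val.quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclasses.dataclass
class OccupancyTable:
    """State occupancy per grid month.

    ``counts``: frame indexed by state (canonical order), one column per grid
    month, integer counts of uncensored patients.  ``n_at_risk``: series of
    denominators per month.  ``percentages``: counts as half-up-rounded
    percentages of the denominator.
    """

    counts: pd.DataFrame
    n_at_risk: pd.Series
    percentages: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """'count (pct)' strings in the published table layout."""
        out = self.counts.astype(str)
        for col in out.columns:
            out[col] = [
                f"{c} ({p:.2f})" for c, p in zip(self.counts[col], self.percentages[col])
            ]
        return out


@dataclasses.dataclass
class TransitionTable:
    """Counts and row-stochastic probabilities of six-state transitions.

    ``counts`` is a 6x6 integer frame (origin rows, destination columns).
    ``probabilities`` divides each row by its sum; rows with zero count are
    left as NaN and listed in ``undefined_rows`` rather than zero-filled.
    ``interval`` is None for the pooled table, else the start month of the
    (t, t+6) interval.
    """

    counts: pd.DataFrame
    probabilities: pd.DataFrame
    undefined_rows: list[str]
    interval: int | None = None
    n_pairs: int = 0


def occupancy(grids: pd.DataFrame, include_filled: bool = True) -> OccupancyTable:
    """State occupancy table from tidy grids (see ``build_state_grids``).

    ``include_filled=False`` restricts to directly observed cells, excluding
    LOCF-filled ones — the sensitivity variant in which the denominator is
    also reduced.
    """
    state_names = [s.value for s in STATE_ORDER]
    g = grids if include_filled else grids[~grids["filled"]]
    if len(g) == 0:
        empty = pd.DataFrame(0, index=state_names, columns=[]).astype(int)
        return OccupancyTable(empty, pd.Series(dtype=int), empty.astype(float))
    counts = (
        g.pivot_table(index="state", columns="grid_month", values="patient_id", aggfunc="count")
        .reindex(state_names)
        .fillna(0)
        .astype(int)
    )
    n_at_risk = counts.sum(axis=0)
    pct = counts.copy().astype(float)
    for col in counts.columns:
        denom = int(n_at_risk[col])
        pct[col] = [format_pct(int(c), denom) if denom else np.nan for c in counts[col]]
    return OccupancyTable(counts, n_at_risk, pct)


def _pairs(grids: pd.DataFrame) -> pd.DataFrame:
    """Adjacent (t, t+6) state pairs over uncensored cells."""
    g = grids.sort_values(["patient_id", "grid_month"], kind="stable")
    nxt = g.groupby("patient_id")[["grid_month", "state"]].shift(-1)
    ok = nxt["grid_month"] == g["grid_month"] + GRID_STEP
    return pd.DataFrame(
        {
            "interval": g.loc[ok, "grid_month"].astype(int),
            "origin": g.loc[ok, "state"],
            "destination": nxt.loc[ok, "state"],
        }
    )


def _count_matrix(pairs: pd.DataFrame) -> pd.DataFrame:
    state_names = [s.value for s in STATE_ORDER]
    mat = (
        pairs.pivot_table(index="origin", columns="destination", values="interval", aggfunc="count")
        .reindex(index=state_names, columns=state_names)
        .fillna(0)
        .astype(int)
    )
    return mat


def transition_counts(grids: pd.DataFrame, pooled: bool = True) -> TransitionTable | list[TransitionTable]:
    """Transition count (and probability) tables from tidy grids.

    ``pooled=True`` sums over all adjacent-interval pairs; ``pooled=False``
    returns one table per (t, t+6) interval, in time order.  Pooled counts
    equal the sum of the per-interval counts by construction.
    """
    pairs = _pairs(grids)
    if pooled:
        counts = _count_matrix(pairs)
        return transition_probabilities(counts, interval=None, n_pairs=len(pairs))
    out = []
    for t, chunk in pairs.groupby("interval", sort=True):
        counts = _count_matrix(chunk)
        out.append(transition_probabilities(counts, interval=int(t), n_pairs=len(chunk)))
    return out


def transition_probabilities(
    counts: pd.DataFrame, interval: int | None = None, n_pairs: int | None = None
) -> TransitionTable:
    """Row-normalise a 6x6 count matrix into a transition table.

    Zero-count origin rows are flagged undefined (NaN), never zero-filled.
    """
    counts = counts.astype(int)
    row_sums = counts.sum(axis=1)
    probs = counts.astype(float).div(row_sums.where(row_sums > 0), axis=0)
    undefined = list(counts.index[row_sums == 0])
    return TransitionTable(
        counts=counts,
        probabilities=probs,
        undefined_rows=undefined,
        interval=interval,
        n_pairs=int(row_sums.sum()) if n_pairs is None else n_pairs,
    )


def empirical_matrix(grids: pd.DataFrame) -> np.ndarray:
    """Pooled transition probabilities as a plain 6x6 array (NaN rows kept)."""
    table = transition_counts(grids, pooled=True)
    return table.probabilities.to_numpy(float)
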