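"""Trajectory mining: episode collapse, catalogs, time-to-target."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmardseq.mining import (
    FIRST_RECORDED,
    collapse_episodes,
    count_bdmards_before,
    episodes_from_grids,
    midpoint_quantile,
    mine_target_trajectories,
    prior_state_distribution,
    time_to_target,
)
from dmardseq.states import STATE_ORDER, TreatmentState
from test_markov import grids_from_sequences

T = TreatmentState


def seqs(*lists):
    return [collapse_episodes(l, patient_id=i) for i, l in enumerate(lists)]


class TestCollapse:
    def test_run_length_collapse_keeps_timing(self):
        seq = collapse_episodes(["TNFI", "TNFI", "TCZ_COMBO", "TCZ_MONO"])
        assert [(e.state, e.start_month, e.duration_months) for e in seq.episodes] == [
            (T.TNFI, 0, 12),
            (T.TCZ_COMBO, 12, 6),
            (T.TCZ_MONO, 18, 6),
        ]

    def test_constant_grid_single_episode(self):
        seq = collapse_episodes(["TNFI"] * 7)
        assert len(seq.episodes) == 1 and seq.episodes[0].duration_months == 42

    def test_empty_grid_empty_sequence(self):
        assert collapse_episodes([]).episodes == []

    def test_no_adjacent_episodes_share_state(self):
        rng = np.random.default_rng(0)
        states = [STATE_ORDER[i].value for i in rng.integers(0, 6, 50)]
        eps = collapse_episodes(states).episodes
        assert all(a.state is not b.state for a, b in zip(eps, eps[1:]))


class TestMine:
    def test_toy_catalog_with_bucket(self):
        episodes = seqs(
            ["TNFI", "TCZ_COMBO", "TCZ_MONO"],
            ["TNFI", "TCZ_COMBO", "TCZ_MONO"],
            ["TNFI", "TNFI", "TCZ_COMBO", "TCZ_MONO"],  # collapses to the same
            ["OTHER_BDMARD", "TCZ_MONO"],
            ["CSDMARD_ONLY", "TCZ_MONO"],
        )
        cat = mine_target_trajectories(episodes, T.TCZ_MONO, lookback=4, min_count=3)
        assert cat.sequences == {("TNFI", "TCZ_COMBO", "TCZ_MONO"): 3}
        assert cat.below_threshold == 2
        assert cat.n_reachers == 5
        assert cat.shares()[("TNFI", "TCZ_COMBO", "TCZ_MONO")] == pytest.approx(0.6)

    def test_no_reachers_empty_catalog(self):
        cat = mine_target_trajectories(seqs(["TNFI", "CSDMARD_ONLY"]), T.TCZ_MONO)
        assert cat.n_reachers == 0 and cat.sequences == {} and cat.below_threshold == 0

    def test_lookback_truncates_to_last_four(self):
        long = ["NO_DMARD", "CSDMARD_ONLY", "TNFI", "OTHER_BDMARD", "CSDMARD_ONLY", "TNFI", "TCZ_MONO"]
        cat = mine_target_trajectories(seqs(long), T.TCZ_MONO, lookback=4, min_count=1)
        (key,) = cat.sequences
        assert key == ("TNFI", "OTHER_BDMARD", "CSDMARD_ONLY", "TNFI", "TCZ_MONO")

    def test_first_target_episode_only(self):
        episodes = seqs(["TNFI", "TCZ_MONO", "TNFI", "TCZ_MONO"])
        cat = mine_target_trajectories(episodes, T.TCZ_MONO, min_count=1)
        (key,) = cat.sequences
        assert key == ("TNFI", "TCZ_MONO")


def brute_force_catalog(state_lists, target, lookback, min_count):
    """Independent enumerator: collapse by itertools.groupby, slice, count."""
    counts = {}
    for states in state_lists:
        eps = [k for k, _ in itertools.groupby(states)]
        if target.value not in eps:
            continue
        i = eps.index(target.value)
        key = tuple(eps[max(0, i - lookback) : i + 1])
        counts[key] = counts.get(key, 0) + 1
    kept = {k: v for k, v in counts.items() if v >= min_count}
    bucket = sum(v for v in counts.values() if v < min_count)
    return kept, bucket, sum(counts.values())


@settings(max_examples=250, deadline=None, derandomize=True)
@given(
    panels=st.lists(
        st.lists(st.sampled_from([s.value for s in STATE_ORDER]), min_size=1, max_size=11),
        min_size=1,
        max_size=12,
    ),
    lookback=st.integers(1, 5),
    min_count=st.integers(1, 4),
)
def test_mining_matches_brute_force_enumeration(panels, lookback, min_count):
    """On random panels of <=12 patients x <=11 intervals the miner agrees
    with an exhaustive groupby-based enumerator, including the bucket."""
    episodes = [collapse_episodes(p, patient_id=i) for i, p in enumerate(panels)]
    cat = mine_target_trajectories(episodes, T.TCZ_MONO, lookback, min_count)
    kept, bucket, total = brute_force_catalog(panels, T.TCZ_MONO, lookback, min_count)
    assert cat.sequences == kept
    assert cat.below_threshold == bucket
    assert cat.n_reachers == total
    # conservation: kept counts + bucket = number of reachers
    assert sum(cat.sequences.values()) + cat.below_threshold == cat.n_reachers


class TestPriorState:
    def test_hand_counted_shares(self):
        episodes = seqs(
            ["TCZ_COMBO", "TCZ_MONO"],
            ["TNFI", "TCZ_MONO"],
            ["TNFI", "TCZ_MONO"],
            ["TCZ_MONO"],
        )
        shares = prior_state_distribution(episodes, T.TCZ_MONO)
        assert shares == {"TCZ_COMBO": 0.25, "TNFI": 0.5, FIRST_RECORDED: 0.25}

    def test_all_first_episode(self):
        shares = prior_state_distribution(seqs(["TCZ_MONO"], ["TCZ_MONO", "TNFI"]), T.TCZ_MONO)
        assert shares == {FIRST_RECORDED: 1.0}


class TestCountBdmards:
    @pytest.mark.parametrize(
        "states, expected",
        [
            # only the second TNFI episode lies strictly between the first
            # episode and the target; the csDMARD episode is not a biologic
            (["TNFI", "CSDMARD_ONLY", "TNFI", "TCZ_MONO"], 1),
            (["TNFI", "TCZ_MONO"], 0),
            (["TNFI", "OTHER_BDMARD", "TCZ_COMBO", "TCZ_MONO"], 2),
            (["CSDMARD_ONLY", "TNFI", "TCZ_MONO"], 1),
            (["TNFI", "NO_DMARD", "TCZ_MONO"], 0),
        ],
    )
    def test_intervening_biologic_episodes(self, states, expected):
        assert count_bdmards_before(collapse_episodes(states), T.TCZ_MONO) == expected

    def test_never_reaches_target(self):
        assert count_bdmards_before(collapse_episodes(["TNFI"]), T.TCZ_MONO) is None


class TestTimeToTarget:
    def test_hand_quantiles(self):
        g = grids_from_sequences(
            {
                1: ["TNFI", "TNFI", "TCZ_MONO"],  # 12 months
                2: ["TNFI"] * 4 + ["TCZ_MONO"],  # 24
                3: ["TNFI"] * 6 + ["TCZ_MONO"],  # 36
                4: ["TNFI", "TNFI"],  # never
            }
        )
        s = time_to_target(g, T.TCZ_MONO)
        assert s.n_reachers == 3 and s.n_never == 1
        assert s.median_months == 24 and s.iqr_months == (18, 30)
        assert s.fraction_within_36 == 1.0

    def test_target_at_month_zero(self):
        s = time_to_target(grids_from_sequences({1: ["TCZ_MONO"]}), T.TCZ_MONO)
        assert s.median_months == 0

    def test_no_reachers_flagged_undefined(self):
        s = time_to_target(grids_from_sequences({1: ["TNFI"]}), T.TCZ_MONO)
        assert s.n_reachers == 0 and s.median_months is None and s.iqr_months is None

    def test_invariant_to_appending_post_target_intervals(self):
        base = {1: ["TNFI", "TCZ_MONO"], 2: ["TNFI", "TNFI", "TCZ_MONO"]}
        extended = {k: v + ["CSDMARD_ONLY", "TNFI"] for k, v in base.items()}
        a = time_to_target(grids_from_sequences(base), T.TCZ_MONO)
        b = time_to_target(grids_from_sequences(extended), T.TCZ_MONO)
        assert (a.median_months, a.iqr_months, a.fraction_within_36) == (
            b.median_months,
            b.iqr_months,
            b.fraction_within_36,
        )

    def test_fraction_within_36_is_empirical_cdf(self):
        g = grids_from_sequences(
            {i: ["TNFI"] * k + ["TCZ_MONO"] for i, k in enumerate([1, 3, 5, 6, 7, 10])}
        )
        s = time_to_target(g, T.TCZ_MONO)
        times = np.array([6, 18, 30, 36, 42, 60])
        assert s.fraction_within_36 == pytest.approx(np.mean(times <= 36))


def test_midpoint_quantile_convention():
    assert midpoint_quantile([50, 54, 58, 62], 0.5) == 56
    assert midpoint_quantile([50, 54, 58, 62], 0.25) == 52
    assert midpoint_quantile([50, 54, 58, 62], 0.75) == 60
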