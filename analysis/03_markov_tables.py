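"""Estimate state occupancy per six-month interval and the Markov
transition matrices (pooled and per interval).

Writes the occupancy table in the count-(percent) layout, the pooled
row-stochastic matrix, and one matrix per interval; prints the pooled
matrix and where the target therapy's inflow comes from.
"""

from pathlib import Path

import pandas as pd

from dmardseq.markov import occupancy, transition_counts

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    grids = pd.read_csv(OUT / "state_grids.csv")
    occ = occupancy(grids)
    occ.formatted().to_csv(OUT / "occupancy.csv")
    occ_strict = occupancy(grids, include_filled=False)
    occ_strict.formatted().to_csv(OUT / "occupancy_observed_only.csv")

    pooled = transition_counts(grids, pooled=True)
    pooled.probabilities.round(4).to_csv(OUT / "transitions_pooled.csv")
    for tbl in transition_counts(grids, pooled=False):
        tbl.probabilities.round(4).to_csv(OUT / f"transitions_{tbl.interval:02d}.csv")

    print(f"pooled transition matrix ({pooled.n_pairs} person-intervals):")
    print(pooled.probabilities.round(3).to_string())
    inflow = pooled.counts["TCZ_MONO"].drop("TCZ_MONO")
    print("\ninflow to TCZ monotherapy by origin state:")
    print(inflow.to_string())


if __name__ == "__main__":
    main()
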