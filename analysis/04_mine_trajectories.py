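"""Mine treatment trajectories ending in the target therapies.

For tocilizumab monotherapy (threshold 4) and, for comparison, TNFi
monotherapy-style paths (threshold 5): counted sequences looking back at
most 4 episodes, pathway figures, time-to-target summaries and the
distribution of immediately-preceding states.
"""

import json
from pathlib import Path

import pandas as pd

from dmardseq.mining import (
    bdmard_preceded_share,
    episodes_from_grids,
    mine_target_trajectories,
    prior_state_distribution,
    time_to_target,
)
from dmardseq.reporting import render_trajectory_plot
from dmardseq.states import TreatmentState

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    grids = pd.read_csv(OUT / "state_grids.csv")
    episodes = episodes_from_grids(grids)

    for target, min_count in ((TreatmentState.TCZ_MONO, 4), (TreatmentState.TNFI, 5)):
        tag = target.value.lower()
        catalog = mine_target_trajectories(episodes, target, lookback=4, min_count=min_count)
        catalog.to_frame().to_csv(OUT / f"trajectories_{tag}.csv", index=False)
        render_trajectory_plot(catalog, str(OUT / f"trajectories_{tag}.svg"))
        ttt = time_to_target(grids, target)
        shares = prior_state_distribution(episodes, target)
        summary = {
            "target": target.value,
            "n_reachers": ttt.n_reachers,
            "median_months": ttt.median_months,
            "iqr_months": ttt.iqr_months,
            "fraction_within_36": ttt.fraction_within_36,
            "median_prior_bdmards": ttt.median_prior_bdmards,
            "range_prior_bdmards": ttt.range_prior_bdmards,
            "prior_state_shares": shares,
            "bdmard_preceded_share": bdmard_preceded_share(shares, target),
        }
        (OUT / f"summary_{tag}.json").write_text(json.dumps(summary, indent=2))
        print(f"--- {target.value} ---")
        print(f"reachers: {ttt.n_reachers}; median {ttt.median_months} months (IQR {ttt.iqr_months})")
        print(f"within 36 months: {100 * ttt.fraction_within_36:.1f}%")
        print(f"preceded by a biologic state: {100 * bdmard_preceded_share(shares, target):.1f}%")
        print(catalog.to_frame().head(8).to_string(index=False))


if __name__ == "__main__":
    main()
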