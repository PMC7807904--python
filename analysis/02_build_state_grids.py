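"""Classify visits into the six treatment states and discretize onto the
six-month grid anchored at the first-biologic baseline.

Reads the registry written by 01, writes state_grids.csv, and prints the
declining at-risk denominators (censoring audit).
"""

from pathlib import Path

import pandas as pd

from dmardseq.grids import build_state_grids, carry_forward_covariates

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    visits = pd.read_csv(OUT / "visits.csv")
    grids = build_state_grids(carry_forward_covariates(visits))
    grids.to_csv(OUT / "state_grids.csv", index=False)

    denom = grids.groupby("grid_month")["patient_id"].count()
    print(f"{grids['patient_id'].nunique()} patients gridded, {len(grids)} cells")
    print("at risk by month:", dict(denom))
    print(f"LOCF-filled cells: {int(grids['filled'].sum())}")
    print(f"prevalent initiators: {int(grids.drop_duplicates('patient_id')['prevalent'].sum())}")


if __name__ == "__main__":
    main()
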