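"""Predictor models of target-therapy use.

Univariable screen (p < 0.2) over baseline candidates, a baseline-only
multivariable logistic model of ever reaching the target, the longitudinal
person-interval model with patient-clustered sandwich covariance, and the
fits stratified on prior TCZ-combination use.
"""

from pathlib import Path

import pandas as pd

from dmardseq.models import ModelSpec, build_panel, fit_logistic, fit_longitudinal, stratified_fit, univariable_screen
from dmardseq.pipeline import BASELINE_CANDIDATES, LONGITUDINAL_CANDIDATES, _baseline_table
from dmardseq.states import TreatmentState

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def show(name: str, fit) -> None:
    print(f"--- {name} (n={fit.n_obs}, clusters={fit.n_clusters}, dropped={fit.dropped}) ---")
    print(fit.odds_ratios().round(3).to_string(index=False))


def main() -> None:
    patients = pd.read_csv(OUT / "patients.csv")
    grids = pd.read_csv(OUT / "state_grids.csv")

    baseline = _baseline_table(patients, grids, TreatmentState.TCZ_MONO)
    selected = univariable_screen(baseline, "outcome", BASELINE_CANDIDATES)
    print("baseline covariates advanced by the p<0.2 screen:", selected)
    fit_base = fit_logistic(baseline, "outcome", selected)
    fit_base.table.to_csv(OUT / "model_baseline.csv", index=False)
    show("baseline-only logistic", fit_base)

    panel = build_panel(grids, patients, ModelSpec(outcome="tcz_mono", time_updated=True))
    selected_l = univariable_screen(panel, "outcome", LONGITUDINAL_CANDIDATES)
    print("\nlongitudinal covariates advanced:", selected_l)
    fit_long = fit_longitudinal(panel, "outcome", selected_l)
    fit_long.table.to_csv(OUT / "model_longitudinal.csv", index=False)
    show("longitudinal (cluster-robust)", fit_long)

    for name, fit in stratified_fit(panel, "outcome", selected_l).items():
        if fit is None:
            print(f"stratum {name}: skipped")
            continue
        fit.table.to_csv(OUT / f"model_{name.replace('=', '_')}.csv", index=False)
        show(f"stratum {name}", fit)


if __name__ == "__main__":
    main()
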