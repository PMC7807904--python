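"""Cohort summary tables and trajectory figures.

The cohort table follows clinical-table convention: median (IQR) for
continuous variables and n (%) for categorical ones, in three columns — all
biologic initiators, patients ever on the target drug in any form, and
patients reaching the target monotherapy — with percentages over stated
denominators (seropositivity over non-missing serostatus only).

The trajectory figure draws one polyline per mined sequence, one marker per
episode, line width linear in patient count, and pools rare sequences into
faint gray lines, mirroring the published pathway plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .markov import format_pct
from .mining import TrajectoryCatalog, midpoint_quantile
from .states import STATE_ORDER, TreatmentState

CONTINUOUS_VARS = [
    ("age_years", "Age, median (IQR), years"),
    ("disease_duration_years", "Disease duration, median (IQR), years"),
    ("cdai_baseline", "CDAI, median (IQR)"),
    ("haq_baseline", "HAQ, median (IQR)"),
]
BINARY_VARS = [
    ("female", "Female, n (%)"),
    ("seropositive", "Seropositive, n (%)"),
    ("csdmard_baseline", "Conventional DMARD use, n (%)"),
    ("glucocorticoid_baseline", "Glucocorticoid use, any, n (%)"),
    ("erosion_flag", "Erosions, n (%)"),
]


def _summarise(chunk: pd.DataFrame) -> dict[str, str]:
    n = len(chunk)
    out = {"N": str(n)}
    if n == 0:
        return out
    work = chunk.copy()
    work["female"] = (work["sex"] == "female").astype(int)
    for col, label in CONTINUOUS_VARS:
        if col not in work:
            continue
        vals = work[col].dropna()
        med = midpoint_quantile(vals, 0.5)
        lo, hi = midpoint_quantile(vals, 0.25), midpoint_quantile(vals, 0.75)
        out[label] = f"{med:g} ({lo:g}, {hi:g})"
    for col, label in BINARY_VARS:
        if col == "seropositive":
            known = work[work["serostatus"] != "missing"]
            k = int((known["serostatus"] == "positive").sum())
            d = len(known)
            out[label] = f"{k} ({format_pct(k, d):.2f})" if d else "0 (-)"
            continue
        if col not in work:
            continue
        k = int(work[col].sum())
        out[label] = f"{k} ({format_pct(k, n):.2f})"
    como = [c for c in work.columns if c.startswith("como_")]
    for c in como:
        k = int(work[c].sum())
        out[f"Comorbidity: {c[5:]}, n (%)"] = f"{k} ({format_pct(k, n):.2f})"
    return out


def cohort_table(
    patients: pd.DataFrame,
    grids: pd.DataFrame,
    target: TreatmentState = TreatmentState.TCZ_MONO,
) -> pd.DataFrame:
    """Three-column baseline characteristics table.

    Columns: all initiators (everyone with a grid), ever on the target drug
    in mono or combination form, and target-monotherapy reachers.
    Seropositivity percentages use the non-missing denominator.
    """
    in_cohort = patients["patient_id"].isin(grids["patient_id"].unique())
    cohort = patients[in_cohort]
    tcz_states = {TreatmentState.TCZ_MONO.value, TreatmentState.TCZ_COMBO.value}
    any_tcz_ids = grids.loc[grids["state"].isin(tcz_states), "patient_id"].unique()
    target_ids = grids.loc[grids["state"] == target.value, "patient_id"].unique()
    cols = {
        "Biologic DMARD, any": cohort,
        "TCZ, any": cohort[cohort["patient_id"].isin(any_tcz_ids)],
        "Target monotherapy": cohort[cohort["patient_id"].isin(target_ids)],
    }
    table = pd.DataFrame({name: pd.Series(_summarise(chunk)) for name, chunk in cols.items()})
    return table


# Display labels for figure legends (clinical shorthand).
PLOT_LABELS = {
    "TCZ_MONO": "TCZm",
    "TCZ_COMBO": "TCZ combo",
    "TNFI": "TNFi",
    "OTHER_BDMARD": "Other bDMARD",
    "CSDMARD_ONLY": "Nonbiologics",
    "NO_DMARD": "No DMARD",
}


def render_trajectory_plot(
    catalog: TrajectoryCatalog,
    path: str,
    max_width: float = 12.0,
    below_threshold_sequences: list[tuple[str, ...]] | None = None,
) -> None:
    """Draw the pathway figure: one line per sequence, ending in the target.

    X axis: step index ending at the target episode; Y axis: treatment state.
    Width is linear in patient count (capped at ``max_width`` points); one
    marker per episode; sequences ordered by count descending then
    lexicographically so the layout is deterministic.  Below-threshold
    sequences render as faint gray lines of minimal width.
    """
    seqs = sorted(catalog.sequences.items(), key=lambda kv: (-kv[1], kv[0]))
    max_count = max((c for _, c in seqs), default=1)
    fig, ax = plt.subplots(figsize=(9, 5))
    y_of = {s.value: len(STATE_ORDER) - 1 - i for i, s in enumerate(STATE_ORDER)}
    cmap = plt.get_cmap("tab10")
    for gi, gray_seq in enumerate(below_threshold_sequences or []):
        x = np.arange(-len(gray_seq) + 1, 1)
        ax.plot(x, [y_of[s] for s in gray_seq], color="0.75", lw=0.8, alpha=0.6, zorder=1)
    for i, (seq, count) in enumerate(seqs):
        x = np.arange(-len(seq) + 1, 1)
        width = max(0.8, max_width * count / max_count)
        label = " -> ".join(PLOT_LABELS.get(s, s) for s in seq) + f"  (n={count})"
        ax.plot(
            x,
            [y_of[s] for s in seq],
            lw=width,
            marker="o",
            markersize=max(4.0, width * 0.7),
            color=cmap(i % 10),
            label=label,
            alpha=0.85,
            zorder=2,
        )
    ax.set_yticks([y_of[s.value] for s in STATE_ORDER])
    ax.set_yticklabels([PLOT_LABELS[s.value] for s in STATE_ORDER])
    ax.set_xlabel("Episode step (0 = first target episode)")
    ax.set_title(f"Treatment sequences ending in {PLOT_LABELS.get(catalog.target.value, catalog.target.value)}")
    if seqs:
        ax.legend(fontsize=7, loc="upper left", framealpha=0.8)
    fig.tight_layout()
    if str(path).endswith(".svg"):
        # stable ids and no timestamp so reruns are byte-identical
        with matplotlib.rc_context({"svg.hashsalt": "dmardseq"}):
            fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path)
    plt.close(fig)
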