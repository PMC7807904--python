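"""Predictor modelling of target-therapy use.

The model-building procedure mirrors common registry practice: a univariable
logistic screen advances candidate covariates with Wald p < 0.2 into the
multivariable model; a baseline-only logistic model uses covariates fixed at
the first-biologic baseline; and a longitudinal model pools person-interval
rows (predictors measured at month t, outcome = treatment state at t+6) in a
marginal logistic regression whose standard errors are made robust to
within-patient correlation with a cluster (sandwich) covariance on patient.
Covariates that prevent convergence (complete separation) are withheld from
the model and recorded, rather than reported with runaway estimates.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import AGE_CENTER, DURATION_CENTER, COMORBIDITY_COLUMNS
from .states import TreatmentState

GRID_STEP = 6

#: CDAI disease-activity categories (upper bounds, inclusive).
CDAI_BINS = [(-np.inf, 2.8, "remission"), (2.8, 10.0, "low"), (10.0, 22.0, "moderate"), (22.0, np.inf, "high")]


def cdai_category(cdai: pd.Series | np.ndarray) -> pd.Series:
    """Categorise CDAI: remission <2.8, low 2.9-10.0, moderate 10.1-22.0, high >22.1."""
    x = pd.Series(np.asarray(cdai, float))
    out = pd.Series(pd.NA, index=x.index, dtype="object")
    for lo, hi, name in CDAI_BINS:
        out[(x > lo) & (x <= hi)] = name
    return out


@dataclasses.dataclass
class ModelSpec:
    """What to fit: outcome, candidate covariates, screen threshold, stratum."""

    outcome: str = "tcz_mono"  # "tcz_mono" or "tcz_any"
    screen_threshold: float = 0.2
    time_updated: bool = False
    stratum: str | None = None  # None | "no_prior_tczc" | "ever_prior_tczc"
    #: model initiation: person-intervals where the patient already occupies
    #: an outcome state are not at risk and are excluded from the panel
    incident_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.screen_threshold < 1:
            raise ValueError("screen_threshold must lie in (0, 1)")
        if self.outcome not in ("tcz_mono", "tcz_any"):
            raise ValueError("outcome must be 'tcz_mono' or 'tcz_any'")


@dataclasses.dataclass
class ModelFit:
    """Coefficients, odds ratios and inference for one fitted model."""

    table: pd.DataFrame  # term, coef, or_, ci_low, ci_high, se, p
    converged: bool
    n_obs: int
    n_clusters: int | None
    cov_type: str
    dropped: list[str] = dataclasses.field(default_factory=list)

    def odds_ratios(self) -> pd.DataFrame:
        return self.table[["term", "or_", "ci_low", "ci_high", "p"]]

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])


def _outcome_states(outcome: str) -> set[str]:
    if outcome == "tcz_any":
        return {TreatmentState.TCZ_MONO.value, TreatmentState.TCZ_COMBO.value}
    return {TreatmentState.TCZ_MONO.value}


def build_panel(
    grids: pd.DataFrame,
    patients: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Person-interval panel: predictors at month t, outcome at month t+6.

    One row per uncensored adjacent grid pair.  Time-updated covariates are
    the current state (dummies vs the TNFi reference), ever-use indicators of
    each biologic category up to and including t, and carried CDAI/HAQ at t;
    baseline covariates repeat on every row.  The strict lag prevents
    outcome-predictor circularity.  With ``spec.incident_only`` (the default)
    rows whose current state is already an outcome state are excluded: the
    model predicts initiation among those at risk of initiating.
    """
    spec = spec or ModelSpec()
    g = grids.sort_values(["patient_id", "grid_month"], kind="stable").copy()
    nxt = g.groupby("patient_id")[["grid_month", "state"]].shift(-1)
    ok = nxt["grid_month"] == g["grid_month"] + GRID_STEP
    out_states = _outcome_states(spec.outcome)

    panel = g.loc[ok, ["patient_id", "grid_month", "state", "cdai", "haq"]].copy()
    panel["outcome"] = nxt.loc[ok, "state"].isin(out_states).astype(int)

    # ever-use flags up to and including t (cumulative within patient)
    for s in (TreatmentState.TCZ_COMBO, TreatmentState.TNFI, TreatmentState.OTHER_BDMARD):
        col = f"ever_{s.value.lower()}"
        g[col] = (g["state"] == s.value).astype(int)
        g[col] = g.groupby("patient_id")[col].cummax()
        panel[col] = g.loc[ok, col]
    panel = panel.rename(columns={"ever_tcz_combo": "ever_tcz_combo"})

    # carried scores at t and CDAI category
    panel["cdai"] = panel.groupby("patient_id")["cdai"].ffill()
    panel["haq"] = panel.groupby("patient_id")["haq"].ffill()
    panel["cdai_cat"] = cdai_category(panel["cdai"])

    base = patients.set_index("patient_id")
    panel = panel.join(base, on="patient_id")
    panel["age_c"] = panel["age_years"] - AGE_CENTER
    panel["duration_c"] = panel["disease_duration_years"] - DURATION_CENTER
    panel["male"] = (panel["sex"] == "male").astype(int)
    como = [c for c in COMORBIDITY_COLUMNS if c in panel.columns]
    if como:
        panel["comorbidity_count"] = panel[como].sum(axis=1)
    if spec.incident_only:
        panel = panel[~panel["state"].isin(out_states)]
    if panel["outcome"].sum() == 0:
        warnings.warn("outcome state never observed in panel", stacklevel=2)
    return panel.reset_index(drop=True)


def _design(
    table: pd.DataFrame, covariates: list[str], exclude_terms: set[str] = frozenset()
) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix with intercept; categoricals expanded to dummies.

    Reference levels follow the published tables: serostatus reference =
    negative, CDAI reference = the severe (high) category, treatment-state
    reference = TNFi; other categoricals drop their first level.
    """
    refs = {"serostatus": "negative", "cdai_cat": "high", "state": TreatmentState.TNFI.value}
    cols = {}
    for cov in covariates:
        s = table[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = [l for l in pd.unique(s.dropna()) if l is not None]
            ref = refs.get(cov)
            if ref in levels:
                levels = [ref] + sorted(l for l in levels if l != ref)
            else:
                levels = sorted(map(str, levels))
            for level in levels[1:]:
                term = f"{cov}[{level}]"
                if term not in exclude_terms:
                    cols[term] = (s.astype(str) == str(level)).astype(float)
        else:
            if cov not in exclude_terms:
                cols[cov] = s.astype(float)
    X = pd.DataFrame(cols, index=table.index)
    X.insert(0, "const", 1.0)
    return X, list(X.columns)


def _wald_table(params, bse, names) -> pd.DataFrame:
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    ci_low = params - 1.959963984540054 * bse
    ci_high = params + 1.959963984540054 * bse
    return pd.DataFrame(
        {
            "term": names,
            "coef": params,
            "se": bse,
            "or_": np.exp(params),
            "ci_low": np.exp(ci_low),
            "ci_high": np.exp(ci_high),
            "p": p,
        }
    )


def _fit_once(y, X, cov_type="nonrobust", groups=None, maxiter=100):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cov_type == "cluster":
            res = model.fit(maxiter=maxiter, cov_type="cluster", cov_kwds={"groups": groups})
        elif cov_type == "HC0":
            res = model.fit(maxiter=maxiter, cov_type="HC0")
        else:
            res = model.fit(maxiter=maxiter)
    return res


def _separated_terms(res, X) -> list[str]:
    """Terms with runaway estimates or exploded SEs (complete separation)."""
    bad = (np.abs(res.params) > 15) | ~np.isfinite(res.bse) | (res.bse > 1e3)
    return [t for t, b in zip(X.columns, bad) if b and t != "const"]


def fit_logistic(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    cov_type: str = "nonrobust",
    groups: str | None = None,
) -> ModelFit:
    """Maximum-likelihood logistic fit with Wald 95% intervals.

    Complete-separation covariates are withheld from the model and listed in
    ``ModelFit.dropped``.  ``cov_type='cluster'`` with ``groups`` gives the
    cluster-robust sandwich covariance of the longitudinal model.
    """
    data = table.dropna(subset=[outcome] + covariates + ([groups] if groups else []))
    y = data[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome must have both levels")
    dropped: list[str] = []
    withheld: set[str] = set()
    covs = list(covariates)
    for _ in range(2 * len(covs) + 6):
        X, names = _design(data, covs, withheld)
        g = data[groups] if groups else None
        res = _fit_once(y, X, cov_type=cov_type, groups=g)
        bad_terms = _separated_terms(res, X)
        if not bad_terms:
            break
        # a degenerate fit can inflate innocent terms too: withhold only the
        # worst offender, then refit.  A separated factor level folds into
        # the reference; a numeric covariate is removed outright.
        magnitudes = dict(zip(X.columns, np.abs(np.asarray(res.params))))
        worst = max(bad_terms, key=lambda t: magnitudes[t])
        dropped.append(worst)
        if "[" in worst:
            withheld.add(worst)
        else:
            covs = [c for c in covs if c != worst]
    tab = _wald_table(np.asarray(res.params), np.asarray(res.bse), names)
    return ModelFit(
        table=tab,
        converged=bool(getattr(res, "converged", True)),
        n_obs=int(len(data)),
        n_clusters=int(data[groups].nunique()) if groups else None,
        cov_type=cov_type,
        dropped=dropped,
    )


def univariable_screen(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    threshold: float = 0.2,
) -> list[str]:
    """Advance covariates whose one-at-a-time logistic Wald p < threshold.

    Multi-level factors are advanced if any non-reference level passes.
    Degenerate (constant) covariates are excluded with a warning.
    """
    selected = []
    for cov in candidates:
        sub = table.dropna(subset=[outcome, cov])
        if sub[cov].nunique() < 2:
            warnings.warn(f"covariate {cov!r} is constant; excluded from screen", stacklevel=2)
            continue
        fit = fit_logistic(sub, outcome, [cov])
        terms = fit.table[fit.table["term"] != "const"]
        if any(d == cov or d.startswith(f"{cov}[") for d in fit.dropped):
            # separation means extreme association; advance it
            selected.append(cov)
        elif len(terms) and (terms["p"] < threshold).any():
            selected.append(cov)
    return selected


def fit_longitudinal(
    panel: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    cluster: str = "patient_id",
) -> ModelFit:
    """Pooled person-interval logistic fit with patient-clustered sandwich SEs.

    Point estimates are identical to :func:`fit_logistic` on the stacked
    rows; only the covariance accounts for within-person correlation.
    """
    n_clusters = panel.dropna(subset=covariates + [outcome])[cluster].nunique()
    if n_clusters < 2:
        raise ValueError("cluster-robust covariance needs at least two clusters")
    return fit_logistic(panel, outcome, covariates, cov_type="cluster", groups=cluster)


def stratified_fit(
    panel: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    stratum_col: str = "ever_tcz_combo",
) -> dict[str, ModelFit | None]:
    """Independent longitudinal fits per stratum of ``stratum_col``.

    Strata with no rows, a single cluster or a one-level outcome are skipped
    (entry None) with a warning.  Row counts across strata partition the
    panel.
    """
    out: dict[str, ModelFit | None] = {}
    for value, chunk in panel.groupby(stratum_col, sort=True):
        label = f"{stratum_col}={value}"
        covs = [c for c in covariates if c != stratum_col]
        try:
            out[label] = fit_longitudinal(chunk, outcome, covs)
        except ValueError as exc:
            warnings.warn(f"stratum {label} skipped: {exc}", stacklevel=2)
            out[label] = None
    return out
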