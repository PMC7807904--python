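"""Predictor models: screen, logistic fits, cluster-robust covariance."""

import math

import numpy as np
import pandas as pd
import pytest

from dmardseq.models import (
    ModelSpec,
    build_panel,
    cdai_category,
    fit_logistic,
    fit_longitudinal,
    stratified_fit,
    univariable_screen,
)
from dmardseq.simulate import SimConfig, generate_registry
from dmardseq.grids import build_state_grids, carry_forward_covariates


def two_by_two(a, b, c, d):
    """Table with a exposed cases, b exposed controls, c unexposed cases,
    d unexposed controls."""
    return pd.DataFrame(
        {
            "outcome": [1] * a + [0] * b + [1] * c + [0] * d,
            "x": [1] * (a + b) + [0] * (c + d),
        }
    )


class TestFitLogistic:
    def test_two_by_two_reproduces_closed_form_odds_ratio(self):
        # exposed 10/20, unexposed 5/25 -> OR = (10*25)/(20*5) = 2.5
        fit = fit_logistic(two_by_two(10, 20, 5, 25), "outcome", ["x"])
        assert fit.table.set_index("term").loc["x", "or_"] == pytest.approx(2.5, abs=1e-6)

    def test_null_covariate_or_near_one_ci_covers(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"outcome": rng.integers(0, 2, 4000), "x": rng.integers(0, 2, 4000)})
        fit = fit_logistic(df, "outcome", ["x"])
        row = fit.table.set_index("term").loc["x"]
        assert row["ci_low"] < 1 < row["ci_high"]
        assert row["or_"] == pytest.approx(1.0, abs=0.2)

    def test_known_age_coefficient_recovered_within_two_se(self):
        """Baseline table with logit P = -3 + 0.05*age_c recovers beta."""
        rng = np.random.default_rng(1)
        n = 5000
        age_c = rng.normal(0, 12, n)
        p = 1 / (1 + np.exp(-(-3 + 0.05 * age_c)))
        df = pd.DataFrame({"outcome": (rng.random(n) < p).astype(int), "age_c": age_c})
        fit = fit_logistic(df, "outcome", ["age_c"])
        assert abs(fit.coef("age_c") - 0.05) < 2 * fit.se("age_c")

    def test_one_level_outcome_rejected(self):
        df = pd.DataFrame({"outcome": [1, 1, 1], "x": [0, 1, 0]})
        with pytest.raises(ValueError, match="both levels"):
            fit_logistic(df, "outcome", ["x"])

    def test_complete_separation_drops_covariate_and_records_it(self):
        rng = np.random.default_rng(2)
        n = 200
        sep = rng.integers(0, 2, n)
        noise = rng.integers(0, 2, n)
        df = pd.DataFrame({"outcome": sep, "sep": sep, "x": noise})
        fit = fit_logistic(df, "outcome", ["sep", "x"])
        assert "sep" in fit.dropped
        assert "x" in list(fit.table["term"])

    def test_or_equals_exp_coef_and_ci_ordered(self):
        fit = fit_logistic(two_by_two(10, 20, 5, 25), "outcome", ["x"])
        t = fit.table
        np.testing.assert_allclose(t["or_"], np.exp(t["coef"]))
        assert (t["ci_low"] <= t["or_"]).all() and (t["or_"] <= t["ci_high"]).all()


class TestScreen:
    def test_strong_association_advanced(self):
        # 40/10 vs 10/40: chi-square p is astronomically small -> advanced
        assert univariable_screen(two_by_two(40, 10, 10, 40), "outcome", ["x"]) == ["x"]

    def test_constant_covariate_excluded_with_warning(self):
        df = two_by_two(10, 10, 10, 10)
        df["c"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            out = univariable_screen(df, "outcome", ["c"])
        assert out == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "outcome": rng.integers(0, 2, 300),
                "a": rng.normal(size=300),
                "b": rng.normal(size=300),
                "c": rng.normal(size=300),
            }
        )
        wide = univariable_screen(df, "outcome", ["a", "b", "c"], threshold=0.999999)
        narrow = univariable_screen(df, "outcome", ["a", "b", "c"], threshold=1e-12)
        assert wide == ["a", "b", "c"]
        assert narrow == []

    def test_categorical_advanced_if_any_level_passes(self):
        df = pd.DataFrame(
            {
                "outcome": [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40 + [1] * 25 + [0] * 25,
                "x": ["a"] * 50 + ["b"] * 50 + ["c"] * 50,
            }
        )
        assert univariable_screen(df, "outcome", ["x"]) == ["x"]


class TestClusterRobust:
    def test_singleton_clusters_equal_hc0(self):
        rng = np.random.default_rng(4)
        n = 500
        df = pd.DataFrame(
            {
                "outcome": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
                "patient_id": np.arange(n),
            }
        )
        clus = fit_longitudinal(df, "outcome", ["x"])
        hc0 = fit_logistic(df, "outcome", ["x"], cov_type="HC0")
        # sandwich with singleton clusters == heteroskedasticity-robust,
        # up to the small-sample cluster correction factor
        g = n
        corr = math.sqrt(g / (g - 1) * (n - 1) / (n - 2))
        np.testing.assert_allclose(clus.table["se"], hc0.table["se"] * corr, rtol=1e-6)
        np.testing.assert_allclose(clus.table["coef"], hc0.table["coef"], atol=1e-10)

    def test_point_estimates_match_unclustered_fit(self):
        rng = np.random.default_rng(5)
        n = 400
        df = pd.DataFrame(
            {
                "outcome": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
                "patient_id": rng.integers(0, 40, n),
            }
        )
        clus = fit_longitudinal(df, "outcome", ["x"])
        plain = fit_logistic(df, "outcome", ["x"])
        np.testing.assert_allclose(clus.table["coef"], plain.table["coef"], atol=1e-8)
        assert clus.n_clusters == 40

    def test_duplicating_rows_within_cluster_keeps_point_estimates(self):
        rng = np.random.default_rng(6)
        n = 300
        df = pd.DataFrame(
            {
                "outcome": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
                "patient_id": rng.integers(0, 30, n),
            }
        )
        doubled = pd.concat([df, df], ignore_index=True)
        a = fit_longitudinal(df, "outcome", ["x"])
        b = fit_longitudinal(doubled, "outcome", ["x"])
        np.testing.assert_allclose(a.table["coef"], b.table["coef"], atol=1e-8)

    def test_single_cluster_rejected(self):
        df = pd.DataFrame({"outcome": [0, 1, 0, 1], "x": [0.0, 1.0, 0.5, 0.2], "patient_id": 1})
        with pytest.raises(ValueError, match="two clusters"):
            fit_longitudinal(df, "outcome", ["x"])


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(n_patients=600, seed=77)
    patients, visits = generate_registry(cfg)
    grids = build_state_grids(carry_forward_covariates(visits))
    return patients, grids


class TestPanel:
    def test_prior_tczc_flag_set_from_first_combination_interval(self):
        from test_markov import grids_from_sequences

        g = grids_from_sequences({1: ["TNFI", "TNFI", "TCZ_COMBO", "TNFI", "TCZ_MONO"]})
        g["cdai"] = np.nan
        g["haq"] = np.nan
        patients = pd.DataFrame(
            {
                "patient_id": [1],
                "age_years": [60.0],
                "sex": ["female"],
                "disease_duration_years": [5.0],
                "serostatus": ["positive"],
            }
        )
        panel = build_panel(g, patients)
        flags = panel.set_index("grid_month")["ever_tcz_combo"]
        assert list(flags.loc[[0, 6, 12, 18]]) == [0, 0, 1, 1]
        # strict lag: outcome at t is the state at t+6
        assert list(panel.sort_values("grid_month")["outcome"]) == [0, 0, 0, 1]

    def test_censored_patient_contributes_only_observed_pairs(self, cohort):
        patients, grids = cohort
        panel = build_panel(grids, patients, ModelSpec(incident_only=False))
        per_patient_cells = grids.groupby("patient_id")["grid_month"].count()
        per_patient_rows = panel.groupby("patient_id")["grid_month"].count()
        joined = pd.concat([per_patient_cells, per_patient_rows], axis=1).fillna(0)
        assert (joined.iloc[:, 1] == joined.iloc[:, 0] - 1).all()

    def test_incident_framing_excludes_rows_already_in_outcome_state(self, cohort):
        patients, grids = cohort
        panel = build_panel(grids, patients, ModelSpec(incident_only=True))
        assert not (panel["state"] == "TCZ_MONO").any()
        full = build_panel(grids, patients, ModelSpec(incident_only=False))
        n_on_target = (full["state"] == "TCZ_MONO").sum()
        assert len(panel) == len(full) - n_on_target

    def test_static_covariates_repeat_unchanged(self, cohort):
        patients, grids = cohort
        panel = build_panel(grids, patients)
        assert (panel.groupby("patient_id")["age_years"].nunique() == 1).all()


def test_stratified_fits_partition_the_panel(cohort):
    patients, grids = cohort
    panel = build_panel(grids, patients)
    fits = stratified_fit(panel, "outcome", ["state", "age_c"], stratum_col="ever_tcz_combo")
    n_rows = sum(f.n_obs for f in fits.values() if f is not None)
    usable = panel.dropna(subset=["outcome", "state", "age_c", "patient_id"])
    assert n_rows == len(usable)
    assert set(fits) == {"ever_tcz_combo=0", "ever_tcz_combo=1"}


def test_constant_stratum_equals_unstratified_fit(cohort):
    patients, grids = cohort
    panel = build_panel(grids, patients).assign(z=0)
    fits = stratified_fit(panel, "outcome", ["state", "age_c"], stratum_col="z")
    whole = fit_longitudinal(panel, "outcome", ["state", "age_c"])
    np.testing.assert_allclose(fits["z=0"].table["coef"], whole.table["coef"], atol=1e-10)


def test_cdai_categories_match_published_cutoffs():
    cats = cdai_category(pd.Series([1.0, 2.8, 2.9, 10.0, 10.1, 22.0, 22.1, 40.0]))
    assert list(cats) == [
        "remission",
        "remission",
        "low",
        "low",
        "moderate",
        "moderate",
        "high",
        "high",
    ]
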