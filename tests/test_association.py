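"""Tests for aggregation, mixed models, AIC selection, VIF, and FDR."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from allomem import (
    AssociationConfig,
    CohortConfig,
    aggregate_scores,
    association_pipeline,
    compute_vif,
    fdr_bh,
    fit_lmm,
    stepwise_aic,
)
from allomem.association import _design
from allomem.errors import InvalidInputError
from allomem.simulate import make_profiles, simulate_tract_measures
from allomem._rng import substream


def _score_rows(sid, values, failed):
    return [
        {"subject_id": sid, "trial_id": f"t{i}", "env_id": "e1",
         "pattern_accuracy": v, "raw_accuracy": v - 0.1,
         "environmental_geometry": np.nan if f else -0.1,
         "object_identity": np.nan if f else 4,
         "failed": f}
        for i, (v, f) in enumerate(zip(values, failed))
    ]


class TestAggregateScores:
    def test_failed_trials_excluded_from_means(self):
        scores = pd.DataFrame(
            _score_rows("S1", [0.8, 0.6, 0.2], [False, False, True]))
        out = aggregate_scores(scores)
        row = out.iloc[0]
        assert row["mean_pattern_accuracy"] == pytest.approx(0.7)
        assert row["n_failed"] == 1
        assert row["n_trials"] == 3

    def test_all_failed_gives_missing_summary(self):
        scores = pd.DataFrame(_score_rows("S1", [0.1, 0.2], [True, True]))
        out = aggregate_scores(scores)
        assert np.isnan(out.iloc[0]["mean_pattern_accuracy"])
        assert out.iloc[0]["n_failed"] == 2

    def test_no_failed_gives_plain_mean(self):
        scores = pd.DataFrame(
            _score_rows("S1", [0.5, 0.9], [False, False]))
        out = aggregate_scores(scores)
        assert out.iloc[0]["mean_pattern_accuracy"] == pytest.approx(0.7)
        assert out.iloc[0]["n_failed"] == 0

    def test_outcome_rates_merged(self):
        scores = pd.DataFrame(_score_rows("S1", [0.5], [False]))
        outcomes = pd.DataFrame([
            {"subject_id": "S1", "trial_id": "t0", "env_id": "e1",
             "objects_association": 1, "objects_room": 0},
            {"subject_id": "S1", "trial_id": "t1", "env_id": "e2",
             "objects_association": 0, "objects_room": 0},
        ])
        out = aggregate_scores(scores, outcomes)
        assert out.iloc[0]["objects_association_rate"] == pytest.approx(0.5)
        assert out.iloc[0]["objects_room_rate"] == pytest.approx(0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate_scores(pd.DataFrame())


def _lmm_frame(rng, n_subj=40, per_subj=2, beta=0.1, re_sd=0.02,
               noise_sd=0.02):
    rows = []
    for i in range(n_subj):
        x = rng.normal()
        u = rng.normal(0, re_sd)
        for h in range(per_subj):
            rows.append({
                "subject_id": f"S{i:03d}", "x": x,
                "z": rng.normal(),
                "value": 0.5 + beta * x + u + rng.normal(0, noise_sd),
            })
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_single_observation_per_subject_equals_ols(self, rng):
        """With one row per subject the random intercept is indistinguishable
        from residual noise and the fixed effects reduce to OLS."""
        df = _lmm_frame(rng, per_subj=1)
        res = fit_lmm(df, ["x"])
        X = _design(df, ["x"])
        ols = np.linalg.lstsq(X, df["value"].to_numpy(), rcond=None)[0]
        est = res.terms.set_index("term")["estimate"]
        assert est["intercept"] == pytest.approx(ols[0], abs=1e-6)
        assert est["x"] == pytest.approx(ols[1], abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        """Cross-check the in-package profiled-ML solver against an
        independent implementation on the same data."""
        df = _lmm_frame(rng)
        res = fit_lmm(df, ["x", "z"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(df["value"].to_numpy(), _design(df, ["x", "z"]),
                             groups=df["subject_id"].to_numpy()
                             ).fit(reml=False, method="bfgs", maxiter=300)
        est = res.terms["estimate"].to_numpy()
        assert np.allclose(est, ref.fe_params, atol=1e-6)
        assert res.loglik == pytest.approx(ref.llf, abs=1e-5)
        # exact GLS standard errors at the reference fit's variance estimates
        X = _design(df, ["x", "z"])
        tau2 = float(np.asarray(ref.cov_re).ravel()[0])
        ids = pd.factorize(df["subject_id"])[0]
        V = np.eye(len(df)) * float(ref.scale)
        for gid in np.unique(ids):
            idx = np.flatnonzero(ids == gid)
            V[np.ix_(idx, idx)] += tau2
        se_gls = np.sqrt(np.diag(np.linalg.inv(X.T @ np.linalg.inv(V) @ X)))
        assert np.allclose(res.terms["se"], se_gls, rtol=1e-4)

    def test_aic_accounting(self, rng):
        df = _lmm_frame(rng)
        res = fit_lmm(df, ["x"])
        k = 2 + 2  # intercept + slope + two variance parameters
        assert res.n_params == k
        assert res.aic == pytest.approx(2 * k - 2 * res.loglik)

    def test_recovers_injected_slope(self, rng):
        df = _lmm_frame(rng, n_subj=83, beta=0.1)
        res = fit_lmm(df, ["x"])
        row = res.terms.set_index("term").loc["x"]
        lo = row["estimate"] - 1.96 * row["se"]
        hi = row["estimate"] + 1.96 * row["se"]
        assert lo < 0.1 < hi

    def test_singular_design_flagged_not_raised(self, rng):
        df = _lmm_frame(rng)
        df["x2"] = df["x"]
        res = fit_lmm(df, ["x", "x2"])
        assert not res.converged
        assert np.isnan(res.aic)

    def test_type_one_error_near_nominal(self, rng):
        """Null slope: |t| > t_crit should occur at close to the nominal
        5% rate across replicates."""
        hits = 0
        reps = 300
        from scipy import stats

        for _ in range(reps):
            df = _lmm_frame(rng, n_subj=40, beta=0.0)
            res = fit_lmm(df, ["x"])
            row = res.terms.set_index("term").loc["x"]
            crit = stats.t.ppf(0.975, 2 * 40 - 2)
            if abs(row["t"]) > crit:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07


class TestStepwiseAic:
    def test_strong_predictor_always_selected(self, rng):
        for _ in range(20):
            df = _lmm_frame(rng, n_subj=60, beta=0.2, noise_sd=0.02)
            res = stepwise_aic(df, ["x", "z"])
            assert "x" in res.selected

    def test_duplicated_term_never_selected(self, rng):
        df = _lmm_frame(rng, n_subj=60, beta=0.2)
        df["x_copy"] = df["x"]
        res = stepwise_aic(df, ["x", "x_copy", "z"])
        assert "x" in res.selected
        assert "x_copy" not in res.selected

    def test_pure_noise_rarely_selected(self, rng):
        selected = 0
        reps = 40
        for _ in range(reps):
            df = _lmm_frame(rng, n_subj=50, beta=0.0)
            res = stepwise_aic(df, ["x", "z"])
            selected += len(res.selected)
        # each noise term enters when its LR statistic exceeds 2 (~16%)
        assert selected / (2 * reps) < 0.35


class TestComputeVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({
            "a": np.cos(2 * np.pi * t / n),
            "b": np.sin(2 * np.pi * t / n),
        })
        vifs = compute_vif(X)
        assert vifs["a"] == pytest.approx(1.0, abs=1e-9)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-9)

    def test_known_correlation_closed_form(self):
        """Sample correlation exactly 0.9 gives VIF = 1/(1-0.81)."""
        n = 200
        rng = np.random.default_rng(4)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b = b - a * (a @ b) / (a @ a)  # residualize
        b = (b - b.mean()) / b.std()
        x2 = 0.9 * a + np.sqrt(1 - 0.81) * b
        vifs = compute_vif(pd.DataFrame({"a": a, "x2": x2}))
        assert vifs["a"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)
        assert vifs["x2"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)

    def test_duplicated_term_is_nonfinite(self, rng):
        a = rng.normal(size=50)
        vifs = compute_vif(pd.DataFrame({"a": a, "b": a}))
        assert not np.isfinite(vifs["a"])

    def test_single_term_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            compute_vif(pd.DataFrame({"a": rng.normal(size=10)}))


class TestFdrBh:
    def test_step_up_thresholds(self):
        flags = fdr_bh([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_none_significant(self):
        assert not fdr_bh([1.0, 1.0, 1.0]).any()

    def test_single_pvalue(self):
        assert fdr_bh([0.04]).tolist() == [True]
        assert fdr_bh([0.06]).tolist() == [False]

    def test_flags_monotone_in_p(self, rng):
        p = rng.uniform(size=50)
        flags = fdr_bh(p, q=0.1)
        if flags.any():
            assert p[flags].max() <= p[~flags].min() or not (~flags).any()

    def test_m_total_makes_correction_stricter(self):
        p = [0.01, 0.02]
        assert fdr_bh(p, q=0.05).all()
        assert not fdr_bh(p, q=0.05, m_total=100).any()


@pytest.fixture(scope="module")
def cohort_tables():
    cfg = CohortConfig(n_subjects=60, seed=21,
                       tracts=tuple(t for t in CohortConfig().tracts
                                    if t[0] in ("ILF", "arcuate", "cc_genu")))
    profiles = make_profiles(cfg)
    rng = np.random.default_rng(22)
    summaries = pd.DataFrame({
        "subject_id": [p.subject_id for p in profiles],
        "mean_pattern_accuracy":
            [p.ability + rng.normal(0, 0.05) for p in profiles],
        "mean_environmental_geometry": rng.normal(-0.3, 0.05, 60),
        "mean_object_identity": rng.normal(4, 0.5, 60),
        "objects_association_rate": rng.uniform(0.3, 1.0, 60),
        "objects_room_rate": rng.uniform(0.3, 1.0, 60),
        "n_trials": 35, "n_failed": 2,
    })
    tracts = simulate_tract_measures(profiles, cfg, substream(21, "t"))
    return summaries, tracts


class TestAssociationPipeline:
    def test_detects_true_link_and_reports_all_terms(self, cohort_tables):
        summaries, tracts = cohort_tables
        res = association_pipeline(summaries, tracts)
        ilf = res[(res["model_id"] == "ILF:FA")
                  & (res["term"] == "mean_pattern_accuracy")].iloc[0]
        assert ilf["selected"] and ilf["fdr_significant"]
        assert ilf["t"] > 0
        # one row per candidate term per model
        per_model = res.groupby("model_id").size()
        assert (per_model >= 9).all()

    def test_vif_reported_for_selected_terms(self, cohort_tables):
        summaries, tracts = cohort_tables
        res = association_pipeline(summaries, tracts)
        multi = res[res["selected"]].groupby("model_id").size()
        for model_id, k in multi.items():
            if k >= 2:
                v = res[(res["model_id"] == model_id) & res["selected"]]["vif"]
                assert (v >= 1.0 - 1e-9).all()

    def test_empty_inputs_rejected(self, cohort_tables):
        summaries, tracts = cohort_tables
        with pytest.raises(InvalidInputError, match="behavioral"):
            association_pipeline(pd.DataFrame(), tracts)
        with pytest.raises(InvalidInputError, match="tract"):
            association_pipeline(summaries, pd.DataFrame())
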