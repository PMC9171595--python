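"""Mixed-model stack: standardization, design, fitting, recovery, reporting."""

import numpy as np
import pandas as pd
import pytest

from wardsense import (
    FitResult,
    ModelSpec,
    RecoveryConfig,
    build_design,
    fit_glmm,
    recovery_experiment,
    report_table,
    standardize,
)
from wardsense.errors import ModelSpecificationError, StandardizationError


def _panel(n=40, v=4, seed=0, sigma_b=0.5, sigma_e=0.7,
           beta_t=0.3, beta_x=0.2, center_within=False):
    rng = np.random.default_rng(seed)
    pid = np.repeat(np.arange(n), v)
    weeks = np.tile(np.arange(v, dtype=float), n)
    x = rng.normal(0, 1, n * v)
    b = rng.normal(0, sigma_b, n)
    eps = rng.normal(0, sigma_e, n * v)
    if center_within:
        eps = eps - np.repeat(eps.reshape(n, v).mean(axis=1), v)
        b = np.zeros(n)
    y = beta_t * weeks + beta_x * x + b[pid] + eps
    return pd.DataFrame(
        {
            "patient_id": [f"S{i:03d}" for i in pid],
            "measure": "m",
            "value": y,
            "time_weeks": weeks,
            "overall_EI": x,
            "resident_room_EI": rng.normal(0, 1, n * v),
            "therapy_room_EI": rng.normal(0, 1, n * v),
            "sitting_EI": rng.normal(0, 1, n * v),
            "standing_EI": rng.normal(0, 1, n * v),
            "laying_EI": rng.normal(0, 1, n * v),
        }
    )


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame({"a": rng.uniform(5, 50, 200)})
        out, _ = standardize(df, ["a"])
        assert abs(out["a"].mean()) < 1e-12
        assert abs(out["a"].std(ddof=0) - 1.0) < 1e-12

    def test_round_trip_exact(self, rng):
        x = rng.normal(100, 7, 500)
        out, rec = standardize(pd.DataFrame({"a": x}), ["a"])
        back = rec.inverse("a", out["a"].to_numpy())
        assert np.allclose(back, x, rtol=0, atol=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(StandardizationError, match="flat"):
            standardize(pd.DataFrame({"flat": np.ones(10)}), ["flat"])


class TestBuildDesign:
    @pytest.mark.parametrize("model_id, n_fixed", [(1, 4), (2, 6), (3, 8)])
    def test_fixed_column_counts(self, model_id, n_fixed):
        spec, design, _, _ = build_design(model_id, "m", _panel())
        assert len(spec.fixed_terms) == n_fixed
        assert spec.fixed_terms[0] == "Intercept"
        assert spec.fixed_terms[1] == "time_weeks"

    def test_model1_covariate_set(self):
        spec, _, _, _ = build_design(1, "m", _panel())
        assert set(spec.fixed_terms) == {
            "Intercept", "time_weeks", "overall_EI", "overall_EI_x_time"
        }

    def test_model3_activity_terms(self):
        spec, _, _, _ = build_design(3, "m", _panel())
        for c in ("sitting_EI", "standing_EI", "laying_EI"):
            assert c in spec.fixed_terms
            assert f"{c}_x_time" in spec.fixed_terms

    def test_unknown_model_rejected(self):
        with pytest.raises(ModelSpecificationError):
            build_design(4, "m", _panel())

    def test_empty_table_rejected(self):
        with pytest.raises(ModelSpecificationError):
            build_design(1, "m", _panel().iloc[:0])

    def test_missing_covariate_rows_dropped_and_counted(self):
        data = _panel()
        data.loc[data.index[:5], "overall_EI"] = np.nan
        _, design, _, n_dropped = build_design(1, "m", data)
        assert n_dropped == 5
        assert len(design) == len(data) - 5

    def test_interaction_is_covariate_times_raw_weeks(self):
        _, design, _, _ = build_design(1, "m", _panel(), standardization="zscore")
        np.testing.assert_allclose(
            design["overall_EI_x_time"],
            design["overall_EI"] * design["time_weeks"],
        )
        # time itself is left on the raw weekly scale
        assert set(np.unique(design["time_weeks"])) == {0.0, 1.0, 2.0, 3.0}


class TestFitGlmm:
    def test_noise_free_linear_trend_recovered_exactly(self):
        data = _panel(n=20, v=4, sigma_b=0.0, sigma_e=0.0,
                      beta_t=0.5, beta_x=0.0)
        spec, design, _, _ = build_design(1, "m", data, standardization="none")
        fit = fit_glmm(spec, design)
        assert fit.terms.loc["time_weeks", "estimate"] == pytest.approx(0.5, abs=1e-8)
        assert fit.sigma_e2 == pytest.approx(0.0, abs=1e-8)

    def test_ols_limit_at_zero_between_patient_variance(self):
        """With no between-patient variance the mixed fit IS the OLS fit."""
        data = _panel(center_within=True, seed=3)
        spec, design, _, _ = build_design(1, "m", data, standardization="none")
        fit = fit_glmm(spec, design)
        X = design[list(spec.fixed_terms)].to_numpy()
        beta_ols = np.linalg.lstsq(X, design["y"].to_numpy(), rcond=None)[0]
        assert fit.sigma_b2 == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            fit.terms["estimate"].to_numpy(), beta_ols, atol=1e-6
        )

    def test_patient_order_invariance(self):
        data = _panel(seed=5)
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fits = []
        for d in (data, shuffled):
            spec, design, _, _ = build_design(1, "m", d)
            fits.append(fit_glmm(spec, design))
        np.testing.assert_allclose(
            fits[0].terms["estimate"], fits[1].terms["estimate"], atol=1e-6
        )

    def test_tstats_invariant_to_standardization(self):
        data = _panel(seed=7)
        t = {}
        for std in ("none", "zscore"):
            spec, design, _, _ = build_design(1, "m", data, standardization=std)
            fit = fit_glmm(spec, design)
            t[std] = fit.terms["estimate"] / fit.terms["se"]
        for term in ("overall_EI", "overall_EI_x_time"):
            assert t["none"][term] == pytest.approx(t["zscore"][term], rel=1e-3)

    def test_single_patient_rejected(self):
        data = _panel(n=1)
        spec, design, _, _ = build_design(1, "m", data)
        with pytest.raises(ModelSpecificationError):
            fit_glmm(spec, design)

    def test_positive_variance_components(self):
        data = _panel(seed=11, sigma_b=0.8)
        spec, design, _, _ = build_design(1, "m", data)
        fit = fit_glmm(spec, design)
        assert fit.sigma_b2 > 0 and fit.sigma_e2 > 0
        assert (fit.terms["se"] > 0).all()
        assert fit.n_patients == 40 and fit.n_obs == 160


class TestRecovery:
    def test_small_replication_recovers_effects(self):
        rep = recovery_experiment(
            RecoveryConfig(n_patients=60), n_replicates=30, seed=9
        )
        by_term = rep.set_index("term")
        for term in ("time_weeks", "overall_EI"):
            assert abs(by_term.loc[term, "bias"]) < 3 * by_term.loc[term, "mc_se"]
        assert by_term["coverage_95"].between(0.8, 1.0).all()

    def test_more_patients_tighter_time_estimates(self):
        small = recovery_experiment(
            RecoveryConfig(n_patients=25), n_replicates=15, seed=2
        ).set_index("term")
        big = recovery_experiment(
            RecoveryConfig(n_patients=100), n_replicates=15, seed=2
        ).set_index("term")
        assert (
            big.loc["time_weeks", "empirical_se"]
            < small.loc["time_weeks", "empirical_se"]
        )


class TestReportTable:
    def _fit(self, outcome, model_id=1, est=0.2249, p=0.0004):
        spec = ModelSpec(model_id, outcome, ("overall_EI",))
        terms = pd.DataFrame(
            {
                "estimate": [0.01, est, 0.1, -0.05],
                "se": [0.09, 0.06, 0.08, 0.05],
                "p": [0.9, p, 0.2, 0.4],
            },
            index=list(spec.fixed_terms),
        )
        return FitResult(spec=spec, terms=terms, sigma_b2=0.2, sigma_e2=0.5,
                         n_obs=100, n_patients=30, converged=True)

    def test_rounding_and_significance_tiers(self):
        text = report_table([self._fit("gait_distance_feet")],
                            outcomes=("gait_distance_feet",))
        assert ".22 (0.06)**" in text  # P=.0004 -> P<.001 tier
        mild = report_table([self._fit("gait_distance_feet", p=0.02)],
                            outcomes=("gait_distance_feet",))
        assert ".22 (0.06)*" in mild and ".22 (0.06)**" not in mild

    def test_grid_covers_models_by_outcomes(self):
        outcomes = tuple(f"o{i}" for i in range(7))
        fits = [self._fit(o, m) for o in outcomes for m in (1, 2, 3)]
        text = report_table(fits, outcomes=outcomes)
        for m in (1, 2, 3):
            assert f"**Model {m}**" in text
        header = text.splitlines()[0]
        assert all(o in header for o in outcomes)

    def test_missing_fit_renders_absent_cell(self):
        text = report_table([self._fit("o1")], outcomes=("o1", "o2"))
        lines = [l for l in text.splitlines() if l.startswith("| time_weeks")]
        assert lines and lines[0].rstrip().endswith("|")
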