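"""Response-rate CIs, logistic and Cox dose effects, KM, covariate selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from y90dosim.cohort import CohortConfig, simulate_cohort
from y90dosim.outcomes import (
    SeparationError,
    fit_cox_tad,
    fit_dose_response_logistic,
    km_curve,
    multivariable_select,
    orr_with_ci,
)


class TestOrrWilson:
    @pytest.mark.parametrize(
        "x,n,rate,lo,hi",
        [
            (129, 209, 61.7, 55.0, 68.0),
            (72, 209, 34.4, 28.3, 41.1),
        ],
    )
    def test_published_style_counts(self, x, n, rate, lo, hi):
        r, (cl, ch) = orr_with_ci(x, n)
        assert (r, cl, ch) == (rate, lo, hi)

    def test_zero_responders_boundary(self):
        r, (lo, hi) = orr_with_ci(0, 10)
        assert r == 0.0 and lo == 0.0 and hi > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            orr_with_ci(1, 0)
        with pytest.raises(ValueError):
            orr_with_ci(11, 10)


class TestLogisticDoseResponse:
    def test_two_group_saturated_odds_ratio(self):
        # Closed form on a 2x2: (8/2)/(5/5) = 4 per 100 Gy.
        df = pd.DataFrame(
            {
                "dose": [100.0] * 10 + [200.0] * 10,
                "resp": [1] * 5 + [0] * 5 + [1] * 8 + [0] * 2,
            }
        )
        fit = fit_dose_response_logistic(df, "dose", "resp")
        assert fit.or_per_100gy == pytest.approx(4.0, rel=1e-4)
        assert fit.ci_low < 4.0 < fit.ci_high

    def test_dose_independent_outcome_gives_unit_or(self):
        df = pd.DataFrame(
            {
                "dose": [100.0, 100.0, 200.0, 200.0, 300.0, 300.0],
                "resp": [0, 1, 0, 1, 0, 1],
            }
        )
        fit = fit_dose_response_logistic(df, "dose", "resp")
        assert fit.or_per_100gy == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_flagged(self):
        df = pd.DataFrame({"dose": np.arange(20.0), "resp": (np.arange(20) >= 10).astype(int)})
        with pytest.raises(SeparationError):
            fit_dose_response_logistic(df, "dose", "resp")

    def test_missing_rows_dropped_and_counted(self):
        df = pd.DataFrame(
            {"dose": [100, 200, 300, None, 150, 250], "resp": [0, 1, 0, 1, None, 1]}
        )
        fit = fit_dose_response_logistic(df, "dose", "resp")
        assert fit.n == 4 and fit.n_dropped_missing == 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct dose"):
            fit_dose_response_logistic(
                pd.DataFrame({"d": [1.0, 1.0], "y": [0, 1]}), "d", "y"
            )
        with pytest.raises(ValueError, match="outcome classes"):
            fit_dose_response_logistic(
                pd.DataFrame({"d": [1.0, 2.0], "y": [1, 1]}), "d", "y"
            )


def _hand_partial_likelihood(beta: float) -> float:
    # Events at t=1 (z=1), 2 (z=0), 3 (z=1), 4 (z=0); risk sets shrink by one.
    r = np.exp(beta)
    return (
        np.log(r / (2 * r + 2)) + np.log(1 / (r + 2)) + np.log(r / (r + 1))
    )


class TestCoxDoseEffect:
    def test_hand_partial_likelihood_example(self):
        df = pd.DataFrame(
            {"z": [1, 0, 1, 0], "t": [1.0, 2.0, 3.0, 4.0], "e": [1, 1, 1, 1]}
        )
        fit = fit_cox_tad(df, "z", time_col="t", event_col="e")
        # Independent oracle: numeric maximization of the hand-written
        # partial likelihood, and the closed form (1 + sqrt(17)) / 2.
        opt = minimize_scalar(lambda b: -_hand_partial_likelihood(b), bounds=(-5, 5), method="bounded")
        assert np.exp(fit.slope_per_gy) == pytest.approx(np.exp(opt.x), rel=1e-3)
        assert np.exp(fit.slope_per_gy) == pytest.approx((1 + np.sqrt(17)) / 2, rel=1e-3)

    def test_exchangeable_groups_give_unit_hr(self):
        df = pd.DataFrame(
            {
                "z": [0, 0, 0, 1, 1, 1],
                "t": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                "e": [1, 1, 1, 1, 1, 1],
            }
        )
        fit = fit_cox_tad(df, "z", time_col="t", event_col="e")
        assert np.exp(fit.slope_per_gy) == pytest.approx(1.0, abs=1e-6)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"z": [0.0, 1.0], "t": [1.0, 2.0], "e": [0, 0]})
        with pytest.raises(ValueError, match="at least one event"):
            fit_cox_tad(df, "z", time_col="t", event_col="e")

    def test_hr_per_100gy_scaling(self):
        df = simulate_cohort(CohortConfig(n_patients=400, seed=21))
        fit = fit_cox_tad(df, "tad_anat_gy")
        assert fit.hr_per_100gy == pytest.approx(np.exp(100 * fit.slope_per_gy))
        assert fit.ci_low < fit.hr_per_100gy < fit.ci_high


class TestKaplanMeier:
    def test_uncensored_1_to_9_median_is_5(self):
        # Product-limit with no censoring = empirical survival; S(5) = 4/9.
        df = pd.DataFrame({"t": np.arange(1.0, 10.0), "e": 1})
        est = km_curve(df, "t", "e")
        assert est.median_months == 5.0

    def test_no_censoring_equals_empirical_survival(self):
        times = np.array([2.0, 2.0, 3.0, 5.0, 8.0, 13.0])
        df = pd.DataFrame({"t": times, "e": 1})
        est = km_curve(df, "t", "e")
        for t, s in zip(est.times, est.survival):
            assert s == pytest.approx((times > t).mean())

    def test_all_censored_median_not_reached(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0], "e": 0})
        est = km_curve(df, "t", "e")
        assert est.median_months is None and not est.median_reached

    def test_identical_times_median(self):
        df = pd.DataFrame({"t": [7.0] * 5, "e": 1})
        assert km_curve(df, "t", "e").median_months == 7.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve(pd.DataFrame({"t": [], "e": []}), "t", "e")


class TestMultivariableSelect:
    def _cohort(self, seed=0, effect=0.0):
        cfg = CohortConfig(
            n_patients=400,
            seed=seed,
            tox_intercept=-2.0,
            tox_covariate_effects={"bclc_c": effect},
        )
        return simulate_cohort(cfg)

    def test_no_candidate_passes_screen(self):
        res = multivariable_select(
            self._cohort(seed=17),
            candidates=["age_years", "sex_male"],
        )
        if res.selected:  # noise can pass p<0.1 by chance; require trail consistency
            for c in res.selected:
                assert res.final_pvalues[c] < 0.1
        assert res.forced_term == "ntad_perfused_gy"
        assert any(step.get("action") == "final" for step in res.trail)

    def test_strong_covariate_retained(self):
        hits = 0
        for seed in range(10):
            res = multivariable_select(
                self._cohort(seed=seed, effect=2.0),
                candidates=["bclc_c", "age_years", "sex_male"],
            )
            hits += "bclc_c" in res.selected
        assert hits >= 9  # >= 90% of replicates keep the causal covariate

    def test_collinear_candidates_resolved_with_warning(self):
        df = self._cohort(seed=5, effect=2.0)
        df["bclc_c_copy"] = df["bclc_c"]
        with pytest.warns(UserWarning, match="collinear"):
            res = multivariable_select(df, candidates=["bclc_c", "bclc_c_copy"])
        assert not ({"bclc_c", "bclc_c_copy"} <= set(res.selected))

    def test_rerun_is_deterministic(self):
        df = self._cohort(seed=3, effect=1.0)
        a = multivariable_select(df, candidates=["bclc_c", "age_years"])
        b = multivariable_select(df, candidates=["bclc_c", "age_years"])
        assert a.selected == b.selected and a.trail == b.trail


class TestEstimatorConsistency:
    def test_or_bias_shrinks_with_n(self):
        """Logistic OR estimates concentrate near truth as n grows 10x."""
        gen_or = 1.22
        errs = {}
        for n, reps in ((209, 30), (2090, 30)):
            vals = []
            for seed in range(reps):
                df = simulate_cohort(CohortConfig(n_patients=n, seed=1000 + seed))
                vals.append(
                    fit_dose_response_logistic(df, "tad_anat_gy", "response_mrecist").or_per_100gy
                )
            errs[n] = abs(np.mean(vals) - gen_or)
        assert errs[2090] <= errs[209] + 0.02
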