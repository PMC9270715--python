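"""Synthetic generator: determinism, structural fidelity, missingness, oracle."""

import numpy as np
import pandas as pd
import pytest

import artswitch as a
from artswitch.cohort import _validate
from artswitch.design import VL_THRESHOLD
from artswitch.synth import (
    ExactRisk,
    GeneratorParams,
    ModeError,
    ParameterError,
    exact_risk,
    toy_baseline_frame,
    true_model_set,
)


class TestGenerateCohort:
    def test_deterministic_under_seed(self):
        p = GeneratorParams(n=100, seed=9)
        c1, c2 = a.generate_cohort(p), a.generate_cohort(p)
        pd.testing.assert_frame_equal(c1.frame, c2.frame)

    def test_generated_cohort_passes_validation(self, synthetic_cohort):
        _validate(synthetic_cohort.frame)  # raises on any invariant violation

    def test_degenerate_hazard_yields_zero_deaths(self):
        p = GeneratorParams(n=300, seed=2,
                            death_coef={"const": -50.0})
        c = a.generate_cohort(p)
        assert c.frame["died"].sum() == 0

    def test_baseline_frequencies_near_targets(self):
        c = a.generate_cohort(GeneratorParams(n=10000, K_max=1, seed=3))
        base = c.baseline()
        assert abs((base.gender == "male").mean() - 0.771) < 0.015
        assert abs((base.cd4 < 200).mean() - 0.81) < 0.03
        assert abs((base.vl >= VL_THRESHOLD).mean() - 0.637) < 0.02

    def test_invalid_params_name_the_field(self):
        with pytest.raises(ParameterError, match="missing_rate"):
            GeneratorParams(missing_rate=1.5)
        with pytest.raises(ParameterError, match="baseline_freqs"):
            GeneratorParams(baseline_freqs={"gender": {"male": 0.9, "female": 0.2}})
        with pytest.raises(ParameterError, match="death_coef"):
            GeneratorParams(death_coef={"not_a_feature": 1.0})

    def test_empirical_hazard_matches_death_model(self):
        """Interval-specific death fraction in a large cohort agrees with the
        logistic hazard evaluated at the realised covariates (3 MC SEs)."""
        from scipy.special import expit
        from artswitch.design import pooled_frame
        from artswitch.design import linear_predictor
        p = GeneratorParams(n=20000, K_max=4, fu_min=4, fu_max=4,
                            dropout_rate=0.0, seed=14)
        c = a.generate_cohort(p)
        pooled, state = pooled_frame(c)
        pred = expit(linear_predictor(state, p.death_coef))
        obs = pooled["died"].to_numpy(dtype=float)
        diff = obs.mean() - pred.mean()
        se = np.sqrt((pred * (1 - pred)).sum()) / len(pred)
        assert abs(diff) < 3 * se


class TestInjectMissingness:
    def test_rate_zero_is_identity(self, synthetic_cohort):
        out = a.inject_missingness(synthetic_cohort, 0.0, "MCAR", seed=1)
        pd.testing.assert_frame_equal(out.frame, synthetic_cohort.frame)

    def test_mcar_rate_recovered(self):
        c = a.generate_cohort(GeneratorParams(n=3000, seed=6))
        out = a.inject_missingness(c, 0.2, "MCAR", seed=7)
        post = out.frame[out.frame.k >= 1]
        assert abs(post.cd4.isna().mean() - 0.2) < 0.02
        assert out.frame[out.frame.k == 0].cd4.notna().all()

    def test_mar_on_vl_planted_odds_recovered(self):
        """Refit the masking indicator on VL level: odds ratio ~ 2."""
        import statsmodels.api as sm
        c = a.generate_cohort(GeneratorParams(n=5000, seed=16))
        out = a.inject_missingness(c, 0.25, "MAR_on_VL", seed=17, mar_vl_odds=2.0)
        post = out.frame[out.frame.k >= 1]
        y = post.cd4.isna().astype(float).to_numpy()
        x = sm.add_constant((post.vl >= VL_THRESHOLD).astype(float).to_numpy())
        res = sm.Logit(y, x).fit(disp=0)
        lo, hi = res.conf_int()[1]
        assert lo < np.log(2.0) < hi

    def test_invalid_rate_rejected(self, synthetic_cohort):
        with pytest.raises(ValueError):
            a.inject_missingness(synthetic_cohort, 1.0, "MCAR", seed=0)


class TestExactRisk:
    def test_enumeration_on_continuous_system_is_mode_error(self):
        p = GeneratorParams(n=10, seed=0)
        with pytest.raises(ModeError):
            exact_risk(p, a.Strategy.natural(), 3, method="enumerate")

    def test_zero_hazard_gives_zero_risk(self, toy_params):
        from dataclasses import replace
        p = replace(toy_params, death_coef={"const": -50.0})
        er = exact_risk(p, a.Strategy.static("PI"), 5)
        assert np.allclose(er.risk_by_k, 0.0)

    def test_protective_pi_orders_static_strategies(self, toy_params):
        pi = exact_risk(toy_params, a.Strategy.static("PI"), 5).risk_by_k
        nnrti = exact_risk(toy_params, a.Strategy.static("NNRTI"), 5).risk_by_k
        assert np.all(pi <= nnrti)

    def test_risk_curves_nondecreasing_in_bounds(self, toy_params):
        for s in a.default_strategies():
            r = exact_risk(toy_params, s, 5).risk_by_k
            assert np.all(np.diff(r) >= 0) and r.min() >= 0 and r.max() <= 1

    def test_dp_matches_brute_force_history_enumeration(self, toy_params):
        """Independent oracle: recursively enumerate every binary-state history
        for K=2 and sum path probabilities; must equal the DP exactly."""
        from scipy.special import expit
        p = toy_params
        strat = a.Strategy.static("PI")

        def eta(coef, c, v, pi):
            return (coef.get("const", 0) + coef.get("lag_cd4_high", 0) * c
                    + coef.get("lag_vl_high", 0) * v + coef.get("lag_pi", 0) * pi
                    + coef.get("cd4_high", 0) * c + coef.get("vl_high", 0) * v
                    + coef.get("pi", 0) * pi)

        def walk(k, c, v, pi, w, horizon):
            # returns total death probability mass accumulated through horizon
            if k > horizon or w == 0:
                return 0.0
            dead = 0.0
            pc = expit(eta(p.cd4_coef, c, v, pi))
            pv = expit(eta(p.vl_coef, c, v, pi))
            for c2 in (0, 1):
                for v2 in (0, 1):
                    w2 = w * (pc if c2 else 1 - pc) * (pv if v2 else 1 - pv)
                    pi2 = 1.0  # static PI
                    pd_ = expit(eta(p.death_coef, c2, v2, pi2))
                    dead += w2 * pd_
                    if k < horizon:
                        dead += walk(k + 1, c2, v2, pi2, w2 * (1 - pd_), horizon)
            return dead

        total = 0.0
        for c0 in (0, 1):
            for v0 in (0, 1):
                w0 = ((p.p_cd4_high0 if c0 else 1 - p.p_cd4_high0)
                      * (p.p_vl_high0 if v0 else 1 - p.p_vl_high0))
                total += walk(1, c0, v0, 1.0, w0, 2)
        dp = exact_risk(p, strat, 2).risk_at(2)
        assert dp == pytest.approx(total, abs=1e-12)

    def test_mc_mode_reports_se_and_agrees_with_dp(self, toy_params):
        er_mc = exact_risk(toy_params, a.Strategy.natural(), 5, method="mc",
                           n_mc=200_000, seed=3)
        er_dp = exact_risk(toy_params, a.Strategy.natural(), 5)
        assert isinstance(er_mc, ExactRisk) and er_mc.se is not None
        z = np.abs(er_mc.risk_by_k[1:] - er_dp.risk_by_k[1:]) / er_mc.se[1:]
        assert z.max() < 3.0


class TestTrueModelSet:
    def test_toy_baseline_frame_requires_toy_mode(self):
        with pytest.raises(ParameterError):
            toy_baseline_frame(GeneratorParams(n=10), 100, np.random.default_rng(0))

    def test_true_models_carry_generator_coefficients(self, toy_params):
        ms = true_model_set(toy_params)
        assert ms.death.params == toy_params.death_coef
        assert ms.cd4_binary and ms.cd4.kind == "logistic"

    def test_truth_record_serialises_risk_curves(self, toy_params, tmp_path):
        import json
        from artswitch.synth import TruthRecord
        risks = {s.name: exact_risk(toy_params, s, 5).risk_by_k
                 for s in a.default_strategies()}
        rec = TruthRecord(params=toy_params, risks=risks)
        path = tmp_path / "truth.json"
        rec.to_json(path)
        back = json.loads(path.read_text())
        assert back["natural_course"][5] == pytest.approx(
            risks["natural_course"][5])
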