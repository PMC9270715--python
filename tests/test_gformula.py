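"""Model fitting, strategy application and Monte Carlo simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import artswitch as a
from artswitch.gformula import (
    FitError,
    Strategy,
    apply_strategy,
    cumulative_risk,
    fit_models,
    simulate,
    zero_treatment_effects,
)
from artswitch.synth import true_model_set


class TestStrategy:
    def test_mode_fields_enforced(self):
        with pytest.raises(ValueError):
            Strategy(name="x", mode="static")  # no regimen
        with pytest.raises(ValueError):
            Strategy(name="x", mode="natural", static_regimen="PI")
        with pytest.raises(ValueError):
            Strategy(name="x", mode="dynamic", trigger_cd4=200.0)  # no target

    def test_default_strategies_are_the_four_scenarios(self):
        modes = [(s.mode, s.static_regimen, s.trigger_cd4) for s in a.default_strategies()]
        assert modes == [("natural", None, None), ("static", "NNRTI", None),
                         ("static", "PI", None), ("dynamic", None, 200.0)]


class TestApplyStrategy:
    def _state(self, cd4):
        cd4 = np.asarray(cd4, dtype=float)
        return {"cd4": cd4, "const": np.ones(len(cd4))}

    def test_static_pi_always_pi(self):
        pi, _ = apply_strategy(Strategy.static("PI"), self._state([350.0]), None,
                               np.random.default_rng(0), np.array([0.0]), np.array([0.0]))
        assert pi[0] == 1.0

    def test_dynamic_trigger_not_fired_keeps_previous(self):
        pi, trig = apply_strategy(Strategy.cd4_triggered(200, "PI"),
                                  self._state([350.0]), None, np.random.default_rng(0),
                                  np.array([0.0]), np.array([0.0]))
        assert pi[0] == 0.0 and trig[0] == 0.0

    def test_dynamic_trigger_is_absorbing(self):
        strat = Strategy.cd4_triggered(200, "PI")
        rng = np.random.default_rng(0)
        pi, trig = apply_strategy(strat, self._state([150.0]), None, rng,
                                  np.array([0.0]), np.array([0.0]))
        assert pi[0] == 1.0 and trig[0] == 1.0
        # CD4 recovers above the threshold: regimen stays PI
        pi2, trig2 = apply_strategy(strat, self._state([400.0]), None, rng,
                                    np.array([0.0]), trig)
        assert pi2[0] == 1.0 and trig2[0] == 1.0


class TestCumulativeRisk:
    def test_closed_form(self):
        np.testing.assert_allclose(cumulative_risk([0.0, 0.0, 0.0]), [0, 0, 0])
        np.testing.assert_allclose(cumulative_risk([0.1, 0.1]), [0.1, 0.19])

    def test_out_of_range_hazard_rejected(self):
        with pytest.raises(ValueError):
            cumulative_risk([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_matches_survival_product(self, h):
        # independent path: explicit survival product per index
        expected = [1.0 - np.prod([1.0 - x for x in h[: i + 1]]) for i in range(len(h))]
        np.testing.assert_allclose(cumulative_risk(h), expected, atol=1e-12)


class TestFitModels:
    def test_missing_cd4_rejected(self, synthetic_cohort):
        masked = a.inject_missingness(synthetic_cohort, 0.1, "MCAR", seed=1)
        with pytest.raises(FitError, match="missing CD4"):
            fit_models(masked, a.SimConfig(seed=0))

    def test_no_deaths_rejected(self):
        from dataclasses import replace
        p = a.GeneratorParams(n=200, seed=2, death_coef={"const": -50.0})
        c = a.generate_cohort(p)
        with pytest.raises(FitError, match="death"):
            fit_models(c, a.SimConfig(seed=0))

    def test_no_switchers_flags_treatment_model_degenerate(self):
        p = a.GeneratorParams(n=300, seed=3, p_pi0=0.0,
                              trt_coef={"const": -50.0})
        c = a.generate_cohort(p)
        ms = fit_models(c, a.SimConfig(seed=0))
        assert ms.trt.degenerate

    def test_saturated_toy_fit_matches_cell_proportions(self, toy_params):
        """With binary predictors and a large cohort, fitted death
        probabilities must reproduce the empirical cell proportions."""
        from dataclasses import replace
        from artswitch.design import pooled_frame
        big = a.generate_cohort(replace(toy_params, n=20000, seed=31))
        ms = fit_models(big, a.SimConfig(seed=0, toy_mode=True))
        pooled, state = pooled_frame(big)
        pred = ms.death.mean(state)
        died = pooled["died"].to_numpy(dtype=float)
        import pandas as pd
        cells = pd.DataFrame({"c": state["cd4_high"], "v": state["vl_high"],
                              "p": state["pi"], "y": died, "yhat": pred})
        for _, g in cells.groupby(["c", "v", "p"]):
            if len(g) < 500:
                continue
            se = np.sqrt(g.y.mean() * (1 - g.y.mean()) / len(g)) + 1e-6
            # main-effects logistic on a 3-bit state is near-saturated; the
            # empirical and fitted cell rates must agree to sampling error
            assert abs(g.y.mean() - g.yhat.mean()) < 4 * se


class TestSimulate:
    def test_zero_hazard_zero_risk(self, toy_mode_cohort, toy_params):
        ms = true_model_set(toy_params)
        ms.death.params = {"const": -50.0}
        cfg = a.SimConfig(n_mc=2000, horizon_K=5, seed=0, toy_mode=True)
        curve = simulate(ms, toy_mode_cohort.baseline(), Strategy.natural(), cfg)
        assert np.allclose(curve.risk_by_k, 0.0)

    def test_deterministic_under_seed(self, fitted_models, synthetic_cohort):
        ms, cfg = fitted_models
        c1 = simulate(ms, synthetic_cohort.baseline(), Strategy.static("PI"), cfg, rng=42)
        c2 = simulate(ms, synthetic_cohort.baseline(), Strategy.static("PI"), cfg, rng=42)
        np.testing.assert_array_equal(c1.risk_by_k, c2.risk_by_k)

    def test_risk_curves_monotone_bounded_all_strategies(self, fitted_models,
                                                         synthetic_cohort):
        ms, cfg = fitted_models
        for s in a.default_strategies():
            r = simulate(ms, synthetic_cohort.baseline(), s, cfg, rng=3).risk_by_k
            assert np.all(np.diff(r) >= 0)
            assert r.min() >= 0.0 and r.max() <= 1.0

    def test_mc_error_shrinks_with_root_n(self, fitted_models, synthetic_cohort):
        """Doubling n_mc shrinks the replicate SD of the 5-year risk ~1/sqrt(2)."""
        ms, _ = fitted_models
        pool = synthetic_cohort.baseline()

        def sd_of(n_mc, reps=40):
            cfg = a.SimConfig(n_mc=n_mc, horizon_K=5, seed=0)
            vals = [simulate(ms, pool, Strategy.natural(), cfg, rng=r).risk_5yr
                    for r in range(reps)]
            return np.std(vals)

        ratio = sd_of(1000) / sd_of(4000)
        assert 1.4 < ratio < 2.9  # expect ~2 with replicate noise

    def test_null_models_equalise_strategies(self, toy_params, toy_mode_cohort):
        ms = zero_treatment_effects(true_model_set(toy_params))
        cfg = a.SimConfig(n_mc=20000, horizon_K=5, seed=0, toy_mode=True)
        risks = [simulate(ms, toy_mode_cohort.baseline(), s, cfg, rng=i).risk_5yr
                 for i, s in enumerate(a.default_strategies())]
        se = np.sqrt(max(risks) * (1 - max(risks)) / cfg.n_mc)
        assert max(risks) - min(risks) < 4 * se  # two draws -> sqrt(2)*se each
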