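"""Contrasts, bootstrap inference, diagnostics and the results table."""

import numpy as np
import pandas as pd
import pytest

import artswitch as a
from artswitch.inference import (
    BootstrapSpec,
    assemble_results,
    bootstrap,
    contrast,
    natural_course_diagnostics,
    observed_interval_means,
    parse_results_table,
)


class TestContrast:
    def test_identity(self):
        assert contrast(7.5, 7.5) == (1.0, 0.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ZeroDivisionError):
            contrast(5.0, 0.0)

    def test_direction_of_protective_strategy(self):
        rr, rd = contrast(5.30, 11.62)
        assert rr < 1 and rd < 0


class TestBootstrap:
    def test_deterministic_replicates(self, synthetic_cohort):
        cfg = a.SimConfig(n_mc=1000, horizon_K=5, seed=1)
        spec = BootstrapSpec(B=50, seed=77)
        strategies = [a.Strategy.natural(), a.Strategy.static("PI")]
        r1 = bootstrap(synthetic_cohort, strategies, cfg, spec)
        r2 = bootstrap(synthetic_cohort, strategies, cfg, spec)
        np.testing.assert_array_equal(r1.risk5["immediate_PI"], r2.risk5["immediate_PI"])

    def test_requires_natural_course_reference(self, synthetic_cohort):
        cfg = a.SimConfig(n_mc=1000, horizon_K=5, seed=1)
        with pytest.raises(ValueError, match="natural"):
            bootstrap(synthetic_cohort, [a.Strategy.static("PI")], cfg,
                      BootstrapSpec(B=50, seed=0))

    def test_internal_consistency_of_replicates(self, synthetic_cohort):
        """Within every replicate rd = risk - ref and rr = risk/ref exactly."""
        cfg = a.SimConfig(n_mc=1000, horizon_K=5, seed=1)
        strategies = [a.Strategy.natural(), a.Strategy.static("NNRTI")]
        res = bootstrap(synthetic_cohort, strategies, cfg, BootstrapSpec(B=60, seed=5))
        ref = res.risk5["natural_course"]
        np.testing.assert_allclose(res.rd["immediate_NNRTI"],
                                   res.risk5["immediate_NNRTI"] - ref, atol=1e-12)
        np.testing.assert_allclose(res.rr["immediate_NNRTI"],
                                   res.risk5["immediate_NNRTI"] / ref, atol=1e-12)

    def test_estimate_contrasts_reference_row_exact(self, synthetic_cohort):
        cfg = a.SimConfig(n_mc=1000, horizon_K=5, seed=2)
        contrasts, curves, manifest = a.estimate_contrasts(
            synthetic_cohort, a.default_strategies(), cfg, BootstrapSpec(B=50, seed=3))
        ref = [c for c in contrasts if c.is_reference][0]
        assert ref.rr == 1.0 and ref.rd == 0.0
        for c in contrasts:
            assert c.risk_ci[0] <= c.risk_5yr + 1e-9 or not c.is_reference
        assert manifest["bootstrap_dropped"] <= 0.05 * manifest["bootstrap_requested"]


class TestDiagnostics:
    def test_observed_means_track_cohort(self, synthetic_cohort):
        obs = observed_interval_means(synthetic_cohort)
        assert obs.loc[0, "cum_mortality"] == 0.0
        assert (obs["cum_mortality"].diff().dropna() >= 0).all()

    def test_correct_specification_calibrates(self, synthetic_cohort):
        """Simulated natural-course means track observed means when the model
        family matches the generator (per-interval, 3 combined SEs)."""
        cfg = a.SimConfig(n_mc=20000, horizon_K=8, seed=4)
        ms = a.fit_models(synthetic_cohort, cfg)
        curve = a.simulate(ms, synthetic_cohort.baseline(), a.Strategy.natural(),
                           cfg, rng=9)
        diag = natural_course_diagnostics(synthetic_cohort, curve)
        obs_n = diag["n"].to_numpy(dtype=float)
        for var, scale in [("vl_high_frac", None), ("pi_frac", None)]:
            o = diag[f"{var}_obs"].to_numpy()
            s = diag[f"{var}_sim"].to_numpy()
            se = np.sqrt(o * (1 - o) / obs_n + s * (1 - s) / cfg.n_mc) + 1e-9
            assert (np.abs(o - s) < 3.5 * se + 0.01).all()

    def test_planted_misspecification_detected(self):
        """Omitting CD4 (the dominant, time-structured hazard driver) from the
        death model on a strongly CD4-driven cohort must move the simulated
        mortality curve away from the observed one by > 3 combined SEs, while
        the correctly specified fit stays within noise.

        Note the death model must lose CD4's time structure too: a pooled
        hazard that keeps an interval main effect largely re-absorbs a single
        omitted covariate under natural-course diagnostics."""
        from artswitch.design import BASELINE_FEATURES
        p = a.GeneratorParams(n=4000, seed=21,
                              death_coef={"const": -1.2, "cd4_100": -2.0,
                                          "pi": -0.5})
        cohort = a.generate_cohort(p)
        cfg = a.SimConfig(n_mc=30000, horizon_K=8, seed=4)
        specs_bad = {
            "cd4": ["const", "k", "lag_cd4_sqrt", "lag_vl_high", "lag_pi"] + BASELINE_FEATURES,
            "vl": ["const", "k", "lag_cd4_100", "lag_vl_high", "lag_pi"] + BASELINE_FEATURES,
            "trt": ["const", "k", "cd4_100", "vl_high"] + BASELINE_FEATURES,
            "death": ["const", "vl_high", "pi"] + BASELINE_FEATURES,  # no CD4
        }

        def max_z(specs):
            ms = a.fit_models(cohort, cfg, specs=specs)
            curve = a.simulate(ms, cohort.baseline(), a.Strategy.natural(), cfg, rng=9)
            diag = natural_course_diagnostics(cohort, curve)
            zs = []
            for kk in range(1, 9):
                row = diag[diag.k == kk]
                o = row["cum_mortality_obs"].iloc[0]
                s = row["cum_mortality_sim"].iloc[0]
                se = np.sqrt(o * (1 - o) / p.n + s * (1 - s) / cfg.n_mc)
                zs.append(abs(o - s) / se)
            return max(zs)

        assert max_z(None) < 3.0
        assert max_z(specs_bad) > 3.0


class TestResultsTable:
    def _contrasts(self):
        return [
            a.ContrastResult("natural_course", 11.62, (7.82, 17.11), 1.0, (1.0, 1.0),
                             0.0, (0.0, 0.0), is_reference=True),
            a.ContrastResult("immediate_NNRTI", 31.88, (20.79, 44.94), 2.74,
                             (2.01, 3.47), 20.26, (10.96, 28.61)),
        ]

    def test_reference_row_formatting(self):
        table = assemble_results(self._contrasts())
        ref = table[table.strategy == "natural_course"].iloc[0]
        assert ref["rr"] == "1 (Ref)" and ref["rd"] == "0 (Ref)"

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            assemble_results(self._contrasts()[1:])

    def test_round_trip_parse(self):
        table = assemble_results(self._contrasts())
        back = parse_results_table(table)
        assert back[1].risk_5yr == pytest.approx(31.88)
        assert back[1].rr == pytest.approx(2.74)
        assert back[1].rd_ci == pytest.approx((10.96, 28.61))
        assert back[0].is_reference

    def test_single_strategy_table(self):
        table = assemble_results(self._contrasts()[:1])
        assert len(table) == 1
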