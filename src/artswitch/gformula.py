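"""Parametric g-formula engine: pooled model fitting and Monte Carlo simulation.

The estimator follows the standard g-computation recipe for a longitudinal
cohort with annual intervals and an absorbing death outcome:

1. Fit pooled person-interval regressions — a linear model for CD4 count, a
   logistic model for the high-viral-load indicator, a logistic model for the
   NNRTI->PI regimen switch (on the subset still on NNRTI), and a pooled
   discrete-time logistic hazard model for death.
2. Draw a pseudo-population from the observed joint baseline distribution and
   simulate it forward under an intervention strategy, updating within each
   interval in the order CD4 -> viral load -> regimen -> death.
3. Read cumulative mortality risk off the simulated population; the 5-year
   risk is the cumulative death fraction at interval 5.

Strategies are the natural course (regimen drawn from its fitted model), the
two static regimes (immediate switch to NNRTI or PI for all intervals), and
the dynamic regime that switches to PI once CD4 drops below 200 cells/uL.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from . import design
from .cohort import Cohort
from .design import (
    CD4_THRESHOLD,
    CONTINUOUS_VL_SPECS,
    DEFAULT_SPECS,
    TOY_SPECS,
    VL_THRESHOLD,
    baseline_dummies,
    derived_state,
    design_matrix,
    linear_predictor,
)

__all__ = [
    "FittedModel",
    "ModelSet",
    "Strategy",
    "SimConfig",
    "RiskCurve",
    "fit_models",
    "apply_strategy",
    "simulate",
    "cumulative_risk",
    "default_strategies",
    "zero_treatment_effects",
]

#: Numeric CD4 (cells/uL) and VL (copies/mL) values the binary toy states map to.
TOY_CD4_VALUES = (100.0, 400.0)  # (low, high)
TOY_VL_VALUES = (1000.0, 100_000.0)  # (suppressed, high)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """One pooled regression model: named coefficients plus fit metadata."""

    kind: str  # "linear" | "logistic"
    outcome: str
    features: list[str]
    params: dict[str, float] | None
    bse: dict[str, float] | None = None
    sd: float | None = None  # residual SD (linear models)
    nobs: int = 0
    flags: tuple[str, ...] = ()

    @property
    def degenerate(self) -> bool:
        return self.params is None or "degenerate" in self.flags

    def eta(self, state: dict[str, np.ndarray]) -> np.ndarray:
        if self.params is None:
            raise RuntimeError(f"model for {self.outcome!r} is degenerate; no coefficients")
        return linear_predictor(state, self.params)

    def mean(self, state: dict[str, np.ndarray]) -> np.ndarray:
        e = self.eta(state)
        if self.kind == "logistic":
            return expit(e)
        return e


@dataclass
class ModelSet:
    """The four fitted pooled models plus the shared covariate specification."""

    cd4: FittedModel
    vl: FittedModel
    trt: FittedModel
    death: FittedModel
    vl_threshold: float = VL_THRESHOLD
    cd4_binary: bool = False  # toy mode: CD4 modelled as a binary state
    cd4_sqrt: bool = True  # CD4 transition model on the square-root scale
    vl_continuous: bool = False  # sensitivity: VL modelled as log10 copies/mL

    def models(self) -> dict[str, FittedModel]:
        return {"cd4": self.cd4, "vl": self.vl, "trt": self.trt, "death": self.death}

    def to_json(self, path) -> None:
        payload = {}
        for name, m in self.models().items():
            payload[name] = {
                "kind": m.kind,
                "outcome": m.outcome,
                "features": m.features,
                "params": m.params,
                "bse": m.bse,
                "sd": m.sd,
                "nobs": m.nobs,
                "flags": list(m.flags),
            }
        payload["vl_threshold"] = self.vl_threshold
        payload["cd4_binary"] = self.cd4_binary
        payload["vl_continuous"] = self.vl_continuous
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass(frozen=True)
class Strategy:
    """Declarative regimen-switch intervention.

    modes
    -----
    natural
        No intervention: the regimen is drawn from the fitted switch model
        (one-way NNRTI -> PI; PI is absorbing).
    static
        ``static_regimen`` at every interval including entry.
    dynamic
        Keep the person's own regimen until the trigger (CD4 below
        ``trigger_cd4``) fires, then ``triggered_regimen`` forever.
    """

    name: str
    mode: str  # "natural" | "static" | "dynamic"
    static_regimen: str | None = None
    trigger_cd4: float | None = None
    triggered_regimen: str | None = None

    def __post_init__(self):
        if self.mode not in ("natural", "static", "dynamic"):
            raise ValueError(f"unknown strategy mode {self.mode!r}")
        if self.mode == "static" and self.static_regimen not in ("NNRTI", "PI"):
            raise ValueError("static strategy requires static_regimen in {NNRTI, PI}")
        if self.mode == "dynamic" and (
            self.trigger_cd4 is None or self.triggered_regimen not in ("NNRTI", "PI")
        ):
            raise ValueError("dynamic strategy requires trigger_cd4 and triggered_regimen")
        if self.mode != "static" and self.static_regimen is not None:
            raise ValueError("static_regimen only valid in static mode")
        if self.mode != "dynamic" and (
            self.trigger_cd4 is not None or self.triggered_regimen is not None
        ):
            raise ValueError("trigger fields only valid in dynamic mode")

    @classmethod
    def natural(cls) -> "Strategy":
        return cls(name="natural_course", mode="natural")

    @classmethod
    def static(cls, regimen: str) -> "Strategy":
        return cls(name=f"immediate_{regimen}", mode="static", static_regimen=regimen)

    @classmethod
    def cd4_triggered(cls, threshold: float = CD4_THRESHOLD, regimen: str = "PI") -> "Strategy":
        return cls(
            name=f"{regimen}_if_cd4_lt_{int(threshold)}",
            mode="dynamic",
            trigger_cd4=float(threshold),
            triggered_regimen=regimen,
        )


def default_strategies() -> list[Strategy]:
    """The four study scenarios: natural course, immediate NNRTI, immediate PI,
    and switch to PI once CD4 < 200 cells/uL."""
    return [
        Strategy.natural(),
        Strategy.static("NNRTI"),
        Strategy.static("PI"),
        Strategy.cd4_triggered(200.0, "PI"),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo simulation settings."""

    n_mc: int = 10_000
    horizon_K: int = 10
    seed: int = 0
    vl_threshold: float = VL_THRESHOLD
    vl_as_continuous: bool = False
    toy_mode: bool = False
    cd4_sqrt_scale: bool = True  # CD4 transition model on the square-root scale

    def __post_init__(self):
        if self.n_mc < 1000:
            raise ValueError("n_mc must be at least 1000")
        if self.horizon_K < 5:
            raise ValueError("horizon_K must be at least 5")


@dataclass
class RiskCurve:
    """Cumulative mortality risk by interval plus simulated covariate means.

    ``risk_by_k[k]`` is the cumulative death probability through interval k
    (index 0 is entry, risk 0).  ``covariate_means`` holds per-interval means
    among survivors: CD4, high-VL fraction, PI fraction, alive fraction.
    """

    risk_by_k: np.ndarray
    covariate_means: pd.DataFrame
    strategy: str = ""
    n_mc: int = 0

    def risk_at(self, k: int) -> float:
        return float(self.risk_by_k[k])

    @property
    def risk_5yr(self) -> float:
        return self.risk_at(5) if len(self.risk_by_k) > 5 else self.risk_at(len(self.risk_by_k) - 1)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class FitError(RuntimeError):
    """A pooled model could not be fitted (e.g. no death events)."""


def _fit_glm(y: np.ndarray, X: np.ndarray, features: list[str], kind: str,
             outcome: str) -> FittedModel:
    flags: list[str] = []
    y = np.asarray(y, dtype=float)
    # columns without variation (e.g. a dummy level absent from a bootstrap
    # resample) are unidentified: exclude from the fit, report coefficient 0
    keep = [j for j, f in enumerate(features)
            if f == "const" or np.ptp(X[:, j]) > 0]
    dropped = [f for j, f in enumerate(features) if j not in keep]
    if dropped:
        flags.extend(f"dropped:{f}" for f in dropped)
        X = X[:, keep]
        kept_features = [features[j] for j in keep]
    else:
        kept_features = features

    def _expand(values, fill) -> dict[str, float]:
        out = dict.fromkeys(features, fill)
        out.update(dict(zip(kept_features, np.asarray(values, dtype=float))))
        return out

    if kind == "logistic":
        if y.min() == y.max():
            return FittedModel(kind, outcome, features, None, nobs=len(y),
                               flags=("degenerate",))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                except (PerfectSeparationError, np.linalg.LinAlgError):
                    res = sm.Logit(y, X).fit(disp=0, maxiter=300, method="bfgs")
            if not res.mle_retvals.get("converged", True):
                flags.append("not_converged")
            # quasi-separation: an empirical cell with outcome probability 0/1;
            # the saturated prediction is kept, Wald SEs are unreliable
            if np.abs(np.asarray(res.params)).max() > 15 \
                    or not np.all(np.isfinite(np.asarray(res.bse))):
                flags.append("quasi_separation")
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return FittedModel(kind, outcome, features, None, nobs=len(y),
                               flags=("degenerate", "separation"))
        params = _expand(res.params, 0.0)
        bse = _expand(res.bse, np.nan)
        return FittedModel(kind, outcome, features, params, bse,
                           nobs=len(y), flags=tuple(flags))
    res = sm.OLS(y, X).fit()
    sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    params = _expand(res.params, 0.0)
    bse = _expand(res.bse, np.nan)
    if sd <= 0:
        flags.append("zero_residual_sd")
    return FittedModel(kind, outcome, features, params, bse, sd=sd,
                       nobs=len(y), flags=tuple(flags))


def fit_models(cohort: Cohort, config: SimConfig, specs: dict[str, list[str]] | None = None
               ) -> ModelSet:
    """Fit the four pooled regressions on the person-interval table (k >= 1).

    Requires complete CD4/VL (run imputation first).  The treatment model is
    fit only on intervals still on NNRTI at k-1 (the at-risk-of-switch set).
    Raises :class:`FitError` if the death model has no events.
    """
    if specs is None:
        if config.toy_mode:
            specs = TOY_SPECS
        elif config.vl_as_continuous:
            specs = CONTINUOUS_VL_SPECS
        else:
            specs = DEFAULT_SPECS
    pooled, state = design.pooled_frame(cohort)
    if np.isnan(state["cd4"]).any() or np.isnan(state["lag_cd4"]).any():
        raise FitError("cohort has missing CD4; impute before fitting")
    if np.isnan(state["vl"]).any() or np.isnan(state["lag_vl"]).any():
        raise FitError("cohort has missing viral load; impute before fitting")

    died = pooled["died"].to_numpy(dtype=float)
    if died.sum() == 0:
        raise FitError("no death events in the pooled table; cannot fit hazard model")

    if config.toy_mode:
        cd4_kind, cd4_y, cd4_name = "logistic", state["cd4_high"], "cd4_high"
    elif config.cd4_sqrt_scale:
        cd4_kind, cd4_y, cd4_name = "linear", state["cd4_sqrt"], "cd4_sqrt"
    else:
        cd4_kind, cd4_y, cd4_name = "linear", state["cd4"], "cd4"
    cd4_model = _fit_glm(cd4_y, design_matrix(state, specs["cd4"]), specs["cd4"],
                         cd4_kind, cd4_name)

    if config.vl_as_continuous:
        vl_model = _fit_glm(state["log10vl"], design_matrix(state, specs["vl"]),
                            specs["vl"], "linear", "log10vl")
    else:
        vl_model = _fit_glm(state["vl_high"], design_matrix(state, specs["vl"]),
                            specs["vl"], "logistic", "vl_high")

    at_risk = state["lag_pi"] == 0.0
    trt_state = {k: v[at_risk] for k, v in state.items()}
    trt_model = _fit_glm(state["pi"][at_risk], design_matrix(trt_state, specs["trt"]),
                         specs["trt"], "logistic", "pi")

    death_model = _fit_glm(died, design_matrix(state, specs["death"]), specs["death"],
                           "logistic", "died")
    if death_model.degenerate:
        raise FitError("death hazard model is degenerate (separation or no variation)")

    return ModelSet(cd4=cd4_model, vl=vl_model, trt=trt_model, death=death_model,
                    vl_threshold=config.vl_threshold, cd4_binary=config.toy_mode,
                    cd4_sqrt=(config.cd4_sqrt_scale and not config.toy_mode),
                    vl_continuous=config.vl_as_continuous)


# ---------------------------------------------------------------------------
# strategies / simulation
# ---------------------------------------------------------------------------


def apply_strategy(strategy: Strategy, state: dict[str, np.ndarray],
                   trt_model: FittedModel, rng: np.random.Generator,
                   lag_pi: np.ndarray, trigger: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Assign the current-interval regimen for every simulated individual.

    ``state`` carries the current CD4/VL features; ``lag_pi`` is the previous
    regimen indicator and ``trigger`` the (absorbing) dynamic-trigger memory.
    Returns ``(pi, trigger)`` as float arrays.
    """
    if strategy.mode == "static":
        pi = np.full(lag_pi.shape, 1.0 if strategy.static_regimen == "PI" else 0.0)
        return pi, trigger
    if strategy.mode == "dynamic":
        fired = trigger.astype(bool) | (np.asarray(state["cd4"], dtype=float)
                                        < strategy.trigger_cd4)
        target = 1.0 if strategy.triggered_regimen == "PI" else 0.0
        pi = np.where(fired, target, lag_pi)
        return pi.astype(float), fired.astype(float)
    # natural course: one-way NNRTI -> PI switch drawn from the fitted model
    if trt_model is None or trt_model.degenerate:
        # nobody switched in the fitting data: natural course keeps regimens
        return lag_pi.astype(float), trigger
    p_switch = trt_model.mean(state)
    switch = rng.random(lag_pi.shape) < p_switch
    pi = np.where(lag_pi == 1.0, 1.0, switch.astype(float))
    return pi, trigger


def _initial_regimen(strategy: Strategy, cd4_0: np.ndarray, observed_pi: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    trigger = np.zeros(len(cd4_0))
    if strategy.mode == "static":
        return np.full(len(cd4_0), 1.0 if strategy.static_regimen == "PI" else 0.0), trigger
    if strategy.mode == "dynamic":
        fired = cd4_0 < strategy.trigger_cd4
        target = 1.0 if strategy.triggered_regimen == "PI" else 0.0
        return np.where(fired, target, observed_pi).astype(float), fired.astype(float)
    return observed_pi.astype(float), trigger


def simulate(models: ModelSet, baseline_pool: pd.DataFrame, strategy: Strategy,
             config: SimConfig, rng: np.random.Generator | int | None = None) -> RiskCurve:
    """Monte Carlo g-formula simulation of one strategy.

    ``baseline_pool`` is a one-row-per-person frame of interval-0 records
    (as returned by :meth:`Cohort.baseline`); individuals are drawn from it
    with replacement, preserving the joint baseline distribution.  Death is
    simulated from interval 1 onward.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    if len(baseline_pool) == 0:
        raise ValueError("baseline pool is empty")

    n = config.n_mc
    idx = rng.integers(0, len(baseline_pool), size=n)
    base = baseline_pool.iloc[idx].reset_index(drop=True)
    dummies = baseline_dummies(base)
    fixed = {c: dummies[c].to_numpy(dtype=float) for c in dummies.columns}

    cd4 = base["cd4"].to_numpy(dtype=float)
    vl = base["vl"].to_numpy(dtype=float)
    observed_pi = (base["regimen"] == "PI").to_numpy(dtype=float)
    if models.cd4_binary:
        cd4 = np.where(cd4 >= CD4_THRESHOLD, TOY_CD4_VALUES[1], TOY_CD4_VALUES[0])
        vl = np.where(vl >= models.vl_threshold, TOY_VL_VALUES[1], TOY_VL_VALUES[0])
    pi, trigger = _initial_regimen(strategy, cd4, observed_pi)

    alive = np.ones(n, dtype=bool)
    risk = np.zeros(config.horizon_K + 1)
    means = [{"k": 0, "cd4_mean": float(cd4.mean()),
              "vl_high_frac": float((vl >= models.vl_threshold).mean()),
              "pi_frac": float(pi.mean()), "alive_frac": 1.0}]

    for k in range(1, config.horizon_K + 1):
        lag_state = derived_state({
            "k": np.full(n, float(k)), "lag_cd4": cd4, "lag_vl": vl,
            "lag_pi": pi, **fixed,
        })
        # CD4 update
        if models.cd4_binary:
            p_hi = models.cd4.mean(lag_state)
            hi = rng.random(n) < p_hi
            cd4_new = np.where(hi, TOY_CD4_VALUES[1], TOY_CD4_VALUES[0])
        else:
            mu = models.cd4.eta(lag_state)
            draw = mu + models.cd4.sd * rng.standard_normal(n)
            if models.cd4_sqrt:
                cd4_new = np.maximum(draw, 0.0) ** 2
            else:
                cd4_new = np.maximum(draw, 0.0)
        # VL update
        if models.vl_continuous:
            l10 = models.vl.eta(lag_state) + models.vl.sd * rng.standard_normal(n)
            vl_new = np.power(10.0, np.clip(l10, 0.0, 9.0))
        else:
            p_hi = models.vl.mean(lag_state)
            hi = rng.random(n) < p_hi
            if models.cd4_binary:
                vl_new = np.where(hi, TOY_VL_VALUES[1], TOY_VL_VALUES[0])
            else:
                vl_new = np.where(hi, models.vl_threshold * 10.0, models.vl_threshold / 10.0)
        cur_state = derived_state({
            "k": np.full(n, float(k)), "cd4": cd4_new, "vl": vl_new, **fixed,
        })
        # regimen decision, then death from the current state
        pi_new, trigger = apply_strategy(strategy, cur_state, models.trt, rng, pi, trigger)
        cur_state["pi"] = pi_new
        p_death = models.death.mean(cur_state)
        dies = alive & (rng.random(n) < p_death)
        alive = alive & ~dies

        cd4, vl, pi = cd4_new, vl_new, pi_new
        risk[k] = 1.0 - alive.mean()
        a = alive
        means.append({
            "k": k,
            "cd4_mean": float(cd4[a].mean()) if a.any() else np.nan,
            "vl_high_frac": float((vl[a] >= models.vl_threshold).mean()) if a.any() else np.nan,
            "pi_frac": float(pi[a].mean()) if a.any() else np.nan,
            "alive_frac": float(a.mean()),
        })

    return RiskCurve(risk_by_k=risk, covariate_means=pd.DataFrame(means),
                     strategy=strategy.name, n_mc=n)


def cumulative_risk(hazards: np.ndarray) -> np.ndarray:
    """Discrete-time identity risk_k = 1 - prod_{j<=k} (1 - h_j)."""
    h = np.asarray(hazards, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("hazards must lie in [0, 1]")
    return 1.0 - np.cumprod(1.0 - h)


def zero_treatment_effects(models: ModelSet) -> ModelSet:
    """Return a copy with the regimen's effect removed from every pathway to
    death (PI coefficients zeroed in the death, CD4 and VL models) — the
    no-effect null under which all strategies share one risk curve."""
    def _strip(m: FittedModel) -> FittedModel:
        if m.params is None:
            return m
        params = {f: (0.0 if f in ("pi", "lag_pi") else b) for f, b in m.params.items()}
        return replace(m, params=params)

    return ModelSet(cd4=_strip(models.cd4), vl=_strip(models.vl), trt=models.trt,
                    death=_strip(models.death), vl_threshold=models.vl_threshold,
                    cd4_binary=models.cd4_binary, cd4_sqrt=models.cd4_sqrt,
                    vl_continuous=models.vl_continuous)
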