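"""Synthetic longitudinal cohort generator with known ground truth.

The generator emulates the structure of an annual-visit ART cohort of people
with NNRTI drug resistance: baseline covariates drawn from the study-scale
frequency table, time-varying CD4 / viral load / regimen whose transitions
depend on the lagged state and the previous regimen, a one-way NNRTI -> PI
switch process, and death as an absorbing outcome driven by the current
state.  All structural coefficients are explicit, so every downstream stage
(model fitting, g-formula simulation, bootstrap, imputation) can be tested
against known truth.

Two modes are supported:

``continuous``
    CD4 in cells/uL with Gaussian innovations, viral load as a continuous
    log10 value dichotomised at 10,000 copies/mL, staggered administrative
    follow-up of 6-9 annual intervals (entry over several calendar years,
    fixed study end).

``toy``
    CD4 and VL reduced to binary states ({low, high} / {suppressed, high})
    with logistic transitions, so the counterfactual risk under any strategy
    can be computed *exactly* by dynamic programming over the state
    distribution (:func:`exact_risk`) — the oracle used to validate the
    Monte Carlo engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import COLUMNS, Cohort
from .design import VL_THRESHOLD, baseline_dummies, derived_state, linear_predictor
from .gformula import TOY_CD4_VALUES, TOY_VL_VALUES, FittedModel, ModelSet, Strategy

__all__ = [
    "GeneratorParams",
    "TruthRecord",
    "ParameterError",
    "generate_cohort",
    "inject_missingness",
    "exact_risk",
    "ExactRisk",
    "true_model_set",
    "toy_baseline_frame",
]


class ParameterError(ValueError):
    """Invalid generator parameter; the message names the field."""


#: Baseline categorical frequencies at study scale (cohort descriptive table).
DEFAULT_BASELINE_FREQS: dict[str, dict[str, float]] = {
    "gender": {"male": 0.771, "female": 0.229},
    "education": {"none": 0.050, "primary_or_junior": 0.704, "senior_or_more": 0.246},
    "marital": {"married": 0.503, "other": 0.497},
    "transmission": {"heterosexual": 0.726, "homosexual": 0.201, "other": 0.073},
    "std_history": {"yes": 0.106, "no": 0.665, "unknown": 0.229},
    "tb_history": {"yes": 0.101, "no": 0.899},
    "subtype": {"CRF01_AE": 0.615, "CRF07_BC": 0.279, "other": 0.106},
}

# Structural coefficients of the continuous-mode data mechanism.  Feature
# names refer to the shared design registry; CD4 enters logistic models per
# 100 cells, age as (age-45)/10.  Chosen once to echo the study setting:
# ~81% baseline CD4 < 200 cells/uL, ~64% baseline VL >= 10,000 copies/mL,
# higher hazard at low CD4 / high VL, protective PI regimen, 5-year
# natural-course mortality risk near 10%.
# CD4 transition model on the square-root scale (sqrt cells/uL).
DEFAULT_CD4_COEF = {"const": 2.8, "lag_cd4_sqrt": 0.85, "lag_vl_high": -1.3,
                    "lag_pi": 0.9, "age_c": -0.4}
DEFAULT_CD4_SD = 2.5
DEFAULT_VL_COEF = {"const": 0.3, "lag_cd4_100": -0.10, "lag_vl_high": 1.5, "lag_pi": -2.0}
DEFAULT_TRT_COEF = {"const": -1.7, "cd4_100": -0.25, "vl_high": 0.6}
DEFAULT_DEATH_COEF = {"const": -3.0, "cd4_100": -0.30, "vl_high": 0.6,
                      "pi": -0.9, "age_c": 0.35}

# Toy-mode logistic coefficients over binary states.
TOY_CD4_COEF = {"const": -1.2, "lag_cd4_high": 2.2, "lag_vl_high": -0.6, "lag_pi": 1.0}
TOY_VL_COEF = {"const": 0.2, "lag_cd4_high": -0.4, "lag_vl_high": 1.4, "lag_pi": -1.8}
TOY_TRT_COEF = {"const": -1.5, "cd4_high": -0.7, "vl_high": 0.5}
TOY_DEATH_COEF = {"const": -3.3, "cd4_high": -1.1, "vl_high": 0.7, "pi": -0.9}

_ALLOWED_FEATURES = {
    "const", "k", "age_c", "female", "edu_none", "edu_senior", "marital_other",
    "trans_homo", "trans_other", "std_yes", "std_unknown", "tb_yes",
    "cd4_100", "cd4_sqrt", "cd4_high", "vl_high", "log10vl", "pi",
    "lag_cd4_100", "lag_cd4_sqrt", "lag_cd4_high", "lag_vl_high", "lag_log10vl", "lag_pi",
}


def _sigmoid(x):
    return expit(x)


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterisation of the synthetic data mechanism."""

    n: int = 179
    K_max: int = 10
    seed: int = 0
    mode: str = "continuous"  # "continuous" | "toy"
    baseline_freqs: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                          DEFAULT_BASELINE_FREQS.items()})
    # continuous-mode baseline state distribution
    age_mean: float = 40.0
    age_sd: float = 12.0
    baseline_cd4_mean: float = 120.0  # exponential mean -> ~81% below 200
    baseline_log10vl_mean: float = 4.35  # -> ~64% at/above 10,000 copies/mL
    baseline_log10vl_sd: float = 1.0
    p_pi0: float = 0.441  # fraction switching straight to a PI regimen at entry
    # follow-up: administrative end after fu_min..fu_max annual intervals
    fu_min: int = 6
    fu_max: int = 9
    dropout_rate: float = 0.02  # per-interval mid-interval loss to follow-up
    # transition / outcome coefficients (feature name -> value)
    cd4_coef: dict = field(default_factory=lambda: dict(DEFAULT_CD4_COEF))
    cd4_sd: float = DEFAULT_CD4_SD
    vl_coef: dict = field(default_factory=lambda: dict(DEFAULT_VL_COEF))
    trt_coef: dict = field(default_factory=lambda: dict(DEFAULT_TRT_COEF))
    death_coef: dict = field(default_factory=lambda: dict(DEFAULT_DEATH_COEF))
    # toy-mode baseline state probabilities
    p_cd4_high0: float = 0.2
    p_vl_high0: float = 0.65
    # missingness of post-baseline CD4
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"  # "MCAR" | "MAR_on_VL"
    mar_vl_odds: float = 2.0  # odds multiplier of masking when VL is high

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if self.K_max < 1:
            raise ParameterError("K_max must be >= 1")
        if self.mode not in ("continuous", "toy"):
            raise ParameterError(f"mode must be 'continuous' or 'toy', got {self.mode!r}")
        for var, freqs in self.baseline_freqs.items():
            s = sum(freqs.values())
            if abs(s - 1.0) > 1e-9:
                raise ParameterError(f"baseline_freqs[{var!r}] sums to {s}, not 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in ("MCAR", "MAR_on_VL"):
            raise ParameterError(f"unknown missing_mechanism {self.missing_mechanism!r}")
        if self.cd4_sd <= 0 or self.age_sd <= 0 or self.baseline_log10vl_sd <= 0:
            raise ParameterError("all SDs must be positive")
        if not (1 <= self.fu_min <= self.fu_max):
            raise ParameterError("need 1 <= fu_min <= fu_max")
        for name in ("cd4_coef", "vl_coef", "trt_coef", "death_coef"):
            bad = set(getattr(self, name)) - _ALLOWED_FEATURES
            if bad:
                raise ParameterError(f"{name} has unknown feature(s) {sorted(bad)}")

    def with_toy_defaults(self) -> "GeneratorParams":
        """Copy with toy-mode defaults for the four coefficient vectors."""
        return replace(self, mode="toy", cd4_coef=dict(TOY_CD4_COEF),
                       vl_coef=dict(TOY_VL_COEF), trt_coef=dict(TOY_TRT_COEF),
                       death_coef=dict(TOY_DEATH_COEF))


@dataclass
class TruthRecord:
    """Generator parameters together with exact per-strategy risk curves."""

    params: GeneratorParams
    risks: dict[str, np.ndarray]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({name: list(map(float, r)) for name, r in self.risks.items()},
                      fh, indent=2)


# ---------------------------------------------------------------------------
# baseline sampling
# ---------------------------------------------------------------------------


def _sample_baseline(params: GeneratorParams, size: int, rng: np.random.Generator
                     ) -> pd.DataFrame:
    base = pd.DataFrame(index=range(size))
    for var, freqs in params.baseline_freqs.items():
        levels = list(freqs)
        base[var] = rng.choice(levels, size=size, p=[freqs[l] for l in levels])
    age = np.clip(np.round(params.age_mean + params.age_sd * rng.standard_normal(size)),
                  16, 80)
    base["age_years"] = age.astype(float)
    if params.mode == "toy":
        cd4h = rng.random(size) < params.p_cd4_high0
        vlh = rng.random(size) < params.p_vl_high0
        base["cd4"] = np.where(cd4h, TOY_CD4_VALUES[1], TOY_CD4_VALUES[0])
        base["vl"] = np.where(vlh, TOY_VL_VALUES[1], TOY_VL_VALUES[0])
    else:
        cd4 = np.clip(rng.exponential(params.baseline_cd4_mean, size=size), 1, 1200)
        base["cd4"] = np.round(cd4)
        l10 = params.baseline_log10vl_mean + params.baseline_log10vl_sd * \
            rng.standard_normal(size)
        base["vl"] = np.round(np.power(10.0, np.clip(l10, 1.7, 7.0)))
    base["regimen"] = np.where(rng.random(size) < params.p_pi0, "PI", "NNRTI")
    return base


def toy_baseline_frame(params: GeneratorParams, size: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    """A baseline pool drawn from the toy theoretical distribution, suitable
    as the ``baseline_pool`` argument of :func:`artswitch.gformula.simulate`."""
    if params.mode != "toy":
        raise ParameterError("toy_baseline_frame requires mode='toy'")
    base = _sample_baseline(params, size, rng)
    base["k"] = 0
    return base


def _draw_vl_numeric(high: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Continuous log10 viral load consistent with the drawn binary level.

    The binary suppression state is the structural variable; the continuous
    value is drawn from a half-normal offset on the appropriate side of the
    10,000 copies/mL threshold (retained for the continuous-VL sensitivity
    analysis)."""
    n = len(high)
    up = 4.0 + np.abs(rng.normal(0.6, 0.5, size=n))
    down = 4.0 - np.abs(rng.normal(0.8, 0.6, size=n))
    l10 = np.where(high, up, np.clip(down, 1.7, None))
    return np.round(np.power(10.0, np.clip(l10, 1.7, 7.0)))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Simulate a cohort from the structural model; deterministic under seed.

    Within interval k >= 1 the sampling order is CD4 | history, VL | history,
    regimen | current state (one-way NNRTI -> PI in the natural course), then
    death | current state.  Interval 0 is the entry interval: observed state,
    no death.  Administrative follow-up ends after a per-person number of
    intervals (uniform ``fu_min..fu_max``, capped at ``K_max``); mid-interval
    dropout is marked ``censored=1`` and ends follow-up.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    base = _sample_baseline(params, n, rng)
    dummies = baseline_dummies(base)
    fixed = {c: dummies[c].to_numpy(dtype=float) for c in dummies.columns}

    if params.mode == "toy":
        K_i = np.full(n, params.K_max)
        dropout = 0.0
    else:
        K_i = np.minimum(rng.integers(params.fu_min, params.fu_max + 1, size=n),
                         params.K_max)
        dropout = params.dropout_rate

    cd4 = base["cd4"].to_numpy(dtype=float)
    vl = base["vl"].to_numpy(dtype=float)
    pi = (base["regimen"] == "PI").to_numpy(dtype=float)

    person_ids = np.array([f"p{i:05d}" for i in range(n)])
    rows = [_records_at_k(base, person_ids, 0, cd4, vl, pi,
                          died=np.zeros(n, bool), censored=np.zeros(n, bool),
                          mask=np.ones(n, bool))]
    in_followup = np.ones(n, bool)  # neither dead nor censored so far

    for k in range(1, params.K_max + 1):
        in_k = in_followup & (K_i > k)  # contributes a record at interval k
        if not in_k.any():
            break
        lag_state = derived_state({"k": np.full(n, float(k)), "lag_cd4": cd4,
                                   "lag_vl": vl, "lag_pi": pi, **fixed})
        if params.mode == "toy":
            hi = rng.random(n) < _sigmoid(linear_predictor(lag_state, params.cd4_coef))
            cd4_new = np.where(hi, TOY_CD4_VALUES[1], TOY_CD4_VALUES[0])
            vhi = rng.random(n) < _sigmoid(linear_predictor(lag_state, params.vl_coef))
            vl_new = np.where(vhi, TOY_VL_VALUES[1], TOY_VL_VALUES[0])
        else:
            # square-root scale draw, floored at 0, squared back to cells/uL
            mu = linear_predictor(lag_state, params.cd4_coef)
            draw = np.maximum(mu + params.cd4_sd * rng.standard_normal(n), 0.0)
            cd4_new = np.round(draw ** 2)
            vhi = rng.random(n) < _sigmoid(linear_predictor(lag_state, params.vl_coef))
            vl_new = _draw_vl_numeric(vhi, rng)
        cur_state = derived_state({"k": np.full(n, float(k)), "cd4": cd4_new,
                                   "vl": vl_new, **fixed})
        p_switch = _sigmoid(linear_predictor(cur_state, params.trt_coef))
        pi_new = np.where(pi == 1.0, 1.0, (rng.random(n) < p_switch).astype(float))
        cur_state["pi"] = pi_new
        p_death = _sigmoid(linear_predictor(cur_state, params.death_coef))
        dies = rng.random(n) < p_death
        drops = rng.random(n) < dropout  # mid-interval loss, checked before death

        cd4, vl, pi = cd4_new, vl_new, pi_new
        cens_k = in_k & drops
        died_k = in_k & ~drops & dies
        rows.append(_records_at_k(base, person_ids, k, cd4, vl, pi,
                                  died=died_k, censored=cens_k, mask=in_k))
        in_followup = in_followup & ~(died_k | cens_k)

    df = pd.concat(rows, ignore_index=True)
    cohort = Cohort.from_frame(df, validate=False)
    if params.missing_rate > 0:
        cohort = inject_missingness(cohort, params.missing_rate,
                                    params.missing_mechanism,
                                    seed=int(rng.integers(2**31 - 1)),
                                    mar_vl_odds=params.mar_vl_odds)
    return cohort


def _records_at_k(base: pd.DataFrame, person_ids: np.ndarray, k: int,
                  cd4: np.ndarray, vl: np.ndarray, pi: np.ndarray,
                  died: np.ndarray, censored: np.ndarray, mask: np.ndarray
                  ) -> pd.DataFrame:
    idx = np.flatnonzero(mask)
    rec = pd.DataFrame({
        "person_id": person_ids[idx],
        "k": k,
        "age_years": base["age_years"].to_numpy()[idx],
        "gender": base["gender"].to_numpy()[idx],
        "education": base["education"].to_numpy()[idx],
        "marital": base["marital"].to_numpy()[idx],
        "transmission": base["transmission"].to_numpy()[idx],
        "std_history": base["std_history"].to_numpy()[idx],
        "tb_history": base["tb_history"].to_numpy()[idx],
        "subtype": base["subtype"].to_numpy()[idx],
        "cd4": cd4[idx],
        "vl": vl[idx],
        "regimen": np.where(pi[idx] == 1.0, "PI", "NNRTI"),
        "died": died[idx].astype(int),
        "censored": censored[idx].astype(int),
    })
    return rec[COLUMNS]


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------


def inject_missingness(cohort: Cohort, rate: float, mechanism: str = "MCAR",
                       seed: int = 0, mar_vl_odds: float = 2.0) -> Cohort:
    """Mask post-baseline CD4 values (baseline CD4 is never masked).

    Under MCAR every post-baseline CD4 is masked with probability ``rate``.
    Under MAR_on_VL the masking odds are multiplied by ``mar_vl_odds`` when
    the concurrent viral load is at/above the 10,000 copies/mL threshold.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if mechanism not in ("MCAR", "MAR_on_VL"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if rate == 0.0:
        return cohort
    df = cohort.frame.copy()
    post = df["k"] >= 1
    if df.loc[post, "cd4"].isna().any():
        raise ValueError("cohort already has missing post-baseline CD4")
    rng = np.random.default_rng(seed)
    if mechanism == "MCAR":
        p = np.full(post.sum(), rate)
    else:
        odds = rate / (1.0 - rate)
        vl_high = (df.loc[post, "vl"] >= VL_THRESHOLD).to_numpy()
        o = np.where(vl_high, mar_vl_odds * odds, odds)
        p = o / (1.0 + o)
    mask = rng.random(post.sum()) < p
    col = df.columns.get_loc("cd4")
    idx = np.flatnonzero(post.to_numpy())[mask]
    df.iloc[idx, col] = np.nan
    return Cohort.from_frame(df, validate=False)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def true_model_set(params: GeneratorParams) -> ModelSet:
    """Package the generator's structural coefficients as a ModelSet, so the
    Monte Carlo engine can be run from known truth (no fitting)."""
    toy = params.mode == "toy"
    cd4 = FittedModel("logistic" if toy else "linear",
                      "cd4_high" if toy else "cd4_sqrt",
                      list(params.cd4_coef), dict(params.cd4_coef),
                      sd=None if toy else params.cd4_sd)
    vl = FittedModel("logistic", "vl_high", list(params.vl_coef), dict(params.vl_coef))
    trt = FittedModel("logistic", "pi", list(params.trt_coef), dict(params.trt_coef))
    death = FittedModel("logistic", "died", list(params.death_coef),
                        dict(params.death_coef))
    return ModelSet(cd4=cd4, vl=vl, trt=trt, death=death, cd4_binary=toy,
                    cd4_sqrt=not toy)


class ModeError(RuntimeError):
    """Exact enumeration requested for a continuous-state system."""


@dataclass
class ExactRisk:
    """Risk curve from the oracle; ``se`` is None in exact enumeration mode."""

    risk_by_k: np.ndarray
    se: np.ndarray | None = None

    def risk_at(self, k: int) -> float:
        return float(self.risk_by_k[k])


def exact_risk(params: GeneratorParams, strategy: Strategy, horizon: int,
               method: str = "auto", n_mc: int = 1_000_000, seed: int = 12345
               ) -> ExactRisk:
    """Counterfactual cumulative risk under ``strategy`` from the true model.

    In toy mode the risk is computed exactly by forward dynamic programming
    over the joint distribution of the binary (CD4, VL, regimen, trigger)
    state — a summation over all covariate/treatment histories.  In
    continuous mode it is approximated by a large Monte Carlo run from the
    true coefficients (with its binomial standard error reported).
    """
    if method == "auto":
        method = "enumerate" if params.mode == "toy" else "mc"
    if method == "enumerate":
        if params.mode != "toy":
            raise ModeError("exact enumeration requires the toy discrete mode")
        return ExactRisk(risk_by_k=_toy_dp_risk(params, strategy, horizon))
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    risks = _mc_truth_risk(params, strategy, horizon, n_mc, seed)
    se = np.sqrt(np.maximum(risks * (1 - risks), 1e-12) / n_mc)
    se[0] = 0.0
    return ExactRisk(risk_by_k=risks, se=se)


def _toy_eta(coef: dict[str, float], c: float, v: float, p: float) -> float:
    return (coef.get("const", 0.0) + coef.get("lag_cd4_high", 0.0) * c
            + coef.get("lag_vl_high", 0.0) * v + coef.get("lag_pi", 0.0) * p
            + coef.get("cd4_high", 0.0) * c + coef.get("vl_high", 0.0) * v
            + coef.get("pi", 0.0) * p)


def _toy_dp_risk(params: GeneratorParams, strategy: Strategy, horizon: int
                 ) -> np.ndarray:
    """Exact forward recursion over the 16 binary (cd4, vl, pi, trigger) states."""
    from itertools import product

    sig = expit
    pi_target = 1.0 if strategy.mode != "static" else (
        1.0 if strategy.static_regimen == "PI" else 0.0)
    dyn_target = 1.0 if (strategy.mode == "dynamic"
                         and strategy.triggered_regimen == "PI") else 0.0

    # initial distribution: independent baseline states
    dist: dict[tuple, float] = {}
    for c0, v0, p0 in product((0.0, 1.0), repeat=3):
        w = ((params.p_cd4_high0 if c0 else 1 - params.p_cd4_high0)
             * (params.p_vl_high0 if v0 else 1 - params.p_vl_high0)
             * (params.p_pi0 if p0 else 1 - params.p_pi0))
        if w == 0:
            continue
        if strategy.mode == "static":
            key = (c0, v0, pi_target, 0.0)
        elif strategy.mode == "dynamic":
            # toy low CD4 (100 cells/uL) is below the 200-cell trigger
            trig = 1.0 if (TOY_CD4_VALUES[1] if c0 else TOY_CD4_VALUES[0]) \
                < strategy.trigger_cd4 else 0.0
            key = (c0, v0, dyn_target if trig else p0, trig)
        else:
            key = (c0, v0, p0, 0.0)
        dist[key] = dist.get(key, 0.0) + w

    dead = 0.0
    risk = np.zeros(horizon + 1)
    for k in range(1, horizon + 1):
        new: dict[tuple, float] = {}
        for (c, v, p, t), w in dist.items():
            pc = sig(_toy_eta(params.cd4_coef, c, v, p))
            pv = sig(_toy_eta(params.vl_coef, c, v, p))
            for c2 in (0.0, 1.0):
                for v2 in (0.0, 1.0):
                    w2 = w * (pc if c2 else 1 - pc) * (pv if v2 else 1 - pv)
                    if w2 == 0:
                        continue
                    branches: list[tuple[float, float, float]] = []  # (pi2, trig2, prob)
                    if strategy.mode == "static":
                        branches.append((pi_target, t, 1.0))
                    elif strategy.mode == "dynamic":
                        cd4_val = TOY_CD4_VALUES[1] if c2 else TOY_CD4_VALUES[0]
                        t2 = 1.0 if (t == 1.0 or cd4_val < strategy.trigger_cd4) else 0.0
                        branches.append((dyn_target if t2 else p, t2, 1.0))
                    else:
                        if p == 1.0:
                            branches.append((1.0, t, 1.0))
                        else:
                            ps = sig(_toy_eta(params.trt_coef, c2, v2, 0.0))
                            branches.append((1.0, t, ps))
                            branches.append((0.0, t, 1 - ps))
                    for p2, t2, pr in branches:
                        if pr == 0:
                            continue
                        pd_ = sig(_toy_eta(params.death_coef, c2, v2, p2))
                        dead += w2 * pr * pd_
                        key = (c2, v2, p2, t2)
                        new[key] = new.get(key, 0.0) + w2 * pr * (1 - pd_)
        dist = new
        risk[k] = dead
    return risk


def _mc_truth_risk(params: GeneratorParams, strategy: Strategy, horizon: int,
                   n_mc: int, seed: int) -> np.ndarray:
    """Large, self-contained Monte Carlo from the true coefficients.

    Written independently of the g-formula engine (its own state loop) so it
    can serve as a cross-check rather than a mirror of it."""
    rng = np.random.default_rng(seed)
    base = _sample_baseline(params, n_mc, rng)
    dummies = baseline_dummies(base)
    fixed = {c: dummies[c].to_numpy(dtype=float) for c in dummies.columns}
    cd4 = base["cd4"].to_numpy(dtype=float)
    vl = base["vl"].to_numpy(dtype=float)
    pi = (base["regimen"] == "PI").to_numpy(dtype=float)
    trigger = np.zeros(n_mc)
    if strategy.mode == "static":
        pi = np.full(n_mc, 1.0 if strategy.static_regimen == "PI" else 0.0)
    elif strategy.mode == "dynamic":
        trigger = (cd4 < strategy.trigger_cd4).astype(float)
        tgt = 1.0 if strategy.triggered_regimen == "PI" else 0.0
        pi = np.where(trigger == 1.0, tgt, pi)

    alive = np.ones(n_mc, bool)
    risk = np.zeros(horizon + 1)
    for k in range(1, horizon + 1):
        lag = derived_state({"k": np.full(n_mc, float(k)), "lag_cd4": cd4,
                             "lag_vl": vl, "lag_pi": pi, **fixed})
        if params.mode == "toy":
            hi = rng.random(n_mc) < _sigmoid(linear_predictor(lag, params.cd4_coef))
            cd4 = np.where(hi, TOY_CD4_VALUES[1], TOY_CD4_VALUES[0])
            vhi = rng.random(n_mc) < _sigmoid(linear_predictor(lag, params.vl_coef))
            vl = np.where(vhi, TOY_VL_VALUES[1], TOY_VL_VALUES[0])
        else:
            mu = linear_predictor(lag, params.cd4_coef)
            cd4 = np.maximum(mu + params.cd4_sd * rng.standard_normal(n_mc), 0.0) ** 2
            vhi = rng.random(n_mc) < _sigmoid(linear_predictor(lag, params.vl_coef))
            vl = np.where(vhi, VL_THRESHOLD * 10.0, VL_THRESHOLD / 10.0)
        cur = derived_state({"k": np.full(n_mc, float(k)), "cd4": cd4, "vl": vl, **fixed})
        if strategy.mode == "static":
            pass  # pi already fixed
        elif strategy.mode == "dynamic":
            trigger = np.maximum(trigger, (cd4 < strategy.trigger_cd4).astype(float))
            tgt = 1.0 if strategy.triggered_regimen == "PI" else 0.0
            pi = np.where(trigger == 1.0, tgt, pi)
        else:
            ps = _sigmoid(linear_predictor(cur, params.trt_coef))
            pi = np.where(pi == 1.0, 1.0, (rng.random(n_mc) < ps).astype(float))
        cur["pi"] = pi
        pd_ = _sigmoid(linear_predictor(cur, params.death_coef))
        alive = alive & ~(alive & (rng.random(n_mc) < pd_))
        risk[k] = 1.0 - alive.mean()
    return risk
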