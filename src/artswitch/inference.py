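"""Bootstrap inference, risk contrasts and natural-course diagnostics.

Point estimates of the 5-year risk under each strategy come from a single
g-formula run on the full cohort; confidence intervals are percentile
bootstrap (default 500 person-level resamples): each replicate resamples
persons with replacement, refits the four pooled models, resimulates every
strategy with a fresh simulation stream, and records the replicate's risk,
risk ratio and risk difference versus the natural course.  Replicates with a
degenerate fit (no deaths, separation) are dropped and counted; the run
fails loudly if more than 5% are dropped.

With multiply imputed data the point estimate is the mean of per-imputation
point estimates and replicate draws are pooled across imputations before
taking percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .gformula import (
    FitError,
    RiskCurve,
    SimConfig,
    Strategy,
    fit_models,
    simulate,
)

__all__ = [
    "BootstrapSpec",
    "ContrastResult",
    "BootstrapResult",
    "contrast",
    "bootstrap",
    "natural_course_diagnostics",
    "assemble_results",
    "estimate_contrasts",
    "parse_results_table",
]


@dataclass(frozen=True)
class BootstrapSpec:
    B: int = 500
    seed: int = 0
    ci_method: str = "percentile"
    max_dropped_frac: float = 0.05

    def __post_init__(self):
        if self.B < 50:
            raise ValueError("B must be >= 50")
        if self.ci_method != "percentile":
            raise ValueError("only the percentile CI method is implemented")


@dataclass
class ContrastResult:
    """One row of the results table: 5-year risk and contrasts vs natural course.

    Risks and risk differences are percents / percentage points; the natural
    course row carries rr=1, rd=0 exactly."""

    strategy: str
    risk_5yr: float
    risk_ci: tuple[float, float]
    rr: float
    rr_ci: tuple[float, float]
    rd: float
    rd_ci: tuple[float, float]
    is_reference: bool = False


def contrast(risk: float, ref_risk: float) -> tuple[float, float]:
    """Risk ratio and risk difference (percentage points) vs a reference risk."""
    rd = risk - ref_risk
    if ref_risk == 0:
        raise ZeroDivisionError(
            f"risk ratio undefined for zero reference risk (rd would be {rd})")
    return risk / ref_risk, rd


@dataclass
class BootstrapResult:
    """Replicate-level bootstrap draws, per strategy."""

    strategies: list[str]
    risk5: dict[str, np.ndarray]  # percent
    rr: dict[str, np.ndarray]
    rd: dict[str, np.ndarray]  # percentage points
    n_requested: int
    n_dropped: int

    def ci(self, which: str, strategy: str, level: float = 0.95
           ) -> tuple[float, float]:
        draws = getattr(self, which)[strategy]
        lo, hi = np.percentile(draws, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
        return float(lo), float(hi)


def _point_risks(cohort: Cohort, strategies: list[Strategy], config: SimConfig,
                 rng: np.random.Generator) -> tuple[dict[str, float], dict[str, RiskCurve]]:
    models = fit_models(cohort, config)
    pool = cohort.baseline()
    risks, curves = {}, {}
    for s in strategies:
        curve = simulate(models, pool, s, config, rng=rng)
        risks[s.name] = 100.0 * curve.risk_5yr
        curves[s.name] = curve
    return risks, curves


def bootstrap(cohort: Cohort, strategies: list[Strategy], sim_config: SimConfig,
              boot_spec: BootstrapSpec) -> BootstrapResult:
    """Person-level (cluster) percentile bootstrap of risk, RR and RD.

    Deterministic under ``boot_spec.seed``; each replicate gets its own
    resampling and simulation streams via seed-sequence spawning.
    """
    natural = [s for s in strategies if s.mode == "natural"]
    if not natural:
        raise ValueError("strategies must include the natural course (reference)")
    ref_name = natural[0].name

    ss = np.random.SeedSequence(boot_spec.seed)
    children = ss.spawn(boot_spec.B)
    risk5 = {s.name: [] for s in strategies}
    rr = {s.name: [] for s in strategies}
    rd = {s.name: [] for s in strategies}
    dropped = 0
    for b in range(boot_spec.B):
        rng = np.random.default_rng(children[b])
        resample = cohort.resample_persons(rng)
        if resample.frame["died"].sum() == 0:
            dropped += 1
            continue
        try:
            risks, _ = _point_risks(resample, strategies, sim_config, rng)
        except FitError:
            dropped += 1
            continue
        for s in strategies:
            r = risks[s.name]
            risk5[s.name].append(r)
            if s.name == ref_name:
                rr[s.name].append(1.0)
                rd[s.name].append(0.0)
            else:
                ratio, diff = contrast(r, risks[ref_name])
                rr[s.name].append(ratio)
                rd[s.name].append(diff)
    if dropped > boot_spec.max_dropped_frac * boot_spec.B:
        raise RuntimeError(
            f"{dropped}/{boot_spec.B} bootstrap replicates were degenerate "
            f"(> {100 * boot_spec.max_dropped_frac:.0f}%); refusing to report CIs")
    return BootstrapResult(
        strategies=[s.name for s in strategies],
        risk5={k: np.asarray(v) for k, v in risk5.items()},
        rr={k: np.asarray(v) for k, v in rr.items()},
        rd={k: np.asarray(v) for k, v in rd.items()},
        n_requested=boot_spec.B, n_dropped=dropped)


def estimate_contrasts(cohorts: Cohort | list[Cohort], strategies: list[Strategy],
                       sim_config: SimConfig, boot_spec: BootstrapSpec
                       ) -> tuple[list[ContrastResult], dict[str, RiskCurve], dict]:
    """Full step-2/step-3 estimation, optionally across multiple imputations.

    ``cohorts`` may be a single complete cohort or the list of imputed
    datasets; point estimates average over imputations and bootstrap draws
    are pooled across them before taking percentile bounds.  Returns the
    contrast rows, the point-estimate natural-course curves of the first
    dataset (for diagnostics/plots), and a small run manifest fragment.
    """
    if isinstance(cohorts, Cohort):
        cohorts = [cohorts]
    natural = [s for s in strategies if s.mode == "natural"]
    if not natural:
        raise ValueError("strategies must include the natural course (reference)")
    ref_name = natural[0].name

    point_runs = []
    curves0: dict[str, RiskCurve] = {}
    ss = np.random.SeedSequence(sim_config.seed)
    point_children = ss.spawn(len(cohorts))
    for i, c in enumerate(cohorts):
        risks, curves = _point_risks(c, strategies, sim_config,
                                     np.random.default_rng(point_children[i]))
        point_runs.append(risks)
        if i == 0:
            curves0 = curves
    point = {s.name: float(np.mean([r[s.name] for r in point_runs]))
             for s in strategies}

    boot_children = np.random.SeedSequence(boot_spec.seed).spawn(len(cohorts))
    pooled: dict[str, dict[str, list]] = {w: {s.name: [] for s in strategies}
                                          for w in ("risk5", "rr", "rd")}
    dropped = requested = 0
    for i, c in enumerate(cohorts):
        spec_i = BootstrapSpec(B=boot_spec.B, seed=int(boot_children[i].generate_state(1)[0]
                                                       % (2**31 - 1)),
                               max_dropped_frac=boot_spec.max_dropped_frac)
        res = bootstrap(c, strategies, sim_config, spec_i)
        requested += res.n_requested
        dropped += res.n_dropped
        for w in ("risk5", "rr", "rd"):
            for name in pooled[w]:
                pooled[w][name].append(getattr(res, w)[name])
    draws = {w: {name: np.concatenate(v) for name, v in d.items()}
             for w, d in pooled.items()}

    results = []
    for s in strategies:
        r = point[s.name]
        is_ref = s.name == ref_name
        if is_ref:
            rr_pt, rd_pt = 1.0, 0.0
        else:
            rr_pt, rd_pt = contrast(r, point[ref_name])
        pct = lambda a: tuple(float(x) for x in np.percentile(a, [2.5, 97.5]))
        results.append(ContrastResult(
            strategy=s.name, risk_5yr=r, risk_ci=pct(draws["risk5"][s.name]),
            rr=rr_pt, rr_ci=(1.0, 1.0) if is_ref else pct(draws["rr"][s.name]),
            rd=rd_pt, rd_ci=(0.0, 0.0) if is_ref else pct(draws["rd"][s.name]),
            is_reference=is_ref))
    manifest = {"bootstrap_requested": requested, "bootstrap_dropped": dropped,
                "n_imputations": len(cohorts)}
    return results, curves0, manifest


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def observed_interval_means(cohort: Cohort) -> pd.DataFrame:
    """Nonparametric per-interval means of the time-varying variables and the
    observed cumulative mortality (discrete product-limit over interval
    hazards, treating censoring as noninformative)."""
    df = cohort.frame
    K = int(df["k"].max())
    rows = []
    cum_surv = 1.0
    for k in range(K + 1):
        at_k = df[df["k"] == k]
        n_k = len(at_k)
        if n_k == 0:
            break
        if k >= 1:
            cum_surv *= 1.0 - at_k["died"].mean()
        rows.append({
            "k": k,
            "n": n_k,
            "cd4_mean": float(at_k["cd4"].mean()),
            "vl_high_frac": float((at_k["vl"] >= 10000).mean()),
            "pi_frac": float((at_k["regimen"] == "PI").mean()),
            "cum_mortality": 1.0 - cum_surv,
        })
    return pd.DataFrame(rows)


def natural_course_diagnostics(cohort: Cohort, natural_curve: RiskCurve
                               ) -> pd.DataFrame:
    """Observed vs g-formula-predicted means per interval, with absolute and
    relative differences — the standard check that the fitted parametric
    models reproduce the cohort they were fit to."""
    obs = observed_interval_means(cohort)
    sim = natural_curve.covariate_means.copy()
    sim["cum_mortality"] = natural_curve.risk_by_k[: len(sim)]
    merged = obs.merge(sim, on="k", suffixes=("_obs", "_sim"))
    for var in ("cd4_mean", "vl_high_frac", "pi_frac", "cum_mortality"):
        merged[f"{var}_absdiff"] = merged[f"{var}_sim"] - merged[f"{var}_obs"]
        denom = merged[f"{var}_obs"].replace(0, np.nan)
        merged[f"{var}_reldiff"] = merged[f"{var}_absdiff"] / denom
    return merged


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def assemble_results(contrasts: list[ContrastResult]) -> pd.DataFrame:
    """Format contrast rows as the study-style results table (2 dp), with the
    natural course printed as '1 (Ref)' / '0 (Ref)'."""
    if not any(c.is_reference for c in contrasts):
        raise ValueError("results require the natural-course reference row")
    rows = []
    for c in contrasts:
        rows.append({
            "strategy": c.strategy,
            "risk_5yr": _fmt(c.risk_5yr),
            "risk_95ci": f"({_fmt(c.risk_ci[0])}-{_fmt(c.risk_ci[1])})",
            "rr": "1 (Ref)" if c.is_reference else _fmt(c.rr),
            "rr_95ci": "" if c.is_reference else f"({_fmt(c.rr_ci[0])}-{_fmt(c.rr_ci[1])})",
            "rd": "0 (Ref)" if c.is_reference else _fmt(c.rd),
            "rd_95ci": "" if c.is_reference else f"({_fmt(c.rd_ci[0])}-{_fmt(c.rd_ci[1])})",
        })
    return pd.DataFrame(rows)


def parse_results_table(table: pd.DataFrame) -> list[ContrastResult]:
    """Inverse of :func:`assemble_results` (numeric round-trip at 2 dp)."""
    out = []
    for _, r in table.iterrows():
        is_ref = str(r["rr"]).endswith("(Ref)")
        ci = lambda s: tuple(float(x) for x in str(s).strip("()").split("-", 1)) \
            if s else (np.nan, np.nan)

        def _ci(s):
            if not s:
                return (np.nan, np.nan)
            body = str(s).strip("()")
            # split on the dash between the two numbers (careful with minus signs)
            for i in range(1, len(body)):
                if body[i] == "-" and body[i - 1].isdigit():
                    return (float(body[:i]), float(body[i + 1:]))
            return tuple(float(x) for x in body.split("-", 1))

        out.append(ContrastResult(
            strategy=r["strategy"],
            risk_5yr=float(r["risk_5yr"]), risk_ci=_ci(r["risk_95ci"]),
            rr=1.0 if is_ref else float(r["rr"]),
            rr_ci=(1.0, 1.0) if is_ref else _ci(r["rr_95ci"]),
            rd=0.0 if is_ref else float(r["rd"]),
            rd_ci=(0.0, 0.0) if is_ref else _ci(r["rd_95ci"]),
            is_reference=is_ref))
    return out
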