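"""Configuration-driven end-to-end runner.

One YAML file describes a complete run: where the cohort comes from (a CSV
path or synthetic generator parameters), whether eligibility filters and
multiple imputation are applied, the simulation and bootstrap settings, the
strategies, and an optional sensitivity-analysis variant.  Every source of
randomness is seeded from one master seed through a fixed seed-sequence
spawning order (generate, impute, simulate, bootstrap), so a rerun with an
identical config reproduces all numeric outputs exactly.

Sensitivity variants (each modifies exactly one axis):

- ``age_le60``       restrict to persons aged <= 60 years at baseline
- ``subtype_CRF01AE`` restrict to the CRF01_AE HIV-1 subtype
- ``vl_continuous``  model viral load as continuous log10 copies/mL
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, apply_eligibility_filters, person_time, read_cohort, write_cohort
from .gformula import SimConfig, Strategy, default_strategies
from .impute import ImputationSpec, emb_impute
from .inference import BootstrapSpec, assemble_results, estimate_contrasts, natural_course_diagnostics
from .synth import GeneratorParams, generate_cohort

log = logging.getLogger("artswitch")

SENSITIVITY_MODES = ("none", "age_le60", "subtype_CRF01AE", "vl_continuous")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    input_path: str | None = None
    generator: GeneratorParams | None = None
    eligibility_filters: bool = True
    imputation: ImputationSpec | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    boot: BootstrapSpec = field(default_factory=BootstrapSpec)
    strategies: list[Strategy] = field(default_factory=default_strategies)
    sensitivity: str = "none"
    output_dir: str = "artswitch_run"
    master_seed: int | None = None

    def __post_init__(self):
        if (self.input_path is None) == (self.generator is None):
            raise ConfigError("exactly one of input path / generator params must be set")
        if self.sensitivity not in SENSITIVITY_MODES:
            raise ConfigError(f"sensitivity must be one of {SENSITIVITY_MODES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        inp = raw.get("input", {}) or {}
        path = inp.get("path")
        gen_raw = inp.get("generator")
        if path is not None and gen_raw is not None:
            raise ConfigError("config provides both input.path and input.generator")
        master = raw.get("seed")
        seeds = _spawn_seeds(master if master is not None else 0)
        gen = None
        if gen_raw is not None:
            gen_raw = dict(gen_raw)
            gen_raw.setdefault("seed", seeds["generate"])
            gen = GeneratorParams(**gen_raw)
        imp = None
        imp_raw = raw.get("imputation")
        if imp_raw and imp_raw.get("enabled", True):
            imp_raw = {k: v for k, v in dict(imp_raw).items() if k != "enabled"}
            imp_raw.setdefault("seed", seeds["impute"])
            imp = ImputationSpec(**imp_raw)
        sim_raw = dict(raw.get("sim", {}) or {})
        sim_raw.setdefault("seed", seeds["simulate"])
        sensitivity = raw.get("sensitivity", "none")
        if sensitivity == "vl_continuous":
            sim_raw["vl_as_continuous"] = True
        sim = SimConfig(**sim_raw)
        boot_raw = dict(raw.get("boot", {}) or {})
        boot_raw.setdefault("seed", seeds["bootstrap"])
        boot = BootstrapSpec(**boot_raw)
        strategies = _parse_strategies(raw.get("strategies", "default"))
        return cls(input_path=path, generator=gen, imputation=imp, sim=sim,
                   boot=boot, strategies=strategies, sensitivity=sensitivity,
                   eligibility_filters=bool(raw.get("filters", {}).get("eligibility", True)
                                            if isinstance(raw.get("filters"), dict)
                                            else raw.get("filters", True)),
                   output_dir=raw.get("output_dir", "artswitch_run"),
                   master_seed=master)


def _spawn_seeds(master: int) -> dict[str, int]:
    """Fixed splitting rule: one child stream per stage, spawn order
    generate -> impute -> simulate -> bootstrap; each reduced below 2^31."""
    children = np.random.SeedSequence(master).spawn(4)
    names = ("generate", "impute", "simulate", "bootstrap")
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def _parse_strategies(raw) -> list[Strategy]:
    if raw == "default" or raw is None:
        return default_strategies()
    out = []
    for item in raw:
        mode = item["mode"]
        if mode == "natural":
            out.append(Strategy.natural())
        elif mode == "static":
            out.append(Strategy.static(item["regimen"]))
        elif mode == "dynamic":
            out.append(Strategy.cd4_triggered(item.get("trigger_cd4", 200.0),
                                              item.get("regimen", "PI")))
        else:
            raise ConfigError(f"unknown strategy mode {mode!r}")
    return out


def _config_digest(config: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    blob = json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute generate/ingest -> filter -> impute -> fit -> simulate ->
    bootstrap -> report; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    manifest: dict = {"config_digest": _config_digest(config),
                      "version": __version__,
                      "master_seed": config.master_seed,
                      "sensitivity": config.sensitivity,
                      "stages": {}}

    # --- stage: ingest / generate -----------------------------------------
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        write_cohort(cohort, out / "cohort.csv")
        manifest["stages"]["generate"] = {"n_persons": cohort.n_persons,
                                          "n_rows": len(cohort)}
        log.info("generated synthetic cohort: %d persons, %d rows",
                 cohort.n_persons, len(cohort))
    else:
        cohort = read_cohort(config.input_path)
        manifest["stages"]["ingest"] = {"n_persons": cohort.n_persons,
                                        "n_rows": len(cohort)}

    # --- stage: sensitivity restriction ------------------------------------
    if config.sensitivity == "age_le60":
        base = cohort.baseline()
        keep = base.loc[base["age_years"] <= 60, "person_id"]
        cohort = cohort.subset(keep)
    elif config.sensitivity == "subtype_CRF01AE":
        base = cohort.baseline()
        keep = base.loc[base["subtype"] == "CRF01_AE", "person_id"]
        cohort = cohort.subset(keep)
    manifest["stages"]["restrict"] = {"n_persons": cohort.n_persons}

    # --- stage: eligibility filters ----------------------------------------
    if config.eligibility_filters:
        cohort, exclusions = apply_eligibility_filters(cohort)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        manifest["stages"]["filter"] = {"n_persons": cohort.n_persons,
                                        "n_excluded": len(exclusions)}
        log.info("eligibility filters: %d persons retained, %d excluded",
                 cohort.n_persons, len(exclusions))
    pm, deaths = person_time(cohort)
    manifest["stages"]["descriptives"] = {"person_months": pm, "deaths": deaths}

    # --- stage: imputation ---------------------------------------------------
    has_missing = bool(cohort.frame["cd4"].isna().any())
    if config.imputation is not None and has_missing:
        imputed = emb_impute(cohort, config.imputation)
        datasets: list[Cohort] | Cohort = imputed.datasets
        imputed.diagnostics.to_csv(out / "imputation_diagnostics.csv", index=False)
        manifest["stages"]["impute"] = {"m": config.imputation.m}
        log.info("EMB imputation: %d datasets", config.imputation.m)
    else:
        if has_missing:
            raise ConfigError("cohort has missing CD4 but imputation is disabled")
        datasets = cohort
    # --- stages: fit + simulate + bootstrap ---------------------------------
    first = datasets[0] if isinstance(datasets, list) else datasets
    from .gformula import fit_models
    fit_models(first, config.sim).to_json(out / "models.json")  # audit copy
    contrasts, curves, boot_manifest = estimate_contrasts(
        datasets, config.strategies, config.sim, config.boot)
    manifest["stages"]["inference"] = boot_manifest

    table = assemble_results(contrasts)
    table.to_csv(out / "results.csv", index=False)
    with open(out / "results.json", "w") as fh:
        json.dump([dataclasses.asdict(c) for c in contrasts], fh, indent=2)

    curve_rows = []
    for name, curve in curves.items():
        cm = curve.covariate_means.copy()
        cm.insert(0, "strategy", name)
        cm["cum_risk"] = curve.risk_by_k[: len(cm)]
        curve_rows.append(cm)
    pd.concat(curve_rows, ignore_index=True).to_csv(out / "risk_curves.csv", index=False)

    natural_name = [s.name for s in config.strategies if s.mode == "natural"][0]
    diag_cohort = datasets[0] if isinstance(datasets, list) else datasets
    diag = natural_course_diagnostics(diag_cohort, curves[natural_name])
    diag.to_csv(out / "diagnostics.csv", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("run complete: %s", out)
    return out
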