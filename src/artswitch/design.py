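"""Feature construction shared by model fitting and Monte Carlo simulation.

Both the pooled person-interval regressions and the g-formula simulator
evaluate linear predictors over the same named features, so a single registry
defines how each feature is derived from primitive state variables
(cd4, vl, regimen, interval index, baseline covariates).  Coefficients are
stored as ``{feature_name: value}`` dicts, which keeps fitted models and
generator ground truth directly comparable.

Scaling: CD4 enters logistic models per 100 cells ("cd4_100") and its own
transition model on the square-root scale ("cd4_sqrt"), the standard
variance-stabilising transform for CD4 counts; age enters as
``(age - 45) / 10`` ("age_c").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Viral-load dichotomisation threshold (copies/mL) for the primary analysis.
VL_THRESHOLD = 10_000.0

#: CD4 threshold (cells/uL) marking advanced immunosuppression.
CD4_THRESHOLD = 200.0

#: Baseline-covariate design columns (dummy coding; reference level omitted).
BASELINE_FEATURES = [
    "age_c",
    "female",
    "edu_none",
    "edu_senior",
    "marital_other",
    "trans_homo",
    "trans_other",
    "std_yes",
    "std_unknown",
    "tb_yes",
]

#: Default covariate specifications of the four pooled models (primary,
#: binary-VL analysis).  CD4/VL transition models see the lagged state;
#: the treatment and death models see the current-interval state.
DEFAULT_SPECS = {
    "cd4": ["const", "k", "lag_cd4_sqrt", "lag_vl_high", "lag_pi"] + BASELINE_FEATURES,
    "vl": ["const", "k", "lag_cd4_100", "lag_vl_high", "lag_pi"] + BASELINE_FEATURES,
    "trt": ["const", "k", "cd4_100", "vl_high"] + BASELINE_FEATURES,
    "death": ["const", "k", "cd4_100", "vl_high", "pi"] + BASELINE_FEATURES,
}

#: Continuous-VL sensitivity variant: viral load enters as log10 copies/mL.
CONTINUOUS_VL_SPECS = {
    "cd4": ["const", "k", "lag_cd4_sqrt", "lag_log10vl", "lag_pi"] + BASELINE_FEATURES,
    "vl": ["const", "k", "lag_cd4_100", "lag_log10vl", "lag_pi"] + BASELINE_FEATURES,
    "trt": ["const", "k", "cd4_100", "log10vl"] + BASELINE_FEATURES,
    "death": ["const", "k", "cd4_100", "log10vl", "pi"] + BASELINE_FEATURES,
}

#: Toy-mode specifications: binary CD4/VL state, no time trend or baseline
#: terms, so exact enumeration over histories stays feasible.
TOY_SPECS = {
    "cd4": ["const", "lag_cd4_high", "lag_vl_high", "lag_pi"],
    "vl": ["const", "lag_cd4_high", "lag_vl_high", "lag_pi"],
    "trt": ["const", "cd4_high", "vl_high"],
    "death": ["const", "cd4_high", "vl_high", "pi"],
}


def baseline_dummies(base: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code baseline covariates of a one-row-per-person frame."""
    out = pd.DataFrame(index=base.index)
    out["age_c"] = (base["age_years"].astype(float) - 45.0) / 10.0
    out["female"] = (base["gender"] == "female").astype(float)
    out["edu_none"] = (base["education"] == "none").astype(float)
    out["edu_senior"] = (base["education"] == "senior_or_more").astype(float)
    out["marital_other"] = (base["marital"] == "other").astype(float)
    out["trans_homo"] = (base["transmission"] == "homosexual").astype(float)
    out["trans_other"] = (base["transmission"] == "other").astype(float)
    out["std_yes"] = (base["std_history"] == "yes").astype(float)
    out["std_unknown"] = (base["std_history"] == "unknown").astype(float)
    out["tb_yes"] = (base["tb_history"] == "yes").astype(float)
    return out


def derived_state(source: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Add transformed features to a dict of primitive state arrays.

    Expects (subsets of) ``cd4``, ``vl``, ``lag_cd4``, ``lag_vl``, ``pi``,
    ``lag_pi`` and passes baseline dummies through unchanged.
    """
    out = dict(source)
    n = len(next(iter(source.values())))
    out.setdefault("const", np.ones(n))
    if "cd4" in out:
        c = np.asarray(out["cd4"], dtype=float)
        out["cd4_100"] = c / 100.0
        out["cd4_sqrt"] = np.sqrt(np.maximum(c, 0.0))
        out["cd4_high"] = (c >= CD4_THRESHOLD).astype(float)
    if "lag_cd4" in out:
        c = np.asarray(out["lag_cd4"], dtype=float)
        out["lag_cd4_100"] = c / 100.0
        out["lag_cd4_sqrt"] = np.sqrt(np.maximum(c, 0.0))
        out["lag_cd4_high"] = (c >= CD4_THRESHOLD).astype(float)
    if "vl" in out:
        v = np.asarray(out["vl"], dtype=float)
        out["vl_high"] = (v >= VL_THRESHOLD).astype(float)
        out["log10vl"] = np.log10(np.maximum(v, 1.0))
    if "lag_vl" in out:
        v = np.asarray(out["lag_vl"], dtype=float)
        out["lag_vl_high"] = (v >= VL_THRESHOLD).astype(float)
        out["lag_log10vl"] = np.log10(np.maximum(v, 1.0))
    return out


def design_matrix(state: dict[str, np.ndarray], features: list[str]) -> np.ndarray:
    """Stack the named feature columns into an (n, p) design matrix."""
    cols = []
    for f in features:
        if f not in state:
            raise KeyError(f"feature {f!r} not available in state")
        cols.append(np.asarray(state[f], dtype=float))
    return np.column_stack(cols)


def linear_predictor(state: dict[str, np.ndarray], coefs: dict[str, float]) -> np.ndarray:
    """Evaluate sum_f coef_f * feature_f over a state dict."""
    n = len(next(iter(state.values())))
    eta = np.zeros(n)
    for f, b in coefs.items():
        if b == 0.0:
            continue
        if f == "const":
            eta += b
        else:
            eta += b * np.asarray(state[f], dtype=float)
    return eta


def pooled_frame(cohort) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Build the pooled person-interval frame (k >= 1) with lagged state.

    Returns the frame and the state dict of feature arrays for it.  Rows of
    interval 0 supply the lagged state of interval 1 and are not themselves
    modelled (there is no prior state to condition on at entry).
    """
    df = cohort.frame  # stored sorted by (person_id, k): lag = previous row
    cd4 = df["cd4"].to_numpy(dtype=float)
    vl = df["vl"].to_numpy(dtype=float)
    pi = (df["regimen"] == "PI").to_numpy(dtype=float)
    k_arr = df["k"].to_numpy(dtype=float)

    def _lag(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x, dtype=float)
        out[0] = np.nan
        out[1:] = x[:-1]
        out[k_arr == 0] = np.nan
        return out

    lag_cd4, lag_vl, lag_pi = _lag(cd4), _lag(vl), _lag(pi)
    keep = k_arr >= 1
    pooled = df[keep].copy().reset_index(drop=True)

    state: dict[str, np.ndarray] = {
        "k": k_arr[keep],
        "cd4": cd4[keep],
        "vl": vl[keep],
        "lag_cd4": lag_cd4[keep],
        "lag_vl": lag_vl[keep],
        "pi": pi[keep],
        "lag_pi": lag_pi[keep],
    }
    dummies = baseline_dummies(pooled)
    for c in dummies.columns:
        state[c] = dummies[c].to_numpy(dtype=float)
    return pooled, derived_state(state)
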