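"""Expectation-maximization-bootstrap (EMB) multiple imputation of CD4.

Missing follow-up CD4 counts are imputed under a working multivariate-normal
model over the person-level *wide* layout: baseline covariates (dummy-coded),
CD4 at every interval, and log10 viral load at every interval.  Because all
time points are columns of one row, each missing CD4_k is conditioned on its
lagged and lead neighbours as well as the concurrent viral load — the wide
layout is what encodes the longitudinal structure.

The EMB scheme (one imputation per bootstrap replicate of the EM fit):

1. draw a nonparametric bootstrap resample of persons;
2. run EM for the MVN mean/covariance on the resample;
3. impute each missing CD4 entry of the *original* data with a draw from its
   conditional normal given the row's observed entries under the resampled
   parameters.

Entries that are structurally absent (after death or censoring) are excluded
from the likelihood and never imputed.  Only CD4 entries are ever replaced;
baseline covariates and viral loads pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .design import baseline_dummies

__all__ = ["ImputationSpec", "ImputedSet", "WideData", "EMResult",
           "to_wide", "em_mvn", "emb_impute"]


@dataclass(frozen=True)
class ImputationSpec:
    m: int = 10
    max_em_iter: int = 200
    em_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")


@dataclass
class WideData:
    """Person-level wide matrix with masks distinguishing the two kinds of
    absence: missing-at-visit (imputable) vs structurally absent (post
    death/censoring, not imputable)."""

    X: np.ndarray  # (n_persons, p), NaN where absent for either reason
    columns: list[str]
    visit_missing: np.ndarray  # bool, imputable entries
    structural: np.ndarray  # bool, excluded from likelihood, never imputed
    person_ids: list
    cd4_cols: list[int]  # column indices of CD4_k
    k_of_col: dict[int, int]  # cd4 column index -> interval k


def to_wide(cohort: Cohort) -> WideData:
    """Pivot a cohort to one row per person (baseline dummies + CD4_k + log10VL_k)."""
    df = cohort.frame
    K = int(df["k"].max())
    base = cohort.baseline()
    dummies = baseline_dummies(base)
    pids = list(base["person_id"])
    n = len(pids)

    cd4_wide = df.pivot(index="person_id", columns="k", values="cd4").reindex(pids)
    vl_wide = df.pivot(index="person_id", columns="k", values="vl").reindex(pids)
    has_row = df.assign(one=1.0).pivot(index="person_id", columns="k",
                                       values="one").reindex(pids)

    cols: list[str] = list(dummies.columns)
    blocks = [dummies.to_numpy(dtype=float)]
    cd4_cols: list[int] = []
    k_of_col: dict[int, int] = {}
    for k in range(K + 1):
        cd4_cols.append(len(cols))
        k_of_col[len(cols)] = k
        cols.append(f"cd4_{k}")
        blocks.append(cd4_wide.get(k, pd.Series(np.nan, index=pids)).to_numpy(
            dtype=float).reshape(-1, 1))
    for k in range(K + 1):
        cols.append(f"lvl_{k}")
        v = vl_wide.get(k, pd.Series(np.nan, index=pids)).to_numpy(dtype=float)
        blocks.append(np.log10(np.maximum(v, 1.0), where=~np.isnan(v),
                               out=np.full_like(v, np.nan)).reshape(-1, 1))
    X = np.hstack(blocks)

    struct = np.zeros(X.shape, dtype=bool)
    present = ~has_row.reindex(columns=range(K + 1), fill_value=np.nan).isna().to_numpy()
    for j, name in enumerate(cols):
        if name.startswith(("cd4_", "lvl_")):
            k = int(name.split("_")[1])
            struct[:, j] = ~present[:, k]
    visit_missing = np.isnan(X) & ~struct
    return WideData(X=X, columns=cols, visit_missing=visit_missing,
                    structural=struct, person_ids=pids, cd4_cols=cd4_cols,
                    k_of_col=k_of_col)


@dataclass
class EMResult:
    mean: np.ndarray
    cov: np.ndarray
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    ridged: bool = False


def _init_moments(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Available-case start: nan-aware means, pairwise-complete covariances
    (n-denominator).  With complete data this *is* the MLE."""
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    Xc = X - mu
    M = (~np.isnan(X)).astype(float)
    Z = np.nan_to_num(Xc)
    counts = M.T @ M
    S = (Z.T @ Z) / np.maximum(counts, 1.0)
    # guard against indefiniteness of the pairwise estimate
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    S = (V * np.maximum(w, 1e-8)) @ V.T
    return mu, S


def _ensure_pd(S: np.ndarray) -> tuple[np.ndarray, bool]:
    try:
        np.linalg.cholesky(S)
        return S, False
    except np.linalg.LinAlgError:
        p = S.shape[0]
        ridge = 1e-6 * np.trace(S) / p
        return S + ridge * np.eye(p), True


def em_mvn(X: np.ndarray, tol: float = 1e-6, max_iter: int = 200,
           start: tuple[np.ndarray, np.ndarray] | None = None) -> EMResult:
    """EM for the mean and covariance of a multivariate normal with missing
    entries (NaN).  The observed-data log-likelihood is nondecreasing across
    iterations; a degenerate covariance is ridge-regularised and flagged.

    With complete data the first iteration already returns the sample mean
    and sample covariance (denominator n) and the loop stops after it.

    Columns are standardised internally (available-case mean/SD), so the
    convergence tolerance acts on a unit scale regardless of measurement
    units; returned parameters are on the original scale.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    obs = ~np.isnan(X)
    if not obs.any(axis=0).all():
        j = int(np.argmin(obs.any(axis=0)))
        raise ValueError(f"column {j} has no observed values")

    centre = np.nanmean(X, axis=0)
    scale = np.nanstd(X, axis=0)
    scale[scale <= 0] = 1.0
    X = (X - centre) / scale

    if start is not None:
        mu = (np.asarray(start[0], dtype=float) - centre) / scale
        S = np.asarray(start[1], dtype=float) / np.outer(scale, scale)
        S = (S + S.T) / 2.0
    else:
        mu, S = _init_moments(X)
    ridged = False
    S, r = _ensure_pd(S)
    ridged |= r

    # group rows by missingness pattern; precompute slices once
    pattern_rows: dict[bytes, list[int]] = {}
    for i in range(n):
        pattern_rows.setdefault(obs[i].tobytes(), []).append(i)
    patterns = []
    for key, rows in pattern_rows.items():
        o = np.frombuffer(key, dtype=bool)
        o_idx = np.flatnonzero(o)
        m_idx = np.flatnonzero(~o)
        rows_idx = np.asarray(rows)
        patterns.append((o_idx, m_idx, rows_idx, X[np.ix_(rows_idx, o_idx)]))

    loglik_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        loglik = 0.0
        for o_idx, m_idx, rows_idx, Xo in patterns:
            r_n = len(rows_idx)
            L = np.linalg.cholesky(S[np.ix_(o_idx, o_idx)])
            dev = Xo - mu[o_idx]
            sol = np.linalg.solve(L, dev.T)  # (p_o, r_n)
            loglik += (-0.5 * (sol ** 2).sum()
                       - r_n * (np.log(np.diag(L)).sum()
                                + 0.5 * len(o_idx) * np.log(2 * np.pi)))
            if len(m_idx):
                Som = S[np.ix_(o_idx, m_idx)]
                B = np.linalg.solve(L.T, np.linalg.solve(L, Som))  # Soo^-1 Som
                cond_mean = mu[m_idx] + dev @ B
                C = S[np.ix_(m_idx, m_idx)] - Som.T @ B  # conditional covariance
                sum_xx[np.ix_(m_idx, m_idx)] += r_n * C
                Xfull = np.empty((r_n, p))
                Xfull[:, o_idx] = Xo
                Xfull[:, m_idx] = cond_mean
            else:
                Xfull = np.empty((r_n, p))
                Xfull[:, o_idx] = Xo
            sum_x += Xfull.sum(axis=0)
            sum_xx += Xfull.T @ Xfull
        loglik_trace.append(float(loglik))
        mu_new = sum_x / n
        S_new = sum_xx / n - np.outer(mu_new, mu_new)
        S_new = (S_new + S_new.T) / 2.0
        S_new, r = _ensure_pd(S_new)
        ridged |= r
        delta = max(np.abs(mu_new - mu).max(), np.abs(S_new - S).max())
        mu, S = mu_new, S_new
        if delta < tol:
            converged = True
            break
    mu_out = centre + scale * mu
    S_out = S * np.outer(scale, scale)
    return EMResult(mean=mu_out, cov=S_out, n_iter=it, loglik_trace=loglik_trace,
                    converged=converged, ridged=ridged)


@dataclass
class ImputedSet:
    datasets: list[Cohort]
    em_params: list[EMResult]
    diagnostics: pd.DataFrame


def emb_impute(cohort: Cohort, spec: ImputationSpec) -> ImputedSet:
    """EMB multiple imputation of missing post-baseline CD4.

    Returns ``spec.m`` completed cohorts.  Observed values are identical
    across all datasets; imputed CD4 is floored at 0 and rounded to whole
    cells/uL.  Deterministic under ``spec.seed``.  Raises if a CD4 column has
    no observed (non-structural) values at all.
    """
    wide = to_wide(cohort)
    X = wide.X
    n, p = X.shape
    for j in wide.cd4_cols:
        observable = ~wide.structural[:, j]
        if observable.any() and not (~np.isnan(X[:, j]) & observable).any():
            raise ValueError(
                f"column {wide.columns[j]!r} has no observed values; cannot impute")

    any_missing = wide.visit_missing[:, wide.cd4_cols].any()
    rng = np.random.default_rng(spec.seed)
    datasets: list[Cohort] = []
    em_params: list[EMResult] = []
    diag_rows = []
    warm = None
    if any_missing:
        # full-data EM once; bootstrap fits warm-start from it
        em0 = em_mvn(X, tol=spec.em_tol, max_iter=spec.max_em_iter)
        warm = (em0.mean, em0.cov)
    for j in range(spec.m):
        if not any_missing:
            datasets.append(cohort)
            diag_rows.append({"imputation": j, "n_iter": 0, "loglik": np.nan,
                              "converged": True, "ridged": False})
            continue
        boot = rng.integers(0, n, size=n)
        em = em_mvn(X[boot], tol=spec.em_tol, max_iter=spec.max_em_iter, start=warm)
        em_params.append(em)
        filled = _conditional_draws(X, wide, em.mean, em.cov, rng)
        datasets.append(_restore(cohort, wide, filled))
        diag_rows.append({"imputation": j, "n_iter": em.n_iter,
                          "loglik": em.loglik_trace[-1] if em.loglik_trace else np.nan,
                          "converged": em.converged, "ridged": em.ridged})
    return ImputedSet(datasets=datasets, em_params=em_params,
                      diagnostics=pd.DataFrame(diag_rows))


def _conditional_draws(X: np.ndarray, wide: WideData, mu: np.ndarray,
                       S: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw every visit-missing CD4 entry from its conditional normal given
    the row's observed entries under (mu, S)."""
    out = X.copy()
    n, p = X.shape
    cd4_set = set(wide.cd4_cols)
    for i in range(n):
        mis = np.flatnonzero(wide.visit_missing[i] & np.isin(np.arange(p),
                                                             wide.cd4_cols))
        if mis.size == 0:
            continue
        o = ~np.isnan(X[i])
        m = wide.visit_missing[i]  # condition on observed; draw all missing jointly
        Soo, _ = _ensure_pd(S[np.ix_(o, o)])
        L = np.linalg.cholesky(Soo)
        dev = X[i, o] - mu[o]
        Som = S[np.ix_(o, m)]
        B = np.linalg.solve(L.T, np.linalg.solve(L, Som))
        cond_mean = mu[m] + dev @ B
        C = S[np.ix_(m, m)] - Som.T @ B
        C = (C + C.T) / 2.0
        w, V = np.linalg.eigh(C)
        half = V * np.sqrt(np.maximum(w, 0.0))
        draw = cond_mean + half @ rng.standard_normal(m.sum())
        mcols = np.flatnonzero(m)
        for jj, col in enumerate(mcols):
            if col in cd4_set:
                out[i, col] = max(0.0, round(float(draw[jj])))
    return out


def _restore(cohort: Cohort, wide: WideData, filled: np.ndarray) -> Cohort:
    """Write imputed CD4 values back into a copy of the long cohort frame."""
    df = cohort.frame.copy()
    pid_pos = {pid: i for i, pid in enumerate(wide.person_ids)}
    cd4 = df["cd4"].to_numpy(dtype=float).copy()
    missing = np.isnan(cd4)
    if missing.any():
        pids = df["person_id"].to_numpy()
        ks = df["k"].to_numpy()
        col_of_k = {k: j for j, k in wide.k_of_col.items()}
        for r in np.flatnonzero(missing):
            cd4[r] = filled[pid_pos[pids[r]], col_of_k[int(ks[r])]]
    df["cd4"] = cd4
    return Cohort.from_frame(df, validate=False)
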