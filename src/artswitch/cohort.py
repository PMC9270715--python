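"""Longitudinal person-period cohort container, CSV I/O and descriptive statistics.

The data model is a long-format table with one row per person per 12-month
follow-up interval.  Interval ``k`` covers months ``[12k, 12(k+1))`` since the
person's entry (the date they switched antiretroviral regimen).  Each row
carries the person's baseline covariates (repeated on every row), the
time-varying CD4 count (cells/uL), viral load (copies/mL), regimen class
(NNRTI- or PI-based), and indicators for death / administrative censoring
during the interval.  Death is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "CohortValidationError",
    "SchemaError",
    "COLUMNS",
    "CATEGORICAL_LEVELS",
    "read_cohort",
    "write_cohort",
    "person_time",
    "crude_mortality_rate",
    "baseline_table",
    "apply_eligibility_filters",
]

#: CSV column order.  Baseline covariates are repeated on every row of a person.
COLUMNS = [
    "person_id",
    "k",
    "age_years",
    "gender",
    "education",
    "marital",
    "transmission",
    "std_history",
    "tb_history",
    "subtype",
    "cd4",
    "vl",
    "regimen",
    "died",
    "censored",
]

CATEGORICAL_LEVELS = {
    "gender": ("male", "female"),
    "education": ("none", "primary_or_junior", "senior_or_more"),
    "marital": ("married", "other"),
    "transmission": ("heterosexual", "homosexual", "other"),
    "std_history": ("yes", "no", "unknown"),
    "tb_history": ("yes", "no"),
    "subtype": ("CRF01_AE", "CRF07_BC", "other"),
    "regimen": ("NNRTI", "PI"),
}

#: Baseline demographic columns that are constant within a person.
BASELINE_COLUMNS = [
    "age_years",
    "gender",
    "education",
    "marital",
    "transmission",
    "std_history",
    "tb_history",
    "subtype",
]

#: Demographic fields whose absence marks an incomplete baseline record
#: (removable by :func:`apply_eligibility_filters`, not a hard validation error).
_DEMOGRAPHIC_FIELDS = [
    "age_years",
    "gender",
    "education",
    "marital",
    "transmission",
    "std_history",
    "tb_history",
    "subtype",
]


class SchemaError(ValueError):
    """Input table does not match the documented column schema."""


class CohortValidationError(ValueError):
    """A cohort invariant is violated; the message names person_id and k."""


@dataclass(frozen=True)
class Cohort:
    """Validated collection of person-period records.

    Attributes
    ----------
    frame : pandas.DataFrame
        Long-format table with :data:`COLUMNS`, sorted by (person_id, k).
        Missing CD4 / viral load are NaN.
    """

    frame: pd.DataFrame = field(repr=False)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, validate: bool = True) -> "Cohort":
        df = _coerce_types(frame)
        if validate:
            _validate(df)
        df = df.sort_values(["person_id", "k"], kind="mergesort").reset_index(drop=True)
        return cls(frame=df)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_persons(self) -> int:
        return self.frame["person_id"].nunique()

    @property
    def person_ids(self) -> list:
        return list(self.frame["person_id"].drop_duplicates())

    def baseline(self) -> pd.DataFrame:
        """One row per person: the interval-0 record (baseline covariates and state)."""
        base = self.frame[self.frame["k"] == 0].copy()
        return base.reset_index(drop=True)

    def subset(self, person_ids) -> "Cohort":
        keep = self.frame["person_id"].isin(set(person_ids))
        return Cohort.from_frame(self.frame[keep], validate=False)

    def resample_persons(self, rng: np.random.Generator) -> "Cohort":
        """Person-level (cluster) bootstrap resample, with fresh unique ids.

        The frame is stored sorted by (person_id, k), so each person is one
        contiguous row block; the resample is a single vectorised gather."""
        codes, _ = pd.factorize(self.frame["person_id"], sort=False)
        counts = np.bincount(codes)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        n_p = len(counts)
        draw = rng.integers(0, n_p, size=n_p)
        lens = counts[draw]
        total = int(lens.sum())
        block_off = np.repeat(np.cumsum(lens) - lens, lens)
        rows = np.repeat(starts[draw], lens) + (np.arange(total) - block_off)
        df = self.frame.iloc[rows].copy()
        df["person_id"] = np.repeat(np.char.add("b", np.arange(n_p).astype(str)), lens)
        df = df.reset_index(drop=True)
        return Cohort(frame=df)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _coerce_types(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = frame[COLUMNS].copy()
    for col in ("k", "died", "censored"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    for col in ("cd4", "vl", "age_years"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    df["person_id"] = df["person_id"].astype(str)
    for col in CATEGORICAL_LEVELS:
        df[col] = df[col].where(df[col].notna(), other=np.nan)
    return df


def _validate(df: pd.DataFrame) -> None:
    for col, levels in CATEGORICAL_LEVELS.items():
        vals = df[col].dropna()
        # empty string = missing-at-baseline demographic (handled by filters)
        vals = vals[vals != ""]
        bad = set(vals) - set(levels)
        if bad:
            raise CohortValidationError(
                f"column {col!r} has unknown level(s) {sorted(bad)}; allowed {levels}"
            )
    if df["regimen"].isna().any() or (df["regimen"] == "").any():
        pid = df.loc[df["regimen"].isna() | (df["regimen"] == ""), "person_id"].iloc[0]
        raise CohortValidationError(f"regimen is missing for person {pid}")
    bad = df[(df["died"] == 1) & (df["censored"] == 1)]
    if len(bad):
        r = bad.iloc[0]
        raise CohortValidationError(
            f"person {r['person_id']} interval {r['k']}: died and censored both set"
        )
    ages = df["age_years"].dropna()
    if len(ages) and ((ages < 15) | (ages > 100)).any():
        pid = df.loc[df["age_years"].notna() & ((df["age_years"] < 15) | (df["age_years"] > 100)), "person_id"].iloc[0]
        raise CohortValidationError(f"person {pid}: age_years outside [15, 100]")

    for pid, g in df.groupby("person_id", sort=False):
        ks = g["k"].to_numpy()
        order = np.argsort(ks)
        ks = ks[order]
        if ks[0] != 0 or not np.array_equal(ks, np.arange(len(ks))):
            raise CohortValidationError(
                f"person {pid}: interval indices {ks.tolist()} are not contiguous from 0"
            )
        died = g["died"].to_numpy()[order]
        if died.sum() > 1 or (died[:-1] == 1).any():
            k_bad = int(ks[np.argmax(died == 1)])
            raise CohortValidationError(
                f"person {pid}: record exists after death in interval {k_bad} "
                "(death must be absorbing)"
            )
        cens = g["censored"].to_numpy()[order]
        if (cens[:-1] == 1).any():
            raise CohortValidationError(
                f"person {pid}: record exists after censoring (censoring ends follow-up)"
            )
        for col in BASELINE_COLUMNS:
            u = g[col].astype(object).where(g[col].notna(), None).nunique(dropna=False)
            if u > 1:
                raise CohortValidationError(
                    f"person {pid}: baseline covariate {col!r} varies across intervals"
                )
        base = g.iloc[int(np.argmin(g["k"].to_numpy()))]
        for col in ("cd4", "vl"):
            if pd.isna(base[col]):
                raise CohortValidationError(
                    f"person {pid}: baseline (k=0) {col} is missing"
                )
        if not pd.isna(base["cd4"]) and not (0 <= base["cd4"] <= 3000):
            raise CohortValidationError(f"person {pid}: baseline cd4 outside [0, 3000]")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_cohort(path, dialect: dict | None = None, validate: bool = True) -> Cohort:
    """Read a long-format cohort CSV into a validated :class:`Cohort`.

    Missing CD4 / viral load are encoded as empty fields; numeric sentinels
    (e.g. ``-1``) are rejected.  ``dialect`` is passed through to
    :func:`pandas.read_csv` (e.g. ``{"sep": ";"}``).
    """
    kwargs = dict(dialect or {})
    try:
        df = pd.read_csv(path, keep_default_na=False, na_values=[""], dtype=str, **kwargs)
    except Exception as exc:  # pragma: no cover - pandas error text is adequate
        raise SchemaError(f"could not parse CSV: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ("cd4", "vl"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        if bad.any():
            raise SchemaError(
                f"unparseable numeric in column {col!r} at row {int(np.argmax(bad.to_numpy())) + 2}"
            )
        if (vals.dropna() < 0).any():
            raise CohortValidationError(
                f"negative value in column {col!r}: sentinel encodings are rejected, "
                "missing values must be empty fields"
            )
        df[col] = vals
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    return Cohort.from_frame(df, validate=validate)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV; NaN becomes an empty field (round-trips)."""
    df = cohort.frame.copy()
    for col in ("cd4", "vl"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else _num_str(v))
    df["age_years"] = df["age_years"].map(lambda v: "" if pd.isna(v) else _num_str(v))
    df.to_csv(path, index=False, lineterminator="\n")


def _num_str(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


def interval_months(died: int, censored: int) -> float:
    """Person-months contributed by one interval record.

    Mid-interval convention: a fully survived interval contributes 12 months,
    the interval of death 6, and the interval of administrative censoring 0
    beyond the last completed interval.
    """
    if died:
        return 6.0
    if censored:
        return 0.0
    return 12.0


def person_time(cohort: Cohort) -> tuple[float, int]:
    """Total person-months of follow-up and number of deaths."""
    df = cohort.frame
    if len(df) == 0:
        return 0.0, 0
    months = np.where(df["died"] == 1, 6.0, np.where(df["censored"] == 1, 0.0, 12.0))
    return float(months.sum()), int(df["died"].sum())


def crude_mortality_rate(n_deaths: int, person_months: float) -> float:
    """Crude mortality rate per 1000 person-months."""
    if person_months <= 0:
        raise ValueError("person_months must be positive")
    return 1000.0 * n_deaths / person_months


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def baseline_table(cohort: Cohort) -> pd.DataFrame:
    """Baseline frequency table: counts and percents (1 dp, half-up) per level.

    Includes the derived splits used in the study's descriptive table:
    age at/below vs above 40 years, baseline CD4 below vs at/above 200
    cells/uL, and baseline viral load below vs at/above 10,000 copies/mL.
    """
    base = cohort.baseline()
    n = len(base)
    rows = []

    def add(variable: str, series: pd.Series, levels) -> None:
        counts = series.value_counts()
        for lev in levels:
            c = int(counts.get(lev, 0))
            rows.append(
                {
                    "variable": variable,
                    "level": lev,
                    "count": c,
                    "percent": _round1(100.0 * c / n) if n else 0.0,
                }
            )

    add("age_group", pd.Series(np.where(base["age_years"] <= 40, "<=40", ">40")), ["<=40", ">40"])
    for col in ("gender", "education", "marital", "transmission", "std_history", "tb_history"):
        add(col, base[col], CATEGORICAL_LEVELS[col])
    add(
        "baseline_cd4_group",
        pd.Series(np.where(base["cd4"] < 200, "<200", ">=200")),
        ["<200", ">=200"],
    )
    add(
        "baseline_vl_group",
        pd.Series(np.where(base["vl"] < 10000, "<10000", ">=10000")),
        ["<10000", ">=10000"],
    )
    add("subtype", base["subtype"], CATEGORICAL_LEVELS["subtype"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eligibility filters
# ---------------------------------------------------------------------------


def apply_eligibility_filters(cohort: Cohort) -> tuple[Cohort, pd.DataFrame]:
    """Drop persons ineligible for analysis; return the filtered cohort and a log.

    Removes persons with no post-baseline CD4 *and* no post-baseline viral-load
    measurement (no immunological follow-up), and persons with incomplete
    baseline demographics.  The log has columns ``person_id`` and ``reason``.
    """
    df = cohort.frame
    log = []
    drop: set = set()
    for pid, g in df.groupby("person_id", sort=False):
        post = g[g["k"] >= 1]
        if post["cd4"].notna().sum() == 0 and post["vl"].notna().sum() == 0:
            drop.add(pid)
            log.append({"person_id": pid, "reason": "no_followup_measurement"})
            continue
        base = g[g["k"] == 0].iloc[0]
        incomplete = any(
            pd.isna(base[c]) or base[c] == "" for c in _DEMOGRAPHIC_FIELDS
        )
        if incomplete:
            drop.add(pid)
            log.append({"person_id": pid, "reason": "incomplete_baseline"})
    kept = Cohort.from_frame(df[~df["person_id"].isin(drop)], validate=False)
    return kept, pd.DataFrame(log, columns=["person_id", "reason"])
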