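"""Score tables, traffic-light zones, mastery counts and descriptives.

The data model is a long-format pandas DataFrame: one row per child x motor
domain carrying the MABC-2 age-adjusted standard score (1-19 scale, population
mean 10, SD 3) and optionally the norm-table percentile.  Three domains are
assessed per child: manual dexterity, aiming-catching and balance.

Traffic-light classification follows the MABC-2 manual cut-offs: percentile
above the 15th is typical performance (green), 6th-15th is "at risk" (amber),
at or below the 5th indicates significant motor difficulty (red).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DOMAINS = ("manual_dexterity", "aiming_catching", "balance")

#: accepted spellings for domain labels (normalized case-insensitively)
DOMAIN_ALIASES: dict[str, str] = {
    "manual_dexterity": "manual_dexterity",
    "manual dexterity": "manual_dexterity",
    "md": "manual_dexterity",
    "c3": "manual_dexterity",
    "aiming_catching": "aiming_catching",
    "aiming-catching": "aiming_catching",
    "aiming catching": "aiming_catching",
    "ac": "aiming_catching",
    "c2": "aiming_catching",
    "balance": "balance",
    "bal": "balance",
    "c1": "balance",
}

SEXES = ("boy", "girl")
SEX_ALIASES = {
    "boy": "boy", "b": "boy", "m": "boy", "male": "boy", "boys": "boy",
    "girl": "girl", "g": "girl", "f": "girl", "female": "girl", "girls": "girl",
}

REQUIRED_COLUMNS = (
    "child_id", "class_id", "school_id", "sex", "age_years", "domain",
    "standard_score",
)


class ValidationError(ValueError):
    """Raised when a score table violates the data-model invariants."""


class ConfigurationError(ValueError):
    """Raised when an input file cannot be mapped onto the expected columns."""


def _normalize_domain(label: object) -> str:
    key = str(label).strip().lower()
    if key not in DOMAIN_ALIASES:
        raise ValidationError(f"unrecognized domain label: {label!r}")
    return DOMAIN_ALIASES[key]


def _normalize_sex(label: object) -> str:
    key = str(label).strip().lower()
    if key not in SEX_ALIASES:
        raise ValidationError(f"unrecognized sex label: {label!r}")
    return SEX_ALIASES[key]


def validate_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a long-format score table.

    Checks the per-child invariants (exactly three domain rows; constant
    class/school/sex/age within child; finite scores) and returns a copy with
    normalized domain and sex labels, sorted by class, child and canonical
    domain order.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise ValidationError("score table is empty")

    out = df.copy()
    for col in ("child_id", "class_id", "school_id"):
        out[col] = out[col].astype(str)
    out["domain"] = out["domain"].map(_normalize_domain)
    out["sex"] = out["sex"].map(_normalize_sex)
    out["age_years"] = pd.to_numeric(out["age_years"], errors="raise")
    out["standard_score"] = pd.to_numeric(out["standard_score"], errors="raise")

    bad_rows = out.index[~np.isfinite(out["standard_score"])].tolist()
    if bad_rows:
        raise ValidationError(f"non-finite standard_score at rows {bad_rows}")
    bad_rows = out.index[~np.isfinite(out["age_years"])].tolist()
    if bad_rows:
        raise ValidationError(f"non-finite age_years at rows {bad_rows}")

    g = out.groupby("child_id", sort=False)
    agg = g.agg(n_rows=("domain", "size"), n_domains=("domain", "nunique"),
                n_class=("class_id", "nunique"), n_school=("school_id", "nunique"),
                n_sex=("sex", "nunique"), n_age=("age_years", "nunique"))
    bad = agg.index[(agg["n_rows"] != 3) | (agg["n_domains"] != 3)
                    | (agg[["n_class", "n_school", "n_sex", "n_age"]]
                       .max(axis=1) > 1)]
    if len(bad):
        raise ValidationError(
            "children with != 3 distinct domain rows or inconsistent "
            f"class/school/sex/age: {list(bad)}")

    order = {d: i for i, d in enumerate(DOMAINS)}
    out["_dom_ord"] = out["domain"].map(order)
    out = (out.sort_values(["school_id", "class_id", "child_id", "_dom_ord"],
                           kind="mergesort")
              .drop(columns="_dom_ord")
              .reset_index(drop=True))
    return out


def read_scores(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format CSV of child assessments into a validated table.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.
    dialect : mapping, optional
        Maps canonical column names (``child_id`` ...) to the names used in
        the file, e.g. ``{"standard_score": "SS"}``.

    Rows with missing required fields are rejected with row-indexed
    diagnostics rather than silently dropped.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError("input file is empty") from exc
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s): {missing}; present: {list(raw.columns)}")
    na_rows = raw.index[raw[list(REQUIRED_COLUMNS)].isna().any(axis=1)].tolist()
    if na_rows:
        raise ValidationError(f"missing required fields at rows {na_rows}")
    return validate_scores(raw)


def write_scores(df: pd.DataFrame, path) -> None:
    """Write a score table in the same CSV dialect ``read_scores`` accepts."""
    cols = [c for c in (*REQUIRED_COLUMNS, "percentile") if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def standard_score_to_percentile(ss):
    """Normal approximation to the MABC-2 percentile of a standard score.

    Standard scores are scaled to mean 10, SD 3, so the percentile is
    ``100 * Phi((ss - 10) / 3)``.  Used only when the norm-table percentile
    column is absent (norm tables are proprietary); preserves ordering and
    the approximate zone cut-points.
    """
    return stats.norm.cdf((np.asarray(ss, dtype=float) - 10.0) / 3.0) * 100.0


def classify_zone(percentile):
    """Traffic-light zone for a percentile in (0, 100).

    red: <= 5th; amber: above 5th up to and including the 15th; green: > 15th.
    """
    p = np.asarray(percentile, dtype=float)
    if np.any((p <= 0) | (p >= 100)):
        raise ValueError("percentile must lie strictly between 0 and 100")
    zone = np.where(p > 15, "green", np.where(p > 5, "amber", "red"))
    return zone.item() if np.isscalar(percentile) else zone


def ensure_percentile(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a filled ``percentile`` column.

    The input percentile is kept where present; gaps are filled with the
    normal approximation from the standard score.
    """
    out = df.copy()
    approx = standard_score_to_percentile(out["standard_score"])
    if "percentile" in out.columns:
        p = pd.to_numeric(out["percentile"], errors="coerce")
        out["percentile"] = p.where(p.notna(), approx)
    else:
        out["percentile"] = approx
    return out


def mastery_count(child_rows: pd.DataFrame) -> int:
    """Number of the three domains (0-3) in the green zone for one child."""
    if len(child_rows) != 3 or child_rows["domain"].nunique() != 3:
        raise ValidationError(
            "mastery_count needs exactly three rows with distinct domains, "
            f"got domains {list(child_rows['domain'])}")
    rows = ensure_percentile(child_rows)
    return int((rows["percentile"] > 15).sum())


def mastery_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-child mastery counts with age (floored years) and sex attached."""
    df = ensure_percentile(df)
    rec = []
    for child, grp in df.groupby("child_id", sort=False):
        rec.append({
            "child_id": child,
            "age": int(np.floor(grp["age_years"].iloc[0])),
            "sex": grp["sex"].iloc[0],
            "mastery": int((grp["percentile"] > 15).sum()),
        })
    return pd.DataFrame(rec)


def zone_table(df: pd.DataFrame) -> pd.DataFrame:
    """Zone proportions by sex and domain (tidy, one row per cell)."""
    df = ensure_percentile(df)
    df = df.assign(zone=classify_zone(df["percentile"].to_numpy()))
    out = (df.groupby(["sex", "domain", "zone"], observed=True)
             .size().rename("n").reset_index())
    totals = out.groupby(["sex", "domain"], observed=True)["n"].transform("sum")
    out["proportion"] = out["n"] / totals
    return out


def decompose_age(df: pd.DataFrame) -> pd.DataFrame:
    """Split each child's age into class-mean and within-class components.

    Adds ``age_between`` (class mean age, computed over unique children, not
    over domain rows) and ``age_within`` (deviation from it).  The two parts
    reconstruct ``age_years`` exactly, and the within part has mean zero in
    every class; the operation is idempotent.
    """
    out = df.copy()
    child_age = out.drop_duplicates("child_id").set_index("child_id")
    class_mean = child_age.groupby("class_id")["age_years"].mean()
    out["age_between"] = out["class_id"].map(class_mean)
    out["age_within"] = out["age_years"] - out["age_between"]
    return out


def _median_ci(values: np.ndarray, rng: np.random.Generator,
               n_boot: int = 1000, level: float = 0.95) -> tuple[float, float]:
    # percentile bootstrap of the median
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    med = np.median(values[idx], axis=1)
    lo, hi = np.quantile(med, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def descriptive_table(df: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Mean, SD, median and bootstrap median CI per age x sex x domain cell.

    SD is reported as NaN for singleton cells.  The median CI uses a seeded
    percentile bootstrap with 1,000 resamples.
    """
    if len(df) == 0:
        raise ValidationError("cannot describe an empty table")
    rng = np.random.default_rng(seed)
    out = []
    work = df.assign(age=np.floor(df["age_years"]).astype(int))
    for (age, sex, domain), grp in work.groupby(["age", "sex", "domain"],
                                                observed=True):
        v = grp["standard_score"].to_numpy(dtype=float)
        lo, hi = _median_ci(v, rng) if len(v) > 1 else (np.nan, np.nan)
        out.append({
            "age": age, "sex": sex, "domain": domain, "n": len(v),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
            "median": float(np.median(v)),
            "median_ci_low": lo, "median_ci_high": hi,
        })
    return pd.DataFrame(out)
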