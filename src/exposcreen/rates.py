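"""Per-zip diagnosis rates with registry-style exclusion rules.

A rate is the number of visits carrying an ICD code divided by the
total billed diagnoses for the zip code and age stratum.  Because every
diagnosis on a visit is counted (not just the primary), a zip's rates
for different codes need not sum to anything in particular and a single
rate may in principle exceed values a one-code-per-visit scheme would
allow; only non-negativity and finiteness are enforced.

Exclusions mirror how anonymized claims registries release data: zips
below a population floor and codes below a national count floor are
withheld at source, and codes used in too small a fraction of zips are
dropped to avoid provider-idiosyncratic coding.
"""

from __future__ import annotations

import logging
import re
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FIVE_BIN_STRATA",
    "TWO_BIN_MAP",
    "TWO_BIN_STRATA",
    "apply_exclusions",
    "collapse_strata",
    "compute_rates",
]

#: Five age strata: 0-5, 6-17, 18-54, 55-74, 75+.
FIVE_BIN_STRATA = ("preK", "pediatric", "adult", "retirement", "geriatric")
#: Collapsed strata: 0-17 and 18+.
TWO_BIN_STRATA = ("pediatric", "adult")
#: five-bin label -> two-bin label (two-bin labels map to themselves).
TWO_BIN_MAP = {
    "preK": "pediatric",
    "pediatric": "pediatric",
    "adult": "adult",
    "retirement": "adult",
    "geriatric": "adult",
}

_ICD_RE = re.compile(r"^[A-Z][0-9A-Z.]+$")

RATE_COLUMNS = ["zip_id", "icd_code", "stratum", "count", "total_billed", "rate"]


def _validate_counts(df: pd.DataFrame) -> None:
    counts = df["count"].to_numpy(dtype=float)
    if np.any(~np.isfinite(counts)) or np.any(counts < 0):
        raise ValueError("count must be non-negative and finite")
    bad = [c for c in df["icd_code"].unique() if not _ICD_RE.match(str(c))]
    if bad:
        raise ValueError(f"malformed icd_code value(s): {', '.join(map(str, bad[:5]))}")


def compute_rates(diagnosis_counts: pd.DataFrame, totals: pd.DataFrame) -> pd.DataFrame:
    """Join counts to denominators and compute rate = count / total_billed.

    Parameters
    ----------
    diagnosis_counts:
        ``zip_id, icd_code, stratum, count`` rows.
    totals:
        ``zip_id, stratum, total_billed`` rows (total billed diagnoses).

    Zips absent from ``totals`` (e.g. withheld at source) are dropped
    with a logged count; rows whose denominator is zero are dropped too.
    """
    for col in ("zip_id", "icd_code", "stratum", "count"):
        if col not in diagnosis_counts.columns:
            raise ValueError(f"diagnosis_counts is missing required column: {col}")
    for col in ("zip_id", "stratum", "total_billed"):
        if col not in totals.columns:
            raise ValueError(f"totals is missing required column: {col}")
    _validate_counts(diagnosis_counts)

    merged = diagnosis_counts.merge(totals, on=["zip_id", "stratum"], how="left")
    missing = merged["total_billed"].isna()
    if missing.any():
        n_zips = merged.loc[missing, "zip_id"].nunique()
        logger.info(
            "dropped %d row(s) across %d zip(s) absent from the totals table",
            int(missing.sum()),
            n_zips,
        )
        merged = merged.loc[~missing]
    merged = merged.loc[merged["total_billed"] > 0].copy()
    merged["rate"] = merged["count"] / merged["total_billed"]
    return merged[RATE_COLUMNS].reset_index(drop=True)


def apply_exclusions(
    rate_table: pd.DataFrame,
    populations: pd.Series | None = None,
    min_zip_fraction: float = 0.02,
    min_national_count: int = 10_000,
    min_zip_population: int = 10_000,
    per_stratum: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Drop small zips and rare or localized ICD codes.

    Order of operations (fixed): the population floor is applied first,
    then occurrence fractions are evaluated over the surviving zips.
    An ICD code is dropped when the fraction of zips with count > 0 is
    strictly below ``min_zip_fraction`` (pooled across strata by
    default; ``per_stratum=True`` evaluates and drops per stratum), or
    when its national total count is strictly below
    ``min_national_count``.

    Returns the filtered table and an exclusion report mapping each
    dropped entity to its reason.
    """
    report: dict = {"zips_excluded_population": [], "icd_excluded": {}}
    table = rate_table.copy()

    if populations is not None and min_zip_population > 0:
        small = {z for z, p in populations.items() if p < min_zip_population}
        dropped_zips = sorted(set(table["zip_id"]) & small)
        if dropped_zips:
            report["zips_excluded_population"] = dropped_zips
            table = table.loc[~table["zip_id"].isin(small)]

    n_zips = table["zip_id"].nunique()
    if n_zips == 0:
        warnings.warn("exclusions removed every zip code", UserWarning, stacklevel=2)
        return table.reset_index(drop=True), report

    grp = table.groupby("icd_code")
    occ_frac = grp.apply(
        lambda g: g.loc[g["count"] > 0, "zip_id"].nunique() / n_zips,
        include_groups=False,
    )
    national = grp["count"].sum()
    for code in occ_frac.index:
        reasons = []
        if not per_stratum and occ_frac[code] < min_zip_fraction:
            reasons.append("zip_fraction")
        if national[code] < min_national_count:
            reasons.append("national_count")
        if reasons:
            report["icd_excluded"][code] = "+".join(reasons)
    dropped_codes = set(report["icd_excluded"])
    table = table.loc[~table["icd_code"].isin(dropped_codes)]

    if per_stratum:
        # occurrence rule evaluated within each stratum's own zip universe
        drop_pairs = []
        for stratum, sub in table.groupby("stratum"):
            n_s = sub["zip_id"].nunique()
            if n_s == 0:
                continue
            frac = sub.groupby("icd_code").apply(
                lambda g: g.loc[g["count"] > 0, "zip_id"].nunique() / n_s,
                include_groups=False,
            )
            for code in frac.index[frac < min_zip_fraction]:
                drop_pairs.append((code, stratum))
        if drop_pairs:
            report["icd_stratum_excluded"] = [
                [code, stratum, "zip_fraction"] for code, stratum in drop_pairs
            ]
            keys = pd.MultiIndex.from_frame(table[["icd_code", "stratum"]])
            table = table.loc[~keys.isin(drop_pairs)]
    if table.empty:
        warnings.warn("exclusions removed every ICD code", UserWarning, stacklevel=2)
    return table.reset_index(drop=True), report


def collapse_strata(rate_table: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Collapse five age strata to two (0-17 and 18+), pooling counts.

    Counts and denominators are summed within the collapsed stratum and
    rates recomputed from the pooled values — a pooled ratio, never a
    mean of ratios.  ``scheme='five_bin'`` validates labels and returns
    the table unchanged.
    """
    if scheme not in ("five_bin", "two_bin"):
        raise ValueError("scheme must be 'five_bin' or 'two_bin'")
    labels = set(rate_table["stratum"].unique())
    unknown = labels - set(FIVE_BIN_STRATA)
    if unknown:
        raise ValueError(f"unknown stratum label(s): {', '.join(sorted(map(str, unknown)))}")
    if scheme == "five_bin":
        return rate_table.copy().reset_index(drop=True)

    table = rate_table.copy()
    table["stratum"] = table["stratum"].map(TWO_BIN_MAP)
    # Denominators live per (zip, original stratum); sum the distinct
    # per-stratum totals, not one copy per ICD row.
    totals = (
        rate_table[["zip_id", "stratum", "total_billed"]]
        .drop_duplicates(["zip_id", "stratum"])
        .assign(stratum=lambda d: d["stratum"].map(TWO_BIN_MAP))
        .groupby(["zip_id", "stratum"], as_index=False)["total_billed"]
        .sum()
    )
    counts = table.groupby(["zip_id", "icd_code", "stratum"], as_index=False)["count"].sum()
    merged = counts.merge(totals, on=["zip_id", "stratum"], how="left")
    merged = merged.loc[merged["total_billed"] > 0].copy()
    merged["rate"] = merged["count"] / merged["total_billed"]
    return merged[RATE_COLUMNS].reset_index(drop=True)
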