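"""SD-distance filtering of coefficient tables and ICD category tallies.

Penalized regression yields no p-values, so associations are ranked by
how far each coefficient sits from the pooled coefficient mean in
sample-SD units: records beyond 2 SD are "flagged", and beyond 5 SD is
the conventional display threshold.  Filtering adds flags — it never
deletes rows — so the full table always survives for audit.

The pooled mean and SD are computed on the beta scale (not the
displayed odds-ratio scale): mean/SD do not commute with the exp
transform, so the choice matters and is fixed here.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["icd_category_tally", "sd_filter", "to_display_or"]

_FAMILY_KEYS = ["medium", "stratum", "model_type"]


def to_display_or(beta):
    """Display transform exp(beta): per-SD multiplicative effect."""
    return np.exp(beta) if np.ndim(beta) else float(np.exp(beta))


def _flag_group(group: pd.DataFrame, k: float) -> pd.DataFrame:
    beta = group["beta"].to_numpy(dtype=float)
    if len(beta) < 2:
        raise ValueError("sd_filter needs at least 2 coefficients per pooling scope")
    m = beta.mean()
    s = beta.std(ddof=1)
    out = group.copy()
    if s == 0:
        warnings.warn(
            "zero spread in pooled betas: no record can pass the SD filter",
            UserWarning,
            stacklevel=4,
        )
        out["sd_distance"] = 0.0
        out["passes"] = False
        out["passes_2sd"] = False
        out["passes_5sd"] = False
        return out
    dist = (beta - m) / s
    out["sd_distance"] = dist
    out["passes"] = np.abs(beta - m) > k * s
    out["passes_2sd"] = np.abs(beta - m) > 2.0 * s
    out["passes_5sd"] = np.abs(beta - m) > 5.0 * s
    return out


def sd_filter(
    coefficient_table: pd.DataFrame,
    k: float = 2.0,
    pool_scope: str = "per_model_family",
    toxicants_only: bool = False,
    toxicant_predictors=None,
) -> pd.DataFrame:
    """Flag coefficients more than ``k`` sample SDs from the pooled mean.

    ``pool_scope`` is ``per_model_family`` (pool within medium x
    stratum x model type — spatial and non-spatial betas live on
    incomparable scales) or ``global`` (one pool, the most literal
    reading of a single cohort-wide mean).  With ``toxicants_only`` the
    pool is restricted to the predictors named in
    ``toxicant_predictors`` (covariate coefficients are otherwise
    eligible to pass, and do in practice — latitude, notably).

    Returns every input row with ``sd_distance``, ``passes`` (at k),
    ``passes_2sd`` and ``passes_5sd`` columns added.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    if pool_scope not in ("global", "per_model_family"):
        raise ValueError("pool_scope must be 'global' or 'per_model_family'")
    table = coefficient_table
    if toxicants_only:
        if toxicant_predictors is None:
            raise ValueError("toxicants_only requires toxicant_predictors")
        table = table.loc[table["predictor"].isin(set(toxicant_predictors))]
    if len(table) < 2:
        raise ValueError("sd_filter needs at least 2 coefficients")

    if pool_scope == "global":
        return _flag_group(table, k).reset_index(drop=True)
    keys = [c for c in _FAMILY_KEYS if c in table.columns]
    parts = [
        _flag_group(group, k) for _, group in table.groupby(keys, dropna=False, sort=True)
    ]
    return pd.concat(parts).sort_index().reset_index(drop=True)


def icd_category_tally(
    rate_table: pd.DataFrame,
    association_records: pd.DataFrame,
    flag_column: str = "passes_2sd",
) -> pd.DataFrame:
    """Per ICD first letter: % of all diagnoses vs % of flagged codes.

    The first column is the share of total diagnosis *counts* carried
    by codes starting with each letter; the second is the share of
    *distinct flagged* ICD codes with that letter.  Letters present in
    one side but not the other get an explicit 0, so each column sums
    to 100 over the letters listed.
    """
    if rate_table.empty and association_records.empty:
        warnings.warn("empty inputs: empty category tally", UserWarning, stacklevel=2)
        return pd.DataFrame(
            columns=["icd_letter", "pct_of_all_diagnoses", "pct_of_filtered_associations"]
        )

    diag = rate_table.assign(icd_letter=rate_table["icd_code"].astype(str).str[0])
    count_by_letter = diag.groupby("icd_letter")["count"].sum()

    flagged = association_records.loc[association_records[flag_column].astype(bool)]
    flagged_codes = flagged["outcome"].astype(str).unique()
    flag_by_letter = pd.Series([c[0] for c in flagged_codes]).value_counts()

    letters = sorted(set(count_by_letter.index) | set(flag_by_letter.index))
    total_counts = count_by_letter.sum()
    total_flags = flag_by_letter.sum()
    rows = []
    for letter in letters:
        pct_all = (
            100.0 * count_by_letter.get(letter, 0) / total_counts if total_counts else 0.0
        )
        pct_flag = (
            100.0 * flag_by_letter.get(letter, 0) / total_flags if total_flags else 0.0
        )
        rows.append(
            {
                "icd_letter": letter,
                "pct_of_all_diagnoses": pct_all,
                "pct_of_filtered_associations": pct_flag,
            }
        )
    return pd.DataFrame(rows)
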