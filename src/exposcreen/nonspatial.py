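"""Untargeted elastic-net screen of one outcome against all exposures.

Each (outcome, age stratum, medium) combination gets its own Gaussian
elastic-net fit over the full predictor matrix — every exposure column
plus the sociodemographic covariates (21 five-year age-bin proportions,
deprivation index, population density, and latitude/longitude for the
non-spatial model).  All predictors are z-scored before fitting, so
coefficients are per-SD effects and comparable across chemicals with
wildly different measurement scales.

The objective is the glmnet one,

    (1/2n) ||y - b0 - X b||^2 + lambda * (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2),

with alpha = 0.5 by default and lambda chosen as the argmin of 10-fold
cross-validated MSE over a 100-point log-spaced path.  Elastic net
produces no p-values; downstream filtering is by SD distance from the
pooled coefficient mean (see :mod:`exposcreen.associations`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_BIN_COLUMNS",
    "BASE_COVARIATES",
    "COEFFICIENT_COLUMNS",
    "DesignMatrix",
    "ElasticNetConfig",
    "assemble_design",
    "fit_elastic_net",
    "screen_all",
]

#: 21 five-year age bins, as proportions of the zip population.
AGE_BIN_COLUMNS = [f"age_{5 * i:02d}_{5 * i + 4:02d}" for i in range(20)] + ["age_100plus"]
BASE_COVARIATES = ["deprivation_index", "pop_density"]

COEFFICIENT_COLUMNS = [
    "outcome",
    "stratum",
    "medium",
    "model_type",
    "predictor",
    "beta",
    "or",
    "lambda_selected",
    "n_zips",
]

INTERCEPT_NAME = "(intercept)"


@dataclass(frozen=True)
class ElasticNetConfig:
    """Mixing weight, CV folds, lambda path and seed for one screen."""

    alpha: float = 0.5
    n_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_lambda < 1 or not 0 < self.lambda_min_ratio <= 1:
            raise ValueError("invalid lambda path specification")


@dataclass
class DesignMatrix:
    """Aligned, z-scored predictors and outcome for one model fit."""

    zip_ids: list
    predictor_names: list
    X: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.zip_ids), len(self.predictor_names)):
            raise ValueError("X shape does not match zip/predictor lists")
        if self.y.shape != (len(self.zip_ids),):
            raise ValueError("y length does not match zip list")
        if np.any(~np.isfinite(self.X)) or np.any(~np.isfinite(self.y)):
            raise ValueError("design contains non-finite values")


def zscore(values: np.ndarray) -> np.ndarray:
    """Column-wise (x - mean) / SD with population (ddof=0) SD."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    return (values - mean) / sd


def assemble_design(
    rate_table: pd.DataFrame | None,
    exposure_matrix,
    zips: pd.DataFrame,
    outcome_spec,
    include_latlon: bool = True,
    exclude_predictors: tuple = (),
) -> DesignMatrix:
    """Inner-join inputs on zip, z-score predictors, return the design.

    ``outcome_spec`` is either an ``(icd_code, stratum)`` pair — the
    outcome is then that disease rate — or the name of a per-zip column
    of ``zips`` (deprivation index, an ethnicity percentage, a
    redlining score ...), which is removed from the predictor side so
    the model never predicts a column from itself.

    Constant predictor columns (z-score undefined) are dropped and
    recorded in the report; an empty zip intersection raises.
    """
    expo = exposure_matrix.to_frame()
    medium = exposure_matrix.medium

    cov_cols = [c for c in AGE_BIN_COLUMNS + BASE_COVARIATES if c in zips.columns]
    if include_latlon:
        cov_cols += [c for c in ("lat", "lon") if c in zips.columns]
    zips_indexed = zips.set_index("zip_id")

    if isinstance(outcome_spec, (tuple, list)):
        icd_code, stratum = outcome_spec
        sub = rate_table.loc[
            (rate_table["icd_code"] == icd_code) & (rate_table["stratum"] == stratum)
        ]
        y = sub.set_index("zip_id")["rate"]
        outcome_name = str(icd_code)
    else:
        outcome_name = str(outcome_spec)
        if outcome_name not in zips.columns:
            raise ValueError(f"outcome column not found in zips: {outcome_name}")
        y = zips_indexed[outcome_name]
        stratum = "all"
        cov_cols = [c for c in cov_cols if c != outcome_name]

    exclude = set(exclude_predictors) | {outcome_name}
    cov_cols = [c for c in cov_cols if c not in exclude]
    expo = expo[[c for c in expo.columns if c not in exclude]]

    predictors = expo.join(zips_indexed[cov_cols], how="inner")
    joined = predictors.join(y.rename("__outcome__"), how="inner").dropna()
    report = {
        "n_zips_exposure": len(expo),
        "n_zips_covariates": len(zips_indexed),
        "n_zips_outcome": int(y.notna().sum()),
        "n_zips_retained": len(joined),
    }
    if joined.empty:
        raise ValueError("no zip codes shared across exposure, covariate and outcome inputs")

    X_raw = joined.drop(columns="__outcome__")
    sds = X_raw.std(axis=0, ddof=0)
    constant = list(sds.index[sds == 0])
    if constant:
        logger.info("dropped %d constant predictor column(s): %s", len(constant), constant[:10])
        X_raw = X_raw.drop(columns=constant)
    report["constant_columns_dropped"] = constant

    return DesignMatrix(
        zip_ids=list(joined.index),
        predictor_names=list(X_raw.columns),
        X=zscore(X_raw.to_numpy()),
        y=joined["__outcome__"].to_numpy(dtype=float),
        meta={"outcome": outcome_name, "stratum": stratum, "medium": medium},
        report=report,
    )


def lambda_path(X: np.ndarray, y: np.ndarray, config: ElasticNetConfig) -> np.ndarray:
    """glmnet-style path: lambda_max down to lambda_max * min_ratio.

    lambda_max is the smallest lambda at which every coefficient is
    zero, max_j |x_j . (y - ybar)| / (n * alpha); for alpha near 0 the
    conventional 1e-3 floor is substituted so the path stays finite.
    """
    n = len(y)
    lam_max = float(np.max(np.abs(X.T @ (y - y.mean())))) / (n * max(config.alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


def fit_elastic_net(
    design: DesignMatrix,
    config: ElasticNetConfig | None = None,
    lambdas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit one elastic net, selecting lambda by CV-MSE argmin.

    Returns long-format coefficient rows (intercept and every
    predictor, zeros included) with both beta and exp(beta).  Fold
    assignment is a pure function of the seed, so repeated runs are
    identical.  A constant outcome short-circuits to the exact solution
    (all slopes zero, intercept = mean).
    """
    if config is None:
        config = ElasticNetConfig()
    X, y = design.X, design.y
    n = len(y)

    if np.std(y) == 0.0:
        betas = np.zeros(X.shape[1])
        intercept, lam_sel = float(y[0]) if n else 0.0, float("nan")
    else:
        if lambdas is None:
            lambdas = lambda_path(X, y, config)
        lambdas = np.sort(np.atleast_1d(np.asarray(lambdas, dtype=float)))[::-1]
        l1_ratio = config.alpha
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)  # l1_ratio=0 advisory
            if len(lambdas) == 1:
                model = ElasticNet(
                    alpha=float(lambdas[0]),
                    l1_ratio=l1_ratio,
                    max_iter=100_000,
                    tol=1e-10,
                )
                model.fit(X, y)
                lam_sel = float(lambdas[0])
            else:
                cv = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
                model = ElasticNetCV(
                    l1_ratio=l1_ratio,
                    alphas=lambdas,
                    cv=cv,
                    max_iter=50_000,
                    tol=1e-7,
                )
                model.fit(X, y)
                lam_sel = float(model.alpha_)
        betas = np.asarray(model.coef_, dtype=float)
        intercept = float(model.intercept_)

    names = [INTERCEPT_NAME] + list(design.predictor_names)
    coefs = np.concatenate([[intercept], betas])
    return pd.DataFrame(
        {
            "outcome": design.meta.get("outcome"),
            "stratum": design.meta.get("stratum"),
            "medium": design.meta.get("medium"),
            "model_type": "nonspatial",
            "predictor": names,
            "beta": coefs,
            "or": np.exp(coefs),
            "lambda_selected": lam_sel,
            "n_zips": n,
        }
    )[COEFFICIENT_COLUMNS]


def screen_all(
    rate_table: pd.DataFrame,
    exposure_matrix,
    zips: pd.DataFrame,
    config: ElasticNetConfig | None = None,
    include_latlon: bool = True,
    out_path=None,
) -> pd.DataFrame:
    """Loop the elastic-net fit over every (outcome x stratum).

    Outcomes are visited in sorted order for determinism.  Individual
    failures are logged and skipped; the screen continues.  When
    ``out_path`` names an existing CSV, outcomes already present there
    are skipped and the new rows appended (resumability).
    """
    if config is None:
        config = ElasticNetConfig()
    columns = COEFFICIENT_COLUMNS
    if rate_table is None or rate_table.empty:
        warnings.warn("empty rate table: nothing to screen", UserWarning, stacklevel=2)
        return pd.DataFrame(columns=columns)

    done: set = set()
    parts: list[pd.DataFrame] = []
    if out_path is not None:
        import os

        if os.path.exists(out_path):
            existing = pd.read_csv(out_path)
            parts.append(existing)
            done = set(zip(existing["outcome"].astype(str), existing["stratum"].astype(str)))

    outcomes = sorted(
        set(zip(rate_table["icd_code"].astype(str), rate_table["stratum"].astype(str)))
    )
    for icd_code, stratum in outcomes:
        if (icd_code, stratum) in done:
            continue
        try:
            design = assemble_design(
                rate_table, exposure_matrix, zips, (icd_code, stratum), include_latlon
            )
            design.meta["stratum"] = stratum
            parts.append(fit_elastic_net(design, config))
        except Exception:  # noqa: BLE001 - a single outcome must not kill the screen
            logger.exception("screen failed for outcome %s / %s; continuing", icd_code, stratum)
    result = (
        pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=columns)
    )
    if out_path is not None:
        result.to_csv(out_path, index=False)
    return result
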