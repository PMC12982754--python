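"""Nested spatial clustering and the negative-binomial mixed model.

Area-level disease counts are spatially autocorrelated: neighbouring
zip codes share providers, demographics and unmeasured environment.  To
absorb that structure, zip centroids are clustered once by
complete-linkage on great-circle distances and the single dendrogram is
cut at four heights, giving four *nested* partitions with target mean
sizes of roughly 81, 27, 9 and 3 zips.  Cutting one tree (rather than
clustering four times) guarantees nesting by construction.

Counts are then modelled per (disease x focal chemical x stratum) as

    y_z ~ NegBin(mu_z, theta),
    log mu_z = log(total visits_z) + b0 + b_tox * x_z + covariates + u1 + u2 + u3 + u4,

with u_l ~ Normal(0, sigma_l^2) independent random intercepts at each
clustering level.  The marginal likelihood is maximized with a Laplace
approximation: an inner penalized IRLS solves jointly for the fixed and
random effects at fixed (sigma^2, theta), and an outer derivative-free
bounded search moves (log sigma_l^2, log theta).  Standard errors for
the focal coefficient are Wald, read off the observed-information block
of the joint penalized system.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln

from .geo import great_circle_distance
from .nonspatial import COEFFICIENT_COLUMNS, zscore
from .rates import collapse_strata

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterHierarchy",
    "SpatialFitResult",
    "build_cluster_hierarchy",
    "fit_nb_glmm",
    "nb_log_likelihood",
    "spatial_screen",
]

DEFAULT_TARGET_SIZES = (81, 27, 9, 3)

#: Box constraints for the outer search, on the log scale.
LOG_VARIANCE_BOUNDS = (-23.0, 5.0)
LOG_THETA_BOUNDS = (-5.0, 12.0)

_ETA_CLIP = 30.0


@dataclass
class ClusterHierarchy:
    """Nested partitions of the zip codes, coarse to fine.

    ``levels[l]`` holds integer cluster labels (0-based, contiguous,
    first-occurrence order over the sorted zip ids) for level ``l``.
    ``cut_counts`` records the cluster count requested at every level
    of ``target_sizes``, including levels later collapsed as duplicate
    partitions.
    """

    zip_ids: list
    levels: list
    target_sizes: tuple
    cut_counts: tuple

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def mean_cluster_size(self, level: int) -> float:
        labels = self.levels[level]
        return len(labels) / len(np.unique(labels))

    def to_frame(self) -> pd.DataFrame:
        data = {"zip_id": self.zip_ids}
        for l, labels in enumerate(self.levels, start=1):
            data[f"level{l}"] = labels + 1
        return pd.DataFrame(data)


def _relabel_first_occurrence(labels: np.ndarray) -> np.ndarray:
    mapping: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def build_cluster_hierarchy(
    zips: pd.DataFrame, target_sizes: tuple = DEFAULT_TARGET_SIZES
) -> ClusterHierarchy:
    """Cut one complete-linkage dendrogram at the per-level cluster counts.

    Level ``l`` is the dendrogram cut into ``K_l = max(1, round(N /
    size_l))`` clusters.  Zips are sorted by id before the distance
    matrix is formed, so the result is invariant to input row order and
    label names are stable across runs.  Levels whose cuts coincide
    (small N) are collapsed with a warning.
    """
    if len(zips) < 4:
        raise ValueError("need at least 4 zip codes to build a hierarchy")
    sizes = tuple(target_sizes)
    if any(a <= b for a, b in zip(sizes, sizes[1:])):
        raise ValueError("target_sizes must be strictly decreasing (coarse to fine)")

    ordered = zips.sort_values("zip_id", kind="mergesort").reset_index(drop=True)
    lat = ordered["lat"].to_numpy(dtype=float)
    lon = ordered["lon"].to_numpy(dtype=float)
    n = len(ordered)
    D = great_circle_distance(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(D, 0.0)
    tree = linkage(squareform(D, checks=False), method="complete")

    levels, cut_counts, seen = [], [], set()
    for size in sizes:
        k = max(1, int(math.floor(n / size + 0.5)))  # round half up
        labels = _relabel_first_occurrence(fcluster(tree, t=k, criterion="maxclust"))
        cut_counts.append(int(labels.max()) + 1)
        key = labels.tobytes()
        if key in seen:
            continue
        seen.add(key)
        levels.append(labels)
    if len(levels) < len(sizes):
        warnings.warn(
            f"{len(sizes) - len(levels)} duplicate cluster level(s) collapsed "
            f"(N={n} too small for distinct cuts)",
            UserWarning,
            stacklevel=2,
        )
    return ClusterHierarchy(
        zip_ids=list(ordered["zip_id"]),
        levels=levels,
        target_sizes=sizes,
        cut_counts=tuple(cut_counts),
    )


def nb_log_likelihood(y, mu, theta: float) -> float:
    """NB2 log-likelihood sum_i [lnG(y+th) - lnG(th) - lnG(y+1) + th ln(th/(th+mu)) + y ln(mu/(th+mu))]."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = float(theta)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain non-negative integers")
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be positive and finite")
    if not theta > 0:
        raise ValueError("theta must be positive")
    ll = (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )
    return float(ll.sum())


@dataclass
class SpatialFitResult:
    """One fitted NB mixed model: coefficients, dispersion, variances."""

    beta: np.ndarray
    se: np.ndarray
    predictor_names: list
    theta: float
    re_variances: np.ndarray
    loglik: float
    converged: bool
    boundary: bool
    n_obs: int
    focal_index: int = 1
    n_outer_evals: int = 0

    @property
    def beta_toxicant(self) -> float:
        return float(self.beta[self.focal_index])

    @property
    def se_toxicant(self) -> float:
        return float(self.se[self.focal_index])


def _build_random_design(levels, mask=None):
    """One-hot random-effect design per level; empty clusters dropped.

    Returns (Z csr, penalty_index) where penalty_index[j] names the
    level of random-effect column j.
    """
    blocks, level_of = [], []
    for l, labels in enumerate(levels):
        labels = np.asarray(labels)
        if mask is not None:
            labels = labels[mask]
        present = np.unique(labels)
        col = np.searchsorted(present, labels)
        Z_l = sparse.csr_matrix(
            (np.ones(len(labels)), (np.arange(len(labels)), col)),
            shape=(len(labels), len(present)),
        )
        blocks.append(Z_l)
        level_of.extend([l] * len(present))
    Z = sparse.hstack(blocks, format="csr")
    return Z, np.asarray(level_of, dtype=int)


def _pirls(y, X, Z, offset, pen, theta, coef0=None, tol=1e-9, max_iter=200, trace=None):
    """Penalized IRLS for the joint (beta, u) mode at fixed (sigma^2, theta).

    ``pen`` is the per-random-effect-column prior precision 1/sigma^2.
    Step-halving keeps the penalized log-likelihood non-decreasing.
    Returns (coef, weights, mu, penalized_ll, converged).
    """
    n, p = X.shape
    q = Z.shape[1] if Z is not None else 0
    m = p + q

    def eta_of(cf):
        eta = offset + X @ cf[:p]
        if q:
            eta = eta + Z @ cf[p:]
        return np.clip(eta, -_ETA_CLIP, _ETA_CLIP)

    def pen_ll(cf, mu):
        ll = nb_log_likelihood(y, mu, theta)
        if q:
            ll -= 0.5 * float(pen @ (cf[p:] ** 2))
        return ll

    if coef0 is not None and len(coef0) == m:
        coef = np.array(coef0, dtype=float)
    else:
        coef = np.zeros(m)
        base = y / np.exp(np.clip(offset, -_ETA_CLIP, _ETA_CLIP))
        coef[0] = math.log(max(float(base.mean()), 1e-8))  # intercept-first convention

    eta = eta_of(coef)
    mu = np.exp(eta)
    cur = pen_ll(coef, mu)
    if trace is not None:
        trace.append(cur)
    converged = False
    for _ in range(max_iter):
        w = mu * theta / (theta + mu)
        z_work = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        A11 = X.T @ Xw
        b1 = X.T @ (w * z_work)
        if q:
            ZT = Z.T.tocsr()
            A21 = ZT @ Xw  # (q, p) dense
            A22 = (ZT @ sparse.diags(w) @ Z).toarray()
            A22[np.diag_indices_from(A22)] += pen
            A = np.block([[A11, A21.T], [A21, A22]])
            b = np.concatenate([b1, ZT @ (w * z_work)])
        else:
            A, b = A11, b1
        try:
            proposal = sla.solve(A, b, assume_a="pos")
        except sla.LinAlgError:
            proposal = np.linalg.lstsq(A, b, rcond=None)[0]

        direction = proposal - coef
        step = 1.0
        for _half in range(30):
            cand = coef + step * direction
            eta_c = eta_of(cand)
            mu_c = np.exp(eta_c)
            obj_c = pen_ll(cand, mu_c)
            if obj_c >= cur - 1e-10:
                break
            step *= 0.5
        delta = float(np.max(np.abs(cand - coef)))
        improved = obj_c - cur
        coef, eta, mu, cur = cand, eta_c, mu_c, obj_c
        if trace is not None:
            trace.append(cur)
        if delta < tol or abs(improved) < 1e-12:
            converged = True
            break
    w = mu * theta / (theta + mu)
    return coef, w, mu, cur, converged


def _laplace_loglik(pen_obj, Z, w, pen):
    """Laplace marginal log-likelihood from the converged inner fit."""
    if Z is None or Z.shape[1] == 0:
        return pen_obj
    ZT = Z.T.tocsr()
    H = (ZT @ sparse.diags(w) @ Z).toarray()
    H[np.diag_indices_from(H)] += pen
    sign, logdet_h = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    # -0.5 logdet(Sigma) = +0.5 sum(log pen)
    return pen_obj + 0.5 * float(np.sum(np.log(pen))) - 0.5 * logdet_h


def fit_nb_glmm(
    y,
    X,
    offset=None,
    hierarchy=None,
    *,
    focal_index: int = 1,
    predictor_names=None,
    fix_variances=None,
    fix_theta=None,
    init_variance: float = 0.05,
    init_theta: float = 1.0,
    outer_tol: float = 1e-6,
    max_outer: int = 400,
) -> SpatialFitResult:
    """Fit the NB GLMM by Laplace approximation.

    Parameters
    ----------
    y, X, offset:
        Counts, fixed-effect design (intercept first) and log-exposure
        offset, all aligned.
    hierarchy:
        A :class:`ClusterHierarchy`, a sequence of per-level label
        vectors aligned with ``y``, or None for no random effects.
    fix_variances:
        Scalar or per-level sequence pinning the random-intercept
        variances instead of estimating them; exact zeros remove the
        level.  ``fix_theta`` pins the dispersion analogously.

    Notes
    -----
    A variance estimated at (or clamped to) the lower box bound
    ``exp(-23) ~ 1e-10`` is reported via ``boundary=True``.  A fit that
    fails to converge is returned flagged, never silently.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset must be finite (exclude zips with zero total visits)")

    if hierarchy is None:
        levels = []
    elif isinstance(hierarchy, ClusterHierarchy):
        levels = list(hierarchy.levels)
    else:
        levels = [np.asarray(lv) for lv in hierarchy]
    nlev = len(levels)

    if fix_variances is not None:
        fixv = np.broadcast_to(np.asarray(fix_variances, dtype=float), (nlev,)).copy()
        keep = fixv > 0
        levels = [lv for lv, k in zip(levels, keep) if k]
        fixv = fixv[keep]
    else:
        fixv = None

    if levels:
        Z, level_of = _build_random_design(levels)
    else:
        Z, level_of = None, np.empty(0, dtype=int)
    n_re_levels = len(levels)

    state = {"coef": None, "w": None, "pen": None}

    def evaluate(log_s2, log_theta, trace=None):
        theta = math.exp(log_theta)
        if n_re_levels:
            s2 = np.exp(np.asarray(log_s2, dtype=float))
            pen = 1.0 / s2[level_of]
        else:
            pen = np.empty(0)
        coef, w, mu, pen_obj, ok = _pirls(
            y, X, Z, offset, pen, theta, coef0=state["coef"], trace=trace
        )
        state.update(coef=coef, w=w, pen=pen, inner_ok=ok)
        ll = _laplace_loglik(pen_obj, Z, w, pen)
        return ll

    free_var = fixv is None and n_re_levels > 0
    free_theta = fix_theta is None

    def objective(params):
        i = 0
        if free_var:
            log_s2 = params[:n_re_levels]
            i = n_re_levels
        else:
            log_s2 = np.log(fixv) if n_re_levels else []
        log_theta = params[i] if free_theta else math.log(fix_theta)
        ll = evaluate(log_s2, log_theta)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    n_free = (n_re_levels if free_var else 0) + (1 if free_theta else 0)
    n_evals = 0
    outer_ok = True
    if n_free == 0:
        fval = objective(np.empty(0))
        xopt = np.empty(0)
        n_evals = 1
    elif n_free == 1 and free_theta and not free_var:
        res = optimize.minimize_scalar(
            lambda lt: objective(np.array([lt])),
            bounds=LOG_THETA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-9},
        )
        xopt, fval, n_evals = np.array([res.x]), res.fun, res.nfev
        outer_ok = bool(res.success)
    else:
        x0 = []
        bounds = []
        if free_var:
            x0 += [math.log(init_variance)] * n_re_levels
            bounds += [LOG_VARIANCE_BOUNDS] * n_re_levels
        if free_theta:
            x0.append(math.log(init_theta))
            bounds.append(LOG_THETA_BOUNDS)
        res = optimize.minimize(
            objective,
            np.asarray(x0),
            method="Powell",
            bounds=bounds,
            options={"maxiter": max_outer, "ftol": outer_tol, "xtol": 1e-3},
        )
        xopt, fval, n_evals = res.x, res.fun, res.nfev
        outer_ok = bool(res.success)

    # Refresh cached state at the optimum and extract the answer.
    fval = objective(xopt)
    coef, w, pen = state["coef"], state["w"], state["pen"]
    inner_ok = bool(state.get("inner_ok", False))

    i = 0
    if free_var:
        log_s2_hat = xopt[:n_re_levels]
        i = n_re_levels
    else:
        log_s2_hat = np.log(fixv) if n_re_levels else np.empty(0)
    theta_hat = math.exp(xopt[i]) if free_theta else float(fix_theta)
    s2_hat = np.exp(np.asarray(log_s2_hat, dtype=float)) if n_re_levels else np.empty(0)
    boundary = bool(np.any(np.asarray(log_s2_hat) <= LOG_VARIANCE_BOUNDS[0] + 1e-3))

    # Wald covariance from the joint penalized observed information.
    eta = np.clip(offset + X @ coef[:p] + (Z @ coef[p:] if Z is not None else 0.0),
                  -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu * theta_hat / (theta_hat + mu)
    Xw = X * w[:, None]
    A11 = X.T @ Xw
    if Z is not None and Z.shape[1]:
        ZT = Z.T.tocsr()
        A21 = ZT @ Xw
        A22 = (ZT @ sparse.diags(w) @ Z).toarray()
        A22[np.diag_indices_from(A22)] += pen
        A = np.block([[A11, A21.T], [A21, A22]])
    else:
        A = A11
    try:
        cov = sla.inv(A)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    except sla.LinAlgError:
        se = np.full(p, np.nan)
        inner_ok = False

    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(p)]
    result = SpatialFitResult(
        beta=coef[:p],
        se=se,
        predictor_names=list(predictor_names),
        theta=theta_hat,
        re_variances=s2_hat,
        loglik=-float(fval),
        converged=bool(outer_ok and inner_ok and np.isfinite(fval)),
        boundary=boundary,
        n_obs=n,
        focal_index=focal_index,
        n_outer_evals=n_evals,
    )
    if not result.converged:
        logger.warning("NB GLMM fit did not converge (outer=%s inner=%s)", outer_ok, inner_ok)
    return result


def spatial_screen(
    rate_table: pd.DataFrame,
    exposure_matrix,
    zips: pd.DataFrame,
    hierarchy: ClusterHierarchy,
    strata: str = "two_bin",
    chemicals=None,
    covariate_columns=(),
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Univariate NB GLMM per (disease x chemical x stratum).

    Each fit carries one focal chemical (z-scored), the requested
    covariate columns, the nested random intercepts, and a log-offset
    for total visits.  Strata with all-zero counts and zips with zero
    total visits are skipped and reported; non-converged fits appear in
    the table flagged ``converged=False`` and are listed in the report
    so downstream filtering can exclude them.
    """
    report: dict = {"skipped": [], "non_converged": [], "zero_total_zips": 0}
    table = collapse_strata(rate_table, strata)
    expo = exposure_matrix.to_frame()
    if chemicals is None:
        chemicals = list(expo.columns)
    zips_indexed = zips.set_index("zip_id")

    zip_order = list(hierarchy.zip_ids)
    pos = {z: i for i, z in enumerate(zip_order)}
    totals = table[["zip_id", "stratum", "total_billed"]].drop_duplicates(
        ["zip_id", "stratum"]
    )

    rows = []
    diseases = sorted(table["icd_code"].unique())
    strata_labels = sorted(table["stratum"].unique())
    for icd in diseases:
        for stratum in strata_labels:
            tot_s = totals.loc[totals["stratum"] == stratum].set_index("zip_id")[
                "total_billed"
            ]
            usable = [
                z
                for z in zip_order
                if z in tot_s.index and tot_s[z] > 0 and z in expo.index
            ]
            report["zero_total_zips"] += int((tot_s <= 0).sum())
            if not usable:
                report["skipped"].append((icd, stratum, "no usable zips"))
                continue
            mask = np.array([pos[z] for z in usable], dtype=int)
            counts = (
                table.loc[
                    (table["icd_code"] == icd) & (table["stratum"] == stratum)
                ]
                .set_index("zip_id")["count"]
                .reindex(usable)
                .fillna(0.0)
                .to_numpy()
            )
            if counts.sum() == 0:
                report["skipped"].append((icd, stratum, "all-zero counts"))
                continue
            offset = np.log(tot_s.reindex(usable).to_numpy(dtype=float))
            levels_sub = [lv[mask] for lv in hierarchy.levels]

            cov_block = None
            cov_names = []
            if covariate_columns:
                cov_df = zips_indexed.loc[usable, list(covariate_columns)]
                sds = cov_df.std(axis=0, ddof=0)
                cov_names = [c for c in cov_df.columns if sds[c] > 0]
                if cov_names:
                    cov_block = zscore(cov_df[cov_names].to_numpy())

            for chem in chemicals:
                x = expo.loc[usable, chem].to_numpy(dtype=float)
                if np.std(x) == 0:
                    report["skipped"].append((icd, stratum, f"constant exposure {chem}"))
                    continue
                parts = [np.ones((len(usable), 1)), zscore(x[:, None])]
                if cov_block is not None:
                    parts.append(cov_block)
                Xmat = np.hstack(parts)
                try:
                    res = fit_nb_glmm(
                        counts,
                        Xmat,
                        offset,
                        levels_sub,
                        focal_index=1,
                        predictor_names=["(intercept)", chem] + cov_names,
                        **fit_kwargs,
                    )
                except Exception:  # noqa: BLE001
                    logger.exception(
                        "spatial fit failed for %s/%s/%s; continuing", icd, stratum, chem
                    )
                    report["skipped"].append((icd, stratum, f"fit error {chem}"))
                    continue
                if not res.converged:
                    report["non_converged"].append((icd, chem, stratum))
                rows.append(
                    {
                        "outcome": icd,
                        "stratum": stratum,
                        "medium": exposure_matrix.medium,
                        "model_type": "spatial",
                        "predictor": chem,
                        "beta": res.beta_toxicant,
                        "or": math.exp(res.beta_toxicant),
                        "lambda_selected": np.nan,
                        "n_zips": res.n_obs,
                        "se": res.se_toxicant,
                        "theta": res.theta,
                        "converged": res.converged,
                    }
                )
    columns = COEFFICIENT_COLUMNS + ["se", "theta", "converged"]
    return pd.DataFrame(rows, columns=columns), report
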