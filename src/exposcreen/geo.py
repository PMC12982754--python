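"""Exposure assignment from point sources to areal units.

Air releases are spread over a circular catchment around each zip-code
centroid using a Gaussian distance kernel: the zip code marks the
location of the healthcare *provider*, not the patient, so facilities
are down-weighted by the distance a patient would plausibly travel.
The kernel width comes from the half-normal mean relation — if travel
distance is |X| with X ~ Normal(0, sigma^2) and the mean trip is 8.6
miles, then sigma = 8.6 * sqrt(pi/2) = 10.7785 miles.

Water measurements are not dispersed at all: a monitor's reading counts
only toward the zip code that hosts the monitor, and zips without a
monitor are simply absent (never imputed to zero).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sphere radius used for all great-circle distances, in miles.
EARTH_RADIUS_MILES = 3958.8

__all__ = [
    "EARTH_RADIUS_MILES",
    "ExposureMatrix",
    "KernelConfig",
    "build_air_exposure",
    "build_water_exposure",
    "great_circle_distance",
    "half_normal_sigma",
]


def _validate_coords(lat, lon, context: str) -> None:
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    if np.any(~np.isfinite(lat)) or np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValueError(f"{context}: latitude must lie in [-90, 90]")
    if np.any(~np.isfinite(lon)) or np.any(lon < -180.0) or np.any(lon > 180.0):
        raise ValueError(f"{context}: longitude must lie in [-180, 180]")


def great_circle_distance(lat1, lon1, lat2, lon2):
    """Haversine distance in miles between WGS84 points.

    Broadcasts over array inputs; returns a float for scalar inputs.
    The Earth is treated as a sphere of radius 3958.8 miles — the
    ellipsoidal correction is negligible at catchment (tens of miles)
    scale.
    """
    _validate_coords(lat1, lon1, "point 1 (lat1/lon1)")
    _validate_coords(lat2, lon2, "point 2 (lat2/lon2)")
    phi1, lam1, phi2, lam2 = (
        np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2)
    )
    h = (
        np.sin((phi2 - phi1) / 2.0) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def half_normal_sigma(mean_distance: float) -> float:
    """Kernel sigma whose half-normal mean equals ``mean_distance``.

    For X ~ Normal(0, sigma^2), E|X| = sigma * sqrt(2/pi).  Inverting
    gives sigma = mean * sqrt(pi/2); with the 8.6-mile assumed mean
    patient-to-provider trip this yields 10.7785 miles.
    """
    mean_distance = float(mean_distance)
    if not math.isfinite(mean_distance) or mean_distance <= 0:
        raise ValueError("mean_distance must be a positive, finite number")
    return mean_distance * math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class KernelConfig:
    """Catchment and kernel parameters for air-exposure weighting.

    Parameters
    ----------
    radius_miles:
        Catchment radius; facilities strictly beyond it contribute
        nothing.  Membership uses ``distance <= radius`` (closed ball).
    sigma_miles:
        Gaussian kernel standard deviation.
    mean_patient_distance_miles:
        The travel-distance assumption sigma was derived from; kept for
        provenance.
    mode:
        ``weighted_mean`` (population- and kernel-weighted mean of the
        release amounts, default) or ``weighted_sum`` (kernel-discounted
        total normalized by the zero-distance weight mass).
    """

    radius_miles: float = 30.0
    sigma_miles: float = 10.7785
    mean_patient_distance_miles: float = 8.6
    mode: str = "weighted_mean"

    def __post_init__(self) -> None:
        if not self.radius_miles > 0:
            raise ValueError("radius_miles must be positive")
        if not self.sigma_miles > 0:
            raise ValueError("sigma_miles must be positive")
        if self.mode not in ("weighted_mean", "weighted_sum"):
            raise ValueError("mode must be 'weighted_mean' or 'weighted_sum'")

    @classmethod
    def from_mean_distance(cls, mean_distance: float, **kwargs) -> "KernelConfig":
        """Build a config with sigma derived from a mean travel distance."""
        return cls(
            sigma_miles=half_normal_sigma(mean_distance),
            mean_patient_distance_miles=float(mean_distance),
            **kwargs,
        )

    def to_dict(self) -> dict:
        return {
            "radius_miles": self.radius_miles,
            "sigma_miles": self.sigma_miles,
            "mean_patient_distance_miles": self.mean_patient_distance_miles,
            "mode": self.mode,
        }


@dataclass
class ExposureMatrix:
    """Zip x chemical exposure values plus provenance.

    For air, every cell is defined and an empty catchment is an explicit
    zero.  For water, only monitored zips appear as rows, and a
    monitored zip may still hold NaN for chemicals its monitors never
    measured — absence of information, not zero exposure.
    """

    zip_ids: list
    chemical_ids: list
    values: np.ndarray
    medium: str
    config: object = None

    def __post_init__(self) -> None:
        self.zip_ids = list(self.zip_ids)
        self.chemical_ids = list(self.chemical_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.zip_ids), len(self.chemical_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.zip_ids)} zips x {len(self.chemical_ids)} chemicals"
            )
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise ValueError("exposure values must be non-negative")
        if self.medium not in ("air", "water"):
            raise ValueError("medium must be 'air' or 'water'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.zip_ids, name="zip_id"),
            columns=list(self.chemical_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, medium: str, config=None) -> "ExposureMatrix":
        return cls(
            zip_ids=list(frame.index),
            chemical_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            medium=medium,
            config=config,
        )


def _require_columns(df: pd.DataFrame, columns: Sequence[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required column(s): {', '.join(missing)}")


def build_air_exposure(
    zips: pd.DataFrame,
    releases: pd.DataFrame,
    config: KernelConfig | None = None,
    chemicals: Sequence[str] | None = None,
) -> ExposureMatrix:
    """Gaussian-catchment exposure matrix from facility point releases.

    For each zip code z and chemical c, facilities releasing c within
    ``radius_miles`` of the centroid contribute with weight
    ``Pop_i * exp(-d_i^2 / (2 sigma^2))`` where ``Pop_i`` is the
    population of the facility's nearest zip unit (or an explicit
    ``population`` column on ``releases``).  In ``weighted_mean`` mode
    the exposure is the weighted mean of the release amounts (units of
    the release); in ``weighted_sum`` mode the kernel-discounted total
    normalized by the zero-distance weight mass.  A zip with no
    in-catchment facility for a chemical is assigned an explicit 0.

    Parameters
    ----------
    zips:
        One row per areal unit with ``zip_id, lat, lon, population``.
    releases:
        ``facility_id, lat, lon, chemical_id, amount`` rows; duplicate
        (facility, chemical) rows are summed.  An optional
        ``population`` column overrides the nearest-zip population.
    chemicals:
        Optional chemical universe; members absent from ``releases``
        are dropped with a logged notice rather than kept as all-zero
        columns.
    """
    if config is None:
        config = KernelConfig()
    _require_columns(zips, ["zip_id", "lat", "lon", "population"], "zips")
    _require_columns(
        releases, ["facility_id", "lat", "lon", "chemical_id", "amount"], "releases"
    )
    if len(releases) == 0 or releases["chemical_id"].nunique() == 0:
        raise ValueError("releases contain no chemicals")
    amounts = releases["amount"].to_numpy(dtype=float)
    if np.any(~np.isfinite(amounts)) or np.any(amounts < 0):
        raise ValueError("release amount must be non-negative and finite")
    _validate_coords(zips["lat"], zips["lon"], "zips")
    _validate_coords(releases["lat"], releases["lon"], "releases")

    if chemicals is not None:
        present = set(releases["chemical_id"])
        dropped = [c for c in chemicals if c not in present]
        if dropped:
            logger.info(
                "%d chemical(s) never released anywhere dropped from the matrix: %s",
                len(dropped),
                ", ".join(map(str, dropped[:10])),
            )

    fac_cols = ["facility_id", "lat", "lon"] + (
        ["population"] if "population" in releases.columns else []
    )
    facilities = releases[fac_cols].drop_duplicates("facility_id").reset_index(drop=True)
    amount_matrix = releases.pivot_table(
        index="facility_id", columns="chemical_id", values="amount", aggfunc="sum"
    ).reindex(facilities["facility_id"])
    chem_ids = list(amount_matrix.columns)
    released = amount_matrix.notna().to_numpy()
    A = amount_matrix.fillna(0.0).to_numpy(dtype=float)

    zlat = zips["lat"].to_numpy(dtype=float)
    zlon = zips["lon"].to_numpy(dtype=float)
    flat = facilities["lat"].to_numpy(dtype=float)
    flon = facilities["lon"].to_numpy(dtype=float)
    D = great_circle_distance(zlat[:, None], zlon[:, None], flat[None, :], flon[None, :])

    if "population" in facilities.columns:
        fac_pop = facilities["population"].to_numpy(dtype=float)
    else:
        # Population_i := population of the facility's nearest zip unit.
        nearest = np.argmin(D, axis=0)
        fac_pop = zips["population"].to_numpy(dtype=float)[nearest]

    in_catchment = D <= config.radius_miles
    # Unnormalized Gaussian kernel: any constant factor cancels in the
    # weighted mean and in the phi(0)-normalized sum.
    kernel = np.exp(-(D**2) / (2.0 * config.sigma_miles**2)) * in_catchment
    W = kernel * fac_pop[None, :]

    numer = W @ A
    if config.mode == "weighted_mean":
        denom = W @ released.astype(float)
    else:  # weighted_sum: normalize by the zero-distance weight mass
        denom = (in_catchment * fac_pop[None, :]) @ released.astype(float)
    values = np.divide(numer, denom, out=np.zeros_like(numer), where=denom > 0)

    return ExposureMatrix(
        zip_ids=list(zips["zip_id"]),
        chemical_ids=chem_ids,
        values=values,
        medium="air",
        config=config,
    )


def build_water_exposure(zips: pd.DataFrame, measurements: pd.DataFrame) -> ExposureMatrix:
    """Monitor-zip water exposures: per zip x chemical mean concentration.

    Each measurement counts only toward the zip code hosting the
    monitor; repeated measurements of the same chemical in a zip (e.g.
    from different source registries) are averaged.  Zips with no
    measurement at all have no row — absent, not zero.  Measurements
    referencing unknown zip codes are skipped with a warning.
    """
    _require_columns(zips, ["zip_id"], "zips")
    _require_columns(measurements, ["zip_id", "chemical_id", "concentration"], "measurements")
    conc = measurements["concentration"].to_numpy(dtype=float)
    if np.any(~np.isfinite(conc)) or np.any(conc < 0):
        raise ValueError("concentration must be non-negative and finite")

    known = set(zips["zip_id"])
    unknown_mask = ~measurements["zip_id"].isin(known)
    n_unknown = int(unknown_mask.sum())
    if n_unknown:
        warnings.warn(
            f"{n_unknown} measurement(s) reference unknown zip codes and were skipped",
            UserWarning,
            stacklevel=2,
        )
        logger.warning(
            "skipped %d water measurement(s) with unknown zip codes: %s",
            n_unknown,
            ", ".join(map(str, measurements.loc[unknown_mask, "zip_id"].unique()[:10])),
        )
        measurements = measurements.loc[~unknown_mask]

    table = (
        measurements.groupby(["zip_id", "chemical_id"])["concentration"].mean().unstack()
    )
    return ExposureMatrix(
        zip_ids=list(table.index),
        chemical_ids=list(table.columns),
        values=table.to_numpy(dtype=float),
        medium="water",
        config="monitor_zip_assignment",
    )
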