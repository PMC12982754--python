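"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator fabricates a small regional health system: uniform zip
centroids with log-normal populations and Dirichlet age structure,
facilities whose per-chemical release amounts share a latent log-normal
factor (inducing the toxicant co-linearity real release inventories
show), water monitors on a subset of zips, and diagnosis counts drawn
from the *same* family the spatial model fits — negative binomial with
nested spatial random intercepts and a log total-visits offset — so
parameter recovery is a fair, well-posed test.  Planted toxicant
effects are expressed on the per-SD scale the screens estimate.

Every generator is a pure function of (config, seed).  What this does
NOT emulate: real US geography or zip shapes, census marginals beyond
simple parametric forms, reporting artifacts of the source registries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .enrichment import GeneSetLibrary, ToxinProteinMap
from .geo import ExposureMatrix
from .nonspatial import AGE_BIN_COLUMNS
from .rates import FIVE_BIN_STRATA

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_diagnoses",
    "simulate_geography",
    "simulate_measurements",
    "simulate_releases",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for one synthetic dataset.

    ``planted_effects`` is a list of (chemical_id, icd_code, beta)
    triples; beta is the log-rate effect per SD of exposure.
    ``colinearity_rho`` is the target pairwise correlation of the
    exposure columns.  ``misspecified`` swaps the NB count draw for a
    Poisson-lognormal one, for robustness checks against the fitted
    family.
    """

    n_zips: int = 300
    bbox: tuple = (37.0, 41.0, -88.0, -83.0)
    n_chemicals: int = 20
    n_facilities: int = 600
    colinearity_rho: float = 0.5
    planted_effects: tuple = ()
    theta: float = 5.0
    re_variances: tuple = (0.05, 0.05, 0.05, 0.05)
    baseline_rate: float = 0.01
    totals_range: tuple = (5000, 20000)
    n_null_diseases: int = 4
    misspecified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_zips, self.n_chemicals, self.n_facilities) <= 0:
            raise ValueError("n_zips, n_chemicals and n_facilities must be positive")
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_min < lat_max and lon_min < lon_max):
            raise ValueError("degenerate bounding box")
        if not 0.0 <= self.colinearity_rho <= 0.95:
            raise ValueError("colinearity_rho must lie in [0, 0.95]")
        if not self.theta > 0:
            raise ValueError("theta must be positive")
        if not 0 < self.baseline_rate < 1:
            raise ValueError("baseline_rate must lie in (0, 1)")

    def chemical_ids(self) -> list:
        return [f"CHEM_{i:03d}" for i in range(self.n_chemicals)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for key in ("bbox", "re_variances", "totals_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "planted_effects" in data and data["planted_effects"] is not None:
            data["planted_effects"] = tuple(tuple(e) for e in data["planted_effects"])
        return cls(**data)


_NULL_ICD_POOL = ["J45.9", "K21.9", "M54.5", "E11.9", "I10", "L20.9", "N39.0", "T78.4"]


def disease_codes(config: SimulationConfig) -> list:
    """Planted diseases plus a deterministic slate of null diseases."""
    planted = sorted({icd for _, icd, _ in config.planted_effects})
    nulls = [c for c in _NULL_ICD_POOL if c not in planted][: config.n_null_diseases]
    return planted + nulls


def simulate_geography(config: SimulationConfig) -> pd.DataFrame:
    """Zip units: centroids, population, covariates, age mix, visit totals."""
    rng = np.random.default_rng(config.seed)
    lat_min, lat_max, lon_min, lon_max = config.bbox
    n = config.n_zips
    zips = pd.DataFrame(
        {
            "zip_id": [f"Z{i:05d}" for i in range(n)],
            "lat": rng.uniform(lat_min, lat_max, n),
            "lon": rng.uniform(lon_min, lon_max, n),
            "population": np.round(rng.lognormal(mean=10.4, sigma=0.6, size=n)).astype(int),
            "deprivation_index": rng.normal(100.0, 20.0, n),
            "pop_density": rng.lognormal(mean=6.0, sigma=1.0, size=n),
        }
    )
    age = rng.dirichlet(np.full(21, 8.0), size=n)
    for j, col in enumerate(AGE_BIN_COLUMNS):
        zips[col] = age[:, j]
    lo, hi = config.totals_range
    for stratum in FIVE_BIN_STRATA:
        zips[f"visits_{stratum}"] = rng.integers(lo, hi + 1, size=n)
    return zips


def simulate_releases(config: SimulationConfig, zips: pd.DataFrame) -> pd.DataFrame:
    """Facilities near random zips, with co-linear per-chemical amounts.

    Log amounts follow a one-factor Gaussian model,
    ``log A_cj = mu + (sqrt(r') z_j + sqrt(1-r') e_cj)``, with the
    factor loading chosen so the *lognormal* amounts (sigma_log = 1)
    correlate at approximately ``colinearity_rho`` across chemicals:
    r' = log(1 + rho (e - 1)).
    """
    rng = np.random.default_rng(config.seed + 1)
    n_fac, n_chem = config.n_facilities, config.n_chemicals
    host = rng.integers(0, len(zips), size=n_fac)
    lat = zips["lat"].to_numpy()[host] + rng.uniform(-0.15, 0.15, n_fac)
    lon = zips["lon"].to_numpy()[host] + rng.uniform(-0.15, 0.15, n_fac)
    lat = np.clip(lat, -90.0, 90.0)
    lon = np.clip(lon, -180.0, 180.0)

    rho = config.colinearity_rho
    r_log = math.log1p(rho * (math.e - 1.0))  # lognormal corr ~= rho at sigma_log=1
    z = rng.standard_normal(n_fac)
    eps = rng.standard_normal((n_fac, n_chem))
    log_amount = 3.0 + math.sqrt(r_log) * z[:, None] + math.sqrt(1.0 - r_log) * eps
    amounts = np.exp(log_amount)

    chem_ids = config.chemical_ids()
    records = []
    for j in range(n_fac):
        fid = f"F{j:04d}"
        for c, chem in enumerate(chem_ids):
            records.append((fid, lat[j], lon[j], chem, amounts[j, c]))
    return pd.DataFrame(
        records, columns=["facility_id", "lat", "lon", "chemical_id", "amount"]
    )


def simulate_measurements(
    config: SimulationConfig, zips: pd.DataFrame, monitor_fraction: float = 0.4
) -> pd.DataFrame:
    """Water-monitor readings on a random subset of zips.

    A few chemicals are measured per monitored zip, with two source
    tags occasionally reporting the same chemical (exercising the
    duplicate-averaging rule downstream).
    """
    rng = np.random.default_rng(config.seed + 4)
    chem_ids = config.chemical_ids()
    n_mon = max(1, int(round(monitor_fraction * len(zips))))
    monitored = rng.choice(zips["zip_id"].to_numpy(), size=n_mon, replace=False)
    rows = []
    for z in monitored:
        measured = rng.choice(
            chem_ids, size=min(len(chem_ids), 1 + rng.integers(0, 5)), replace=False
        )
        for chem in measured:
            rows.append((z, chem, rng.lognormal(0.0, 1.0), "survey_a"))
            if rng.random() < 0.3:  # a second registry re-measures
                rows.append((z, chem, rng.lognormal(0.0, 1.0), "survey_b"))
    return pd.DataFrame(rows, columns=["zip_id", "chemical_id", "concentration", "source"])


def _cluster_effects(rng, hierarchy, re_variances) -> np.ndarray:
    """Sum of per-level random intercepts, one value per zip."""
    u = np.zeros(len(hierarchy.zip_ids))
    for labels, s2 in zip(hierarchy.levels, re_variances):
        k = int(labels.max()) + 1
        u += rng.normal(0.0, math.sqrt(s2), size=k)[labels]
    return u


def simulate_diagnoses(
    config: SimulationConfig,
    zips: pd.DataFrame,
    exposure_matrix: ExposureMatrix,
    hierarchy,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw NB counts from the generative twin of the spatial model.

    For each disease and five-bin stratum,
    ``log mu_z = log(totals_z) + log(baseline_rate) + sum planted
    beta * x_z + u_z`` with ``x`` the z-scored exposure column and
    ``u_z`` the nested random intercepts; counts are NB(mu, theta)
    (Poisson for theta > 1e6, or Poisson-lognormal when
    ``misspecified``).  Returns (diagnosis_counts, totals) frames.
    """
    rng = np.random.default_rng(config.seed + 2)
    expo = exposure_matrix.to_frame().reindex(hierarchy.zip_ids)
    effects_by_disease: dict = {}
    for chem, icd, beta in config.planted_effects:
        if chem not in expo.columns:
            raise ValueError(f"planted chemical not in exposure matrix: {chem}")
        effects_by_disease.setdefault(icd, []).append((chem, beta))

    def zscored(chem):
        x = expo[chem].to_numpy(dtype=float)
        return (x - x.mean()) / x.std()

    zips_indexed = zips.set_index("zip_id").reindex(hierarchy.zip_ids)
    count_rows, total_rows = [], []
    for stratum in FIVE_BIN_STRATA:
        totals = zips_indexed[f"visits_{stratum}"].to_numpy(dtype=float)
        for z, t in zip(hierarchy.zip_ids, totals):
            total_rows.append((z, stratum, int(t)))

    for icd in disease_codes(config):
        signal = np.zeros(len(hierarchy.zip_ids))
        for chem, beta in effects_by_disease.get(icd, []):
            signal += beta * zscored(chem)
        u = _cluster_effects(rng, hierarchy, config.re_variances)
        for stratum in FIVE_BIN_STRATA:
            totals = zips_indexed[f"visits_{stratum}"].to_numpy(dtype=float)
            # Cap the latent rate at 1: even counting every diagnosis on a
            # visit, a single code cannot outnumber the billing denominator
            # by orders of magnitude; without the cap the heavy right tail
            # of z-scored exposures can push exp(signal) past any total.
            log_rate = np.minimum(math.log(config.baseline_rate) + signal + u, 0.0)
            mu = np.exp(np.clip(np.log(totals) + log_rate, -30.0, 30.0))
            if config.misspecified:
                noise = rng.normal(0.0, 1.0 / math.sqrt(config.theta), size=len(mu))
                counts = rng.poisson(mu * np.exp(noise))
            elif config.theta > 1e6:
                counts = rng.poisson(mu)
            else:
                p = config.theta / (config.theta + mu)
                counts = rng.negative_binomial(config.theta, p)
            for z, cnt in zip(hierarchy.zip_ids, counts):
                count_rows.append((z, icd, stratum, int(cnt)))

    counts_df = pd.DataFrame(count_rows, columns=["zip_id", "icd_code", "stratum", "count"])
    totals_df = pd.DataFrame(total_rows, columns=["zip_id", "stratum", "total_billed"])
    return counts_df, totals_df


def simulate_annotation(
    config: SimulationConfig,
    n_proteins: int = 30,
    n_targets: int = 3,
    n_pathways: int = 10,
    n_extra_genes: int = 170,
) -> tuple[ToxinProteinMap, GeneSetLibrary]:
    """Toxin-protein map and GMT library with a planted mechanism.

    Planted-effect chemicals interact with each "target" protein with
    probability 0.8 versus a 0.1 background rate; the target proteins
    are concentrated in a single planted pathway, so a successful
    end-to-end run should rank that pathway first.
    """
    rng = np.random.default_rng(config.seed + 3)
    proteins = [f"PROT{i:03d}" for i in range(n_proteins)]
    targets = proteins[:n_targets]
    planted_chems = {chem for chem, _, _ in config.planted_effects}

    pairs = []
    for chem in config.chemical_ids():
        for protein in proteins:
            if protein in targets and chem in planted_chems:
                p_hit = 0.8
            else:
                p_hit = 0.1
            if rng.random() < p_hit:
                pairs.append((chem, protein))
    tmap = ToxinProteinMap(pd.DataFrame(pairs, columns=["toxin_id", "protein_symbol"]))

    universe = proteins + [f"GENE{i:03d}" for i in range(n_extra_genes)]
    sets = {
        "planted_target_pathway": set(targets)
        | set(rng.choice(universe[n_proteins:], size=2, replace=False))
    }
    for i in range(n_pathways - 1):
        sets[f"random_pathway_{i:02d}"] = set(
            rng.choice(universe, size=20, replace=False)
        )
    library = GeneSetLibrary(name="synthetic_library", sets=sets)
    return tmap, library
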