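"""Cluster hierarchy and the negative-binomial mixed model."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import gammaln

from exposcreen import spatial, synthetic, geo
from exposcreen.spatial import (
    _pirls,
    build_cluster_hierarchy,
    fit_nb_glmm,
    nb_log_likelihood,
)

from conftest import make_zips


def grid_zips(n, seed=0, spread=2.0):
    return make_zips(n=n, seed=seed, spread=spread)


class TestClusterHierarchy:
    def test_two_separated_groups_recovered(self):
        rows = []
        for i in range(3):
            rows.append((f"A{i}", 40.0 + 0.01 * i, -85.0, 1000))
        for i in range(3):
            rows.append((f"B{i}", 47.0 + 0.01 * i, -85.0, 1000))  # ~500 mi away
        zips = pd.DataFrame(rows, columns=["zip_id", "lat", "lon", "population"])
        h = build_cluster_hierarchy(zips, target_sizes=(3, 1))
        coarse = h.levels[0]
        labels_a = {coarse[i] for i, z in enumerate(h.zip_ids) if z.startswith("A")}
        labels_b = {coarse[i] for i, z in enumerate(h.zip_ids) if z.startswith("B")}
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b

    def test_cut_count_formula(self):
        zips = grid_zips(100, seed=2)
        h = build_cluster_hierarchy(zips, target_sizes=(40, 10, 3))
        # K = max(1, round(N / size)), halves rounded up: 100/40 -> 3
        assert h.cut_counts == (3, 10, 33)

    def test_small_n_collapses_duplicate_levels(self):
        zips = grid_zips(12, seed=3)
        with pytest.warns(UserWarning, match="duplicate cluster level"):
            h = build_cluster_hierarchy(zips, target_sizes=(81, 27, 9, 3))
        assert h.cut_counts == (1, 1, 1, 4)
        assert h.n_levels == 2  # the three K=1 cuts collapse to one

    def test_levels_nest(self):
        zips = grid_zips(120, seed=4)
        h = build_cluster_hierarchy(zips, target_sizes=(30, 10, 3))
        for coarse, fine in zip(h.levels, h.levels[1:]):
            parents = {}
            for c_lab, f_lab in zip(coarse, fine):
                parents.setdefault(f_lab, set()).add(c_lab)
            assert all(len(p) == 1 for p in parents.values())

    def test_invariant_to_input_row_order(self):
        zips = grid_zips(60, seed=5)
        h1 = build_cluster_hierarchy(zips, target_sizes=(20, 5))
        h2 = build_cluster_hierarchy(
            zips.sample(frac=1.0, random_state=1), target_sizes=(20, 5)
        )
        assert h1.zip_ids == h2.zip_ids
        for l1, l2 in zip(h1.levels, h2.levels):
            np.testing.assert_array_equal(l1, l2)


class TestNbLogLikelihood:
    def test_zero_count_closed_form(self):
        mu, theta = 3.7, 2.2
        assert nb_log_likelihood([0], [mu], theta) == pytest.approx(
            theta * math.log(theta / (theta + mu))
        )

    def test_term_by_term_gamma_evaluation(self):
        y = np.array([2.0, 5.0])
        mu = np.array([3.0, 3.0])
        theta = 4.0
        expected = sum(
            gammaln(yi + theta)
            - gammaln(theta)
            - gammaln(yi + 1)
            + theta * math.log(theta / (theta + mi))
            + yi * math.log(mi / (theta + mi))
            for yi, mi in zip(y, mu)
        )
        assert nb_log_likelihood(y, mu, theta) == pytest.approx(float(expected), rel=1e-12)

    def test_poisson_limit(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(5.0, size=50).astype(float)
        mu = np.full(50, 5.0)
        poisson_ll = float(np.sum(-mu + y * np.log(mu) - gammaln(y + 1)))
        assert nb_log_likelihood(y, mu, 1e8) == pytest.approx(poisson_ll, abs=1e-4)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            nb_log_likelihood([-1], [1.0], 1.0)
        with pytest.raises(ValueError):
            nb_log_likelihood([1], [0.0], 1.0)
        with pytest.raises(ValueError):
            nb_log_likelihood([1], [1.0], 0.0)


def simulate_counts(n=400, beta=0.3, theta=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    offset = np.log(rng.integers(500, 2000, n).astype(float))
    mu = np.exp(offset + np.log(0.01) + beta * x)
    y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
    return y, X, offset


class TestFitNbGlmm:
    def test_no_random_effects_matches_statsmodels_nb(self):
        y, X, offset = simulate_counts(seed=1)
        ours = fit_nb_glmm(y, X, offset, None)
        ref = sm.NegativeBinomial(y, X, offset=offset).fit(
            method="newton", maxiter=200, tol=1e-10, disp=0
        )
        np.testing.assert_allclose(ours.beta, ref.params[:2], atol=1e-4)
        assert ours.theta == pytest.approx(1.0 / ref.params[-1], abs=1e-4)

    def test_poisson_limit_matches_glm(self):
        y, X, offset = simulate_counts(seed=2, theta=1e8)
        ours = fit_nb_glmm(y, X, offset, None, fix_theta=1e8)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-3)

    def test_variances_fixed_at_zero_ignore_hierarchy(self, sim_bundle):
        y, X, offset = simulate_counts(seed=3, n=300)
        levels = [np.arange(300) // 30, np.arange(300) // 10]
        with_re = fit_nb_glmm(y, X, offset, levels, fix_variances=0.0)
        without = fit_nb_glmm(y, X, offset, None)
        np.testing.assert_allclose(with_re.beta, without.beta, atol=1e-8)
        assert with_re.re_variances.size == 0

    def test_pirls_objective_monotone(self):
        y, X, offset = simulate_counts(seed=4, n=200)
        levels = [np.arange(200) // 20]
        Z, level_of = spatial._build_random_design(levels)
        pen = np.full(Z.shape[1], 1.0 / 0.05)
        trace = []
        _pirls(y, X, Z, offset, pen, theta=5.0, trace=trace)
        diffs = np.diff(np.asarray(trace))
        assert np.all(diffs >= -1e-8)

    def test_recovers_planted_effect_with_nested_res(self):
        cfg = synthetic.SimulationConfig(
            n_zips=400, n_chemicals=3, seed=5,
            planted_effects=(("CHEM_000", "F90.0", 0.3),),
            theta=5.0, re_variances=(0.05, 0.05, 0.05, 0.05),
        )
        zips = synthetic.simulate_geography(cfg)
        releases = synthetic.simulate_releases(cfg, zips)
        exposure = geo.build_air_exposure(zips, releases)
        h = build_cluster_hierarchy(zips)
        counts, totals = synthetic.simulate_diagnoses(cfg, zips, exposure, h)
        sub = (
            counts[(counts.icd_code == "F90.0") & (counts.stratum == "adult")]
            .set_index("zip_id")["count"].reindex(h.zip_ids)
        )
        tot = (
            totals[totals.stratum == "adult"]
            .set_index("zip_id")["total_billed"].reindex(h.zip_ids)
        )
        x = exposure.to_frame().reindex(h.zip_ids)["CHEM_000"].to_numpy()
        x = (x - x.mean()) / x.std()
        X = np.column_stack([np.ones(len(x)), x])
        res = fit_nb_glmm(sub.to_numpy(), X, np.log(tot.to_numpy(float)), h)
        assert res.converged
        assert abs(res.beta_toxicant - 0.3) < 3 * res.se_toxicant
        assert res.se_toxicant > 0
        assert np.all(res.re_variances >= 0)

    def test_infinite_offset_rejected(self):
        y, X, _ = simulate_counts(n=20)
        with pytest.raises(ValueError, match="offset"):
            fit_nb_glmm(y, X, np.full(20, -np.inf), None)


@pytest.fixture(scope="module")
def screen_inputs():
    cfg = synthetic.SimulationConfig(
        n_zips=40, n_chemicals=3, n_facilities=60, seed=6, n_null_diseases=2
    )
    zips = synthetic.simulate_geography(cfg)
    releases = synthetic.simulate_releases(cfg, zips)
    exposure = geo.build_air_exposure(zips, releases)
    h = build_cluster_hierarchy(zips, target_sizes=(13, 4))
    counts, totals = synthetic.simulate_diagnoses(cfg, zips, exposure, h)
    from exposcreen import rates as rates_mod

    table = rates_mod.compute_rates(counts, totals)
    return table, exposure, zips, h


class TestSpatialScreen:
    def test_bookkeeping_and_determinism(self, screen_inputs):
        table, exposure, zips, h = screen_inputs
        chems = ["CHEM_000", "CHEM_001"]
        out1, report = spatial.spatial_screen(table, exposure, zips, h, chemicals=chems)
        # 2 diseases x 2 chemicals x 2 strata
        assert len(out1) <= 8
        assert (out1["model_type"] == "spatial").all()
        out2, _ = spatial.spatial_screen(table, exposure, zips, h, chemicals=chems)
        pd.testing.assert_frame_equal(out1, out2)

    def test_all_zero_stratum_skipped(self, screen_inputs):
        table, exposure, zips, h = screen_inputs
        crippled = table.copy()
        mask = (crippled["icd_code"] == "J45.9") & (crippled["stratum"].isin(
            ["preK", "pediatric"]))
        crippled.loc[mask, "count"] = 0
        out, report = spatial.spatial_screen(
            crippled, exposure, zips, h, chemicals=["CHEM_000"]
        )
        skipped = [s for s in report["skipped"] if s[0] == "J45.9" and s[1] == "pediatric"]
        assert skipped and skipped[0][2] == "all-zero counts"
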