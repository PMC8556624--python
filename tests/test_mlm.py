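"""Multilevel logistic model: sampler correctness, shrinkage, bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit, logit

from acprev import mlm
from acprev.mlm import (
    HierarchyError,
    MCMCConfig,
    PosteriorDraws,
    cluster_prevalence,
    fit_five_level,
    fit_four_level,
)
from acprev.synthetic import FourLevelSpec, GeographySpec, make_geography, simulate_children


def quadrature_intercept_posterior(n_success, n_total, prior_var=1e6):
    """1-D quadrature oracle: posterior mean/var of the logistic intercept."""

    def unnorm(b):
        return np.exp(
            n_success * b - n_total * np.log1p(np.exp(b)) - b * b / (2 * prior_var)
        )

    z, _ = quad(unnorm, -15, 15)
    m, _ = quad(lambda b: b * unnorm(b), -15, 15)
    m2, _ = quad(lambda b: b * b * unnorm(b), -15, 15)
    mean = m / z
    return mean, m2 / z - mean * mean


def single_cluster_sample(n=20, k=7):
    return pd.DataFrame(
        {
            "child_id": range(n),
            "y": [1] * k + [0] * (n - k),
            "cluster_id": "c0",
            "district_id": "d0",
            "state_id": "s0",
        }
    )


def simulate_sample(spec, geo_shape=(4, 2, 4), n_children=25, seed=0):
    """Balanced hierarchy without geography: states x districts x clusters."""
    n_s, n_d, n_c = geo_shape
    rng = np.random.default_rng(seed)
    rows = []
    cid = 0
    for s in range(n_s):
        u = rng.normal(0, np.sqrt(spec.var_state))
        for d in range(n_d):
            v = rng.normal(0, np.sqrt(spec.var_district))
            for c in range(n_c):
                w = rng.normal(0, np.sqrt(spec.var_cluster))
                p = expit(spec.beta0 + u + v + w)
                y = (rng.random(n_children) < p).astype(int)
                for yy in y:
                    rows.append(
                        {
                            "child_id": len(rows), "y": int(yy),
                            "cluster_id": f"c{cid}", "district_id": f"d{s}_{d}",
                            "state_id": f"s{s}", "p_true": p,
                        }
                    )
                cid += 1
    return pd.DataFrame(rows)


class TestSampler:
    def test_intercept_matches_quadrature(self):
        """Variances pinned at zero reduce the model to a logistic intercept,
        whose posterior is known by numerical integration."""
        sample = single_cluster_sample()
        cfg = MCMCConfig(burn_in=500, n_iter=4000, seed=1)
        draws = fit_four_level(
            sample, cfg, fix_zero=("state_id", "district_id", "cluster_id")
        )
        mean, _ = quadrature_intercept_posterior(7, 20)
        diag = draws.diagnostics()
        ess = float(diag.loc[diag["param"] == "beta0", "ess"].iloc[0])
        mcse = float(np.std(draws.beta0)) / np.sqrt(ess)
        assert abs(float(np.mean(draws.beta0)) - mean) < 3 * mcse

    def test_reproducible_with_seed(self):
        sample = single_cluster_sample()
        cfg = MCMCConfig(burn_in=50, n_iter=200, seed=9)
        a = fit_four_level(sample, cfg)
        b = fit_four_level(sample, cfg)
        assert np.array_equal(a.beta0, b.beta0)
        assert a.sig2.equals(b.sig2)

    def test_zero_variance_truth_concentrates(self):
        spec = FourLevelSpec(beta0=0.3, var_state=0, var_district=0, var_cluster=0)
        sample = simulate_sample(spec, geo_shape=(4, 2, 4), n_children=40, seed=3)
        cfg = MCMCConfig(burn_in=300, n_iter=1200, seed=4)
        draws = fit_four_level(sample, cfg)
        for col in draws.sig2.columns:
            assert draws.sig2[col].median() < 0.15

    def test_all_equal_outcomes_warns_but_runs(self):
        sample = single_cluster_sample(n=10, k=10)
        with pytest.warns(UserWarning, match="weakly identified"):
            draws = fit_four_level(sample, MCMCConfig(burn_in=20, n_iter=50, seed=0))
        assert draws.n_draws == 50

    def test_inconsistent_hierarchy_rejected(self):
        sample = single_cluster_sample()
        sample.loc[5, "district_id"] = "d-other"  # same cluster in two districts
        with pytest.raises(HierarchyError):
            fit_four_level(sample, MCMCConfig(burn_in=10, n_iter=10, seed=0))

    def test_label_invariance(self):
        spec = FourLevelSpec(beta0=-0.4)
        sample = simulate_sample(spec, geo_shape=(2, 2, 3), n_children=15, seed=6)
        cfg = MCMCConfig(burn_in=100, n_iter=400, seed=7)
        cp1 = cluster_prevalence(fit_four_level(sample, cfg))
        relabel = {f"c{i}": f"z{99 - i}" for i in range(12)}
        sample2 = sample.assign(cluster_id=sample["cluster_id"].map(relabel))
        cp2 = cluster_prevalence(fit_four_level(sample2, cfg))
        m = cp1.assign(cluster_id=cp1["cluster_id"].map(relabel)).merge(
            cp2, on="cluster_id", suffixes=("_a", "_b")
        )
        assert np.allclose(m["prevalence_a"], m["prevalence_b"])


class TestFiveLevel:
    def test_zero_ac_variance_concentrates(self):
        spec = FourLevelSpec(beta0=0.0, var_state=0.2, var_district=0.1, var_cluster=0.3)
        sample = simulate_sample(spec, geo_shape=(3, 2, 4), n_children=30, seed=8)
        # ACs = pairs of clusters within a district
        sample["ac_id"] = "a" + (sample["cluster_id"].str.slice(1).astype(int) // 2).astype(str)
        ac_map = (
            sample[["ac_id", "district_id"]].drop_duplicates("ac_id").reset_index(drop=True)
        )
        draws = fit_five_level(sample, ac_map, MCMCConfig(burn_in=300, n_iter=1000, seed=9))
        assert draws.sig2["sig2_ac"].median() < 0.2

    def test_unresolved_ac_spanning_districts_rejected(self):
        sample = single_cluster_sample()
        sample["ac_id"] = "a0"
        ac_map = pd.DataFrame({"ac_id": ["a0", "a0"], "district_id": ["d0", "d1"]})
        with pytest.raises(HierarchyError):
            fit_five_level(sample, ac_map, MCMCConfig(burn_in=5, n_iter=5, seed=0))


class TestClusterPrevalence:
    @staticmethod
    def make_draws(beta0_draws, cluster_eff):
        t = len(beta0_draws)
        return PosteriorDraws(
            beta0=np.asarray(beta0_draws, dtype=float),
            sig2=pd.DataFrame({"sig2_state": np.zeros(t)}),
            effects={
                "state_id": np.zeros((t, 1)),
                "district_id": np.zeros((t, 1)),
                "cluster_id": np.asarray(cluster_eff, dtype=float).reshape(t, -1),
            },
            unit_ids={
                "state_id": np.array(["s0"]),
                "district_id": np.array(["d0"]),
                "cluster_id": np.array(["c0"]),
            },
            lineage=pd.DataFrame(
                {"cluster_id": ["c0"], "district_id": ["d0"], "state_id": ["s0"]}
            ),
            config=MCMCConfig(burn_in=0, n_iter=t),
            levels=("state_id", "district_id", "cluster_id"),
        )

    def test_degenerate_draws_half(self):
        cp = cluster_prevalence(self.make_draws([0.0, 0.0], [[0.0], [0.0]]))
        assert cp.loc[0, "prevalence"] == pytest.approx(0.5)

    def test_constant_logit(self):
        b = float(logit(0.3))
        cp = cluster_prevalence(self.make_draws([b, b], [[0.0], [0.0]]))
        assert cp.loc[0, "prevalence"] == pytest.approx(0.30)

    def test_two_iteration_mean(self):
        draws = self.make_draws(
            [float(logit(0.2)), float(logit(0.4))], [[0.0], [0.0]]
        )
        cp = cluster_prevalence(draws)
        assert cp.loc[0, "prevalence"] == pytest.approx(0.3)

    def test_transform_vs_plugin_jensen(self):
        """Averaging after the inverse logit differs from plug-in of the mean."""
        draws = self.make_draws([-2.0, 2.0], [[0.0], [0.0]])
        p_transform = cluster_prevalence(draws, mode="transform").loc[0, "prevalence"]
        p_plugin = cluster_prevalence(draws, mode="plugin").loc[0, "prevalence"]
        assert p_plugin == pytest.approx(0.5)
        assert p_transform == pytest.approx(0.5)  # symmetric case agrees
        draws2 = self.make_draws([-3.0, 1.0], [[0.0], [0.0]])
        p_t = cluster_prevalence(draws2, mode="transform").loc[0, "prevalence"]
        p_p = cluster_prevalence(draws2, mode="plugin").loc[0, "prevalence"]
        assert p_t > p_p  # expit is convex below 0

    def test_bounds_bracket_mean(self):
        spec = FourLevelSpec(beta0=0.0)
        sample = simulate_sample(spec, geo_shape=(2, 2, 3), n_children=20, seed=10)
        cp = cluster_prevalence(
            fit_four_level(sample, MCMCConfig(burn_in=100, n_iter=400, seed=11))
        )
        assert ((cp["ci_lo"] <= cp["prevalence"]) & (cp["prevalence"] <= cp["ci_hi"])).all()
        assert cp["prevalence"].between(0, 1).all()
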