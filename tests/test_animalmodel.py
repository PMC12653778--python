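"""Threshold animal model: MME assembly, augmentation, Gibbs recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.linalg import spsolve

import markqg._gibbs as gibbs
from markqg.animalmodel import (
    ChainConfig,
    ThresholdAnimalModel,
    ThresholdModelSpec,
    dempster_lerner,
    ensure_known_dams,
    heritability_from_components,
)
from markqg.pedigree import UNKNOWN, Pedigree, relationship_matrix
from markqg.posterior import hpd_interval
from markqg.simulate import (
    SimConfig,
    model_scale_truth,
    pre_like,
    simulate_dataset,
)

from conftest import random_pedigree


def gaussian_frame(ped, y, trait="lf"):
    return pd.DataFrame(
        {
            "animal": ped.ids,
            "sex": "female",
            "coat": "grey",
            "F": 0.0,
            "dam": ["" if d == UNKNOWN else ped.ids[d] for d in ped.dam],
            trait: y,
        }
    )


class TestModelConstruction:
    def test_mme_dimension_bookkeeping(self):
        """Three phenotyped animals, intercept only, no maternal: the MME
        has one fixed-effect equation plus one per pedigree animal."""
        ped = random_pedigree(12, n_founders=4, seed=1)
        frame = gaussian_frame(ped, np.zeros(ped.n)).iloc[:3]
        spec = ThresholdModelSpec(
            traits=["lf"], response_scale="gaussian", fixed_effects=(), include_maternal=False
        )
        model = ThresholdAnimalModel(frame, ped, spec)
        lhs, rhs, slices = model.build_mme(frame["lf"].to_numpy(), 1.0, 1.0)
        assert lhs.shape[0] == 1 + model.n_ped
        assert "maternal" not in slices

    def test_maternal_toggle_changes_system(self):
        ped = random_pedigree(12, n_founders=4, seed=1)
        frame = gaussian_frame(ped, np.zeros(ped.n))
        with_m = ThresholdAnimalModel(
            frame, ped, ThresholdModelSpec(traits=["lf"], response_scale="gaussian",
                                           fixed_effects=(), include_maternal=True)
        )
        without_m = ThresholdAnimalModel(
            frame, ped, ThresholdModelSpec(traits=["lf"], response_scale="gaussian",
                                           fixed_effects=(), include_maternal=False)
        )
        lhs_m, _, _ = with_m.build_mme(frame["lf"].to_numpy(), 1.0, 1.0, sigma_m2=0.5)
        lhs, _, _ = without_m.build_mme(frame["lf"].to_numpy(), 1.0, 1.0)
        assert lhs_m.shape[0] == lhs.shape[0] + with_m.n_ped

    def test_blup_matches_dense_gls_oracle(self):
        """With variances fixed and liabilities observed, the sparse MME
        solution equals the dense GLS/BLUP estimator."""
        rng = np.random.default_rng(4)
        ped = random_pedigree(30, n_founders=8, seed=4)
        y = rng.standard_normal(ped.n) + 1.0
        frame = gaussian_frame(ped, y)
        spec = ThresholdModelSpec(
            traits=["lf"], response_scale="gaussian", fixed_effects=(), include_maternal=True
        )
        model = ThresholdAnimalModel(frame, ped, spec)
        su2, sm2, se2 = 1.5, 0.4, 1.0
        lhs, rhs, slices = model.build_mme(y, su2, se2, sigma_m2=sm2)
        sol = spsolve(lhs.tocsc(), rhs)

        # dense oracle on the model's (phantom-extended) pedigree
        A = relationship_matrix(model.ped)
        n = model.n_ped
        Z = np.zeros((model.nrec, n))
        Z[np.arange(model.nrec), model.rec_animal] = 1.0
        W = np.zeros((model.nrec, n))
        W[np.arange(model.nrec), model.rec_dam] = 1.0
        X = model.X
        V = su2 * Z @ A @ Z.T + sm2 * W @ A @ W.T + se2 * np.eye(model.nrec)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        resid = y - X @ beta
        u_hat = su2 * A @ Z.T @ Vi @ resid
        m_hat = sm2 * A @ W.T @ Vi @ resid
        assert np.abs(sol[slices["fixed"]] - beta).max() < 1e-8
        assert np.abs(sol[slices["direct"]] - u_hat).max() < 1e-8
        assert np.abs(sol[slices["maternal"]] - m_hat).max() < 1e-8

    def test_phantom_dam_insertion(self):
        ped = random_pedigree(10, n_founders=5, seed=0)
        ext = ensure_known_dams(ped, [ped.ids[0]])  # a founder: unknown dam
        assert ext.n == ped.n + 1
        assert ext.dam[ext.index_of(ped.ids[0])] != UNKNOWN

    def test_single_category_response_rejected(self):
        ped = random_pedigree(10, n_founders=5, seed=0)
        frame = gaussian_frame(ped, np.zeros(ped.n, dtype=int))
        with pytest.raises(ValueError, match="single observed category"):
            ThresholdAnimalModel(frame, ped, ThresholdModelSpec(traits=["lf"], fixed_effects=()))

    def test_ordinal_requires_all_classes(self):
        ped = random_pedigree(10, n_founders=5, seed=0)
        scores = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])  # class 3 absent
        frame = gaussian_frame(ped, scores)
        with pytest.raises(ValueError, match="class 3 absent"):
            ThresholdAnimalModel(
                frame, ped,
                ThresholdModelSpec(traits=["lf"], response_scale="ordinal4", fixed_effects=()),
            )

    def test_chain_config_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            ChainConfig(total_iterations=100, burn_in=100).validate()
        with pytest.raises(ValueError, match="thinning"):
            ChainConfig(total_iterations=100, burn_in=10, thinning=0).validate()


class TestLiabilitySampling:
    def test_draws_respect_category_intervals(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = rng.integers(0, 4, size=(n, 1))
        liab = np.zeros((n, 1))
        mean = rng.standard_normal((n, 1))
        cat_lo = np.array([[-np.inf, 0.0, 1.0, 2.0]])
        cat_hi = np.array([[0.0, 1.0, 2.0, np.inf]])
        gibbs.sample_liabilities(liab, y, mean, np.ones(1), cat_lo, cat_hi, rng)
        lo = cat_lo[0, y[:, 0]]
        hi = cat_hi[0, y[:, 0]]
        assert np.all(liab[:, 0] >= lo) and np.all(liab[:, 0] <= hi)

    def test_half_normal_moment(self):
        """Affected records with zero mean and threshold 0 draw from a
        half-normal whose mean is sqrt(2/pi) ~ 0.798."""
        rng = np.random.default_rng(1)
        n = 10_000
        y = np.ones((n, 1), dtype=np.int64)
        liab = np.zeros((n, 1))
        mean = np.zeros((n, 1))
        gibbs.sample_liabilities(
            liab, y, mean, np.ones(1),
            np.array([[-np.inf, 0.0]]), np.array([[0.0, np.inf]]), rng,
        )
        target = np.sqrt(2.0 / np.pi)
        sd = np.sqrt(1.0 - target**2)
        assert abs(liab.mean() - target) < 3 * sd / np.sqrt(n)

    def test_extreme_mean_stays_finite_and_in_interval(self):
        rng = np.random.default_rng(2)
        draws = [gibbs.rtnorm(-40.0, 1.0, 2.0, np.inf, rng) for _ in range(100)]
        assert np.all(np.isfinite(draws))
        assert np.all(np.array(draws) >= 2.0)
        narrow = [gibbs.rtnorm(50.0, 1.0, -1.0, -0.999, rng) for _ in range(50)]
        assert np.all(np.isfinite(narrow))
        assert np.all((np.array(narrow) >= -1.0) & (np.array(narrow) <= -0.999))


class TestGibbsSampler:
    def test_conjugate_limit_matches_analytic_posterior(self):
        """Unrelated animals, effectively observed genetic values, flat
        prior: sigma_u2 posterior is scaled-inverse-chi-square with df
        n - 2 and scale y'y; the chain mean must match its analytic mean
        within 3 Monte Carlo SE."""
        rng = np.random.default_rng(5)
        n = 200
        frame = pd.DataFrame({"animal": [f"a{i}" for i in range(n)], "sire": "", "dam": ""})
        ped = Pedigree.from_frame(frame)
        y = rng.standard_normal(n) * np.sqrt(2.0)
        data = gaussian_frame(ped, y)
        spec = ThresholdModelSpec(
            traits=["lf"], response_scale="gaussian", fixed_effects=(),
            include_intercept=False, include_maternal=False, fix_residual=1e-8,
        )
        res = ThresholdAnimalModel(data, ped, spec).fit(
            ChainConfig(total_iterations=3000, burn_in=500, thinning=1, seed=2)
        )
        su = res.chain.sigma_u[:, 0, 0]
        analytic_mean = (y @ y) / (n - 2 - 2)
        mc_se = su.std(ddof=1) / np.sqrt(len(su))
        assert abs(su.mean() - analytic_mean) < 3 * mc_se

    def test_dichotomous_recovery_truth_in_hpd(self):
        """Binary threshold model recovers the generating h2 (within the
        95% HPD) on a single seeded replicate at desk scale."""
        cfg = pre_like(n_founders=150, n_generations=3, offspring_per_mating=3, seed=101)
        ped, data = simulate_dataset(cfg)
        tr = model_scale_truth(cfg, 2, "dichotomous")
        spec = ThresholdModelSpec(traits=["lh"], response_scale="dichotomous")
        res = ThresholdAnimalModel(data, ped, spec).fit(
            ChainConfig(total_iterations=8000, burn_in=3000, thinning=5, seed=501)
        )
        h2 = res.heritability_samples("lh")
        lo, hi = hpd_interval(h2)
        assert lo <= tr["h2"] <= hi

    def test_constraints_constant_across_draws(self):
        cfg = pre_like(n_founders=80, n_generations=2, seed=3)
        ped, data = simulate_dataset(cfg)
        spec = ThresholdModelSpec(traits=["lh"], response_scale="dichotomous")
        res = ThresholdAnimalModel(data, ped, spec).fit(
            ChainConfig(total_iterations=600, burn_in=200, thinning=2, seed=1)
        )
        assert res.chain.constraints == {"t1": 0.0, "sigma_e2": 1.0}
        assert np.all(res.chain.sigma_e == 1.0)
        assert np.all(res.chain.thresholds == 0.0)

    def test_ordinal_thresholds_ascending_every_draw(self):
        cfg = pre_like(n_founders=120, n_generations=2, offspring_per_mating=3, seed=8)
        ped, data = simulate_dataset(cfg)
        spec = ThresholdModelSpec(traits=["lh"], response_scale="ordinal4")
        res = ThresholdAnimalModel(data, ped, spec).fit(
            ChainConfig(total_iterations=1200, burn_in=400, thinning=2, seed=4)
        )
        thr = res.chain.thresholds
        assert np.all(thr[:, :, 0] == 0.0) and np.all(thr[:, :, 1] == 1.0)
        assert np.all(np.diff(thr, axis=2) > 0)

    def test_determinism_given_seed(self):
        cfg = pre_like(n_founders=80, n_generations=2, seed=3)
        ped, data = simulate_dataset(cfg)
        spec = ThresholdModelSpec(traits=["lh"], response_scale="dichotomous")
        cc = ChainConfig(total_iterations=400, burn_in=100, thinning=2, seed=11)
        a = ThresholdAnimalModel(data, ped, spec).fit(cc)
        b = ThresholdAnimalModel(data, ped, spec).fit(cc)
        assert np.array_equal(a.chain.sigma_u, b.chain.sigma_u)
        assert np.array_equal(a.chain.b, b.chain.b)

    def test_gaussian_bivariate_genetic_correlation(self):
        """Multi-trait chain recovers a moderate genetic correlation from
        continuous records (truth 0.6 inside the 95% HPD)."""
        r = 0.6
        Su = np.array([[2.0, r * np.sqrt(3.0)], [r * np.sqrt(3.0), 1.5]])
        cfg = SimConfig(
            n_founders=150, n_generations=3, offspring_per_mating=3,
            sigma_u=Su, sigma_m=0.2 * np.eye(2), sigma_e=np.eye(2),
            sigma_um=np.zeros(2), thresholds=np.tile([0.0, 1.0, 2.0], (2, 1)), seed=41,
        )
        ped, data = simulate_dataset(cfg)
        frame = data.frame.copy()
        frame["y1"] = data.truth["liabilities"][:, 0]
        frame["y2"] = data.truth["liabilities"][:, 1]
        spec = ThresholdModelSpec(
            traits=["y1", "y2"], response_scale="gaussian", fixed_effects=("sex", "coat", "F")
        )
        res = ThresholdAnimalModel(frame, ped, spec).fit(
            ChainConfig(total_iterations=4000, burn_in=1500, thinning=2, seed=4)
        )
        rg = res.genetic_correlation_samples((0, 1))
        lo, hi = hpd_interval(rg)
        assert lo <= r <= hi
        assert np.all((rg >= -1.0) & (rg <= 1.0))


class TestDerivedQuantities:
    def test_heritability_ratio_values(self):
        assert heritability_from_components(1.540, 0.059, 1.000) == pytest.approx(0.5925, abs=1e-3)
        assert heritability_from_components(0.0, 0.5, 1.0) == 0.0
        assert heritability_from_components(1.0, 1.0, 1.0) == pytest.approx(1 / 3)

    def test_dempster_lerner_values(self):
        assert dempster_lerner(0.5, 0.5) == pytest.approx(0.318, abs=5e-4)
        assert dempster_lerner(0.0, 0.1) == 0.0

    def test_dempster_lerner_maximized_at_half(self):
        grid = np.linspace(0.01, 0.99, 197)
        vals = [dempster_lerner(0.4, p) for p in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.01)

    def test_dempster_lerner_domain_errors(self):
        with pytest.raises(ValueError):
            dempster_lerner(0.5, 0.0)
        with pytest.raises(ValueError):
            dempster_lerner(1.5, 0.2)
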