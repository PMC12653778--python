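"""Generator checks: pedigree structure, breeding values, phenotypes."""

import numpy as np
import pytest
from scipy import stats

from markqg.pedigree import UNKNOWN, inbreeding_coefficients
from markqg.simulate import (
    LIMBS,
    SimConfig,
    dichotomous_preset,
    model_scale_truth,
    nearest_psd_correlation,
    pre_like,
    simulate_breeding_values,
    simulate_dataset,
    simulate_pedigree,
    simulate_phenotypes,
)


def small_config(**overrides):
    base = dict(
        n_founders=60,
        n_generations=2,
        offspring_per_mating=2,
        sigma_u=np.array([[2.0]]),
        sigma_m=np.array([[0.3]]),
        sigma_e=np.array([[1.0]]),
        sigma_um=np.zeros(1),
        thresholds=np.array([[0.0, 1.0, 2.0]]),
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestPedigreeSimulation:
    def test_zero_generations_founders_only(self):
        cfg = small_config(n_founders=10, n_generations=0)
        ped = simulate_pedigree(cfg, np.random.default_rng(0))
        assert ped.n == 10 and ped.n_founders == 10

    def test_same_seed_identical(self):
        cfg = small_config(seed=5)
        a = simulate_pedigree(cfg, np.random.default_rng(5))
        b = simulate_pedigree(cfg, np.random.default_rng(5))
        assert a.ids == b.ids
        assert (a.sire == b.sire).all() and (a.dam == b.dam).all()

    def test_single_sex_errors(self):
        cfg = small_config(n_founders=5, sex_ratio=0.0)
        with pytest.raises(ValueError, match="males"):
            simulate_pedigree(cfg, np.random.default_rng(0))

    def test_mean_inbreeding_rises_by_generation(self):
        cfg = small_config(n_founders=16, n_generations=5, offspring_per_mating=3, sex_ratio=0.5)
        ped = simulate_pedigree(cfg, np.random.default_rng(11))
        F = inbreeding_coefficients(ped)
        by_gen = {}
        for i, aid in enumerate(ped.ids):
            g = int(aid.split("_")[0][1:])
            by_gen.setdefault(g, []).append(F[i])
        means = [float(np.mean(by_gen[g])) for g in sorted(by_gen)]
        # F is identically 0 for the first two generations, then positive
        # with an increasing trend (small populations fluctuate, so the
        # check is on the trend, not strict per-generation monotonicity)
        assert means[0] == means[1] == 0.0
        assert all(v > 0 for v in means[2:])
        slope = np.polyfit(range(len(means) - 2), means[2:], 1)[0]
        assert slope > 0


class TestBreedingValues:
    def test_zero_variance_gives_zero_effects(self):
        cfg = small_config(sigma_u=np.zeros((1, 1)), sigma_m=np.zeros((1, 1)))
        rng = np.random.default_rng(1)
        ped = simulate_pedigree(cfg, rng)
        u, m = simulate_breeding_values(ped, cfg, rng)
        assert np.all(u == 0.0) and np.all(m == 0.0)

    def test_founder_variance_matches_truth(self):
        """Founder sample variance of u is within 3 SE of the target
        direct-genetic variance (chi-square sampling bound)."""
        cfg = pre_like(n_founders=2000, n_generations=0)
        rng = np.random.default_rng(3)
        ped = simulate_pedigree(cfg, rng)
        u, _ = simulate_breeding_values(ped, cfg, rng)
        n = ped.n
        for t, truth in enumerate([4.877, 4.772, 7.904, 5.659]):
            v = u[:, t].var(ddof=1)
            se = truth * np.sqrt(2.0 / (n - 1))
            assert abs(v - truth) < 3 * se

    def test_hind_pair_correlation_matches_truth(self):
        cfg = pre_like(n_founders=2000, n_generations=0)
        rng = np.random.default_rng(4)
        ped = simulate_pedigree(cfg, rng)
        u, _ = simulate_breeding_values(ped, cfg, rng)
        r = np.corrcoef(u[:, 2], u[:, 3])[0, 1]
        se = (1 - 0.995**2) / np.sqrt(ped.n - 3)  # Fisher-style bound
        assert abs(r - 0.995) < max(3 * se, 0.003)

    def test_midparent_regression_slope_one(self):
        """Offspring u regressed on mid-parent u has slope 1 (Mendelian
        sampling adds mean-zero noise around the parent average)."""
        cfg = small_config(n_founders=150, n_generations=3, offspring_per_mating=3)
        rng = np.random.default_rng(9)
        ped = simulate_pedigree(cfg, rng)
        u, _ = simulate_breeding_values(ped, cfg, rng)
        both = (ped.sire != UNKNOWN) & (ped.dam != UNKNOWN)
        mid = 0.5 * (u[ped.sire[both], 0] + u[ped.dam[both], 0])
        child = u[both, 0]
        slope = np.polyfit(mid, child, 1)[0]
        n = both.sum()
        assert abs(slope - 1.0) < 0.15
        assert n > 500

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        cfg = small_config(
            sigma_u=bad, sigma_m=0.1 * np.eye(2), sigma_e=np.eye(2),
            sigma_um=np.zeros(2), thresholds=np.tile([0.0, 1.0, 2.0], (2, 1)),
        )
        with pytest.raises(ValueError, match="positive semidefinite"):
            cfg.validate()


class TestPhenotypes:
    def test_all_zero_variances_and_effects_give_score_zero(self):
        cfg = small_config(
            sigma_u=np.zeros((1, 1)), sigma_m=np.zeros((1, 1)), sigma_e=np.zeros((1, 1)),
            thresholds=np.array([[0.5, 1.0, 2.0]]),
        )
        rng = np.random.default_rng(2)
        ped = simulate_pedigree(cfg, rng)
        u, m = simulate_breeding_values(ped, cfg, rng)
        data = simulate_phenotypes(ped, u, m, cfg, rng)
        assert np.all(data.truth["liabilities"] == 0.0)
        assert np.all(data.frame["lf"] == 0)

    def test_very_low_thresholds_saturate_at_three(self):
        cfg = small_config(thresholds=np.array([[-50.0, -49.0, -48.0]]))
        _, data = simulate_dataset(cfg)
        assert np.all(data.frame["lf"] == 3)

    def test_sex_effect_raises_male_prevalence(self):
        from markqg.simulate import FixedEffects

        fx = FixedEffects.zero(1)
        fx.sex_male = np.array([1.0])
        cfg = small_config(n_founders=5000, n_generations=0, fixed_effects=fx, sex_ratio=0.5)
        _, data = simulate_dataset(cfg)
        f = data.frame
        male = (f.loc[f.sex == "male", "lf"] > 0).mean()
        female = (f.loc[f.sex == "female", "lf"] > 0).mean()
        assert male > female

    def test_marginal_prevalence_matches_normal_cdf(self):
        """Observed prevalence agrees with the Phi-implied prevalence
        within 3 binomial SE at n = 10,000."""
        cfg = small_config(n_founders=10_000, n_generations=0)
        _, data = simulate_dataset(cfg)
        total_sd = np.sqrt(2.0 + 0.3 + 1.0)
        p_expected = 1.0 - stats.norm.cdf(0.0 / total_sd)
        p_obs = (data.frame["lf"] > 0).mean()
        se = np.sqrt(p_expected * (1 - p_expected) / 10_000)
        assert abs(p_obs - p_expected) < 3 * se

    def test_limb_exchangeability_without_fixed_effects(self):
        """Symmetric truth across limbs leaves no systematic limb bias."""
        cfg = SimConfig(
            n_founders=8000, n_generations=0,
            sigma_u=2.0 * np.eye(4), sigma_m=0.2 * np.eye(4), sigma_e=np.eye(4),
            sigma_um=np.zeros(4), thresholds=np.tile([0.0, 1.0, 2.0], (4, 1)), seed=6,
        )
        _, data = simulate_dataset(cfg)
        prevs = [(data.frame[limb] > 0).mean() for limb in LIMBS]
        se = np.sqrt(0.5 * 0.5 / 8000)
        assert max(prevs) - min(prevs) < 6 * se


class TestPresets:
    def test_pre_like_prevalence_calibration(self):
        """The default preset reproduces the studied per-limb prevalences
        (about 5.3/4.6/17.9/14.5% affected) at generation depth."""
        cfg = pre_like(n_founders=400, n_generations=3, offspring_per_mating=3, seed=2)
        _, data = simulate_dataset(cfg)
        targets = {"lf": 0.053, "rf": 0.046, "lh": 0.179, "rh": 0.145}
        n = data.n
        for limb, p in targets.items():
            obs = (data.frame[limb] > 0).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 5 * se, (limb, obs, p)

    def test_correlation_matrix_projection_is_psd_unit_diag(self):
        C = np.array([[1.0, 0.99, 0.99], [0.99, 1.0, 0.5], [0.99, 0.5, 1.0]])
        P = nearest_psd_correlation(C)
        assert np.allclose(np.diag(P), 1.0)
        assert np.linalg.eigvalsh(P).min() >= 0
        assert np.abs(P - P.T).max() == 0.0

    def test_model_scale_truth_h2_is_scale_invariant(self):
        cfg = pre_like()
        for t in range(4):
            a = model_scale_truth(cfg, t, "ordinal4")["h2"]
            b = model_scale_truth(cfg, t, "dichotomous")["h2"]
            assert a == pytest.approx(b)

    def test_dichotomous_preset_on_model_scale(self):
        cfg = dichotomous_preset()
        tr = model_scale_truth(cfg, 0, "dichotomous")
        assert tr["sigma_e2"] == pytest.approx(1.0)
        assert tr["sigma_u2"] == pytest.approx(1.540)

    def test_dataset_roundtrip(self, tmp_path):
        cfg = small_config(seed=4)
        _, data = simulate_dataset(cfg)
        p = tmp_path / "phe.csv"
        data.to_csv(p)
        from markqg.simulate import MarkingDataset

        back = MarkingDataset.from_csv(p)
        assert (back.frame["lf"] == data.frame["lf"]).all()
        assert back.frame["F"].to_numpy() == pytest.approx(data.frame["F"].to_numpy())
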