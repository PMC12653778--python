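"""Synthetic pedigrees and four-limb ordinal marking phenotypes.

The generator draws data under the same liability model the estimation code
fits: for animal *i* and limb trait *t*,

    l_it = x_i' b_t + u_it + m_{dam(i),t} + e_it ,

where ``u`` (direct) and ``m`` (maternal) are pedigree-structured additive
genetic effects with 4x4 covariance matrices, ``e`` is an independent
residual, and the observed score 0..3 is the interval of ``l`` among three
ascending thresholds.  Covariates are sex (2 levels), coat colour (4
levels) and the pedigree inbreeding coefficient F.

The default preset (:func:`pre_like`) reproduces the variance structure
estimated in a large Iberian horse studbook: direct-genetic variances
around 4.8-7.9 on the liability scale, small maternal variances, genetic
correlations 0.99+ between contralateral limb pairs and ~0.86-0.91 across
fore/hind pairs, and thresholds calibrated so marginal prevalences are
~5% (forelegs) and ~15-18% (hindlegs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import (
    UNKNOWN,
    Pedigree,
    inbreeding_coefficients,
    mendelian_sampling_variance,
)

LIMBS = ("lf", "rf", "lh", "rh")
COATS = ("grey", "bay", "chestnut", "black")
SEXES = ("male", "female")


@dataclass
class FixedEffects:
    """Per-trait liability shifts for the systematic effects.

    ``sex_male``: added for males (females are the reference).
    ``coat``: shift per coat level, keyed like :data:`COATS`; grey is the
    conventional reference (shift 0).
    ``f_slope``: liability change per unit inbreeding coefficient.
    All arrays have one entry per trait.
    """

    sex_male: np.ndarray
    coat: dict[str, np.ndarray]
    f_slope: np.ndarray

    def mean_shift(self, p_male: float, coat_freq: np.ndarray, mean_f: float) -> np.ndarray:
        """Population-average fixed-effect contribution per trait."""
        shift = p_male * self.sex_male + mean_f * self.f_slope
        for c, freq in zip(COATS, coat_freq):
            shift = shift + freq * self.coat[c]
        return shift

    @classmethod
    def zero(cls, n_traits: int = 4) -> "FixedEffects":
        z = np.zeros(n_traits)
        return cls(sex_male=z.copy(), coat={c: z.copy() for c in COATS}, f_slope=z.copy())


@dataclass
class SimConfig:
    """Full specification of one synthetic study.

    Covariance matrices are on the liability scale; ``sigma_um`` holds the
    per-trait direct-maternal covariance (zero by default — the estimation
    models include the term but no estimate is reported for it, so the
    generator's null is the study condition).
    """

    n_founders: int = 80
    n_generations: int = 4
    offspring_per_mating: int = 2
    sex_ratio: float = 0.339  # P(male); studbook records are ~34% male
    # studbook coat counts (grey, bay, chestnut, black) as frequencies
    coat_frequencies: np.ndarray = field(
        default_factory=lambda: np.array([15681, 15011, 3292, 4841]) / 38825.0
    )
    fixed_effects: FixedEffects = field(default_factory=FixedEffects.zero)
    sigma_u: np.ndarray = field(default_factory=lambda: np.eye(4))
    sigma_m: np.ndarray = field(default_factory=lambda: 0.05 * np.eye(4))
    sigma_um: np.ndarray = field(default_factory=lambda: np.zeros(4))
    sigma_e: np.ndarray = field(default_factory=lambda: np.eye(4))
    thresholds: np.ndarray = field(
        default_factory=lambda: np.tile(np.array([0.0, 1.0, 2.0]), (4, 1))
    )
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return self.sigma_u.shape[0]

    def validate(self) -> None:
        for name in ("sigma_u", "sigma_m", "sigma_e"):
            M = np.atleast_2d(getattr(self, name))
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-8:
                raise ValueError(f"{name} must be positive semidefinite")
        G = self.joint_genetic_covariance()
        if np.linalg.eigvalsh(G).min() < -1e-8:
            raise ValueError("joint direct-maternal covariance is not PSD")
        t = np.atleast_2d(self.thresholds)
        if not (np.diff(t, axis=1) > 0).all():
            raise ValueError("thresholds must be strictly ascending per trait")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be a probability")
        cf = np.asarray(self.coat_frequencies, dtype=float)
        if (cf < 0).any() or abs(cf.sum() - 1.0) > 1e-8:
            raise ValueError("coat_frequencies must be nonnegative and sum to 1")

    def joint_genetic_covariance(self) -> np.ndarray:
        """2T x 2T covariance of the stacked (u, m) effect per animal."""
        T = self.n_traits
        G = np.zeros((2 * T, 2 * T))
        G[:T, :T] = self.sigma_u
        G[T:, T:] = self.sigma_m
        cov = np.diag(np.asarray(self.sigma_um, dtype=float))
        G[:T, T:] = cov
        G[T:, :T] = cov
        return G


@dataclass
class MarkingDataset:
    """Phenotype records plus (for simulated data) the latent truth.

    ``frame`` columns: ``animal, sex, coat, F, dam`` and one score column
    per limb.  ``truth`` optionally holds the per-animal direct and
    maternal breeding values and the realized liabilities.
    """

    frame: pd.DataFrame
    truth: dict[str, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return len(self.frame)

    def scores(self, limb: str) -> np.ndarray:
        return self.frame[limb].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MarkingDataset":
        return cls(frame=load_phenotypes(path))


def load_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV with header ``animal,sex,coat,F,dam,lf,rf,lh,rh``.

    Scores are validated to lie in {0,1,2,3}; the offending row id is named
    on failure.
    """
    frame = pd.read_csv(path, sep=None, engine="python", dtype={"animal": str, "dam": str},
                        keep_default_na=False, na_values=[])
    frame.columns = [c.strip().lower() if c != "F" else "F" for c in frame.columns]
    if "f" in frame.columns:
        frame = frame.rename(columns={"f": "F"})
    for limb in LIMBS:
        if limb in frame.columns:
            s = pd.to_numeric(frame[limb])
            bad = ~s.isin([0, 1, 2, 3])
            if bad.any():
                rid = frame.loc[bad, "animal"].iloc[0]
                raise ValueError(f"score out of range 0..3 for animal {rid!r} in column {limb}")
            frame[limb] = s.astype(int)
    return frame


# -- presets ------------------------------------------------------------

# Study-condition truth: direct/maternal/residual liability variances per
# limb (lf, rf, lh, rh) and the genetic correlation structure estimated on
# the full four-class studbook analysis.
_PRE_SIGMA_U_DIAG = np.array([4.877, 4.772, 7.904, 5.659])
_PRE_SIGMA_M_DIAG = np.array([0.185, 0.130, 0.398, 0.273])
_PRE_SIGMA_E_DIAG = np.array([4.000, 3.420, 8.046, 5.898])
_PRE_GENETIC_CORR = np.array(
    [
        [1.000, 0.991, 0.907, 0.886],
        [0.991, 1.000, 0.887, 0.863],
        [0.907, 0.887, 1.000, 0.995],
        [0.886, 0.863, 0.995, 1.000],
    ]
)
# marginal score distribution per limb: P(affected), then the split of the
# affected among classes 1..3 (below fetlock / above fetlock / cannon bone)
_PRE_PREVALENCE = {
    "lf": (0.0529, (0.162, 0.662, 0.176)),
    "rf": (0.0465, (0.169, 0.650, 0.181)),
    "lh": (0.1795, (0.121, 0.639, 0.240)),
    "rh": (0.1451, (0.127, 0.638, 0.235)),
}


def nearest_psd_correlation(C: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix with unit
    diagonal (eigenvalue clipping followed by renormalization).

    Rounded printed correlation tables need not be PSD; this restores
    validity while moving entries as little as possible.
    """
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    Cp = (V * np.clip(w, eps, None)) @ V.T
    d = np.sqrt(np.diag(Cp))
    Cp = Cp / np.outer(d, d)
    Cp = (Cp + Cp.T) / 2.0
    np.fill_diagonal(Cp, 1.0)
    return Cp


def pre_like(**overrides) -> SimConfig:
    """Default study-condition preset.

    Genetic covariances combine the per-limb variances with the PSD-projected
    correlation matrix; maternal and residual covariances are diagonal.
    Thresholds are placed so the marginal normal-CDF score probabilities
    match the observed per-limb prevalences and class shares, after
    centring the average fixed-effect contribution.
    """
    corr = nearest_psd_correlation(_PRE_GENETIC_CORR)
    sd_u = np.sqrt(_PRE_SIGMA_U_DIAG)
    sigma_u = corr * np.outer(sd_u, sd_u)
    sigma_m = np.diag(_PRE_SIGMA_M_DIAG)
    sigma_e = np.diag(_PRE_SIGMA_E_DIAG)

    total_sd = np.sqrt(_PRE_SIGMA_U_DIAG + _PRE_SIGMA_M_DIAG + _PRE_SIGMA_E_DIAG)
    # fixed effects scaled by each trait's liability SD: males and chestnut
    # coats shift toward marking, black away (effect sizes from the observed
    # raw unaffected-percentage gaps on the probit scale)
    fx = FixedEffects(
        sex_male=0.19 * total_sd,
        coat={
            "grey": np.zeros(4),
            "bay": -0.05 * total_sd,
            "chestnut": 0.18 * total_sd,
            "black": -0.24 * total_sd,
        },
        f_slope=1.2 * total_sd / 3.0,
    )

    cfg = SimConfig(
        fixed_effects=fx,
        sigma_u=sigma_u,
        sigma_m=sigma_m,
        sigma_e=sigma_e,
    )
    # calibrate thresholds against the marginal liability distribution
    mean_shift = fx.mean_shift(cfg.sex_ratio, cfg.coat_frequencies, mean_f=0.074)
    thresholds = np.zeros((4, 3))
    for t, limb in enumerate(LIMBS):
        p_aff, shares = _PRE_PREVALENCE[limb]
        cum = np.array(
            [
                1.0 - p_aff,
                1.0 - p_aff + p_aff * shares[0],
                1.0 - p_aff + p_aff * (shares[0] + shares[1]),
            ]
        )
        thresholds[t] = total_sd[t] * stats.norm.ppf(cum) + mean_shift[t]
    cfg.thresholds = thresholds
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def dichotomous_preset(**overrides) -> SimConfig:
    """Single-limb-style truth on the binary-model scale.

    Residual variance 1 and threshold at 0 per trait (the binary threshold
    model's identification), with direct/maternal variances matching the
    dichotomous-analysis estimates for the four limbs; intercepts place the
    marginal prevalence at the observed per-limb values.
    """
    sigma_u = np.diag(np.array([1.540, 1.945, 1.223, 1.150]))
    sigma_m = np.diag(np.array([0.059, 0.067, 0.043, 0.037]))
    sigma_e = np.eye(4)
    total_sd = np.sqrt(np.diag(sigma_u) + np.diag(sigma_m) + np.diag(sigma_e))
    fx = FixedEffects.zero()
    cfg = SimConfig(
        fixed_effects=fx,
        sigma_u=sigma_u,
        sigma_m=sigma_m,
        sigma_e=sigma_e,
    )
    thresholds = np.zeros((4, 3))
    for t, limb in enumerate(LIMBS):
        p_aff, _ = _PRE_PREVALENCE[limb]
        t1 = total_sd[t] * stats.norm.ppf(1.0 - p_aff)
        thresholds[t] = [t1, t1 + 1.0, t1 + 2.0]  # upper cuts unused for binary view
    cfg.thresholds = thresholds
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def model_scale_truth(config: SimConfig, trait: int, response_scale: str) -> dict[str, float]:
    """Map the generator's truth onto the fitted model's identified scale.

    The threshold model is identified only up to an affine transform of the
    liability: the binary model fixes the threshold at 0 and sigma_e^2 = 1,
    the four-class model fixes t1 = 0 and t2 = 1.  This returns the true
    variance components expressed on that scale (h2 is scale-invariant).
    """
    su = float(np.atleast_2d(config.sigma_u)[trait, trait])
    sm = float(np.atleast_2d(config.sigma_m)[trait, trait])
    se = float(np.atleast_2d(config.sigma_e)[trait, trait])
    t = np.atleast_2d(config.thresholds)[trait]
    if response_scale == "dichotomous":
        c2 = se
    elif response_scale == "ordinal4":
        c2 = (t[1] - t[0]) ** 2
    else:
        raise ValueError(f"unknown response scale {response_scale!r}")
    return {
        "sigma_u2": su / c2,
        "sigma_m2": sm / c2,
        "sigma_e2": se / c2,
        "h2": su / (su + sm + se),
    }


# -- pedigree simulation ------------------------------------------------


def simulate_pedigree(config: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Discrete-generation pedigree with random mating within generation.

    Every female of the previous generation is mated to a random male of
    that generation and produces ``offspring_per_mating`` offspring.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    sexes: list[str] = []
    years: list[int] = []

    def draw_sex(n: int) -> np.ndarray:
        return np.where(rng.random(n) < config.sex_ratio, "male", "female")

    gen_ids = [f"g0_{k}" for k in range(config.n_founders)]
    gen_sex = draw_sex(config.n_founders)
    ids += gen_ids
    sires += [""] * config.n_founders
    dams += [""] * config.n_founders
    sexes += list(gen_sex)
    years += [0] * config.n_founders

    for g in range(1, config.n_generations + 1):
        males = [a for a, s in zip(gen_ids, gen_sex) if s == "male"]
        females = [a for a, s in zip(gen_ids, gen_sex) if s == "female"]
        if not males or not females:
            raise ValueError(
                f"generation {g - 1} has no {'males' if not males else 'females'}; "
                "cannot mate (adjust sex_ratio or n_founders)"
            )
        next_ids: list[str] = []
        k = 0
        chosen = rng.integers(0, len(males), size=len(females))
        for f_idx, female in enumerate(females):
            male = males[chosen[f_idx]]
            for _ in range(config.offspring_per_mating):
                aid = f"g{g}_{k}"
                k += 1
                next_ids.append(aid)
                ids.append(aid)
                sires.append(male)
                dams.append(female)
                years.append(g)
        next_sex = draw_sex(len(next_ids))
        sexes += list(next_sex)
        gen_ids, gen_sex = next_ids, next_sex

    frame = pd.DataFrame(
        {"animal": ids, "sire": sires, "dam": dams, "birth_year": years, "sex": sexes}
    )
    return Pedigree.from_frame(frame)


def _psd_factor(G: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (handles rank
    deficiency, e.g. zero covariance matrices)."""
    w, V = np.linalg.eigh(G)
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_breeding_values(
    ped: Pedigree, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Direct (u) and maternal (m) breeding values for every animal.

    Founders are drawn from N(0, G) with G the joint (u, m) covariance;
    descendants get the parent average plus a Mendelian-sampling deviation
    with variance d_i * G, d_i shrinking with parental inbreeding.
    Returns arrays of shape (n_animals, n_traits) each.
    """
    config.validate()
    T = config.n_traits
    G = config.joint_genetic_covariance()
    Lf = _psd_factor(G)
    n = ped.n
    F = inbreeding_coefficients(ped)
    d = mendelian_sampling_variance(ped, F)
    g = np.zeros((n, 2 * T))
    z = rng.standard_normal((n, 2 * T))
    for i in range(n):
        mean = np.zeros(2 * T)
        if ped.sire[i] != UNKNOWN:
            mean += 0.5 * g[ped.sire[i]]
        if ped.dam[i] != UNKNOWN:
            mean += 0.5 * g[ped.dam[i]]
        g[i] = mean + np.sqrt(d[i]) * (Lf @ z[i])
    return g[:, :T].copy(), g[:, T:].copy()


def simulate_phenotypes(
    ped: Pedigree,
    u: np.ndarray,
    m: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> MarkingDataset:
    """Observed ordinal scores for every pedigree animal.

    Liability = fixed effects + own direct effect + dam's maternal effect
    + residual; animals with an unknown dam receive an independent maternal
    draw.  The latent truth (u, m, liabilities) is retained on the result.
    """
    config.validate()
    T = config.n_traits
    n = ped.n
    F = inbreeding_coefficients(ped)
    sex = np.asarray(
        ped.sex if ped.sex is not None else np.array(["female"] * n, dtype=object)
    )
    coat = np.asarray(COATS)[rng.choice(len(COATS), size=n, p=np.asarray(config.coat_frequencies))]

    fx = config.fixed_effects

    def fxa(a) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        if a.size < T:
            raise ValueError("fixed-effect coefficient vector shorter than trait count")
        return a[:T]

    xb = np.zeros((n, T))
    xb += np.where(sex[:, None] == "male", fxa(fx.sex_male)[None, :], 0.0)
    for c in COATS:
        xb += np.where(coat[:, None] == c, fxa(fx.coat[c])[None, :], 0.0)
    xb += F[:, None] * fxa(fx.f_slope)[None, :]

    m_dam = np.zeros((n, T))
    known = ped.dam != UNKNOWN
    m_dam[known] = m[ped.dam[known]]
    n_unknown = int((~known).sum())
    if n_unknown:
        Lm = _psd_factor(np.atleast_2d(config.sigma_m))
        m_dam[~known] = rng.standard_normal((n_unknown, T)) @ Lm.T

    se = np.sqrt(np.diag(np.atleast_2d(config.sigma_e)))
    e = rng.standard_normal((n, T)) * se[None, :]
    liab = xb + u + m_dam + e

    thresholds = np.atleast_2d(config.thresholds)
    scores = np.zeros((n, T), dtype=int)
    for t in range(T):
        scores[:, t] = np.searchsorted(thresholds[t], liab[:, t], side="right")

    dam_label = np.array(
        ["" if ped.dam[i] == UNKNOWN else ped.ids[ped.dam[i]] for i in range(n)], dtype=object
    )
    frame = pd.DataFrame({"animal": ped.ids, "sex": sex, "coat": coat, "F": F, "dam": dam_label})
    for t, limb in enumerate(LIMBS[:T]):
        frame[limb] = scores[:, t]
    truth = {"u": u, "m": m, "liabilities": liab, "xb": xb}
    return MarkingDataset(frame=frame, truth=truth)


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Pedigree, MarkingDataset]:
    """Pedigree + phenotypes in one call (all randomness from one stream)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    u, m = simulate_breeding_values(ped, config, rng)
    data = simulate_phenotypes(ped, u, m, config, rng)
    return ped, data
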