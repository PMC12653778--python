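"""Bayesian threshold animal models over a pedigree.

The core estimator of the package: a liability threshold model

    l = X b + Z u + W m + e ,   (u, m) pedigree-structured via A

fitted by Gibbs sampling with data augmentation.  The observed score
(binary affected/unaffected, or the four-class ordinal scale) determines
which threshold interval the latent liability falls in; each Gibbs cycle
draws (1) liabilities from truncated normals, (2) location effects by
single-site updates over the sparse system embedding A^-1, (3) (co)variance
components from their scaled-inverse-chi-square / inverse-Wishart
conditionals, and (4) the free ordinal threshold from its uniform
conditional.

Identification follows the standard threshold-model constraints: the
binary model fixes the threshold at 0 and the residual variance at 1; the
four-class model fixes t1 = 0 and t2 = 1 and estimates the residual
variance.  Heritabilities and genetic correlations are computed per draw
and summarized, never as ratios of summaries.

Usage follows the statsmodels convention::

    model = ThresholdAnimalModel(data, ped, ThresholdModelSpec(traits=["lf"]))
    res = model.fit(ChainConfig(total_iterations=8000, burn_in=2000, seed=7))
    res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from . import _gibbs
from .pedigree import UNKNOWN, Pedigree, a_inverse, inbreeding_coefficients
from .posterior import summary_table
from .simulate import COATS, LIMBS, MarkingDataset

DIVERGENCE_BOUND = 1e8


@dataclass
class ThresholdModelSpec:
    """Declarative description of one threshold-model fit.

    ``fixed_effects`` may contain ``"sex"`` (reference: female), ``"coat"``
    (reference: grey) and ``"F"`` (the inbreeding covariate); an intercept
    is always included.  ``include_direct_maternal_covariance`` requires a
    single trait (the coupled 2x2 update is implemented univariately).
    """

    traits: list[str] = field(default_factory=lambda: ["lf"])
    response_scale: str = "dichotomous"  # "dichotomous", "ordinal4" or "gaussian"
    fixed_effects: tuple[str, ...] = ("sex", "coat", "F")
    include_intercept: bool = True
    include_maternal: bool = True
    include_direct_maternal_covariance: bool = False
    fix_residual: float | None = None  # fix sigma_e2 (gaussian scale only)
    # variance priors: flat on the positive-definite cone, the multivariate
    # analog of the flat scaled-inv-chi2 (nu = -2, S = 0) univariate prior.
    # An inverse-Wishart with small positive df and a near-zero scale matrix
    # looks innocuous but piles prior mass on singular matrices, dragging
    # genetic correlations to +-1; the flat prior has no boundary spike.
    prior_nu_u: float | None = None  # None -> -(T+1), flat
    prior_scale_u: float = 0.0
    prior_iw_scale: float = 0.0
    store_effects: bool = False

    def validate(self) -> None:
        if not self.traits:
            raise ValueError("at least one trait required")
        if self.response_scale not in ("dichotomous", "ordinal4", "gaussian"):
            raise ValueError(f"unknown response scale {self.response_scale!r}")
        if self.fix_residual is not None and self.response_scale != "gaussian":
            raise ValueError("fix_residual only applies to the gaussian scale")
        if self.include_direct_maternal_covariance and (
            len(self.traits) > 1 or not self.include_maternal
        ):
            raise ValueError(
                "direct-maternal covariance is supported for univariate "
                "maternal models only"
            )


@dataclass
class ChainConfig:
    total_iterations: int = 10000
    burn_in: int = 2000
    thinning: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.burn_in >= self.total_iterations:
            raise ValueError("burn_in must be smaller than total_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.total_iterations - self.burn_in) // self.thinning


@dataclass
class GibbsChain:
    """Post-burn-in, thinned draws plus bookkeeping of fixed constraints."""

    sigma_u: np.ndarray  # (ndraws, T, T)
    sigma_m: np.ndarray | None  # (ndraws, T) diagonal maternal variances
    sigma_um: np.ndarray | None  # (ndraws,) univariate direct-maternal cov
    sigma_e: np.ndarray  # (ndraws, T)
    thresholds: np.ndarray  # (ndraws, T, n_thresholds)
    b: np.ndarray  # (ndraws, T, p)
    u: np.ndarray | None = None  # (ndraws, n, T) when stored
    m: np.ndarray | None = None
    constraints: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.sigma_u.shape[0]


def ensure_known_dams(ped: Pedigree, animal_ids: list[str]) -> Pedigree:
    """Return a pedigree where every listed animal has a known dam,
    inserting a unique phantom founder dam where needed (so the maternal
    term of a record never dangles)."""
    need = [a for a in animal_ids if ped.dam[ped.index_of(a)] == UNKNOWN]
    if not need:
        return ped
    frame = ped.to_frame()
    phantom = pd.DataFrame(
        {"animal": [f"phantom_dam_{a}" for a in need], "sire": "", "dam": ""}
    )
    frame = frame.drop(columns=[c for c in ("birth_year", "sex") if c in frame], errors="ignore")
    dam_map = dict(zip(need, phantom["animal"]))
    frame["dam"] = [
        dam_map.get(a, d) for a, d in zip(frame["animal"], frame["dam"])
    ]
    return Pedigree.from_frame(pd.concat([phantom, frame], ignore_index=True))


def _design_matrix(frame: pd.DataFrame, fixed_effects: tuple[str, ...], intercept: bool = True):
    """Intercept + dummy/covariate columns; reference levels excluded."""
    cols = [np.ones(len(frame))] if intercept else []
    names = ["intercept"] if intercept else []
    for eff in fixed_effects:
        if eff == "sex":
            cols.append((frame["sex"].to_numpy() == "male").astype(float))
            names.append("sex[male]")
        elif eff == "coat":
            for c in COATS[1:]:  # grey is the reference
                cols.append((frame["coat"].to_numpy() == c).astype(float))
                names.append(f"coat[{c}]")
        elif eff == "F":
            cols.append(frame["F"].to_numpy(dtype=float))
            names.append("F")
        else:
            raise ValueError(f"unknown fixed effect {eff!r}")
    if not cols:
        return np.zeros((len(frame), 0)), []
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient beyond reference constraints")
    return X, names


def _group_csr(codes: np.ndarray, n_groups: int):
    """CSR-style (ptr, idx) mapping group -> record indices."""
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes, minlength=n_groups)
    ptr = np.zeros(n_groups + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, order.astype(np.int64)


class ThresholdAnimalModel:
    """Threshold liability animal model bound to data and a pedigree."""

    def __init__(self, data, ped: Pedigree, spec: ThresholdModelSpec):
        spec.validate()
        self.spec = spec
        frame = data.frame if isinstance(data, MarkingDataset) else data
        for trait in spec.traits:
            if trait not in frame.columns:
                raise ValueError(f"trait column {trait!r} missing from data")
        self.frame = frame.reset_index(drop=True)
        ped = ensure_known_dams(ped, list(self.frame["animal"]))
        self.ped = ped
        self.n_ped = ped.n
        self.rec_animal = np.array(
            [ped.index_of(a) for a in self.frame["animal"]], dtype=np.int64
        )
        self.rec_dam = ped.dam[self.rec_animal]
        if (self.rec_dam == UNKNOWN).any():
            raise AssertionError("phantom dam insertion failed")

        self.X, self.fixed_names = _design_matrix(
            self.frame, spec.fixed_effects, spec.include_intercept
        )
        self.nrec, self.p = self.X.shape
        self.T = len(spec.traits)

        if spec.response_scale == "gaussian":
            self.y_cont = np.column_stack(
                [self.frame[t].to_numpy(dtype=float) for t in spec.traits]
            )
            self.y = None
            self.n_cat = 0
        else:
            scores = np.column_stack(
                [self.frame[t].to_numpy(dtype=int) for t in spec.traits]
            )
            if scores.min() < 0 or scores.max() > 3:
                raise ValueError("scores must lie in 0..3")
            self.y_cont = None
            if spec.response_scale == "dichotomous":
                self.y = (scores > 0).astype(np.int64)
                self.n_cat = 2
            else:
                self.y = scores.astype(np.int64)
                self.n_cat = 4
                for t, trait in enumerate(spec.traits):
                    present = np.bincount(self.y[:, t], minlength=4)
                    if (present == 0).any():
                        missing = int(np.where(present == 0)[0][0])
                        raise ValueError(
                            f"trait {trait!r}: ordinal4 requires every class observed "
                            f"(class {missing} absent)"
                        )
            for t, trait in enumerate(spec.traits):
                if len(np.unique(self.y[:, t])) < 2:
                    raise ValueError(f"trait {trait!r} has a single observed category")

        self.F = inbreeding_coefficients(ped)
        self.Ainv = a_inverse(ped, self.F).tocsr()
        self.an_ptr, self.an_idx = _group_csr(self.rec_animal, self.n_ped)
        self.dam_ptr, self.dam_idx = _group_csr(self.rec_dam, self.n_ped)
        self.Sxx = (self.X**2).sum(axis=0)

    def _nu0(self, T: int) -> float:
        """Prior degrees of freedom: flat prior -(T+1) unless overridden."""
        return self.spec.prior_nu_u if self.spec.prior_nu_u is not None else -(T + 1.0)

    # -- mixed-model system (used for BLUP cross-checks and diagnostics) --

    def build_mme(
        self,
        y: np.ndarray,
        sigma_u2: float,
        sigma_e2: float,
        sigma_m2: float | None = None,
    ):
        """Assemble Henderson's mixed-model equations for one trait with
        the given variance components, treating ``y`` as observed Gaussian
        data.

        Returns (LHS sparse, rhs, block slices).  The coefficient order is
        fixed effects, direct genetic effects (all pedigree animals), then
        maternal effects when the model includes them; animals without
        records enter only through the A^-1 blocks.
        """
        X = sparse.csr_matrix(self.X)
        Z = sparse.csr_matrix(
            (np.ones(self.nrec), (np.arange(self.nrec), self.rec_animal)),
            shape=(self.nrec, self.n_ped),
        )
        lam_u = sigma_e2 / sigma_u2
        blocks = [X, Z]
        if self.spec.include_maternal:
            if sigma_m2 is None:
                raise ValueError("sigma_m2 required when the model includes a maternal term")
            W = sparse.csr_matrix(
                (np.ones(self.nrec), (np.arange(self.nrec), self.rec_dam)),
                shape=(self.nrec, self.n_ped),
            )
            blocks.append(W)
        M = sparse.hstack(blocks, format="csr")
        lhs = (M.T @ M).tolil()
        pu = slice(self.p, self.p + self.n_ped)
        lhs[pu, pu] = lhs[pu, pu] + self.Ainv * lam_u
        slices = {"fixed": slice(0, self.p), "direct": pu}
        if self.spec.include_maternal:
            lam_m = sigma_e2 / sigma_m2
            pm = slice(self.p + self.n_ped, self.p + 2 * self.n_ped)
            lhs[pm, pm] = lhs[pm, pm] + self.Ainv * lam_m
            slices["maternal"] = pm
        rhs = M.T @ np.asarray(y, dtype=float)
        return lhs.tocsr(), rhs, slices

    # -- fitting ----------------------------------------------------------

    def _category_bounds(self, thresholds: np.ndarray):
        """Per trait, per category (lo, hi) liability interval."""
        T, n_thr = thresholds.shape
        lo = np.full((T, self.n_cat), -np.inf)
        hi = np.full((T, self.n_cat), np.inf)
        for t in range(T):
            for c in range(self.n_cat):
                if c > 0:
                    lo[t, c] = thresholds[t, c - 1]
                if c < self.n_cat - 1:
                    hi[t, c] = thresholds[t, c]
        return lo, hi

    def _initial_state(self, rng: np.random.Generator):
        T, nrec = self.T, self.nrec
        b = np.zeros((T, self.p))
        u = np.zeros((self.n_ped, T))
        m = np.zeros((self.n_ped, T))
        if self.spec.response_scale == "gaussian":
            thr = np.zeros((T, 0))
            v = self.y_cont.var(axis=0, ddof=1)
            sigma_e2 = 0.5 * v
            if self.spec.fix_residual is not None:
                sigma_e2 = np.full(T, self.spec.fix_residual)
            sigma_u2 = np.diag(np.maximum(0.5 * v, 1e-8))
            sigma_m2 = np.maximum(0.1 * v, 1e-8)
            if self.p and self.fixed_names and self.fixed_names[0] == "intercept":
                b[:, 0] = self.y_cont.mean(axis=0)
        elif self.spec.response_scale == "dichotomous":
            thr = np.zeros((T, 1))
            sigma_e2 = np.ones(T)
            sigma_u2 = 0.5 * np.eye(T)
            sigma_m2 = 0.1 * np.ones(T)
            for t in range(T):
                p1 = self.y[:, t].mean()
                if self.p and self.fixed_names and self.fixed_names[0] == "intercept":
                    b[t, 0] = -stats.norm.ppf(1 - p1)
        else:
            thr = np.zeros((T, 3))
            sigma_e2 = np.ones(T)
            sigma_u2 = 0.5 * np.eye(T)
            sigma_m2 = 0.1 * np.ones(T)
            for t in range(T):
                freq = np.bincount(self.y[:, t], minlength=4) / nrec
                z = stats.norm.ppf(np.clip(np.cumsum(freq)[:3], 1e-4, 1 - 1e-4))
                scale = z[1] - z[0]
                thr[t] = [0.0, 1.0, (z[2] - z[0]) / scale]
                if self.p and self.fixed_names and self.fixed_names[0] == "intercept":
                    b[t, 0] = -z[0] / scale
                # the t1=0, t2=1 constraint fixes the latent scale at
                # 1/(z1-z0) marginal SDs; start the variance components there
                v_tot = 1.0 / (scale * scale)
                sigma_u2[t, t] = 0.45 * v_tot
                sigma_m2[t] = 0.05 * v_tot
                sigma_e2[t] = 0.5 * v_tot
        sigma_u2 = sigma_u2 + 1e-12 * np.eye(T)
        return b, u, m, thr, sigma_u2, sigma_m2, sigma_e2

    def _scale_move_u(self, e, u, Su, se2, rng, step=0.05):
        """Joint Metropolis rescaling of (u, Sigma_u) by a common factor.

        The single-site sweep mixes the overall scale of the genetic-effect
        vector slowly when category information is sparse; this move
        proposes u -> c u, Sigma_u -> c^2 Sigma_u and accepts with the
        exact posterior ratio (the prior density change cancels against the
        Jacobian except for a T(T+1) log c term plus the inverse-Wishart
        scale-matrix contribution).
        """
        T = u.shape[1]
        c = float(np.exp(step * rng.standard_normal()))
        ua = u[self.rec_animal]
        dll = 0.0
        for t in range(T):
            en = e[:, t] - (c - 1.0) * ua[:, t]
            dll += float((e[:, t] @ e[:, t] - en @ en) / (2.0 * se2[t]))
        nu0 = self._nu0(T)
        log_alpha = dll + T * (T + 1) * np.log(c) - T * (nu0 + T + 1) * np.log(c)
        if self.spec.prior_iw_scale > 0.0:
            tr = float(np.trace(np.linalg.inv(np.atleast_2d(Su)))) * self.spec.prior_iw_scale
            log_alpha -= 0.5 * tr * (1.0 / c**2 - 1.0)
        if np.log(rng.random()) < log_alpha:
            u *= c
            Su = np.atleast_2d(Su) * c * c
            e[:] = e - (c - 1.0) * ua
            return Su, True
        return Su, False

    def _asis_update_Su(self, e, u, Su, se2, rng, steps, adapt):
        """Interweaving (ASIS) update of the genetic covariance.

        The centered draws (Sigma_u | u from the inverse Wishart) mix very
        slowly when the genetic correlations sit near the boundary: u and
        Sigma_u reinforce each other.  Re-drawing the Cholesky factor L of
        Sigma_u in the *non-centered* parameterization u = u_tilde L' (with
        u_tilde held fixed) makes the update likelihood-driven and breaks
        the coupling.  Each element of L gets a random-walk Metropolis step
        with the exact residual-likelihood + prior + Jacobian ratio; step
        sizes adapt during burn-in only.
        """
        T = u.shape[1]
        nu0 = self._nu0(T)
        s0 = self.spec.prior_iw_scale
        L = np.linalg.cholesky(Su)
        # ancillary effects: u = u_tilde @ L.T
        from scipy.linalg import solve_triangular

        u_tilde = solve_triangular(L, u.T, lower=True).T

        def log_prior(Lc):
            dg = np.diag(Lc)
            if (dg <= 0).any():
                return -np.inf
            Linv = solve_triangular(Lc, np.eye(T), lower=True)
            tr = float(np.sum(Linv * Linv))
            lp = -(nu0 + T + 1) * float(np.sum(np.log(dg)))
            lp += float(np.sum((T - np.arange(T)) * np.log(dg)))
            lp -= 0.5 * s0 * tr
            return lp

        lp_cur = log_prior(L)
        ua = u_tilde[self.rec_animal]
        for t in range(T):
            for s in range(t + 1):
                k = t * (t + 1) // 2 + s
                if s == t:
                    # multiplicative proposal keeps the non-centered move
                    # well scaled however small the loading is; the extra
                    # log L_tt Jacobian enters the ratio
                    prop = L[t, t] * np.exp(steps[k] * rng.standard_normal())
                    log_q = np.log(prop) - np.log(L[t, t])
                else:
                    # off-diagonals scale naturally with the trait SD
                    prop = L[t, s] + steps[k] * np.sqrt(Su[s, s]) * rng.standard_normal()
                    log_q = 0.0
                Lp = L.copy()
                Lp[t, s] = prop
                lp_new = log_prior(Lp)
                if np.isfinite(lp_new):
                    delta = prop - L[t, s]
                    en = e[:, t] - delta * ua[:, s]
                    dll = float((e[:, t] @ e[:, t] - en @ en) / (2.0 * se2[t]))
                    log_alpha = dll + lp_new - lp_cur + log_q
                else:
                    log_alpha = -np.inf
                accepted = np.log(rng.random()) < log_alpha
                if accepted:
                    e[:, t] = en
                    L = Lp
                    lp_cur = lp_new
                if adapt:
                    steps[k] = float(
                        np.clip(steps[k] * (1.05 if accepted else 0.97), 0.02, 1.0)
                    )
        u[:] = u_tilde @ L.T
        return L @ L.T

    def _marginal_loglik_ordinal(self, b, u, m, thr, se2) -> float:
        """Observed-category log likelihood with liabilities integrated out
        (product of normal-CDF differences)."""
        from scipy.special import ndtr

        mu = self.X @ b.T + u[self.rec_animal] + m[self.rec_dam]
        total = 0.0
        for t in range(self.T):
            edges = np.concatenate(([-np.inf], thr[t], [np.inf]))
            lo = edges[self.y[:, t]]
            hi = edges[self.y[:, t] + 1]
            s = np.sqrt(se2[t])
            p = ndtr((hi - mu[:, t]) / s) - ndtr((lo - mu[:, t]) / s)
            total += float(np.sum(np.log(np.maximum(p, 1e-300))))
        return total

    def _collapsed_scale_move(self, b, u, m, Su, sm2, se2, thr, rng, step=0.10):
        """Global scale move with liabilities integrated out (ordinal only).

        With t1 = 0 and t2 = 1 fixed, the overall latent scale is informed
        only by the class frequencies between the fixed thresholds; the
        augmented sampler random-walks along this direction very slowly.
        Proposing (b, u, m) -> c(b, u, m), variances -> c^2, t3 -> c t3 and
        accepting against the exact categorical likelihood equilibrates the
        scale directly.  Liabilities are refreshed from their conditionals
        at the start of the next cycle, keeping the chain valid.
        """
        T = self.T
        c = float(np.exp(step * rng.standard_normal()))
        thr_new = thr.copy()
        thr_new[:, 2] = c * thr[:, 2]
        if (thr_new[:, 2] <= thr_new[:, 1]).any():
            return b, u, m, Su, sm2, se2, thr, False
        ll_cur = self._marginal_loglik_ordinal(b, u, m, thr, se2)
        ll_new = self._marginal_loglik_ordinal(c * b, c * u, c * m, thr_new, c * c * se2)
        # flat priors on b, variances and t3: the prior x Jacobian factor is
        # c^{pT} (b) * c^{2T} (sigma_e) * c^{2T} (sigma_m) * c^{T(T+1)}
        # (Sigma_u) * c^{T} (t3); the u and m prior ratios cancel their
        # Jacobians exactly
        log_jac = (self.p * T + 2 * T + 2 * T + T * (T + 1) + T) * np.log(c)
        if np.log(rng.random()) < ll_new - ll_cur + log_jac:
            return c * b, c * u, c * m, c * c * Su, c * c * sm2, c * c * se2, thr_new, True
        return b, u, m, Su, sm2, se2, thr, False

    def _scale_move_m(self, e, m, sm2, se2, rng, step=0.05):
        """Metropolis rescaling of (m, sigma_m2), one common factor across
        traits (diagonal maternal covariance, flat variance priors)."""
        T = m.shape[1]
        c = float(np.exp(step * rng.standard_normal()))
        md = m[self.rec_dam]
        dll = 0.0
        for t in range(T):
            en = e[:, t] - (c - 1.0) * md[:, t]
            dll += float((e[:, t] @ e[:, t] - en @ en) / (2.0 * se2[t]))
        log_alpha = dll + 2.0 * T * np.log(c)
        if np.log(rng.random()) < log_alpha:
            m *= c
            sm2 *= c * c
            e[:] = e - (c - 1.0) * md
            return True
        return False

    def fit(self, chain: ChainConfig, progress: bool = False) -> "ThresholdAnimalResults":
        """Run the Gibbs sampler and return posterior results."""
        chain.validate()
        spec = self.spec
        rng = np.random.default_rng(chain.seed)
        T, nrec = self.T, self.nrec

        b, u, m, thr, Su, sm2, se2 = self._initial_state(rng)
        um_cov = 0.0
        liab = np.zeros((nrec, T))
        mean = np.zeros((nrec, T))

        n_store = chain.n_stored
        store = {
            "sigma_u": np.zeros((n_store, T, T)),
            "sigma_m": np.zeros((n_store, T)) if spec.include_maternal else None,
            "sigma_um": np.zeros(n_store) if spec.include_direct_maternal_covariance else None,
            "sigma_e": np.zeros((n_store, T)),
            "thresholds": np.zeros((n_store,) + thr.shape),
            "b": np.zeros((n_store, T, self.p)),
            "u": np.zeros((n_store, self.n_ped, T)) if spec.store_effects else None,
            "m": (
                np.zeros((n_store, self.n_ped, T))
                if spec.store_effects and spec.include_maternal
                else None
            ),
        }
        kept = 0
        dichotomous = spec.response_scale == "dichotomous"
        gaussian = spec.response_scale == "gaussian"
        asis_steps = 0.1 * np.ones(T * (T + 1) // 2)  # RW steps, tuned in burn-in
        if gaussian:
            liab = self.y_cont.astype(float).copy()

        for it in range(chain.total_iterations):
            # (1) liabilities (observed directly on the gaussian scale)
            mean[:] = self.X @ b.T + u[self.rec_animal] + m[self.rec_dam]
            if not gaussian:
                lo, hi = self._category_bounds(thr)
                _gibbs.sample_liabilities(
                    liab, self.y, mean, np.sqrt(se2), lo, hi, rng
                )
            e = liab - mean

            # (2) location effects
            if spec.include_direct_maternal_covariance:
                G0 = np.array([[Su[0, 0], um_cov], [um_cov, sm2[0]]])
                G0inv = np.linalg.inv(G0)
                _gibbs.location_sweep_um(
                    e, self.X, b, u, m,
                    self.an_ptr, self.an_idx, self.dam_ptr, self.dam_idx,
                    self.Ainv.indptr, self.Ainv.indices, self.Ainv.data,
                    G0inv, se2, self.Sxx, rng,
                )
            else:
                Suinv = np.linalg.inv(Su)
                _gibbs.location_sweep(
                    e, self.X, b, u, m,
                    self.rec_animal, self.rec_dam,
                    self.an_ptr, self.an_idx, self.dam_ptr, self.dam_idx,
                    self.Ainv.indptr, self.Ainv.indices, self.Ainv.data,
                    Suinv, sm2, se2, self.Sxx,
                    spec.include_maternal, rng,
                )

            # (3) variance components
            if spec.include_direct_maternal_covariance:
                g = np.column_stack([u[:, 0], m[:, 0]])
                S = g.T @ (self.Ainv @ g) + self.spec.prior_iw_scale * np.eye(2)
                df = self.n_ped + self._nu0(2)
                G0 = stats.invwishart.rvs(df=df, scale=S, random_state=rng)
                Su = np.array([[G0[0, 0]]])
                sm2 = np.array([G0[1, 1]])
                um_cov = float(G0[0, 1])
            elif T == 1:
                q = float(u[:, 0] @ (self.Ainv @ u[:, 0]))
                df = self.n_ped + self._nu0(1)
                Su = np.array([[(q + spec.prior_scale_u) / rng.chisquare(df)]])
                if spec.include_maternal:
                    qm = float(m[:, 0] @ (self.Ainv @ m[:, 0]))
                    sm2 = np.array([(qm + spec.prior_scale_u) / rng.chisquare(df)])
            else:
                S = u.T @ (self.Ainv @ u) + spec.prior_iw_scale * np.eye(T)
                df = self.n_ped + self._nu0(T)
                Su = stats.invwishart.rvs(df=df, scale=S, random_state=rng)
                if spec.include_maternal:
                    # diagonal maternal covariance: per-trait univariate rule
                    for t in range(T):
                        qm = float(m[:, t] @ (self.Ainv @ m[:, t]))
                        sm2[t] = (qm + spec.prior_scale_u) / rng.chisquare(
                            self.n_ped + self._nu0(1)
                        )
            if not dichotomous and spec.fix_residual is None:
                for t in range(T):
                    q = float(e[:, t] @ e[:, t])
                    se2[t] = q / rng.chisquare(nrec - 2)
            # scale moves: accelerate the slow overall-scale mode of the
            # genetic-effect vectors (exact MH, targets the same posterior)
            if not spec.include_direct_maternal_covariance:
                Su, _ = self._scale_move_u(e, u, Su, se2, rng)
                Su = np.atleast_2d(Su)
                if T > 1:
                    Su = self._asis_update_Su(
                        e, u, Su, se2, rng, asis_steps, adapt=it < chain.burn_in
                    )
                if spec.include_maternal:
                    self._scale_move_m(e, m, sm2, se2, rng)

            if np.max(np.diag(np.atleast_2d(Su))) > DIVERGENCE_BOUND or np.max(
                se2
            ) > DIVERGENCE_BOUND:
                raise RuntimeError(
                    f"variance draw diverged at iteration {it} "
                    f"(sigma_u diag {np.diag(np.atleast_2d(Su))}, sigma_e {se2}); "
                    "check model identification and data"
                )

            # (4) free ordinal threshold t3 from its uniform conditional
            if spec.response_scale == "ordinal4":
                for t in range(T):
                    in2 = liab[self.y[:, t] == 2, t]
                    in3 = liab[self.y[:, t] == 3, t]
                    lo_t = in2.max() if in2.size else thr[t, 1]
                    hi_t = in3.min() if in3.size else lo_t + 1.0
                    lo_t = max(lo_t, thr[t, 1])
                    thr[t, 2] = lo_t + (hi_t - lo_t) * rng.random()

            # collapsed global-scale move (ordinal: the latent scale is the
            # slowest direction of the augmented sampler)
            if (
                spec.response_scale == "ordinal4"
                and not spec.include_direct_maternal_covariance
            ):
                if not spec.include_maternal:
                    sm2_eff = np.zeros(T)
                else:
                    sm2_eff = sm2
                b, u, m, Su, sm2_eff, se2, thr, _ = self._collapsed_scale_move(
                    b, u, m, Su, sm2_eff, se2, thr, rng
                )
                if spec.include_maternal:
                    sm2 = sm2_eff

            if it >= chain.burn_in and (it - chain.burn_in) % chain.thinning == 0:
                store["sigma_u"][kept] = np.atleast_2d(Su)
                if store["sigma_m"] is not None:
                    store["sigma_m"][kept] = sm2
                if store["sigma_um"] is not None:
                    store["sigma_um"][kept] = um_cov
                store["sigma_e"][kept] = se2
                store["thresholds"][kept] = thr
                store["b"][kept] = b
                if store["u"] is not None:
                    store["u"][kept] = u
                if store["m"] is not None:
                    store["m"][kept] = m
                kept += 1

        if gaussian:
            constraints = {}
            if spec.fix_residual is not None:
                constraints["sigma_e2"] = spec.fix_residual
        elif dichotomous:
            constraints = {"t1": 0.0, "sigma_e2": 1.0}
        else:
            constraints = {"t1": 0.0, "t2": 1.0}
        gchain = GibbsChain(
            sigma_u=store["sigma_u"][:kept],
            sigma_m=None if store["sigma_m"] is None else store["sigma_m"][:kept],
            sigma_um=None if store["sigma_um"] is None else store["sigma_um"][:kept],
            sigma_e=store["sigma_e"][:kept],
            thresholds=store["thresholds"][:kept],
            b=store["b"][:kept],
            u=None if store["u"] is None else store["u"][:kept],
            m=None if store["m"] is None else store["m"][:kept],
            constraints=constraints,
        )
        return ThresholdAnimalResults(self, gchain, chain)


class ThresholdAnimalResults:
    """Posterior draws with derived genetic parameters.

    All derived quantities (h2, genetic correlations, observed-scale h2)
    are computed per draw and summarized with means, medians, SDs and the
    empirical 95% HPD interval.
    """

    def __init__(self, model: ThresholdAnimalModel, chain: GibbsChain, config: ChainConfig):
        self.model = model
        self.chain = chain
        self.config = config

    def _trait_index(self, trait) -> int:
        if isinstance(trait, str):
            return self.model.spec.traits.index(trait)
        return int(trait)

    def heritability_samples(self, trait) -> np.ndarray:
        """Per-draw h2 = sigma_u2 / (sigma_u2 + sigma_m2 + sigma_e2)."""
        t = self._trait_index(trait)
        su = self.chain.sigma_u[:, t, t]
        sm = self.chain.sigma_m[:, t] if self.chain.sigma_m is not None else 0.0
        se = self.chain.sigma_e[:, t]
        return su / (su + sm + se)

    def genetic_correlation_samples(self, trait_pair) -> np.ndarray:
        """Per-draw r_g for a pair of traits; draws with a zero variance
        are excluded (their count is available as ``.n_excluded_rg``)."""
        i = self._trait_index(trait_pair[0])
        j = self._trait_index(trait_pair[1])
        if i == j:
            raise ValueError("need two distinct traits")
        vi = self.chain.sigma_u[:, i, i]
        vj = self.chain.sigma_u[:, j, j]
        cij = self.chain.sigma_u[:, i, j]
        ok = (vi > 0) & (vj > 0)
        self.n_excluded_rg = int((~ok).sum())
        return cij[ok] / np.sqrt(vi[ok] * vj[ok])

    def observed_scale_h2_samples(self, trait) -> np.ndarray:
        """Per-draw observed-scale h2 for the binary view of a trait,
        using the classical liability transformation at the observed
        prevalence."""
        t = self._trait_index(trait)
        scores = self.model.y[:, t]
        p = float((scores > 0).mean())
        return np.array([dempster_lerner(h2, p) for h2 in self.heritability_samples(trait)])

    def named_samples(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        traits = self.model.spec.traits
        for t, name in enumerate(traits):
            out[f"sigma_u2[{name}]"] = self.chain.sigma_u[:, t, t]
            if self.chain.sigma_m is not None:
                out[f"sigma_m2[{name}]"] = self.chain.sigma_m[:, t]
            out[f"sigma_e2[{name}]"] = self.chain.sigma_e[:, t]
            out[f"h2[{name}]"] = self.heritability_samples(t)
            if self.model.spec.response_scale == "ordinal4":
                out[f"t3[{name}]"] = self.chain.thresholds[:, t, 2]
            for j, fname in enumerate(self.model.fixed_names):
                out[f"b[{name}:{fname}]"] = self.chain.b[:, t, j]
        if self.chain.sigma_um is not None:
            out["sigma_um"] = self.chain.sigma_um
        for i in range(len(traits)):
            for j in range(i + 1, len(traits)):
                out[f"r_g[{traits[i]},{traits[j]}]"] = self.genetic_correlation_samples((i, j))
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior summary table (mean, median, SD, HPD95)."""
        return summary_table(self.named_samples())

    def plot_trace(self, names: list[str] | None = None, path=None):
        """Trace plots for selected parameters (all variance components
        and h2 by default)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        samples = self.named_samples()
        if names is None:
            names = [k for k in samples if k.startswith(("sigma", "h2", "r_g"))]
        fig, axes = plt.subplots(len(names), 1, figsize=(7, 1.8 * len(names)), squeeze=False)
        for ax, name in zip(axes[:, 0], names):
            ax.plot(samples[name], lw=0.5)
            ax.set_ylabel(name, fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=100)
            plt.close(fig)
        return fig

    def save(self, path) -> None:
        """Persist the chain as a compressed npz container."""
        arrays = {
            "sigma_u": self.chain.sigma_u,
            "sigma_e": self.chain.sigma_e,
            "thresholds": self.chain.thresholds,
            "b": self.chain.b,
        }
        if self.chain.sigma_m is not None:
            arrays["sigma_m"] = self.chain.sigma_m
        if self.chain.sigma_um is not None:
            arrays["sigma_um"] = self.chain.sigma_um
        np.savez_compressed(path, **arrays)


def heritability_from_components(sigma_u2: float, sigma_m2: float, sigma_e2: float) -> float:
    """h2 on the liability scale: direct variance over total variance
    (the denominator includes the maternal variance)."""
    return sigma_u2 / (sigma_u2 + sigma_m2 + sigma_e2)


def dempster_lerner(h2_liability: float, prevalence: float) -> float:
    """Classical liability-to-observed-scale heritability transformation.

    h2_obs = h2 * z^2 / (p (1 - p)) with z the standard normal density at
    the threshold Phi^-1(1 - p).  Maximized over p at p = 0.5.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    if not 0.0 <= h2_liability <= 1.0:
        raise ValueError("liability h2 must lie in [0, 1]")
    z = stats.norm.pdf(stats.norm.ppf(1.0 - prevalence))
    return h2_liability * z * z / (prevalence * (1.0 - prevalence))
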