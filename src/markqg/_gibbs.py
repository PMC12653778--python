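"""Numba kernels for the threshold-model Gibbs sampler.

These are the inner loops: truncated-normal liability draws and the
single-site location sweep over the sparse mixed-model system.  Everything
here is deterministic given the ``numpy.random.Generator`` passed in; all
parameter blocks are updated in a fixed order (fixed effects, then direct
genetic effects in pedigree order, then maternal effects) so runs are
reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _norm_ppf(p):
    """Acklam's rational approximation to the standard normal quantile,
    refined with one Halley step (|error| ~ 1e-15 over (0,1))."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    a = (-3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02,
         1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00)
    b = (-5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02,
         6.680131188771972e01, -1.328068155288572e01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00,
         -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e00,
         3.754408661907416e00)
    plow = 0.02425
    if p < plow:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
            ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    elif p <= 1.0 - plow:
        q = p - 0.5
        r = q * q
        x = (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q / \
            (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1.0)
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
            ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    # one Halley refinement
    e = _norm_cdf(x) - p
    u = e * math.sqrt(2.0 * math.pi) * math.exp(0.5 * x * x)
    x = x - u / (1.0 + 0.5 * x * u)
    return x


@njit(cache=True)
def _rtnorm_tail(a, b, rng):
    """Robert's exponential-rejection sampler for a standard normal
    truncated to [a, b] with a >= 0 large; never returns NaN."""
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    for _ in range(1000):
        z = a - math.log(1.0 - rng.random()) / alpha
        if z > b:
            continue
        rho = math.exp(-0.5 * (z - alpha) * (z - alpha))
        if rng.random() <= rho:
            return z
    # pathologically narrow interval: uniform draw inside it is an
    # acceptable guard (density is nearly flat over a sliver)
    hi = min(b, a + 1.0)
    return a + (hi - a) * rng.random()


@njit(cache=True)
def _rtnorm_std(a, b, rng):
    """Standard normal truncated to [a, b] (either bound may be infinite)."""
    if a > 5.0:
        return _rtnorm_tail(a, b, rng)
    if b < -5.0:
        return -_rtnorm_tail(-b, -a, rng)
    pa = _norm_cdf(a) if a > -np.inf else 0.0
    pb = _norm_cdf(b) if b < np.inf else 1.0
    if pb - pa < 1e-14:
        if a > 0.0:
            return _rtnorm_tail(a, b, rng)
        if b < 0.0:
            return -_rtnorm_tail(-b, -a, rng)
        lo = max(a, -1.0)
        hi = min(b, 1.0)
        return lo + (hi - lo) * rng.random()
    u = pa + (pb - pa) * rng.random()
    x = _norm_ppf(u)
    if x < a:
        x = a
    elif x > b:
        x = b
    return x


@njit(cache=True)
def rtnorm(mu, sd, lo, hi, rng):
    """Normal(mu, sd^2) truncated to [lo, hi]."""
    a = (lo - mu) / sd if lo > -np.inf else -np.inf
    b = (hi - mu) / sd if hi < np.inf else np.inf
    return mu + sd * _rtnorm_std(a, b, rng)


@njit(cache=True)
def sample_liabilities(liab, ycat, mean, se, cat_lo, cat_hi, rng):
    """Draw each record x trait liability from its truncated normal.

    ``cat_lo``/``cat_hi`` give per trait, per category the threshold
    interval; residuals are independent across traits (diagonal residual
    covariance), so draws factorize.
    """
    nrec, T = liab.shape
    for t in range(T):
        s = se[t]
        for r in range(nrec):
            c = ycat[r, t]
            liab[r, t] = rtnorm(mean[r, t], s, cat_lo[t, c], cat_hi[t, c], rng)


@njit(cache=True)
def location_sweep(
    e, X, b, u, m,
    rec_animal, rec_dam,
    an_ptr, an_idx, dam_ptr, dam_idx,
    ai_indptr, ai_indices, ai_data,
    Suinv, sigma_m2, sigma_e2,
    Sxx, use_maternal, rng,
):
    """One Gibbs sweep over all location effects, single site.

    ``e`` holds the current residuals (liability minus full linear
    predictor) and is updated in place as effects move.  Fixed effects get
    flat priors; genetic effects get the pedigree prior via the sparse
    A-inverse and the current (co)variance components.
    """
    nrec, T = e.shape
    p = X.shape[1]
    n = u.shape[0]

    # fixed effects
    for t in range(T):
        ve = sigma_e2[t]
        for j in range(p):
            rhs = 0.0
            for r in range(nrec):
                rhs += X[r, j] * e[r, t]
            rhs = rhs / ve + Sxx[j] * b[t, j] / ve
            prec = Sxx[j] / ve
            new = rhs / prec + rng.standard_normal() / math.sqrt(prec)
            delta = new - b[t, j]
            b[t, j] = new
            for r in range(nrec):
                e[r, t] -= X[r, j] * delta

    # direct genetic effects: block update per animal over all traits (the
    # T-dimensional joint draw keeps mixing healthy when the genetic
    # correlations are near the boundary)
    w = np.zeros(T)
    rhs = np.zeros(T)
    P = np.zeros((T, T))
    for i in range(n):
        aii = 0.0
        for s in range(T):
            w[s] = 0.0
        for k in range(ai_indptr[i], ai_indptr[i + 1]):
            j = ai_indices[k]
            v = ai_data[k]
            if j == i:
                aii += v
            for s in range(T):
                w[s] += v * u[j, s]
        n_i = an_ptr[i + 1] - an_ptr[i]
        for t in range(T):
            for s in range(T):
                P[t, s] = aii * Suinv[t, s]
            P[t, t] += n_i / sigma_e2[t]
            acc = 0.0
            for k in range(an_ptr[i], an_ptr[i + 1]):
                acc += e[an_idx[k], t] + u[i, t]
            rhs[t] = acc / sigma_e2[t]
            for s in range(T):
                rhs[t] -= Suinv[t, s] * (w[s] - aii * u[i, s])
        # in-place Cholesky P = L L^T (T is tiny: 1..4)
        for a in range(T):
            for bb in range(a, T):
                s_ = P[bb, a]
                for k2 in range(a):
                    s_ -= P[a, k2] * P[bb, k2]
                if a == bb:
                    P[a, a] = math.sqrt(s_)
                else:
                    P[bb, a] = s_ / P[a, a]
        # mean = P^-1 rhs via forward/back substitution
        for a in range(T):
            s_ = rhs[a]
            for k2 in range(a):
                s_ -= P[a, k2] * w[k2]
            w[a] = s_ / P[a, a]
        # solve L^T x = v + z so that x ~ N(P^-1 rhs, P^-1)
        for a in range(T - 1, -1, -1):
            s_ = w[a] + rng.standard_normal()
            for k2 in range(a + 1, T):
                s_ -= P[k2, a] * rhs[k2]
            rhs[a] = s_ / P[a, a]
        for t in range(T):
            new = rhs[t]
            delta = new - u[i, t]
            u[i, t] = new
            for k in range(an_ptr[i], an_ptr[i + 1]):
                e[an_idx[k], t] -= delta

    # maternal genetic effects (diagonal maternal covariance)
    if use_maternal:
        for i in range(n):
            aii = 0.0
            for s in range(T):
                w[s] = 0.0
            for k in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[k]
                v = ai_data[k]
                if j == i:
                    aii += v
                for s in range(T):
                    w[s] += v * m[j, s]
            for t in range(T):
                ve = sigma_e2[t]
                vm = sigma_m2[t]
                prec = aii / vm
                rhs = -(w[t] - aii * m[i, t]) / vm
                for k in range(dam_ptr[i], dam_ptr[i + 1]):
                    r = dam_idx[k]
                    rhs += (e[r, t] + m[i, t]) / ve
                    prec += 1.0 / ve
                new = rhs / prec + rng.standard_normal() / math.sqrt(prec)
                delta = new - m[i, t]
                m[i, t] = new
                for k in range(dam_ptr[i], dam_ptr[i + 1]):
                    e[dam_idx[k], t] -= delta


@njit(cache=True)
def location_sweep_um(
    e, X, b, u, m,
    an_ptr, an_idx, dam_ptr, dam_idx,
    ai_indptr, ai_indices, ai_data,
    G0inv, sigma_e2,
    Sxx, rng,
):
    """Single-trait sweep with a direct-maternal covariance.

    The stacked per-animal effect (u_i, m_i) has prior N(0, A (x) G0) with
    G0 the 2x2 direct-maternal covariance; ``G0inv`` couples the two
    single-site updates.
    """
    nrec = e.shape[0]
    p = X.shape[1]
    n = u.shape[0]
    ve = sigma_e2[0]

    for j in range(p):
        rhs = 0.0
        for r in range(nrec):
            rhs += X[r, j] * e[r, 0]
        rhs = rhs / ve + Sxx[j] * b[0, j] / ve
        prec = Sxx[j] / ve
        new = rhs / prec + rng.standard_normal() / math.sqrt(prec)
        delta = new - b[0, j]
        b[0, j] = new
        for r in range(nrec):
            e[r, 0] -= X[r, j] * delta

    for i in range(n):
        aii = 0.0
        wu = 0.0
        wm = 0.0
        for k in range(ai_indptr[i], ai_indptr[i + 1]):
            j = ai_indices[k]
            v = ai_data[k]
            if j == i:
                aii += v
            wu += v * u[j, 0]
            wm += v * m[j, 0]
        # direct effect
        prec = aii * G0inv[0, 0]
        rhs = -(G0inv[0, 0] * (wu - aii * u[i, 0]) + G0inv[0, 1] * wm)
        for k in range(an_ptr[i], an_ptr[i + 1]):
            r = an_idx[k]
            rhs += (e[r, 0] + u[i, 0]) / ve
            prec += 1.0 / ve
        new = rhs / prec + rng.standard_normal() / math.sqrt(prec)
        delta = new - u[i, 0]
        u[i, 0] = new
        wu += aii * delta
        for k in range(an_ptr[i], an_ptr[i + 1]):
            e[an_idx[k], 0] -= delta
        # maternal effect
        prec = aii * G0inv[1, 1]
        rhs = -(G0inv[1, 1] * (wm - aii * m[i, 0]) + G0inv[0, 1] * wu)
        for k in range(dam_ptr[i], dam_ptr[i + 1]):
            r = dam_idx[k]
            rhs += (e[r, 0] + m[i, 0]) / ve
            prec += 1.0 / ve
        new = rhs / prec + rng.standard_normal() / math.sqrt(prec)
        delta = new - m[i, 0]
        m[i, 0] = new
        for k in range(dam_ptr[i], dam_ptr[i + 1]):
            e[dam_idx[k], 0] -= delta
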