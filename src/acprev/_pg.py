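"""Polya-Gamma random variates and the Gibbs kernel for random-intercept logit models.

The Bernoulli-logit likelihood with Gaussian random effects admits an exact
Gibbs sampler once each observation is augmented with a latent
``omega_i ~ PG(1, psi_i)`` (Polson, Scott & Windle augmentation): conditional
on the omegas every location parameter is Gaussian, and conditional on the
effects each omega is again Polya-Gamma.  No package in the target
environment provides PG variates, so the sampler is implemented here with
Devroye's alternating-series method for ``J*(1, z)`` (``PG(1, z) =
J*(1, z/2) / 4``), jit-compiled with numba.  The whole Gibbs sweep also lives
in this module so the per-observation loops run at native speed.

Randomness uses numba's internal np.random state, seeded inside the jitted
code; a fixed seed therefore gives bit-identical chains across runs.
"""

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # series/exponential switch point of Devroye's method


@njit(cache=True)
def _a_coef(n, x):
    # n-th term of the alternating series for the J*(1, 0) density at x
    np5 = n + 0.5
    if x <= _TRUNC:
        return math.pi * np5 * (2.0 / (math.pi * x)) ** 1.5 * math.exp(-2.0 * np5 * np5 / x)
    return math.pi * np5 * math.exp(-np5 * np5 * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _mass_texpon(z):
    # probability that the proposal comes from the exponential right tail
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    sqrt_inv_t = math.sqrt(1.0 / _TRUNC)
    b = sqrt_inv_t * (_TRUNC * z - 1.0)
    a = -sqrt_inv_t * (_TRUNC * z + 1.0)
    x0 = math.log(fz) + fz * _TRUNC
    cb = _norm_cdf(b)
    ca = _norm_cdf(a)
    xb = 0.0 if cb <= 0.0 else math.exp(x0 - z + math.log(cb))
    xa = 0.0 if ca <= 0.0 else math.exp(x0 + z + math.log(ca))
    qdivp = 4.0 / math.pi * (xb + xa)
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    # inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC]
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection from truncated inverse-chi-square
        while True:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
        return x
    return x


@njit(cache=True)
def pg_draw(c):
    """One draw from PG(1, c)."""
    z = abs(c) * 0.5
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    while True:
        if np.random.random() < _mass_texpon(z):
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def pg_draw_vec(c, out):
    for i in range(c.shape[0]):
        out[i] = pg_draw(c[i])


@njit(cache=True)
def gibbs_logit_ranef(
    y,            # float64[n] of 0/1 outcomes
    mem,          # int64[K, n] unit index of obs i at random level k
    n_units,      # int64[K]
    free_level,   # bool[K]: False -> variance fixed at 0, effects stay 0
    beta0_prior_var,
    ig_shape,
    ig_rate,
    burn_in,
    n_keep,
    thin,
    seed,
):
    """Gibbs sampler for logit P(y=1) = beta0 + sum_k eff_k[mem_k].

    Priors: beta0 ~ N(0, beta0_prior_var); eff_k[j] ~ N(0, sig2_k);
    sig2_k ~ InvGamma(ig_shape, ig_rate).  Returns (beta0 draws,
    sig2 draws [n_keep, K], effect draws [n_keep, total_units] with
    levels concatenated in order).
    """
    np.random.seed(seed)
    n = y.shape[0]
    k_levels = mem.shape[0]

    offsets = np.zeros(k_levels + 1, dtype=np.int64)
    for k in range(k_levels):
        offsets[k + 1] = offsets[k] + n_units[k]
    total_units = offsets[k_levels]

    kappa = y - 0.5
    beta0 = 0.0
    eff = np.zeros(total_units)
    sig2 = np.ones(k_levels)
    psi = np.zeros(n)
    omega = np.zeros(n)
    for i in range(n):
        psi[i] = beta0

    out_beta0 = np.empty(n_keep)
    out_sig2 = np.empty((n_keep, k_levels))
    out_eff = np.empty((n_keep, total_units))

    n_iter = burn_in + n_keep * thin
    kept = 0
    for it in range(n_iter):
        # omega | psi
        for i in range(n):
            omega[i] = pg_draw(psi[i])

        # beta0 | rest
        prec = 1.0 / beta0_prior_var
        m = 0.0
        for i in range(n):
            prec += omega[i]
            m += kappa[i] - omega[i] * (psi[i] - beta0)
        new_beta0 = m / prec + np.random.standard_normal() / math.sqrt(prec)
        shift = new_beta0 - beta0
        beta0 = new_beta0
        for i in range(n):
            psi[i] += shift

        # random effects level by level
        for k in range(k_levels):
            if not free_level[k]:
                continue
            off = offsets[k]
            nk = n_units[k]
            prec_u = np.full(nk, 1.0 / sig2[k])
            m_u = np.zeros(nk)
            for i in range(n):
                j = mem[k, i]
                e = eff[off + j]
                prec_u[j] += omega[i]
                m_u[j] += kappa[i] - omega[i] * (psi[i] - e)
            ss = 0.0
            for j in range(nk):
                new_e = m_u[j] / prec_u[j] + np.random.standard_normal() / math.sqrt(prec_u[j])
                ss += new_e * new_e
                m_u[j] = new_e  # reuse as delta store
            for i in range(n):
                j = mem[k, i]
                psi[i] += m_u[j] - eff[off + j]
            for j in range(nk):
                eff[off + j] = m_u[j]

            # translation sweep (ASIS): the likelihood is invariant under
            # beta0 += c, eff_k -= c, so c has a Gaussian conditional from the
            # priors alone; sampling it decouples beta0 from the level mean
            # and fixes the otherwise slow intercept mixing.
            sum_e = 0.0
            for j in range(nk):
                sum_e += eff[off + j]
            prec_c = nk / sig2[k] + 1.0 / beta0_prior_var
            mean_c = (sum_e / sig2[k] - beta0 / beta0_prior_var) / prec_c
            c = mean_c + np.random.standard_normal() / math.sqrt(prec_c)
            beta0 += c
            ss = 0.0
            for j in range(nk):
                eff[off + j] -= c
                ss += eff[off + j] * eff[off + j]

            # sig2_k | effects
            a_post = ig_shape + 0.5 * nk
            b_post = ig_rate + 0.5 * ss
            sig2[k] = b_post / np.random.gamma(a_post, 1.0)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_beta0[kept] = beta0
            for k in range(k_levels):
                out_sig2[kept, k] = sig2[k]
            for j in range(total_units):
                out_eff[kept, j] = eff[j]
            kept += 1

    return out_beta0, out_sig2, out_eff
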