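"""JIT-compiled slice-within-Gibbs kernels for the NB and ZINB fits.

These implement exactly the sampling scheme of
:func:`clademix.model.slice_within_gibbs` (univariate stepping-out +
shrinkage slice updates in a fixed sweep order), specialized to the two
posteriors the classifier visits thousands of times per sample. Counts are
passed collapsed to unique values ``u`` with multiplicities ``w``; additive
constants of the likelihood are dropped.

Sweep order and priors match the public fit functions: NB step samples
(lambda, alpha) with a flat bounded lambda and lognormal(0, 2^2) alpha;
ZINB step samples (lambda, alpha, pi) with a lognormal informed prior on
alpha (or alpha held fixed) and uniform pi.
"""

import math

import numpy as np
from numba import njit

_MAX_STEPOUT = 20


@njit(cache=True)
def _nb_ll(u, w, n, S, lam, alpha):
    """Weighted NB log likelihood up to a constant (Poisson limit at tiny alpha)."""
    if alpha < 1e-12:
        return S * math.log(lam) - n * lam
    r = 1.0 / alpha
    tot = -n * math.lgamma(r) + n * r * math.log(r / (r + lam)) + S * math.log(lam / (r + lam))
    for i in range(u.size):
        tot += w[i] * math.lgamma(u[i] + r)
    return tot


@njit(cache=True)
def _zinb_ll(u, w, lam, alpha, pi):
    """Weighted ZINB log likelihood up to a constant."""
    if alpha < 1e-12:
        nb0 = -lam
    else:
        r = 1.0 / alpha
        nb0 = r * math.log(r / (r + lam))
    w0 = w[0] if u[0] == 0 else 0.0
    n_pos = 0.0
    S_pos = 0.0
    start = 1 if u[0] == 0 else 0
    for i in range(start, u.size):
        n_pos += w[i]
        S_pos += w[i] * u[i]
    if pi >= 1.0:
        return 0.0 if n_pos == 0.0 else -np.inf
    log1mpi = math.log1p(-pi)
    if w0 > 0.0:
        if pi > 0.0:
            a = math.log(pi)
            b = log1mpi + nb0
            hi = a if a > b else b
            zero = w0 * (hi + math.log(math.exp(a - hi) + math.exp(b - hi)))
        else:
            zero = w0 * (log1mpi + nb0)
    else:
        zero = 0.0
    if n_pos == 0.0:
        return zero
    if alpha < 1e-12:
        pos = S_pos * math.log(lam) - n_pos * lam
    else:
        r = 1.0 / alpha
        pos = (
            -n_pos * math.lgamma(r)
            + n_pos * r * math.log(r / (r + lam))
            + S_pos * math.log(lam / (r + lam))
        )
        for i in range(start, u.size):
            pos += w[i] * math.lgamma(u[i] + r)
    return zero + n_pos * log1mpi + pos


@njit(cache=True)
def _nb_target(u, w, n, S, lam, alpha):
    la = math.log(alpha)
    return _nb_ll(u, w, n, S, lam, alpha) - la - la * la / 8.0


@njit(cache=True)
def _zinb_target(u, w, lam, alpha, pi, a_mu, a_sigma, fixed_alpha):
    ll = _zinb_ll(u, w, lam, alpha, pi)
    if fixed_alpha or a_sigma <= 0.0:  # point mass or flat prior: no density term
        return ll
    z = (math.log(alpha) - a_mu) / a_sigma
    return ll - math.log(alpha) - 0.5 * z * z


@njit(cache=True)
def _slice_nb_coord(u, w, n, S, coord, x0, other, fx0, width, lo, hi):
    """One slice update of NB coordinate ``coord`` (0=lambda, 1=alpha)."""
    log_y = fx0 + math.log(np.random.random())
    uu = np.random.random()
    left = x0 - width * uu
    right = left + width
    j = int(math.floor(_MAX_STEPOUT * np.random.random()))
    k = _MAX_STEPOUT - 1 - j
    while j > 0 and left > lo:
        f = _nb_target(u, w, n, S, left, other) if coord == 0 else _nb_target(u, w, n, S, other, left)
        if f <= log_y:
            break
        left -= width
        j -= 1
    while k > 0 and right < hi:
        f = _nb_target(u, w, n, S, right, other) if coord == 0 else _nb_target(u, w, n, S, other, right)
        if f <= log_y:
            break
        right += width
        k -= 1
    if left < lo:
        left = lo
    if right > hi:
        right = hi
    while True:
        x1 = left + np.random.random() * (right - left)
        f = _nb_target(u, w, n, S, x1, other) if coord == 0 else _nb_target(u, w, n, S, other, x1)
        if f > log_y:
            return x1, f
        if x1 < x0:
            left = x1
        else:
            right = x1
        if right - left < 1e-15:
            return x0, fx0


@njit(cache=True)
def gibbs_nb(u, w, n_steps, burn, seed, lam_lo, lam_hi, a_lo, a_hi,
             lam0, a0, width_lam, width_a):
    """Slice-within-Gibbs chain for the NB posterior; returns (kept, 2) draws."""
    np.random.seed(seed)
    n = 0.0
    S = 0.0
    for i in range(u.size):
        n += w[i]
        S += w[i] * u[i]
    lam = lam0
    alpha = a0
    fx = _nb_target(u, w, n, S, lam, alpha)
    out = np.empty((n_steps - burn, 2))
    for step in range(n_steps):
        lam, fx = _slice_nb_coord(u, w, n, S, 0, lam, alpha, fx, width_lam, lam_lo, lam_hi)
        alpha, fx = _slice_nb_coord(u, w, n, S, 1, alpha, lam, fx, width_a, a_lo, a_hi)
        if step >= burn:
            out[step - burn, 0] = lam
            out[step - burn, 1] = alpha
    return out


@njit(cache=True)
def _slice_zinb_coord(u, w, coord, x0, lam, alpha, pi, fx0, width, lo, hi,
                      a_mu, a_sigma, fixed_alpha):
    """One slice update of ZINB coordinate ``coord`` (0=lambda, 1=alpha, 2=pi)."""
    log_y = fx0 + math.log(np.random.random())
    uu = np.random.random()
    left = x0 - width * uu
    right = left + width
    j = int(math.floor(_MAX_STEPOUT * np.random.random()))
    k = _MAX_STEPOUT - 1 - j

    def _eval(v):
        if coord == 0:
            return _zinb_target(u, w, v, alpha, pi, a_mu, a_sigma, fixed_alpha)
        elif coord == 1:
            return _zinb_target(u, w, lam, v, pi, a_mu, a_sigma, fixed_alpha)
        return _zinb_target(u, w, lam, alpha, v, a_mu, a_sigma, fixed_alpha)

    while j > 0 and left > lo and _eval(left) > log_y:
        left -= width
        j -= 1
    while k > 0 and right < hi and _eval(right) > log_y:
        right += width
        k -= 1
    if left < lo:
        left = lo
    if right > hi:
        right = hi
    while True:
        x1 = left + np.random.random() * (right - left)
        f = _eval(x1)
        if f > log_y:
            return x1, f
        if x1 < x0:
            left = x1
        else:
            right = x1
        if right - left < 1e-15:
            return x0, fx0


@njit(cache=True)
def gibbs_zinb(u, w, n_steps, burn, seed, lam_lo, lam_hi, a_lo, a_hi,
               lam0, a0, pi0, width_lam, width_a, width_pi,
               a_mu, a_sigma, fixed_alpha):
    """Slice-within-Gibbs chain for the ZINB posterior; returns (kept, 3) draws.

    With ``fixed_alpha`` the alpha coordinate is pinned at ``a0`` (point-mass
    prior) and only (lambda, pi) are sampled.
    """
    np.random.seed(seed)
    lam = lam0
    alpha = a0
    pi = pi0
    fx = _zinb_target(u, w, lam, alpha, pi, a_mu, a_sigma, fixed_alpha)
    out = np.empty((n_steps - burn, 3))
    for step in range(n_steps):
        lam, fx = _slice_zinb_coord(u, w, 0, lam, lam, alpha, pi, fx, width_lam,
                                    lam_lo, lam_hi, a_mu, a_sigma, fixed_alpha)
        if not fixed_alpha:
            alpha, fx = _slice_zinb_coord(u, w, 1, alpha, lam, alpha, pi, fx, width_a,
                                          a_lo, a_hi, a_mu, a_sigma, fixed_alpha)
        pi, fx = _slice_zinb_coord(u, w, 2, pi, lam, alpha, pi, fx, width_pi,
                                   0.0, 1.0, a_mu, a_sigma, fixed_alpha)
        if step >= burn:
            out[step - burn, 0] = lam
            out[step - burn, 1] = alpha
            out[step - burn, 2] = pi
    return out
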