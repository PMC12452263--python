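"""Count distributions and posterior sampling primitives.

The classifier models read depth at clade-informative positions with a
negative binomial (NB) and a zero-inflated negative binomial (ZINB).
Parameterization used throughout: mean ``lambda`` and overdispersion
``alpha``, so that ``Var[X] = lambda * (1 + alpha * lambda)``. ``alpha -> 0``
recovers the Poisson distribution (the NB "size" is ``1/alpha``).

The ZINB is the two-component mixture

    P(X = x) = pi * 1[x == 0] + (1 - pi) * NB(x; lambda, alpha)

where ``pi`` is the proportion of systematic zeros. When classifying a
metagenome, ``pi`` for a clade is the estimated fraction of that clade's
marker alleles that are systematically absent from the sample, i.e. its
divergence from the nearest database clade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NBParams",
    "ZINBParams",
    "nb_logpmf",
    "zinb_logpmf",
    "slice_within_gibbs",
    "hpd_interval",
]

# below this, the NB is numerically indistinguishable from Poisson and the
# gammaln route loses precision, so we switch to the exact Poisson limit
_ALPHA_POISSON_LIMIT = 1e-12


@dataclass(frozen=True)
class NBParams:
    """Negative binomial with mean `lam` and variance ``lam*(1+alpha*lam)``."""

    lam: float
    alpha: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam) or self.lam <= 0:
            raise ValueError(f"lambda must be positive and finite, got {self.lam}")
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")

    @property
    def mean(self) -> float:
        return self.lam

    @property
    def variance(self) -> float:
        return self.lam * (1.0 + self.alpha * self.lam)


@dataclass(frozen=True)
class ZINBParams:
    """ZINB with NB component (`lam_cs`, `alpha_cs`) and zero-inflation `pi`."""

    lam_cs: float
    alpha_cs: float
    pi: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam_cs) or self.lam_cs <= 0:
            raise ValueError(f"lambda must be positive and finite, got {self.lam_cs}")
        if not np.isfinite(self.alpha_cs) or self.alpha_cs < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha_cs}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must lie in [0, 1], got {self.pi}")


def nb_logpmf(x, lam: float, alpha: float):
    """Log pmf of the NB distribution (Poisson limit at alpha ~ 0).

    Parameters
    ----------
    x
        Non-negative integer count or array of counts.
    lam
        Expected count (> 0).
    alpha
        Overdispersion (>= 0); variance is ``lam * (1 + alpha * lam)``.
    """
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if lam <= 0 or alpha < 0 or not np.isfinite(lam) or not np.isfinite(alpha):
        raise ValueError(f"invalid NB parameters lam={lam}, alpha={alpha}")
    if alpha < _ALPHA_POISSON_LIMIT:
        out = x * np.log(lam) - lam - gammaln(x + 1.0)
    else:
        r = 1.0 / alpha
        out = (
            gammaln(x + r)
            - gammaln(r)
            - gammaln(x + 1.0)
            + r * np.log(r / (r + lam))
            + x * np.log(lam / (r + lam))
        )
    return out if out.shape else float(out)


def zinb_logpmf(x, lam: float, alpha: float, pi: float):
    """Log pmf of the zero-inflated NB: ``pi*1[x=0] + (1-pi)*NB(x)``."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must lie in [0, 1], got {pi}")
    x = np.asarray(x)
    nb = nb_logpmf(x, lam, alpha)
    if pi == 0.0:
        return nb if np.ndim(nb) else float(nb)
    with np.errstate(divide="ignore"):
        log1mpi = np.log1p(-pi)
    body = log1mpi + nb
    if pi == 1.0:
        out = np.where(x == 0, 0.0, -np.inf)
    else:
        out = np.where(x == 0, np.logaddexp(np.log(pi), body), body)
    return out if out.shape else float(out)


def _slice_update(
    logf, x0: float, fx0: float, width: float, lo: float, hi: float, rng: np.random.Generator,
    max_steps: int = 20,
):
    """One univariate slice-sampling update (stepping-out + shrinkage).

    ``logf`` is the conditional log density (up to a constant) of the
    coordinate being updated; ``(lo, hi)`` bound its support.
    """
    log_y = fx0 + np.log(rng.random())
    # stepping out
    u = rng.random()
    left = x0 - width * u
    right = left + width
    j = int(np.floor(max_steps * rng.random()))
    k = max_steps - 1 - j
    while j > 0 and left > lo and logf(left) > log_y:
        left -= width
        j -= 1
    while k > 0 and right < hi and logf(right) > log_y:
        right += width
        k -= 1
    left = max(left, lo)
    right = min(right, hi)
    # shrinkage
    while True:
        x1 = left + rng.random() * (right - left)
        fx1 = logf(x1)
        if fx1 > log_y:
            return x1, fx1
        if x1 < x0:
            left = x1
        else:
            right = x1
        if right - left < 1e-15:  # numerically degenerate slice
            return x0, fx0


def slice_within_gibbs(
    log_target,
    init,
    widths,
    bounds,
    n_steps: int = 10_000,
    burn_frac: float = 0.10,
    seed=None,
):
    """Sample from ``log_target`` by univariate slice updates within Gibbs sweeps.

    Each sweep updates the coordinates in fixed order with Neal's
    stepping-out/shrinkage slice sampler. Deterministic given ``seed``.

    Parameters
    ----------
    log_target
        Callable mapping a parameter vector (1-D array) to a finite or -inf
        log density (up to an additive constant).
    init
        Starting point; ``log_target(init)`` must be finite.
    widths
        Initial slice width per coordinate (posterior-scale guesses).
    bounds
        Sequence of ``(lo, hi)`` support bounds per coordinate.
    n_steps
        Total sweeps; the first ``burn_frac`` fraction is discarded.
    seed
        Integer seed, ``SeedSequence`` or ``Generator``.

    Returns
    -------
    ndarray of shape ``(n_kept, n_dim)`` with the post-burn-in draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(init, dtype=float).copy()
    widths = np.asarray(widths, dtype=float)
    ndim = x.size
    fx = log_target(x)
    if not np.isfinite(fx):
        raise ValueError("log_target is not finite at the initial point")
    n_burn = int(np.floor(burn_frac * n_steps))
    draws = np.empty((n_steps - n_burn, ndim))
    for step in range(n_steps):
        for d in range(ndim):
            lo, hi = bounds[d]

            def logf(v, _d=d):
                x[_d] = v
                return log_target(x)

            x0 = x[d]
            x[d], fx = _slice_update(logf, x0, fx, widths[d], lo, hi, rng)
        if step >= n_burn:
            draws[step - n_burn] = x
    return draws


def hpd_interval(draws, mass: float = 0.95):
    """Shortest (highest-posterior-density) interval from MCMC draws.

    Scans every contiguous window of sorted draws spanning
    ``floor(mass * n)`` index offsets and returns the narrowest one
    (leftmost on ties). ``mass=1`` returns ``(min, max)``.
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    n = draws.size
    if n < 10:
        raise ValueError("need at least 10 draws for an HPD interval")
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must lie in (0, 1], got {mass}")
    k = int(np.floor(mass * n))
    if k >= n:
        return float(draws[0]), float(draws[-1])
    widths = draws[k:] - draws[: n - k]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + k])
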