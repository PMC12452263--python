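"""Clade abundance and divergence inference from metagenomic allele counts.

For each clade the classifier runs a two-step fit at the clade's informative
positions. Step one models the total read depth (all alleles) with a
negative binomial, capturing the sample's depth and overdispersion. Step two
models the depth supporting only the clade-specific allele with a
zero-inflated negative binomial whose overdispersion prior is moment-matched
to the step-one posterior: because both counts are drawn from the same
sequencing process at the same loci, the step-one dispersion constrains the
otherwise weakly identified zero-inflation ``pi`` at low coverage. ``pi``
estimates the fraction of the clade's markers that are systematically
absent — the divergence of a novel strain from that clade — and the ratio
of expected depths gives the clade's relative abundance.

Each clade is modeled independently; frequencies over a non-overlapping
clade set need not sum to one, and the shortfall is the sample's estimated
novel (unclassified) fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .clades import ReferenceDatabase
from .model import hpd_interval, nb_logpmf

__all__ = [
    "NoCoverageError",
    "LogNormalPrior",
    "PointMassPrior",
    "FlatPrior",
    "SampleCounts",
    "InformativeCounts",
    "NBFit",
    "ZINBFit",
    "CladeFit",
    "ClassifyParams",
    "ClassificationResult",
    "extract_counts",
    "fit_nb",
    "fit_zinb",
    "fit_nb_mle",
    "fit_zinb_mle",
    "detect",
    "clade_frequency",
    "classify_sample",
]

_ALPHA_LO, _ALPHA_HI = 1e-4, 1e3
_LAM_LO = 1e-3


class NoCoverageError(ValueError):
    """Raised when a fit is requested on all-zero counts."""


# --- priors over the overdispersion ---------------------------------------

@dataclass(frozen=True)
class LogNormalPrior:
    mu: float
    sigma: float

    @classmethod
    def from_draws(cls, draws, sigma_floor: float = 0.05) -> "LogNormalPrior":
        """Moment-match a lognormal to posterior draws (the informed prior)."""
        logd = np.log(np.clip(np.asarray(draws, dtype=float), _ALPHA_LO, None))
        return cls(mu=float(np.mean(logd)), sigma=float(max(np.std(logd), sigma_floor)))

    def logpdf(self, alpha: float) -> float:
        if alpha <= 0:
            return -np.inf
        z = (np.log(alpha) - self.mu) / self.sigma
        return -np.log(alpha) - 0.5 * z * z


@dataclass(frozen=True)
class PointMassPrior:
    value: float


@dataclass(frozen=True)
class FlatPrior:
    lo: float = _ALPHA_LO
    hi: float = _ALPHA_HI

    def logpdf(self, alpha: float) -> float:
        return 0.0 if self.lo <= alpha <= self.hi else -np.inf


# --- count containers -----------------------------------------------------

class SampleCounts:
    """Per-position allele counts for one metagenomic sample.

    ``positions`` are sorted 0-based reference coordinates; ``counts`` is a
    (P, 4) array of total read counts per allele (A, C, G, T).
    """

    def __init__(self, positions, counts, sample_id: str = "sample"):
        self.positions = np.asarray(positions, dtype=np.int64)
        self.counts = np.asarray(counts)
        self.sample_id = sample_id
        if self.counts.shape != (self.positions.size, 4):
            raise ValueError("counts must have shape (n_positions, 4)")
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.counts = self.counts[order]

    @classmethod
    def from_tsv(cls, path) -> "SampleCounts":
        df = pd.read_csv(path, sep="\t", comment="#")
        id_col = "sample_id" if "sample_id" in df.columns else "genome_id"
        fwd = df[["A_fwd", "C_fwd", "G_fwd", "T_fwd"]].to_numpy()
        rev_cols = ["A_rev", "C_rev", "G_rev", "T_rev"]
        total = fwd + (df[rev_cols].to_numpy() if set(rev_cols) <= set(df.columns) else 0)
        return cls(df["pos"].to_numpy(dtype=np.int64) - 1, total,
                   sample_id=str(df[id_col].iloc[0]) if len(df) else "sample")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# clademix sample counts; pos is 1-based\n")
            fh.write("sample_id\tpos\tA_fwd\tC_fwd\tG_fwd\tT_fwd\n")
            for p, row in zip(self.positions, self.counts):
                fh.write(f"{self.sample_id}\t{p + 1}\t" + "\t".join(str(int(c)) for c in row) + "\n")


@dataclass(frozen=True)
class InformativeCounts:
    """Depths at one clade's informative positions.

    ``x_all`` is the total depth (any allele); ``x_cs`` is the depth
    supporting the clade-specific allele. Positions not covered by the
    sample appear with zeros — zeros carry signal here.
    """

    clade_id: str
    positions: np.ndarray
    x_all: np.ndarray
    x_cs: np.ndarray

    def __post_init__(self):
        if np.any(self.x_cs > self.x_all) or np.any(self.x_all < 0):
            raise ValueError("require 0 <= x_cs <= x_all")


def extract_counts(sample: SampleCounts, db: ReferenceDatabase, clade_id: str) -> InformativeCounts:
    """Align a sample's counts to one clade's marker positions."""
    clade = db.get(clade_id)
    pos = clade.positions()
    alleles = clade.alleles()
    idx = np.searchsorted(sample.positions, pos)
    idx = np.clip(idx, 0, max(sample.positions.size - 1, 0))
    if sample.positions.size:
        found = sample.positions[idx] == pos
    else:
        found = np.zeros(pos.size, dtype=bool)
    x_all = np.zeros(pos.size, dtype=np.int64)
    x_cs = np.zeros(pos.size, dtype=np.int64)
    if found.any():
        rows = sample.counts[idx[found]]
        x_all[found] = rows.sum(axis=1)
        x_cs[found] = rows[np.arange(rows.shape[0]), alleles[found]]
    return InformativeCounts(clade_id=clade_id, positions=pos, x_all=x_all, x_cs=x_cs)


# --- weighted likelihoods (counts collapsed to unique values) -------------

class _Weighted:
    """Counts collapsed to unique values with multiplicities.

    Read depths at marker positions take few distinct values, so the
    likelihood cost is O(#unique) per evaluation regardless of n.
    """

    def __init__(self, x):
        x = np.asarray(x, dtype=np.int64)
        self.u, self.w = np.unique(x, return_counts=True)
        self.w = self.w.astype(float)
        self.n = float(x.size)
        self.S = float(x.sum())
        self._gammaln_u1 = gammaln(self.u + 1.0)
        self.has_zero = self.u.size > 0 and self.u[0] == 0
        self.w0 = self.w[0] if self.has_zero else 0.0
        self.u_pos = self.u[1:] if self.has_zero else self.u
        self.w_pos = self.w[1:] if self.has_zero else self.w
        self._gammaln_pos = gammaln(self.u_pos + 1.0)
        self.S_pos = float((self.u_pos * self.w_pos).sum())
        self.n_pos = float(self.w_pos.sum())

    def nb_loglik(self, lam: float, alpha: float) -> float:
        if alpha < 1e-12:
            return float(self.S * np.log(lam) - self.n * lam - (self.w * self._gammaln_u1).sum())
        r = 1.0 / alpha
        return float(
            (self.w * gammaln(self.u + r)).sum()
            - self.n * gammaln(r)
            - (self.w * self._gammaln_u1).sum()
            + self.n * r * np.log(r / (r + lam))
            + self.S * np.log(lam / (r + lam))
        )

    def zinb_loglik(self, lam: float, alpha: float, pi: float) -> float:
        # NB log-probability of zero
        if alpha < 1e-12:
            nb0 = -lam
        else:
            r = 1.0 / alpha
            nb0 = r * np.log(r / (r + lam))
        if pi >= 1.0:
            return -np.inf if self.n_pos > 0 else float(self.w0 * 0.0)
        log1mpi = np.log1p(-pi)
        if self.has_zero:
            zero_term = self.w0 * (
                np.logaddexp(np.log(pi), log1mpi + nb0) if pi > 0 else log1mpi + nb0
            )
        else:
            zero_term = 0.0
        if self.n_pos == 0:
            return float(zero_term)
        if alpha < 1e-12:
            pos = (
                self.S_pos * np.log(lam) - self.n_pos * lam
                - (self.w_pos * self._gammaln_pos).sum()
            )
        else:
            r = 1.0 / alpha
            pos = (
                (self.w_pos * gammaln(self.u_pos + r)).sum()
                - self.n_pos * gammaln(r)
                - (self.w_pos * self._gammaln_pos).sum()
                + self.n_pos * r * np.log(r / (r + lam))
                + self.S_pos * np.log(lam / (r + lam))
            )
        return float(zero_term + self.n_pos * log1mpi + pos)


# --- fits ------------------------------------------------------------------

@dataclass
class NBFit:
    """Posterior (or Laplace-approximate) draws for the all-allele NB step."""

    draws: np.ndarray  # (n, 2): lam, alpha
    method: str = "bayes"
    mle: Optional[tuple] = None
    se: Optional[tuple] = None

    @property
    def lam_draws(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def alpha_draws(self) -> np.ndarray:
        return self.draws[:, 1]

    @property
    def lam_mean(self) -> float:
        return float(self.lam_draws.mean())


@dataclass
class ZINBFit:
    """Posterior draws for the clade-specific ZINB step."""

    draws: np.ndarray  # (n, 3): lam_cs, alpha_cs, pi
    method: str = "bayes"
    mle: Optional[tuple] = None
    se: Optional[tuple] = None

    @property
    def lam_draws(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def alpha_draws(self) -> np.ndarray:
        return self.draws[:, 1]

    @property
    def pi_draws(self) -> np.ndarray:
        return self.draws[:, 2]


def _as_int_seed(seed) -> int:
    """Normalize seed-like inputs (None, int, SeedSequence) to one int32."""
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31))
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))


def fit_nb(
    x_all,
    n_steps: int = 10_000,
    burn_frac: float = 0.10,
    seed=None,
    lambda_max: Optional[float] = None,
) -> NBFit:
    """Posterior over (lambda, alpha) for total depth at informative positions.

    Priors: lambda half-flat on (0, ``lambda_max``] (default 10x the maximum
    observed count), alpha lognormal(0, 2^2). Sampling is slice-within-Gibbs
    (stepping-out + shrinkage, fixed lambda -> alpha sweep order) via a
    compiled kernel; deterministic given ``seed``.
    """
    from ._gibbs import gibbs_nb

    x = np.asarray(x_all, dtype=np.int64)
    if x.size == 0 or not np.any(x > 0):
        raise NoCoverageError("no coverage: all-zero depth at informative positions")
    wx = _Weighted(x)
    lam_hi = lambda_max if lambda_max is not None else 10.0 * float(x.max()) + 10.0
    mean = float(x.mean())
    var = float(x.var())
    lam0 = float(np.clip(mean, _LAM_LO * 2, lam_hi * 0.9))
    alpha0 = float(np.clip((var - mean) / mean**2 if mean > 0 else 0.5, 0.05, _ALPHA_HI * 0.9))
    draws = gibbs_nb(
        wx.u.astype(np.float64), wx.w, int(n_steps), int(np.floor(burn_frac * n_steps)),
        _as_int_seed(seed), _LAM_LO, lam_hi, _ALPHA_LO, _ALPHA_HI,
        lam0, alpha0, max(mean, 1.0), 0.5,
    )
    return NBFit(draws=draws, method="bayes")


def fit_zinb(
    x_cs,
    alpha_prior,
    n_steps: int = 10_000,
    burn_frac: float = 0.10,
    seed=None,
    lambda_max: Optional[float] = None,
) -> ZINBFit:
    """Joint posterior over (lambda_cs, alpha_cs, pi) for marker-supporting depth.

    ``alpha_prior`` is the informed prior over the overdispersion, typically
    :meth:`LogNormalPrior.from_draws` of the step-one alpha posterior; a
    :class:`PointMassPrior` fixes alpha instead of sampling it (the sampler
    then visits only lambda and pi). ``pi`` has a uniform prior on [0, 1]
    and ``lambda_cs`` is half-flat. Sweep order lambda -> alpha -> pi.
    """
    from ._gibbs import gibbs_zinb

    x = np.asarray(x_cs, dtype=np.int64)
    if x.size == 0:
        raise ValueError("empty count vector")
    wx = _Weighted(x)
    xmax = float(x.max())
    lam_hi = lambda_max if lambda_max is not None else 10.0 * xmax + 10.0
    pos_mean = float(x[x > 0].mean()) if np.any(x > 0) else 0.5
    lam0 = float(np.clip(pos_mean, _LAM_LO * 2, lam_hi * 0.9))
    zero_frac = float((x == 0).mean())
    pi0 = float(np.clip(zero_frac * 0.5, 0.01, 0.95))
    burn = int(np.floor(burn_frac * n_steps))

    if isinstance(alpha_prior, PointMassPrior):
        a_fix = float(np.clip(alpha_prior.value, _ALPHA_LO, _ALPHA_HI))
        draws = gibbs_zinb(
            wx.u.astype(np.float64), wx.w, int(n_steps), burn, _as_int_seed(seed),
            _LAM_LO, lam_hi, _ALPHA_LO, _ALPHA_HI,
            lam0, a_fix, pi0, max(pos_mean, 1.0), 0.5, 0.25,
            0.0, 1.0, True,
        )
        return ZINBFit(draws=draws, method="bayes")
    if isinstance(alpha_prior, LogNormalPrior):
        a_mu, a_sigma = alpha_prior.mu, alpha_prior.sigma
        alpha0 = float(np.clip(np.exp(a_mu), 0.02, 10.0))
    elif isinstance(alpha_prior, FlatPrior):
        a_mu, a_sigma = 0.0, -1.0  # sentinel: kernel applies no alpha density
        alpha0 = 0.3
    else:
        raise TypeError(f"unsupported alpha prior: {alpha_prior!r}")
    draws = gibbs_zinb(
        wx.u.astype(np.float64), wx.w, int(n_steps), burn, _as_int_seed(seed),
        _LAM_LO, lam_hi, _ALPHA_LO, _ALPHA_HI,
        lam0, alpha0, pi0, max(pos_mean, 1.0), 0.5, 0.25,
        a_mu, a_sigma, False,
    )
    return ZINBFit(draws=draws, method="bayes")


# --- maximum-likelihood path ----------------------------------------------

def _laplace_draws(point, se, bounds, n=2000, seed=None):
    rng = np.random.default_rng(seed)
    point = np.asarray(point, dtype=float)
    se = np.asarray(se, dtype=float)
    draws = rng.normal(point, np.maximum(se, 1e-8), size=(n, point.size))
    for d, (lo, hi) in enumerate(bounds):
        draws[:, d] = np.clip(draws[:, d], lo, hi)
    return draws


def _numeric_se(negll, point, bounds):
    """SEs from the numerically differentiated observed information."""
    point = np.asarray(point, dtype=float)
    k = point.size
    h = np.maximum(1e-4, 1e-4 * np.abs(point))
    H = np.zeros((k, k))
    f0 = negll(point)
    for i in range(k):
        for j in range(i, k):
            pi_, pj = np.zeros(k), np.zeros(k)
            pi_[i] = h[i]
            pj[j] = h[j]
            if i == j:
                H[i, i] = (negll(point + pi_) - 2 * f0 + negll(point - pi_)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    negll(point + pi_ + pj) - negll(point + pi_ - pj)
                    - negll(point - pi_ + pj) + negll(point - pi_ - pj)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    se = np.where(np.isfinite(se) & (se > 0), se, 0.25 * (1 + np.abs(point)))
    return se


def fit_nb_mle(x_all, seed=None, n_draws: int = 2000) -> NBFit:
    """NB maximum likelihood with observed-information SEs.

    Also materializes Laplace-approximate draws so the downstream detection
    machinery treats both inference paths uniformly.
    """
    from scipy.optimize import minimize

    x = np.asarray(x_all, dtype=np.int64)
    if x.size == 0 or not np.any(x > 0):
        raise NoCoverageError("no coverage: all-zero depth at informative positions")
    wx = _Weighted(x)
    lam_hi = 10.0 * float(x.max()) + 10.0

    def negll(theta):
        lam, alpha = theta
        if not (_LAM_LO < lam <= lam_hi and _ALPHA_LO <= alpha <= _ALPHA_HI):
            return 1e12
        return -wx.nb_loglik(lam, alpha)

    mean = float(x.mean())
    var = float(x.var())
    a0 = float(np.clip((var - mean) / mean**2 if mean > 0 else 0.3, 0.01, 10.0))
    res = minimize(negll, [max(mean, 0.01), a0], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    point = res.x
    se = _numeric_se(negll, point, [(_LAM_LO, lam_hi), (_ALPHA_LO, _ALPHA_HI)])
    draws = _laplace_draws(point, se, [(_LAM_LO, lam_hi), (_ALPHA_LO, _ALPHA_HI)],
                           n=n_draws, seed=seed)
    return NBFit(draws=draws, method="mle", mle=tuple(point), se=tuple(se))


def fit_zinb_mle(x_cs, alpha_fixed: float, seed=None, n_draws: int = 2000,
                 n_restarts: int = 5) -> ZINBFit:
    """ZINB maximum likelihood over (lambda_cs, pi) with alpha fixed.

    Bounded Nelder-Mead from ``n_restarts`` starting points spread over pi.
    """
    from scipy.optimize import minimize

    x = np.asarray(x_cs, dtype=np.int64)
    if x.size == 0:
        raise ValueError("empty count vector")
    wx = _Weighted(x)
    xmax = float(x.max())
    lam_hi = 10.0 * xmax + 10.0
    a_fix = float(np.clip(alpha_fixed, _ALPHA_LO, _ALPHA_HI))

    def negll(theta):
        lam, pi = theta
        if not (_LAM_LO < lam <= lam_hi and 0.0 <= pi <= 1.0):
            return 1e12
        return -wx.zinb_loglik(lam, a_fix, pi)

    pos_mean = float(x[x > 0].mean()) if np.any(x > 0) else 0.5
    best = None
    for pi0 in np.linspace(0.05, 0.95, n_restarts):
        res = minimize(negll, [max(pos_mean, 0.01), pi0], method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    point = np.array([best.x[0], np.clip(best.x[1], 0.0, 1.0)])
    se = _numeric_se(negll, point, [(_LAM_LO, lam_hi), (0.0, 1.0)])
    d2 = _laplace_draws(point, se, [(_LAM_LO, lam_hi), (0.0, 1.0)], n=n_draws, seed=seed)
    draws = np.column_stack([d2[:, 0], np.full(len(d2), a_fix), d2[:, 1]])
    return ZINBFit(draws=draws, method="mle",
                   mle=(float(point[0]), a_fix, float(point[1])),
                   se=(float(se[0]), 0.0, float(se[1])))


# --- per-clade result -----------------------------------------------------

@dataclass
class CladeFit:
    """Per-clade classification outcome."""

    clade_id: str
    modeled: bool
    n_reads_cs: int
    nb: Optional[NBFit] = None
    zinb: Optional[ZINBFit] = None
    map_pi: float = np.nan
    pi_mean: float = np.nan
    hpd_pi: tuple = (np.nan, np.nan)
    frequency: float = 0.0
    detected: bool = False

    @property
    def hpd_width(self) -> float:
        return self.hpd_pi[1] - self.hpd_pi[0]


def map_estimate(draws, lo: float = 0.0, hi: float = 1.0, grid: int = 512) -> float:
    """MAP from draws: mode of a Silverman-bandwidth Gaussian KDE on a grid."""
    from scipy.stats import gaussian_kde

    draws = np.asarray(draws, dtype=float)
    if np.std(draws) < 1e-12:
        return float(draws[0])
    kde = gaussian_kde(draws, bw_method="silverman")
    xs = np.linspace(lo, hi, grid)
    return float(xs[np.argmax(kde(xs))])


def detect(fit: CladeFit, d: float = 0.35, p: float = 0.5, h: float = 0.1) -> bool:
    """Presence call: P(pi < d) >= p and the 95% HPD lower bound of pi < h."""
    if not fit.modeled or fit.zinb is None:
        return False
    pi = fit.zinb.pi_draws
    return bool(np.mean(pi < d) >= p and fit.hpd_pi[0] < h)


def clade_frequency(fit: CladeFit) -> float:
    """Relative abundance: mean(lambda_cs) / mean(lambda_all), clipped to [0, 1]."""
    if fit.nb is None or fit.zinb is None:
        raise ValueError("both fits are required for a frequency")
    lam_all = fit.nb.lam_mean
    lam_cs = float(fit.zinb.lam_draws.mean())
    return float(np.clip(lam_cs / lam_all, 0.0, 1.0))


@dataclass(frozen=True)
class ClassifyParams:
    """Classifier settings (defaults: -d 0.35 -p 0.5 -h 0.1, >10-read gate,
    10,000 Gibbs steps with 10% burn-in)."""

    d: float = 0.35
    p: float = 0.5
    h: float = 0.1
    min_reads: int = 10
    n_steps: int = 10_000
    burn_frac: float = 0.10
    hpd_mass: float = 0.95
    method: str = "bayes"  # or "mle"
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "d": self.d, "p": self.p, "h": self.h, "min_reads": self.min_reads,
            "n_steps": self.n_steps, "burn_frac": self.burn_frac,
            "hpd_mass": self.hpd_mass, "method": self.method, "seed": self.seed,
        }


@dataclass
class ClassificationResult:
    """All per-clade fits plus the composition over a non-overlapping clade set."""

    sample_id: str
    fits: list
    clade_set: list
    frequencies: np.ndarray
    normalized: bool
    unclassified_fraction: float
    params: ClassifyParams

    def get(self, clade_id: str) -> CladeFit:
        for f in self.fits:
            if f.clade_id == clade_id:
                return f
        raise KeyError(clade_id)

    def detected_clades(self) -> list:
        return [f.clade_id for f in self.fits if f.detected]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append({
                "clade_id": f.clade_id, "map_pi": f.map_pi, "pi_mean": f.pi_mean,
                "hpd_lo": f.hpd_pi[0], "hpd_hi": f.hpd_pi[1], "hpd_width": f.hpd_width,
                "frequency": f.frequency, "n_reads_cs": f.n_reads_cs,
                "detected": f.detected, "modeled": f.modeled,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# clademix classification; per-clade fits\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "params": self.params.to_dict(),
            "clade_set": list(self.clade_set),
            "frequencies": [float(v) for v in self.frequencies],
            "normalized": self.normalized,
            "unclassified_fraction": float(self.unclassified_fraction),
            "detected": self.detected_clades(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _fit_one_clade(counts: InformativeCounts, params: ClassifyParams, seed_pair) -> CladeFit:
    n_reads = int(counts.x_cs.sum())
    if n_reads <= params.min_reads or not np.any(counts.x_all > 0):
        return CladeFit(clade_id=counts.clade_id, modeled=False, n_reads_cs=n_reads)
    lam_hi = 10.0 * float(counts.x_all.max()) + 10.0
    if params.method == "mle":
        nb = fit_nb_mle(counts.x_all, seed=seed_pair[0])
        zinb = fit_zinb_mle(counts.x_cs, alpha_fixed=float(nb.mle[1]), seed=seed_pair[1])
    else:
        nb = fit_nb(counts.x_all, n_steps=params.n_steps, burn_frac=params.burn_frac,
                    seed=seed_pair[0])
        prior = LogNormalPrior.from_draws(nb.alpha_draws)
        zinb = fit_zinb(counts.x_cs, alpha_prior=prior, n_steps=params.n_steps,
                        burn_frac=params.burn_frac, seed=seed_pair[1], lambda_max=lam_hi)
    pi = zinb.pi_draws
    fit = CladeFit(
        clade_id=counts.clade_id, modeled=True, n_reads_cs=n_reads, nb=nb, zinb=zinb,
        map_pi=map_estimate(pi), pi_mean=float(pi.mean()),
        hpd_pi=hpd_interval(pi, mass=params.hpd_mass),
    )
    fit.frequency = clade_frequency(fit)
    fit.detected = detect(fit, d=params.d, p=params.p, h=params.h)
    return fit


def classify_sample(
    sample: SampleCounts,
    db: ReferenceDatabase,
    params: ClassifyParams = ClassifyParams(),
    clade_ids: Optional[Sequence[str]] = None,
    clade_set: Optional[Sequence[str]] = None,
) -> ClassificationResult:
    """Classify one metagenomic sample against a reference database.

    Every clade (or the subset ``clade_ids``) is fitted independently;
    clades with at most ``min_reads`` total marker-supporting reads are left
    unmodeled. The composition is reported over ``clade_set`` (default: the
    database's minimal, mutually disjoint clades): detected clades
    contribute their frequency, and if the total exceeds 1 the vector is
    rescaled to sum to 1 and flagged. Fully reproducible for a fixed seed —
    per-clade seeds fan out deterministically from ``params.seed`` by the
    clade's index in the database.
    """
    all_ids = db.clade_ids()
    wanted = set(all_ids if clade_ids is None else clade_ids)
    unknown = wanted - set(all_ids)
    if unknown:
        raise KeyError(f"clades not in database: {sorted(unknown)}")
    children = np.random.SeedSequence(params.seed).spawn(2 * len(all_ids))
    fits = []
    for i, cid in enumerate(all_ids):
        if cid not in wanted:
            continue
        counts = extract_counts(sample, db, cid)
        fits.append(_fit_one_clade(counts, params, (children[2 * i], children[2 * i + 1])))

    if clade_set is None:
        set_ids = [c.clade_id for c in db.minimal_clades() if c.clade_id in wanted]
    else:
        set_ids = list(clade_set)
        members = [db.get(cid).members for cid in set_ids]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[i] & members[j]:
                    raise ValueError(
                        f"clade set is not non-overlapping: {set_ids[i]} and {set_ids[j]} share genomes"
                    )
    by_id = {f.clade_id: f for f in fits}
    freqs = np.array([
        by_id[cid].frequency if cid in by_id and by_id[cid].detected else 0.0
        for cid in set_ids
    ])
    normalized = False
    total = freqs.sum()
    if total > 1.0:
        freqs = freqs / total
        normalized = True
        total = 1.0
    return ClassificationResult(
        sample_id=sample.sample_id,
        fits=fits,
        clade_set=set_ids,
        frequencies=freqs,
        normalized=normalized,
        unclassified_fraction=float(max(0.0, 1.0 - total)),
        params=params,
    )
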