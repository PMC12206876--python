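"""Gamma-Poisson shrinker (GPS / "MGPS") for drug-event pair counts.

Model: the observed count a for a drug-event pair is Poisson(lambda * E),
where E is the pair's expected count under independence and the relative
reporting rate lambda follows a two-component gamma mixture prior

    lambda ~ w * Gamma(alpha1, beta1) + (1 - w) * Gamma(alpha2, beta2)

(shape/rate parameterization).  The marginal of a is then a mixture of
negative binomials, which is maximized over the hyperparameters to fit the
prior ("empirical Bayes").  Conjugacy gives a posterior mixture of gammas
per pair, from which:

    EBGM   = exp(E[ln lambda | a])       (geometric-mean shrunk rate)
    EBGM05 = posterior 5th percentile of lambda

A brute-force quadrature oracle over the unnormalized posterior density is
included for verification; it never feeds the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import DegenerateSampleError
from .signal_engine import ContingencyTable

#: Canonical GPS starting point for the hyperparameter search.
DEFAULT_INIT_PARAMS = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class GpsPrior:
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")

    @property
    def geometric_mean(self) -> float:
        """exp(E[ln lambda]) under the prior."""
        g1 = special.digamma(self.alpha1) - math.log(self.beta1)
        g2 = special.digamma(self.alpha2) - math.log(self.beta2)
        return math.exp(self.w * g1 + (1.0 - self.w) * g2)


DEFAULT_INIT = GpsPrior(*DEFAULT_INIT_PARAMS)


@dataclass(frozen=True)
class FitResult:
    prior: GpsPrior
    converged: bool
    loglik: float
    n_tables: int


@dataclass(frozen=True)
class GpsPosterior:
    q: float        # posterior weight of component 1
    shape1: float
    rate1: float
    shape2: float
    rate2: float
    ebgm: float
    ebgm05: float


# ---------------------------------------------------------------------------
# marginal likelihood


def _as_counts(tables: Sequence[ContingencyTable]) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    return a, e


def _log_marginal_components(a: np.ndarray, e: np.ndarray, prior: GpsPrior,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Log negative-binomial marginal of each count under each component.

    With lambda ~ Gamma(alpha, beta) and a | lambda ~ Poisson(lambda*E),
    a ~ NB(alpha, p) with success probability p = beta / (beta + E).
    """
    p1 = prior.beta1 / (prior.beta1 + e)
    p2 = prior.beta2 / (prior.beta2 + e)
    return (stats.nbinom.logpmf(a, prior.alpha1, p1),
            stats.nbinom.logpmf(a, prior.alpha2, p2))


def log_marginal_likelihood(tables_or_counts, prior: GpsPrior) -> float:
    """Total log marginal likelihood of the counts under the mixture prior."""
    if isinstance(tables_or_counts, tuple):
        a, e = tables_or_counts
    else:
        a, e = _as_counts(tables_or_counts)
    l1, l2 = _log_marginal_components(a, e, prior)
    with np.errstate(divide="ignore"):
        terms = np.logaddexp(np.log(prior.w) + l1 if prior.w > 0 else -np.inf + l1,
                             np.log1p(-prior.w) + l2 if prior.w < 1 else -np.inf + l2)
    return float(np.sum(terms))


# ---------------------------------------------------------------------------
# prior fitting


def fit_prior(tables: Sequence[ContingencyTable] | tuple[np.ndarray, np.ndarray],
              init: GpsPrior = DEFAULT_INIT,
              fix_w: float | None = None,
              maxiter: int = 500) -> FitResult:
    """Maximize the mixture negative-binomial marginal over hyperparameters.

    The search runs in log-parameter space (logit space for w) so positivity
    and the [0,1] constraint hold by construction; deterministic given
    ``init``.  ``fix_w`` pins the mixture weight (e.g. 1.0 for a
    single-component fit).  ``maxiter=0`` returns ``init`` unchanged with
    ``converged=False``.
    """
    if isinstance(tables, tuple):
        a, e = tables
    else:
        if len(tables) < 2:
            raise DegenerateSampleError("prior fitting needs at least 2 tables")
        a, e = _as_counts(tables)
    if np.any(e <= 0):
        keep = e > 0
        a, e = a[keep], e[keep]
    if maxiter == 0:
        return FitResult(prior=init, converged=False,
                         loglik=log_marginal_likelihood((a, e), init),
                         n_tables=len(a))

    def unpack(theta: np.ndarray) -> GpsPrior:
        al1, be1, al2, be2 = np.exp(np.clip(theta[:4], -20, 20))
        if fix_w is not None:
            w = fix_w
        else:
            w = 1.0 / (1.0 + math.exp(-float(np.clip(theta[4], -30, 30))))
        return GpsPrior(al1, be1, al2, be2, min(max(w, 0.0), 1.0))

    def nll(theta: np.ndarray) -> float:
        val = -log_marginal_likelihood((a, e), unpack(theta))
        return val if np.isfinite(val) else 1e12

    theta0 = np.array([math.log(init.alpha1), math.log(init.beta1),
                       math.log(init.alpha2), math.log(init.beta2),
                       special.logit(min(max(init.w, 1e-9), 1 - 1e-9))])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": maxiter * 10, "xatol": 1e-8,
                                     "fatol": 1e-10})
    prior = unpack(res.x)
    return FitResult(prior=prior, converged=bool(res.success),
                     loglik=-float(res.fun), n_tables=len(a))


# ---------------------------------------------------------------------------
# posterior per table


def posterior(t: ContingencyTable, prior: GpsPrior) -> GpsPosterior:
    """Conjugate posterior mixture for one table and its EBGM summaries."""
    a, e = float(t.a), float(t.expected)
    if e <= 0 and a > 0:
        raise DegenerateSampleError("posterior undefined: E = 0 with a > 0")
    # posterior component weight via marginal likelihood ratio
    l1, l2 = _log_marginal_components(np.array([a]), np.array([max(e, 0.0)]), prior)
    if prior.w >= 1.0:
        q = 1.0
    elif prior.w <= 0.0:
        q = 0.0
    else:
        num = math.log(prior.w) + float(l1[0])
        den = np.logaddexp(num, math.log1p(-prior.w) + float(l2[0]))
        q = math.exp(num - den)
    s1, r1 = prior.alpha1 + a, prior.beta1 + e
    s2, r2 = prior.alpha2 + a, prior.beta2 + e
    ebgm = math.exp(q * (special.digamma(s1) - math.log(r1))
                    + (1.0 - q) * (special.digamma(s2) - math.log(r2)))
    ebgm05 = _mixture_gamma_ppf(0.05, q, s1, r1, s2, r2)
    return GpsPosterior(q=q, shape1=s1, rate1=r1, shape2=s2, rate2=r2,
                        ebgm=ebgm, ebgm05=ebgm05)


def _mixture_gamma_ppf(p: float, q: float, s1: float, r1: float,
                       s2: float, r2: float) -> float:
    """Quantile of q*Gamma(s1, r1) + (1-q)*Gamma(s2, r2) by bracketed root
    finding; the bracket endpoints are the component quantiles."""
    g1 = stats.gamma(s1, scale=1.0 / r1)
    g2 = stats.gamma(s2, scale=1.0 / r2)

    def cdf(x: float) -> float:
        return q * g1.cdf(x) + (1.0 - q) * g2.cdf(x)

    lo = min(g1.ppf(p), g2.ppf(p))
    hi = max(g1.ppf(p), g2.ppf(p))
    if hi <= lo:  # identical components
        return lo
    f_lo, f_hi = cdf(lo) - p, cdf(hi) - p
    if f_lo >= 0:
        return lo
    if f_hi <= 0:
        return hi
    return optimize.brentq(lambda x: cdf(x) - p, lo, hi, xtol=1e-12, rtol=1e-12)


# ---------------------------------------------------------------------------
# quadrature oracle (verification only)


def ebgm_oracle(t: ContingencyTable, prior: GpsPrior,
                grid_points: int = 200_001) -> tuple[float, float]:
    """EBGM and EBGM05 by direct numerical integration of the unnormalized
    posterior density Poisson(a; lambda*E) * prior(lambda) on a log-spaced
    grid.  Independent of the conjugate closed form; used in tests only.
    """
    a, e = float(t.a), float(t.expected)
    lam = np.geomspace(1e-10, 1e5, grid_points)
    with np.errstate(divide="ignore"):
        log_pois = a * np.log(lam * e) - lam * e - special.gammaln(a + 1.0)
        log_prior = np.logaddexp(
            math.log(prior.w) + stats.gamma.logpdf(lam, prior.alpha1,
                                                   scale=1.0 / prior.beta1)
            if prior.w > 0 else np.full_like(lam, -np.inf),
            math.log1p(-prior.w) + stats.gamma.logpdf(lam, prior.alpha2,
                                                      scale=1.0 / prior.beta2)
            if prior.w < 1 else np.full_like(lam, -np.inf))
    log_dens = log_pois + log_prior
    log_dens -= log_dens.max()
    dens = np.exp(log_dens)
    z = np.trapezoid(dens, lam)
    ebgm = math.exp(float(np.trapezoid(dens * np.log(lam), lam)) / z)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(lam) * 0.5 * (dens[1:] + dens[:-1]))]) / z
    ebgm05 = float(np.interp(0.05, cum, lam))
    return ebgm, ebgm05
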