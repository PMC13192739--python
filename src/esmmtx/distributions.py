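"""Distribution primitives for the exponential scale mixture (ESM) model.

The model rests on a small set of identities:

* A Lomax (Pareto type II) random variable with shape ``a`` and scale ``b``
  has density ``(a/b) (1 + y/b)^(-a-1)`` on ``y >= 0``.
* Mixing an exponential with mean ``mu * U`` over ``U ~ IG(theta+1, theta)``
  marginalizes to ``Lomax(theta+1, mu*theta)``, whose mean is ``mu`` for
  ``theta > 0`` and whose variance is ``mu^2 (theta+1)/(theta-1)`` for
  ``theta > 1``.

Exponential distributions are parameterized by their SCALE (= mean)
throughout this package, never by rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "LomaxParams",
    "IGParams",
    "lomax_pdf",
    "lomax_cdf",
    "lomax_rng",
    "invgamma_logpdf",
    "invgamma_rng",
    "esm_marginal_equivalence_check",
    "truncated_exponential_rng",
    "truncated_normal_rng",
    "tail_index_estimate",
]


@dataclass(frozen=True)
class LomaxParams:
    """Shape/scale of a Lomax distribution.

    In the model's parameterization the sampling distribution of an
    abundance with mean ``mu`` and precision ``theta`` is
    ``Lomax(shape=theta+1, scale=mu*theta)``.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("Lomax shape and scale must be positive")

    @property
    def mean(self) -> float:
        """Mean ``scale/(shape-1)``; defined only for shape > 1."""
        if self.shape <= 1:
            return np.inf
        return self.scale / (self.shape - 1.0)

    @classmethod
    def from_mean_precision(cls, mu: float, theta: float) -> "LomaxParams":
        return cls(shape=theta + 1.0, scale=mu * theta)


@dataclass(frozen=True)
class IGParams:
    """Shape/scale of an inverse-gamma distribution."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("inverse-gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        if self.shape <= 1:
            return np.inf
        return self.scale / (self.shape - 1.0)

    @property
    def variance(self) -> float:
        if self.shape <= 2:
            return np.inf
        return self.scale**2 / ((self.shape - 1.0) ** 2 * (self.shape - 2.0))


def _check_nonneg(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("Lomax support is y >= 0")
    return y


def lomax_pdf(y, params: LomaxParams) -> np.ndarray:
    y = _check_nonneg(y)
    return stats.lomax.pdf(y, params.shape, scale=params.scale)


def lomax_cdf(y, params: LomaxParams) -> np.ndarray:
    y = _check_nonneg(y)
    return stats.lomax.cdf(y, params.shape, scale=params.scale)


def lomax_rng(params: LomaxParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-cdf sampler: ``y = b((1-u)^(-1/a) - 1)``. Exact, no rejection."""
    u = rng.random(n)
    return params.scale * (np.power(1.0 - u, -1.0 / params.shape) - 1.0)


def invgamma_logpdf(x, shape: float, scale: float) -> np.ndarray:
    """log density of IG(shape, scale); vectorized, -inf for x <= 0."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.full(x.shape, -np.inf)
    pos = x > 0
    xp = x[pos]
    out[pos] = (
        shape * np.log(scale)
        - special.gammaln(shape)
        - (shape + 1.0) * np.log(xp)
        - scale / xp
    )
    return out if out.size > 1 else out[0]


def invgamma_rng(shape, scale, rng: np.random.Generator, size=None) -> np.ndarray:
    """IG draws as the reciprocal of gamma draws (scale convention)."""
    g = rng.gamma(shape, 1.0, size=size)
    return np.asarray(scale) / g


def esm_marginal_equivalence_check(
    theta: float, mu: float, n: int, rng: np.random.Generator
) -> tuple[float, float]:
    """KS test of the scale-mixture marginal against the closed-form Lomax.

    Draws ``U ~ IG(theta+1, theta)`` then ``y ~ Exp(mean mu*U)`` and returns
    the one-sample Kolmogorov-Smirnov (statistic, p-value) against
    ``Lomax(theta+1, mu*theta)``.
    """
    if n <= 0:
        raise ValueError("need at least one draw")
    u = invgamma_rng(theta + 1.0, theta, rng, size=n)
    y = rng.exponential(mu * u)
    params = LomaxParams.from_mean_precision(mu, theta)
    res = stats.kstest(y, lambda q: stats.lomax.cdf(q, params.shape, scale=params.scale))
    return float(res.statistic), float(res.pvalue)


def truncated_exponential_rng(
    scale,
    n: int,
    rng: np.random.Generator,
    upper=None,
    lower=None,
) -> np.ndarray:
    """Sample an exponential (scale = mean) truncated above or below.

    Upper truncation uses the closed-form inverse cdf on ``[0, upper)``.
    Lower truncation exploits memorylessness: ``lower + Exp(scale)``.
    ``scale`` and the bound may be arrays broadcastable against ``n``.
    """
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("scale must be positive")
    if (upper is None) == (lower is None):
        raise ValueError("exactly one of upper/lower must be given")
    if upper is not None:
        upper = np.asarray(upper, dtype=float)
        if np.any(upper <= 0):
            raise ValueError("upper truncation bound must be positive")
        u = rng.random(n)
        # F(y)/F(upper) inverted; log1p/expm1 keep small upper/scale exact
        return -scale * np.log1p(u * np.expm1(-upper / scale))
    lower = np.asarray(lower, dtype=float)
    return lower + rng.exponential(scale, size=n)


def _ndtri_exp(logp: np.ndarray) -> np.ndarray:
    return special.ndtri_exp(logp)


def truncated_normal_rng(
    mean,
    sd,
    lower,
    upper,
    rng: np.random.Generator,
    size=None,
) -> np.ndarray:
    """Normal draws conditioned on ``lower < x < upper``, stable in far tails.

    Uses log-space cdf inversion (``log_ndtr`` + ``ndtri_exp``); when the
    window lies in the upper tail the problem is reflected so both cdf
    evaluations happen in the well-conditioned lower tail. Accurate for
    ``|bound - mean|/sd`` well beyond 8, where naive ``Phi`` inversion
    collapses to the bound.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(~(lower < upper)):
        raise ValueError("require lower < upper (inconsistent truncation bounds)")
    with np.errstate(invalid="ignore"):
        a = (lower - mean) / sd
        b = (upper - mean) / sd
    a = np.where(np.isneginf(lower), -np.inf, a)
    b = np.where(np.isposinf(upper), np.inf, b)
    a, b, mean_b, sd_b = np.broadcast_arrays(a, b, mean, sd)
    shape = a.shape if size is None else size
    u = rng.random(shape)
    # reflect windows sitting in the right tail into the left tail, so both
    # cdf evaluations happen where log_ndtr is well conditioned
    with np.errstate(invalid="ignore"):
        flip = np.where(
            np.isposinf(b), True, np.where(np.isneginf(a), False, (a + b) > 0)
        )
    a_ = np.where(flip, -b, a)
    b_ = np.where(flip, -a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        la = special.log_ndtr(a_)
        lb = special.log_ndtr(b_)
        # log cdf of the draw inside the window:
        # q = Phi(a) + u (Phi(b) - Phi(a)) = Phi(b) (1 + (1-u) expm1(la - lb));
        # expm1(la-lb) in [-1, 0] makes this stable for any window, including
        # la = -inf where it reduces to lb + log(u)
        logq = lb + np.log1p((1.0 - u) * np.expm1(la - lb))
    z = _ndtri_exp(logq)
    z = np.where(flip, -z, z)
    x = mean_b + sd_b * z
    # guard against roundoff pushing draws onto a bound
    lo = np.where(np.isfinite(lower), np.nextafter(lower, np.inf), lower)
    hi = np.where(np.isfinite(upper), np.nextafter(upper, -np.inf), upper)
    return np.clip(x, lo, hi)


def tail_index_estimate(
    samples: np.ndarray,
    scale_b: float,
    q_lo: float = 0.90,
    q_hi: float = 0.999,
    n_grid: int = 40,
) -> float:
    """Slope of log survival vs ``log(1 + y/b)`` over high quantiles.

    For Lomax(a, b) samples the survival function is ``(1+y/b)^(-a)`` so the
    regression slope estimates ``-a = -(theta+1)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 10_000:
        raise ValueError("tail index estimation needs >= 1e4 samples")
    qs = np.quantile(samples, np.linspace(q_lo, q_hi, n_grid))
    surv = np.array([(samples > q).mean() for q in qs])
    keep = surv > 0
    x = np.log1p(qs[keep] / scale_b)
    y = np.log(surv[keep])
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)
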