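"""Discrete heavy-tailed probability families for spacer-count data.

The central family is the truncated power law ``p(i) ∝ i^{-alpha} e^{-lam*i}``
on integer support ``{i_min, i_min+1, ...}`` — the law that pooled CRISPR
spacer-count histograms follow — together with the standard candidate
families it is compared against: pure power law, exponential, stretched
exponential, and (discretized) lognormal.

All pmfs are normalized by direct summation of the unnormalized weights over
the declared support, with a tail bound when the support is unbounded; the
pure power law uses the Hurwitz zeta function in closed form.  Fitting is
discrete maximum likelihood by numerical optimization over the family's
natural parameter box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "FitResult",
    "FitError",
    "pmf",
    "log_pmf",
    "sample",
    "fit_mle",
    "loglikelihood",
]

FAMILIES = (
    "truncated_powerlaw",
    "powerlaw",
    "exponential",
    "stretched_exponential",
    "lognormal",
)

#: names of required parameters per family
_FAMILY_PARAMS = {
    "truncated_powerlaw": ("alpha", "lam"),
    "powerlaw": ("alpha",),
    "exponential": ("lam",),
    "stretched_exponential": ("lam", "beta"),
    "lognormal": ("mu", "sigma"),
}

NEG_INF = float("-inf")  # sentinel returned by log_pmf outside the support

# Direct summation of the normalizer is used up to this many terms; beyond it
# (unbounded support, very small exponential rate) we fall back to the
# polylog closed form.
_MAX_SUM_TERMS = 500_000


class ParameterError(ValueError):
    """Invalid distribution parameters."""


class FitError(RuntimeError):
    """Raised when maximum-likelihood fitting cannot proceed."""


@dataclass(frozen=True)
class DistributionSpec:
    """A discrete heavy-tailed family with fixed parameters and support.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    params
        Named real parameters, e.g. ``{"alpha": 2.57, "lam": 0.004}``.
    support_min
        Smallest integer in the support (>= 1).
    support_max
        Largest integer in the support, or ``None`` for unbounded.
    """

    family: str
    params: dict = field(default_factory=dict)
    support_min: int = 1
    support_max: Optional[int] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        missing = set(_FAMILY_PARAMS[self.family]) - set(self.params)
        if missing:
            raise ParameterError(f"{self.family}: missing parameters {sorted(missing)}")
        if self.support_min < 1:
            raise ParameterError("support_min must be >= 1")
        if self.support_max is not None and self.support_max < self.support_min:
            raise ParameterError("support_max < support_min")
        _validate_params(self.family, self.params, self.support_max)

    # dataclass is frozen so the spec can be used as a dict key / cached on
    def __hash__(self):
        return hash((self.family, tuple(sorted(self.params.items())),
                     self.support_min, self.support_max))


@dataclass
class FitResult:
    """Outcome of a discrete maximum-likelihood fit."""

    spec: DistributionSpec
    loglikelihood: float
    n: float
    i_min: int
    alpha_ci: Optional[tuple] = None
    converged: bool = True
    message: str = ""


def _validate_params(family: str, params: dict, support_max: Optional[int]) -> None:
    p = params
    if family == "truncated_powerlaw":
        if p["alpha"] < 0 or p["lam"] < 0:
            raise ParameterError("truncated_powerlaw requires alpha >= 0, lam >= 0")
        if support_max is None and p["lam"] == 0 and p["alpha"] <= 1:
            raise ParameterError("unbounded truncated_powerlaw with lam=0 needs alpha > 1")
    elif family == "powerlaw":
        if support_max is None and p["alpha"] <= 1:
            raise ParameterError("unbounded powerlaw requires alpha > 1")
        if p["alpha"] <= 0:
            raise ParameterError("powerlaw requires alpha > 0")
    elif family == "exponential":
        if p["lam"] <= 0:
            raise ParameterError("exponential requires lam > 0")
    elif family == "stretched_exponential":
        if p["lam"] <= 0 or p["beta"] <= 0:
            raise ParameterError("stretched_exponential requires lam > 0, beta > 0")
    elif family == "lognormal":
        if p["sigma"] <= 0:
            raise ParameterError("lognormal requires sigma > 0")


def _log_weight(family: str, params: dict, i: np.ndarray) -> np.ndarray:
    """Unnormalized log weight log w(i) of each family, vectorized over i >= 1."""
    x = np.asarray(i, dtype=float)
    logx = np.log(x)
    p = params
    if family == "truncated_powerlaw":
        return -p["alpha"] * logx - p["lam"] * x
    if family == "powerlaw":
        return -p["alpha"] * logx
    if family == "exponential":
        return -p["lam"] * x
    if family == "stretched_exponential":
        return (p["beta"] - 1.0) * logx - p["lam"] * x ** p["beta"]
    if family == "lognormal":
        return -logx - (logx - p["mu"]) ** 2 / (2.0 * p["sigma"] ** 2)
    raise ParameterError(f"unknown family {family!r}")


def _log_norm(family: str, params: dict, support_min: int,
              support_max: Optional[int]) -> float:
    """log of the normalization constant Z = sum_i w(i) over the support.

    Finite supports are summed exactly (log-sum-exp).  Unbounded supports are
    summed in blocks until the residual tail, bounded by a geometric/integral
    estimate, falls below 1e-13 of the running total; the pure power law uses
    the Hurwitz zeta closed form and the small-rate truncated power law the
    polylog Li_alpha(e^{-lam}).
    """
    if support_max is not None:
        i = np.arange(support_min, support_max + 1, dtype=float)
        return float(special.logsumexp(_log_weight(family, params, i)))

    if family == "powerlaw":
        return float(np.log(special.zeta(params["alpha"], support_min)))
    if family == "exponential":
        # geometric series: sum_{i>=m} e^{-lam i} = e^{-lam m} / (1 - e^{-lam})
        lam = params["lam"]
        return -lam * support_min - math.log1p(-math.exp(-lam))
    if family == "truncated_powerlaw" and 0 < params["lam"] < 1e-4:
        return _log_norm_polylog(params["alpha"], params["lam"], support_min)

    # blockwise direct summation with tail bound
    total = NEG_INF
    start = support_min
    block = 4096
    while True:
        i = np.arange(start, start + block, dtype=float)
        total = np.logaddexp(total, special.logsumexp(_log_weight(family, params, i)))
        start += block
        block = min(2 * block, 262_144)
        tail = _log_tail_bound(family, params, start)
        if tail < total + math.log(1e-13):
            return float(total)
        if start > _MAX_SUM_TERMS + support_min:
            if family == "truncated_powerlaw" and params["lam"] > 0:
                return _log_norm_polylog(params["alpha"], params["lam"], support_min)
            raise ParameterError(
                f"{family}{params}: normalizer did not converge within "
                f"{_MAX_SUM_TERMS} terms")


def _log_norm_polylog(alpha: float, lam: float, support_min: int) -> float:
    """log Z via Li_alpha(e^{-lam}) minus the head below support_min."""
    import mpmath

    z = mpmath.polylog(mpmath.mpf(alpha), mpmath.e ** (-mpmath.mpf(lam)))
    if support_min > 1:
        head = np.arange(1, support_min, dtype=float)
        z -= mpmath.mpf(float(np.sum(np.exp(_log_weight(
            "truncated_powerlaw", {"alpha": alpha, "lam": lam}, head)))))
    return float(mpmath.log(z))


def _log_tail_bound(family: str, params: dict, start: int) -> float:
    """Upper bound on log sum_{i>=start} w(i); used to stop the summation."""
    p = params
    if family == "truncated_powerlaw":
        # w(i) <= start^{-alpha_-} e^{-lam i} for i >= start (alpha may be < 0
        # only on finite supports, which never reach here)
        lam = p["lam"]
        if lam <= 0:
            if p["alpha"] > 1:  # integral bound of the zeta tail
                return (1 - p["alpha"]) * math.log(start - 1) - math.log(p["alpha"] - 1)
            return math.inf
        return (-p["alpha"] * math.log(start) - lam * start
                - math.log1p(-math.exp(-lam)))
    if family == "stretched_exponential":
        lam, beta = p["lam"], p["beta"]
        # bound i^{beta-1} e^{-lam i^beta} by the exponential of rate r at start
        r = lam * (start ** beta - (start - 1) ** beta)
        if r <= 0:
            return math.inf
        top = (beta - 1) * math.log(start) if beta >= 1 else 0.0
        return top - lam * start ** beta - math.log1p(-math.exp(-min(r, 700.0)))
    if family == "lognormal":
        # tail of w(i) = exp(-(log i - mu)^2 / (2 sigma^2)) / i is bounded by
        # the Gaussian integral in y = log x
        mu, sigma = p["mu"], p["sigma"]
        y = (math.log(start) - mu) / sigma
        if y <= 0:
            return math.inf
        return math.log(sigma * math.sqrt(2 * math.pi)) + float(
            special.log_ndtr(-y))
    return math.inf


def log_pmf(spec: DistributionSpec, i) -> np.ndarray | float:
    """Log probability mass at integer(s) ``i``.

    Points outside the support return ``-inf`` (the package-wide sentinel for
    zero probability); the computation never forms the pmf itself, so values
    far in the tail stay finite in log space.
    """
    scalar = np.isscalar(i)
    x = np.atleast_1d(np.asarray(i, dtype=float))
    out = np.full(x.shape, NEG_INF)
    ok = (x >= spec.support_min) & (x == np.floor(x))
    if spec.support_max is not None:
        ok &= x <= spec.support_max
    if ok.any():
        logz = _cached_log_norm(spec)
        out[ok] = _log_weight(spec.family, spec.params, x[ok]) - logz
    return float(out[0]) if scalar else out


_NORM_CACHE: dict = {}


def _cached_log_norm(spec: DistributionSpec) -> float:
    try:
        return _NORM_CACHE[spec]
    except KeyError:
        z = _log_norm(spec.family, spec.params, spec.support_min, spec.support_max)
        if len(_NORM_CACHE) > 4096:
            _NORM_CACHE.clear()
        _NORM_CACHE[spec] = z
        return z


def pmf(spec: DistributionSpec, i) -> np.ndarray | float:
    """Probability mass at integer(s) ``i``; 0 outside the support."""
    lp = log_pmf(spec, i)
    return np.exp(lp) if not np.isscalar(lp) else math.exp(lp) if lp > NEG_INF else 0.0


def _cdf_table(spec: DistributionSpec, q: float = 1e-10):
    """Support points and cumulative probabilities covering quantile 1-q.

    For unbounded supports the table is extended until the remaining tail
    mass is below ``q`` (capped at 1e6 points); the residual is folded into
    the last entry so the table is a proper distribution.
    """
    if spec.support_max is not None:
        xs = np.arange(spec.support_min, spec.support_max + 1)
        probs = np.exp(log_pmf(spec, xs))
    else:
        hi = spec.support_min + 1024
        while True:
            xs = np.arange(spec.support_min, hi + 1)
            probs = np.exp(log_pmf(spec, xs))
            if 1.0 - probs.sum() < q or hi - spec.support_min >= 1_000_000:
                break
            hi = min(hi * 4, spec.support_min + 1_000_000)
        probs = probs.copy()
        probs[-1] += max(0.0, 1.0 - probs.sum())
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    return xs, cdf


def sample(spec: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` iid integers by inverse-CDF over the discrete support.

    Deterministic for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    xs, cdf = _cdf_table(spec)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return xs[np.searchsorted(cdf, u, side="right")]


def mean(spec: DistributionSpec) -> float:
    """Analytic mean by direct summation over the (tail-truncated) support."""
    xs, cdf = _cdf_table(spec, q=1e-12)
    p = np.diff(np.concatenate([[0.0], cdf]))
    return float(np.sum(xs * p))


# ---------------------------------------------------------------------------
# maximum likelihood fitting
# ---------------------------------------------------------------------------

# optimizer boxes: (name, lo, hi) per family, in the order _FAMILY_PARAMS
_FIT_BOUNDS = {
    "truncated_powerlaw": [(1e-6, 20.0), (1e-9, 5.0)],
    "powerlaw": [(1.000001, 20.0)],
    "exponential": [(1e-9, 5.0)],
    "stretched_exponential": [(1e-9, 5.0), (0.05, 4.0)],
    # Table-2 style constraint mu > 0 on the lognormal location
    "lognormal": [(1e-9, 20.0), (1e-3, 10.0)],
}


def _compress(data, weights):
    data = np.asarray(data)
    if weights is None:
        vals, cnt = np.unique(data, return_counts=True)
        return vals.astype(float), cnt.astype(float)
    w = np.asarray(weights, dtype=float)
    if w.shape != data.shape:
        raise ValueError("weights must match data shape")
    vals, inv = np.unique(data, return_inverse=True)
    cnt = np.zeros(len(vals))
    np.add.at(cnt, inv, w)
    return vals.astype(float), cnt


def _neg_loglik(theta, family, vals, cnt, i_min, support_max):
    params = dict(zip(_FAMILY_PARAMS[family], theta))
    try:
        logz = _log_norm(family, params, i_min, support_max)
    except (ParameterError, OverflowError):
        return 1e12
    ll = float(np.dot(cnt, _log_weight(family, params, vals))) - cnt.sum() * logz
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _starts(family, vals, cnt):
    """Moment-flavoured starting points; several to dodge local optima."""
    m = np.dot(cnt, vals) / cnt.sum()
    logm = np.dot(cnt, np.log(vals)) / cnt.sum()
    logsd = math.sqrt(max(np.dot(cnt, (np.log(vals) - logm) ** 2) / cnt.sum(), 1e-4))
    if family == "truncated_powerlaw":
        return [(2.5, 0.005), (1.5, 0.05), (0.5, 1.0 / max(m, 1.0)), (3.0, 1e-4)]
    if family == "powerlaw":
        return [(1.0 + 1.0 / max(logm, 0.05),), (2.5,), (1.2,)]
    if family == "exponential":
        return [(1.0 / max(m, 0.5),)]
    if family == "stretched_exponential":
        return [(1.0 / max(m, 0.5), 1.0), (0.5, 0.5), (1.0, 0.3)]
    if family == "lognormal":
        return [(max(logm, 0.01), logsd), (max(logm, 0.01), 2 * logsd)]
    raise ParameterError(family)


def fit_mle(family: str, data: Sequence[int], i_min: int = 1,
            weights: Optional[Sequence[float]] = None,
            support_max: Optional[int] = None,
            min_obs: int = 30) -> FitResult:
    """Fit one family to integer observations ``>= i_min`` by discrete MLE.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    data
        Integer observations; values below ``i_min`` are excluded before
        fitting.
    i_min
        Support minimum used for fitting (default 1: whole distributions).
    weights
        Optional non-negative weights per observation.  Used to fit model
        class-probability vectors without resampling; the weighted
        log-likelihood ``sum_j w_j log p(x_j)`` is maximized.
    support_max
        Optional finite upper support bound (used when fitting model output
        with a hard class cap).
    min_obs
        Minimum number of (weighted) observations required.

    Returns
    -------
    FitResult
        With ``alpha_ci`` (asymptotic normal 95% interval from the observed
        information) for the power-law families, and ``converged=False`` on
        optimizer failure — never a silent bad fit.
    """
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}")
    data = np.asarray(data)
    keep = data >= i_min
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[keep]
    data = data[keep]
    if data.size == 0:
        raise FitError("no observations >= i_min")
    n = float(data.size if weights is None else np.sum(weights > 0))
    if n < min_obs:
        raise FitError(f"too few observations ({n:g} < {min_obs})")
    vals, cnt = _compress(data, weights)
    if len(vals) < 2:
        raise FitError("degenerate data: a single repeated value")

    bounds = _FIT_BOUNDS[family]
    best = None
    for x0 in _starts(family, vals, cnt):
        res = optimize.minimize(
            _neg_loglik, np.asarray(x0, dtype=float),
            args=(family, vals, cnt, i_min, support_max),
            method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    theta = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    params = {k: float(v) for k, v in zip(_FAMILY_PARAMS[family], theta)}
    spec = DistributionSpec(family, params, support_min=i_min, support_max=support_max)
    ll = -best.fun

    alpha_ci = None
    if family in ("truncated_powerlaw", "powerlaw"):
        alpha_ci = _alpha_ci(family, theta, vals, cnt, i_min, support_max)

    return FitResult(spec=spec, loglikelihood=float(ll), n=float(cnt.sum()),
                     i_min=i_min, alpha_ci=alpha_ci,
                     converged=bool(best.success),
                     message="" if best.success else str(best.message))


def _alpha_ci(family, theta, vals, cnt, i_min, support_max):
    """95% CI for the power-law exponent from the observed information."""
    k = len(theta)
    h = 1e-4
    hess = np.zeros((k, k))
    f0 = _neg_loglik(theta, family, vals, cnt, i_min, support_max)
    for a in range(k):
        for b in range(a, k):
            ea = np.eye(k)[a] * h
            eb = np.eye(k)[b] * h
            hess[a, b] = hess[b, a] = (
                _neg_loglik(theta + ea + eb, family, vals, cnt, i_min, support_max)
                - _neg_loglik(theta + ea - eb, family, vals, cnt, i_min, support_max)
                - _neg_loglik(theta - ea + eb, family, vals, cnt, i_min, support_max)
                + _neg_loglik(theta - ea - eb, family, vals, cnt, i_min, support_max)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
        se = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        return None
    if se == 0 or not math.isfinite(se):
        return None
    return (float(theta[0] - 1.959963984540054 * se),
            float(theta[0] + 1.959963984540054 * se))


def loglikelihood(spec: DistributionSpec, data, weights=None) -> float:
    """Sum of (optionally weighted) log-pmf over observations."""
    lp = log_pmf(spec, np.asarray(data))
    if weights is None:
        return float(np.sum(lp))
    return float(np.dot(np.asarray(weights, dtype=float), lp))
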