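"""Discrete-time Markov-chain model of CRISPR spacer-array length dynamics.

A bacterial population is partitioned into classes i = 1..N by the number of
spacers in the (single) CRISPR array.  Each time step has two stages:

* **Infection.**  With probability ``p`` a cell meets a phage.  With
  probability ``q_i`` its array holds a matching spacer, which works
  perfectly with probability ``h`` (survive, gain ~Geom(mu_n) spacers) or
  imperfectly (survive with probability ``g``, gain ~Geom(mu_m)); with
  probability ``1 - q_i`` there is no match (survive with probability ``s``,
  naive gain ~Geom(mu_k)).  Cells that fail to survive die; cells that meet
  no phage are unchanged.
* **Replication.**  Survivors replicate to refill the carrying capacity
  ``F_const``.  The parent keeps its array; the daughter loses a
  Geom(mu_delta(i)) number of spacers with ``mu_delta(i) = S_L * i``.  The
  per-class replication rate ``nu_i`` is rescaled each step by the factor
  ``N_nu`` that restores the total to exactly ``F_const``.

Gains are capped at class N, losses at class 1 (excess mass accumulates at
the boundary class), so cells are conserved.  The rich-get-richer regime —
``q_i`` increasing and ``nu_i`` decreasing in i — yields heavy-tailed
stationary distributions of spacer counts; constant profiles give light
tails.

All "exponential" gain/loss laws are the geometric distribution with the
stated mean, P(k) = (1/(1+mu)) (mu/(1+mu))^k on k >= 0: the maximum-entropy
discrete law with mode 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse.linalg

from .distributions import FitResult, fit_mle

__all__ = [
    "DynamicsParams", "StateVector", "StationaryResult",
    "q_of_i", "nu_of_i", "gain_pmf",
    "build_infection_matrix", "build_replication_matrix", "compute_scaling",
    "iterate_to_stationarity", "stationary_eigen", "fit_stationary", "sweep",
    "ExtinctionError",
]


class ExtinctionError(RuntimeError):
    """The whole population died during an infection stage."""


Q_PROFILES = ("constant", "linear", "logistic")
NU_PROFILES = ("constant", "linear", "gaussian")


@dataclass(frozen=True)
class DynamicsParams:
    """Full parameter set of the two-stage Markov model.

    Defaults follow the standard configuration: N = 1000 classes, carrying
    capacity F_const = 1e6, linear immune-efficiency profile
    q_i = (i-1)/N and linear replication profile nu_i = (N+1-i)/N, priming
    constraint 100*mu_k = mu_m = mu_n.
    """

    p: float = 0.7          # probability of a phage encounter per step
    h: float = 1.0          # probability the matching spacer works perfectly
    s: float = 0.4          # survival probability with no matching spacer
    g: float = 0.7          # survival probability with an inefficient spacer
    mu_n: float = 10.0      # mean gain, perfect match (interference-driven)
    mu_m: float = 10.0      # mean gain, inefficient match (priming)
    mu_k: float = 0.1       # mean gain, naive adaptation
    S_L: float = 1 / 8      # fraction of spacers the daughter loses
    N: int = 1000           # maximum spacer count (number of classes)
    F_const: float = 1e6    # carrying capacity (total population)
    q_profile: str = "linear"
    q_params: dict = field(default_factory=dict)   # constant: q; logistic: midpoint, steepness
    nu_profile: str = "linear"
    nu_params: dict = field(default_factory=dict)  # constant: nu; gaussian: width
    tol: float = 1e-10      # L1 stationarity tolerance on the normalized distribution
    max_iter: int = 10000
    include_zero_gain: bool = True  # count zero-gain infection survivors on the diagonal
    boundary: str = "discard"       # over-cap gains: "discard" (implicit death) or
                                    # "accumulate" (pile up in class N)

    def __post_init__(self):
        for name in ("p", "h", "s", "g"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.s <= self.g <= self.h:
            raise ValueError("constraint s <= g <= h violated")
        for name in ("mu_n", "mu_m", "mu_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.S_L < 1.0:
            raise ValueError("S_L must be in (0, 1)")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.q_profile not in Q_PROFILES:
            raise ValueError(f"unknown q_profile {self.q_profile!r}")
        if self.nu_profile not in NU_PROFILES:
            raise ValueError(f"unknown nu_profile {self.nu_profile!r}")
        if self.boundary not in ("discard", "accumulate"):
            raise ValueError("boundary must be 'discard' or 'accumulate'")

    def q_vector(self) -> np.ndarray:
        return q_of_i(self.q_profile, np.arange(1, self.N + 1), self.N,
                      **self.q_params)

    def nu_vector(self) -> np.ndarray:
        return nu_of_i(self.nu_profile, np.arange(1, self.N + 1), self.N,
                       **self.nu_params)


@dataclass
class StateVector:
    """Class abundances F_i (i = 1..N as indices 0..N-1) at iteration t."""

    F: np.ndarray
    t: int = 0


@dataclass
class StationaryResult:
    """Equilibrium spacer-number distribution and how it was obtained."""

    distribution: np.ndarray     # F*/F_const, sums to 1
    iterations: int
    converged: bool
    N_nu_star: float
    method: str                  # "iteration" or "eigenvector"
    degenerate: bool = False     # eigenvalue-1 eigenspace not one-dimensional

    @property
    def classes(self) -> np.ndarray:
        return np.arange(1, len(self.distribution) + 1)


def q_of_i(profile: str, i, N: int, *, q: float = 0.5,
           midpoint: Optional[float] = None, steepness: float = 10.0):
    """Immune-system efficiency q_i: probability the array holds a (possibly
    inefficient) spacer matching the infecting phage.

    ``constant``: fixed ``q``.  ``linear``: (i-1)/N.  ``logistic``: a
    monotone increasing sigmoid in i with configurable midpoint (default
    N/2) and steepness (in classes).  All profiles return values in [0, 1].
    """
    i = np.asarray(i, dtype=float)
    if np.any((i < 1) | (i > N)):
        raise ValueError("class index outside 1..N")
    if profile == "constant":
        if not 0.0 <= q <= 1.0:
            raise ValueError("constant q must be in [0, 1]")
        return np.full_like(i, q)
    if profile == "linear":
        return (i - 1.0) / N
    if profile == "logistic":
        if steepness <= 0:
            raise ValueError("steepness must be > 0")
        mid = N / 2.0 if midpoint is None else midpoint
        return 1.0 / (1.0 + np.exp(-(i - mid) / steepness))
    raise ValueError(f"unknown q profile {profile!r}")


def nu_of_i(profile: str, i, N: int, *, nu: float = 1.0,
            width: Optional[float] = None):
    """Replication-rate profile nu_i (before the N_nu rescaling).

    ``constant``: 1 (or ``nu``).  ``linear``: (N+1-i)/N, the cost of a long
    array.  ``gaussian``: exp(-(i/width)^2), a zero-centred decreasing bell
    (default width N/2).
    """
    i = np.asarray(i, dtype=float)
    if np.any((i < 1) | (i > N)):
        raise ValueError("class index outside 1..N")
    if profile == "constant":
        if nu <= 0:
            raise ValueError("constant nu must be > 0")
        return np.full_like(i, nu)
    if profile == "linear":
        return (N + 1.0 - i) / N
    if profile == "gaussian":
        w = N / 2.0 if width is None else width
        if w <= 0:
            raise ValueError("width must be > 0")
        return np.exp(-((i / w) ** 2))
    raise ValueError(f"unknown nu profile {profile!r}")


def gain_pmf(mu: float, k) -> np.ndarray | float:
    """Geometric gain/loss pmf with mean ``mu``: P(k) = (mu/(1+mu))^k / (1+mu)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    k = np.asarray(k)
    out = np.where(k >= 0,
                   np.exp(k * (math.log(mu) - math.log1p(mu)) - math.log1p(mu)),
                   0.0)
    return float(out) if out.ndim == 0 else out


def _gain_tail(mu: float, k: int) -> float:
    """P(K >= k) for the geometric gain law."""
    if k <= 0:
        return 1.0
    return math.exp(k * (math.log(mu) - math.log1p(mu)))


def build_infection_matrix(params: DynamicsParams) -> np.ndarray:
    """Infection-stage transition matrix A1 (rows: source class).

    For j > i the entry is the spacer-acquisition probability
    Q_{i,j} = p [ q_i { h P(mu_n, j-i) + (1-h) g P(mu_m, j-i) }
                  + (1-q_i) s P(mu_k, j-i) ].
    The diagonal is the no-encounter term (1-p) plus (by default) the
    zero-gain survival term Q_{i,i}.  The row deficit 1 - sum_j A1[i, :] is
    the per-class death probability, later compensated by replication.

    Gain mass that would exceed class N is handled per ``params.boundary``:
    ``discard`` (default) treats it as part of the death deficit, so the
    array cap acts as a hard viability limit and class N never becomes
    absorbing; ``accumulate`` piles it into class N, conserving survivors
    exactly.
    """
    N = params.N
    q = params.q_vector()
    A = np.zeros((N, N))
    # per-gain-count coefficients: rows i, gains k = j - i
    k = np.arange(N)
    pn = gain_pmf(params.mu_n, k)
    pm = gain_pmf(params.mu_m, k)
    pk = gain_pmf(params.mu_k, k)
    # survival weights per source class
    w_perfect = params.p * q * params.h
    w_inexact = params.p * q * (1.0 - params.h) * params.g
    w_naive = params.p * (1.0 - q) * params.s
    for idx in range(N):          # source class i = idx + 1
        gains = np.arange(N - idx)  # destinations idx..N-1 (gain 0..N-1-idx)
        row = (w_perfect[idx] * pn[gains] + w_inexact[idx] * pm[gains]
               + w_naive[idx] * pk[gains])
        if params.boundary == "accumulate":
            # gains that would exceed class N land in class N
            row[-1] = (w_perfect[idx] * _gain_tail(params.mu_n, N - 1 - idx)
                       + w_inexact[idx] * _gain_tail(params.mu_m, N - 1 - idx)
                       + w_naive[idx] * _gain_tail(params.mu_k, N - 1 - idx))
        A[idx, idx:] = row
        if not params.include_zero_gain:
            A[idx, idx] = 0.0
        A[idx, idx] += 1.0 - params.p
    rs = A.sum(axis=1)
    if np.any(rs > 1.0 + 1e-12):
        raise AssertionError("infection matrix row sum exceeds 1")
    return A


def _loss_increment(params: DynamicsParams) -> np.ndarray:
    """Daughter-cell matrix D with D[i, j] = nu_i P(mu_delta(i), i-j) for
    j <= i (loss mass below class 1 accumulated in class 1); the replication
    matrix is A2 = I + N_nu * D.  Each row of D sums to nu_i exactly.
    """
    N = params.N
    nu = params.nu_vector()
    D = np.zeros((N, N))
    for idx in range(N):          # parent class i = idx + 1
        mu_d = params.S_L * (idx + 1)
        losses = np.arange(idx + 1)          # destinations idx..0 (loss 0..idx)
        row = gain_pmf(mu_d, losses)
        row = row[::-1].copy()               # index j-1 = idx - loss
        row[0] += _gain_tail(mu_d, idx + 1)  # over-deletion lands in class 1
        D[idx, : idx + 1] = nu[idx] * row
    return D


def build_replication_matrix(params: DynamicsParams, N_nu: float) -> np.ndarray:
    """Replication-stage matrix A2: parents stay put (identity), daughters
    descend by the geometric loss law scaled by N_nu * nu_i.  Row i sums to
    1 + N_nu * nu_i.
    """
    if N_nu < 0:
        raise ValueError("N_nu must be >= 0")
    A2 = N_nu * _loss_increment(params)
    A2[np.diag_indices_from(A2)] += 1.0
    if np.any(A2 < 0):
        raise AssertionError("negative entry in replication matrix")
    return A2


def compute_scaling(state_after_infection: StateVector | np.ndarray,
                    nu: np.ndarray, F_const: float) -> float:
    """Replication scaling N_nu that restores the population to F_const.

    N_nu = (F_const - sum_i F_i(t+1/2)) / (sum_i nu_i F_i(t+1/2)): each
    surviving cell of class i contributes N_nu * nu_i daughters, exactly
    compensating the infection-stage deaths.
    """
    F = state_after_infection.F if isinstance(state_after_infection, StateVector) \
        else np.asarray(state_after_infection)
    total = float(F.sum())
    if total <= 0:
        raise ExtinctionError("no survivors after infection stage")
    weighted = float(np.dot(nu, F))
    if weighted <= 0:
        raise ExtinctionError("no replicating survivors")
    return max((F_const - total) / weighted, 0.0)


def iterate_to_stationarity(params: DynamicsParams,
                            init="uniform") -> StationaryResult:
    """Evolve the class-abundance vector to its stationary distribution.

    Alternates the infection and replication half-steps, recomputing the
    replication scaling N_nu each iteration so the total stays at F_const;
    stops when one full iteration moves the normalized distribution by less
    than ``params.tol`` in L1, or at ``params.max_iter``.
    """
    N = params.N
    if isinstance(init, str):
        if init != "uniform":
            raise ValueError("init must be 'uniform' or a StateVector")
        F = np.full(N, params.F_const / N)
    else:
        F = np.asarray(init.F, dtype=float).copy()
        if not math.isclose(F.sum(), params.F_const, rel_tol=1e-9):
            raise ValueError("init must sum to F_const")
    A1 = build_infection_matrix(params)
    D = _loss_increment(params)
    nu = params.nu_vector()
    N_nu = 0.0
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        F_half = F @ A1
        try:
            N_nu = compute_scaling(F_half, nu, params.F_const)
        except ExtinctionError as exc:
            raise ExtinctionError(f"extinction at iteration {it}: {exc}") from exc
        F_new = F_half + N_nu * (F_half @ D)
        delta = float(np.abs(F_new - F).sum()) / params.F_const
        F = F_new
        if delta < params.tol:
            converged = True
            break
    return StationaryResult(distribution=F / params.F_const, iterations=it,
                            converged=converged, N_nu_star=N_nu,
                            method="iteration")


def stationary_eigen(params: DynamicsParams, N_nu_star: float) -> StationaryResult:
    """Stationary distribution as the left principal eigenvector of
    A = A1 A2(N_nu*).

    At the equilibrium scaling the full-step matrix has principal eigenvalue
    1; an eigenvalue further than 1e-6 from 1 signals that ``N_nu_star`` is
    not the equilibrium value and raises.  The degenerate case (A = I, whole
    eigenspace at 1) is returned flagged rather than as a spurious vector.
    """
    if N_nu_star < 0:
        raise ValueError("N_nu_star must be >= 0")
    A1 = build_infection_matrix(params)
    A = A1 @ build_replication_matrix(params, N_nu_star)
    if np.allclose(A, np.eye(params.N), atol=1e-12):
        return StationaryResult(distribution=np.full(params.N, 1.0 / params.N),
                                iterations=0, converged=False,
                                N_nu_star=N_nu_star, method="eigenvector",
                                degenerate=True)
    vals, vecs = scipy.sparse.linalg.eigs(A.T, k=1, which="LM")
    lam = vals[0].real
    if abs(lam - 1.0) > 1e-6:
        raise ValueError(
            f"principal eigenvalue {lam:.8f} differs from 1: N_nu_star is not "
            "the equilibrium scaling")
    v = vecs[:, 0].real
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-12 * max(v.max(), 1.0)):
        raise ValueError("principal eigenvector has negative entries")
    v = np.clip(v, 0.0, None)
    return StationaryResult(distribution=v / v.sum(), iterations=0,
                            converged=True, N_nu_star=N_nu_star,
                            method="eigenvector")


def fit_stationary(result: StationaryResult,
                   family: str = "truncated_powerlaw",
                   population: float = 1e6) -> FitResult:
    """Fit a family to the stationary distribution by weight-aware MLE.

    The class probabilities are converted to integer cell counts in a
    population of ``population`` cells (classes holding less than one cell
    are empty and excluded, mirroring the finite simulated population); the
    counts are used as observation weights, so the fitted exponents are
    deterministic — no Monte-Carlo resampling noise.
    """
    classes = result.classes
    w = np.rint(result.distribution * population)
    keep = w >= 1.0
    if keep.sum() < 2:
        raise ValueError("stationary distribution is degenerate (single class)")
    return fit_mle(family, classes[keep], weights=w[keep],
                   support_max=int(classes[-1]), min_obs=1)


def sweep(params_base: DynamicsParams, vary: str,
          values: Sequence[float]) -> list[dict]:
    """Run the model to stationarity across a sweep of one scalar parameter.

    Returns one record per value with the stationary result and the fitted
    truncated-power-law (alpha, lambda); a failing point records its error
    and the sweep continues.
    """
    if not hasattr(params_base, vary):
        raise ValueError(f"unknown parameter {vary!r}")
    out = []
    for v in values:
        rec = {"value": float(v), "stationary": None, "fit": None, "error": None}
        try:
            p = replace(params_base, **{vary: v})
            res = iterate_to_stationarity(p)
            rec["stationary"] = res
            rec["fit"] = fit_stationary(res)
        except (ValueError, ExtinctionError, AssertionError) as exc:
            rec["error"] = str(exc)
        out.append(rec)
    return out
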