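"""The two-stage Markov chain: matrices, scaling, stationarity, sweeps."""

import math
from dataclasses import replace

import numpy as np
import pytest

from spacerlaw.dynamics import (DynamicsParams, ExtinctionError,
                                StationaryResult, StateVector,
                                build_infection_matrix,
                                build_replication_matrix, compute_scaling,
                                fit_stationary, gain_pmf,
                                iterate_to_stationarity, nu_of_i, q_of_i,
                                stationary_eigen, sweep, _loss_increment)

# a fast heavy-tail-regime parameter point used by several tests
SMALL = dict(p=0.7, h=1.0, s=0.4, g=0.7, mu_n=10, mu_m=10, mu_k=0.1,
             S_L=1 / 8, N=200)


# ---------------------------------------------------------------------- q, nu

def test_linear_q_boundaries():
    assert q_of_i("linear", 1, 100) == 0.0
    assert q_of_i("linear", 100, 100) == pytest.approx(99 / 100)


def test_logistic_q_is_monotone_nondecreasing():
    i = np.arange(1, 201)
    for steep in (1.0, 10.0, 50.0):
        q = q_of_i("logistic", i, 200, steepness=steep)
        assert np.all(np.diff(q) >= 0)
        assert np.all((q >= 0) & (q <= 1))


def test_linear_nu_boundaries():
    assert nu_of_i("linear", 1, 100) == pytest.approx(1.0)
    assert nu_of_i("linear", 100, 100) == pytest.approx(1 / 100)


def test_gaussian_nu_is_strictly_decreasing():
    i = np.arange(1, 201)
    nu = nu_of_i("gaussian", i, 200, width=80.0)
    assert np.all(np.diff(nu) < 0)


def test_unknown_profile_rejected():
    with pytest.raises(ValueError):
        q_of_i("quadratic", 1, 10)
    with pytest.raises(ValueError):
        DynamicsParams(q_profile="weird")


# ------------------------------------------------------------------- gain law

def test_gain_pmf_closed_form():
    assert gain_pmf(1.0, 0) == pytest.approx(0.5)
    assert gain_pmf(1.0, 1) == pytest.approx(0.25)
    assert gain_pmf(1e-9, 0) == pytest.approx(1.0)  # degenerate-mean limit
    with pytest.raises(ValueError):
        gain_pmf(0.0, 1)


def test_gain_pmf_mean_and_mass():
    k = np.arange(0, 5000)
    for mu in (0.1, 1.0, 10.0):
        p = gain_pmf(mu, k)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert float(k @ p) == pytest.approx(mu, rel=1e-9)


# ---------------------------------------------------------------- A1 matrix

def test_infection_matrix_identity_without_phage():
    params = DynamicsParams(**{**SMALL, "p": 0.0, "N": 20})
    assert np.allclose(build_infection_matrix(params), np.eye(20))


def test_infection_matrix_direct_entry():
    """With p=1, q=1, h=1, mu_n=1: the one-spacer-gain entry is
    p*q*h*P(1,1) = 1/4."""
    params = DynamicsParams(p=1.0, h=1.0, s=0.4, g=0.7, mu_n=1.0, mu_m=1.0,
                            mu_k=0.1, S_L=1 / 8, N=5,
                            q_profile="constant", q_params={"q": 1.0})
    A1 = build_infection_matrix(params)
    assert A1[1, 2] == pytest.approx(0.25)  # class 2 -> class 3


def test_infection_matrix_rows_substochastic():
    params = DynamicsParams(**SMALL)
    A1 = build_infection_matrix(params)
    rs = A1.sum(axis=1)
    assert np.all(rs <= 1 + 1e-12)
    assert np.all(A1 >= 0)


def test_death_probability_nonincreasing_in_q_when_ordered():
    """Under the survivor-conserving boundary, more immune classes never die
    more often as long as s <= g <= h."""
    params = DynamicsParams(p=0.8, h=0.9, s=0.2, g=0.5, mu_n=5, mu_m=5,
                            mu_k=0.05, S_L=0.1, N=30, boundary="accumulate")
    death = 1.0 - build_infection_matrix(params).sum(axis=1)
    assert np.all(np.diff(death) <= 1e-12)  # q_i increases with i


# ------------------------------------------------------- scaling, A2 matrix

def test_scaling_zero_when_no_deaths():
    F = np.full(10, 100.0)
    assert compute_scaling(F, np.ones(10), 1000.0) == 0.0


def test_scaling_one_daughter_per_survivor_at_half_population():
    F = np.full(10, 50.0)  # half of 1000 died
    assert compute_scaling(F, np.ones(10), 1000.0) == pytest.approx(1.0)


def test_scaling_rejects_extinct_population():
    with pytest.raises(ExtinctionError):
        compute_scaling(np.zeros(5), np.ones(5), 100.0)


def test_replication_matrix_identity_at_zero_scaling():
    params = DynamicsParams(**{**SMALL, "N": 20})
    assert np.allclose(build_replication_matrix(params, 0.0), np.eye(20))


def test_replication_row_sums_are_one_plus_nu():
    params = DynamicsParams(**{**SMALL, "N": 50})
    N_nu = 0.37
    A2 = build_replication_matrix(params, N_nu)
    expected = 1.0 + N_nu * params.nu_vector()
    assert np.allclose(A2.sum(axis=1), expected, rtol=1e-12)
    assert np.all(A2 >= 0)


def test_replication_small_loss_concentrates_on_diagonal():
    params = DynamicsParams(**{**SMALL, "N": 20, "S_L": 1e-6})
    A2 = build_replication_matrix(params, 1.0)
    off = A2 - np.diag(np.diag(A2))
    assert off.sum() < 1e-3  # P(mu_delta, 0) -> 1 as S_L -> 0


# ----------------------------------------------------------- full iteration

def test_population_is_conserved_every_iteration():
    params = DynamicsParams(**{**SMALL, "N": 50})
    A1 = build_infection_matrix(params)
    D = _loss_increment(params)
    nu = params.nu_vector()
    F = np.full(50, params.F_const / 50)
    for _ in range(100):
        F_half = F @ A1
        N_nu = compute_scaling(F_half, nu, params.F_const)
        F = F_half + N_nu * (F_half @ D)
        assert F.sum() == pytest.approx(params.F_const, rel=1e-9)


def test_everything_drains_to_class_one_without_gains():
    """With negligible gain means, daughters' spacer loss drags the whole
    population to the single-spacer class."""
    params = DynamicsParams(p=0.5, h=1.0, s=0.5, g=0.75,
                            mu_n=1e-6, mu_m=1e-6, mu_k=1e-6,
                            S_L=1 / 8, N=50,
                            q_profile="constant", q_params={"q": 0.5})
    res = iterate_to_stationarity(params)
    assert res.converged
    assert res.distribution[0] > 0.999


def test_extinction_is_reported():
    params = DynamicsParams(p=1.0, h=0.0, s=0.0, g=0.0, mu_n=1, mu_m=1,
                            mu_k=1, S_L=0.1, N=10)
    with pytest.raises(ExtinctionError, match="iteration"):
        iterate_to_stationarity(params)


# the full-iteration enumeration oracle lives in test_acceptance.py

# ------------------------------------------------------------- stationarity

def test_iteration_and_eigenvector_agree():
    params = DynamicsParams(**SMALL)
    it = iterate_to_stationarity(params)
    assert it.converged
    eig = stationary_eigen(params, it.N_nu_star)
    assert np.abs(eig.distribution - it.distribution).sum() < 1e-6


def test_eigen_degenerate_identity_chain_is_flagged():
    params = DynamicsParams(**{**SMALL, "p": 0.0, "N": 20})
    res = stationary_eigen(params, 0.0)
    assert res.degenerate
    assert not res.converged


def test_eigen_rejects_wrong_scaling():
    params = DynamicsParams(**{**SMALL, "N": 50})
    it = iterate_to_stationarity(params)
    with pytest.raises(ValueError, match="eigenvalue"):
        stationary_eigen(params, 3.0 * it.N_nu_star + 0.5)


def test_stationary_fit_is_deterministic():
    params = DynamicsParams(**{**SMALL, "N": 100})
    a = fit_stationary(iterate_to_stationarity(params))
    b = fit_stationary(iterate_to_stationarity(params))
    assert a.spec.params == b.spec.params


def test_init_state_must_match_population():
    params = DynamicsParams(**{**SMALL, "N": 10})
    bad = StateVector(F=np.ones(10))
    with pytest.raises(ValueError, match="F_const"):
        iterate_to_stationarity(params, init=bad)


# ------------------------------------------------------------------- sweeps

def test_sweep_empty_values_is_empty():
    assert sweep(DynamicsParams(**{**SMALL, "N": 20}), "S_L", []) == []


def test_sweep_records_per_point_errors_and_continues():
    params = DynamicsParams(**{**SMALL, "N": 50})
    recs = sweep(params, "S_L", [1.5, 1 / 8])  # 1.5 is outside (0, 1)
    assert recs[0]["error"] is not None
    assert recs[0]["fit"] is None
    assert recs[1]["error"] is None
    assert recs[1]["fit"] is not None


def test_sweep_unknown_parameter_rejected():
    with pytest.raises(ValueError, match="unknown parameter"):
        sweep(DynamicsParams(**{**SMALL, "N": 20}), "speed", [1.0])
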