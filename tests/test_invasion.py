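"""Unit and property tests for the serial-passage invasion simulator."""

import math

import numpy as np
import pytest
from scipy import stats

from mutspectra import (
    InvasionResult,
    PopulationState,
    SimulationParams,
    apply_lethal,
    bottleneck,
    equilibrate,
    estimate_s_eff,
    growth_rate,
    lethal_rate_estimate,
    mutate,
    recovery_generations,
    reproduce,
    round_to_sig,
    run_invasion,
)
from mutspectra.invasion import ExtinctError, deterministic_balance, replicate_s_eff

from conftest import scaled_params


# ---------------------------------------------------------------------------
# parameters and growth
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    dict(m=0.5),                      # mutator strength below 1
    dict(kappa=0.0),
    dict(s_d=0.0),
    dict(s_d=1.0),
    dict(u_d=1e-4, u_l=2e-4),         # lethal rate above deleterious rate
    dict(n_bottleneck=10, n_max=10),
    dict(kappa_target="beneficial"),
])
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationParams(**kwargs)


def test_growth_rate_formula():
    p = SimulationParams(s_d=0.064, kappa=1.0)
    assert growth_rate(0, p, "mutator") == 2.0
    assert growth_rate(0, p, "antimutator") == 2.0
    assert growth_rate(1, p, "mutator") == pytest.approx(1.936)

    p2 = SimulationParams(s_d=0.064, kappa=2.0)
    assert growth_rate(2, p2, "mutator") == pytest.approx(1.744)
    assert growth_rate(2, p2, "antimutator") == pytest.approx(1.872)
    # kappa applies only to the mutator background, and only when routed to s_d
    p3 = SimulationParams(s_d=0.064, kappa=2.0, kappa_target="lethal", u_l=1e-5)
    assert growth_rate(2, p3, "mutator") == pytest.approx(1.872)


def test_growth_rate_clamped_nonnegative():
    p = SimulationParams(s_d=0.5)
    assert growth_rate(1000, p, "mutator") == 0.0
    n = np.arange(10)
    r = growth_rate(n, p, "mutator")
    assert np.all(r >= 0) and np.all(np.diff(r) <= 0)


def test_reproduce_doubles_and_applies_cost():
    p = SimulationParams(s_d=0.5, kappa=1.0, class_cap=4)
    pop = PopulationState.empty(4)
    pop.mutator[0], pop.mutator[1] = 100.0, 100.0
    out = reproduce(pop, p)
    assert out.mutator[0] == 200.0
    assert out.mutator[1] == 150.0
    assert out.generation == 1

    # mutation-free class doubles exactly whatever s_d is
    pop2 = PopulationState.empty(4)
    pop2.antimutator[0] = 37.0
    assert reproduce(pop2, p).antimutator[0] == 74.0


def test_reproduce_near_zero_cost_doubles_every_class():
    p = SimulationParams(s_d=1e-12, class_cap=6)
    pop = PopulationState.empty(6)
    pop.mutator[:] = [10, 20, 30, 0, 5, 1, 2]
    out = reproduce(pop, p)
    np.testing.assert_allclose(out.mutator, 2 * pop.mutator, rtol=1e-9)


def test_reproduce_signals_total_extinction():
    p = SimulationParams(s_d=0.5, class_cap=6)
    pop = PopulationState.empty(6)
    pop.mutator[5] = 100.0      # growth rate 2 - 5*0.5 < 0 -> clamped to 0
    with pytest.raises(ExtinctError):
        reproduce(pop, p)


# ---------------------------------------------------------------------------
# mutation and lethality
# ---------------------------------------------------------------------------

def test_mutate_noop_without_mutation(rng):
    p = SimulationParams(u_d=0.0, class_cap=8)
    pop = PopulationState.empty(8)
    pop.mutator[0] = 1e6
    out = mutate(pop, p, rng)
    np.testing.assert_array_equal(out.mutator, pop.mutator)


def test_mutate_zero_class_survival_matches_poisson(rng):
    # class 0 retention ~ exp(-m u_d) = exp(-0.2)
    p = scaled_params(m=1000, u_d=2e-4, s_d=0.064)
    pop = PopulationState.empty(p.resolved_class_cap())
    pop.mutator[0] = 1e6
    out = mutate(pop, p, rng)
    assert out.mutator[0] / 1e6 == pytest.approx(math.exp(-0.2), abs=5e-3)
    assert out.total == pytest.approx(pop.total, rel=1e-9)


def test_mutate_antimutator_rate_is_basal(rng):
    # mean new mutations per individual = u_d regardless of m
    p = scaled_params(m=1000, u_d=2e-4, s_d=0.064)
    pop = PopulationState.empty(p.resolved_class_cap())
    pop.antimutator[0] = 1e7
    out = mutate(pop, p, rng)
    n = np.arange(out.antimutator.size)
    mean_new = float(out.antimutator @ n) / out.antimutator.sum()
    assert mean_new == pytest.approx(2e-4, rel=0.1)


def test_mutate_pools_overflow_in_top_class(rng):
    p = SimulationParams(m=1000, u_d=1.6e-3, s_d=0.064, class_cap=3)
    pop = PopulationState.empty(3)
    pop.mutator[3] = 1e6
    out = mutate(pop, p, rng)
    assert out.total == pytest.approx(1e6, rel=1e-9)
    assert out.mutator[3] == pytest.approx(1e6, rel=1e-9)


def test_apply_lethal_noop_and_expected_rate(rng):
    p0 = scaled_params(u_l=0.0)
    pop = PopulationState.empty(p0.resolved_class_cap())
    pop.mutator[0] = 1e6
    out = apply_lethal(pop, p0, rng)
    np.testing.assert_array_equal(out.mutator, pop.mutator)

    # expected removals = rate x size = m * u_l * size under deleterious routing
    p = scaled_params(m=300, u_d=2e-4, u_l=2e-6, kappa=1.0)
    pop = PopulationState.empty(p.resolved_class_cap())
    pop.mutator[0] = 1e6
    deaths = [1e6 - apply_lethal(pop, p, rng).mutator[0] for _ in range(200)]
    assert np.mean(deaths) == pytest.approx(300 * 2e-6 * 1e6, rel=0.05)


def test_lethal_kappa_routing_scales_rate():
    base = dict(m=300, u_d=2e-4, u_l=2e-6)
    p1 = SimulationParams(kappa=1.0, kappa_target="lethal", **base)
    p4 = SimulationParams(kappa=4.0, kappa_target="lethal", **base)
    assert p4.lethal_rate("mutator") == pytest.approx(4 * p1.lethal_rate("mutator"))
    # antimutator never sees kappa
    assert p4.lethal_rate("antimutator") == p1.lethal_rate("antimutator") == 2e-6
    # deleterious routing leaves the lethal rate alone
    p = SimulationParams(kappa=4.0, kappa_target="deleterious", **base)
    assert p.lethal_rate("mutator") == pytest.approx(300 * 2e-6)


# ---------------------------------------------------------------------------
# bottleneck and recovery
# ---------------------------------------------------------------------------

def test_bottleneck_returns_exact_integer_sample(rng):
    p = scaled_params()
    pop = PopulationState.empty(p.resolved_class_cap())
    pop.mutator[0] = 1e5
    out = bottleneck(pop, p, rng)
    assert out.total == 1000
    assert np.all(out.mutator == np.floor(out.mutator))


def test_bottleneck_splits_equal_classes_binomially(rng):
    p = SimulationParams(n_bottleneck=10_000_000, n_max=1e9)
    pop = PopulationState.empty(p.resolved_class_cap())
    pop.mutator[0] = pop.mutator[1] = 5e8
    out = bottleneck(pop, p, rng)
    sd = math.sqrt(1e7 * 0.25)
    assert abs(out.mutator[0] - 5e6) < 6 * sd


def test_bottleneck_requires_excess_population(rng):
    p = scaled_params()
    pop = PopulationState.empty(p.resolved_class_cap())
    pop.mutator[0] = 500.0
    with pytest.raises(ValueError):
        bottleneck(pop, p, rng)


def test_rare_class_survival_probability(rng):
    # 100 copies among 1e9 survive a 1e7 sample with p ~ 1 - exp(-1)
    p = SimulationParams(n_bottleneck=10_000_000, n_max=1e9)
    pop = PopulationState.empty(4)
    survived = 0
    trials = 400
    for _ in range(trials):
        pop.mutator[:] = 0.0
        pop.mutator[0], pop.mutator[1] = 1e9 - 100, 100.0
        survived += bottleneck(pop, p, rng).mutator[1] > 0
    expect = 1 - math.exp(-1)
    assert survived / trials == pytest.approx(expect, abs=4 * math.sqrt(expect * (1 - expect) / trials))


@pytest.mark.parametrize("nb,nm,expected", [
    (10_000_000, 1e9, 7),
    (10_000_000, 1.28e9, 7),
    (500, 1000, 1),
])
def test_recovery_generations(nb, nm, expected):
    assert recovery_generations(SimulationParams(n_bottleneck=nb, n_max=nm)) == expected


# ---------------------------------------------------------------------------
# equilibration and the deterministic recursion oracle
# ---------------------------------------------------------------------------

def _recursion_oracle(U, cost, cap, iters=40000):
    """Independent mutation-selection recursion (frequency space)."""
    n = np.arange(cap + 1)
    w = np.clip(2.0 - cost * n, 0, None)
    kmax = 30
    pmf = stats.poisson.pmf(np.arange(kmax + 1), U)
    f = np.zeros(cap + 1)
    f[0] = 1.0
    for _ in range(iters):
        a = f * w
        new = np.zeros_like(a)
        for k in range(kmax + 1):
            if pmf[k] < 1e-16:
                break
            new[k:] += pmf[k] * a[: cap + 1 - k]
            new[-1] += pmf[k] * a[cap + 1 - k:].sum()
        f = new / new.sum()
    return f


def test_deterministic_balance_matches_independent_recursion():
    p = SimulationParams(m=1000, u_d=2e-4, s_d=0.064, kappa=1.0)
    f = deterministic_balance(p)
    oracle = _recursion_oracle(0.2, 0.064, p.resolved_class_cap())
    n = np.arange(f.size)
    assert float(f @ n) == pytest.approx(float(oracle @ n), abs=1e-3)


def test_deterministic_step_matches_recursion_for_100_generations(rng):
    # expectation-mode growth+mutation, renormalized, equals the oracle path
    p = SimulationParams(m=300, u_d=4e-4, s_d=0.032, kappa=2.0, class_cap=60)
    pop = PopulationState.empty(60)
    pop.mutator[0] = 1.0
    n = np.arange(61)
    w = np.clip(2.0 - p.kappa * p.s_d * n, 0, None)
    pmf = stats.poisson.pmf(np.arange(31), p.m * p.u_d)
    f = np.zeros(61)
    f[0] = 1.0
    for _ in range(100):
        pop = mutate(reproduce(pop, p), p, rng, deterministic=True)
        a = f * w
        new = np.zeros(61)
        for k in range(31):
            new[k:] += pmf[k] * a[: 61 - k]
            new[-1] += pmf[k] * a[61 - k:].sum()
        f = new / new.sum()
    np.testing.assert_allclose(pop.mutator / pop.mutator.sum(), f, atol=1e-9)


def test_equilibrate_mutation_free_stays_unloaded(rng):
    p = scaled_params(u_d=0.0, u_l=0.0, burn_in_cycles=2)
    pop = equilibrate(p, rng)
    assert pop.mutator[0] == p.n_bottleneck
    assert pop.mutator[1:].sum() == 0


def test_equilibrate_mean_load_near_deterministic_balance(rng):
    p = scaled_params(m=1000, u_d=2e-4, s_d=0.064, n_bottleneck=10_000,
                      n_max=1_000_000.0, burn_in_cycles=0)
    pop = equilibrate(p, rng)
    n = np.arange(pop.mutator.size)
    mean_load = float(pop.mutator @ n) / pop.mutator.sum()
    oracle = _recursion_oracle(0.2, 0.064, p.resolved_class_cap())
    assert mean_load == pytest.approx(float(oracle @ n), abs=0.2)


# ---------------------------------------------------------------------------
# invasions and s_eff
# ---------------------------------------------------------------------------

def test_run_invasion_deterministic_under_seed():
    p = scaled_params(m=300, s_d=0.064, u_d=2e-4)
    r1 = run_invasion(p, 7)
    r2 = run_invasion(p, 7)
    np.testing.assert_array_equal(r1.p, r2.p)
    assert r1.outcome == r2.outcome and r1.founder_load == r2.founder_load


def test_run_invasion_frequencies_sum_to_one_and_absorb():
    p = scaled_params(m=300, s_d=0.064, u_d=2e-4)
    for seed in range(6):
        r = run_invasion(p, seed)
        np.testing.assert_allclose(r.p + r.q, 1.0, atol=1e-12)
        if r.outcome == "fixed":
            assert r.q[-1] == 0.0
        elif r.outcome == "lost":
            assert r.p[-1] == 0.0


def test_run_invasion_censors_at_max_generations():
    p = scaled_params(m=300, s_d=0.064, u_d=2e-4, max_generations=5)
    r = run_invasion(p, 3)
    assert r.outcome == "censored"
    assert r.generations[-1] == 5


def _traj(logratio, total=1e9):
    r = np.exp(np.asarray(logratio, dtype=float))
    p = r / (1 + r)
    g = np.arange(len(p))
    return InvasionResult(g, p, 1 - p, np.full(len(p), total), "censored", 0)


def test_replicate_s_eff_closed_forms():
    # constant ratio -> 0
    assert replicate_s_eff(_traj([math.log(0.02)] * 50)) == pytest.approx(0.0, abs=1e-12)
    # ratio doubling every 10 generations -> ln(2)/10
    lr = [math.log(1e-4) + math.log(2) * g / 10 for g in range(200)]
    assert replicate_s_eff(_traj(lr)) == pytest.approx(math.log(2) / 10, rel=1e-9)
    # endpoint form: p0/q0 = 1e-7/(1-1e-7), ratio 1 at g = 100
    lr = np.linspace(math.log(1e-7 / (1 - 1e-7)), 0.0, 101)
    assert replicate_s_eff(_traj(lr)) == pytest.approx(math.log(1e7) / 100, rel=1e-3)


def test_estimate_s_eff_flags_undefined():
    # every replicate lost immediately: no qualifying window
    g = np.arange(3)
    lost = InvasionResult(g, np.array([1e-3, 1e-4, 0.0]), np.array([0.999, 0.9999, 1.0]),
                          np.full(3, 1e3), "lost", 0)
    est = estimate_s_eff([lost, lost])
    assert not est.defined and est.n_used == 0
    assert math.isnan(est.mean)
    assert est.fixation_fraction == 0.0


def test_estimate_s_eff_reports_protocol_metadata():
    lr = np.linspace(math.log(1e-4), 1.0, 300)
    est = estimate_s_eff([_traj(lr)])
    assert est.n_used == 1 and est.defined
    assert "slope" in est.protocol["statistic"]


# ---------------------------------------------------------------------------
# closed-form helpers
# ---------------------------------------------------------------------------

def test_lethal_rate_estimate_and_rounding():
    # u_d scaled by essential genome fraction and inactivating fraction
    val = lethal_rate_estimate(2e-4)
    assert val == pytest.approx(2e-4 * 0.07 * 0.13)
    assert round_to_sig(val, 1) == pytest.approx(2e-6)
    assert round_to_sig(0.0) == 0.0
    assert round_to_sig(1234, 2) == 1200
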