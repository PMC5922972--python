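"""ATP-coupled rates, the R ratio, and energy depletion."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mitoclock.core_model import RateParams, hill_down, hill_up
from mitoclock.energy import (
    EnergyParams,
    EnergyState,
    active_fraction_cdc25,
    active_fraction_wee1,
    atp_R_curve,
    balance_ratio_R,
    default_c0,
    default_w0,
    depletion_cycle_table,
    gillespie_run_energy,
    propensities_energy,
    simulate_energy_depletion,
)
from mitoclock.stochastic import CountState, VolumeSpec, gillespie_run, propensities


def test_active_fraction_wee1_reference_points():
    for w0 in (0.2, 0.5, 0.8):
        assert active_fraction_wee1(0.5, w0) == pytest.approx(w0)
        assert active_fraction_wee1(1.0, w0) == pytest.approx(0.0)
        assert active_fraction_wee1(0.0, w0) == pytest.approx(1.0)


def test_active_fraction_cdc25_reference_points():
    for c0 in (0.2, 0.5, 0.8):
        assert active_fraction_cdc25(0.5, c0) == pytest.approx(c0)
        assert active_fraction_cdc25(0.0, c0) == pytest.approx(0.0)
        assert active_fraction_cdc25(1.0, c0) == pytest.approx(1.0)


def test_active_fraction_wee1_against_equilibrium_oracle():
    """Solve the phosphorylation equilibrium numerically for the same k1/k2.

    k1*f*A = k2*(1-f)*(1-A) with k1/k2 fixed by f(1/2) = w0 gives
    k1/k2 = (1-w0)/w0; the closed form must match the numeric root.
    """
    w0, A = 0.3, 0.25
    k_ratio = (1 - w0) / w0

    def balance(f):
        return k_ratio * f * A - (1 - f) * (1 - A)

    f_num = brentq(balance, 0.0, 1.0, xtol=1e-14)
    assert active_fraction_wee1(A, w0) == pytest.approx(f_num, rel=1e-10)


def test_active_fraction_monotonicity():
    A = np.linspace(0.0, 1.0, 101)
    fw = [active_fraction_wee1(a, 0.35) for a in A]
    fc = [active_fraction_cdc25(a, 0.35) for a in A]
    assert np.all(np.diff(fw) <= 0)
    assert np.all(np.diff(fc) >= 0)


def test_active_fraction_domain_errors():
    with pytest.raises(ValueError):
        active_fraction_wee1(1.5, 0.3)
    with pytest.raises(ValueError):
        active_fraction_cdc25(-0.1, 0.3)


def test_reference_identity_at_half_atp(default_params, omega50, rng):
    """At A = 1/2 the energy propensities equal the plain table exactly."""
    e = EnergyParams()
    for _ in range(1000):
        s = CountState(int(rng.integers(0, 5000)), int(rng.integers(0, 5000)))
        plain = propensities(s, default_params, omega50)
        energized = propensities_energy(s, default_params, e, omega50, atp_frac=0.5)
        assert np.array_equal(plain, energized)


def test_energy_limits(default_params, omega50):
    e = EnergyParams()
    s = CountState(800, 600)
    conc = s.n_cdk1a / omega50.omega
    base = propensities(s, default_params, omega50)
    at0 = propensities_energy(s, default_params, e, omega50, atp_frac=0.0)
    assert at0[2] == pytest.approx(0.0)  # no Cdc25 reactivation without ATP
    w0 = default_w0(conc, default_params)
    assert at0[1] == pytest.approx(base[1] / w0, rel=1e-9)  # Wee1 fully active
    at1 = propensities_energy(s, default_params, e, omega50, atp_frac=1.0)
    assert at1[1] == pytest.approx(0.0)  # no active Wee1 fully phosphorylated
    assert np.array_equal(at0[[0, 3, 4]], base[[0, 3, 4]])


def test_energy_multiplier_monotonicity(default_params, omega50):
    e = EnergyParams()
    s = CountState(800, 600)
    grid = np.linspace(0.05, 0.95, 19)
    rho = np.array([propensities_energy(s, default_params, e, omega50, atp_frac=a) for a in grid])
    assert np.all(np.diff(rho[:, 1]) <= 1e-12)  # Wee1 channel falls with A
    assert np.all(np.diff(rho[:, 2]) >= -1e-12)  # Cdc25 channel rises with A


def test_balance_ratio_R_reference_identity(default_params):
    """At A = 1/2, R reduces to the plain-model coefficient ratio."""
    e = EnergyParams()
    for conc in (5.0, 25.0, 40.0):
        for r in (0.8, 1.5):
            p = default_params.with_(r=r)
            expect = (
                np.sqrt(r) * hill_down(conc, p.a_wee1, p.b_wee1, p.n_wee1, p.ec50_wee1)
            ) / (hill_up(conc, p.a_cdc25, p.b_cdc25, p.n_cdc25, p.ec50_cdc25) / np.sqrt(r))
            assert balance_ratio_R(conc, p, e, atp_frac=0.5) == pytest.approx(expect, rel=1e-12)


def test_balance_ratio_R_rises_as_atp_falls(default_params):
    e = EnergyParams()
    assert balance_ratio_R(25.0, default_params, e, atp_frac=0.2) > balance_ratio_R(
        25.0, default_params, e, atp_frac=0.5
    )


def test_balance_ratio_R_defined_at_zero_counts(default_params, omega50):
    e = EnergyParams()
    val = balance_ratio_R(CountState(0, 0), default_params, e, omega50, atp_frac=0.5)
    assert np.isfinite(val) and val > 0


def test_energy_state_validation():
    s = EnergyState(1, 2, 30, 70)
    assert s.atp_frac == pytest.approx(0.3)
    with pytest.raises(ValueError):
        EnergyState(1, 2, -1, 5)
    with pytest.raises(ValueError):
        EnergyParams(atp_frac0=1.5)
    with pytest.raises(ValueError):
        EnergyParams(depletion_mode="bogus")
    with pytest.raises(ValueError):
        EnergyParams(depletion_mode="scheduled")


def test_depletion_conserves_pool_and_is_one_way(default_params, omega50):
    e = EnergyParams(depletion_mode="stoichiometric")
    run = simulate_energy_depletion(default_params, e, omega50, (0, 0), t_end=800.0, seed=5)
    assert run.atp_frac is not None
    assert np.all(np.diff(run.atp_frac) <= 1e-15)  # ATP only ever converts to ADP
    # ATP consumed reconciles with interconversion firings channel by channel
    n_atp0 = np.rint(e.atp_frac0 * e.pool)
    consumed = run.firing_counts[:, 1] + run.firing_counts[:, 2]
    assert np.allclose(run.atp_frac * e.pool, n_atp0 - consumed)


def test_schedule_pinned_at_half_matches_plain_run(default_params, omega50):
    """A schedule pinned at A = 1/2 reproduces the plain table bit-for-bit."""
    e = EnergyParams(
        depletion_mode="scheduled",
        schedule=(np.array([0.0]), np.array([0.5])),
    )
    dep = simulate_energy_depletion(default_params, e, omega50, (0, 0), t_end=600.0, seed=21)
    plain = gillespie_run(default_params, omega50, (0, 0), t_end=600.0, seed=21)
    assert np.array_equal(dep.n_cdk1a, plain.n_cdk1a)
    assert np.array_equal(dep.firing_counts, plain.firing_counts)


def test_depletion_eventually_arrests(default_params, omega50):
    """A small pool exhausts and oscillations stop well before t_end."""
    e = EnergyParams(atp_frac0=0.6, pool=600_000, depletion_mode="stoichiometric")
    run = simulate_energy_depletion(default_params, e, omega50, (0, 0), t_end=3000.0, seed=2)
    assert run.atp_frac[-1] < 0.05
    tot = (run.n_cdk1a + run.n_cdk1i).astype(float)
    late = tot[-500:]
    assert late.max() - late.min() < 0.2 * (tot.max() - tot.min())


def test_depletion_cycle_trend_single_seed(default_params, omega50):
    from scipy.stats import kendalltau

    e = EnergyParams(depletion_mode="stoichiometric")
    run = simulate_energy_depletion(default_params, e, omega50, (0, 0), t_end=2500.0, seed=1)
    tab = depletion_cycle_table(run)
    assert len(tab) >= 6
    for col in ("period_min", "amplitude", "baseline"):
        assert kendalltau(tab["cycle_index"], tab[col]).statistic > 0


def test_atp_R_curve_monotone_and_deterministic(default_params, omega50):
    e = EnergyParams()
    grid = [0.6, 0.5, 0.4]
    a = atp_R_curve(default_params, e, omega50, grid, n_reps=2, seed=9, t_end=500.0)
    b = atp_R_curve(default_params, e, omega50, grid, n_reps=2, seed=9, t_end=500.0)
    assert a.equals(b)
    assert np.all(np.diff(a["R_mean"].to_numpy()) > 0)  # R rises as A falls
    assert np.all(a["R_min"] <= a["R_mean"]) and np.all(a["R_mean"] <= a["R_max"])


def test_fixed_atp_run_records_constant_A(default_params, omega50):
    e = EnergyParams(atp_frac0=0.45)
    run = gillespie_run_energy(default_params, omega50, e, (0, 0), t_end=300.0, seed=4)
    assert np.all(run.atp_frac == 0.45)
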