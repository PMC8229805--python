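"""Coated-bubble dynamics tests: shell law, equation algebra, integration."""

import math

import numpy as np
import pytest

from cavigap.bubble import (
    AcousticDrive,
    GasModel,
    LiquidProperties,
    ShellModel,
    effective_surface_tension,
    equilibrium_internal_pressure,
    excursion_metrics,
    internal_pressure,
    minnaert_frequency,
    rp_rhs,
    simulate,
)

WATER = LiquidProperties()


def _undriven(f=1e6, duration=1e-4):
    return AcousticDrive(f=f, pnp=0.0, n_cycles=1,
                         rep_period=duration, total_duration=duration)


class TestEffectiveSurfaceTension:
    def test_vanishes_at_buckling_radius(self):
        shell = ShellModel(chi=0.5, R_buckling=1e-6)
        assert effective_surface_tension(1e-6, shell) == 0.0
        assert effective_surface_tension(0.5e-6, shell) == 0.0

    def test_elastic_branch_value(self):
        shell = ShellModel(chi=0.5, R_buckling=1e-6, R_breakup=5e-6)
        assert effective_surface_tension(math.sqrt(2) * 1e-6, shell) == pytest.approx(0.5)

    def test_broken_shell_is_bare_interface(self):
        shell = ShellModel(chi=0.5, R_buckling=1e-6, sigma_water=0.0725, broken=True)
        for r in (0.3e-6, 1e-6, 9e-6):
            assert effective_surface_tension(r, shell) == 0.0725

    def test_continuous_at_buckling_and_default_breakup(self):
        shell = ShellModel(chi=0.55, R_buckling=1e-6, sigma_water=0.072)
        eps = 1e-12
        rb = shell.R_buckling
        assert effective_surface_tension(rb + eps, shell) == pytest.approx(0.0, abs=1e-5)
        # default break-up radius is where the elastic branch meets sigma_water
        rbr = shell.R_breakup
        below = effective_surface_tension(rbr * (1 - 1e-9), shell)
        assert below == pytest.approx(shell.sigma_water, rel=1e-6)
        assert effective_surface_tension(rbr, shell) == shell.sigma_water

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            ShellModel(chi=0.5, R_buckling=2e-6, R_breakup=1e-6)


class TestInternalPressure:
    def test_equilibrium_definition(self):
        gas = GasModel(R0=2e-6, kappa=1.07, p_B0=1.5e5)
        assert internal_pressure(2e-6, gas) == pytest.approx(1.5e5)

    def test_isothermal_cube_law(self):
        gas = GasModel(R0=2e-6, kappa=1.0, p_B0=1e5)
        assert internal_pressure(1e-6, gas) == pytest.approx(8e5)

    def test_polytropic_exponent_via_log_identity(self):
        gas = GasModel(R0=1e-6, kappa=1.07, p_B0=1e5)
        got = internal_pressure(2e-6, gas)
        assert math.log2(got / 1e5) == pytest.approx(-3.21, abs=1e-12)

    def test_kappa_bounds(self):
        with pytest.raises(ValueError):
            GasModel(kappa=0.9)
        with pytest.raises(ValueError):
            GasModel(kappa=1.8)


class TestEquationAlgebra:
    def test_static_balance(self):
        """At R0 with p_B0 = p_inf + 2 sigma(R0)/R0 the acceleration vanishes."""
        shell = ShellModel(chi=0.55, R_buckling=0.8e-6)
        gas = GasModel(R0=1e-6, kappa=1.07,
                       p_B0=equilibrium_internal_pressure(GasModel(R0=1e-6), shell, WATER))
        rdot, rddot = rp_rhs(0.0, (1e-6, 0.0), WATER, shell, gas, _undriven())
        assert rdot == 0.0
        assert rddot == pytest.approx(0.0, abs=1e-4)  # m/s^2, vs ~1e12 typical scale

    def test_density_scaling_inviscid_tensionless(self):
        shell = ShellModel(chi=0.0, R_buckling=1.0)  # buckled everywhere: sigma = 0
        gas = GasModel(R0=1e-6, kappa=1.07, p_B0=2e5)
        inviscid = LiquidProperties(mu_L=1e-30)
        heavy = LiquidProperties(mu_L=1e-30, rho_L=2 * inviscid.rho_L)
        state = (1.3e-6, 0.0)  # zero velocity isolates the pressure term
        _, a1 = rp_rhs(0.0, state, inviscid, shell, gas, _undriven())
        _, a2 = rp_rhs(0.0, state, heavy, shell, gas, _undriven())
        assert a2 == pytest.approx(a1 / 2, rel=1e-12)

    def test_matches_symbolically_derived_form(self, rng):
        """R'' from the implementation equals an independent sympy solve of
        the radial momentum balance, on random states."""
        import sympy as sp

        R_, Rd_, Rdd_, rho, mu, sig, pb, pinf = sp.symbols(
            "R Rd Rdd rho mu sigma pb pinf", positive=True
        )
        eq = sp.Eq((pb - pinf) / rho,
                   R_ * Rdd_ + sp.Rational(3, 2) * Rd_**2 + 4 * mu * Rd_ / (rho * R_)
                   + 2 * sig / (rho * R_))
        rdd_expr = sp.solve(eq, Rdd_)[0]
        f = sp.lambdify((R_, Rd_, rho, mu, sig, pb, pinf), rdd_expr, "math")

        shell = ShellModel(chi=0.55, R_buckling=1e-6)
        gas = GasModel(R0=1e-6, kappa=1.07, p_B0=1.2e5)
        drive = AcousticDrive(f=1e6, pnp=0.3e6, n_cycles=10, rep_period=1e-5, total_duration=1e-5)
        for _ in range(50):
            r = float(rng.uniform(0.3e-6, 3e-6))
            rd = float(rng.uniform(-50.0, 50.0))
            t = float(rng.uniform(0.0, 1e-5))
            _, got = rp_rhs(t, (r, rd), WATER, shell, gas, drive)
            sig_val = effective_surface_tension(r, shell)
            pb_val = internal_pressure(r, gas)
            pinf_val = WATER.p_ambient - drive.pnp * math.sin(2 * math.pi * drive.f * t)
            want = f(r, rd, WATER.rho_L, WATER.mu_L, sig_val, pb_val, pinf_val)
            assert got == pytest.approx(want, rel=1e-10)

    def test_nonfinite_state_rejected(self):
        shell, gas = ShellModel(), GasModel(p_B0=1e5)
        with pytest.raises(FloatingPointError):
            rp_rhs(0.0, (float("nan"), 0.0), WATER, shell, gas, _undriven())


class TestSimulation:
    def test_equilibrium_persists_100_cycles(self):
        shell = ShellModel(chi=0.55, R_buckling=0.9e-6)
        gas = GasModel(R0=1e-6, kappa=1.07)  # p_B0 auto-set for equilibrium
        traj = simulate(WATER, shell, gas, _undriven(), (0.0, 100e-6))
        assert np.abs(traj.R / gas.R0 - 1).max() < 1e-3
        assert not traj.collapsed

    def test_convergence_under_tolerance_halving(self):
        shell = ShellModel(chi=0.55, R_buckling=1e-6)
        gas = GasModel(R0=1e-6, kappa=1.07)
        drive = AcousticDrive(f=1e6, pnp=0.05e6, n_cycles=10, rep_period=1e-5, total_duration=1e-5)
        t1 = simulate(WATER, shell, gas, drive, (0.0, 1e-5), rtol=1e-8, atol=1e-12)
        t2 = simulate(WATER, shell, gas, drive, (0.0, 1e-5), rtol=5e-9, atol=5e-13)
        assert np.abs(t1.R - t2.R).max() / gas.R0 < 1e-3

    def test_breakup_latches_permanently(self):
        shell = ShellModel(chi=0.55, R_buckling=1e-6)
        gas = GasModel(R0=1e-6, kappa=1.07)
        drive = AcousticDrive(f=1e6, pnp=0.3e6, n_cycles=10, rep_period=1e-5, total_duration=1e-5)
        traj = simulate(WATER, shell, gas, drive, (0.0, 1e-5))
        broken = np.flatnonzero(traj.state == 2)
        assert broken.size > 0, "drive should break the shell"
        first = broken[0]
        assert (traj.state[first:] == 2).all()
        assert np.allclose(traj.sigma[first:], shell.sigma_water)

    def test_ringing_matches_minnaert_oracle(self):
        """1% radial perturbation of an uncoated, inviscid, tensionless
        bubble rings within 2% of the Minnaert closed form."""
        inviscid = LiquidProperties(mu_L=1e-9)
        shell = ShellModel(chi=0.0, R_buckling=1.0)  # sigma = 0 for any R
        gas = GasModel(R0=3e-6, kappa=1.4)
        f0 = minnaert_frequency(3e-6, gas, inviscid)
        traj = simulate(inviscid, shell, gas, _undriven(f=f0, duration=30 / f0),
                        (0.0, 30 / f0), R_init=1.01 * 3e-6, samples_per_cycle=200)
        f_meas = _zero_crossing_frequency(traj.t, traj.R - 3e-6)
        assert f_meas == pytest.approx(f0, rel=0.02)

    def test_shell_elasticity_stiffens_resonance(self):
        """chi > 0 shifts the small-amplitude ringing frequency upward.

        The buckling radius sits below the oscillation range so the whole
        ring-down stays on the smooth elastic branch.
        """
        inviscid = LiquidProperties(mu_L=1e-9)
        gas = GasModel(R0=3e-6, kappa=1.4)  # p_B0 auto-set per shell
        f0 = minnaert_frequency(3e-6, gas, inviscid)
        span = (0.0, 15 / f0)
        bare = ShellModel(chi=0.0, R_buckling=1.0)
        coated = ShellModel(chi=0.5, R_buckling=2.8e-6, R_breakup=30e-6)
        freqs = []
        for shell in (bare, coated):
            traj = simulate(inviscid, shell, gas, _undriven(f=f0, duration=span[1]),
                            span, R_init=1.01 * 3e-6, samples_per_cycle=200)
            freqs.append(_zero_crossing_frequency(traj.t, traj.R - 3e-6))
        assert freqs[1] > freqs[0]

    def test_minnaert_worked_value_and_scalings(self):
        gas = GasModel(R0=3e-6, kappa=1.4)
        f0 = minnaert_frequency(3e-6, gas, LiquidProperties(rho_L=998.0))
        assert f0 == pytest.approx(1.10e6, rel=0.01)
        assert minnaert_frequency(6e-6, gas, WATER) == pytest.approx(
            minnaert_frequency(3e-6, gas, WATER) / 2)
        high_p = LiquidProperties(p_ambient=4 * WATER.p_ambient)
        assert minnaert_frequency(3e-6, gas, high_p) == pytest.approx(
            2 * minnaert_frequency(3e-6, gas, WATER))


class TestExcursionMetrics:
    def test_undriven_equilibrium_ratio_is_one(self):
        shell = ShellModel(chi=0.55, R_buckling=0.9e-6)
        gas = GasModel(R0=1e-6)
        traj = simulate(WATER, shell, gas, _undriven(), (0.0, 2e-5))
        rmax, rmin, ratio, collapsed = excursion_metrics(traj)
        assert ratio == pytest.approx(1.0, abs=1e-3)
        assert not collapsed

    def test_extrema_bracket_equilibrium(self):
        shell = ShellModel(chi=0.55, R_buckling=1e-6)
        gas = GasModel(R0=1e-6)
        drive = AcousticDrive(f=1e6, pnp=0.05e6, n_cycles=10, rep_period=1e-5, total_duration=1e-5)
        traj = simulate(WATER, shell, gas, drive, (0.0, 1e-5))
        rmax, rmin, _, _ = excursion_metrics(traj)
        assert rmin <= gas.R0 <= rmax

    def test_expansion_ratio_monotone_in_pressure(self):
        ratios = []
        for pnp in (0.1e6, 0.4e6, 0.72e6):
            shell = ShellModel(chi=0.55, R_buckling=1e-6)
            gas = GasModel(R0=1e-6, kappa=1.07)
            drive = AcousticDrive(f=1e6, pnp=pnp, n_cycles=20,
                                  rep_period=2e-5, total_duration=2e-5)
            traj = simulate(WATER, shell, gas, drive, (0.0, 2e-5))
            ratios.append(excursion_metrics(traj, transient_skip_frac=0.25)[2])
        assert ratios[0] < ratios[1] < ratios[2]


def _zero_crossing_frequency(t: np.ndarray, x: np.ndarray) -> float:
    up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    assert up.size >= 3, "too few oscillations to estimate a frequency"
    tz = t[up]
    return (tz.size - 1) / (tz[-1] - tz[0])
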