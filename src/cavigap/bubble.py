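"""Coated-microbubble radial dynamics.

A lipid-shelled contrast-agent bubble (SonoVue-like) driven by an
ultrasound burst is modelled with the Rayleigh-Plesset equation

    (p_B - p_Linf)/rho_L = R R'' + (3/2) R'^2 + 4 mu_L R'/(rho_L R)
                           + 2 sigma(R)/(rho_L R)

closed by a polytropic gas law p_B = p_B0 (R0/R)^{3 kappa} and the
piecewise effective surface tension of the buckled/elastic/broken shell:

    sigma(R) = 0                                   R <= R_buckling
             = chi (R^2/R_buckling^2 - 1)          R_buckling <= R <= R_breakup
             = sigma_water                         after break-up (latched)

The shell stays buckled (tensionless) below the buckling radius, behaves
as a 2-D elastic membrane of modulus chi above it, and once the radius
ever exceeds the break-up radius the coating ruptures permanently,
exposing a clean gas/water interface.  No radiation damping term is
included: the liquid is incompressible apart from the viscous term.

Default shell parameters are external literature values for SonoVue-type
phospholipid shells (chi ~ 0.55 N/m, sigma_water ~ 0.072 N/m); they are
placeholders to be overridden with values characterised for the actual
agent and preparation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "LiquidProperties",
    "ShellModel",
    "GasModel",
    "AcousticDrive",
    "Trajectory",
    "effective_surface_tension",
    "internal_pressure",
    "acoustic_pressure",
    "rp_rhs",
    "simulate",
    "minnaert_frequency",
    "excursion_metrics",
]

STATE_BUCKLED = 0
STATE_ELASTIC = 1
STATE_BROKEN = 2

_STATE_NAMES = {STATE_BUCKLED: "buckled", STATE_ELASTIC: "elastic", STATE_BROKEN: "broken"}


@dataclass(frozen=True)
class LiquidProperties:
    """Host liquid: density, viscosity, static pressure, clean surface
    tension and sound speed (the latter only used by intensity relations)."""

    rho_L: float = 998.0        # kg/m^3
    mu_L: float = 1.0e-3        # Pa s
    p_ambient: float = 101325.0  # Pa
    sigma_water: float = 0.072   # N/m
    c_sound: float = 1482.0      # m/s

    def __post_init__(self) -> None:
        for name in ("rho_L", "mu_L", "p_ambient", "sigma_water", "c_sound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ShellModel:
    """Phospholipid-monolayer shell state.

    R_buckling = sqrt(A_buckling/pi) is set by the number of lipid
    molecules on the interface; chi is the shell elastic modulus.  If
    R_breakup is omitted it defaults to the radius where the elastic
    branch reaches sigma_water, R_buckling*sqrt(1 + sigma_water/chi),
    which makes sigma(R) continuous at break-up.
    """

    chi: float = 0.55            # N/m, literature value for SonoVue-type shells
    R_buckling: float = 1.0e-6   # m
    R_breakup: float | None = None
    sigma_water: float = 0.072   # N/m
    broken: bool = False

    def __post_init__(self) -> None:
        if self.chi < 0:
            raise ValueError("chi must be >= 0")
        if self.R_buckling <= 0:
            raise ValueError("R_buckling must be positive")
        if self.R_breakup is None:
            if self.chi > 0:
                self.R_breakup = self.R_buckling * math.sqrt(1.0 + self.sigma_water / self.chi)
            else:
                self.R_breakup = math.inf
        if not self.R_buckling < self.R_breakup:
            raise ValueError("require 0 < R_buckling < R_breakup")


@dataclass(frozen=True)
class GasModel:
    """Polytropic gas core: p_B = p_B0 (R0/R)^{3 kappa}.

    kappa = 1.07 by default (near-isothermal heavy inert gas such as SF6);
    kappa in [1, 5/3].
    """

    R0: float = 1.0e-6    # m
    kappa: float = 1.07
    p_B0: float | None = None  # Pa; if None, set by `simulate` for equilibrium

    def __post_init__(self) -> None:
        if not (1.0 <= self.kappa <= 5.0 / 3.0 + 1e-12):
            raise ValueError("kappa must lie in [1, 5/3]")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.p_B0 is not None and self.p_B0 <= 0:
            raise ValueError("p_B0 must be positive")


@dataclass(frozen=True)
class AcousticDrive:
    """Rectangular-envelope sinusoidal burst train.

    Inside a burst p_Linf(t) = p_ambient - pnp*sin(2 pi f t) so the first
    half-cycle is rarefaction; between bursts p_Linf = p_ambient.
    """

    f: float = 1.0e6          # Hz
    pnp: float = 0.0          # Pa
    n_cycles: int = 500
    rep_period: float = 50e-3  # s
    total_duration: float = 30.0  # s
    phase: float = 0.0        # rad, added to 2*pi*f*t

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("f must be positive")
        if self.pnp < 0:
            raise ValueError("pnp must be >= 0")
        if self.n_cycles / self.f > self.rep_period * (1 + 1e-12):
            raise ValueError("burst longer than repetition period")

    @property
    def burst_duration(self) -> float:
        return self.n_cycles / self.f


def effective_surface_tension(R: float, shell: ShellModel) -> float:
    """Marmottant-style piecewise effective surface tension sigma(R)."""
    if R <= 0:
        raise ValueError("R must be positive")
    if shell.broken:
        return shell.sigma_water
    if R <= shell.R_buckling:
        return 0.0
    if R >= shell.R_breakup:
        return shell.sigma_water
    return shell.chi * (R * R / (shell.R_buckling * shell.R_buckling) - 1.0)


def internal_pressure(R: float, gas: GasModel) -> float:
    """Polytropic internal gas pressure p_B = p_B0 (R0/R)^{3 kappa}."""
    if R <= 0:
        raise ValueError("R must be positive")
    if gas.p_B0 is None:
        raise ValueError("gas.p_B0 is unset; call simulate() or set it explicitly")
    return gas.p_B0 * (gas.R0 / R) ** (3.0 * gas.kappa)


def acoustic_pressure(t: float, drive: AcousticDrive, p_ambient: float) -> float:
    """Far-field liquid pressure p_Linf(t) for a burst train."""
    if drive.pnp == 0.0:
        return p_ambient
    t_in = t % drive.rep_period
    if t >= drive.total_duration or t_in > drive.burst_duration:
        return p_ambient
    return p_ambient - drive.pnp * math.sin(2.0 * math.pi * drive.f * t_in + drive.phase)


def rp_rhs(
    t: float,
    state: tuple[float, float] | np.ndarray,
    liquid: LiquidProperties,
    shell: ShellModel,
    gas: GasModel,
    drive: AcousticDrive,
) -> tuple[float, float]:
    """Right-hand side (R', R'') of the shelled Rayleigh-Plesset equation."""
    R, Rdot = float(state[0]), float(state[1])
    if not (math.isfinite(R) and math.isfinite(Rdot)):
        raise FloatingPointError(f"non-finite bubble state at t={t}: {state}")
    if R <= 0:
        raise ValueError(f"non-positive radius at t={t}")
    sigma = effective_surface_tension(R, shell)
    p_b = internal_pressure(R, gas)
    p_inf = acoustic_pressure(t, drive, liquid.p_ambient)
    rddot = (
        (p_b - p_inf) / liquid.rho_L
        - 1.5 * Rdot * Rdot
        - 4.0 * liquid.mu_L * Rdot / (liquid.rho_L * R)
        - 2.0 * sigma / (liquid.rho_L * R)
    ) / R
    return Rdot, rddot


def equilibrium_internal_pressure(gas: GasModel, shell: ShellModel, liquid: LiquidProperties) -> float:
    """p_B0 = p_ambient + 2 sigma(R0)/R0, making R0 a true rest state."""
    return liquid.p_ambient + 2.0 * effective_surface_tension(gas.R0, shell) / gas.R0


@dataclass
class Trajectory:
    """Sampled radial trajectory with the shell state history."""

    t: np.ndarray
    R: np.ndarray
    Rdot: np.ndarray
    sigma: np.ndarray
    state: np.ndarray  # int codes: 0 buckled, 1 elastic, 2 broken
    R0: float
    collapsed: bool = False

    def state_names(self) -> list[str]:
        return [_STATE_NAMES[int(s)] for s in self.state]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "R": self.R,
                "Rdot": self.Rdot,
                "sigma": self.sigma,
                "state": self.state_names(),
            }
        )


def _classify_state(R: np.ndarray, shell: ShellModel, broken_from: float | None, t: np.ndarray) -> np.ndarray:
    codes = np.where(R <= shell.R_buckling, STATE_BUCKLED, STATE_ELASTIC)
    if broken_from is not None:
        codes[t >= broken_from] = STATE_BROKEN
    return codes


def simulate(
    liquid: LiquidProperties,
    shell: ShellModel,
    gas: GasModel,
    drive: AcousticDrive,
    t_span: tuple[float, float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
    samples_per_cycle: int = 50,
    R_init: float | None = None,
    Rdot_init: float = 0.0,
    collapse_floor_frac: float = 0.01,
    method: str = "Radau",
) -> Trajectory:
    """Integrate the shelled Rayleigh-Plesset equation over ``t_span``.

    The stiff solver (Radau by default) integrates in segments: when the
    radius first reaches the shell break-up radius the shell is latched
    broken and integration restarts with sigma = sigma_water.  A collapse
    below ``collapse_floor_frac * R0`` truncates the trajectory and sets
    ``collapsed`` instead of raising.

    If ``gas.p_B0`` is unset it is initialised to the equilibrium value
    p_ambient + 2 sigma(R0)/R0 so that an undriven bubble stays at R0.
    """
    shell = replace(shell)  # do not mutate the caller's shell state
    if gas.p_B0 is None:
        gas = replace(gas, p_B0=equilibrium_internal_pressure(gas, shell, liquid))
    # atol is the radius tolerance (m); the velocity component gets the
    # matching scale atol*f (one radius tolerance per drive period)
    atol_vec = np.array([atol, atol * drive.f])

    t0, t1 = t_span
    n_samples = max(2, int(round((t1 - t0) * drive.f * samples_per_cycle)) + 1)
    t_eval = np.linspace(t0, t1, n_samples)
    y0 = np.array([gas.R0 if R_init is None else R_init, Rdot_init], float)
    floor = collapse_floor_frac * gas.R0

    def rhs(t, y):
        return rp_rhs(t, y, liquid, shell, gas, drive)

    def ev_breakup(t, y):
        return y[0] - shell.R_breakup

    ev_breakup.terminal = True
    ev_breakup.direction = 1

    def ev_collapse(t, y):
        return y[0] - floor

    ev_collapse.terminal = True
    ev_collapse.direction = -1

    ts: list[np.ndarray] = []
    Rs: list[np.ndarray] = []
    Rds: list[np.ndarray] = []
    broken_from: float | None = None
    collapsed = False
    t_cur, y_cur = t0, y0
    remaining = t_eval

    for _ in range(4):  # at most: elastic -> broken (+ safety margin)
        events = [ev_collapse] if shell.broken or not math.isfinite(shell.R_breakup) else [ev_breakup, ev_collapse]
        te = remaining[remaining >= t_cur]
        sol = solve_ivp(
            rhs,
            (t_cur, t1),
            y_cur,
            method=method,
            rtol=rtol,
            atol=atol_vec,
            t_eval=te if te.size else None,
            events=events,
            dense_output=False,
            max_step=1.0 / drive.f / 4.0,
        )
        if not sol.success and sol.status != 1:
            warnings.warn(f"integration truncated: {sol.message}", stacklevel=2)
            collapsed = True
        ts.append(sol.t)
        Rs.append(sol.y[0])
        Rds.append(sol.y[1])
        if sol.status != 1:  # reached t1 (or failed)
            break
        # an event fired
        hit_breakup = not shell.broken and len(sol.t_events[0]) > 0
        t_ev_idx = 0 if hit_breakup else (1 if not shell.broken else 0)
        t_ev = sol.t_events[t_ev_idx][0]
        y_ev = sol.y_events[t_ev_idx][0]
        if hit_breakup:
            shell.broken = True
            broken_from = t_ev
            t_cur, y_cur = t_ev, y_ev
            continue
        collapsed = True  # collapse event
        break

    t_arr = np.concatenate(ts) if ts else np.array([t0])
    R_arr = np.concatenate(Rs) if Rs else np.array([y0[0]])
    Rd_arr = np.concatenate(Rds) if Rds else np.array([y0[1]])
    # de-duplicate the restart sample
    keep = np.concatenate(([True], np.diff(t_arr) > 0))
    t_arr, R_arr, Rd_arr = t_arr[keep], R_arr[keep], Rd_arr[keep]

    state = _classify_state(R_arr, shell, broken_from, t_arr)
    sig = np.empty_like(R_arr)
    for i, (r, st) in enumerate(zip(R_arr, state)):
        probe = replace(shell, broken=bool(st == STATE_BROKEN))
        sig[i] = effective_surface_tension(float(r), probe)
    return Trajectory(t=t_arr, R=R_arr, Rdot=Rd_arr, sigma=sig, state=state, R0=gas.R0, collapsed=collapsed)


def minnaert_frequency(R0: float, gas: GasModel, liquid: LiquidProperties) -> float:
    """Minnaert resonance f0 = (1/2 pi R0) sqrt(3 kappa p_ambient / rho_L).

    Surface-tension-free linearisation of the free gas bubble; used as an
    independent oracle for the small-amplitude ringing frequency.
    """
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    return math.sqrt(3.0 * gas.kappa * liquid.p_ambient / liquid.rho_L) / (2.0 * math.pi * R0)


def excursion_metrics(
    traj: Trajectory, transient_skip_frac: float = 0.0
) -> tuple[float, float, float, bool]:
    """(R_max, R_min, expansion_ratio, collapsed) over the trajectory tail.

    ``transient_skip_frac`` drops that initial fraction of the time span
    before taking extrema, so start-up transients can be excluded.
    """
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    t_start = traj.t[0] + transient_skip_frac * (traj.t[-1] - traj.t[0])
    sel = traj.t >= t_start
    r = traj.R[sel]
    return float(r.max()), float(r.min()), float(r.max() / traj.R0), traj.collapsed
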