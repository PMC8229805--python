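"""Ultrasound dose and microfluidic design calculators.

Pure arithmetic around an insonation protocol: burst/pulse bookkeeping
(pulse duration, repetition frequency, duty cycle), the clinical safety
indices MI and TI, the plane-wave pressure-to-intensity correspondence,
and the hemodynamics of the perfused channel (mean velocity, wall shear
stress for slit and exact rectangular-duct profiles, capillary Poiseuille
relations) plus the insonation-chamber volume.

Units are carried in argument names (`_MHz`, `_uL_min`, `_dyn_cm2`, ...);
internally everything is converted to SI before computing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "ExposureScheme",
    "PulseReport",
    "DoseReport",
    "ChannelGeometry",
    "pulse_report",
    "mechanical_index",
    "thermal_index",
    "plane_wave_intensity",
    "mean_channel_velocity",
    "capillary_velocity_from_shear",
    "capillary_shear_from_velocity",
    "rect_wall_shear",
    "box_volume",
    "classify_safety",
]

# clinical window for therapeutic/diagnostic insonation frequency
_F_CLINICAL_MHZ = (0.3, 3.0)
# safety-class boundaries for MI/TI
_SAFE_INDEX = 1.0
_FDA_MI_LIMIT = 1.9

DYN_CM2_PER_PA = 10.0  # 1 Pa = 10 dyn/cm^2


@dataclass(frozen=True)
class ExposureScheme:
    """A rectangular-envelope burst exposure.

    Parameters
    ----------
    f_MHz : centre frequency in MHz.  Values outside the 0.3-3 MHz
        clinical window trigger a warning (not an error).
    pnp_MPa : peak negative pressure of the burst, MPa.
    n_cycles : sine cycles per burst.
    rep_period_s : burst repetition period, s.
    total_duration_s : total insonation time, s.
    """

    f_MHz: float
    pnp_MPa: float
    n_cycles: int
    rep_period_s: float
    total_duration_s: float

    def __post_init__(self) -> None:
        for name in ("f_MHz", "pnp_MPa", "n_cycles", "rep_period_s", "total_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (_F_CLINICAL_MHZ[0] < self.f_MHz < _F_CLINICAL_MHZ[1]):
            warnings.warn(
                f"centre frequency {self.f_MHz} MHz is outside the "
                f"{_F_CLINICAL_MHZ[0]}-{_F_CLINICAL_MHZ[1]} MHz clinical window",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PulseReport:
    """Derived pulse arithmetic for an :class:`ExposureScheme`."""

    PD_s: float
    PRF_Hz: float
    DC: float  # duty cycle as a fraction in (0, 1]
    n_pulses: int
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class DoseReport:
    """Safety indices and intensity for an exposure."""

    MI: float
    TI: float
    intensity_W_cm2: float
    safety_class: str


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular duct (width x height) or circular capillary (diameter).

    Exactly one of (width_um, height_um) / diameter_um describes the
    cross-section.  Flow rate in uL/min, viscosity in mPa s (= cP).
    """

    flow_rate_uL_min: float
    width_um: float | None = None
    height_um: float | None = None
    diameter_um: float | None = None
    viscosity_mPa_s: float = 1.0

    def __post_init__(self) -> None:
        rect = self.width_um is not None and self.height_um is not None
        circ = self.diameter_um is not None
        if rect == circ:
            raise ValueError("specify either width_um+height_um or diameter_um")
        for name in ("flow_rate_uL_min", "width_um", "height_um", "diameter_um", "viscosity_mPa_s"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def is_rectangular(self) -> bool:
        return self.diameter_um is None

    @property
    def section_m2(self) -> float:
        if self.is_rectangular:
            return (self.width_um * 1e-6) * (self.height_um * 1e-6)
        r = self.diameter_um * 1e-6 / 2.0
        return math.pi * r * r

    @property
    def flow_rate_m3_s(self) -> float:
        return self.flow_rate_uL_min * 1e-9 / 60.0


def pulse_report(scheme: ExposureScheme) -> PulseReport:
    """Pulse duration, PRF, duty cycle and pulse count of a burst scheme.

    PD = n_cycles/f, PRF = 1/rep_period, DC = PD*PRF,
    n_pulses = floor(total_duration * PRF).  Raises if bursts would
    overlap (PD > rep_period).
    """
    f_hz = scheme.f_MHz * 1e6
    pd = scheme.n_cycles / f_hz
    if pd > scheme.rep_period_s * (1 + 1e-12):
        raise ValueError(
            f"pulse duration {pd:.3g} s exceeds repetition period "
            f"{scheme.rep_period_s:.3g} s (overlapping bursts)"
        )
    prf = 1.0 / scheme.rep_period_s
    dc = pd * prf
    n_pulses = math.floor(scheme.total_duration_s * prf + 1e-9)
    return PulseReport(PD_s=pd, PRF_Hz=prf, DC=dc, n_pulses=n_pulses)


def mechanical_index(pnp_MPa: float, f_MHz: float) -> float:
    """MI = peak negative pressure (MPa) / sqrt(centre frequency (MHz))."""
    if pnp_MPa < 0 or f_MHz <= 0:
        raise ValueError("pnp_MPa must be >= 0 and f_MHz > 0")
    return pnp_MPa / math.sqrt(f_MHz)


def thermal_index(W_p: float, W_deg: float) -> float:
    """TI = acoustic power at target / power raising tissue temperature 1 degC."""
    if W_deg <= 0:
        raise ValueError(f"W_deg must be positive, got {W_deg}")
    return W_p / W_deg


def plane_wave_intensity(pnp_Pa: float, rho: float = 998.0, c: float = 1482.0) -> float:
    """Time-averaged plane-wave intensity I = p^2/(2 rho c), in W/cm^2.

    Defaults are water at body-temperature-ish conditions
    (rho = 998 kg/m^3, c = 1482 m/s).
    """
    if pnp_Pa < 0 or rho <= 0 or c <= 0:
        raise ValueError("inputs must be positive (pnp_Pa >= 0)")
    i_w_m2 = pnp_Pa**2 / (2.0 * rho * c)
    return i_w_m2 * 1e-4


def mean_channel_velocity(geom: ChannelGeometry) -> float:
    """Mean velocity V = Q/S in mm/s for a rectangular duct."""
    if not geom.is_rectangular:
        raise ValueError("mean_channel_velocity expects a rectangular geometry")
    return geom.flow_rate_m3_s / geom.section_m2 * 1e3


def capillary_velocity_from_shear(
    tau_dyn_cm2: float, diameter_um: float, mu_mPa_s: float = 1.0
) -> float:
    """Mean Poiseuille velocity (mm/s) in a capillary of given wall shear.

    For fully developed Poiseuille flow tau_wall = 4 mu V / R, hence
    V = tau R / (4 mu) with R the capillary radius.
    """
    if min(tau_dyn_cm2, diameter_um, mu_mPa_s) <= 0:
        raise ValueError("all inputs must be positive")
    tau_pa = tau_dyn_cm2 / DYN_CM2_PER_PA
    r_m = diameter_um * 1e-6 / 2.0
    mu = mu_mPa_s * 1e-3
    return tau_pa * r_m / (4.0 * mu) * 1e3


def capillary_shear_from_velocity(
    v_mm_s: float, diameter_um: float, mu_mPa_s: float = 1.0
) -> float:
    """Wall shear stress (dyn/cm^2) from mean capillary velocity; inverse of
    :func:`capillary_velocity_from_shear`."""
    if min(v_mm_s, diameter_um, mu_mPa_s) <= 0:
        raise ValueError("all inputs must be positive")
    r_m = diameter_um * 1e-6 / 2.0
    mu = mu_mPa_s * 1e-3
    tau_pa = 4.0 * mu * (v_mm_s * 1e-3) / r_m
    return tau_pa * DYN_CM2_PER_PA


def rect_wall_shear(
    geom: ChannelGeometry,
    method: Literal["slit", "series"] = "slit",
    n_terms: int = 50,
) -> float:
    """Wall shear stress (dyn/cm^2) on the wide wall of a rectangular duct.

    method="slit" uses the infinite-parallel-plate closure
    tau = 6 mu Q / (w h^2) with h the smaller dimension -- an upper bound
    that ignores side-wall drag.  method="series" evaluates the exact
    rectangular-duct Fourier series at the wide-wall midpoint, where the
    shear is maximal on that wall.
    """
    if not geom.is_rectangular:
        raise ValueError("rect_wall_shear expects a rectangular geometry")
    mu = geom.viscosity_mPa_s * 1e-3
    q = geom.flow_rate_m3_s
    w = max(geom.width_um, geom.height_um) * 1e-6
    h = min(geom.width_um, geom.height_um) * 1e-6
    if method == "slit":
        tau_pa = 6.0 * mu * q / (w * h * h)
    elif method == "series":
        # Exact solution for pressure-driven flow in a w x h duct (h <= w):
        #   Q = (h^3 w G / 12 mu) * [1 - sum_{n odd} 192 h/(pi^5 n^5 w) tanh(n pi w / 2h)]
        #   du/dz|wall,midpoint = (4 h G / pi^2 mu) sum_{n odd} n^-2 [1 - sech(n pi w / 2h)]
        # with G = -dp/dx.  Solve G from Q, then tau = mu du/dz.
        odd = range(1, 2 * n_terms, 2)
        s_q = sum(192.0 * h / (math.pi**5 * n**5 * w) * math.tanh(n * math.pi * w / (2 * h)) for n in odd)
        g = 12.0 * mu * q / (h**3 * w * (1.0 - s_q))
        s_t = sum((1.0 - 1.0 / math.cosh(n * math.pi * w / (2 * h))) / n**2 for n in odd)
        tau_pa = (4.0 * h * g / math.pi**2) * s_t
    else:
        raise ValueError(f"unknown method {method!r}; use 'slit' or 'series'")
    return tau_pa * DYN_CM2_PER_PA


def box_volume(l_cm: float, w_cm: float, h_cm: float) -> float:
    """Volume in litres of a rectangular box given its sides in cm."""
    if min(l_cm, w_cm, h_cm) <= 0:
        raise ValueError("dimensions must be positive")
    return l_cm * w_cm * h_cm / 1000.0


def classify_safety(MI: float, TI: float) -> str:
    """Classify an exposure: 'safe' if both indices < 1, 'above_FDA_limit'
    if MI exceeds the 1.9 regulatory ceiling, else 'caution'."""
    if MI < 0 or TI < 0:
        raise ValueError("MI and TI must be non-negative")
    if MI > _FDA_MI_LIMIT:
        return "above_FDA_limit"
    if MI < _SAFE_INDEX and TI < _SAFE_INDEX:
        return "safe"
    return "caution"


def dose_report(
    scheme: ExposureScheme,
    W_p: float = 0.0,
    W_deg: float = 1.0,
    rho: float = 998.0,
    c: float = 1482.0,
) -> DoseReport:
    """Convenience bundle: MI, TI, plane-wave intensity, safety class."""
    mi = mechanical_index(scheme.pnp_MPa, scheme.f_MHz)
    ti = thermal_index(W_p, W_deg)
    inten = plane_wave_intensity(scheme.pnp_MPa * 1e6, rho=rho, c=c)
    return DoseReport(MI=mi, TI=ti, intensity_W_cm2=inten, safety_class=classify_safety(mi, ti))
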