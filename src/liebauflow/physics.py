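"""Closed-form pump physics for a valveless (Liebau) pumping loop.

The calculators here cover everything needed to set up and interpret a
Liebau-pump flow measurement on a compliant tube segment:

* Young modulus of the compliant wall from a single-point tensile test.
* Womersley number ``Wo = r * sqrt(rho * omega / mu)`` of the pulsatile
  regime, the oscillatory (Womersley) velocity profile, and the ``k_w``
  centerline-to-mean correction used to convert a tracked tracer velocity
  into a cross-section-mean velocity (``Q = k_w * A * v``).
* Moens-Korteweg pressure-wave speed ``c = sqrt(E*h/(rho*d))`` and the
  natural (resonant) frequency ``F_n = c / (2 L)`` of the compliant segment.
* The peristaltic reference output ``Q = F * A * P`` of an idealized
  peristaltic pump with the same lumen, pincher width and frequency.
* A glycerol-water viscosity correlation and Poiseuille resistance scaling
  ``R ~ mu * L / r^4`` for interpreting viscosity sweeps.

All quantities are strictly SI internally (m, kg, s, Pa, Pa.s); the
reporting helpers at the bottom convert to the units conventional in this
literature (mm/s, ul/s, ml/min, cP, kPa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson
from scipy.special import jv

__all__ = [
    "STANDARD_GRAVITY",
    "GLYCEROL_DENSITY",
    "TensileTest",
    "TubeGeometry",
    "FluidProperties",
    "CompressionProtocol",
    "WomersleyRegime",
    "WavePropagation",
    "young_modulus",
    "compression_frequency",
    "womersley_number",
    "womersley_profile",
    "kw_correction",
    "womersley_regime",
    "moens_korteweg_speed",
    "natural_frequency",
    "wave_propagation",
    "peristaltic_flowrate",
    "glycerin_water_viscosity",
    "poiseuille_resistance_scaling",
    "pa_s_to_cp",
    "cp_to_pa_s",
    "m3_s_to_ul_s",
    "ul_s_to_ml_min",
]

#: Standard acceleration of free fall used in the tensile-test formula.
STANDARD_GRAVITY = 9.81  # m/s^2

#: Density of pure glycerol, used to convert volume to mass fraction.
GLYCEROL_DENSITY = 1.26  # g/ml


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TensileTest:
    """Single-point tensile test of a rectangular strip of wall material.

    A mass ``attached_mass`` hangs from a strip of length ``strip_length``
    and cross section ``cross_section_area``; the strip elongates by
    ``elongation``.  Strains up to 1 (100 % elongation) are accepted: the
    stress-stretch relation of the soft silicone used for compliant
    segments stays linear over that whole range, so the secant modulus at
    any point of it equals the Young modulus.
    """

    attached_mass: float  # kg
    strip_length: float  # m
    cross_section_area: float  # m^2
    elongation: float  # m
    gravity: float = STANDARD_GRAVITY  # m/s^2

    def __post_init__(self) -> None:
        _require_positive(
            attached_mass=self.attached_mass,
            strip_length=self.strip_length,
            cross_section_area=self.cross_section_area,
            elongation=self.elongation,
            gravity=self.gravity,
        )
        if self.strain > 1.0 + 1e-12:
            raise ValueError(
                f"strain {self.strain:.3f} exceeds the linear regime (strain <= 1)"
            )

    @property
    def strain(self) -> float:
        return self.elongation / self.strip_length

    @property
    def stress(self) -> float:
        return self.gravity * self.attached_mass / self.cross_section_area


@dataclass(frozen=True)
class TubeGeometry:
    """Cylindrical tube segment: length, inner diameter, wall thickness."""

    segment_length: float  # m
    inner_diameter: float  # m
    wall_thickness: float  # m

    def __post_init__(self) -> None:
        _require_positive(
            segment_length=self.segment_length,
            inner_diameter=self.inner_diameter,
            wall_thickness=self.wall_thickness,
        )

    @property
    def radius(self) -> float:
        """Lumen radius d/2 (m)."""
        return self.inner_diameter / 2.0

    @property
    def lumen_area(self) -> float:
        """Lumen cross-sectional area pi r^2 (m^2)."""
        return math.pi * self.radius**2


@dataclass(frozen=True)
class FluidProperties:
    """Working fluid: density and dynamic viscosity, optionally the
    glycerin volume fraction and temperature it was mixed at."""

    density: float  # kg/m^3
    dynamic_viscosity: float  # Pa.s
    glycerin_volume_fraction: float | None = None  # 0..1
    temperature: float | None = None  # degC

    def __post_init__(self) -> None:
        _require_positive(density=self.density, dynamic_viscosity=self.dynamic_viscosity)
        if self.glycerin_volume_fraction is not None and not (
            0.0 <= self.glycerin_volume_fraction <= 1.0
        ):
            raise ValueError(
                f"glycerin_volume_fraction must be in [0, 1], got {self.glycerin_volume_fraction}"
            )

    @classmethod
    def glycerin_water(
        cls, volume_fraction: float, temperature: float = 22.0, density: float | None = None
    ) -> "FluidProperties":
        """Build a glycerin-water mixture from its volume fraction."""
        mu = glycerin_water_viscosity(volume_fraction, temperature)
        if density is None:
            # ideal volume-additive mixture density
            density = 1000.0 * (1.0 - volume_fraction) + 1260.0 * volume_fraction
        return cls(
            density=density,
            dynamic_viscosity=mu,
            glycerin_volume_fraction=volume_fraction,
            temperature=temperature,
        )


@dataclass(frozen=True)
class CompressionProtocol:
    """Pincher actuation protocol: on/off times and pincher placement.

    ``time_on`` is the compression duration per cycle, ``time_off`` the
    release; the compression frequency is 1/(time_on + time_off).
    ``pincher_length`` is the axial width of the rectangular piston and
    ``pincher_offset_from_junction`` its distance from the junction between
    the compliant tube and the stiff connector.
    """

    time_on: float  # s
    time_off: float  # s
    pincher_length: float = 3.5e-3  # m
    pincher_offset_from_junction: float = 2.0e-3  # m
    occlusion_fraction: float = 1.0  # 0..1, 1 = full lumen compression

    def __post_init__(self) -> None:
        _require_positive(time_on=self.time_on, time_off=self.time_off,
                          pincher_length=self.pincher_length)
        if self.pincher_offset_from_junction < 0:
            raise ValueError("pincher_offset_from_junction must be >= 0")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must be in [0, 1]")

    @property
    def frequency(self) -> float:
        """Compression frequency F = 1/(time_on + time_off) (Hz)."""
        return compression_frequency(self.time_on, self.time_off)

    @property
    def angular_frequency(self) -> float:
        """omega = 2 pi F (rad/s)."""
        return 2.0 * math.pi * self.frequency

    @classmethod
    def from_frequency(
        cls, frequency: float, time_on: float = 0.2, **kwargs
    ) -> "CompressionProtocol":
        """Protocol with a fixed compression time and the release time set
        to reach ``frequency`` (the experimental convention here)."""
        _require_positive(frequency=frequency, time_on=time_on)
        period = 1.0 / frequency
        if period <= time_on:
            raise ValueError(
                f"frequency {frequency} Hz unreachable with time_on={time_on} s"
            )
        return cls(time_on=time_on, time_off=period - time_on, **kwargs)


@dataclass(frozen=True)
class WomersleyRegime:
    """Oscillatory-flow regime of one configuration: omega, Wo, k_w."""

    angular_frequency: float  # rad/s
    womersley_number: float
    kw: float

    def __post_init__(self) -> None:
        if self.womersley_number < 0:
            raise ValueError("womersley_number must be >= 0")
        if not 0.5 <= self.kw <= 1.0:
            raise ValueError(f"kw must lie in [0.5, 1], got {self.kw}")

    @property
    def frequency(self) -> float:
        return self.angular_frequency / (2.0 * math.pi)


@dataclass(frozen=True)
class WavePropagation:
    """Pressure-wave characteristics of a compliant segment."""

    wave_speed: float  # m/s
    natural_frequency: float  # Hz
    relative_resistance: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        _require_positive(wave_speed=self.wave_speed, natural_frequency=self.natural_frequency)


# ---------------------------------------------------------------------------
# calculators
# ---------------------------------------------------------------------------


def young_modulus(test: TensileTest) -> float:
    """Young modulus E = stress/strain = g*m*L / (A*dL), in Pa."""
    return test.stress / test.strain


def compression_frequency(time_on: float, time_off: float) -> float:
    """Compression frequency 1/(time_on + time_off), in Hz."""
    _require_positive(time_on=time_on, time_off=time_off)
    return 1.0 / (time_on + time_off)


def womersley_number(
    geom: TubeGeometry, fluid: FluidProperties, protocol: CompressionProtocol
) -> float:
    """Womersley number Wo = r * sqrt(rho * omega / mu) (dimensionless)."""
    return geom.radius * math.sqrt(
        fluid.density * protocol.angular_frequency / fluid.dynamic_viscosity
    )


def womersley_profile(wo: float, radial_positions) -> np.ndarray:
    """Normalized axial velocity-magnitude profile of oscillatory pipe flow.

    Evaluates the fundamental-mode Womersley solution

        u(xi) = 1 - J0(i^{3/2} Wo xi) / J0(i^{3/2} Wo)

    at radial fractions ``xi = r/R`` and returns ``|u(xi)| / |u(0)|`` so the
    centerline value is 1 and the wall value 0 (no slip).  ``wo = 0``
    returns the Poiseuille limit ``1 - xi^2``; the solution converges to it
    continuously as Wo -> 0.

    Parameters
    ----------
    wo : non-negative Womersley number.
    radial_positions : array-like of fractions of the radius, each in [0, 1].
    """
    if not math.isfinite(wo) or wo < 0:
        raise ValueError(f"Womersley number must be finite and >= 0, got {wo!r}")
    xi = np.asarray(radial_positions, dtype=float)
    if xi.size and (xi.min() < 0.0 or xi.max() > 1.0):
        raise ValueError("radial positions must lie in [0, 1]")
    # below Wo ~ 0.05 the Bessel ratio is numerically 1 - xi^2 anyway;
    # switch to the closed form to avoid 0/0 at Wo = 0
    if wo < 0.05:
        return 1.0 - xi**2
    arg = 1j**1.5 * wo
    u = 1.0 - jv(0, arg * xi) / jv(0, arg)
    u0 = 1.0 - 1.0 / jv(0, arg)
    return np.abs(u) / np.abs(u0)


def kw_correction(wo: float, n_nodes: int = 513) -> float:
    """Centerline-to-mean velocity correction k_w for a Womersley regime.

    k_w is the ratio of the cross-section-averaged to the centerline
    time-averaged velocity magnitude of the fundamental oscillatory mode,

        k_w = 2 * integral_0^1 |u(xi)| xi dxi / |u(0)|,

    computed by composite-Simpson radial quadrature of
    :func:`womersley_profile` and clamped to [0.5, 1].  It converts a
    tracked centerline tracer velocity v into the mean flow, Q = k_w A v.
    The Poiseuille limit (Wo -> 0) gives exactly 0.5; a flat profile
    (Wo -> inf) gives 1.  k_w is monotone non-decreasing in Wo.

    ``n_nodes`` must be odd and >= 257 so the Simpson rule resolves the
    near-wall Stokes layer at large Wo.
    """
    if not math.isfinite(wo) or wo < 0:
        raise ValueError(f"Womersley number must be finite and >= 0, got {wo!r}")
    if n_nodes < 257 or n_nodes % 2 == 0:
        raise ValueError("n_nodes must be an odd integer >= 257")
    xi = np.linspace(0.0, 1.0, n_nodes)
    mean_over_center = 2.0 * simpson(womersley_profile(wo, xi) * xi, x=xi)
    return float(np.clip(mean_over_center, 0.5, 1.0))


def womersley_regime(
    geom: TubeGeometry, fluid: FluidProperties, protocol: CompressionProtocol
) -> WomersleyRegime:
    """Bundle omega, Wo and k_w for one experimental configuration."""
    wo = womersley_number(geom, fluid, protocol)
    return WomersleyRegime(
        angular_frequency=protocol.angular_frequency,
        womersley_number=wo,
        kw=kw_correction(wo),
    )


def moens_korteweg_speed(
    elastic_modulus: float, geom: TubeGeometry, fluid: FluidProperties
) -> float:
    """Moens-Korteweg pressure-wave speed c = sqrt(E h / (rho d)), in m/s.

    Thin-wall approximation for an incompressible fluid in an elastic tube
    of wall thickness h and inner diameter d.
    """
    _require_positive(elastic_modulus=elastic_modulus)
    return math.sqrt(
        elastic_modulus * geom.wall_thickness / (fluid.density * geom.inner_diameter)
    )


def natural_frequency(wave_speed: float, geom: TubeGeometry) -> float:
    """Natural (resonant) frequency F_n = c / (2 L) of a compliant segment, Hz."""
    _require_positive(wave_speed=wave_speed)
    return wave_speed / (2.0 * geom.segment_length)


def wave_propagation(
    elastic_modulus: float, geom: TubeGeometry, fluid: FluidProperties
) -> WavePropagation:
    """Wave speed, natural frequency and Poiseuille resistance scaling."""
    c = moens_korteweg_speed(elastic_modulus, geom, fluid)
    return WavePropagation(
        wave_speed=c,
        natural_frequency=natural_frequency(c, geom),
        relative_resistance=poiseuille_resistance_scaling(fluid, geom),
    )


def peristaltic_flowrate(
    protocol: CompressionProtocol | None,
    geom: TubeGeometry,
    *,
    frequency: float | None = None,
    pincher_length: float | None = None,
) -> float:
    """Output of an idealized peristaltic pump, Q = F * A * P, in m^3/s.

    The reference baseline against which Liebau output is judged: at full
    efficiency a peristaltic pump moves, per cycle, the volume displaced by
    a pincher of axial length P sweeping the whole lumen of area A.
    F and P are taken from ``protocol``, or may be given directly
    (``frequency = 0``, a stationary pincher, yields 0).
    """
    if protocol is not None:
        frequency = protocol.frequency
        pincher_length = protocol.pincher_length
    if frequency is None or pincher_length is None:
        raise ValueError("provide a protocol or both frequency and pincher_length")
    if frequency < 0:
        raise ValueError(f"frequency must be >= 0, got {frequency!r}")
    _require_positive(pincher_length=pincher_length)
    return frequency * geom.lumen_area * pincher_length


def glycerin_water_viscosity(volume_fraction: float, temperature: float = 22.0) -> float:
    """Dynamic viscosity of a glycerol-water mixture, in Pa.s.

    Exponential-mixing correlation (Cheng 2008 form): the mixture viscosity
    is ``mu_w^alpha * mu_g^(1-alpha)`` with temperature-dependent water and
    glycerol viscosities and a weighting exponent ``alpha`` that depends on
    the glycerol *mass* fraction.  ``volume_fraction`` is the glycerin
    volume fraction of the mixture as prepared; it is converted to a mass
    fraction with a glycerol density of 1.26 g/ml.  Valid for temperatures
    between 0 and 100 degC; monotone increasing in the glycerin fraction.
    """
    if not 0.0 <= volume_fraction <= 1.0:
        raise ValueError(f"volume_fraction must be in [0, 1], got {volume_fraction!r}")
    if not 0.0 <= temperature <= 100.0:
        raise ValueError(f"temperature must be within 0-100 degC, got {temperature!r}")
    t = temperature
    # volume -> mass fraction (water density 1.00 g/ml)
    cm = (
        volume_fraction
        * GLYCEROL_DENSITY
        / (volume_fraction * GLYCEROL_DENSITY + (1.0 - volume_fraction))
    )
    mu_water = 1.790 * math.exp((-1230.0 - t) * t / (36100.0 + 360.0 * t))  # cP
    mu_glycerol = 12100.0 * math.exp((-1233.0 + t) * t / (9900.0 + 70.0 * t))  # cP
    a = 0.705 - 0.0017 * t
    b = (4.9 + 0.036 * t) * a**2.5
    alpha = 1.0 - cm + a * b * cm * (1.0 - cm) / (a * cm + b * (1.0 - cm))
    return cp_to_pa_s(mu_water**alpha * mu_glycerol ** (1.0 - alpha))


def poiseuille_resistance_scaling(fluid: FluidProperties, geom: TubeGeometry) -> float:
    """Relative Poiseuille resistance mu * L / r^4 (arbitrary units).

    Proportionality constant 1 (the true Poiseuille constant 8/pi cancels
    in ratios); meaningful only as a ratio between configurations.
    """
    return fluid.dynamic_viscosity * geom.segment_length / geom.radius**4


# ---------------------------------------------------------------------------
# unit conversions (reporting layer)
# ---------------------------------------------------------------------------


def pa_s_to_cp(mu: float) -> float:
    """Pa.s -> centipoise."""
    return mu * 1e3


def cp_to_pa_s(mu_cp: float) -> float:
    """centipoise -> Pa.s."""
    return mu_cp * 1e-3


def m3_s_to_ul_s(q: float) -> float:
    """m^3/s -> microliters per second."""
    return q * 1e9


def ul_s_to_ml_min(q_ul_s: float) -> float:
    """ul/s -> ml/min (exactly x 0.06)."""
    return q_ul_s * 0.06
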