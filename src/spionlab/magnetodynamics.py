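"""Closed-form magnetic response of single-domain nanoparticles.

This module implements the standard linear-response description of a dilute
suspension of superparamagnetic particles driven by an AC magnetic field:

* thermally activated (Neel) and rotational (Brownian) relaxation times and
  their harmonic combination,
* the Langevin equilibrium magnetization and its small-field slope
  (equilibrium susceptibility),
* the Debye complex susceptibility spectrum,
* the dissipated heating power, together with a brute-force numerical
  hysteresis-loop integrator that serves as an independent oracle for it,
* a diameter sweep locating the heating optimum.

All quantities are SI internally.  Field amplitudes may be given either as
H0 [A/m] or as an induction B0 [T] (converted through mu0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import CONSTANTS, PhysicalConstants

__all__ = [
    "ModelDomainError",
    "ParticleSpec",
    "MediumSpec",
    "FieldExcitation",
    "SuspensionSpec",
    "SusceptibilitySpectrum",
    "PowerSweepResult",
    "neel_time",
    "brown_time",
    "effective_time",
    "langevin",
    "langevin_magnetization",
    "equilibrium_susceptibility",
    "susceptibility_spectrum",
    "heating_power",
    "hysteresis_energy_numeric",
    "power_vs_diameter",
    "linear_response_parameter",
    "warn_if_nonlinear",
]

#: Cap on the Neel exponent K*V/(kB*T).  exp(700) is near the double
#: overflow limit; particles beyond this are not superparamagnetic and the
#: Arrhenius model does not apply.
NEEL_EXPONENT_CAP = 700.0

#: Below this |xi| the Langevin function switches to its Taylor series to
#: avoid catastrophic cancellation in coth(xi) - 1/xi.
_LANGEVIN_SERIES_SWITCH = 1e-4


class ModelDomainError(ValueError):
    """Raised when inputs leave the domain of validity of a model."""


def _volume_from_diameter(d: float) -> float:
    return math.pi * d**3 / 6.0


@dataclass(frozen=True)
class ParticleSpec:
    """Geometry and magnetic constants of one particle type.

    Parameters
    ----------
    core_diameter : float
        Magnetic core diameter dm [m].
    anisotropy_constant : float
        Effective anisotropy constant K [J/m^3].
    core_saturation_magnetization : float
        Saturation magnetization of the core material MSP [A/m].
    hydrodynamic_diameter : float, optional
        Hydrodynamic diameter dh [m].  Mutually exclusive with
        ``hydrodynamic_ratio``; if neither is given dh defaults to dm.
    hydrodynamic_ratio : float, optional
        dh/dm ratio, an alternative way to specify dh.
    attempt_time : float
        Attempt time tau0 [s], default 1e-9.
    """

    core_diameter: float
    anisotropy_constant: float
    core_saturation_magnetization: float
    hydrodynamic_diameter: float | None = None
    hydrodynamic_ratio: float | None = None
    attempt_time: float = 1e-9

    def __post_init__(self) -> None:
        if self.core_diameter <= 0:
            raise ValueError("core_diameter must be > 0")
        if self.anisotropy_constant <= 0:
            raise ValueError("anisotropy_constant must be > 0")
        if self.core_saturation_magnetization <= 0:
            raise ValueError("core_saturation_magnetization must be > 0")
        if self.attempt_time <= 0:
            raise ValueError("attempt_time must be > 0")
        if self.hydrodynamic_diameter is not None and self.hydrodynamic_ratio is not None:
            raise ValueError("give hydrodynamic_diameter or hydrodynamic_ratio, not both")
        if self.hydrodynamic_diameter is None:
            ratio = 1.0 if self.hydrodynamic_ratio is None else self.hydrodynamic_ratio
            object.__setattr__(self, "hydrodynamic_diameter", ratio * self.core_diameter)
            object.__setattr__(self, "hydrodynamic_ratio", ratio)
        if self.hydrodynamic_diameter < self.core_diameter:
            raise ValueError("hydrodynamic_diameter must be >= core_diameter")

    @property
    def core_volume(self) -> float:
        """Magnetic core volume Vm = pi*dm^3/6 [m^3]."""
        return _volume_from_diameter(self.core_diameter)

    @property
    def hydrodynamic_volume(self) -> float:
        """Hydrodynamic volume Vh = pi*dh^3/6 [m^3]."""
        return _volume_from_diameter(self.hydrodynamic_diameter)

    @property
    def magnetic_moment(self) -> float:
        """Particle magnetic moment MSP*Vm [A m^2]."""
        return self.core_saturation_magnetization * self.core_volume


@dataclass(frozen=True)
class MediumSpec:
    """Carrier-liquid properties: viscosity eta [Pa s] and temperature T [K]."""

    viscosity: float
    temperature: float

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class FieldExcitation:
    """AC field excitation H = H0 cos(omega t).

    Exactly one of ``amplitude`` (H0, A/m) or ``induction`` (B0, T) must be
    given; the other is derived through mu0.
    """

    frequency: float
    amplitude: float | None = None
    induction: float | None = None
    constants: PhysicalConstants = field(default=CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")
        if (self.amplitude is None) == (self.induction is None):
            raise ValueError("give exactly one of amplitude [A/m] or induction [T]")
        mu0 = self.constants.vacuum_permeability
        if self.amplitude is None:
            object.__setattr__(self, "amplitude", self.induction / mu0)
        else:
            object.__setattr__(self, "induction", self.amplitude * mu0)
        if self.amplitude < 0:
            raise ValueError("field amplitude must be >= 0")

    @property
    def angular_frequency(self) -> float:
        """omega = 2*pi*f [rad/s]."""
        return 2.0 * math.pi * self.frequency


@dataclass(frozen=True)
class SuspensionSpec:
    """A particle type in a carrier medium at a given concentration.

    The concentration may be given as a number density ``number_density``
    [1/m^3] or a mass concentration ``mass_concentration`` [kg/m^3]; the
    conversion between them requires ``core_density`` [kg/m^3] and uses the
    core volume of the particle.
    """

    particle: ParticleSpec
    medium: MediumSpec
    number_density: float | None = None
    mass_concentration: float | None = None
    core_density: float | None = None

    def __post_init__(self) -> None:
        if self.number_density is None and self.mass_concentration is None:
            raise ValueError("give number_density and/or mass_concentration")
        mass_per_particle = None
        if self.core_density is not None:
            if self.core_density <= 0:
                raise ValueError("core_density must be > 0")
            mass_per_particle = self.core_density * self.particle.core_volume
        if self.number_density is None:
            if mass_per_particle is None:
                raise ValueError("core_density required to convert mass to number density")
            object.__setattr__(
                self, "number_density", self.mass_concentration / mass_per_particle
            )
        elif self.mass_concentration is None and mass_per_particle is not None:
            object.__setattr__(
                self, "mass_concentration", self.number_density * mass_per_particle
            )
        if self.number_density < 0:
            raise ValueError("number_density must be >= 0")
        if self.mass_concentration is not None and self.mass_concentration < 0:
            raise ValueError("mass_concentration must be >= 0")

    @property
    def saturation_magnetization(self) -> float:
        """Sample saturation magnetization Ms = Nm * MSP * Vm [A/m]."""
        return self.number_density * self.particle.magnetic_moment


@dataclass(frozen=True)
class SusceptibilitySpectrum:
    """Debye susceptibility evaluated on a frequency grid.

    ``frequencies`` are in Hz, sorted ascending.  The output invariants
    (chi'' >= 0, chi' <= chi0, chi' nonincreasing) are enforced on
    construction.
    """

    frequencies: np.ndarray
    chi_real: np.ndarray
    chi_imag: np.ndarray
    equilibrium_chi: float
    effective_tau: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        cr = np.asarray(self.chi_real, dtype=float)
        ci = np.asarray(self.chi_imag, dtype=float)
        if not (f.shape == cr.shape == ci.shape):
            raise ValueError("frequency/chi arrays must share a shape")
        if np.any(np.diff(f) < 0):
            raise ValueError("frequencies must be sorted ascending")
        if np.any(ci < 0):
            raise ValueError("chi_imag must be nonnegative")
        if np.any(cr > self.equilibrium_chi * (1 + 1e-12)):
            raise ValueError("chi_real must not exceed the equilibrium susceptibility")
        if np.any(np.diff(cr) > 1e-12 * max(self.equilibrium_chi, 1.0)):
            raise ValueError("chi_real must be nonincreasing in frequency")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "chi_real", cr)
        object.__setattr__(self, "chi_imag", ci)


# ---------------------------------------------------------------------------
# relaxation times
# ---------------------------------------------------------------------------

def neel_time(
    particle: ParticleSpec,
    medium: MediumSpec,
    *,
    exponent_cap: float = NEEL_EXPONENT_CAP,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Thermally activated internal relaxation time tau0*exp(K*V/(kB*T)).

    Raises
    ------
    ModelDomainError
        If the Arrhenius exponent exceeds ``exponent_cap``, signalling a
        particle outside the superparamagnetic regime.
    """
    exponent = (
        particle.anisotropy_constant
        * particle.core_volume
        / (constants.boltzmann * medium.temperature)
    )
    if exponent > exponent_cap:
        raise ModelDomainError(
            f"Neel exponent K*V/(kB*T) = {exponent:.3g} exceeds the cap "
            f"{exponent_cap:g}; the particle is not superparamagnetic at this size"
        )
    return particle.attempt_time * math.exp(exponent)


def brown_time(
    particle: ParticleSpec,
    medium: MediumSpec,
    *,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Rotational (Brownian) relaxation time 3*Vh*eta/(kB*T)."""
    return (
        3.0
        * particle.hydrodynamic_volume
        * medium.viscosity
        / (constants.boltzmann * medium.temperature)
    )


def effective_time(tau_neel: float, tau_brown: float) -> float:
    """Harmonic combination tauN*tauB/(tauN + tauB) of the two mechanisms.

    Either time may be infinite, in which case the other is returned; both
    infinite is an error.
    """
    for t in (tau_neel, tau_brown):
        if not t > 0:
            raise ValueError("relaxation times must be positive")
    n_inf = math.isinf(tau_neel) + math.isinf(tau_brown)
    if n_inf == 2:
        raise ValueError("at least one relaxation time must be finite")
    if math.isinf(tau_neel):
        return tau_brown
    if math.isinf(tau_brown):
        return tau_neel
    return tau_neel * tau_brown / (tau_neel + tau_brown)


# ---------------------------------------------------------------------------
# equilibrium magnetization and susceptibility
# ---------------------------------------------------------------------------

def langevin(xi):
    """Langevin function L(xi) = coth(xi) - 1/xi, numerically stable.

    Switches to the series xi/3 - xi^3/45 below |xi| < 1e-4 where the direct
    expression loses precision to cancellation.  Accepts scalars or arrays.
    """
    x = np.asarray(xi, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _LANGEVIN_SERIES_SWITCH
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    if np.isscalar(xi) or np.ndim(xi) == 0:
        return float(out)
    return out


def langevin_argument(
    field_h, suspension: SuspensionSpec, *, constants: PhysicalConstants = CONSTANTS
):
    """Dimensionless Langevin argument xi = mu0*H*MSP*Vm/(kB*T)."""
    p = suspension.particle
    return (
        constants.vacuum_permeability
        * np.asarray(field_h, dtype=float)
        * p.magnetic_moment
        / (constants.boltzmann * suspension.medium.temperature)
    )


def langevin_magnetization(
    field_h, suspension: SuspensionSpec, *, constants: PhysicalConstants = CONSTANTS
):
    """Equilibrium magnetization M(H) = Ms * L(xi) [A/m].

    Odd in H, saturates at Ms = Nm*MSP*Vm, and stable near H = 0.
    """
    xi = langevin_argument(field_h, suspension, constants=constants)
    return suspension.saturation_magnetization * langevin(xi)


def equilibrium_susceptibility(
    suspension: SuspensionSpec, *, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Small-field slope of the Langevin law.

    chi0 = mu0 * Nm * (MSP*Vm)^2 / (3*kB*T).  This is the exact H -> 0
    derivative of :func:`langevin_magnetization` and is dimensionless.
    """
    p = suspension.particle
    return (
        constants.vacuum_permeability
        * suspension.number_density
        * p.magnetic_moment**2
        / (3.0 * constants.boltzmann * suspension.medium.temperature)
    )


def linear_response_parameter(
    excitation: FieldExcitation,
    suspension: SuspensionSpec,
    *,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """xi evaluated at the excitation amplitude H0."""
    return float(langevin_argument(excitation.amplitude, suspension, constants=constants))


def warn_if_nonlinear(
    excitation: FieldExcitation,
    suspension: SuspensionSpec,
    *,
    threshold: float = 0.5,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Warn when xi(H0) exceeds ``threshold``; returns xi(H0).

    The Debye susceptibility and the loss formula assume the linear response
    regime; beyond xi ~ 0.5 they progressively overestimate the losses.
    """
    xi0 = linear_response_parameter(excitation, suspension, constants=constants)
    if xi0 > threshold:
        warnings.warn(
            f"xi(H0) = {xi0:.3g} exceeds {threshold:g}: the linear-response "
            "susceptibility model is outside its validity range",
            stacklevel=2,
        )
    return xi0


# ---------------------------------------------------------------------------
# dynamic susceptibility and losses
# ---------------------------------------------------------------------------

def susceptibility_spectrum(
    suspension: SuspensionSpec,
    frequencies: Sequence[float],
    *,
    constants: PhysicalConstants = CONSTANTS,
) -> SusceptibilitySpectrum:
    """Debye spectrum chi'(f), chi''(f) of the suspension.

    chi' = chi0/(1+(tau*omega)^2) and chi'' = tau*omega*chi0/(1+(tau*omega)^2)
    with tau the effective relaxation time of the particle in the medium.
    """
    f = np.sort(np.asarray(frequencies, dtype=float))
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    tau = effective_time(
        neel_time(suspension.particle, suspension.medium, constants=constants),
        brown_time(suspension.particle, suspension.medium, constants=constants),
    )
    chi0 = equilibrium_susceptibility(suspension, constants=constants)
    wt = 2.0 * math.pi * f * tau
    denom = 1.0 + wt**2
    return SusceptibilitySpectrum(
        frequencies=f,
        chi_real=chi0 / denom,
        chi_imag=wt * chi0 / denom,
        equilibrium_chi=chi0,
        effective_tau=tau,
    )


def debye_chi(chi0: float, tau: float, omega):
    """Bare Debye pair (chi', chi'') for given chi0, tau at angular freq omega."""
    wt = np.asarray(omega, dtype=float) * tau
    denom = 1.0 + wt**2
    return chi0 / denom, wt * chi0 / denom


def heating_power(
    excitation: FieldExcitation,
    chi_imag: float,
    *,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Volumetric dissipated power P = f*pi*mu0*H0^2*chi'' [W/m^3]."""
    if chi_imag < 0:
        raise ValueError("chi_imag must be >= 0")
    return (
        excitation.frequency
        * math.pi
        * constants.vacuum_permeability
        * excitation.amplitude**2
        * chi_imag
    )


def hysteresis_energy_numeric(
    magnetization, field_h, *, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Loop energy density -mu0 * closed-integral of M dH [J/m^3].

    Both series must sample exactly one period on the same uniform time grid
    (endpoint excluded; the wrap-around segment closes the loop).  Serves as
    the brute-force oracle for the closed-form per-cycle loss
    pi*mu0*H0^2*chi''.
    """
    m = np.asarray(magnetization, dtype=float)
    h = np.asarray(field_h, dtype=float)
    if m.shape != h.shape or m.ndim != 1:
        raise ValueError("magnetization and field series must be equal-length 1-D arrays")
    if m.size < 16:
        raise ValueError("need at least 16 samples per period")
    dh = np.diff(h)
    wrap = h[0] - h[-1]
    interior = np.max(np.abs(dh))
    if interior > 0 and abs(wrap) > 5.0 * interior:
        raise ValueError("field series does not close into a cycle (non-periodic grid?)")
    # cyclic trapezoid: sum over segments i -> i+1 (mod N)
    h_next = np.roll(h, -1)
    m_next = np.roll(m, -1)
    integral = float(np.sum(0.5 * (m + m_next) * (h_next - h)))
    return -constants.vacuum_permeability * integral


@dataclass(frozen=True)
class PowerSweepResult:
    """Heating power evaluated across core diameters."""

    diameters: np.ndarray          # m
    power: np.ndarray              # W/m^3 (or relative units, see normalization)
    effective_tau: np.ndarray      # s
    chi_imag: np.ndarray
    normalization: str
    argmax_diameter: float
    argmax_index: int
    interior_maximum: bool

    @property
    def unimodal(self) -> bool:
        """True when the curve rises to a single maximum and then falls."""
        d = np.sign(np.diff(self.power))
        d = d[d != 0]
        if d.size == 0:
            return True
        drops = np.flatnonzero(np.diff(d) != 0)
        return drops.size <= 1 and (drops.size == 0 or d[0] > 0)


def power_vs_diameter(
    template: ParticleSpec,
    medium: MediumSpec,
    excitation: FieldExcitation,
    diameters: Sequence[float],
    *,
    hydrodynamic_ratio: float = 1.5,
    normalization: str = "unit_chi0",
    number_density: float | None = None,
    mass_concentration: float | None = None,
    core_density: float | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> PowerSweepResult:
    """Heating power P(dm) over a diameter sweep and its argmax.

    For each diameter the chain tauN -> tauB -> tau -> chi0 -> chi'' -> P is
    evaluated.  The equilibrium susceptibility normalization is selectable:

    ``"unit_chi0"`` (default)
        chi0 = 1 for every diameter; the curve is the relative per-unit-chi0
        power, which isolates the relaxation-time dependence.
    ``"number_density"``
        chi0 from a fixed particle number density [1/m^3].
    ``"mass_concentration"``
        chi0 from a fixed mass concentration [kg/m^3] (requires
        ``core_density``).
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("diameter list must not be empty")
    if np.any(np.diff(d) <= 0):
        raise ValueError("diameters must be sorted strictly ascending")
    if normalization not in ("unit_chi0", "number_density", "mass_concentration"):
        raise ValueError(f"unknown normalization {normalization!r}")

    taus = np.empty_like(d)
    chi0s = np.empty_like(d)
    for i, dm in enumerate(d):
        particle = replace(
            template,
            core_diameter=float(dm),
            hydrodynamic_diameter=None,
            hydrodynamic_ratio=hydrodynamic_ratio,
        )
        taus[i] = effective_time(
            neel_time(particle, medium, constants=constants),
            brown_time(particle, medium, constants=constants),
        )
        if normalization == "unit_chi0":
            chi0s[i] = 1.0
        else:
            kwargs = dict(core_density=core_density)
            if normalization == "number_density":
                kwargs["number_density"] = number_density
            else:
                kwargs["mass_concentration"] = mass_concentration
            susp = SuspensionSpec(particle=particle, medium=medium, **kwargs)
            chi0s[i] = equilibrium_susceptibility(susp, constants=constants)

    omega = excitation.angular_frequency
    wt = omega * taus
    chi_imag = wt * chi0s / (1.0 + wt**2)
    power = (
        excitation.frequency
        * math.pi
        * constants.vacuum_permeability
        * excitation.amplitude**2
        * chi_imag
    )
    idx = int(np.argmax(power))
    return PowerSweepResult(
        diameters=d,
        power=power,
        effective_tau=taus,
        chi_imag=chi_imag,
        normalization=normalization,
        argmax_diameter=float(d[idx]),
        argmax_index=idx,
        interior_maximum=bool(0 < idx < d.size - 1),
    )
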