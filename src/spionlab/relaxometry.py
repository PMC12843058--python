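"""Outer-sphere proton relaxation enhancement by magnetic nanoparticles.

Two printed formulations of the theory are provided: the "large-crystal"
rates built from the Ayant spectral density ``spectral_density_JA`` and the
fluctuation-aware density ``spectral_density_JF``, and the microscopic
outer-sphere rates built from the Freed function ``freed_j``.  Both scale
linearly with particle concentration and quadratically with the particle
magnetic moment.

Empirical relaxivities (slope of relaxation rate versus concentration) are
extracted with an ordinary least-squares fit.

Notes on two typographic ambiguities in the source formulas and how they are
resolved here:

* the prefactors are parsed as division by ``R*D`` (the standard
  concentration/(radius * diffusion) scaling of outer-sphere theory), with
  the bracketed spectral-density sums starting at the ``3 JF``/``7 J`` terms;
* the argument of JA in the transverse large-crystal rate is taken as
  ``sqrt(2*omegaI*tauD)`` by default (``ja_argument="sqrt"``), matching the
  source theory where JA is a function of the square root of the frequency
  variable; pass ``ja_argument="identity"`` for a literal reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import CONSTANTS, PhysicalConstants

__all__ = [
    "OuterSphereContext",
    "RelaxationSeries",
    "RelaxivityResult",
    "DiameterRelaxivitySweep",
    "diffusion_time",
    "spectral_density_JA",
    "spectral_density_JF",
    "freed_j",
    "rates_large_crystal",
    "rates_outer_sphere",
    "fit_relaxivity",
    "relaxivity_vs_diameter",
    "larmor_frequencies",
]


def diffusion_time(radius: float, diffusion: float) -> float:
    """Diffusion correlation time tauD = R^2/D [s]."""
    if radius <= 0 or diffusion <= 0:
        raise ValueError("radius and diffusion constant must be > 0")
    return radius**2 / diffusion


def larmor_frequencies(
    field_t: float, *, constants: PhysicalConstants = CONSTANTS
) -> tuple[float, float]:
    """(omegaI, omegaS) = (gammaI*B0, gammaS*B0) [rad/s] for a static field B0 [T]."""
    return (
        constants.proton_gyromagnetic * field_t,
        constants.electron_gyromagnetic * field_t,
    )


@dataclass(frozen=True)
class OuterSphereContext:
    """Inputs of the outer-sphere rate formulas.

    Parameters
    ----------
    particle_radius : float
        Particle radius R [m].
    water_diffusion : float
        Water self-diffusion constant D [m^2/s].  Not tabulated in the model;
        must be supplied (about 2.3e-9 m^2/s for water at 25 C, 3.0e-9 at
        37 C are common literature choices).
    molar_concentration : float
        Particle concentration C [mol/L].
    proton_larmor, electron_larmor : float
        omegaI, omegaS [rad/s].
    neel_time : float
        Internal fluctuation time tauN [s]; ``inf`` freezes the moment.
    spin_quantum : float, optional
        Effective spin quantum number S; used to build mu^2 via
        mu^2 = gammaS^2*hbar^2*S*(S+1) when ``magnetic_moment`` is absent.
    magnetic_moment : float, optional
        Particle moment mu [A m^2 = J/T], used directly when given.
    sz_mean, sz_variance : float
        <Sz> and Delta Sz^2 of the spin projection (large-crystal formulas
        only).  The theory does not prescribe them for a superparamagnet;
        they are plain inputs.
    """

    particle_radius: float
    water_diffusion: float
    molar_concentration: float
    proton_larmor: float
    electron_larmor: float
    neel_time: float = math.inf
    spin_quantum: float | None = None
    magnetic_moment: float | None = None
    sz_mean: float = 0.0
    sz_variance: float = 0.0
    constants: PhysicalConstants = field(default=CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        if self.particle_radius <= 0 or self.water_diffusion <= 0:
            raise ValueError("particle_radius and water_diffusion must be > 0")
        if self.molar_concentration < 0:
            raise ValueError("molar_concentration must be >= 0")
        if self.neel_time <= 0:
            raise ValueError("neel_time must be > 0 (may be inf)")
        if self.sz_variance < 0:
            raise ValueError("sz_variance must be >= 0")

    @property
    def diffusion_tau(self) -> float:
        """tauD = R^2/D [s]."""
        return diffusion_time(self.particle_radius, self.water_diffusion)

    @property
    def moment_squared(self) -> float:
        """mu^2 [J^2/T^2], direct or from the spin quantum number."""
        if self.magnetic_moment is not None:
            return self.magnetic_moment**2
        if self.spin_quantum is None:
            raise ValueError("need magnetic_moment or spin_quantum to form mu^2")
        c = self.constants
        return (
            c.electron_gyromagnetic**2
            * c.reduced_planck**2
            * self.spin_quantum
            * (self.spin_quantum + 1.0)
        )


# ---------------------------------------------------------------------------
# spectral densities
# ---------------------------------------------------------------------------

def spectral_density_JA(z):
    """Ayant spectral density, a rational function of z >= 0 with JA(0) = 1.

    JA(z) = (1 + 5z/8 + z^2/8) /
            (1 + z + z^2/2 + z^3/6 + 4z^4/81 + z^5/81 + z^6/648)
    """
    zz = np.asarray(z, dtype=float)
    if np.any(zz < 0):
        raise ValueError("JA argument must be nonnegative")
    num = 1.0 + 5.0 * zz / 8.0 + zz**2 / 8.0
    den = (
        1.0
        + zz
        + zz**2 / 2.0
        + zz**3 / 6.0
        + 4.0 * zz**4 / 81.0
        + zz**5 / 81.0
        + zz**6 / 648.0
    )
    out = num / den
    return float(out) if np.ndim(z) == 0 else out


def _freed_rational(omega_c):
    """Re[(1 + sqrt(W)/4) / (1 + sqrt(W) + 4W/9 + W^(3/2)/9)], principal branch."""
    w = np.asarray(omega_c, dtype=complex)
    s = np.sqrt(w)
    val = (1.0 + s / 4.0) / (1.0 + s + 4.0 * w / 9.0 + w * s / 9.0)
    out = np.real(val)
    return float(out) if np.ndim(omega_c) == 0 else out


def spectral_density_JF(omega, tau_d: float, tau_n: float):
    """Spectral density combining diffusion and moment fluctuation.

    Evaluates the Freed rational at Omega = (i*omega + 1/tauN)*tauD with the
    principal branch of the complex square root.  ``tau_n = inf`` reduces it
    to :func:`freed_j` evaluated at omega*tauD.
    """
    if tau_d <= 0 or tau_n <= 0:
        raise ValueError("tau_d and tau_n must be > 0 (tau_n may be inf)")
    inv_tn = 0.0 if math.isinf(tau_n) else 1.0 / tau_n
    omega_c = (1j * np.asarray(omega, dtype=float) + inv_tn) * tau_d
    return _freed_rational(omega_c)


def freed_j(x):
    """Freed function J(x) of the dimensionless argument x = omega*tauD >= 0.

    J(0) = 1 and J decays to zero for large x.
    """
    xx = np.asarray(x, dtype=float)
    if np.any(xx < 0):
        raise ValueError("Freed argument must be nonnegative")
    return _freed_rational(1j * xx)


# ---------------------------------------------------------------------------
# rate formulas
# ---------------------------------------------------------------------------

def rates_large_crystal(
    ctx: OuterSphereContext, *, ja_argument: str = "sqrt"
) -> tuple[float, float]:
    """(1/T1, 1/T2) [1/s] of the large-crystal formulation.

    1/T1 = pref * [3*JF(wI)*DSz2 + 3*JA(zA)*<Sz>^2]
    1/T2 = pref * [(3/2*JF(wI) + 2*JF(0))*DSz2 + (3/2*JA(zA) + 2*JA(0))*<Sz>^2]

    with pref = 32*pi*hbar^2*gammaI^2*gammaS^2*NA*C/135000 / (R*D) and
    zA = sqrt(2*wI*tauD) (default) or 2*wI*tauD (``ja_argument="identity"``).
    """
    if ja_argument not in ("sqrt", "identity"):
        raise ValueError("ja_argument must be 'sqrt' or 'identity'")
    c = ctx.constants
    tau_d = ctx.diffusion_tau
    pref = (
        32.0
        * math.pi
        * c.reduced_planck**2
        * c.proton_gyromagnetic**2
        * c.electron_gyromagnetic**2
        * c.avogadro
        * ctx.molar_concentration
        / 135000.0
        / (ctx.particle_radius * ctx.water_diffusion)
    )
    z_raw = 2.0 * ctx.proton_larmor * tau_d
    z_a = math.sqrt(z_raw) if ja_argument == "sqrt" else z_raw
    jf_w = spectral_density_JF(ctx.proton_larmor, tau_d, ctx.neel_time)
    jf_0 = spectral_density_JF(0.0, tau_d, ctx.neel_time)
    ja_w = spectral_density_JA(z_a)
    ja_0 = spectral_density_JA(0.0)
    sz2 = ctx.sz_mean**2
    r1 = pref * (3.0 * jf_w * ctx.sz_variance + 3.0 * ja_w * sz2)
    r2 = pref * (
        (1.5 * jf_w + 2.0 * jf_0) * ctx.sz_variance + (1.5 * ja_w + 2.0 * ja_0) * sz2
    )
    return r1, r2


def rates_outer_sphere(ctx: OuterSphereContext) -> tuple[float, float]:
    """(1/T1, 1/T2) [1/s] of the microscopic outer-sphere formulation.

    1/T1 = pref * [7*J(tauD*wS) + 3*J(tauD*wI)]
    1/T2 = pref * [6.5*J(tauD*wS) + 1.5*J(tauD*wI) + 2*J(0)]

    with pref = 32*pi*gammaI^2*mu^2*NA*C/405000 / (R*D).  The hbar^2 of the
    spin-quantum form is absorbed into mu^2 (mu^2 = gammaS^2*hbar^2*S(S+1)),
    so supplying either mu or S gives consistent results.
    """
    c = ctx.constants
    tau_d = ctx.diffusion_tau
    pref = (
        32.0
        * math.pi
        * c.proton_gyromagnetic**2
        * ctx.moment_squared
        * c.avogadro
        * ctx.molar_concentration
        / 405000.0
        / (ctx.particle_radius * ctx.water_diffusion)
    )
    j_s = freed_j(tau_d * ctx.electron_larmor)
    j_i = freed_j(tau_d * ctx.proton_larmor)
    j_0 = freed_j(0.0)
    r1 = pref * (7.0 * j_s + 3.0 * j_i)
    r2 = pref * (6.5 * j_s + 1.5 * j_i + 2.0 * j_0)
    return r1, r2


# ---------------------------------------------------------------------------
# empirical relaxivity extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxationSeries:
    """Concentration series of measured relaxation rates at one field.

    ``concentrations`` must be strictly increasing with at least 3 points;
    ``rates`` are the matching R1 or R2 values [1/s]; ``channel`` tags which.
    """

    concentrations: np.ndarray
    rates: np.ndarray
    field_t: float
    channel: str = "T2"
    concentration_unit: str = "mg/mL"

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if conc.ndim != 1 or conc.shape != rates.shape:
            raise ValueError("concentrations and rates must be equal-length 1-D arrays")
        if conc.size < 3:
            raise ValueError("need at least 3 points to fit a relaxivity")
        if np.any(conc < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(rates <= 0):
            raise ValueError("rates must be positive")
        if self.channel not in ("T1", "T2"):
            raise ValueError("channel must be 'T1' or 'T2'")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "rates", rates)


@dataclass(frozen=True)
class RelaxivityResult:
    """Line fit 1/Ti = 1/Ti,water + ri*C."""

    baseline_rate: float
    relaxivity: float
    baseline_se: float
    relaxivity_se: float
    r_squared: float
    n: int
    channel: str
    field_t: float
    concentration_unit: str

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided CI for the relaxivity from the t distribution (n-2 df)."""
        half = stats.t.ppf(0.5 + level / 2.0, self.n - 2) * self.relaxivity_se
        return self.relaxivity - half, self.relaxivity + half


def fit_relaxivity(series: RelaxationSeries) -> RelaxivityResult:
    """Ordinary least-squares line through (concentration, rate).

    Intercept is the host-liquid baseline rate, slope the relaxivity;
    standard errors come from the residual variance.
    """
    x = series.concentrations
    y = series.rates
    if np.ptp(x) == 0:
        raise ValueError("zero concentration spread")
    res = stats.linregress(x, y)
    return RelaxivityResult(
        baseline_rate=float(res.intercept),
        relaxivity=float(res.slope),
        baseline_se=float(res.intercept_stderr),
        relaxivity_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        channel=series.channel,
        field_t=series.field_t,
        concentration_unit=series.concentration_unit,
    )


# ---------------------------------------------------------------------------
# theoretical relaxivity versus diameter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiameterRelaxivitySweep:
    """Model relaxivities per diameter, normalized per unit concentration."""

    diameters: np.ndarray       # m
    r1: np.ndarray              # 1/(s * mol/L)
    r2: np.ndarray
    field_t: float
    argmax_r1: float
    argmax_r2: float


def relaxivity_vs_diameter(
    diameters: Sequence[float],
    field_t: float,
    water_diffusion: float,
    core_saturation_magnetization: float,
    *,
    neel_times: Sequence[float] | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> DiameterRelaxivitySweep:
    """Outer-sphere r1(d), r2(d) curves over a core-diameter sweep.

    Per diameter, R = dm/2, tauD = R^2/D and mu = MSP*pi*dm^3/6; the rates
    are evaluated at unit molar concentration so the output is already a
    relaxivity.  The argmax diameter of each curve is reported.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter sweep")
    if np.any(np.diff(d) <= 0):
        raise ValueError("diameters must be sorted strictly ascending")
    w_i, w_s = larmor_frequencies(field_t, constants=constants)
    tn = np.full(d.size, math.inf) if neel_times is None else np.asarray(neel_times, float)
    r1 = np.empty_like(d)
    r2 = np.empty_like(d)
    for i, dm in enumerate(d):
        moment = core_saturation_magnetization * math.pi * dm**3 / 6.0
        ctx = OuterSphereContext(
            particle_radius=dm / 2.0,
            water_diffusion=water_diffusion,
            molar_concentration=1.0,
            proton_larmor=w_i,
            electron_larmor=w_s,
            neel_time=float(tn[i]),
            magnetic_moment=moment,
            constants=constants,
        )
        r1[i], r2[i] = rates_outer_sphere(ctx)
    return DiameterRelaxivitySweep(
        diameters=d,
        r1=r1,
        r2=r2,
        field_t=field_t,
        argmax_r1=float(d[int(np.argmax(r1))]),
        argmax_r2=float(d[int(np.argmax(r2))]),
    )
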