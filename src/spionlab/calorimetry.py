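"""Calorimetric estimation of the specific absorption rate (SAR).

SAR = C * (rho / cn) * dT/dt|_{t=0}, i.e. the initial slope of the
temperature rise scaled by the suspension's heat capacity per unit mass of
nanoparticles.  The slope estimator is not prescribed by the measurement
protocol, so two are provided: a windowed linear fit and a saturating
single-exponential fit (the default, appropriate for hour-long exposures
that are far beyond the linear regime).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "HeatingCurve",
    "ThermalSpec",
    "SarResult",
    "SarSweepResult",
    "initial_slope",
    "compute_sar",
    "sar_vs_diameter",
]


@dataclass(frozen=True)
class HeatingCurve:
    """Temperature-time record starting at field-on (t = 0).

    Temperatures may be degrees Celsius or kelvin; slopes are unit-invariant
    between the two.  ``metadata`` typically carries frequency_hz,
    induction_t, concentration_kg_per_m3 and duration_s.
    """

    times_s: np.ndarray
    temperatures: np.ndarray
    metadata: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        temp = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or t.shape != temp.shape:
            raise ValueError("times and temperatures must be equal-length 1-D arrays")
        if t.size < 10:
            raise ValueError("need at least 10 samples")
        if t[0] != 0:
            raise ValueError("first time sample must be 0 (exposure onset)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "temperatures", temp)


@dataclass(frozen=True)
class ThermalSpec:
    """Thermophysical description of the suspension.

    specific_heat C [J/(kg K)], density rho [kg/m^3], and the nanoparticle
    concentration cn.  ``concentration_dialect`` records whether cn is a mass
    fraction [kg/kg] or a volumetric concentration [kg/m^3]; mg/mL inputs are
    numerically identical to kg/m^3.
    """

    specific_heat: float
    density: float
    nanoparticle_concentration: float
    concentration_dialect: str = "kg_per_m3"

    def __post_init__(self) -> None:
        if self.specific_heat <= 0 or self.density <= 0:
            raise ValueError("specific_heat and density must be > 0")
        if self.nanoparticle_concentration <= 0:
            raise ValueError("nanoparticle_concentration must be > 0")
        if self.concentration_dialect not in ("kg_per_m3", "kg_per_kg"):
            raise ValueError("concentration_dialect must be 'kg_per_m3' or 'kg_per_kg'")

    @property
    def heat_capacity_per_particle_mass(self) -> float:
        """C * rho / cn [J/(kg-of-particles K)] resolving the dialect."""
        if self.concentration_dialect == "kg_per_m3":
            return self.specific_heat * self.density / self.nanoparticle_concentration
        return self.specific_heat / self.nanoparticle_concentration


@dataclass(frozen=True)
class SarResult:
    """SAR estimate with its provenance."""

    slope_k_per_s: float
    slope_se: float
    sar_w_per_g: float
    sar_se: float
    method: str
    window_s: float | None


def _linear_window_slope(curve: HeatingCurve, window_s: float) -> tuple[float, float]:
    sel = curve.times_s <= window_s
    if int(np.sum(sel)) < 5:
        raise ValueError(f"window {window_s} s covers fewer than 5 samples")
    t = curve.times_s[sel]
    y = curve.temperatures[sel]
    res = stats.linregress(t, y)
    return float(res.slope), float(res.stderr)


def _exponential_slope(curve: HeatingCurve) -> tuple[float, float]:
    t = curve.times_s
    y = curve.temperatures
    span = max(float(y[-1] - y[0]), 1e-12)
    p0 = (float(y[0]), span, max(float(t[-1]) / 3.0, float(t[1])))

    def model(tt, t0, dt_inf, tau):
        return t0 + dt_inf * (1.0 - np.exp(-tt / tau))

    popt, pcov = optimize.curve_fit(model, t, y, p0=p0, maxfev=20000)
    _, dt_inf, tau = popt
    slope = dt_inf / tau
    # delta method: grad of dt_inf/tau w.r.t. (t0, dt_inf, tau)
    grad = np.array([0.0, 1.0 / tau, -dt_inf / tau**2])
    var = float(grad @ pcov @ grad)
    se = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else np.nan
    return float(slope), se


def initial_slope(
    curve: HeatingCurve,
    method: str = "exponential-fit",
    window_s: float | None = None,
) -> tuple[float, float, str]:
    """Estimate dT/dt at t = 0 with its standard error.

    ``"linear-window"`` fits a least-squares line over [0, window_s];
    ``"exponential-fit"`` fits T(t) = T0 + dT_inf*(1 - exp(-t/tau_c)) and
    returns dT_inf/tau_c (SE by the delta method).  A non-convergent
    exponential fit falls back to a full-range linear fit and tags the
    returned method accordingly.

    Returns ``(slope, se, method_used)``.
    """
    if method == "linear-window":
        if window_s is None:
            window_s = float(curve.times_s[-1])
        slope, se = _linear_window_slope(curve, window_s)
        return slope, se, "linear-window"
    if method == "exponential-fit":
        try:
            slope, se = _exponential_slope(curve)
            return slope, se, "exponential-fit"
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            warnings.warn(
                f"exponential fit failed ({exc}); falling back to a linear fit",
                stacklevel=2,
            )
            slope, se = _linear_window_slope(curve, float(curve.times_s[-1]))
            return slope, se, "linear-window (fallback)"
    raise ValueError("method must be 'linear-window' or 'exponential-fit'")


def compute_sar(
    slope_k_per_s: float,
    thermal: ThermalSpec,
    *,
    slope_se: float = 0.0,
    method: str = "linear-window",
    window_s: float | None = None,
) -> SarResult:
    """SAR = C * rho / cn * slope, reported in W per gram of nanoparticles.

    The slope standard error propagates linearly.
    """
    factor = thermal.heat_capacity_per_particle_mass / 1000.0  # W/kg -> W/g
    return SarResult(
        slope_k_per_s=float(slope_k_per_s),
        slope_se=float(slope_se),
        sar_w_per_g=factor * slope_k_per_s,
        sar_se=factor * slope_se,
        method=method,
        window_s=window_s,
    )


def sar_from_curve(
    curve: HeatingCurve,
    thermal: ThermalSpec,
    method: str = "exponential-fit",
    window_s: float | None = None,
) -> SarResult:
    """Convenience chain: initial_slope followed by compute_sar."""
    slope, se, used = initial_slope(curve, method=method, window_s=window_s)
    return compute_sar(slope, thermal, slope_se=se, method=used, window_s=window_s)


@dataclass(frozen=True)
class SarSweepResult:
    """SAR per nominal diameter with an argmax and a significance flag."""

    diameters_nm: np.ndarray
    sar_w_per_g: np.ndarray
    sar_se: np.ndarray
    argmax_diameter_nm: float
    argmax_significant: bool


def sar_vs_diameter(
    curves_by_diameter: Mapping[float, Sequence[HeatingCurve]],
    thermal: ThermalSpec,
    method: str = "exponential-fit",
) -> SarSweepResult:
    """Per-diameter SAR (mean over replicate curves) and its argmax.

    The argmax is flagged non-significant when the two-SE band of the peak
    overlaps the band of any other diameter, i.e. the curve may be flat.
    """
    if not curves_by_diameter:
        raise ValueError("empty input")
    diam = np.array(sorted(curves_by_diameter), dtype=float)
    sar = np.empty_like(diam)
    se = np.empty_like(diam)
    for i, d in enumerate(diam):
        results = [
            sar_from_curve(c, thermal, method=method) for c in curves_by_diameter[d]
        ]
        if not results:
            raise ValueError(f"no heating curves for diameter {d}")
        vals = np.array([r.sar_w_per_g for r in results])
        sar[i] = vals.mean()
        if vals.size > 1:
            se[i] = vals.std(ddof=1) / np.sqrt(vals.size)
        else:
            se[i] = results[0].sar_se
    idx = int(np.argmax(sar))
    others = np.delete(np.arange(diam.size), idx)
    significant = bool(
        others.size == 0
        or np.all(sar[idx] - 2.0 * se[idx] > sar[others] + 2.0 * se[others])
    )
    return SarSweepResult(
        diameters_nm=diam,
        sar_w_per_g=sar,
        sar_se=se,
        argmax_diameter_nm=float(diam[idx]),
        argmax_significant=significant,
    )
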