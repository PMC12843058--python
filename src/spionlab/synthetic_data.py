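"""Seeded generators emulating every measured input of the study.

Each generator is a pure function of its parameters plus an explicit integer
seed and returns the generated object together with a :class:`GroundTruth`
record that can be serialized next to the data.  The STEM emulator renders
particles dark on a bright background, as acquired, so the analysis
pipeline's inversion step is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calorimetry import HeatingCurve, ThermalSpec
from .relaxometry import RelaxationSeries
from .tem_morphometry import CalibratedImage

__all__ = [
    "PopulationSpec",
    "GroundTruth",
    "gen_diameters",
    "gen_stem_image",
    "gen_heating_curve",
    "gen_relaxation_series",
    "gen_study_table",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Core-diameter population to draw from.

    ``family`` is ``"lognormal"`` (median + geometric SD) or
    ``"normal-truncated"`` (mean = median, sd = median*(gsd-1), resampled
    until positive).
    """

    median_diameter_nm: float
    geometric_sd: float
    n: int
    seed: int
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.median_diameter_nm <= 0:
            raise ValueError("median_diameter_nm must be > 0")
        if self.geometric_sd < 1:
            raise ValueError("geometric_sd must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.family not in ("lognormal", "normal-truncated"):
            raise ValueError("family must be 'lognormal' or 'normal-truncated'")


@dataclass(frozen=True)
class GroundTruth:
    """True generated values plus the seed that produced them."""

    kind: str
    seed: int
    payload: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")

        Path(path).write_text(
            json.dumps(
                {"kind": self.kind, "seed": self.seed, "payload": self.payload},
                indent=2,
                default=default,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(kind=data["kind"], seed=data["seed"], payload=data["payload"])


def gen_diameters(spec: PopulationSpec) -> tuple[np.ndarray, GroundTruth]:
    """Draw a diameter sample [nm] from the population."""
    rng = np.random.default_rng(spec.seed)
    if spec.family == "lognormal":
        d = rng.lognormal(
            mean=np.log(spec.median_diameter_nm),
            sigma=np.log(spec.geometric_sd),
            size=spec.n,
        )
    else:
        sd = spec.median_diameter_nm * (spec.geometric_sd - 1.0)
        d = rng.normal(spec.median_diameter_nm, sd, size=spec.n)
        while np.any(d <= 0):  # truncate at zero by resampling
            bad = d <= 0
            d[bad] = rng.normal(spec.median_diameter_nm, sd, size=int(bad.sum()))
    truth = GroundTruth(
        kind="diameters",
        seed=spec.seed,
        payload={
            "diameters_nm": d,
            "median_diameter_nm": spec.median_diameter_nm,
            "geometric_sd": spec.geometric_sd,
            "family": spec.family,
        },
    )
    return d, truth


# ---------------------------------------------------------------------------
# STEM image emulation
# ---------------------------------------------------------------------------

def _place_disks(
    radii_px: np.ndarray,
    image_size: int,
    touching_fraction: float,
    rng: np.random.Generator,
    min_gap_px: float = 3.0,
    border_margin_px: float = 4.0,
    max_tries: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """Random non-overlapping placement with a controlled fraction of
    touching pairs.  Returns (centers yx, touching flags)."""
    n = radii_px.size
    n_pairs = int(round(touching_fraction * n / 2.0))
    touching = np.zeros(n, dtype=bool)
    order = rng.permutation(n)
    pair_members = order[: 2 * n_pairs].reshape(n_pairs, 2)
    singles = order[2 * n_pairs:]

    centers = np.full((n, 2), np.nan)
    placed: list[int] = []

    def fits(c, r, ignore=()):
        lo = r + border_margin_px
        hi = image_size - r - border_margin_px
        if not (lo <= c[0] <= hi and lo <= c[1] <= hi):
            return False
        for j in placed:
            if j in ignore:
                continue
            if np.hypot(*(c - centers[j])) < r + radii_px[j] + min_gap_px:
                return False
        return True

    def place_one(i):
        r = radii_px[i]
        for _ in range(max_tries):
            c = rng.uniform(r + border_margin_px, image_size - r - border_margin_px, 2)
            if fits(c, r):
                centers[i] = c
                placed.append(i)
                return
        raise RuntimeError("placement failed: image too crowded")

    for a, b in pair_members:
        ra, rb = radii_px[a], radii_px[b]
        overlap = 0.2 * min(ra, rb)  # centers closer than tangency by 20 %
        dist = ra + rb - overlap
        for _ in range(max_tries):
            ca = rng.uniform(
                ra + rb + border_margin_px, image_size - ra - rb - border_margin_px, 2
            )
            theta = rng.uniform(0, 2 * np.pi)
            cb = ca + dist * np.array([np.sin(theta), np.cos(theta)])
            if fits(ca, ra) and fits(cb, rb + min_gap_px, ignore=(a,)):
                # pair members may touch each other but nothing else
                centers[a], centers[b] = ca, cb
                placed.extend([a, b])
                touching[[a, b]] = True
                break
        else:
            raise RuntimeError("placement failed for a touching pair")
    for i in singles:
        place_one(i)
    return centers, touching


def gen_stem_image(
    diameters_nm: Sequence[float],
    image_size_px: int,
    pixel_size_nm: float,
    *,
    touching_fraction: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: int = 200,
    foreground: int = 40,
) -> tuple[CalibratedImage, GroundTruth]:
    """Render anti-aliased dark disks on a bright background (pre-inversion).

    A controlled fraction of particles is placed as touching pairs (centres
    20 % of the smaller radius inside tangency); everything else keeps at
    least a 3-px edge gap.  Gaussian pixel noise of ``noise_sd`` grey levels
    is added, and all true centres/diameters go into the ground truth.
    """
    if not 0.0 <= touching_fraction <= 1.0:
        raise ValueError("touching_fraction must be in [0, 1]")
    d_nm = np.asarray(diameters_nm, dtype=float)
    radii_px = d_nm / (2.0 * pixel_size_nm)
    if np.any(2 * radii_px + 8 > image_size_px):
        raise ValueError("particles do not fit in the image")
    rng = np.random.default_rng(seed)
    centers, touching = _place_disks(radii_px, image_size_px, touching_fraction, rng)

    img = np.full((image_size_px, image_size_px), float(background))
    contrast = float(background - foreground)
    for (cy, cx), r in zip(centers, radii_px):
        y0 = max(int(np.floor(cy - r - 2)), 0)
        y1 = min(int(np.ceil(cy + r + 2)) + 1, image_size_px)
        x0 = max(int(np.floor(cx - r - 2)), 0)
        x1 = min(int(np.ceil(cx + r + 2)) + 1, image_size_px)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(yy - cy, xx - cx)
        cov = np.clip(r + 0.5 - dist, 0.0, 1.0)  # linear anti-aliasing ramp
        region = img[y0:y1, x0:x1]
        img[y0:y1, x0:x1] = np.minimum(region, background - cov * contrast)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image = CalibratedImage(
        pixels=pixels, pixel_size_nm=pixel_size_nm, provenance=f"synthetic seed={seed}"
    )
    truth = GroundTruth(
        kind="stem_image",
        seed=seed,
        payload={
            "centers_px": centers,
            "diameters_px": 2.0 * radii_px,
            "diameters_nm": d_nm,
            "touching": touching,
            "pixel_size_nm": pixel_size_nm,
            "noise_sd": noise_sd,
            "touching_fraction": touching_fraction,
        },
    )
    return image, truth


# ---------------------------------------------------------------------------
# calorimetry emulation
# ---------------------------------------------------------------------------

def gen_heating_curve(
    true_sar_w_per_g: float,
    thermal: ThermalSpec,
    tau_c_s: float,
    duration_s: float,
    dt_s: float,
    *,
    noise_sd_k: float = 0.0,
    seed: int = 0,
    start_temperature_k: float = 293.15,
) -> tuple[HeatingCurve, GroundTruth]:
    """Saturating-exponential heating record with a known initial slope.

    The initial slope is set by inverting the SAR relation:
    slope = SAR[W/g] * 1000 / (C*rho/cn), then T(t) = T0 +
    slope*tau_c*(1 - exp(-t/tau_c)) plus optional Gaussian noise.
    """
    if tau_c_s <= 0 or duration_s <= 0 or dt_s <= 0:
        raise ValueError("tau_c_s, duration_s and dt_s must be > 0")
    rng = np.random.default_rng(seed)
    slope = true_sar_w_per_g * 1000.0 / thermal.heat_capacity_per_particle_mass
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    temp = start_temperature_k + slope * tau_c_s * (1.0 - np.exp(-t / tau_c_s))
    if noise_sd_k > 0:
        temp = temp + rng.normal(0.0, noise_sd_k, t.shape)
    curve = HeatingCurve(
        times_s=t,
        temperatures=temp,
        metadata={
            "concentration_kg_per_m3": thermal.nanoparticle_concentration,
            "duration_s": duration_s,
        },
    )
    truth = GroundTruth(
        kind="heating_curve",
        seed=seed,
        payload={
            "true_sar_w_per_g": true_sar_w_per_g,
            "initial_slope_k_per_s": slope,
            "tau_c_s": tau_c_s,
            "noise_sd_k": noise_sd_k,
        },
    )
    return curve, truth


def gen_relaxation_series(
    r_true: float,
    baseline: float,
    concentrations: Sequence[float],
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    field_t: float = 0.55,
    channel: str = "T2",
) -> tuple[RelaxationSeries, GroundTruth]:
    """Linear rate-versus-concentration series with known relaxivity."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 concentrations")
    rng = np.random.default_rng(seed)
    rates = baseline + r_true * conc
    if noise_sd > 0:
        rates = rates + rng.normal(0.0, noise_sd, conc.shape)
    rates = np.maximum(rates, 1e-9)  # rates must stay positive
    series = RelaxationSeries(
        concentrations=conc, rates=rates, field_t=field_t, channel=channel
    )
    truth = GroundTruth(
        kind="relaxation_series",
        seed=seed,
        payload={"r_true": r_true, "baseline": baseline, "noise_sd": noise_sd},
    )
    return series, truth


# ---------------------------------------------------------------------------
# cross-modality study table
# ---------------------------------------------------------------------------

def gen_study_table(
    n_samples: int,
    correlation: np.ndarray,
    seed: int,
    *,
    columns: Sequence[str] | None = None,
    log_sigma: float = 0.25,
    log_mu: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Multivariate draws with a target correlation, mapped to positive scales.

    Correlated standard normals (eigen-decomposition factor, so exactly
    singular targets such as perfectly correlated pairs are allowed) are
    mapped through ``exp(log_mu + log_sigma*z)`` column-wise; a monotone map,
    so perfectly correlated columns stay identical.
    """
    corr = np.asarray(correlation, dtype=float)
    k = corr.shape[0]
    if corr.shape != (k, k) or not np.allclose(corr, corr.T):
        raise ValueError("correlation must be a symmetric square matrix")
    vals, vecs = np.linalg.eigh(corr)
    if np.min(vals) < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    factor = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, k)) @ factor.T
    mu = np.zeros(k) if log_mu is None else np.asarray(log_mu, dtype=float)
    data = np.exp(mu + log_sigma * z)
    if columns is None:
        columns = [f"prop_{i}" for i in range(k)]
    table = pd.DataFrame(data, columns=list(columns))
    truth = GroundTruth(
        kind="study_table",
        seed=seed,
        payload={"correlation": corr, "log_sigma": log_sigma, "n_samples": n_samples},
    )
    return table, truth
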