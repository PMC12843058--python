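"""Electron-microscopy morphometry: image to core-diameter distribution.

Pipeline stages, in order: grayscale inversion + median filtering, Otsu
thresholding, morphological closing, distance-transform/watershed particle
separation, and per-particle minimum-enclosing-circle diameter measurement.

The acquired images show dark particles on a bright background; after
inversion the particles are bright and the threshold selects intensities
strictly above the Otsu value.  Diameters are always reported both in pixels
and, through the calibration, in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import peak_local_max
from skimage.filters import median as skimage_median
from skimage.morphology import closing as _morph_closing, disk
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "CalibratedImage",
    "SegmentationResult",
    "DiameterDistribution",
    "TemConfig",
    "preprocess",
    "otsu_threshold",
    "binarize_and_close",
    "separate_particles",
    "measure_diameters",
    "minimum_enclosing_circle",
    "run_tem_pipeline",
]


@dataclass(frozen=True)
class CalibratedImage:
    """Grayscale image with a physical pixel-size calibration.

    ``pixels`` must be an integer array of bit depth 8 or 16;
    ``pixel_size_nm`` is the edge length of one pixel in nanometres.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if px.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise ValueError("image must be uint8 or uint16")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        return int(np.iinfo(self.pixels.dtype).max)


@dataclass(frozen=True)
class SegmentationResult:
    """Labelled particles with per-particle geometry.

    ``labels`` uses 0 for background and contiguous 1..N for particles;
    ``records`` has one row per label with columns label, row, col,
    diameter_px, diameter_nm, area_px.
    """

    mask: np.ndarray
    labels: np.ndarray
    records: pd.DataFrame

    def __post_init__(self) -> None:
        n = int(self.labels.max())
        present = np.unique(self.labels)
        expected = np.arange(0, n + 1)
        if not np.array_equal(present[present > 0], expected[1:]):
            raise ValueError("labels must be contiguous 1..N")
        if np.any(self.labels[~self.mask] != 0):
            raise ValueError("labelled pixels must lie inside the mask")
        if len(self.records) and (self.records["diameter_px"] <= 0).any():
            raise ValueError("diameters must be > 0")

    @property
    def n_particles(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class DiameterDistribution:
    """Core-diameter sample with a fixed-width histogram and summary stats."""

    diameters_nm: np.ndarray
    bin_edges_nm: np.ndarray
    counts: np.ndarray
    summary: dict

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_nm, dtype=float)
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        if int(np.sum(self.counts)) != d.size:
            raise ValueError("histogram counts must sum to n")
        object.__setattr__(self, "diameters_nm", d)

    @classmethod
    def from_diameters(
        cls, diameters_nm: Sequence[float], bin_width_nm: float = 1.0
    ) -> "DiameterDistribution":
        d = np.asarray(diameters_nm, dtype=float)
        if d.size == 0:
            raise ValueError("no diameters to bin")
        lo = bin_width_nm * np.floor(d.min() / bin_width_nm)
        hi = bin_width_nm * np.ceil(d.max() / bin_width_nm)
        if hi <= lo:
            hi = lo + bin_width_nm
        edges = np.arange(lo, hi + bin_width_nm / 2, bin_width_nm)
        counts, edges = np.histogram(d, bins=edges)
        mode_bin = int(np.argmax(counts))
        summary = {
            "n": int(d.size),
            "mean_nm": float(np.mean(d)),
            "median_nm": float(np.median(d)),
            "sd_nm": float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
            "mode_bin_center_nm": float(0.5 * (edges[mode_bin] + edges[mode_bin + 1])),
        }
        return cls(diameters_nm=d, bin_edges_nm=edges, counts=counts, summary=summary)


@dataclass(frozen=True)
class TemConfig:
    """Tunable knobs of the pipeline (the source procedure names the
    operations but no kernel sizes, so all sizes are configuration)."""

    median_radius: int = 1
    closing_radius: int = 2
    min_marker_distance: int = 10
    exclude_border: bool = True
    bin_width_nm: float = 1.0
    debug: bool = False


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def preprocess(image: CalibratedImage, median_radius: int = 1) -> CalibratedImage:
    """Invert the grayscale (max_value - v) and median-filter with a disk.

    The inversion turns dark particles into bright objects on a dark
    background; the median filter suppresses impulse noise while keeping
    edges.  Output keeps the shape and bit depth of the input.
    """
    if median_radius < 1:
        raise ValueError("median_radius must be >= 1")
    inverted = (image.max_value - image.pixels).astype(image.pixels.dtype)
    filtered = skimage_median(inverted, footprint=disk(median_radius))
    return replace(image, pixels=filtered.astype(image.pixels.dtype))


def otsu_threshold(image: CalibratedImage) -> int:
    """Between-class-variance-maximizing threshold over integer levels.

    Foreground is defined as intensities strictly greater than the returned
    value.  Ties are broken toward the lowest threshold (first argmax).
    Implemented directly on the integer histogram so the tie-break rule is
    explicit and checkable against a brute-force scan.
    """
    v = image.pixels.ravel()
    lo, hi = int(v.min()), int(v.max())
    if lo == hi:
        raise ValueError("constant image: no separable intensity classes")
    hist = np.bincount(v, minlength=hi + 1).astype(float)
    levels = np.arange(hist.size, dtype=float)
    # cumulative class weights/means for thresholds t = 0..hi-1 (class0: v<=t)
    w0 = np.cumsum(hist)[:-1]
    w1 = v.size - w0
    m0 = np.cumsum(hist * levels)[:-1]
    total = float(np.sum(hist * levels))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (total - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[np.isnan(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def binarize_and_close(
    image: CalibratedImage, threshold: int, closing_radius: int = 2
) -> np.ndarray:
    """Threshold (strictly greater) then morphologically close with a disk."""
    mask = image.pixels > threshold
    if closing_radius >= 1:
        mask = _morph_closing(mask, footprint=disk(closing_radius)).astype(bool)
    return mask


def separate_particles(mask: np.ndarray, min_marker_distance: int = 10) -> np.ndarray:
    """Split touching particles by distance-transform watershed.

    Markers are local maxima of the Euclidean distance transform separated by
    at least ``min_marker_distance`` pixels; the watershed runs on the
    negated distance map restricted to the mask.  An empty mask yields an
    all-zero label image.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    distance = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        distance, min_distance=max(1, int(min_marker_distance)), labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = 1
    markers, _ = ndi.label(markers)
    if markers.max() == 0:  # degenerate: fall back to connected components
        markers, _ = ndi.label(mask)
    ws = watershed(-distance, markers, mask=mask)
    labels, _, _ = relabel_sequential(ws)
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# minimum enclosing circle
# ---------------------------------------------------------------------------

def _circumcircle(a, b, c):
    """Circumcircle of three points, or the diametric circle of the farthest
    pair when the points are (near-)collinear."""
    (ay, ax), (by, bx), (cy, cx) = a, b, c
    d = 2.0 * (ay * (bx - cx) + by * (cx - ax) + cy * (ax - bx))
    scale = max(abs(ay), abs(ax), abs(by), abs(bx), abs(cy), abs(cx), 1.0)
    if abs(d) < 1e-12 * scale**2:
        pts = [np.asarray(p, float) for p in (a, b, c)]
        best = max(
            ((i, j) for i in range(3) for j in range(i + 1, 3)),
            key=lambda ij: np.sum((pts[ij[0]] - pts[ij[1]]) ** 2),
        )
        center = 0.5 * (pts[best[0]] + pts[best[1]])
        return center, float(np.linalg.norm(pts[best[0]] - center))
    ua = ay**2 + ax**2
    ub = by**2 + bx**2
    uc = cy**2 + cx**2
    uy = (ua * (bx - cx) + ub * (cx - ax) + uc * (ax - bx)) / d
    ux = (ua * (cy - by) + ub * (ay - cy) + uc * (by - ay)) / d
    center = np.array([uy, ux])
    return center, float(np.linalg.norm(np.asarray(a, float) - center))


def minimum_enclosing_circle(points) -> tuple[np.ndarray, float]:
    """Exact minimum enclosing circle of a 2-D point set.

    Uses the randomized incremental (Welzl move-to-front) algorithm, expected
    linear time, after an optional convex-hull reduction for large sets.
    Returns ``(center, radius)``; a single point gives radius 0.
    """
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if pts.shape[0] == 0:
        raise ValueError("empty point set")
    if pts.shape[0] == 1:
        return pts[0].copy(), 0.0
    if pts.shape[0] > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear input; Welzl handles it directly
    rng = np.random.default_rng(0)  # deterministic: MEC is unique anyway
    p = pts[rng.permutation(pts.shape[0])]
    eps = 1e-10 * (1.0 + float(np.max(np.abs(p))))

    def inside(pt, center, radius):
        return np.linalg.norm(pt - center) <= radius + eps

    center, radius = p[0].copy(), 0.0
    for i in range(1, p.shape[0]):
        if inside(p[i], center, radius):
            continue
        center, radius = p[i].copy(), 0.0
        for j in range(i):
            if inside(p[j], center, radius):
                continue
            center = 0.5 * (p[i] + p[j])
            radius = float(np.linalg.norm(p[i] - center))
            for k in range(j):
                if inside(p[k], center, radius):
                    continue
                center, radius = _circumcircle(p[i], p[j], p[k])
    return center, radius


def measure_diameters(
    labels: np.ndarray,
    pixel_size_nm: float,
    *,
    bin_width_nm: float = 1.0,
) -> tuple[pd.DataFrame, DiameterDistribution]:
    """Per-label minimum-enclosing-circle diameters, in px and nm.

    The circle is computed over pixel centres; degenerate regions whose
    enclosing radius is zero (single pixels) are padded to a 1-px diameter so
    no particle reports a zero size.  Returns the per-particle table ordered
    by label id plus the assembled distribution.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    n = int(labels.max())
    if n < 1:
        raise ValueError("no labelled particles to measure")
    rows = []
    objects = ndi.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        ys, xs = np.nonzero(labels[sl] == lab)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        coords = np.column_stack([ys, xs]).astype(float)
        center, radius = minimum_enclosing_circle(coords)
        diameter_px = 2.0 * radius if radius > 0 else 1.0
        rows.append(
            {
                "label": lab,
                "row": float(center[0]),
                "col": float(center[1]),
                "diameter_px": diameter_px,
                "diameter_nm": diameter_px * pixel_size_nm,
                "area_px": int(coords.shape[0]),
            }
        )
    records = pd.DataFrame(rows)
    dist = DiameterDistribution.from_diameters(
        records["diameter_nm"].to_numpy(), bin_width_nm=bin_width_nm
    )
    return records, dist


def _drop_border_labels(labels: np.ndarray) -> np.ndarray:
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border = border[border > 0]
    if border.size:
        labels = labels.copy()
        labels[np.isin(labels, border)] = 0
        labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def run_tem_pipeline(
    image: CalibratedImage, config: TemConfig = TemConfig()
) -> tuple[SegmentationResult, DiameterDistribution]:
    """Compose the five stages in acquisition order.

    invert+median -> Otsu -> threshold+close -> watershed split -> enclosing
    circles.  Border-touching particles are dropped by default since their
    enclosing circles are truncated.  With ``config.debug`` the intermediate
    images are attached to the returned ``SegmentationResult.records.attrs``.
    """
    pre = preprocess(image, median_radius=config.median_radius)
    threshold = otsu_threshold(pre)
    mask = binarize_and_close(pre, threshold, closing_radius=config.closing_radius)
    labels = separate_particles(mask, min_marker_distance=config.min_marker_distance)
    if config.exclude_border:
        labels = _drop_border_labels(labels)
    if labels.max() < 1:
        raise ValueError("segmentation found no particles")
    records, dist = measure_diameters(
        labels, image.pixel_size_nm, bin_width_nm=config.bin_width_nm
    )
    seg = SegmentationResult(mask=labels > 0, labels=labels, records=records)
    if config.debug:
        records.attrs["preprocessed"] = pre.pixels
        records.attrs["threshold"] = threshold
        records.attrs["mask"] = mask
    return seg, dist
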