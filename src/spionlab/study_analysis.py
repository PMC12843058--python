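"""Cross-modality synthesis: correlation matrix and optimum-diameter overlap.

Pearson correlations (the choice is recorded in the report) with two-sided
p-values from the exact t transform, labelled ``significant`` (p < 0.05),
``trend`` (0.05 <= p < 0.1) or ``ns``.  The optimum-diameter analysis treats
all grid points within a plateau fraction (default 5 %) of a curve's peak as
its "maximum range" and intersects the transverse-relaxivity and
heating-power ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationReport",
    "OverlapReport",
    "pearson_matrix",
    "optimum_overlap",
    "feasibility_report",
    "significance_label",
]

SIGNIFICANT_P = 0.05
TREND_P = 0.10


def significance_label(p: float) -> str:
    if np.isnan(p):
        return "missing"
    if p < SIGNIFICANT_P:
        return "significant"
    if p < TREND_P:
        return "trend"
    return "ns"


@dataclass(frozen=True)
class CorrelationReport:
    """Symmetric Pearson matrix with p-values and significance labels."""

    columns: list[str]
    r: np.ndarray
    p: np.ndarray
    labels: np.ndarray  # dtype=object, strings
    n: int
    method: str = "pearson"
    bonferroni: bool = False

    def __post_init__(self) -> None:
        k = len(self.columns)
        if self.r.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError("matrix shapes must match the column count")
        finite = ~np.isnan(self.r)
        if not np.allclose(self.r[finite], self.r.T[finite]):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r)[~np.isnan(np.diag(self.r))], 1.0):
            raise ValueError("diagonal must be 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.columns, columns=self.columns)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "bonferroni": self.bonferroni,
            "columns": self.columns,
            "r": np.where(np.isnan(self.r), None, self.r.round(12)).tolist(),
            "p": np.where(np.isnan(self.p), None, self.p).tolist(),
            "labels": self.labels.tolist(),
        }


def pearson_matrix(
    table: pd.DataFrame, *, bonferroni: bool = False
) -> CorrelationReport:
    """Pairwise Pearson r with two-sided p from t = r*sqrt((n-2)/(1-r^2)).

    Requires at least 3 complete rows.  A zero-variance column gives an
    undefined correlation, reported as missing with a warning.  No
    multiple-testing correction is applied unless ``bonferroni`` is set.
    """
    if table.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    if table.isna().any().any():
        raise ValueError("table must have no missing cells")
    cols = list(table.columns)
    k = len(cols)
    n = table.shape[0]
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        bad = [c for c, z in zip(cols, zero_var) if z]
        warnings.warn(f"zero-variance column(s) {bad}: correlations undefined")
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    labels = np.full((k, k), "missing", dtype=object)
    n_pairs = k * (k - 1) // 2
    df = n - 2
    for i in range(k):
        if not zero_var[i]:
            r[i, i], p[i, i] = 1.0, 0.0
            labels[i, i] = "significant"
        for j in range(i + 1, k):
            if zero_var[i] or zero_var[j]:
                continue
            xi = x[:, i] - x[:, i].mean()
            xj = x[:, j] - x[:, j].mean()
            rij = float(np.dot(xi, xj) / np.sqrt(np.dot(xi, xi) * np.dot(xj, xj)))
            rij = float(np.clip(rij, -1.0, 1.0))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt(df / (1.0 - rij**2))
                pij = float(2.0 * stats.t.sf(abs(t), df))
            if bonferroni:
                pij = min(1.0, pij * n_pairs)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            labels[i, j] = labels[j, i] = significance_label(pij)
    return CorrelationReport(
        columns=cols, r=r, p=p, labels=labels, n=n, bonferroni=bonferroni
    )


@dataclass(frozen=True)
class OverlapReport:
    """Per-curve argmax/plateau ranges and the r2-power intersection."""

    argmax_nm: dict
    max_range_nm: dict         # curve name -> (lo, hi)
    overlap_nm: tuple | None   # (lo, hi) intersection of r2 and power, or None
    verdict: str
    plateau_fraction: float


def _max_range(diameters: np.ndarray, values: np.ndarray, frac: float):
    peak = float(np.max(values))
    qual = diameters[values >= (1.0 - frac) * peak]
    return float(qual.min()), float(qual.max())


def optimum_overlap(
    diameters_nm: Sequence[float],
    r1: Sequence[float],
    r2: Sequence[float],
    power: Sequence[float],
    *,
    plateau_fraction: float = 0.05,
) -> OverlapReport:
    """Intersect the r2 and heating-power maximum ranges on a common grid.

    All grid points within ``plateau_fraction`` of a curve's peak form its
    maximum range.  The verdict is "joint optimum exists" when the r2 and
    power ranges intersect, otherwise "no joint optimum".
    """
    d = np.asarray(diameters_nm, dtype=float)
    curves = {"r1": np.asarray(r1, float), "r2": np.asarray(r2, float),
              "power": np.asarray(power, float)}
    for name, c in curves.items():
        if c.shape != d.shape:
            raise ValueError(f"curve {name!r} is not on the common diameter grid")
    argmax = {name: float(d[int(np.argmax(c))]) for name, c in curves.items()}
    ranges = {name: _max_range(d, c, plateau_fraction) for name, c in curves.items()}
    lo = max(ranges["r2"][0], ranges["power"][0])
    hi = min(ranges["r2"][1], ranges["power"][1])
    if lo <= hi:
        overlap, verdict = (lo, hi), "joint optimum exists"
    else:
        overlap, verdict = None, "no joint optimum"
    return OverlapReport(
        argmax_nm=argmax,
        max_range_nm=ranges,
        overlap_nm=overlap,
        verdict=verdict,
        plateau_fraction=plateau_fraction,
    )


def feasibility_report(
    property_table: pd.DataFrame,
    curves: Mapping[str, Sequence[float]] | None = None,
    config: Mapping | None = None,
    *,
    plateau_fraction: float = 0.05,
    bonferroni: bool = False,
) -> dict:
    """Structured joint report: correlations, optima overlap, parameter echo.

    ``curves``, when given, must contain ``diameters_nm`` plus any of
    ``r1``, ``r2``, ``power``; the overlap section is produced only when
    both ``r2`` and ``power`` are present (a warning is issued otherwise).
    Small tables (n < 5) are flagged as having low significance power.
    """
    corr = pearson_matrix(property_table, bonferroni=bonferroni)
    report: dict = {
        "correlations": corr.to_dict(),
        "parameters": dict(config) if config else {},
        "notes": [],
    }
    if corr.n < 5:
        report["notes"].append(
            f"only {corr.n} rows: correlation confidence intervals are very wide"
        )
    if curves is not None:
        have = set(curves) - {"diameters_nm"}
        if {"r2", "power"} <= have:
            d = np.asarray(curves["diameters_nm"], dtype=float)
            r1 = np.asarray(curves.get("r1", np.zeros_like(d)), dtype=float)
            overlap = optimum_overlap(
                d, r1, curves["r2"], curves["power"], plateau_fraction=plateau_fraction
            )
            report["optimum"] = {
                "argmax_nm": overlap.argmax_nm,
                "max_range_nm": overlap.max_range_nm,
                "overlap_nm": overlap.overlap_nm,
                "verdict": overlap.verdict,
                "plateau_fraction": overlap.plateau_fraction,
            }
        else:
            missing = {"r2", "power"} - have
            warnings.warn(f"curves missing {sorted(missing)}: overlap section omitted")
            report["notes"].append("optimum-overlap section omitted (missing curves)")
    return report


def report_to_markdown(report: dict) -> str:
    """Render a feasibility report as a short human-readable summary."""
    lines = ["# Feasibility report", ""]
    corr = report["correlations"]
    cols = corr["columns"]
    lines.append(f"Correlation method: {corr['method']} (n = {corr['n']})")
    lines.append("")
    header = "| | " + " | ".join(cols) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (len(cols) + 1))
    for i, ci in enumerate(cols):
        cells = []
        for j in range(len(cols)):
            r = corr["r"][i][j]
            label = corr["labels"][i][j]
            cell = "–" if r is None else f"{r:.3f}"
            if label in ("significant", "trend") and i != j:
                cell += f" ({label})"
            cells.append(cell)
        lines.append(f"| {ci} | " + " | ".join(cells) + " |")
    if "optimum" in report:
        opt = report["optimum"]
        lines += ["", "## Optimum diameters"]
        for name, val in opt["argmax_nm"].items():
            lo, hi = opt["max_range_nm"][name]
            lines.append(f"- {name}: argmax {val:.1f} nm, range {lo:.1f}-{hi:.1f} nm")
        if opt["overlap_nm"]:
            lo, hi = opt["overlap_nm"]
            lines.append(f"- r2/power overlap: {lo:.1f}-{hi:.1f} nm")
        lines.append(f"- verdict: **{opt['verdict']}**")
    for note in report.get("notes", []):
        lines.append(f"\n> {note}")
    return "\n".join(lines) + "\n"
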