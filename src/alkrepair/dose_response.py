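"""Dose sweeps and the quadratic DSB dose-response fit.

The plotted quantity follows the gel convention: percent linear form among
nicked/linearized molecules, 100 * linear / (linear + oc), with covalently
closed circles excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .lesions import (
    AdductSpectrum,
    DoseCalibration,
    DEFAULT_CALIBRATION,
    PlasmidSpec,
    dose_to_density,
)
from .repair import BatchSummary, RepairParams, batch_simulate


@dataclass(frozen=True)
class DoseResponsePoint:
    dose_mM: float
    nalkyl_density: float
    linear_fraction: float  # percent of (linear + oc), the gel-plot convention
    linear_pct_total: float  # percent of all molecules (linear band amount)
    oc_fraction: float  # percent of all molecules
    ccc_fraction: float  # percent of all molecules
    se_linear: float  # percent, for linear_fraction
    se_linear_total: float  # percent, for linear_pct_total
    n_linear: int
    n_oc: int
    n_ccc: int

    @property
    def n_molecules(self) -> int:
        return self.n_linear + self.n_oc + self.n_ccc


@dataclass(frozen=True)
class QuadraticFit:
    slope: float  # percent per mM^2
    intercept: float  # percent
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")


def point_from_summary(
    dose_mM: float, nalkyl_density: float, summary: BatchSummary
) -> DoseResponsePoint:
    denom = summary.n_linear + summary.n_oc
    if denom > 0:
        p = summary.n_linear / denom
        lin_pct = 100.0 * p
        se = 100.0 * math.sqrt(p * (1 - p) / denom)
    else:
        lin_pct, se = 0.0, 0.0
    n = summary.n_molecules
    return DoseResponsePoint(
        dose_mM=dose_mM,
        nalkyl_density=nalkyl_density,
        linear_fraction=lin_pct,
        linear_pct_total=100.0 * summary.frac_linear,
        oc_fraction=100.0 * summary.n_oc / n,
        ccc_fraction=100.0 * summary.n_ccc / n,
        se_linear=se,
        se_linear_total=100.0 * summary.se_linear,
        n_linear=summary.n_linear,
        n_oc=summary.n_oc,
        n_ccc=summary.n_ccc,
    )


def sweep_doses(
    doses_mM: Sequence[float],
    plasmid: PlasmidSpec,
    spectrum: AdductSpectrum,
    params: RepairParams,
    n: int,
    seed: Optional[int] = None,
    cal: DoseCalibration = DEFAULT_CALIBRATION,
) -> list[DoseResponsePoint]:
    """One simulated :class:`DoseResponsePoint` per dose (n molecules each)."""
    if len(doses_mM) == 0:
        raise ValueError("empty dose list")
    if n < 1:
        raise ValueError("n per dose must be >= 1")
    rng = np.random.default_rng(seed)
    points = []
    for dose in doses_mM:
        density = dose_to_density(dose, cal)
        summary = batch_simulate(plasmid, density, spectrum, params, n, rng=rng)
        points.append(point_from_summary(dose, density, summary))
    return points


def fit_linear_fraction_vs_dose_squared(
    points: Sequence[DoseResponsePoint],
    weighted: bool = False,
    quantity: str = "ratio",
) -> QuadraticFit:
    """OLS of linear-fraction percent against dose^2 (mM^2).

    ``weighted`` switches to inverse-variance weighting using each point's
    SE (points with zero SE get unit weight); the default is the unweighted
    fit used for the three-point experimental series.  ``quantity`` picks
    the y variable as in :func:`fold_change` (default: the plotted
    linear/(linear+oc) convention).
    """
    if quantity not in ("ratio", "total"):
        raise ValueError(f"unknown quantity {quantity!r}")
    attr, se_attr = (
        ("linear_fraction", "se_linear")
        if quantity == "ratio"
        else ("linear_pct_total", "se_linear_total")
    )
    if len(points) < 2:
        raise ValueError("need at least 2 points to fit")
    x = np.array([p.dose_mM**2 for p in points], dtype=float)
    y = np.array([getattr(p, attr) for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in dose^2; cannot fit")
    if weighted:
        se = np.array([getattr(p, se_attr) for p in points], dtype=float)
        w = np.where(se > 0, 1.0 / se**2, 1.0)
    else:
        w = np.ones_like(x)
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    yhat = slope * x + intercept
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return QuadraticFit(float(slope), float(intercept), min(1.0, max(0.0, r2)))


@dataclass(frozen=True)
class FoldChange:
    value: float
    se: float


def fold_change(
    point_low: DoseResponsePoint,
    point_high: DoseResponsePoint,
    quantity: str = "ratio",
) -> FoldChange:
    """Fold change (high/low) of the linear fraction, with propagated SE.

    ``quantity="ratio"`` compares the gel-plot convention
    linear/(linear+oc); ``quantity="total"`` compares the linear band
    amount per input molecule (linear/total), the quantity whose ~fourfold
    increase per doubled dose expresses the quadratic law directly.
    """
    attr, se_attr = (
        ("linear_fraction", "se_linear")
        if quantity == "ratio"
        else ("linear_pct_total", "se_linear_total")
    )
    if quantity not in ("ratio", "total"):
        raise ValueError(f"unknown quantity {quantity!r}")
    lo, hi = getattr(point_low, attr), getattr(point_high, attr)
    lo_se, hi_se = getattr(point_low, se_attr), getattr(point_high, se_attr)
    if lo <= 0:
        raise ValueError("low point has zero linear fraction; ratio undefined")
    ratio = hi / lo
    rel = (lo_se / lo) ** 2
    if hi > 0:
        rel += (hi_se / hi) ** 2
    return FoldChange(ratio, ratio * math.sqrt(rel))


def loglog_slope(points: Sequence[DoseResponsePoint], quantity: str = "total") -> float:
    """Least-squares slope of log(linear fraction) vs log(density).

    Uses the linear-per-total-molecules fraction by default (the quantity
    that is quadratic in density in the rare-event regime; the
    linear/(linear+oc) ratio is only quadratic once oc saturates).  Points
    with zero linear fraction are excluded (log undefined).
    """
    attr = "linear_pct_total" if quantity == "total" else "linear_fraction"
    pts = [p for p in points if getattr(p, attr) > 0]
    if len(pts) < 2:
        raise ValueError("need >= 2 points with positive linear fraction")
    x = np.log([p.nalkyl_density for p in pts])
    y = np.log([getattr(p, attr) for p in pts])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def write_points_tsv(points: Sequence[DoseResponsePoint], path) -> None:
    cols = (
        "dose_mM",
        "nalkyl_density",
        "linear_fraction",
        "linear_pct_total",
        "oc_fraction",
        "ccc_fraction",
        "se_linear",
        "se_linear_total",
        "n_linear",
        "n_oc",
        "n_ccc",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in points:
            fh.write("\t".join(f"{getattr(p, c):.8g}" if isinstance(getattr(p, c), float)
                               else str(getattr(p, c)) for c in cols) + "\n")


def plot_dose_response(points, fit: QuadraticFit, path) -> None:
    """Optional dose^2 vs %linear figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p.dose_mM**2 for p in points])
    y = np.array([p.linear_fraction for p in points])
    yerr = np.array([p.se_linear for p in points])
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(x, y, yerr=yerr, fmt="o", capsize=3)
    xs = np.linspace(0, x.max() * 1.05 if x.max() > 0 else 1, 50)
    ax.plot(xs, fit.slope * xs + fit.intercept, "-", lw=1)
    ax.set_xlabel("dose$^2$ (mM$^2$)")
    ax.set_ylabel("% linear (linear / (linear + oc))")
    ax.set_title(f"y = {fit.slope:.4f}x + {fit.intercept:.4f}  (R$^2$={fit.r_squared:.4f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
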