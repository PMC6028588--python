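"""CsrA titration analysis: repression ratios and hyperbolic K_d fits.

A reporter fused to a target 5' UTR is measured at a series of CsrA
expression levels (the RBS-design proxy, in arbitrary units; the uninduced
condition is the RBS level times the promoter-leakiness factor 0.000645).
Per dataset the repression ratio of each point is the maximum of all
average mean fluorescences divided by that point's average mean
fluorescence (>= 1, equal to 1 at the brightest point), then min-max
normalized to [0, 1].  Treating the normalized repression ratio as the
fractional occupancy theta, the dissociation constant is approximated by
fitting the hyperbola

    theta = [CsrA] / (K_d + [CsrA])

by nonlinear least squares.  Because observed ratios are min-max normalized,
the fitted model is the same hyperbola passed through the identical min-max
normalization over the measured expression levels, which makes a noiseless
simulate -> analyze -> fit round trip recover K_d exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LEAKINESS",
    "TitrationPoint",
    "TitrationFit",
    "uninduced_expression",
    "compute_ratios",
    "fit_kd",
    "simulate_titration",
    "points_from_table",
]

#: Promoter leakiness: fractional expression of the uninduced condition
#: relative to the RBS's putative translation level.
LEAKINESS = 0.000645


def uninduced_expression(rbs_level: float) -> float:
    """CsrA expression proxy of the uninduced condition for a given RBS."""
    return rbs_level * LEAKINESS


@dataclass
class TitrationPoint:
    """One construct (RBS variant x induction state) in a titration series."""

    label: str
    csra_expression: float  # putative translation level, AU
    fluorescences: tuple[float, ...]  # replicate mean fluorescences
    repression_ratio: float | None = None
    normalized_repression_ratio: float | None = None

    @property
    def mean_fluorescence(self) -> float:
        return float(np.mean(self.fluorescences))


@dataclass
class TitrationFit:
    kd: float
    theta_predicted: np.ndarray
    residual_sum_of_squares: float
    converged: bool
    message: str = ""
    n_points: int = 0


class DegenerateDataError(ValueError):
    """Raised when the dataset has no dynamic range to normalize."""


def compute_ratios(points: list[TitrationPoint]) -> list[TitrationPoint]:
    """Attach repression ratios and their min-max normalization to *points*.

    Points with non-positive mean fluorescence are excluded with a
    diagnostic.  Requires at least two valid points; all-equal fluorescences
    have no dynamic range and raise :class:`DegenerateDataError`.
    """
    valid, dropped = [], []
    for p in points:
        if p.mean_fluorescence > 0:
            valid.append(p)
        else:
            dropped.append(p.label)
    if dropped:
        import warnings

        warnings.warn(
            f"excluded {len(dropped)} point(s) with non-positive fluorescence: "
            f"{', '.join(dropped)}",
            stacklevel=2,
        )
    if len(valid) < 2:
        raise ValueError("need at least two points with positive fluorescence")
    fmax = max(p.mean_fluorescence for p in valid)
    for p in valid:
        p.repression_ratio = fmax / p.mean_fluorescence
    ratios = np.array([p.repression_ratio for p in valid])
    rmin, rmax = ratios.min(), ratios.max()
    if rmax == rmin:
        raise DegenerateDataError(
            "degenerate dynamic range: all repression ratios equal; cannot normalize"
        )
    for p in valid:
        p.normalized_repression_ratio = (p.repression_ratio - rmin) / (rmax - rmin)
    return valid


def _normalized_hyperbola(x: np.ndarray, kd: float) -> np.ndarray:
    theta = x / (kd + x)
    tmin, tmax = theta.min(), theta.max()
    if tmax == tmin:
        return np.zeros_like(theta)
    return (theta - tmin) / (tmax - tmin)


def fit_kd(points: list[TitrationPoint]) -> TitrationFit:
    """Least-squares K_d of the normalized binding hyperbola.

    Positivity is enforced by optimizing log K_d; initialization is
    multi-start from the expression levels nearest theta = 0.5 plus the
    geometric mean of the design.  A fit that fails to converge is returned
    flagged, never silently.
    """
    pts = [p for p in points if p.normalized_repression_ratio is not None]
    x = np.array([p.csra_expression for p in pts], dtype=float)
    y = np.array([p.normalized_repression_ratio for p in pts], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 points with distinct CsrA expression levels")

    def residuals(log_kd: np.ndarray) -> np.ndarray:
        return _normalized_hyperbola(x, np.exp(log_kd[0])) - y

    mid_idx = int(np.argmin(np.abs(y - 0.5)))
    positive = x[x > 0]
    starts = [x[mid_idx], float(np.exp(np.mean(np.log(positive))))]
    starts = [s for s in starts if s > 0] or [1.0]
    best = None
    for s0 in starts:
        res = least_squares(residuals, x0=[np.log(s0)], method="lm")
        if best is None or res.cost < best.cost:
            best = res
    rss = float(2 * best.cost)
    kd = float(np.exp(best.x[0]))
    return TitrationFit(
        kd=kd,
        theta_predicted=_normalized_hyperbola(x, kd),
        residual_sum_of_squares=rss,
        converged=bool(best.success),
        message=best.message,
        n_points=len(pts),
    )


def simulate_titration(
    kd: float,
    expression_levels: list[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    max_repression: float = 10.0,
    f0: float = 10000.0,
    replicates: int = 3,
) -> list[TitrationPoint]:
    """Synthetic titration series drawn from the binding hyperbola.

    Fluorescence is generated as F = f0 / (1 + (max_repression - 1) * theta)
    with multiplicative Gaussian noise of relative standard deviation
    *noise_sd* per replicate, which makes the repression ratio affine in
    theta: at zero noise the normalized repression ratios reproduce the
    generating theta curve exactly.  Deterministic for a fixed seed.
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    rng = np.random.default_rng(seed)
    points = []
    for x in expression_levels:
        theta = x / (kd + x)
        f = f0 / (1.0 + (max_repression - 1.0) * theta)
        reps = tuple(
            float(f * (1.0 + rng.normal(0.0, noise_sd))) if noise_sd > 0 else float(f)
            for _ in range(replicates)
        )
        points.append(
            TitrationPoint(label=f"x={x:g}", csra_expression=float(x), fluorescences=reps)
        )
    return points


def points_from_table(df: pd.DataFrame) -> list[TitrationPoint]:
    """Build titration points from a delimited table.

    Expected columns: ``construct``, ``csra_expression``, then one or more
    replicate fluorescence columns.  A single replicate column is treated as
    the mean.
    """
    required = {"construct", "csra_expression"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    rep_cols = [c for c in df.columns if c not in required]
    if not rep_cols:
        raise ValueError("no replicate fluorescence columns found")
    return [
        TitrationPoint(
            label=str(row["construct"]),
            csra_expression=float(row["csra_expression"]),
            fluorescences=tuple(float(row[c]) for c in rep_cols if pd.notna(row[c])),
        )
        for _, row in df.iterrows()
    ]
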