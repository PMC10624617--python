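"""Structure-factor extrapolation and N_EXT determination.

Difference amplitudes are added along the dark calculated phase:
F_EXT = | |F_dark,calc| + n_ext * dF | (difference-Fourier convention; the
factor of two of the half-weighted difference map makes the characteristic
N_EXT equal 2/f for a perturbed-state population fraction f, hence the
population transfer estimate PT = 200 / N_EXT in percent).

The characteristic N_EXT is the onset of negative-density buildup around
the perturbed region.  The default estimator is a continuous two-segment
piecewise-linear least-squares fit: in the tall-peak regime the scan
curve is a flat (near-zero) baseline followed by a linear rise, and the
fitted breakpoint is the onset.  A derivative-threshold estimator and a
quadratic-onset variant (useful when the over-threshold integral grows
convexly over a wide window) are available as alternatives.

Scans are run on the raw (unweighted) differences when available: the
Bayesian Q-weight shrinks large |dF| toward zero even for noise-free data,
which rescales the onset and biases PT = 200/N_EXT low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import integrate_negative_density, synthesize_map
from .types import RealSpaceMap, ReflectionError, ReflectionSet, StructureModel


class InconclusiveScanError(RuntimeError):
    def __init__(self, message: str, scan: "ExtrapolationScan"):
        super().__init__(message)
        self.scan = scan


@dataclass
class ExtrapolationScan:
    n_ext_values: np.ndarray
    integrated_negative_density: np.ndarray
    characteristic_n_ext: float | None = None
    population_transfer_percent: float | None = None
    breakpoint_fit: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_ext": self.n_ext_values,
            "integrated_negative_density": self.integrated_negative_density,
        })


def extrapolate_structure_factors(weighted_diff: ReflectionSet,
                                  dark_calc: ReflectionSet,
                                  n_ext: float) -> ReflectionSet:
    """Extrapolated amplitudes |F_dark,calc| + n_ext·ΔF with dark phases.

    Sign flips (over-extrapolated amplitudes) are kept in the complex
    representation: the amplitude is the absolute value and the phase is
    rotated by 180 degrees, so extrapolation stays linear in n_ext.
    """
    if n_ext < 0:
        raise ValueError("n_ext must be non-negative")
    if dark_calc.phases_deg is None:
        raise ReflectionError("dark calculated set carries no phases")
    merged = weighted_diff.join_common(dark_calc)
    signed = merged["F_b"].to_numpy(float) + n_ext * merged["F_a"].to_numpy(float)
    phase = merged["phase"].to_numpy(float).copy()
    phase[signed < 0] = (phase[signed < 0] + 180.0) % 360.0
    df = merged[["h", "k", "l"]].copy()
    df["F"] = np.abs(signed)
    df["sigF"] = n_ext * merged["sigF_a"].to_numpy(float)
    df["phase"] = phase
    return ReflectionSet(weighted_diff.cell, df, d_min=dark_calc.d_min)


def _breakpoint_search(x: np.ndarray, y: np.ndarray, design) -> tuple[float, np.ndarray]:
    """Minimize the SSE of a breakpoint-parameterized linear design."""

    def sse_at(b: float):
        A = design(x, b)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        return float(resid @ resid), coef

    candidates = np.linspace(x[1], x[-2], 200)
    sses = np.array([sse_at(b)[0] for b in candidates])
    i = int(np.argmin(sses))
    lo = candidates[max(0, i - 1)]
    hi = candidates[min(len(candidates) - 1, i + 1)]
    fine = np.linspace(lo, hi, 50)
    sses_f = np.array([sse_at(b)[0] for b in fine])
    b = float(fine[int(np.argmin(sses_f))])
    return b, sse_at(b)[1]


def fit_two_segment_elbow(x: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
    """Continuous two-segment piecewise-linear least squares.

    Returns the breakpoint and a fit report.  The breakpoint is optimized
    over a fine grid between interior sample points (continuous value, not
    restricted to the scan grid).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def design(x, b):
        return np.column_stack([np.ones_like(x), np.minimum(x, b),
                                np.maximum(x - b, 0.0)])

    b, coef = _breakpoint_search(x, y, design)
    resid = y - design(x, b) @ coef
    return b, {"breakpoint": b, "intercept": float(coef[0]),
               "slope_left": float(coef[1]),
               "slope_right": float(coef[1] + coef[2]),
               "sse": float(resid @ resid), "method": "two_segment"}


def fit_quadratic_onset(x: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
    """Linear baseline with a linear+quadratic rise after the breakpoint.

    Model: y = a + c1*x + c2*(x-b)_+ + c3*(x-b)_+^2; the quadratic term
    absorbs the convex growth of the over-threshold integral just past the
    onset, removing the late bias of the pure two-segment fit.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def design(x, b):
        r = np.maximum(x - b, 0.0)
        return np.column_stack([np.ones_like(x), x, r, r * r])

    b, coef = _breakpoint_search(x, y, design)
    resid = y - design(x, b) @ coef
    return b, {"breakpoint": b, "intercept": float(coef[0]),
               "slope_baseline": float(coef[1]),
               "slope_onset": float(coef[1] + coef[2]),
               "curvature_onset": float(coef[3]),
               "sse": float(resid @ resid), "method": "quadratic_onset"}


def derivative_threshold_elbow(x: np.ndarray, y: np.ndarray,
                               fraction: float = 0.1) -> float:
    """Alternative estimator: first point where the local slope exceeds a
    fraction of the final slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slopes = np.gradient(y, x)
    ref = slopes[-1]
    if ref <= 0:
        raise ValueError("scan has no rising tail")
    above = np.nonzero(slopes > fraction * ref)[0]
    if len(above) == 0:
        raise ValueError("no slope above threshold")
    return float(x[above[0]])


def scan_n_ext(
    weighted_diff: ReflectionSet,
    dark_calc: ReflectionSet,
    dark_model: StructureModel,
    region: list[tuple[str, int, str]] | np.ndarray,
    radius: float = 7.0,
    level: float = 3.0,
    n_ext_grid: np.ndarray | None = None,
    grid_factor: float = 3.0,
    method: str = "two_segment",
) -> ExtrapolationScan:
    """Integrate negative density around a region across an N_EXT grid and
    locate the characteristic N_EXT (PT = 200/N_EXT percent).

    ``region`` is either an array of Cartesian centers or a list of
    (chain, resseq, atom-name) selections resolved against ``dark_model``.
    If the difference set carries a raw ``delta_F`` column (as produced by
    Q-weighting) the scan extrapolates those unweighted differences.
    """
    if n_ext_grid is None:
        n_ext_grid = np.arange(1.0, 41.0, 1.0)
    n_ext_grid = np.asarray(n_ext_grid, float)
    if isinstance(region, np.ndarray):
        centers = np.atleast_2d(region)
    else:
        if len(region) == 0:
            raise ValueError("empty region selection")
        centers = np.array([[a.pos.x, a.pos.y, a.pos.z]
                            for a in (dark_model.find_atom(*sel) for sel in region)])
    diff = weighted_diff
    if "delta_F" in diff.data.columns:
        diff = diff.copy_with(F=diff.data["delta_F"].to_numpy(float))
    # fixed threshold from the dark map: per-map rms grows with n_ext
    # (the added differences raise the map power), which would deepen a
    # relative cut and mask the onset the scan is looking for
    dark_map = synthesize_map(dark_calc, grid_factor=grid_factor)
    threshold = -level * dark_map.rms
    # the extrapolated complex coefficient (F_dark + n*dF) e^{i phi_dark}
    # is linear in n, so every map on the grid is a linear combination of
    # the dark map and the unit-difference map: two FFTs cover the scan
    ext0 = synthesize_map(
        extrapolate_structure_factors(diff, dark_calc, 0.0),
        grid_factor=grid_factor)
    ext1 = synthesize_map(
        extrapolate_structure_factors(diff, dark_calc, 1.0),
        grid_factor=grid_factor)
    unit_diff = ext1.values - ext0.values
    density = []
    for n in n_ext_grid:
        ext_map = RealSpaceMap(ext0.cell, ext0.values + float(n) * unit_diff)
        density.append(integrate_negative_density(ext_map, centers, radius,
                                                  threshold=threshold))
    density = np.array(density)
    scan = ExtrapolationScan(n_ext_grid, density)

    span = density.max() - density.min()
    if span <= 1e-12 or density.max() <= 0:
        raise InconclusiveScanError(
            "negative density flat across the scan; no elbow detectable", scan)
    if method == "quadratic_onset":
        b, report = fit_quadratic_onset(n_ext_grid, density)
        if report["slope_onset"] + report["curvature_onset"] <= 0:
            raise InconclusiveScanError(
                "no rising segment found in the negative-density scan", scan)
        scan.breakpoint_fit = report
    elif method == "two_segment":
        b, report = fit_two_segment_elbow(n_ext_grid, density)
        # a real elbow needs the right-hand slope to dominate
        if report["slope_right"] <= 0 or (
                report["slope_left"] > 0
                and report["slope_right"] < 2.0 * report["slope_left"]):
            raise InconclusiveScanError(
                "no slope break found in the negative-density scan", scan)
        scan.breakpoint_fit = report
    else:
        b = derivative_threshold_elbow(n_ext_grid, density)
        scan.breakpoint_fit = {"breakpoint": b, "method": "derivative_threshold"}
    scan.characteristic_n_ext = float(b)
    scan.population_transfer_percent = 200.0 / float(b)
    return scan
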