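"""Dose-comparison metrics: curve extraction, output factors, gamma index.

The gamma index uses global normalization (dose difference relative to the
reference maximum over the grid) with a low-dose threshold, and exhaustive
search within 3x the distance-to-agreement at sub-voxel interpolation
steps. The gamma map is signed with the sign of the local dose difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt

from .types import BeamDataError, DoseGrid, PDDCurve, ProfileCurve

__all__ = [
    "GammaResult",
    "ReferencePoint",
    "extract_pdd",
    "extract_profile",
    "compute_output_factors",
    "gamma_index",
    "gamma_index_curves",
    "reference_point",
    "point_dose_difference",
]


@dataclass(frozen=True)
class GammaResult:
    """Signed gamma map and pass rate among evaluated points."""

    gamma: np.ndarray
    pass_rate: float
    dd_percent: float
    dta_mm: float
    threshold_percent: float

    @property
    def n_evaluated(self) -> int:
        return int(np.sum(np.isfinite(self.gamma)))


@dataclass(frozen=True)
class ReferencePoint:
    """Deepest point of the 90% isodose volume (distance-transform argmax)."""

    index: tuple
    location_cm: tuple
    distance_cm: float


def _axis_index(dose: DoseGrid, axis: int, coord_cm: float) -> int:
    c = dose.axis_coords(axis)
    return int(np.argmin(np.abs(c - coord_cm)))


def extract_pdd(dose: DoseGrid, axis_xy_cm=(0.0, 0.0)) -> PDDCurve:
    """Central-axis depth curve, 3x3-voxel ROI average, max normalized to 100."""
    ix = _axis_index(dose, 0, axis_xy_cm[0])
    iy = _axis_index(dose, 1, axis_xy_cm[1])
    nx, ny, _ = dose.shape
    sl_x = slice(max(ix - 1, 0), min(ix + 2, nx))
    sl_y = slice(max(iy - 1, 0), min(iy + 2, ny))
    curve = dose.dose[sl_x, sl_y, :].mean(axis=(0, 1))
    if curve.max() <= 0:
        raise BeamDataError("cannot extract a PDD from an all-zero dose")
    return PDDCurve(dose.axis_coords(2), 100.0 * curve / curve.max())


def extract_profile(
    dose: DoseGrid,
    depth_cm: float,
    direction: str = "x",
    projection_scale: float = 1.0,
    norm: str | float = "center",
) -> ProfileCurve:
    """Line profile at depth along x, y, or the diagonal.

    Offsets are multiplied by ``projection_scale`` (geometric projection of
    the measurement plane to the SAD plane). ``norm`` is "center" (profile
    normalized to 1 on the axis), "none", or a numeric reference value
    (values become percent of it).
    """
    iz = _axis_index(dose, 2, depth_cm)
    ix = _axis_index(dose, 0, 0.0)
    iy = _axis_index(dose, 1, 0.0)
    xs = dose.axis_coords(0)
    ys = dose.axis_coords(1)
    ny = dose.shape[1]
    nx = dose.shape[0]
    if direction == "x":
        offsets = xs
        # 3-row band average across the orthogonal direction (the lateral
        # analogue of the PDD's 3x3 ROI; does not blur the x-penumbra)
        sl = slice(max(iy - 1, 0), min(iy + 2, ny))
        vals = dose.dose[:, sl, iz].mean(axis=1)
    elif direction == "y":
        offsets = ys
        sl = slice(max(ix - 1, 0), min(ix + 2, nx))
        vals = dose.dose[sl, :, iz].mean(axis=0)
    elif direction == "diagonal":
        interp = RegularGridInterpolator(
            (xs, ys), dose.dose[:, :, iz], bounds_error=False, fill_value=0.0
        )
        r_max = min(xs[-1], ys[-1], -xs[0], -ys[0])
        step = np.hypot(dose.voxel_cm[0], dose.voxel_cm[1])
        r = np.arange(-r_max, r_max + step / 2, step)
        u = r / np.sqrt(2.0)
        # average the two diagonals (the field is four-fold symmetric),
        # which halves the statistical noise of the extracted profile
        vals = 0.5 * (
            interp(np.stack([u, u], axis=1)) + interp(np.stack([u, -u], axis=1))
        )
        offsets = r
    else:
        raise ValueError(f"unknown profile direction: {direction}")
    offsets = offsets * projection_scale
    if norm == "center":
        c = float(np.interp(0.0, offsets, vals))
        if c <= 0:
            raise BeamDataError("profile center value is non-positive")
        vals = vals / c
    elif norm == "none":
        pass
    else:
        vals = 100.0 * vals / float(norm)
    return ProfileCurve(offsets, vals)


def compute_output_factors(central_dose_fn, field_sizes_cm, d_ref_cm: float):
    """Output factors at the reference depth, normalized to the 10x10 field.

    ``central_dose_fn(field_cm, depth_cm)`` returns the central-axis dose
    for a square open field of the given side.
    """
    fields = np.asarray(field_sizes_cm, dtype=float)
    doses = np.array([central_dose_fn(f, d_ref_cm) for f in fields])
    d10 = central_dose_fn(10.0, d_ref_cm) if not np.any(np.isclose(fields, 10.0)) else (
        doses[np.argmin(np.abs(fields - 10.0))]
    )
    if d10 <= 0:
        raise BeamDataError("zero reference-field dose")
    return doses / d10


# ---------------------------------------------------------------------------
# Gamma index
# ---------------------------------------------------------------------------


def _offsets_within(radius_mm: float, step_mm: float, ndim: int) -> np.ndarray:
    ax = np.arange(-radius_mm, radius_mm + step_mm / 2, step_mm)
    grids = np.meshgrid(*([ax] * ndim), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    return pts[np.linalg.norm(pts, axis=1) <= radius_mm + 1e-9]


def gamma_index(
    reference: DoseGrid,
    evaluated: DoseGrid,
    dd_percent: float = 3.0,
    dta_mm: float = 2.0,
    threshold_percent: float = 10.0,
    subsample: int = 4,
) -> GammaResult:
    """Global-normalization 3-D gamma with signed output.

    The evaluated dose is tri-linearly interpolated; the search is
    exhaustive within 3x dta at dta/subsample steps. Reference and
    evaluated roles are not interchangeable.
    """
    ref = reference.dose
    dmax = ref.max()
    if dmax <= 0:
        raise BeamDataError("reference dose is empty")
    mask = ref >= threshold_percent / 100.0 * dmax
    if not mask.any():
        raise BeamDataError("no voxels above the low-dose threshold")
    dd_abs = dd_percent / 100.0 * dmax
    axes = [evaluated.axis_coords(i) for i in range(3)]
    interp = RegularGridInterpolator(
        axes, evaluated.dose, bounds_error=False, fill_value=np.nan
    )
    idx = np.argwhere(mask)
    coords = np.stack(
        [reference.axis_coords(i)[idx[:, i]] for i in range(3)], axis=1
    )
    ref_vals = ref[mask]
    offsets_cm = _offsets_within(3.0 * dta_mm, dta_mm / subsample, 3) / 10.0
    best = np.full(ref_vals.shape, np.inf)
    for off in offsets_cm:
        ev = interp(coords + off)
        d2 = (ev - ref_vals) ** 2 / dd_abs**2
        r2 = np.sum(off**2) / (dta_mm / 10.0) ** 2
        g2 = d2 + r2
        np.fmin(best, g2, out=best)
    gamma_vals = np.sqrt(best)
    # sign of the local dose difference
    local = interp(coords)
    sign = np.where(np.nan_to_num(local - ref_vals) >= 0, 1.0, -1.0)
    gmap = np.full(ref.shape, np.nan)
    gmap[mask] = sign * gamma_vals
    finite = np.isfinite(gamma_vals)
    pass_rate = 100.0 * float(np.mean(gamma_vals[finite] <= 1.0)) if finite.any() else 0.0
    return GammaResult(gmap, pass_rate, dd_percent, dta_mm, threshold_percent)


def gamma_index_curves(
    ref_x_cm,
    ref_vals,
    eval_x_cm,
    eval_vals,
    dd_percent: float = 2.0,
    dta_mm: float = 2.0,
    threshold_percent: float = 10.0,
    subsample: int = 10,
) -> GammaResult:
    """1-D gamma between two curves (PDDs or profiles), global normalization."""
    rx = np.asarray(ref_x_cm, dtype=float)
    rv = np.asarray(ref_vals, dtype=float)
    ex = np.asarray(eval_x_cm, dtype=float)
    ev = np.asarray(eval_vals, dtype=float)
    dmax = rv.max()
    if dmax <= 0:
        raise BeamDataError("reference curve is empty")
    mask = rv >= threshold_percent / 100.0 * dmax
    if not mask.any():
        raise BeamDataError("no points above the low-dose threshold")
    dd_abs = dd_percent / 100.0 * dmax
    dta_cm = dta_mm / 10.0
    shifts = np.arange(-3 * dta_cm, 3 * dta_cm + 1e-9, dta_cm / subsample)
    best = np.full(mask.sum(), np.inf)
    x_m = rx[mask]
    v_m = rv[mask]
    for s in shifts:
        ev_at = np.interp(x_m + s, ex, ev, left=np.nan, right=np.nan)
        g2 = (ev_at - v_m) ** 2 / dd_abs**2 + (s / dta_cm) ** 2
        np.fmin(best, g2, out=best)
    gamma_vals = np.sqrt(best)
    local = np.interp(x_m, ex, ev)
    sign = np.where(local - v_m >= 0, 1.0, -1.0)
    gmap = np.full(rv.shape, np.nan)
    gmap[mask] = sign * gamma_vals
    finite = np.isfinite(gamma_vals)
    pass_rate = 100.0 * float(np.mean(gamma_vals[finite] <= 1.0)) if finite.any() else 0.0
    return GammaResult(gmap, pass_rate, dd_percent, dta_mm, threshold_percent)


# ---------------------------------------------------------------------------
# Reference point
# ---------------------------------------------------------------------------


def reference_point(dose: DoseGrid, isodose_percent: float = 90.0) -> ReferencePoint:
    """Point of maximum distance from within the 90% isodose volume to its surface.

    Invariant to uniform dose rescaling; ties broken by the lowest flat
    index (np.argmax convention).
    """
    d = dose.dose
    if d.max() <= 0:
        raise BeamDataError("dose grid is empty")
    v90 = d >= isodose_percent / 100.0 * d.max()
    if not v90.any():
        raise BeamDataError("isodose volume is empty")
    dist = distance_transform_edt(v90, sampling=dose.voxel_cm)
    flat = int(np.argmax(dist))
    index = np.unravel_index(flat, d.shape)
    loc = tuple(float(dose.axis_coords(i)[index[i]]) for i in range(3))
    return ReferencePoint(tuple(int(i) for i in index), loc, float(dist[index]))


def point_dose_difference(reference: DoseGrid, evaluated: DoseGrid) -> float:
    """Percent dose difference (eval - ref)/ref at the reference point."""
    rp = reference_point(reference)
    dr = reference.dose[rp.index]
    de = evaluated.dose[rp.index]
    return 100.0 * (de - dr) / dr
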