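"""Plan/segment fluence calculation on the SAD plane.

The delivered fluence of a beam is built in stages: (1) MU-weighted segment
intensity with tongue-and-groove and leakage corrections, (2) scaling by
the off-axis map, (3) convolution with the collimator-scatter kernel, and
(4) weighting by the energy spectrum. The fluence grid has 1 mm pixels,
cell-centered, with the central pixel exactly on the beam axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import convolve2d, fftconvolve

from .spectrum import EnergySpectrum
from .types import Beam, BeamDataError

__all__ = [
    "FluenceMap",
    "SegmentIntensityModel",
    "EnergyFluence",
    "segment_boundary",
    "segment_intensity",
    "apply_oas",
    "convolve_fluence",
    "energy_weight",
]

PIXEL_CM = 0.1


def grid_size(half_extent_cm: float, pixel_cm: float = PIXEL_CM) -> int:
    """Odd pixel count covering +/- half_extent, center pixel on the axis."""
    return 2 * int(round(half_extent_cm / pixel_cm)) + 1


@dataclass(frozen=True)
class FluenceMap:
    """2-D map on the SAD plane: intensity, fluence, or a scale map.

    values is (ny, nx); stage tags the pipeline step this map represents.
    """

    values: np.ndarray
    stage: str = "intensity"
    pixel_cm: float = PIXEL_CM

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise BeamDataError("fluence map must be 2-D")
        if v.shape[0] % 2 == 0 or v.shape[1] % 2 == 0:
            raise BeamDataError("fluence grid must have odd dimensions (axis-centered)")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise BeamDataError("fluence values must be finite and >= 0")
        object.__setattr__(self, "values", v)

    def xs(self) -> np.ndarray:
        nx = self.values.shape[1]
        return (np.arange(nx) - (nx - 1) / 2) * self.pixel_cm

    def ys(self) -> np.ndarray:
        ny = self.values.shape[0]
        return (np.arange(ny) - (ny - 1) / 2) * self.pixel_cm

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def center_value(self) -> float:
        ny, nx = self.values.shape
        return float(self.values[ny // 2, nx // 2])


@dataclass(frozen=True)
class SegmentIntensityModel:
    """Intensity correction parameters (tongue-and-groove and leakage).

    alpha scales the segment boundary along y, beta models transmission
    outside the aperture; boundary_width_px is the flagged edge width.
    """

    alpha: float = 0.75
    beta: float = 0.0
    boundary_width_px: int = 1

    def __post_init__(self):
        if not (0.0 <= self.beta <= self.alpha <= 1.0):
            raise BeamDataError("require 0 <= beta <= alpha <= 1")
        if self.boundary_width_px < 1:
            raise BeamDataError("boundary width must be >= 1 pixel")


def segment_boundary(mask: np.ndarray, width_px: int = 1) -> np.ndarray:
    """Aperture pixels whose y-neighbor (within width_px rows) lies outside.

    Leaf motion is along x, so the tongue-and-groove boundary runs along
    the y-direction only (rows). Neighbors beyond the grid edge do not
    count as outside.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise BeamDataError("aperture mask must be 2-D")
    boundary = np.zeros_like(m)
    for k in range(1, width_px + 1):
        up = np.zeros_like(m)
        down = np.zeros_like(m)
        up[k:, :] = ~m[:-k, :]
        down[:-k, :] = ~m[k:, :]
        boundary |= m & (up | down)
    return boundary


def segment_intensity(
    beam: Beam, model: SegmentIntensityModel = SegmentIntensityModel()
) -> FluenceMap:
    """MU-weighted intensity I = sum_i M_i T_i over the beam's segments.

    T_i is 1 in the aperture interior, alpha on the y-boundary and beta
    outside the aperture.
    """
    shape = beam.segments[0].mask.shape
    out = np.zeros(shape, dtype=np.float64)
    for seg in beam.segments:
        if seg.mask.shape != shape:
            raise BeamDataError("segment masks must share one grid")
        t = np.full(shape, model.beta, dtype=np.float64)
        t[seg.mask] = 1.0
        edge = segment_boundary(seg.mask, model.boundary_width_px)
        t[edge] = model.alpha
        out += seg.mu * t
    return FluenceMap(out, stage="intensity")


def apply_oas(intensity: FluenceMap, oas) -> FluenceMap:
    """Scale the intensity pixel-wise by the off-axis map C."""
    c = oas.values if hasattr(oas, "values") else np.asarray(oas, dtype=float)
    if c.shape != intensity.values.shape:
        raise BeamDataError("OAS grid must match the fluence grid")
    return FluenceMap(intensity.values * c, stage="scaled")


def convolve_fluence(intensity: FluenceMap, kernel) -> FluenceMap:
    """Collimator-scatter convolution f = I (x) K.

    The kernel is a per-cm^2 density; the discrete convolution therefore
    multiplies by the pixel area. Zero padding outside the grid. FFT is
    used for wide kernels, direct summation otherwise; both agree to
    better than 1e-8.
    """
    k = kernel.values if hasattr(kernel, "values") else np.asarray(kernel, dtype=float)
    if k.ndim != 2:
        raise BeamDataError("kernel must be a 2-D grid")
    area = intensity.pixel_cm**2
    if max(k.shape) > 15:
        out = fftconvolve(intensity.values, k * area, mode="same")
    else:
        out = convolve2d(intensity.values, k * area, mode="same", boundary="fill")
    out = np.clip(out, 0.0, None)
    return FluenceMap(out, stage="fluence")


@dataclass(frozen=True)
class EnergyFluence:
    """Separable energy-fluence density proportional to f(x,y) * g(E)."""

    fluence: FluenceMap
    spectrum: EnergySpectrum

    @property
    def total_mass(self) -> float:
        return self.fluence.total

    def spatial_marginal(self) -> np.ndarray:
        return self.fluence.values.copy()

    def energy_marginal(self) -> np.ndarray:
        return self.spectrum.weight.copy()

    def joint(self) -> np.ndarray:
        """(n_bins, ny, nx) density; sums to the fluence total."""
        return self.spectrum.weight[:, None, None] * self.fluence.values[None, :, :]


def energy_weight(fluence: FluenceMap, spectrum: EnergySpectrum) -> EnergyFluence:
    """Weight the fluence by the energy spectrum to form the energy fluence."""
    if abs(spectrum.weight.sum() - 1.0) > 1e-9:
        raise BeamDataError("spectrum must be normalized")
    return EnergyFluence(fluence, spectrum)
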