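"""Core domain containers for beam data, plans, phantoms and dose.

Conventions
-----------
* Right-handed beam's-eye-view (BEV) frame on the SAD plane, origin on the
  central axis, ``x`` along the leaf-travel direction.
* Units are cm internally (file formats use mm for lateral coordinates).
* All 2-D maps on the SAD plane are cell-centered with 1 mm pixels.
* Depth ``z`` is measured from the phantom surface along the beam axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "BeamDataError",
    "PDDCurve",
    "ProfileCurve",
    "OutputFactorTable",
    "MachineMeta",
    "BeamDataSet",
    "Segment",
    "Beam",
    "PlanSegmentSet",
    "VoxelPhantom",
    "MagneticFieldVolume",
    "DoseGrid",
]


class BeamDataError(ValueError):
    """Raised on malformed or inconsistent beam data."""


@dataclass(frozen=True)
class PDDCurve:
    """Percent depth dose: central-axis dose vs. depth, max normalized to 100.

    depth_cm must be strictly increasing; values are percent of the
    central-axis maximum.
    """

    depth_cm: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depth_cm, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if d.ndim != 1 or d.shape != v.shape or d.size < 2:
            raise BeamDataError("PDD needs matching 1-D depth/value arrays")
        if np.any(d < 0):
            raise BeamDataError("PDD depths must be >= 0")
        if np.any(np.diff(d) <= 0):
            raise BeamDataError("PDD depths must be strictly increasing")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise BeamDataError("PDD values must be finite and >= 0")
        object.__setattr__(self, "depth_cm", d)
        object.__setattr__(self, "value", v)

    def normalized(self) -> "PDDCurve":
        """Return a copy rescaled so that max(value) == 100."""
        return PDDCurve(self.depth_cm, 100.0 * self.value / self.value.max())

    @property
    def d_max_cm(self) -> float:
        """Depth of maximum dose (grid argmax)."""
        return float(self.depth_cm[int(np.argmax(self.value))])

    def at(self, depth_cm) -> np.ndarray:
        return np.interp(depth_cm, self.depth_cm, self.value)


@dataclass(frozen=True)
class ProfileCurve:
    """Lateral dose/fluence profile, offsets on the SAD plane, center = 1."""

    offset_cm: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.offset_cm, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if r.ndim != 1 or r.shape != v.shape or r.size < 2:
            raise BeamDataError("profile needs matching 1-D offset/value arrays")
        if np.any(np.diff(r) <= 0):
            raise BeamDataError("profile offsets must be strictly increasing")
        object.__setattr__(self, "offset_cm", r)
        object.__setattr__(self, "value", v)

    def center_value(self) -> float:
        return float(np.interp(0.0, self.offset_cm, self.value))

    def normalized(self) -> "ProfileCurve":
        c = self.center_value()
        if c <= 0:
            raise BeamDataError("profile center value must be positive")
        return ProfileCurve(self.offset_cm, self.value / c)

    def at(self, offset_cm) -> np.ndarray:
        # clamp beyond measured support
        return np.interp(offset_cm, self.offset_cm, self.value)


@dataclass(frozen=True)
class OutputFactorTable:
    """Total scatter factors Scp for square fields at the reference depth.

    Normalized so that the 10x10 cm^2 entry equals one.
    """

    field_size_cm: np.ndarray
    scp: np.ndarray
    d_ref_cm: float

    def __post_init__(self):
        f = np.asarray(self.field_size_cm, dtype=float)
        s = np.asarray(self.scp, dtype=float)
        if f.ndim != 1 or f.shape != s.shape or f.size < 2:
            raise BeamDataError("output factor table needs >= 2 entries")
        if np.any(np.diff(f) <= 0):
            raise BeamDataError("field sizes must be strictly increasing")
        if not np.any(np.isclose(f, 10.0)):
            raise BeamDataError("output factor table must contain the 10x10 entry")
        if np.any(np.diff(s) <= 0):
            raise BeamDataError("Scp must be strictly increasing in field size")
        i10 = int(np.argmin(np.abs(f - 10.0)))
        if abs(s[i10] - 1.0) > 1e-9:
            raise BeamDataError("Scp must be normalized to 1 at the 10x10 field")
        object.__setattr__(self, "field_size_cm", f)
        object.__setattr__(self, "scp", s)

    def at(self, field_cm: float) -> float:
        return float(np.interp(field_cm, self.field_size_cm, self.scp))


@dataclass(frozen=True)
class MachineMeta:
    """Geometric and dosimetric metadata of the treatment machine."""

    sad_cm: float = 100.0
    ssd_cm: float = 100.0
    d_ref_cm: float = 5.0
    d_max_cm: float = 1.5
    largest_field_cm: float = 20.0
    energy_label: str = "6X"

    def __post_init__(self):
        for name in ("sad_cm", "ssd_cm", "d_ref_cm", "d_max_cm", "largest_field_cm"):
            if getattr(self, name) <= 0:
                raise BeamDataError(f"{name} must be positive")


@dataclass(frozen=True)
class BeamDataSet:
    """The water-phantom beam data triplet used for commissioning."""

    pdd_ref: PDDCurve
    diagonal_profile: ProfileCurve
    scp_table: OutputFactorTable
    machine_meta: MachineMeta

    def __post_init__(self):
        half_diag = self.machine_meta.largest_field_cm * np.sqrt(2.0) / 2.0
        if self.diagonal_profile.offset_cm.max() < half_diag - 1e-6:
            raise BeamDataError(
                "diagonal profile must cover the half-diagonal of the largest field"
            )


@dataclass(frozen=True)
class Segment:
    """One control point: an aperture mask on the SAD-plane grid plus its MU."""

    mu: float
    mask: np.ndarray  # boolean, shape (ny, nx), 1 mm pixels

    def __post_init__(self):
        if self.mu < 0:
            raise BeamDataError("segment MU must be >= 0")
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise BeamDataError("aperture mask must be 2-D")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class Beam:
    gantry_deg: float
    segments: tuple

    def __post_init__(self):
        if len(self.segments) == 0:
            raise BeamDataError("beam must contain at least one segment")
        shape = self.segments[0].mask.shape
        for s in self.segments:
            if s.mask.shape != shape:
                raise BeamDataError("all segment masks of a beam must share one grid")


@dataclass(frozen=True)
class PlanSegmentSet:
    """A minimal treatment plan: beams of MU-weighted aperture segments."""

    beams: tuple
    grid_half_extent_cm: float  # SAD-plane grid spans +/- this in x and y


@dataclass(frozen=True)
class VoxelPhantom:
    """Density grid (g/cm^3); axes ordered (x, y, z), z = depth from surface."""

    density: np.ndarray
    voxel_cm: tuple
    origin_cm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        rho = np.asarray(self.density, dtype=np.float32)
        if rho.ndim != 3 or min(rho.shape) == 0:
            raise BeamDataError("phantom density must be a non-empty 3-D grid")
        if np.any(rho < 0):
            raise BeamDataError("densities must be >= 0")
        if len(self.voxel_cm) != 3 or any(v <= 0 for v in self.voxel_cm):
            raise BeamDataError("voxel size must be a positive triplet")
        object.__setattr__(self, "density", rho)
        object.__setattr__(self, "voxel_cm", tuple(float(v) for v in self.voxel_cm))
        object.__setattr__(self, "origin_cm", tuple(float(v) for v in self.origin_cm))

    @property
    def shape(self):
        return self.density.shape


@dataclass(frozen=True)
class MagneticFieldVolume:
    """Static magnetic field, three components on the phantom grid (tesla)."""

    bx: np.ndarray
    by: np.ndarray
    bz: np.ndarray

    def __post_init__(self):
        bx = np.asarray(self.bx, dtype=np.float32)
        by = np.asarray(self.by, dtype=np.float32)
        bz = np.asarray(self.bz, dtype=np.float32)
        if not (bx.shape == by.shape == bz.shape) or bx.ndim != 3:
            raise BeamDataError("Bx, By, Bz must be 3-D arrays of equal shape")
        object.__setattr__(self, "bx", bx)
        object.__setattr__(self, "by", by)
        object.__setattr__(self, "bz", bz)

    @classmethod
    def uniform(cls, shape, b_tesla) -> "MagneticFieldVolume":
        b = np.asarray(b_tesla, dtype=np.float32)
        return cls(
            np.full(shape, b[0], np.float32),
            np.full(shape, b[1], np.float32),
            np.full(shape, b[2], np.float32),
        )

    def check_matches(self, phantom: VoxelPhantom):
        if self.bx.shape != phantom.shape:
            raise BeamDataError("magnetic field dimensions must equal the phantom's")


@dataclass(frozen=True)
class DoseGrid:
    """3-D dose with per-voxel relative statistical uncertainty.

    component is one of {"photon", "electron", "combined"}.
    """

    dose: np.ndarray
    uncertainty: np.ndarray
    voxel_cm: tuple
    origin_cm: tuple = (0.0, 0.0, 0.0)
    component: str = "combined"

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=np.float64)
        u = np.asarray(self.uncertainty, dtype=np.float64)
        if d.ndim != 3 or min(d.shape) == 0:
            raise BeamDataError("dose must be a non-empty 3-D grid")
        if d.shape != u.shape:
            raise BeamDataError("dose and uncertainty shapes must match")
        if np.any(~np.isfinite(d)):
            raise BeamDataError("dose contains non-finite values")
        if np.any(d < 0) or np.any(u < 0):
            raise BeamDataError("dose and uncertainty must be >= 0")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "uncertainty", u)
        object.__setattr__(self, "voxel_cm", tuple(float(v) for v in self.voxel_cm))
        object.__setattr__(self, "origin_cm", tuple(float(v) for v in self.origin_cm))

    @property
    def shape(self):
        return self.dose.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Cell-center coordinates along one axis (cm)."""
        n = self.shape[axis]
        dv = self.voxel_cm[axis]
        return self.origin_cm[axis] + (np.arange(n) + 0.5) * dv
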