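"""Readers and writers for beam data, plans, phantoms and dose volumes.

File formats (all plain text except the raw dose payload):

* Beam data: a JSON manifest referencing one CSV per curve. Lateral and
  depth coordinates are stored in mm, converted to cm on read.
* Plans: a JSON dialect with per-beam gantry angle and per-segment MU plus
  either MLC bank positions or an aperture mask CSV. Apertures are
  rasterized onto the 1 mm SAD-plane grid (a pixel belongs to the aperture
  when it lies fully inside the opening).
* Dose: raw little-endian float array plus a JSON sidecar holding grid
  geometry, dtype and component; values and uncertainties round-trip
  losslessly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fluence import grid_size
from .types import (
    Beam,
    BeamDataError,
    BeamDataSet,
    DoseGrid,
    MachineMeta,
    MagneticFieldVolume,
    OutputFactorTable,
    PDDCurve,
    PlanSegmentSet,
    ProfileCurve,
    Segment,
    VoxelPhantom,
)

logger = logging.getLogger("beamforge")

__all__ = [
    "read_beam_data",
    "write_beam_data",
    "read_plan",
    "plan_from_dict",
    "write_plan",
    "read_dose",
    "write_dose",
    "read_phantom",
    "write_phantom",
    "read_field_volume",
    "write_field_volume",
]

_MANIFEST_FORMAT = "beamforge-beamdata"


def write_beam_data(ds: BeamDataSet, directory) -> Path:
    """Write the beam-data triplet as CSV curves plus a JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"depth_mm": ds.pdd_ref.depth_cm * 10.0, "value": ds.pdd_ref.value}
    ).to_csv(d / "pdd_10x10.csv", index=False)
    pd.DataFrame(
        {
            "offset_mm": ds.diagonal_profile.offset_cm * 10.0,
            "value": ds.diagonal_profile.value,
        }
    ).to_csv(d / "diagonal_profile.csv", index=False)
    pd.DataFrame(
        {
            "field_size_mm": ds.scp_table.field_size_cm * 10.0,
            "scp": ds.scp_table.scp,
        }
    ).to_csv(d / "scp.csv", index=False)
    meta = ds.machine_meta
    manifest = {
        "format": _MANIFEST_FORMAT,
        "version": 1,
        "machine": {
            "sad_mm": meta.sad_cm * 10.0,
            "ssd_mm": meta.ssd_cm * 10.0,
            "d_ref_mm": meta.d_ref_cm * 10.0,
            "d_max_mm": meta.d_max_cm * 10.0,
            "largest_field_mm": meta.largest_field_cm * 10.0,
            "energy_label": meta.energy_label,
        },
        "files": {
            "pdd": "pdd_10x10.csv",
            "diagonal_profile": "diagonal_profile.csv",
            "scp": "scp.csv",
        },
    }
    path = d / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_beam_data(path) -> BeamDataSet:
    """Read a beam-data manifest; the PDD is renormalized so max = 100."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"beam data manifest not found: {path}")
    manifest = json.loads(path.read_text())
    if manifest.get("format") != _MANIFEST_FORMAT:
        raise BeamDataError(f"not a beam-data manifest: {path}")
    d = path.parent
    m = manifest["machine"]
    meta = MachineMeta(
        sad_cm=m["sad_mm"] / 10.0,
        ssd_cm=m["ssd_mm"] / 10.0,
        d_ref_cm=m["d_ref_mm"] / 10.0,
        d_max_cm=m["d_max_mm"] / 10.0,
        largest_field_cm=m["largest_field_mm"] / 10.0,
        energy_label=m.get("energy_label", "6X"),
    )
    pdd_df = pd.read_csv(d / manifest["files"]["pdd"])
    pdd = PDDCurve(pdd_df["depth_mm"].to_numpy() / 10.0, pdd_df["value"].to_numpy())
    pdd = pdd.normalized()
    prof_df = pd.read_csv(d / manifest["files"]["diagonal_profile"])
    prof = ProfileCurve(
        prof_df["offset_mm"].to_numpy() / 10.0, prof_df["value"].to_numpy()
    ).normalized()
    scp_df = pd.read_csv(d / manifest["files"]["scp"])
    fields = scp_df["field_size_mm"].to_numpy() / 10.0
    if not np.any(np.isclose(fields, 10.0)):
        raise BeamDataError(
            "Scp table is missing the reference 10x10 cm^2 row (field_size_mm=100)"
        )
    scp = OutputFactorTable(fields, scp_df["scp"].to_numpy(), meta.d_ref_cm)
    return BeamDataSet(pdd, prof, scp, meta)


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------


def _rasterize_rect(rect_mm, xs_mm, ys_mm):
    # half-open [lo, hi): a w-mm opening rasterizes to exactly w pixels
    x1, x2, y1, y2 = (float(v) for v in rect_mm)
    inx = (xs_mm >= x1 - 1e-9) & (xs_mm < x2 - 1e-9)
    iny = (ys_mm >= y1 - 1e-9) & (ys_mm < y2 - 1e-9)
    return iny[:, None] & inx[None, :]


def _rasterize_leaves(leaves, xs_mm, ys_mm):
    bank_a = np.asarray(leaves["bank_a"], dtype=float)
    bank_b = np.asarray(leaves["bank_b"], dtype=float)
    if bank_a.shape != bank_b.shape:
        raise BeamDataError("leaf banks must have equal length")
    width = float(leaves["leaf_width_mm"])
    n_leaves = bank_a.size
    y0 = -n_leaves * width / 2.0
    mask = np.zeros((ys_mm.size, xs_mm.size), dtype=bool)
    for i in range(n_leaves):
        lo, hi = y0 + i * width, y0 + (i + 1) * width
        rows = (ys_mm >= lo - 1e-9) & (ys_mm < hi - 1e-9)
        if bank_b[i] - bank_a[i] <= 0:
            continue
        cols = (xs_mm >= bank_a[i] - 1e-9) & (xs_mm < bank_b[i] - 1e-9)
        mask[np.ix_(rows, cols)] = True
    return mask


def read_plan(path) -> PlanSegmentSet:
    """Read the JSON plan dialect and rasterize apertures to the 1 mm grid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plan file not found: {path}")
    doc = json.loads(path.read_text())
    return plan_from_dict(doc, base_dir=path.parent)


def plan_from_dict(doc: dict, base_dir=None) -> PlanSegmentSet:
    """Rasterize a plan document (the JSON dialect) to a PlanSegmentSet."""
    base_dir = Path(base_dir) if base_dir is not None else Path(".")
    half_mm = float(doc.get("grid_half_extent_mm", 150.0))
    half_cm = half_mm / 10.0
    n = grid_size(half_cm)
    coords_mm = (np.arange(n) - (n - 1) / 2) * 1.0
    beams = []
    for bidx, b in enumerate(doc["beams"]):
        segs = []
        for sidx, s in enumerate(b["segments"]):
            mu = float(s["mu"])
            if mu < 0:
                raise BeamDataError(f"beam {bidx} segment {sidx}: negative MU")
            if "leaves" in s:
                mask = _rasterize_leaves(s["leaves"], coords_mm, coords_mm)
            elif "mask_csv" in s:
                mask = np.loadtxt(base_dir / s["mask_csv"], delimiter=",") > 0.5
                if mask.shape != (n, n):
                    raise BeamDataError(
                        f"mask grid {mask.shape} does not match the plan grid ({n}, {n})"
                    )
            elif "rect_mm" in s:
                mask = _rasterize_rect(s["rect_mm"], coords_mm, coords_mm)
            else:
                raise BeamDataError(
                    f"beam {bidx} segment {sidx}: no aperture definition"
                )
            if not mask.any():
                logger.warning(
                    "beam %d segment %d rasterizes to an empty aperture", bidx, sidx
                )
            segs.append(Segment(mu, mask))
        beams.append(Beam(float(b.get("gantry_deg", 0.0)), tuple(segs)))
    return PlanSegmentSet(tuple(beams), half_cm)


def write_plan(plan_doc: dict, path) -> Path:
    """Write a plan dictionary (the JSON dialect) to disk."""
    path = Path(path)
    path.write_text(json.dumps(plan_doc, indent=2))
    return path


# ---------------------------------------------------------------------------
# Raw volume + JSON sidecar (dose, phantom, magnetic field)
# ---------------------------------------------------------------------------


def _write_raw(arr: np.ndarray, path: Path, dtype: str):
    arr.astype(dtype).tofile(path)


def _read_raw(path: Path, dtype: str, shape):
    arr = np.fromfile(path, dtype=dtype)
    expect = int(np.prod(shape))
    if arr.size != expect:
        raise BeamDataError(
            f"raw payload {path.name} has {arr.size} values, expected {expect}"
        )
    return arr.reshape(shape)


def write_dose(dose: DoseGrid, basepath, dtype: str = "<f8") -> Path:
    """Write a dose grid as raw arrays plus a JSON header.

    Default float64 payload so values round-trip losslessly; float32 is
    available for compact storage.
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    _write_raw(dose.dose, base.with_suffix(".dose.raw"), dtype)
    _write_raw(dose.uncertainty, base.with_suffix(".unc.raw"), dtype)
    header = {
        "format": "beamforge-dose",
        "version": 1,
        "shape": list(dose.shape),
        "voxel_mm": [v * 10.0 for v in dose.voxel_cm],
        "origin_mm": [v * 10.0 for v in dose.origin_cm],
        "component": dose.component,
        "dtype": dtype,
        "byte_order": "little",
        "files": {
            "dose": base.with_suffix(".dose.raw").name,
            "uncertainty": base.with_suffix(".unc.raw").name,
        },
    }
    hp = base.with_suffix(".json")
    hp.write_text(json.dumps(header, indent=2))
    return hp


def read_dose(headerpath) -> DoseGrid:
    hp = Path(headerpath)
    if not hp.exists():
        raise FileNotFoundError(f"dose header not found: {hp}")
    header = json.loads(hp.read_text())
    if header.get("format") != "beamforge-dose":
        raise BeamDataError(f"not a dose header: {hp}")
    shape = tuple(header["shape"])
    if len(shape) != 3 or min(shape) <= 0:
        raise BeamDataError("invalid dose grid shape")
    dtype = header["dtype"]
    d = _read_raw(hp.parent / header["files"]["dose"], dtype, shape)
    u = _read_raw(hp.parent / header["files"]["uncertainty"], dtype, shape)
    return DoseGrid(
        d,
        u,
        tuple(v / 10.0 for v in header["voxel_mm"]),
        tuple(v / 10.0 for v in header["origin_mm"]),
        component=header.get("component", "combined"),
    )


def write_phantom(phantom: VoxelPhantom, basepath) -> Path:
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    _write_raw(phantom.density, base.with_suffix(".rho.raw"), "<f4")
    header = {
        "format": "beamforge-phantom",
        "shape": list(phantom.shape),
        "voxel_mm": [v * 10.0 for v in phantom.voxel_cm],
        "origin_mm": [v * 10.0 for v in phantom.origin_cm],
        "dtype": "<f4",
        "files": {"density": base.with_suffix(".rho.raw").name},
    }
    hp = base.with_suffix(".json")
    hp.write_text(json.dumps(header, indent=2))
    return hp


def read_phantom(headerpath) -> VoxelPhantom:
    hp = Path(headerpath)
    header = json.loads(hp.read_text())
    if header.get("format") != "beamforge-phantom":
        raise BeamDataError(f"not a phantom header: {hp}")
    shape = tuple(header["shape"])
    rho = _read_raw(hp.parent / header["files"]["density"], header["dtype"], shape)
    return VoxelPhantom(
        rho,
        tuple(v / 10.0 for v in header["voxel_mm"]),
        tuple(v / 10.0 for v in header["origin_mm"]),
    )


def write_field_volume(b: MagneticFieldVolume, basepath) -> Path:
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    for name, arr in (("bx", b.bx), ("by", b.by), ("bz", b.bz)):
        _write_raw(arr, base.with_suffix(f".{name}.raw"), "<f4")
    header = {
        "format": "beamforge-bfield",
        "shape": list(b.bx.shape),
        "dtype": "<f4",
        "files": {n: base.with_suffix(f".{n}.raw").name for n in ("bx", "by", "bz")},
    }
    hp = base.with_suffix(".json")
    hp.write_text(json.dumps(header, indent=2))
    return hp


def read_field_volume(headerpath) -> MagneticFieldVolume:
    hp = Path(headerpath)
    header = json.loads(hp.read_text())
    if header.get("format") != "beamforge-bfield":
        raise BeamDataError(f"not a magnetic-field header: {hp}")
    shape = tuple(header["shape"])
    comps = {
        n: _read_raw(hp.parent / header["files"][n], header["dtype"], shape)
        for n in ("bx", "by", "bz")
    }
    return MagneticFieldVolume(comps["bx"], comps["by"], comps["bz"])
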