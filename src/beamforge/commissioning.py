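"""Automatic beam-model commissioning from water-phantom beam data.

The commissioning workflow runs four steps in a fixed order, each tuning a
component that later steps depend on as little as possible:

1. spectrum — slope tuning against the reference-field PDD;
2. electron contamination — buildup-region weighting factor;
3. OAS — initial map from the diagonal profile plus one multiplicative
   refinement against the calculated profile;
4. collimator scatter — phantom-scatter extraction from the output
   factors and kernel derivation.

The result is a serializable BeamModel carrying enough provenance (seeds,
engine configuration, stage log) to reproduce the commissioning run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from . import __version__ as _pkg_version
from .forward import WaterForwardModel
from .oas_kernel import (
    OASMap,
    ScatterKernel,
    build_oas,
    derive_kernel,
    extract_sc,
    interpolate_sc_surface,
    monotone_projection,
    update_oas,
)
from .spectrum import (
    EnergySpectrum,
    default_spectrum_6mv,
    fit_spectrum_slope,
    tune_spectrum,
)
from .transport import EngineConfig
from .types import BeamDataError, BeamDataSet, MachineMeta, PDDCurve

__all__ = [
    "BeamModel",
    "fit_electron_weight",
    "commission",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "beamforge-model"
MODEL_VERSION = 1


@dataclass(frozen=True)
class BeamModel:
    """Commissioned beam model bundle."""

    spectrum: EnergySpectrum
    electron_weight: float
    oas: OASMap
    kernel: ScatterKernel
    machine_meta: MachineMeta
    provenance: dict

    def __post_init__(self):
        if self.electron_weight < 0:
            raise BeamDataError("electron weight must be >= 0")


def fit_electron_weight(
    dx: PDDCurve, de: PDDCurve, pdd_meas: PDDCurve, d_max_cm: float
) -> float:
    """Electron-contamination weight from the buildup-region discrepancy.

    Minimizes the squared deviation of Dx + we*De from the measured PDD
    over depths z <= d_max. Because measured PDDs are normalized to their
    own maximum, the candidate curve is renormalized the same way inside
    the objective; the 1-D problem is solved by bounded scalar search
    seeded by the closed-form least-squares value.
    """
    if dx.depth_cm.shape != de.depth_cm.shape or not np.allclose(
        dx.depth_cm, de.depth_cm
    ):
        raise BeamDataError("Dx and De must share one depth grid")
    if not np.allclose(dx.depth_cm, pdd_meas.depth_cm):
        raise BeamDataError("curves must be on the measured depth grid")
    mask = dx.depth_cm <= d_max_cm + 1e-9
    if not mask.any():
        raise BeamDataError("empty buildup region: d_max below the first sample")
    dxv = dx.value / dx.value.max()
    dev = de.value / de.value.max()
    meas = pdd_meas.value / pdd_meas.value.max()

    # closed-form (unnormalized) nonnegative least squares as initializer
    num = float(np.sum(dev[mask] * (meas[mask] - dxv[mask])))
    den = float(np.sum(dev[mask] ** 2))
    we0 = max(num / den, 0.0) if den > 0 else 0.0

    def objective(we: float) -> float:
        model = dxv + we * dev
        model = model / model.max()
        return float(np.sum((model[mask] - meas[mask]) ** 2))

    hi = max(2.0 * we0, 0.5)
    res = minimize_scalar(
        objective, bounds=(0.0, hi), method="bounded", options={"xatol": 1e-6}
    )
    we = float(res.x)
    if objective(we0) < objective(we):
        we = we0
    # fixed-point polish: with the renormalization factor frozen, the
    # problem is linear; iterating converges to machine precision in the
    # noiseless case
    for _ in range(4):
        m = float(np.max(dxv + we * dev))
        num = float(np.sum(dev[mask] * (meas[mask] * m - dxv[mask])))
        we_new = max(num / den, 0.0) if den > 0 else 0.0
        if objective(we_new) <= objective(we) + 1e-18:
            we = we_new
        else:
            break
    return we


def commission(
    beam_data: BeamDataSet,
    config: EngineConfig = EngineConfig(),
    g0: EnergySpectrum | None = None,
    slope_bounds: tuple = (-0.12, 0.25),
    forward: WaterForwardModel | None = None,
    n_passes: int = 4,
) -> BeamModel:
    """Run the four-step automatic commissioning workflow.

    The four stages always execute in the fixed order (spectrum, electron
    contamination, OAS, kernel) and the whole sequence is iterated
    (``n_passes``, default 4): the first pass has no scatter kernel, so
    its forward model underestimates the out-of-field fluence halo, and
    the initial OAS carries the phantom-scatter dome of the measured
    diagonal, which biases the first phantom-scatter extraction; later
    passes revisit the stages with the current kernel and the refined OAS
    in the forward model until the parameters settle. The single OAS
    refinement runs in pass 2, once a kernel exists. Any stage failure
    aborts with a stage-labeled error; a partial model is never produced.
    """
    meta = beam_data.machine_meta
    g0 = g0 if g0 is not None else default_spectrum_6mv()
    fwd = forward if forward is not None else WaterForwardModel(meta, config)
    seed = config.seed
    stages = []
    prov: dict = {
        "engine_config": asdict(config),
        "seed": seed,
        "stages": stages,
        "n_passes": n_passes,
        "package_version": _pkg_version,
    }
    meas = beam_data.pdd_ref
    oas = None
    kernel = None
    s_hat = 0.0
    we = 0.0
    basis_nokernel = None
    prov["passes"] = []
    for ip in range(n_passes):
        try:
            stages.append("spectrum")
            if oas is None:
                oas = build_oas(
                    beam_data.diagonal_profile, fwd.half_extent_cm, smooth_flat=True
                )
            basis, z = fwd.pdd_basis(
                10.0, g0, oas=oas, kernel=kernel, seed=fwd.seed_for("basis-10")
            )
            if kernel is None:
                basis_nokernel = basis
            else:
                # kernel-free reference with the *current* OAS so the halo
                # nuisance isolates the kernel contribution alone
                basis_nokernel, _ = fwd.pdd_basis(
                    10.0, g0, oas=oas, kernel=None, seed=fwd.seed_for("basis-10")
                )

            def handle(gs: EnergySpectrum) -> np.ndarray:
                return fwd.pdd_from_basis(basis, z, gs, meas.depth_cm)

            # match beyond the reach of contaminant electrons: the buildup
            # and the first few cm belong to the electron-weight stage
            from . import physics as _physics

            e_range = float(_physics.csda_range(float(g0.energy_mev.max())))
            nuisance = None
            if kernel is not None and basis_nokernel is not None:
                # the collimator-scatter halo adds a smooth depth trend the
                # slope must not absorb; its signature (kernel on - off at
                # the previous slope) is fitted as a nuisance amplitude
                spec_prev = tune_spectrum(g0, s_hat)
                nuisance = fwd.pdd_from_basis(
                    basis, z, spec_prev, meas.depth_cm
                ) - fwd.pdd_from_basis(basis_nokernel, z, spec_prev, meas.depth_cm)
            s_hat = fit_spectrum_slope(
                meas, handle, g0, bounds=slope_bounds,
                min_depth_cm=max(meas.d_max_cm, e_range),
                free_scale=True, nuisance=nuisance,
            )
            spectrum = tune_spectrum(g0, s_hat)
        except Exception as exc:
            raise BeamDataError(
                f"commissioning stage 'spectrum' (pass {ip + 1}) failed: {exc}"
            ) from exc

        try:
            stages.append("electron_contamination")
            dx = PDDCurve(meas.depth_cm, fwd.pdd_from_basis(basis, z, spectrum, meas.depth_cm))
            de_grid = fwd.electron_dose(
                10.0, spectrum, oas=oas, kernel=kernel, seed=fwd.seed_for("de-10")
            )
            de_curve = fwd.pdd_curve(de_grid)
            de = PDDCurve(
                meas.depth_cm,
                np.interp(meas.depth_cm, de_curve.depth_cm, de_curve.value),
            )
            we = fit_electron_weight(dx, de, meas, meas.d_max_cm)
        except BeamDataError as exc:
            raise BeamDataError(
                f"commissioning stage 'electron_contamination' (pass {ip + 1}) "
                f"failed: {exc}"
            ) from exc

        try:
            stages.append("oas")
            # the refinement needs the kernel in the forward model: without
            # it the ratio h/h0 absorbs the scatter halo into C, which the
            # next pass would then double-count. Pass 1 keeps C0; the single
            # refinement happens in pass 2 (repeating it lets residual
            # kernel-shape mismatch accumulate into the map).
            if kernel is not None and ip == 1:
                dose_large = fwd.photon_dose(
                    meta.largest_field_cm, spectrum, oas=oas, kernel=kernel,
                    seed=fwd.seed_for(f"full-{meta.largest_field_cm:g}"),
                )
                h0 = fwd.diagonal_profile(dose_large, meas.d_max_cm)
                r_max = meta.largest_field_cm * np.sqrt(2.0) / 2.0
                prov.setdefault("_debug", {})[f"oas_pass{ip}"] = {
                    "h": beam_data.diagonal_profile,
                    "h0": h0,
                    "oas_before": oas,
                }
                oas = update_oas(
                    oas, beam_data.diagonal_profile, h0, r_max_cm=r_max, smooth=True
                )
        except BeamDataError as exc:
            raise BeamDataError(
                f"commissioning stage 'oas' (pass {ip + 1}) failed: {exc}"
            ) from exc

        try:
            stages.append("kernel")
            fields = beam_data.scp_table.field_size_cm
            sp = np.empty_like(fields)
            for i, f in enumerate(fields):
                dose_f = fwd.photon_dose(
                    float(f), spectrum, oas=oas, kernel=None,
                    seed=fwd.seed_for(f"sp-{f:g}"),
                )
                sp[i] = fwd.central_dose(dose_f, meta.d_ref_cm)
            sc = extract_sc(beam_data.scp_table, sp)
            if np.any(np.diff(sc) <= 0):
                sc = monotone_projection(sc)
                i10 = int(np.argmin(np.abs(fields - 10.0)))
                sc = sc / sc[i10]
            surface = interpolate_sc_surface(fields, sc)
            kernel = derive_kernel(surface, oas, roundtrip_fields_cm=fields)
            prov["sc_square"] = {float(f): float(v) for f, v in zip(fields, sc)}
        except BeamDataError as exc:
            raise BeamDataError(
                f"commissioning stage 'kernel' (pass {ip + 1}) failed: {exc}"
            ) from exc

        prov["passes"].append({"slope": s_hat, "electron_weight": we})

    prov["slope"] = s_hat
    prov["electron_weight"] = we
    return BeamModel(spectrum, we, oas, kernel, meta, prov)


# ---------------------------------------------------------------------------
# Serialization: zip archive of component arrays + JSON manifest
# ---------------------------------------------------------------------------


def _array_checksum(arrays: dict) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    return h.hexdigest()


def save_model(model: BeamModel, path) -> Path:
    path = Path(path)
    arrays = {
        "spectrum_energy": model.spectrum.energy_mev,
        "spectrum_weight": model.spectrum.weight,
        "oas": model.oas.values,
        "kernel": model.kernel.values,
    }
    manifest = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "electron_weight": model.electron_weight,
        "spectrum_slope": model.spectrum.slope,
        "oas_pixel_cm": model.oas.pixel_cm,
        "kernel_pixel_cm": model.kernel.pixel_cm,
        "machine_meta": asdict(model.machine_meta),
        # in-memory diagnostics (underscore keys) are not serialized
        "provenance": {
            k: v for k, v in model.provenance.items() if not k.startswith("_")
        },
        "checksum": _array_checksum(arrays),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        for name, arr in arrays.items():
            with zf.open(f"{name}.npy", "w") as fh:
                np.save(fh, np.asarray(arr))
    return path


def load_model(path) -> BeamModel:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("format") != MODEL_FORMAT:
            raise BeamDataError(f"not a beam model archive: {path}")
        if manifest.get("version") != MODEL_VERSION:
            raise BeamDataError(
                f"unsupported model version {manifest.get('version')}"
            )
        arrays = {}
        for name in ("spectrum_energy", "spectrum_weight", "oas", "kernel"):
            with zf.open(f"{name}.npy") as fh:
                arrays[name] = np.load(fh)
    if _array_checksum(arrays) != manifest["checksum"]:
        raise BeamDataError("model archive checksum mismatch (file corrupted?)")
    spectrum = EnergySpectrum(
        arrays["spectrum_energy"], arrays["spectrum_weight"],
        slope=manifest.get("spectrum_slope", 0.0),
    )
    return BeamModel(
        spectrum,
        manifest["electron_weight"],
        OASMap(arrays["oas"], manifest["oas_pixel_cm"]),
        ScatterKernel(arrays["kernel"], manifest["kernel_pixel_cm"]),
        MachineMeta(**manifest["machine_meta"]),
        manifest["provenance"],
    )
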