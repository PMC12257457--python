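"""Synthetic "golden machine": beam data generated from known ground truth.

The golden machine owns a true spectrum slope, electron-contamination
weight, off-axis profile and collimator-scatter kernel, and produces the
commissioning beam-data triplet (reference-field PDD, diagonal profile of
the largest field, output-factor table) by running the same forward dose
model used for commissioning. Closed-loop tests then check that
commissioning recovers the ground truth from the generated data alone.

The default parameters are the study conditions for all closed-loop
tests: a flattened 6 MV-like machine with a mild spectral hardening
(s* = 0.05), a small electron-contamination weight (we* = 0.04), a gently
horned off-axis profile, and a kernel of the delta-plus-exponential-tail
family whose sharp central drop mirrors measured collimator-scatter
kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .fluence import PIXEL_CM, grid_size
from .forward import WaterForwardModel
from .oas_kernel import OASMap, ScatterKernel, sc_roundtrip, _radius_grid
from .spectrum import EnergySpectrum, default_spectrum_6mv, tune_spectrum
from .transport import EngineConfig
from .types import (
    BeamDataError,
    BeamDataSet,
    MachineMeta,
    OutputFactorTable,
    PDDCurve,
    PlanSegmentSet,
    ProfileCurve,
)

__all__ = ["GoldenMachine", "generate_beam_data", "generate_reference_curves",
           "generate_plan"]


@dataclass(frozen=True)
class GoldenMachine:
    """Ground-truth parameters of the synthetic machine."""

    s_star: float = 0.05
    we_star: float = 0.04
    kernel_tail_mass: float = 0.10
    kernel_tail_range_cm: float = 1.5
    oas_quadratic: float = 3.0e-4  # per cm^2, gentle horn of a flattened beam
    oas_quartic: float = -1.0e-6
    noise_frac: float = 0.0
    seed: int = 1
    scp_fields_cm: tuple = (2.0, 3.0, 5.0, 10.0, 20.0)
    meta: MachineMeta = field(default_factory=MachineMeta)

    def __post_init__(self):
        if self.noise_frac < 0:
            raise BeamDataError("noise level must be >= 0")
        if not (0.0 <= self.kernel_tail_mass < 1.0):
            raise BeamDataError("kernel tail mass must be in [0, 1)")

    def initial_spectrum(self) -> EnergySpectrum:
        return default_spectrum_6mv()

    def true_spectrum(self) -> EnergySpectrum:
        return tune_spectrum(self.initial_spectrum(), self.s_star)

    def true_oas(self, half_extent_cm: float) -> OASMap:
        n = grid_size(half_extent_cm)
        r = _radius_grid(n, PIXEL_CM)
        c = 1.0 + self.oas_quadratic * r**2 + self.oas_quartic * r**4
        return OASMap(np.clip(c, 0.0, None))

    def true_kernel(self, support_radius_cm: float = 10.0) -> ScatterKernel:
        """Delta at the center plus a circularly symmetric exponential tail."""
        n = grid_size(support_radius_cm)
        r = _radius_grid(n, PIXEL_CM)
        area = PIXEL_CM**2
        tail = np.exp(-r / self.kernel_tail_range_cm)
        tail[n // 2, n // 2] = 0.0
        tail *= self.kernel_tail_mass / (tail.sum() * area)
        tail[n // 2, n // 2] = (1.0 - self.kernel_tail_mass) / area
        return ScatterKernel(tail)

    def true_sc(self, oas: OASMap, fields_cm) -> np.ndarray:
        """Sc(f) from the defining integral of the true kernel, normalized at 10."""
        k = self.true_kernel()
        vals = np.array([sc_roundtrip(k, oas, f) for f in fields_cm])
        i10 = int(np.argmin(np.abs(np.asarray(fields_cm) - 10.0)))
        return vals / vals[i10]


def _golden_pdd(fwd: WaterForwardModel, gm: GoldenMachine, field_cm, spectrum,
                oas, kernel) -> PDDCurve:
    """Full PDD including the weighted electron-contamination component.

    The photon component is assembled from the per-energy-bin basis (the
    same decomposition commissioning uses), with the engine seed derived
    from the field tag so that closed-loop comparisons share their random
    numbers.
    """
    basis, z = fwd.pdd_basis(
        field_cm, gm.initial_spectrum(), oas=oas, kernel=kernel,
        seed=fwd.seed_for(f"basis-{field_cm:g}"),
    )
    dx = fwd.pdd_from_basis(basis, z, spectrum)  # max 100
    dose_e = fwd.electron_dose(field_cm, spectrum, oas=oas, kernel=kernel,
                               seed=fwd.seed_for(f"de-{field_cm:g}"))
    de = fwd.pdd_curve(dose_e)
    total = dx / dx.max() + gm.we_star * de.value / de.value.max()
    return PDDCurve(z, 100.0 * total / total.max())


def generate_beam_data(
    gm: GoldenMachine,
    config: EngineConfig = EngineConfig(),
    forward: WaterForwardModel | None = None,
    max_regen: int = 5,
) -> BeamDataSet:
    """Produce the commissioning beam-data triplet from the ground truth.

    The PDD and diagonal profile come from forward transport with the true
    spectrum, OAS and kernel; Scp(f) is the product of the kernel's Sc
    integral and the engine's phantom-scatter factor Sp (calculated with
    the convolution omitted). Optional multiplicative Gaussian noise is
    applied; if it destroys Scp monotonicity the table is regenerated with
    a fresh sub-seed (with a warning).
    """
    fwd = forward if forward is not None else WaterForwardModel(gm.meta, config)
    spectrum = gm.true_spectrum()
    oas = gm.true_oas(fwd.half_extent_cm)
    kernel = gm.true_kernel()
    rng = np.random.default_rng(gm.seed)

    pdd = _golden_pdd(fwd, gm, 10.0, spectrum, oas, kernel)
    d_max = pdd.d_max_cm

    dose_large = fwd.photon_dose(
        gm.meta.largest_field_cm, spectrum, oas=oas, kernel=kernel,
        seed=fwd.seed_for(f"full-{gm.meta.largest_field_cm:g}"),
    )
    diag = fwd.diagonal_profile(dose_large, d_max)

    fields = np.asarray(gm.scp_fields_cm, dtype=float)
    sp = np.empty_like(fields)
    for i, f in enumerate(fields):
        dose_f = fwd.photon_dose(
            float(f), spectrum, oas=oas, kernel=None,
            seed=fwd.seed_for(f"sp-{f:g}"),
        )
        sp[i] = fwd.central_dose(dose_f, gm.meta.d_ref_cm)
    i10 = int(np.argmin(np.abs(fields - 10.0)))
    sp /= sp[i10]
    sc = gm.true_sc(oas, fields)
    scp = sc * sp
    scp /= scp[i10]

    pdd_vals = pdd.value.copy()
    diag_vals = diag.value.copy()
    if gm.noise_frac > 0:
        pdd_vals *= 1.0 + gm.noise_frac * rng.standard_normal(pdd_vals.shape)
        diag_vals *= 1.0 + gm.noise_frac * rng.standard_normal(diag_vals.shape)
        for attempt in range(max_regen):
            noisy = scp * (1.0 + gm.noise_frac * rng.standard_normal(scp.shape))
            noisy /= noisy[i10]
            if np.all(np.diff(noisy) > 0):
                scp = noisy
                break
            warnings.warn(
                "noise destroyed Scp monotonicity; regenerating", stacklevel=2
            )
        else:
            raise BeamDataError("could not generate a monotone noisy Scp table")

    meta = replace(gm.meta, d_max_cm=d_max)
    return BeamDataSet(
        PDDCurve(pdd.depth_cm, pdd_vals).normalized(),
        ProfileCurve(diag.offset_cm, diag_vals).normalized(),
        OutputFactorTable(fields, scp, gm.meta.d_ref_cm),
        meta,
    )


def generate_reference_curves(
    gm: GoldenMachine,
    config: EngineConfig = EngineConfig(),
    forward: WaterForwardModel | None = None,
    pdd_fields_cm=(5.0, 10.0, 20.0),
    profile_depths_cm=(1.5, 5.0, 10.0),
):
    """Reference PDDs and 10x10 cross-profiles for closed-loop validation.

    Returns a dict with noiseless golden curves: ``pdd[f]`` (max-100
    PDDCurve per field) and ``profile[d]`` (x-profiles of the 10x10 field
    in percent of the 10x10 central dose at d_max).
    """
    fwd = forward if forward is not None else WaterForwardModel(gm.meta, config)
    spectrum = gm.true_spectrum()
    oas = gm.true_oas(fwd.half_extent_cm)
    kernel = gm.true_kernel()
    out = {"pdd": {}, "profile": {}}
    for f in pdd_fields_cm:
        out["pdd"][float(f)] = _golden_pdd(fwd, gm, float(f), spectrum, oas, kernel)
    dose10 = fwd.photon_dose(10.0, spectrum, oas=oas, kernel=kernel,
                             seed=fwd.seed_for("full-10"))
    d_max = out["pdd"][10.0].d_max_cm if 10.0 in out["pdd"] else 1.5
    norm = fwd.central_dose(dose10, d_max)
    for d in profile_depths_cm:
        out["profile"][float(d)] = fwd.cross_profile(dose10, float(d), norm)
    out["d_max_cm"] = d_max
    return out


def generate_plan(kind: str, params: dict | None = None, seed: int = 1) -> dict:
    """Deterministic toy plans in the JSON plan dialect.

    Kinds: ``open_square`` (one segment), ``sliding_window`` (20 abutting
    windows sweeping in x; their composite interior intensity is the total
    MU), ``step_and_shoot`` (5 nested rectangles with MU weights drawn
    reproducibly from the seed).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "open_square":
        f_mm = float(params.get("field_mm", 100.0))
        mu = float(params.get("mu", 100.0))
        segments = [
            {"mu": mu, "rect_mm": [-f_mm / 2, f_mm / 2, -f_mm / 2, f_mm / 2]}
        ]
    elif kind == "sliding_window":
        # overlapping windows sweeping in x; each interior point is covered
        # by exactly window/step windows, so the composite interior
        # intensity is the total MU with an analytic staircase at the edges
        f_mm = float(params.get("field_mm", 100.0))
        mu = float(params.get("mu", 100.0))
        step = float(params.get("step_mm", 5.0))
        window = float(params.get("window_mm", 20.0))
        n_seg = int(round((f_mm - window) / step)) + 1
        segments = [
            {
                "mu": mu * step / window,
                "rect_mm": [-f_mm / 2 + i * step, -f_mm / 2 + i * step + window,
                            -f_mm / 2, f_mm / 2],
            }
            for i in range(n_seg)
        ]
    elif kind == "step_and_shoot":
        f_mm = float(params.get("field_mm", 100.0))
        mu = float(params.get("mu", 100.0))
        weights = rng.uniform(0.5, 1.5, size=5)
        weights = weights / weights.sum() * mu
        segments = []
        for i in range(5):
            half = f_mm / 2 * (1.0 - 0.15 * i)
            segments.append(
                {"mu": float(weights[i]), "rect_mm": [-half, half, -half, half]}
            )
    else:
        raise ValueError(f"unknown plan kind: {kind}")
    return {
        "beams": [{"gantry_deg": float(params.get("gantry_deg", 0.0)),
                   "segments": segments}],
        "grid_half_extent_mm": float(params.get("grid_half_extent_mm", 160.0)),
    }


def generate_plan_segments(
    kind: str, params: dict | None = None, seed: int = 1
) -> PlanSegmentSet:
    """Rasterized version of :func:`generate_plan`."""
    from .io import plan_from_dict

    return plan_from_dict(generate_plan(kind, params, seed))
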