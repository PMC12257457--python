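"""Water-phantom forward dose model shared by commissioning and the
synthetic golden machine.

Wraps the fluence pipeline and the dose engine for the standard
commissioning geometry: square open fields at the measurement SSD, a
homogeneous water tank, central-axis and profile extraction. Because the
dose is linear in the spectrum weights, the reference-field PDD can be
decomposed into per-energy-bin basis curves computed once; spectrum tuning
then evaluates candidate spectra by recombining the basis, which makes the
1-D slope search essentially free after one transport run.
"""

from __future__ import annotations

import numpy as np

from .evaluation import extract_pdd, extract_profile
from .fluence import FluenceMap, apply_oas, convolve_fluence, grid_size
from .oas_kernel import OASMap, ScatterKernel
from .spectrum import EnergySpectrum
from .transport import (
    BeamGeometry,
    DoseEngine,
    EngineConfig,
    make_water_phantom,
)
from .types import BeamDataError, DoseGrid, MachineMeta, PDDCurve, ProfileCurve

__all__ = ["WaterForwardModel"]


class WaterForwardModel:
    """Forward calculations on a water tank for one machine geometry."""

    def __init__(
        self,
        meta: MachineMeta,
        config: EngineConfig = EngineConfig(),
        lateral_cm: float = 36.0,
        depth_cm: float = 32.0,
        voxel_cm: float = 0.2,
    ):
        self.meta = meta
        self.config = config
        self.engine = DoseEngine(config)
        self.phantom = make_water_phantom(lateral_cm, depth_cm, voxel_cm)
        self.geometry = BeamGeometry(sad_cm=meta.sad_cm, ssd_cm=meta.ssd_cm)
        # fluence grid covering the largest field's half-diagonal
        self.half_extent_cm = float(
            np.ceil(meta.largest_field_cm * np.sqrt(2.0) / 2.0) + 2.0
        )
        self._dose_cache: dict = {}

    def seed_for(self, tag: str) -> int:
        """Deterministic engine seed for a named forward calculation.

        Corresponding calculations in the golden-machine generator and in
        commissioning share tags, hence seeds: closed-loop comparisons then
        use common random numbers and measure estimator consistency rather
        than engine noise.
        """
        import zlib

        return (self.config.seed * 1009 + zlib.crc32(tag.encode()) % 1000003) % (
            2**31 - 1
        )

    # -- fluence ----------------------------------------------------------

    def open_field_mask(self, field_cm: float) -> np.ndarray:
        n = grid_size(self.half_extent_cm)
        c = (np.arange(n) - (n - 1) / 2) * 0.1
        # half-open interval: an f-cm field is exactly 10*f pixels wide
        inside = (c >= -field_cm / 2.0 - 1e-9) & (c < field_cm / 2.0 - 1e-9)
        return inside[:, None] & inside[None, :]

    def open_field_fluence(
        self,
        field_cm: float,
        oas: OASMap | None = None,
        kernel: ScatterKernel | None = None,
    ) -> FluenceMap:
        mask = self.open_field_mask(field_cm)
        flu = FluenceMap(mask.astype(float), stage="intensity")
        if oas is not None:
            if oas.values.shape != flu.values.shape:
                raise BeamDataError("OAS grid does not match the fluence grid")
            flu = apply_oas(flu, oas)
        if kernel is not None:
            flu = convolve_fluence(flu, kernel)
        return flu

    # -- dose -------------------------------------------------------------

    def photon_dose(
        self,
        field_cm: float,
        spectrum: EnergySpectrum,
        oas: OASMap | None = None,
        kernel: ScatterKernel | None = None,
        seed: int | None = None,
        n_photons: int | None = None,
    ) -> DoseGrid:
        import hashlib

        h = hashlib.sha1()
        h.update(np.asarray(spectrum.weight).tobytes())
        if oas is not None:
            h.update(oas.values.tobytes())
        if kernel is not None:
            h.update(kernel.values.tobytes())
        key = (float(field_cm), seed, n_photons, h.hexdigest())
        if key in self._dose_cache:
            return self._dose_cache[key]
        flu = self.open_field_fluence(field_cm, oas, kernel)
        dose = self.engine.photon_dose(
            flu, spectrum, self.phantom, self.geometry, seed=seed, n_photons=n_photons
        )
        self._dose_cache[key] = dose
        return dose

    def electron_dose(
        self,
        field_cm: float,
        spectrum: EnergySpectrum,
        oas: OASMap | None = None,
        kernel: ScatterKernel | None = None,
        seed: int | None = None,
        n_electrons: int | None = None,
    ) -> DoseGrid:
        flu = self.open_field_fluence(field_cm, oas, kernel)
        return self.engine.electron_dose(
            flu, spectrum, self.phantom, self.geometry, seed=seed,
            n_electrons=n_electrons,
        )

    def pdd_basis(
        self,
        field_cm: float,
        g0: EnergySpectrum,
        oas: OASMap | None = None,
        kernel: ScatterKernel | None = None,
        seed: int | None = None,
        n_photons: int | None = None,
    ):
        """Per-energy-bin central-axis dose curves (n_bins, nz) and depths.

        Histories are spread uniformly over the bins; each curve is the
        dose per unit bin weight, so any spectrum's PDD is the
        weight-combination of these curves.
        """
        import hashlib

        h = hashlib.sha1()
        h.update(np.asarray(g0.weight).tobytes())
        if oas is not None:
            h.update(oas.values.tobytes())
        if kernel is not None:
            h.update(kernel.values.tobytes())
        key = ("basis", float(field_cm), seed, n_photons, h.hexdigest())
        if key in self._dose_cache:
            return self._dose_cache[key]
        flu = self.open_field_fluence(field_cm, oas, kernel)
        uniform = np.full(g0.n_bins, 1.0 / g0.n_bins)

        def reduce(dose_arr: np.ndarray):
            ix = dose_arr.shape[0] // 2
            iy = dose_arr.shape[1] // 2
            return dose_arr[ix - 1 : ix + 2, iy - 1 : iy + 2, :].mean(axis=(0, 1))

        _, curves = self.engine.photon_dose_bins(
            flu, g0, self.phantom, self.geometry, seed,
            n_photons, uniform, per_bin_reduce=reduce,
        )
        z = self._z_coords()
        basis = np.stack([c for c in curves])
        self._dose_cache[key] = (basis, z)
        return basis, z

    def _z_coords(self) -> np.ndarray:
        nz = self.phantom.shape[2]
        dz = self.phantom.voxel_cm[2]
        return (np.arange(nz) + 0.5) * dz

    @staticmethod
    def combine_basis(basis: np.ndarray, spectrum: EnergySpectrum) -> np.ndarray:
        """Raw central-axis curve for a spectrum from the basis decomposition."""
        return spectrum.weight @ basis

    def pdd_from_basis(
        self, basis: np.ndarray, z: np.ndarray, spectrum: EnergySpectrum,
        depth_grid_cm: np.ndarray | None = None,
    ) -> np.ndarray:
        """PDD values (max 100) for a spectrum, optionally on a target grid."""
        curve = self.combine_basis(basis, spectrum)
        if depth_grid_cm is not None:
            curve = np.interp(depth_grid_cm, z, curve)
        return 100.0 * curve / curve.max()

    # -- extraction helpers ------------------------------------------------

    def pdd_curve(self, dose: DoseGrid) -> PDDCurve:
        return extract_pdd(dose)

    def central_dose(self, dose: DoseGrid, depth_cm: float) -> float:
        """Central-axis dose at depth, 5x5x5-voxel ROI mean (1 cm cube)."""
        ix = dose.shape[0] // 2
        iy = dose.shape[1] // 2
        z = dose.axis_coords(2)
        iz = int(np.argmin(np.abs(z - depth_cm)))
        z0 = max(iz - 2, 0)
        return float(
            dose.dose[ix - 2 : ix + 3, iy - 2 : iy + 3, z0 : iz + 3].mean()
        )

    def diagonal_profile(
        self, dose: DoseGrid, depth_cm: float
    ) -> ProfileCurve:
        """Diagonal dose profile at depth, projected to SAD scale, center = 1."""
        scale = self.meta.sad_cm / (self.meta.ssd_cm + depth_cm)
        return extract_profile(
            dose, depth_cm, direction="diagonal", projection_scale=scale,
            norm="center",
        )

    def cross_profile(
        self, dose: DoseGrid, depth_cm: float, norm_value: float
    ) -> ProfileCurve:
        """x-profile at depth in percent of ``norm_value`` on the SAD scale."""
        scale = self.meta.sad_cm / (self.meta.ssd_cm + depth_cm)
        return extract_profile(
            dose, depth_cm, direction="x", projection_scale=scale, norm=norm_value
        )
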