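"""Segment intensity, boundary correction, OAS scaling and convolution."""

import numpy as np
import pytest
from scipy.signal import convolve2d, fftconvolve

from beamforge import (
    BeamDataError,
    FluenceMap,
    SegmentIntensityModel,
    apply_oas,
    convolve_fluence,
    energy_weight,
    segment_boundary,
    segment_intensity,
)
from beamforge.oas_kernel import ScatterKernel
from beamforge.types import Beam, Segment

N = 41  # 41 x 41 mm grid


def square_mask(side_mm, n=N):
    # half-open rasterization: a w-mm side spans exactly w pixels
    c = np.arange(n) - (n - 1) / 2
    inside = (c >= -side_mm / 2 - 1e-9) & (c < side_mm / 2 - 1e-9)
    return inside[:, None] & inside[None, :]


def brute_force_boundary(mask, width=1):
    """Independent neighborhood-enumeration oracle for the y-boundary."""
    ny, nx = mask.shape
    out = np.zeros_like(mask)
    for iy in range(ny):
        for ix in range(nx):
            if not mask[iy, ix]:
                continue
            for k in range(1, width + 1):
                for dy in (-k, k):
                    jy = iy + dy
                    if 0 <= jy < ny and not mask[jy, ix]:
                        out[iy, ix] = True
    return out


class TestSegmentBoundary:
    def test_full_grid_has_no_boundary(self):
        mask = np.ones((N, N), dtype=bool)
        assert not segment_boundary(mask).any()

    def test_square_flags_top_and_bottom_rows(self):
        mask = square_mask(10)
        b = segment_boundary(mask)
        assert b.sum() == 20  # two 10-pixel rows
        np.testing.assert_array_equal(b, brute_force_boundary(mask))

    def test_abutting_apertures_flag_shared_edge(self):
        upper = np.zeros((N, N), dtype=bool)
        lower = np.zeros((N, N), dtype=bool)
        upper[10:20, 5:35] = True
        lower[20:30, 5:35] = True
        for m in (upper, lower):
            np.testing.assert_array_equal(
                segment_boundary(m), brute_force_boundary(m)
            )
        assert segment_boundary(upper)[19, 10] and segment_boundary(lower)[20, 10]


class TestSegmentIntensity:
    def test_default_values_interior_boundary_outside(self):
        beam = Beam(0.0, (Segment(1.0, square_mask(10)),))
        flu = segment_intensity(beam)
        c = N // 2
        assert flu.values[c, c] == 1.0
        assert flu.values[c - 5, c] == 0.75  # y-boundary pixel (alpha)
        assert flu.values[0, 0] == 0.0  # outside (beta = 0)

    def test_mu_linearity(self):
        m = square_mask(10)
        beam = Beam(0.0, (Segment(2.0, m), Segment(3.0, m)))
        flu = segment_intensity(beam)
        assert flu.values[N // 2, N // 2] == pytest.approx(5.0)

    def test_leakage_beta(self):
        beam = Beam(0.0, (Segment(100.0, square_mask(10)),))
        flu = segment_intensity(beam, SegmentIntensityModel(beta=0.02))
        assert flu.values[0, 0] == pytest.approx(2.0)

    def test_open_field_total(self):
        mask = square_mask(20)
        beam = Beam(0.0, (Segment(3.0, mask),))
        model = SegmentIntensityModel(alpha=0.75)
        flu = segment_intensity(beam, model)
        boundary = segment_boundary(mask)
        interior = mask & ~boundary
        expected = 3.0 * (interior.sum() + 0.75 * boundary.sum())
        assert flu.values.sum() == pytest.approx(expected)

    def test_segment_order_invariance(self):
        rng = np.random.default_rng(3)
        masks = [square_mask(s) for s in (8, 14, 20)]
        mus = [5.0, 2.0, 7.0]
        beam_a = Beam(0.0, tuple(Segment(m, s) for m, s in zip(mus, masks)))
        beam_b = Beam(0.0, tuple(Segment(m, s) for m, s in zip(mus[::-1], masks[::-1])))
        np.testing.assert_allclose(
            segment_intensity(beam_a).values, segment_intensity(beam_b).values
        )

    def test_invalid_model_rejected(self):
        with pytest.raises(BeamDataError):
            SegmentIntensityModel(alpha=0.5, beta=0.7)


class TestApplyOAS:
    def test_identity_map(self):
        flu = FluenceMap(square_mask(10).astype(float))
        out = apply_oas(flu, np.ones((N, N)))
        np.testing.assert_array_equal(out.values, flu.values)

    def test_pixelwise_product_and_center(self):
        flu = FluenceMap(np.ones((N, N)))
        c = np.linspace(0.8, 1.2, N * N).reshape(N, N)
        c[N // 2, N // 2] = 1.0
        out = apply_oas(flu, c)
        assert out.values[3, 7] == pytest.approx(c[3, 7])
        assert out.values[N // 2, N // 2] == pytest.approx(1.0)


class TestConvolveFluence:
    def test_impulse_kernel_is_identity(self):
        flu = FluenceMap(square_mask(10).astype(float))
        out = convolve_fluence(flu, ScatterKernel.impulse())
        np.testing.assert_allclose(out.values, flu.values, atol=1e-12)

    def test_unit_pixel_with_constant_patch_kernel(self):
        vals = np.zeros((N, N))
        vals[N // 2, N // 2] = 1.0
        flu = FluenceMap(vals)
        k = ScatterKernel(np.full((3, 3), 5.0))
        out = convolve_fluence(flu, k)
        # kernel density 5 per cm^2 over a 3x3 mm patch, pixel area 0.01 cm^2
        patch = out.values[N // 2 - 1 : N // 2 + 2, N // 2 - 1 : N // 2 + 2]
        np.testing.assert_allclose(patch, 0.05)
        assert out.values.sum() == pytest.approx(9 * 0.05)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = 2.0, 3.0
        i1 = FluenceMap(rng.random((N, N)))
        i2 = FluenceMap(rng.random((N, N)))
        k = ScatterKernel(np.abs(rng.random((21, 21))))
        lhs = convolve_fluence(FluenceMap(a * i1.values + b * i2.values), k)
        rhs = a * convolve_fluence(i1, k).values + b * convolve_fluence(i2, k).values
        np.testing.assert_allclose(lhs.values, rhs, atol=1e-10)

    def test_fft_and_direct_agree(self):
        rng = np.random.default_rng(1)
        vals = rng.random((N, N))
        k = np.abs(rng.random((17, 17)))  # wide: FFT path
        area = 0.01
        fft = fftconvolve(vals, k * area, mode="same")
        direct = convolve2d(vals, k * area, mode="same", boundary="fill")
        np.testing.assert_allclose(fft, direct, atol=1e-8)

    def test_mass_conservation_up_to_padding(self):
        flu = FluenceMap(square_mask(10).astype(float))
        k = ScatterKernel(np.full((9, 9), 1.0))
        out = convolve_fluence(flu, k)
        mass_k = k.values.sum() * 0.01
        assert out.values.sum() <= flu.values.sum() * mass_k + 1e-9


class TestEnergyWeight:
    def test_marginals_and_mass(self, g0):
        flu = FluenceMap(square_mask(10).astype(float))
        ef = energy_weight(flu, g0)
        joint = ef.joint()
        np.testing.assert_allclose(joint.sum(axis=0), flu.values, atol=1e-12)
        np.testing.assert_allclose(
            joint.sum(axis=(1, 2)) / flu.total, g0.weight, atol=1e-12
        )
        assert ef.total_mass == pytest.approx(flu.values.sum())
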