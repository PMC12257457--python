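"""Off-axis scale map and collimator-scatter kernel derivation."""

import numpy as np
import pytest

from beamforge import BeamDataError, OASMap, ProfileCurve
from beamforge.fluence import PIXEL_CM, grid_size
from beamforge.oas_kernel import (
    build_oas,
    derive_kernel,
    extract_sc,
    interpolate_sc_surface,
    monotone_projection,
    sc_roundtrip,
    update_oas,
    _radius_grid,
)
from beamforge.synthetic import GoldenMachine
from beamforge.types import OutputFactorTable

FIELDS = np.array([2.0, 3.0, 5.0, 10.0, 20.0])


def _profile(fn, r_max=16.0, n=161):
    r = np.linspace(-r_max, r_max, n)
    return ProfileCurve(r, fn(np.abs(r)))


class TestBuildOAS:
    def test_flat_profile_gives_unit_map(self):
        oas = build_oas(_profile(lambda r: np.ones_like(r)), 16.0)
        assert np.allclose(oas.values, 1.0)

    def test_linear_profile_hand_value(self):
        # h(r) = 1 - 0.01 r, so C(3, 4) = h(5) = 0.95
        oas = build_oas(_profile(lambda r: 1 - 0.01 * r), 16.0)
        n = oas.values.shape[0]
        iy = n // 2 + int(round(4.0 / PIXEL_CM))
        ix = n // 2 + int(round(3.0 / PIXEL_CM))
        assert oas.values[iy, ix] == pytest.approx(0.95, abs=1e-6)

    def test_center_is_one(self):
        oas = build_oas(_profile(lambda r: 1 - 0.005 * r), 16.0)
        n = oas.values.shape[0]
        assert oas.values[n // 2, n // 2] == pytest.approx(1.0)

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(BeamDataError, match="normalized"):
            build_oas(_profile(lambda r: 2.0 - 0.01 * r), 16.0)


class TestUpdateOAS:
    def test_identity_when_profiles_match(self):
        oas = build_oas(_profile(lambda r: 1 - 0.01 * r), 16.0)
        h = _profile(lambda r: 1 - 0.012 * r)
        c1 = update_oas(oas, h, h)
        np.testing.assert_allclose(c1.values, oas.values, atol=1e-12)

    def test_uniform_scaling_renormalized(self):
        oas = build_oas(_profile(lambda r: 1 - 0.01 * r), 16.0)
        h0 = _profile(lambda r: 1 - 0.012 * r)
        h = ProfileCurve(h0.offset_cm, 1.02 * h0.value)
        c1 = update_oas(oas, h, h0)
        # a uniform ratio cancels after center renormalization
        np.testing.assert_allclose(c1.values, oas.values, atol=1e-9)

    def test_degenerate_calculated_profile_rejected(self):
        oas = build_oas(_profile(lambda r: 1 - 0.01 * r), 16.0)
        h = _profile(lambda r: 1 - 0.01 * r)
        bad = ProfileCurve(h.offset_cm, np.where(np.abs(h.offset_cm) > 10, -1.0, h.value))
        with pytest.raises(BeamDataError):
            update_oas(oas, h, bad)


class TestExtractSc:
    def test_equal_tables_give_unity(self):
        scp = OutputFactorTable(FIELDS, np.array([0.92, 0.95, 0.97, 1.0, 1.02]), 5.0)
        sc = extract_sc(scp, scp.scp.copy())
        np.testing.assert_allclose(sc, 1.0)

    def test_hand_division(self):
        scp = OutputFactorTable(
            np.array([5.0, 10.0]), np.array([0.95, 1.0]), 5.0
        )
        sc = extract_sc(scp, np.array([0.97, 1.0]))
        assert sc[0] == pytest.approx(0.95 / 0.97, abs=1e-12)
        assert sc[1] == pytest.approx(1.0)

    def test_nonpositive_sp_rejected(self):
        scp = OutputFactorTable(np.array([5.0, 10.0]), np.array([0.95, 1.0]), 5.0)
        with pytest.raises(BeamDataError):
            extract_sc(scp, np.array([0.0, 1.0]))


class TestScSurface:
    def test_diagonal_consistency(self):
        sc = np.array([0.93, 0.95, 0.97, 1.0, 1.02])
        surf = interpolate_sc_surface(FIELDS, sc)
        for f, v in zip(FIELDS, sc):
            assert surf.eval(f, f) == pytest.approx(v, abs=1e-12)

    def test_geometric_mean_rule(self):
        # Sc(f) = f^2/400 implies Sc(fx, fy) = fx*fy/400 at knot-equivalent squares
        surf = interpolate_sc_surface(FIELDS, FIELDS**2 / 400.0)
        assert surf.eval(5.0, 20.0) == pytest.approx(100.0 / 400.0, abs=1e-12)
        assert surf.eval(4.0, 2.25) == pytest.approx(9.0 / 400.0, abs=1e-12)

    def test_monotone_in_each_argument(self):
        surf = interpolate_sc_surface(FIELDS, np.array([0.93, 0.95, 0.97, 1.0, 1.02]))
        fy = 7.0
        vals = [surf.eval(fx, fy) for fx in np.linspace(2.0, 20.0, 30)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_extrapolation_clamped_with_warning(self):
        surf = interpolate_sc_surface(FIELDS, np.array([0.93, 0.95, 0.97, 1.0, 1.02]))
        with pytest.warns(UserWarning, match="clamped"):
            v = surf.eval(25.0, 25.0)
        assert v == pytest.approx(1.02, abs=1e-12)


class TestDeriveKernel:
    def test_separable_surface_gives_constant_kernel(self):
        # Sc(fx,fy) = fx*fy/400 solves the defining integral with K = 1/400;
        # the uniform core prior keeps the unresolved center flat too
        n = grid_size(16.0)
        oas = OASMap(np.ones((n, n)))
        surf = interpolate_sc_surface(FIELDS, FIELDS**2 / 400.0)
        k = derive_kernel(surf, oas, roundtrip_fields_cm=FIELDS, core_prior=False)
        m = k.values.shape[0] // 2
        assert k.values[m, m] == pytest.approx(1 / 400.0, rel=1e-6)
        assert k.values[m, m + 70] == pytest.approx(1 / 400.0, rel=1e-6)

    @pytest.fixture(scope="class")
    def golden_kernel_setup(self):
        gm = GoldenMachine()
        oas = gm.true_oas(16.0)
        sc = gm.true_sc(oas, FIELDS)
        surf = interpolate_sc_surface(FIELDS, sc)
        derived = derive_kernel(surf, oas, roundtrip_fields_cm=FIELDS)
        return gm, oas, surf, derived

    def test_roundtrip_within_half_percent(self, golden_kernel_setup):
        _, oas, surf, k = golden_kernel_setup
        for f in FIELDS:
            want = surf.square(f)
            got = sc_roundtrip(k, oas, f)
            assert abs(got - want) / want <= 0.005

    def test_circular_symmetry_exact(self, golden_kernel_setup):
        _, _, _, k = golden_kernel_setup
        r, prof = k.radial_profile()
        n = k.values.shape[0]
        rng = np.random.default_rng(0)
        for _ in range(50):
            iy, ix = rng.integers(0, n, 2)
            rad = np.hypot(
                (ix - n // 2) * PIXEL_CM, (iy - n // 2) * PIXEL_CM
            )
            idx = int(round(rad / PIXEL_CM))
            if idx < prof.size:
                assert k.values[iy, ix] == prof[min(idx, prof.size - 1)]

    def test_monotone_radial_falloff(self, golden_kernel_setup):
        _, _, _, k = golden_kernel_setup
        _, prof = k.radial_profile()
        assert np.all(np.diff(prof[1:]) <= 1e-12)

    def test_core_mass_recovered(self, golden_kernel_setup):
        gm, _, _, k = golden_kernel_setup
        true_k = gm.true_kernel()
        area = PIXEL_CM**2

        def core(kernel, rmax=1.0):
            rr = _radius_grid(kernel.values.shape[0], PIXEL_CM)
            return kernel.values[rr <= rmax].sum() * area

        assert core(k) == pytest.approx(core(true_k), rel=0.02)

    def test_generalizes_to_unmeasured_fields(self, golden_kernel_setup):
        gm, oas, _, k = golden_kernel_setup
        true_k = gm.true_kernel()
        norm = sc_roundtrip(true_k, oas, 10.0)
        for f in [4.0, 7.0, 12.0, 15.0]:
            want = sc_roundtrip(true_k, oas, f) / norm
            got = sc_roundtrip(k, oas, f)
            assert got == pytest.approx(want, rel=0.02)

    def test_roundtrip_violation_raises(self):
        n = grid_size(16.0)
        oas = OASMap(np.ones((n, n)))
        surf = interpolate_sc_surface(FIELDS, FIELDS**2 / 400.0)
        with pytest.raises(BeamDataError, match="round-trip"):
            derive_kernel(surf, oas, roundtrip_fields_cm=FIELDS, roundtrip_tol=1e-16)


def test_monotone_projection_restores_order():
    noisy = np.array([0.92, 0.95, 0.94, 1.0, 1.02])
    fixed = monotone_projection(noisy)
    assert np.all(np.diff(fixed) > 0)
    # projection only pools the violating pair
    assert fixed[0] == pytest.approx(0.92)
    assert fixed[3] == pytest.approx(1.0)
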