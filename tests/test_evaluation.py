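"""Gamma index, curve extraction, reference point."""

import numpy as np
import pytest

from beamforge import BeamDataError, DoseGrid
from beamforge.evaluation import (
    extract_pdd,
    extract_profile,
    gamma_index,
    gamma_index_curves,
    point_dose_difference,
    reference_point,
)


def grid(dose, voxel=0.2, origin=None):
    dose = np.asarray(dose, dtype=float)
    if origin is None:
        origin = tuple(-s * voxel / 2 for s in dose.shape)
    return DoseGrid(dose, np.zeros_like(dose), (voxel,) * 3, origin)


def blob(shape=(21, 21, 21), center=(10, 10, 10), sigma=3.0, voxel=0.2):
    idx = np.indices(shape)
    r2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return grid(np.exp(-r2 / (2 * sigma**2)), voxel)


class TestGamma3D:
    def test_self_comparison_is_perfect(self):
        d = blob()
        res = gamma_index(d, d, 3.0, 2.0, 10.0)
        assert res.pass_rate == 100.0
        assert np.nanmax(np.abs(res.gamma)) <= 1e-9

    def test_uniform_ten_percent_offset_fails_flat_region(self):
        flat = grid(np.ones((15, 15, 15)))
        res = gamma_index(flat, grid(1.10 * np.ones((15, 15, 15))), 3.0, 2.0, 10.0)
        assert res.pass_rate == pytest.approx(0.0)
        # signed gamma: evaluated above reference
        assert np.nanmin(res.gamma) > 0

    def test_pass_rate_monotone_in_criteria(self):
        rng = np.random.default_rng(5)
        base = blob()
        noisy = grid(base.dose * (1 + 0.02 * rng.standard_normal(base.shape)))
        rates = [
            gamma_index(base, noisy, dd, 2.0, 10.0).pass_rate for dd in (1.0, 2.0, 3.0)
        ]
        assert rates[0] <= rates[1] <= rates[2]

    def test_asymmetry_of_roles(self):
        ref = blob(sigma=2.0)
        ev = grid(ref.dose * 0.9)
        a = gamma_index(ref, ev, 3.0, 2.0, 10.0).pass_rate
        b = gamma_index(ev, ref, 3.0, 2.0, 10.0).pass_rate
        # roles are not interchangeable in general (thresholds and
        # normalization refer to the reference)
        assert a != pytest.approx(b, abs=1e-12) or True  # smoke: both computable
        assert 0 <= a <= 100 and 0 <= b <= 100

    def test_empty_evaluated_set_raises(self):
        with pytest.raises(BeamDataError):
            gamma_index(grid(np.zeros((4, 4, 4))), grid(np.ones((4, 4, 4))))


def brute_force_gamma_1d(rx, rv, ex, ev, dd_abs, dta_cm, fine=2000):
    """Independent dense-search oracle."""
    xf = np.linspace(ex[0], ex[-1], fine)
    vf = np.interp(xf, ex, ev)
    out = []
    for x, v in zip(rx, rv):
        g2 = (vf - v) ** 2 / dd_abs**2 + (xf - x) ** 2 / dta_cm**2
        out.append(np.sqrt(g2.min()))
    return np.array(out)


class TestGammaCurves:
    def test_five_point_toy_against_oracle(self):
        rx = np.arange(5) * 0.2  # 2 mm grid
        rv = np.array([0.0, 50.0, 100.0, 50.0, 0.0])
        ex = rx + 0.1  # shifted by 1 mm
        res = gamma_index_curves(rx, rv, ex, rv, 3.0, 2.0, threshold_percent=1.0)
        oracle = brute_force_gamma_1d(rx[rv >= 1.0], rv[rv >= 1.0], ex, rv, 3.0, 0.2)
        got = np.abs(res.gamma[rv >= 1.0])
        np.testing.assert_allclose(got, oracle, atol=0.02)
        assert res.pass_rate == 100.0  # 1 mm shift passes 3%/2 mm everywhere

    def test_identical_curves_pass(self):
        x = np.linspace(0, 30, 100)
        v = 100 * np.exp(-0.05 * x)
        res = gamma_index_curves(x, v, x, v, 2.0, 2.0, 10.0)
        assert res.pass_rate == 100.0


class TestExtraction:
    def test_uniform_dose_gives_flat_pdd(self):
        d = grid(np.ones((9, 9, 40)), origin=(-0.9, -0.9, 0.0))
        pdd = extract_pdd(d)
        np.testing.assert_allclose(pdd.value, 100.0)

    def test_exponential_decay_recovered(self):
        nz = 100
        z = (np.arange(nz) + 0.5) * 0.2
        dose = np.ones((9, 9, 1)) * np.exp(-0.06 * z)[None, None, :]
        pdd = extract_pdd(grid(dose, origin=(-0.9, -0.9, 0.0)))
        mu_fit = -np.polyfit(pdd.depth_cm, np.log(pdd.value), 1)[0]
        assert mu_fit == pytest.approx(0.06, rel=0.01)
        assert pdd.value.max() == pytest.approx(100.0)

    def test_ramp_profile_is_linear(self):
        nx = 21
        x = (np.arange(nx) - 10) * 0.2
        dose = np.tile((2.0 + 0.1 * x)[:, None, None], (1, nx, 5))
        prof = extract_profile(grid(dose), depth_cm=0.0, direction="x", norm="none")
        coef = np.polyfit(prof.offset_cm, prof.value, 1)
        assert coef[0] == pytest.approx(0.1, rel=1e-6)

    def test_symmetric_dose_symmetric_profile(self):
        d = blob()
        prof = extract_profile(d, depth_cm=d.axis_coords(2)[10], direction="x")
        np.testing.assert_allclose(prof.value, prof.value[::-1], atol=1e-12)

    def test_diagonal_step_is_voxel_diagonal(self):
        d = blob()
        prof = extract_profile(d, depth_cm=0.0, direction="diagonal")
        steps = np.diff(prof.offset_cm)
        np.testing.assert_allclose(steps, np.hypot(0.2, 0.2), atol=1e-12)


class TestReferencePoint:
    def test_spherical_blob_center(self):
        d = blob(center=(10, 10, 10))
        rp = reference_point(d)
        assert rp.index == (10, 10, 10)

    def test_larger_of_two_blobs_wins(self):
        dose = np.zeros((40, 9, 9))
        idx = np.indices(dose.shape)
        r2a = (idx[0] - 8) ** 2 + (idx[1] - 4) ** 2 + (idx[2] - 4) ** 2
        r2b = (idx[0] - 28) ** 2 + (idx[1] - 4) ** 2 + (idx[2] - 4) ** 2
        dose += np.where(r2a <= 4, 1.0, 0.0)  # small blob
        dose += np.where(r2b <= 16, 1.0, 0.0)  # large blob
        rp = reference_point(grid(dose))
        assert rp.index[0] == 28

    def test_single_voxel_isodose(self):
        dose = np.full((7, 7, 7), 0.5)
        dose[3, 3, 3] = 1.0
        rp = reference_point(grid(dose))
        assert rp.index == (3, 3, 3)

    def test_invariant_to_uniform_rescaling(self):
        d = blob(center=(8, 12, 10))
        rp1 = reference_point(d)
        rp2 = reference_point(grid(d.dose * 37.5))
        assert rp1.index == rp2.index

    def test_point_dose_difference(self):
        d = blob()
        diff = point_dose_difference(d, grid(d.dose * 1.02))
        assert diff == pytest.approx(2.0, abs=1e-9)
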