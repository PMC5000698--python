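import warnings

import numpy as np
import pytest

from conftest import random_physical_mueller
from silkpol.montecarlo import (
    INPUT_BASIS,
    DetectorConfig,
    MediumConfig,
    TOILET_SOAP_RATIOS,
    baseline_silk_medium,
    degradation_sweep,
    meridian_rotate,
    mueller_from_stokes_basis,
    region_mueller,
    run_simulation,
)
from silkpol.mueller import StokesVector
from silkpol.scattering import CylinderSpecies, SphereSpecies

SMALL_DET = DetectorConfig(grid=(16, 16), extent_cm=0.4)


def quiet_run(medium, n_photons, seed, detector=SMALL_DET):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_simulation(medium, detector, n_photons=n_photons, seed=seed)


class TestMeridianRotate:
    def test_zero_and_pi_are_identity(self):
        s = StokesVector(1.0, 0.3, -0.2, 0.4)
        for ang in (0.0, np.pi):
            out = meridian_rotate(s, ang)
            np.testing.assert_allclose(out.as_array(), s.as_array(), atol=1e-15)

    def test_polarization_invariant(self, rng):
        for _ in range(50):
            q, u, v = rng.uniform(-0.5, 0.5, 3)
            s = StokesVector(1.0, q, u, v)
            out = meridian_rotate(s, rng.uniform(0, 2 * np.pi))
            inv_in = 1.0 - (q**2 + u**2 + v**2)
            inv_out = out.s0**2 - (out.s1**2 + out.s2**2 + out.s3**2)
            assert inv_out == pytest.approx(inv_in, abs=1e-12)
            assert out.s0 == 1.0 and out.s3 == v


class TestMuellerFromStokesBasis:
    def test_exact_recovery_of_known_matrix(self, rng):
        m = random_physical_mueller(rng)
        outs = (m @ INPUT_BASIS)[None].transpose(2, 1, 0)  # (4 states, 4, 1)
        rec = mueller_from_stokes_basis(outs).reshape(4, 4)
        np.testing.assert_allclose(rec, m, atol=1e-12)

    def test_linearity_for_depolarizing_mixture(self, rng):
        m1, m2 = random_physical_mueller(rng), random_physical_mueller(rng)
        outs = (((m1 + m2) / 2) @ INPUT_BASIS)[None].transpose(2, 1, 0)
        rec = mueller_from_stokes_basis(outs).reshape(4, 4)
        np.testing.assert_allclose(rec, (m1 + m2) / 2, atol=1e-12)

    def test_per_pixel_against_loop_oracle(self, rng):
        mats = np.stack([random_physical_mueller(rng) for _ in range(64)]).reshape(8, 8, 4, 4)
        outs = np.einsum("hwij,jk->kihw", mats, INPUT_BASIS)
        planes = mueller_from_stokes_basis(outs)
        binv = np.linalg.inv(INPUT_BASIS)
        for i in range(8):
            for j in range(8):
                want = (outs[:, :, i, j].T @ binv).ravel()
                np.testing.assert_allclose(planes[:, i, j], want, atol=1e-12)

    def test_singular_basis_rejected(self):
        bad = np.ones((4, 4))
        with pytest.raises(ValueError, match="span"):
            mueller_from_stokes_basis(np.zeros((4, 4, 2, 2)), input_basis=bad)


class TestDegradationSweep:
    def test_toilet_soap_step1(self):
        m = degradation_sweep("toilet_soap", 1)
        assert m.sphere.scattering_coefficient == 10.0
        assert m.cylinder.scattering_coefficient == 70.0

    def test_color_stain_net_step7(self):
        m = degradation_sweep("color_stain_net", 7)
        assert m.cylinder.diameter_um == pytest.approx(0.68)
        assert m.cylinder.orientation_std_deg == pytest.approx(22.0)

    def test_toilet_soap_total_constant(self):
        for step in range(1, 8):
            m = degradation_sweep("toilet_soap", step)
            assert m.mu_total == pytest.approx(80.0)
        assert all(s + c == 80 for s, c in TOILET_SOAP_RATIOS)

    @pytest.mark.parametrize("mode,step", [("rinse", 1), ("toilet_soap", 0), ("toilet_soap", 8)])
    def test_invalid_sweeps_rejected(self, mode, step):
        with pytest.raises(ValueError):
            degradation_sweep(mode, step)


class TestRunSimulation:
    def test_zero_scattering_rejected_at_config(self):
        with pytest.raises(ValueError, match="scattering coefficient"):
            MediumConfig(
                sphere=SphereSpecies(0.2, 1.56, 0.0),
                cylinder=CylinderSpecies(1.5, 1.56, 0.0),
            )

    def test_seeded_determinism(self):
        med = baseline_silk_medium()
        a = quiet_run(med, 3_000, seed=7)
        b = quiet_run(med, 3_000, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.stokes_sums, b.stokes_sums)
        np.testing.assert_array_equal(a.image.planes, b.image.planes)

    def test_different_seed_differs(self):
        med = baseline_silk_medium()
        a = quiet_run(med, 3_000, seed=7)
        b = quiet_run(med, 3_000, seed=8)
        assert (a.counts != b.counts).any()

    def test_normalized_output_and_mask(self):
        res = quiet_run(baseline_silk_medium(), 20_000, seed=3)
        img = res.image
        np.testing.assert_allclose(img.plane("m11")[img.mask], 1.0)
        assert (res.counts >= 0).all()
        assert np.isfinite(img.planes).all()

    def test_aggregate_matrix_physical(self):
        res = quiet_run(baseline_silk_medium(), 50_000, seed=4)
        m = region_mueller(res)
        assert np.abs(m).max() <= 1.0 + 1e-9  # m11-normalized bound

    def test_fiber_axis_signature_shrinks_with_n(self):
        """Region-mean m13/m31 are noise around 0 whose spread drops ~n^-1/2."""
        med = baseline_silk_medium()
        spreads = {}
        for n, seeds in ((4_000, range(6)), (16_000, range(6, 12))):
            vals = []
            for s in seeds:
                m = region_mueller(quiet_run(med, n, seed=100 + s))
                vals.append([m[0, 2], m[2, 0]])
            vals = np.asarray(vals)
            se = vals.std(axis=0, ddof=1) / np.sqrt(len(vals))
            assert np.abs(vals.mean(axis=0)).max() <= 4 * se.max() + 0.01
            spreads[n] = vals.std(axis=0, ddof=1).mean()
        # quadrupling the photons should roughly halve the spread
        assert spreads[16_000] < spreads[4_000]

    def test_min_photon_budget_validated(self):
        with pytest.raises(ValueError, match="n_photons"):
            run_simulation(baseline_silk_medium(), SMALL_DET, n_photons=0, seed=0)


class TestOrientationInsensitivity:
    def test_sphere_only_fdh_invariant_under_scene_rotation(self):
        """Rotating an isotropic-medium image by 90 deg leaves every element
        FDH unchanged up to sampling error.

        A 90 deg scene rotation maps the planes by np.rot90 spatially and
        conjugates the matrix by the Stokes rotation diag(1,-1,-1,1), i.e.
        elements with exactly one index in {2,3} flip sign.
        """
        from silkpol.fdh import central_moments
        from silkpol.mueller import ELEMENT_NAMES

        med = MediumConfig(
            sphere=SphereSpecies(0.2, 1.56, 80.0),
            cylinder=CylinderSpecies(1.5, 1.56, 0.0),
        )
        res = quiet_run(med, 60_000, seed=17, detector=DetectorConfig(grid=(24, 24)))
        img = res.image
        ok = img.mask & (res.counts >= 20).all(axis=0)
        r = np.array([1.0, -1.0, -1.0, 1.0])
        sign = np.outer(r, r).ravel()
        rot_planes = sign[:, None, None] * np.rot90(img.planes, k=1, axes=(1, 2))
        rot_ok = np.rot90(ok, k=1)
        for k, name in enumerate(ELEMENT_NAMES):
            a = central_moments(img.planes[k], ok)
            b = central_moments(rot_planes[k], rot_ok)
            n = ok.sum()
            se = np.sqrt(a.p2 / n)
            assert abs(a.p1 - b.p1) <= 5 * np.sqrt(2) * se + 1e-12, name
            assert b.p2 == pytest.approx(a.p2, rel=0.5, abs=1e-6), name
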