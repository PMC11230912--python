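"""Generators: determinism, conservation laws and closed-form limits."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from condkit import kinetics, synthgen
from condkit.synthgen import (
    DoseResponseTruth,
    DropletFieldTruth,
    FcsTruth,
    FrapTruth,
    OrientationField,
    ThtTruth,
)


class TestDropletImage:
    def test_five_disks_give_five_components(self, five_disk_truth):
        img = synthgen.gen_droplet_image(five_disk_truth)
        labels, n = ndi.label(img.frame() > 50.0)
        assert n == 5

    def test_same_seed_bit_identical(self, five_disk_truth):
        t = five_disk_truth
        t.noise_sd = 5.0
        a = synthgen.gen_droplet_image(t).frames
        b = synthgen.gen_droplet_image(t).frames
        np.testing.assert_array_equal(a, b)

    def test_different_seed_differs(self, five_disk_truth):
        t = five_disk_truth
        t.noise_sd = 5.0
        a = synthgen.gen_droplet_image(t).frames
        t.seed += 1
        b = synthgen.gen_droplet_image(t).frames
        assert not np.array_equal(a, b)

    def test_rim_annulus_levels(self):
        t = DropletFieldTruth([(50, 50)], [20], 0.0, 10.0, rim_level=20.0,
                              shape=(101, 101))
        frame = synthgen.gen_droplet_image(t).frame()
        assert frame[50, 50] == 10.0           # core
        assert frame[50, 50 + 19] == 20.0      # rim (r ≈ 0.95R)
        assert frame[50, 50 + 30] == 0.0       # background

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(centers=[(20, 20), (30, 20)], radii=[10, 10]),        # overlap
            dict(centers=[(5, 50)], radii=[10]),                       # out of frame
            dict(centers=[(50, 50)], radii=[-3]),                      # bad radius
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DropletFieldTruth(dilute_level=1, dense_level=10, shape=(100, 100),
                              **kwargs)

    def test_rim_below_dense_rejected(self):
        with pytest.raises(ValueError):
            DropletFieldTruth([(50, 50)], [10], 1, 10, rim_level=5, shape=(100, 100))


class TestPolarizedPair:
    def test_vertical_dipoles_extinguish_horizontal(self):
        theta = np.full((8, 8), np.pi / 2)
        amp = np.random.default_rng(0).uniform(1, 5, (8, 8))
        i_v, i_h = synthgen.gen_polarized_pair(OrientationField(theta, amp), gain=3.0)
        np.testing.assert_allclose(i_h, 0.0, atol=1e-12)
        np.testing.assert_allclose(i_v, 3.0 * amp)

    def test_diagonal_dipoles_balance(self):
        f = OrientationField(np.full((5, 5), np.pi / 4), np.ones((5, 5)))
        i_v, i_h = synthgen.gen_polarized_pair(f, gain=2.0)
        np.testing.assert_allclose(i_v, i_h)

    def test_isotropic_ensemble_ignores_theta(self, rng):
        theta = rng.uniform(0, np.pi, (6, 6))
        f = OrientationField(theta, np.ones((6, 6)), isotropic_fraction=1.0)
        i_v, i_h = synthgen.gen_polarized_pair(f, gain=4.0)
        np.testing.assert_allclose(i_v, 2.0)
        np.testing.assert_allclose(i_h, 2.0)

    def test_intensity_conservation(self, rng):
        theta = rng.uniform(0, np.pi, (16, 16))
        amp = rng.uniform(0, 10, (16, 16))
        f = OrientationField(theta, amp, isotropic_fraction=0.3)
        i_v, i_h = synthgen.gen_polarized_pair(f, gain=7.0)
        np.testing.assert_allclose(i_v + i_h, 7.0 * amp, rtol=1e-12)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            OrientationField(np.zeros((3, 3)), np.full((3, 3), -1.0))


class TestTangentialRing:
    """Tangential dipoles give local dichroism d(φ) = cos 2φ."""

    def test_closed_form_at_cardinal_points(self):
        ring = synthgen.gen_tangential_ring(30.0, 6.0, shape=(101, 101))
        i_v, i_h = synthgen.gen_polarized_pair(ring, gain=1.0)
        d = np.where(ring.amplitude > 0, (i_v - i_h) / np.maximum(i_v + i_h, 1e-30), np.nan)
        assert d[50, 80] == pytest.approx(1.0)    # φ = 0: tangent vertical
        assert d[20, 50] == pytest.approx(-1.0)   # φ = π/2: tangent horizontal

    def test_ring_average_vanishes(self):
        ring = synthgen.gen_tangential_ring(30.0, 6.0, shape=(101, 101))
        i_v, i_h = synthgen.gen_polarized_pair(ring, gain=1.0)
        sel = ring.amplitude > 0
        d = (i_v[sel] - i_h[sel]) / (i_v[sel] + i_h[sel])
        assert abs(d.mean()) < 0.02  # ∫cos2φ dφ = 0, up to pixel discretization

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            synthgen.gen_tangential_ring(5.0, 10.0)


class TestFrapTrace:
    t_grid = np.concatenate([np.linspace(-5, -1, 5), np.linspace(0, 200, 81)])

    def test_plateau_matches_mobile_fraction(self):
        truth = FrapTruth(0.98, 5.0, prebleach_level=1000, postbleach_level=200)
        tr = synthgen.gen_frap_trace(truth, self.t_grid)
        expected = 200 + 0.98 * 800
        assert tr.signal[-1] == pytest.approx(expected, rel=1e-6)

    def test_immobile_limit_flat(self):
        tr = synthgen.gen_frap_trace(FrapTruth(0.0, 5.0), self.t_grid)
        post = tr.signal[tr.time >= 0]
        np.testing.assert_allclose(post, 200.0)

    def test_one_tau_closed_form(self):
        truth = FrapTruth(1.0, 5.0, prebleach_level=1000, postbleach_level=200)
        tr = synthgen.gen_frap_trace(truth, np.array([-2.0, -1.0, 5.0]))
        assert tr.signal[-1] == pytest.approx(200 + (1 - np.e**-1) * 800, rel=1e-9)

    def test_plateau_never_exceeds_prebleach(self, rng):
        for _ in range(20):
            truth = FrapTruth(float(rng.uniform(0, 1)), float(rng.uniform(1, 20)))
            tr = synthgen.gen_frap_trace(truth, self.t_grid)
            assert tr.signal.max() <= truth.prebleach_level + 1e-9

    def test_missing_segment_rejected(self):
        with pytest.raises(ValueError):
            synthgen.gen_frap_trace(FrapTruth(0.5, 5.0), np.linspace(0, 30, 40))


class TestThtCurve:
    t_grid = np.arange(0.0, 72.25, 0.25)

    def test_sigmoid_half_time_by_construction(self):
        tr = synthgen.gen_tht_curve(ThtTruth(t_half_h=20.0), self.t_grid)
        res = kinetics.half_time(kinetics.normalize_tht(tr, smooth=False))
        assert res.t_half == pytest.approx(20.0, abs=0.25)

    def test_flat_curve_fails_downstream(self):
        tr = synthgen.gen_tht_curve(ThtTruth(plateau=5.0, baseline=5.0), self.t_grid)
        with pytest.raises(kinetics.FlatCurveError):
            kinetics.normalize_tht(tr)

    def test_seeds_differ(self):
        a = synthgen.gen_tht_curve(ThtTruth(noise_sd=1.0, seed=1), self.t_grid)
        b = synthgen.gen_tht_curve(ThtTruth(noise_sd=1.0, seed=2), self.t_grid)
        assert not np.array_equal(a.signal, b.signal)


class TestFcsCurve:
    def test_amplitude_limit(self):
        truth = FcsTruth(n_particles=10.0, tau_d_s=1e-3,
                         lag_grid_s=np.geomspace(1e-9, 1.0, 60))
        tau, g = synthgen.gen_fcs_curve(truth)
        assert g[0] == pytest.approx(0.1, rel=1e-5)

    def test_two_dimensional_limit(self):
        truth = FcsTruth(n_particles=1.0, tau_d_s=1e-4, k=1e6,
                         lag_grid_s=np.geomspace(1e-7, 1.0, 50))
        tau, g = synthgen.gen_fcs_curve(truth)
        idx = np.argmin(np.abs(tau - 1e-4))
        assert g[idx] == pytest.approx(0.5, rel=1e-3)

    def test_strictly_decreasing(self):
        tau, g = synthgen.gen_fcs_curve(FcsTruth())
        assert np.all(np.diff(g) < 0)


class TestDoseResponse:
    def test_noiseless_peak_at_specified_location(self):
        truth = DoseResponseTruth(turbidity_peak_location=12.0)
        conc, od = synthgen.gen_dose_response(truth)
        assert conc[np.argmax(od)] == 12.0

    def test_zero_peak_height_flat(self):
        truth = DoseResponseTruth(peak_height=0.0)
        _, od = synthgen.gen_dose_response(truth)
        np.testing.assert_allclose(od, truth.baseline)

    def test_infinite_suppression_is_monotone(self):
        truth = DoseResponseTruth(suppression_scale=np.inf)
        _, od = synthgen.gen_dose_response(truth)
        assert np.all(np.diff(od) >= 0)

    def test_expected_dome_is_unimodal(self):
        truth = DoseResponseTruth()
        grid = np.linspace(0.0, 500.0, 5000)
        od = synthgen.dose_response_expectation(truth, grid)
        sign_changes = np.sum(np.diff(np.sign(np.diff(od))) != 0)
        assert sign_changes == 1  # exactly one local maximum
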