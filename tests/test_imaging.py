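"""Segmentation, morphometrics and radial profiles against ground truth."""

import numpy as np
import pytest

from condkit import imaging, synthgen
from condkit.imaging import ImageStack
from condkit.synthgen import DropletFieldTruth

from conftest import random_disks


class TestSegmentation:
    def test_five_disks_recovered_exactly(self, five_disk_truth):
        img = synthgen.gen_droplet_image(five_disk_truth)
        ds = imaging.segment_droplets(img, min_diameter_um=0.5)
        assert ds.count == 5
        found = {tuple(np.round([r.x, r.y]).astype(int)) for r in ds.table.itertuples()}
        truth = {tuple(np.round(c).astype(int)) for c in five_disk_truth.centers}
        # every truth center matched within 1 px
        for tx, ty in truth:
            assert any(abs(fx - tx) <= 1 and abs(fy - ty) <= 1 for fx, fy in found)

    def test_zero_contrast_finds_nothing(self):
        t = DropletFieldTruth([(50, 50)], [10], 20.0, 20.0, shape=(100, 100))
        img = synthgen.gen_droplet_image(t)
        assert imaging.segment_droplets(img).count == 0

    def test_noise_only_finds_nothing(self, rng):
        frame = rng.normal(100.0, 5.0, (128, 128))
        ds = imaging.segment_droplets(ImageStack(frame, 0.1), min_diameter_um=1.0)
        assert ds.count == 0

    def test_snr10_recovers_all_radii_within_10pct(self, rng):
        centers, radii = random_disks(rng, 12, (512, 512), r_range=(5, 20), gap=6)
        truth = DropletFieldTruth(
            centers, radii, dilute_level=20.0, dense_level=120.0,
            noise_sd=10.0, shape=(512, 512), seed=11,  # SNR = contrast/noise = 10
        )
        img = synthgen.gen_droplet_image(truth)
        ds = imaging.segment_droplets(img, min_diameter_um=0.5)
        assert ds.count == 12
        for (tx, ty), tr in zip(centers, radii):
            dist = np.hypot(ds.table.x - tx, ds.table.y - ty)
            row = ds.table.iloc[int(np.argmin(dist))]
            assert dist.min() < 2.0
            assert abs(row.radius_px - tr) / tr < 0.10

    def test_saturated_frame_flagged(self):
        frame = np.full((64, 64), 10.0)
        frame[:32] = 100.0  # half the frame pinned at max
        ds = imaging.segment_droplets(ImageStack(frame, 0.1))
        assert ds.saturated

    def test_non_2d_rejected(self):
        stack = ImageStack(np.zeros((2, 16, 16)), 0.1)
        stack.frames = np.zeros((2, 2, 16, 16))  # corrupt on purpose
        with pytest.raises(ValueError):
            imaging.segment_droplets(stack)


class TestMorphometrics:
    @pytest.mark.parametrize("d_um, sv", [(2.0, 3.0), (4.0, 1.5)])
    def test_sphere_equivalent_sv(self, d_um, sv):
        import pandas as pd

        r_px = d_um / 2 / 0.1
        tbl = pd.DataFrame([dict(x=0, y=0, radius_px=r_px, diameter_um=d_um,
                                 area_px=np.pi * r_px**2, mean_intensity=1.0,
                                 circularity=1.0)])
        s = imaging.morphometrics(imaging.DropletSet(tbl, 0.1))
        assert s.per_droplet.sv_per_um.iloc[0] == pytest.approx(sv)

    def test_median_diameter(self):
        import pandas as pd

        rows = [dict(x=0, y=0, radius_px=d / 0.2, diameter_um=d, area_px=1.0,
                     mean_intensity=1.0, circularity=1.0) for d in (1, 2, 3, 4)]
        s = imaging.morphometrics(imaging.DropletSet(pd.DataFrame(rows), 0.1))
        assert s.diameter_quartiles[1] == pytest.approx(2.5)

    def test_empty_set_gives_empty_summary(self):
        import pandas as pd

        s = imaging.morphometrics(imaging.DropletSet(pd.DataFrame(
            columns=["x", "y", "radius_px", "diameter_um", "area_px",
                     "mean_intensity", "circularity"]), 0.1))
        assert s.count == 0
        assert np.isnan(s.diameter_quartiles[1])

    def test_sv_antitone_in_diameter(self, five_disk_truth):
        img = synthgen.gen_droplet_image(five_disk_truth)
        ds = imaging.segment_droplets(img, min_diameter_um=0.5)
        s = imaging.morphometrics(ds)
        order = np.argsort(s.per_droplet.diameter_um.to_numpy())
        sv = s.per_droplet.sv_per_um.to_numpy()[order]
        assert np.all(np.diff(sv) < 0)


def brute_force_profile(frame, center, radius, n_bins, r_max=1.5):
    """Independent per-pixel oracle for the radial binning."""
    cx, cy = center
    edges = np.linspace(0, r_max, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for y in range(frame.shape[0]):
        for x in range(frame.shape[1]):
            rn = np.hypot(x - cx, y - cy) / radius
            for b in range(n_bins):
                if edges[b] <= rn < edges[b + 1]:
                    sums[b] += frame[y, x]
                    counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


class TestRadialProfile:
    def test_uniform_disk_flat_then_drop(self):
        t = DropletFieldTruth([(50, 50)], [20], 1.0, 11.0, shape=(101, 101))
        img = synthgen.gen_droplet_image(t)
        p = imaging.radial_profile(img, (50, 50), 20, n_bins=15)
        inner = p.mean_intensity[p.r_norm < 0.8]
        np.testing.assert_allclose(inner, 11.0)
        assert p.mean_intensity[p.r_norm > 1.2].max() == pytest.approx(1.0)

    def test_bright_rim_peaks_at_interface(self):
        t = DropletFieldTruth([(50, 50)], [20], 1.0, 10.0, rim_level=20.0,
                              shape=(101, 101))
        img = synthgen.gen_droplet_image(t)
        p = imaging.radial_profile(img, (50, 50), 20, n_bins=15)
        peak_bin = p.r_norm[np.nanargmax(p.mean_intensity)]
        assert 0.8 <= peak_bin <= 1.0

    def test_matches_brute_force_oracle_off_center(self, rng):
        frame = rng.uniform(0, 100, (60, 60))
        img = imaging.ImageStack(frame, 0.1)
        center, radius = (22.3, 31.7), 12.0
        p = imaging.radial_profile(img, center, radius, n_bins=10)
        means, counts = brute_force_profile(frame, center, radius, 10)
        np.testing.assert_allclose(p.counts, counts)
        np.testing.assert_allclose(p.mean_intensity, means, rtol=1e-12)

    def test_binning_conserves_total_intensity(self, rng):
        frame = rng.uniform(0, 50, (80, 80))
        img = imaging.ImageStack(frame, 0.1)
        p = imaging.radial_profile(img, (40, 40), 15, n_bins=12)
        yy, xx = np.mgrid[0:80, 0:80]
        rn = np.hypot(xx - 40, yy - 40) / 15
        used = rn < 1.5
        total = np.nansum(p.mean_intensity * p.counts)
        assert total == pytest.approx(frame[used].sum(), rel=1e-9)

    def test_edge_droplet_flags_partial_bins(self):
        frame = np.ones((50, 50))
        img = imaging.ImageStack(frame, 0.1)
        with pytest.warns(UserWarning):
            p = imaging.radial_profile(img, (4, 25), 10, n_bins=8)
        assert p.partial.any()


class TestRimEnrichment:
    def _profile(self, rim_level=None, dense=10.0, rim_width=0.2):
        t = DropletFieldTruth([(60, 60)], [30], 0.0, dense, rim_level=rim_level,
                              rim_width_frac=rim_width, shape=(121, 121))
        img = synthgen.gen_droplet_image(t)
        return imaging.radial_profile(img, (60, 60), 30, n_bins=15)

    def test_uniform_disk_ratio_one(self):
        assert imaging.rim_enrichment(self._profile()) == pytest.approx(1.0)

    def test_double_rim_ratio_two(self):
        p = self._profile(rim_level=20.0)
        assert imaging.rim_enrichment(p) == pytest.approx(2.0, rel=0.08)

    def test_dim_rim_ratio_half(self):
        # rim at half the core intensity (built directly: the generator
        # only makes bright rims)
        yy, xx = np.mgrid[0:121, 0:121]
        rn = np.hypot(xx - 60, yy - 60) / 30.0
        frame = np.zeros((121, 121))
        frame[rn <= 1.0] = 20.0
        frame[(rn >= 0.8) & (rn <= 1.0)] = 10.0
        img = imaging.ImageStack(frame, 0.1)
        p = imaging.radial_profile(img, (60, 60), 30, n_bins=15)
        assert imaging.rim_enrichment(p) == pytest.approx(0.5, rel=0.08)

    def test_zero_core_reported_missing(self):
        t = DropletFieldTruth([(60, 60)], [30], 0.0, 0.0, shape=(121, 121))
        img = synthgen.gen_droplet_image(t)
        p = imaging.radial_profile(img, (60, 60), 30, n_bins=15)
        assert np.isnan(imaging.rim_enrichment(p))

    def test_short_profile_rejected(self):
        t = DropletFieldTruth([(60, 60)], [30], 0.0, 10.0, shape=(121, 121))
        img = synthgen.gen_droplet_image(t)
        p = imaging.radial_profile(img, (60, 60), 30, n_bins=8, r_max=1.0)
        with pytest.raises(ValueError):
            imaging.rim_enrichment(p)
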