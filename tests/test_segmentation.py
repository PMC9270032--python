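"""Denoising, blob detection, volume filtering and centroid export."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from cnscensus.core import ParameterError, SegmentationConfig, VolumeImage
from cnscensus.segmentation import (SegmentationResult, concordance_report,
                                    denoise_curvature_flow, detect_blobs,
                                    extract_centroids, filter_by_volume)
from cnscensus.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="module")
def phantom50():
    spec = PhantomSpec(n_nuclei=50, seed=1, noise_sd=0.0)
    return generate_phantom(spec)


class TestDenoise:
    def test_zero_iterations_is_identity(self, rng):
        vol = VolumeImage(rng.uniform(0, 1, (4, 8, 8)), (0.317, 0.317, 1.0))
        out = denoise_curvature_flow(vol, iterations=0)
        np.testing.assert_array_equal(out.intensities, vol.intensities)

    def test_constant_volume_is_fixed_point(self):
        vol = VolumeImage(np.full((4, 8, 8), 7.0), (1.0, 1.0, 1.0))
        out = denoise_curvature_flow(vol, iterations=3, timestep=0.125)
        np.testing.assert_allclose(out.intensities, 7.0, atol=1e-6)

    def test_reduces_background_variance(self):
        spec = PhantomSpec(n_nuclei=5, volume_shape_vox=(16, 64, 64),
                          noise_sd=50.0, seed=2)
        vol, _ = generate_phantom(spec)
        out = denoise_curvature_flow(vol, iterations=5, timestep=0.125)
        # Compare variance in a corner region far from any nucleus margin.
        assert out.intensities[:4, :8, :8].var() < vol.intensities[:4, :8, :8].var()
        assert out.intensities.shape == vol.intensities.shape

    def test_invalid_timestep_rejected(self):
        vol = VolumeImage(np.zeros((2, 4, 4)), (1, 1, 1))
        with pytest.raises(ParameterError):
            denoise_curvature_flow(vol, iterations=1, timestep=0.0)


class TestDetect:
    def test_blank_volume_gives_no_objects(self):
        vol = VolumeImage(np.full((8, 32, 32), 10.0), (0.317, 0.317, 1.0))
        seg = detect_blobs(vol, SegmentationConfig())
        assert seg.n_objects == 0
        assert extract_centroids(seg).n_points == 0

    def test_recovers_planted_nuclei(self, phantom50):
        vol, truth = phantom50
        seg = detect_blobs(vol, SegmentationConfig())
        assert seg.n_objects == 50
        cloud = extract_centroids(seg)
        d, idx = cKDTree(truth.points).query(cloud.points)
        assert len(set(idx)) == 50  # one-to-one match
        assert np.sqrt((d**2).mean()) < 0.5

    def test_close_pair_not_merged(self):
        spec = PhantomSpec(n_nuclei=0, volume_shape_vox=(24, 96, 96), seed=0)
        vol, _ = generate_phantom(spec)
        img = vol.intensities.copy()
        sigma = 4.5 / (2 * np.sqrt(2 * np.log(2)))
        zz, yy, xx = np.mgrid[0:24, 0:96, 0:96]
        for cx in (12.0, 18.0):  # 6 um apart along x
            d2 = ((xx * 0.317 - cx) ** 2 + (yy * 0.317 - 10) ** 2
                  + (zz * 1.0 - 12) ** 2)
            img += 1000 * np.exp(-d2 / (2 * sigma**2))
        seg = detect_blobs(VolumeImage(img, vol.spacing), SegmentationConfig())
        assert seg.n_objects == 2

    def test_intensity_scaling_equivariance(self, phantom50):
        vol, _ = phantom50
        seg1 = detect_blobs(vol, SegmentationConfig())
        seg2 = detect_blobs(VolumeImage(vol.intensities * 10.0, vol.spacing),
                            SegmentationConfig())
        assert seg1.n_objects == seg2.n_objects


class TestVolumeFilter:
    @staticmethod
    def _sphere_segmentation(diameter_um):
        """Segment a phantom containing one blob of the given FWHM."""
        spec = PhantomSpec(n_nuclei=1, nucleus_diameter_um=diameter_um,
                           volume_shape_vox=(24, 96, 96), seed=3)
        vol, _ = generate_phantom(spec)
        return detect_blobs(vol, SegmentationConfig(
            blob_diameter_um=diameter_um))

    def test_small_sphere_removed_large_kept(self):
        # A 3 um sphere is ~14.1 um^3 (< 15); a 4.5 um one ~47.7 (>= 15).
        small = self._sphere_segmentation(3.0)
        large = self._sphere_segmentation(4.5)
        assert small.n_objects == 1 and large.n_objects == 1
        assert filter_by_volume(small, 15.0).n_objects == 0
        assert filter_by_volume(large, 15.0).n_objects == 1

    def test_zero_threshold_is_identity(self, phantom50):
        vol, _ = phantom50
        seg = detect_blobs(vol, SegmentationConfig())
        out = filter_by_volume(seg, 0.0)
        assert out.n_objects == seg.n_objects
        np.testing.assert_array_equal(out.labels, seg.labels)

    def test_composition_equals_max_threshold(self, phantom50):
        vol, _ = phantom50
        seg = detect_blobs(vol, SegmentationConfig())
        a = filter_by_volume(filter_by_volume(seg, 20.0), 40.0)
        b = filter_by_volume(seg, 40.0)
        assert [r[1] for r in a.per_object] == [r[1] for r in b.per_object]

    def test_negative_threshold_rejected(self, phantom50):
        vol, _ = phantom50
        seg = detect_blobs(vol, SegmentationConfig())
        with pytest.raises(ParameterError):
            filter_by_volume(seg, -1.0)


class TestCentroidsAndConcordance:
    def test_single_voxel_object_world_coordinates(self):
        labels = np.zeros((32, 32, 40), dtype=np.int32)
        labels[10, 20, 30] = 1
        seg = SegmentationResult(
            labels=labels,
            per_object=[(1, 0.1, (30 * 0.317, 20 * 0.317, 10 * 1.0), 5.0)],
            spacing=(0.317, 0.317, 1.0))
        cloud = extract_centroids(seg)
        np.testing.assert_allclose(cloud.points[0], [9.51, 6.34, 10.0])

    def test_concordance_values(self):
        assert concordance_report(9444, 9430)[0] == 14
        assert concordance_report(100, 100) == (0, 0.0)
        diff, pct = concordance_report(101, 100)
        assert diff == 1 and pct == pytest.approx(1.0)

    def test_concordance_zero_manual_with_detections_errors(self):
        with pytest.raises(ParameterError):
            concordance_report(5, 0)
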