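"""Otsu thresholding against a brute-force oracle, component labelling,
nuclear masks, the any-overlap exclusion rule and object measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulekit.imagestack import ImageStack
from granulekit.segmentation import (
    DegenerateHistogramError,
    LabelMap,
    exclude_nuclear_objects,
    label_objects,
    measure_objects,
    otsu_threshold,
    segment_nuclei,
    segment_puncta,
)
from granulekit.synthetic import generate_scene

from conftest import make_scene_spec


def brute_force_otsu(values: np.ndarray, n_bins: int = 256) -> float:
    """Independent oracle: exhaustive search of the bin edge maximising
    between-class variance, computed from first principles per candidate."""
    counts, edges = np.histogram(values, bins=n_bins,
                                 range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_edge = -1.0, None
    for k in range(n_bins - 1):
        c0, c1 = counts[:k + 1], counts[k + 1:]
        w0, w1 = c0.sum(), c1.sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (c0 * centers[:k + 1]).sum() / w0
        mu1 = (c1 * centers[k + 1:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_var + 1e-9 * max(best_var, 1.0):
            best_var, best_edge = v, edges[k + 1]
    return best_edge


class TestOtsu:
    def test_two_separated_modes_split_purely(self):
        x = np.concatenate([np.zeros(100), np.full(100, 200.0)])
        thr = otsu_threshold(x)
        assert 0 < thr < 200
        assert ((x > thr) == (x == 200.0)).all()

    def test_matches_brute_force_on_random_16bit_histograms(self, rng):
        for _ in range(50):
            n_modes = rng.integers(2, 5)
            parts = [rng.normal(rng.uniform(0, 65535), rng.uniform(50, 5000),
                                size=rng.integers(50, 500))
                     for _ in range(n_modes)]
            x = np.clip(np.concatenate(parts), 0, 65535).round()
            if x.min() == x.max():
                continue
            assert otsu_threshold(x) == pytest.approx(brute_force_otsu(x))

    def test_tie_break_returns_lowest_threshold(self):
        # symmetric three-level histogram: cutting below or above the middle
        # level gives the same between-class variance
        x = np.concatenate([np.zeros(100), np.full(100, 100.0),
                            np.full(100, 200.0)])
        thr = otsu_threshold(x)
        assert thr < 100.0

    def test_constant_image_raises_degenerate(self):
        with pytest.raises(DegenerateHistogramError, match="degenerate"):
            otsu_threshold(np.full(64, 7.0))

    @given(scale=st.floats(0.5, 20.0), offset=st.floats(-50.0, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_segmentation_invariant_to_affine_rescaling(self, scale, offset):
        rng = np.random.default_rng(99)
        img = np.zeros((1, 48, 48))
        img[0, 10:14, 10:14] = 100.0
        img[0, 30:33, 30:33] = 90.0
        img += rng.normal(10, 2, size=img.shape)
        thr = otsu_threshold(img)
        mask = img > thr
        img2 = scale * img + offset
        mask2 = img2 > otsu_threshold(img2)
        assert np.array_equal(mask, mask2)


class TestLabelObjects:
    def test_two_separated_spots_get_two_labels(self):
        img = np.zeros((1, 32, 32))
        img[0, 5:9, 5:9] = 10
        img[0, 20:24, 20:24] = 10
        lm = label_objects(img, threshold=5.0)
        assert lm.n_objects == 2

    def test_spot_below_min_size_removed(self):
        img = np.zeros((1, 16, 16))
        img[0, 5, 5] = 10
        assert label_objects(img, threshold=5.0, min_size_voxels=4).n_objects == 0

    def test_labels_partition_the_volume(self):
        img = np.zeros((1, 32, 32))
        img[0, 5:9, 5:9] = 10
        img[0, 20:24, 20:24] = 10
        lm = label_objects(img, threshold=5.0)
        sizes = np.bincount(lm.labels.ravel())
        assert sizes.sum() == img.size
        assert set(np.unique(lm.labels)) == {0, 1, 2}

    def test_detection_recovers_ground_truth_on_high_snr_scene(self):
        spec = make_scene_spec(seed=21, n_cells=2, n_sg=6, noise_sd=4.0,
                               poisson=True)
        stack, gt = generate_scene(spec)
        labels, _, _ = segment_puncta(stack, "gfp", exclude_nuclear=False)
        assert labels.n_objects == len(gt.objects)


class TestSegmentNuclei:
    def test_three_nuclei_found(self):
        spec = make_scene_spec(seed=22, n_cells=3, n_sg=0, shape=(1, 384, 384))
        stack, gt = generate_scene(spec)
        from scipy import ndimage
        mask = segment_nuclei(stack.channel("dapi"))
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 3

    def test_dim_interior_hole_is_filled(self):
        img = np.zeros((1, 64, 64))
        img[0, 20:40, 20:40] = 100.0
        img[0, 28:32, 28:32] = 0.0          # hole
        mask = segment_nuclei(img, min_nuclear_size_voxels=10)
        assert mask[0, 30, 30]

    def test_empty_dapi_channel_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no nucleus"):
            mask = segment_nuclei(np.zeros((1, 32, 32)))
        assert not mask.any()


class TestExcludeNuclearObjects:
    def _labels(self):
        img = np.zeros((1, 32, 32))
        img[0, 2:6, 2:6] = 10       # fully inside nucleus
        img[0, 10:14, 10:14] = 10   # one-voxel overlap
        img[0, 24:28, 24:28] = 10   # clear
        lm = label_objects(img, threshold=5.0)
        nm = np.zeros((1, 32, 32), dtype=bool)
        nm[0, 0:8, 0:8] = True
        nm[0, 13, 13] = True
        return lm, nm

    def test_any_overlap_rule(self):
        lm, nm = self._labels()
        out = exclude_nuclear_objects(lm, nm)
        assert out.n_objects == 1
        kept = out.labels > 0
        assert kept[0, 24:28, 24:28].all()
        assert not kept[0, :16, :16].any()

    def test_retained_object_keeps_voxel_set(self):
        lm, nm = self._labels()
        out = exclude_nuclear_objects(lm, nm)
        assert np.array_equal(out.labels > 0, (lm.labels == 3))

    def test_idempotent(self):
        lm, nm = self._labels()
        once = exclude_nuclear_objects(lm, nm)
        twice = exclude_nuclear_objects(once, nm)
        assert np.array_equal(once.labels, twice.labels)


class TestMeasureObjects:
    def _cube_stack(self, voxel_size):
        data = np.zeros((1, 3, 9, 9))
        data[0, 0:3, 3:6, 3:6] = 10.0
        labels = LabelMap(labels=(data[0] > 0).astype(np.int32))
        return labels, ImageStack(data=data, channel_names=["gfp"],
                                  voxel_size=voxel_size)

    def test_uniform_cube_intensity_arithmetic(self):
        labels, stack = self._cube_stack((0.1, 0.1, 0.1))
        t = measure_objects(labels, stack)
        assert t["n_voxels"].iloc[0] == 27
        assert t["mean_gfp"].iloc[0] == pytest.approx(10.0)
        assert t["integrated_gfp"].iloc[0] == pytest.approx(270.0)

    def test_physical_volume_uses_anisotropic_voxels(self):
        labels, stack = self._cube_stack((0.5, 0.1, 0.1))
        t = measure_objects(labels, stack)
        assert t["size"].iloc[0] == pytest.approx(27 * 0.5 * 0.1 * 0.1)
        assert t.attrs["size_unit"] == "um3"

    def test_missing_voxel_size_warns_and_reports_voxels(self):
        labels, stack = self._cube_stack(None)
        with pytest.warns(UserWarning, match="voxel size"):
            t = measure_objects(labels, stack)
        assert t["size"].iloc[0] == 27
        assert t.attrs["size_unit"] == "voxel"

    def test_integrated_intensity_matches_ground_truth_noiseless(self):
        from granulekit.synthetic import ground_truth_labelmap

        spec = make_scene_spec(seed=23, n_cells=1, n_sg=4)
        stack, gt = generate_scene(spec)
        t = measure_objects(ground_truth_labelmap(gt), stack)
        # remove the diffuse cytoplasmic floor under each object before comparing
        got = t["integrated_gfp"] - 20.0 * t["n_voxels"]
        want = gt.objects["intensity_gfp"]
        assert got.to_numpy() == pytest.approx(want.to_numpy(), rel=0.05)
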