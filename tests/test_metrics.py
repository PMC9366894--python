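"""Condensate metrics: signal fractions, partition, per-object Pearson,
content classification, docking detection and per-cell counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulekit import metrics, segmentation as seg
from granulekit.metrics import (
    classify_body_content,
    count_and_size,
    docking_events,
    nucleocytoplasmic_partition,
    per_object_pearson,
    percent_signal_in_objects,
)
from granulekit.segmentation import LabelMap
from granulekit.synthetic import generate_scene, ground_truth_labelmap

from conftest import make_scene_spec


def _labelmap(mask: np.ndarray) -> LabelMap:
    from scipy import ndimage
    lab, _ = ndimage.label(np.atleast_3d(mask).reshape(
        (1,) + mask.shape if mask.ndim == 2 else mask.shape),
        structure=np.ones((3, 3, 3)))
    return LabelMap(labels=lab.astype(np.int32))


class TestPercentSignal:
    def test_all_signal_in_objects_gives_100(self):
        img = np.zeros((1, 16, 16))
        img[0, 4:8, 4:8] = 50.0
        cm = np.ones_like(img, dtype=bool)
        assert percent_signal_in_objects(img, _labelmap(img > 0), cm) == 100.0

    def test_no_objects_gives_0(self):
        img = np.full((1, 16, 16), 5.0)
        lm = LabelMap(labels=np.zeros((1, 16, 16), dtype=np.int32))
        assert percent_signal_in_objects(img, lm, np.ones_like(img, bool)) == 0.0

    def test_zero_total_signal_raises(self):
        img = np.zeros((1, 8, 8))
        lm = LabelMap(labels=np.zeros((1, 8, 8), dtype=np.int32))
        with pytest.raises(ValueError, match="zero total"):
            percent_signal_in_objects(img, lm, np.ones_like(img, bool))

    def test_inside_plus_outside_is_exactly_100(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(1, 10, size=(1, 32, 32))
        mask = np.zeros((1, 32, 32), bool)
        mask[0, 5:15, 5:15] = True
        lm = _labelmap(mask[0])
        cm = np.ones_like(img, bool)
        inside = percent_signal_in_objects(img, lm, cm)
        outside = 100.0 * img[cm & ~(lm.labels > 0)].sum() / img[cm].sum()
        assert inside + outside == pytest.approx(100.0, abs=1e-9)

    def test_ground_truth_percentage_recovered_on_noiseless_scene(self):
        """A cell whose foci hold a known ~1% of total signal reports that
        fraction within 0.2 percentage points."""
        spec = make_scene_spec(seed=31, n_cells=1, n_sg=3)
        stack, gt = generate_scene(spec)
        labels = ground_truth_labelmap(gt)
        cm = gt.cell_labels > 0
        got = percent_signal_in_objects(stack.channel("gfp"), labels, cm,
                                        background="mode")
        total = gt.cell_totals.query("channel == 'gfp'")["total"].sum()
        want = 100.0 * gt.objects["intensity_gfp"].sum() / total
        assert got == pytest.approx(want, abs=0.2)


class TestPartition:
    def test_all_nuclear_signal_gives_0_percent_cytoplasmic(self):
        img = np.zeros((1, 16, 16))
        nm = np.zeros((1, 16, 16), bool)
        nm[0, 4:8, 4:8] = True
        img[nm] = 10.0
        assert nucleocytoplasmic_partition(img, nm, np.ones_like(nm)) == 0.0

    def test_nucleus_free_cell_gives_100(self):
        img = np.full((1, 16, 16), 3.0)
        nm = np.zeros((1, 16, 16), bool)
        assert nucleocytoplasmic_partition(img, nm, np.ones_like(nm)) == 100.0

    def test_nuclear_mask_outside_cell_rejected(self):
        nm = np.ones((1, 8, 8), bool)
        cm = np.zeros((1, 8, 8), bool)
        with pytest.raises(ValueError, match="outside"):
            nucleocytoplasmic_partition(np.ones((1, 8, 8)), nm, cm)

    def test_generator_truth_recovered_noiseless(self):
        spec = make_scene_spec(seed=32, n_cells=1, n_sg=4)
        stack, gt = generate_scene(spec)
        cm = gt.cell_labels > 0
        got = nucleocytoplasmic_partition(stack.channel("gfp"),
                                          gt.nuclear_mask & cm, cm)
        ch = gt.channels.index("gfp")
        want = 100.0 * gt.noiseless[ch][cm & ~gt.nuclear_mask].sum() / \
            gt.noiseless[ch][cm].sum()
        assert got == pytest.approx(want, abs=2.0)


class TestPerObjectPearson:
    def _object(self):
        mask = np.zeros((1, 8, 8), bool)
        mask[0, 2:6, 2:6] = True
        return _labelmap(mask[0]), mask

    def test_affine_relation_gives_r_1(self, rng):
        lm, mask = self._object()
        a = np.zeros((1, 8, 8))
        a[mask] = rng.uniform(1, 10, mask.sum())
        b = 2.0 * a + 5.0
        (res,) = per_object_pearson(lm, a, b)
        assert res.r == pytest.approx(1.0)

    def test_negated_channel_gives_r_minus_1(self, rng):
        lm, mask = self._object()
        a = np.zeros((1, 8, 8))
        a[mask] = rng.uniform(1, 10, mask.sum())
        (res,) = per_object_pearson(lm, a, -a)
        assert res.r == pytest.approx(-1.0)

    def test_hand_computed_four_voxel_example(self):
        lab = np.zeros((1, 2, 2), dtype=np.int32)
        lab[0] = 1
        lm = LabelMap(labels=lab)
        a = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        b = np.array([[[2.0, 1.0], [4.0, 3.0]]])
        (res,) = per_object_pearson(lm, a, b)
        assert res.r == pytest.approx(0.6, abs=1e-12)

    def test_constant_channel_flagged_undefined(self):
        lm, mask = self._object()
        a = np.zeros((1, 8, 8))
        a[mask] = 7.0
        b = np.zeros((1, 8, 8))
        b[mask] = np.arange(mask.sum())
        (res,) = per_object_pearson(lm, a, b)
        assert not res.defined and np.isnan(res.r)

    @given(sa=st.floats(0.1, 10), oa=st.floats(-5, 5),
           sb=st.floats(0.1, 10), ob=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_positive_affine_rescaling(self, sa, oa, sb, ob):
        rng = np.random.default_rng(7)
        lm, mask = self._object()
        a = np.zeros((1, 8, 8)); b = np.zeros((1, 8, 8))
        a[mask] = rng.uniform(0, 10, mask.sum())
        b[mask] = rng.uniform(0, 10, mask.sum())
        (r0,) = per_object_pearson(lm, a, b)
        (r1,) = per_object_pearson(lm, sa * a + oa, sb * b + ob)
        assert r1.r == pytest.approx(r0.r, abs=1e-9)


class TestClassifyBodyContent:
    def _scene(self, positive_fraction):
        from granulekit.synthetic import CondensateClassSpec, SceneSpec
        return SceneSpec(
            image_shape=(1, 320, 320), n_cells=1, cytoplasm_scale=3.0,
            cytoplasm_intensity={"gfp": 20.0, "stain": 20.0},
            condensates=[CondensateClassSpec(
                name="pbody", compartment="cytoplasmic", count_mean=20,
                radius_mean_um=0.3, peak_intensity={"stain": 150.0, "gfp": 80.0},
                positive_fraction={"gfp": positive_fraction})],
            seed=33)

    def test_object_at_background_is_negative(self):
        img = np.full((1, 32, 32), 10.0)
        mask = np.zeros((1, 32, 32), bool)
        mask[0, 10:14, 10:14] = True
        lm = _labelmap(mask[0])
        cells = np.ones((1, 32, 32), dtype=np.int32)
        df = classify_body_content(lm, img, cells)
        assert not df["positive"].iloc[0]

    def test_bright_object_is_positive(self):
        img = np.full((1, 32, 32), 10.0)
        mask = np.zeros((1, 32, 32), bool)
        mask[0, 10:14, 10:14] = True
        img[mask] = 100.0
        lm = _labelmap(mask[0])
        cells = np.ones((1, 32, 32), dtype=np.int32)
        df = classify_body_content(lm, img, cells, enrichment_factor=1.5)
        assert df["positive"].iloc[0]

    def test_no_objects_flagged_undefined(self):
        lm = LabelMap(labels=np.zeros((1, 8, 8), dtype=np.int32))
        df = classify_body_content(lm, np.ones((1, 8, 8)),
                                   np.ones((1, 8, 8), dtype=np.int32))
        assert np.isnan(df.attrs["percent_positive"])

    def test_recovers_rendered_positive_fraction(self):
        """With 60% of P-bodies carrying channel-B signal, the classifier
        reports 60 ± 5 percentage points on the noiseless render."""
        pcts = []
        for seed in range(5):
            spec = self._scene(0.6).model_copy(update={"seed": 40 + seed})
            stack, gt = generate_scene(spec)
            labels, _, _ = seg.segment_puncta(stack, "stain")
            df = classify_body_content(labels, stack.channel("gfp"),
                                       gt.cell_labels)
            pcts.append(df.attrs["percent_positive"])
            want = 100.0 * (gt.objects["peak_gfp"] > 0).mean()
            assert df.attrs["percent_positive"] == pytest.approx(want, abs=1e-6)
        assert np.mean(pcts) == pytest.approx(60.0, abs=5.0)


class TestDockingEvents:
    def _pair(self, gap):
        sg = np.zeros((1, 32, 32), dtype=np.int32)
        pb = np.zeros((1, 32, 32), dtype=np.int32)
        sg[0, 10:14, 10:14] = 1
        pb[0, 10:14, 14 + gap:18 + gap] = 1
        return LabelMap(labels=sg), LabelMap(labels=pb)

    def test_face_sharing_pair_is_one_event(self):
        sg, pb = self._pair(gap=0)
        df = docking_events(sg, pb, max_gap_voxels=1)
        assert df.attrs["n_events"] == 1

    def test_three_voxel_separation_is_no_event(self):
        sg, pb = self._pair(gap=3)
        df = docking_events(sg, pb, max_gap_voxels=1)
        assert df.attrs["n_events"] == 0

    def test_symmetric_in_arguments(self):
        sg, pb = self._pair(gap=1)
        a = docking_events(sg, pb, max_gap_voxels=1)
        b = docking_events(pb, sg, max_gap_voxels=1)
        assert a.attrs["n_events"] == b.attrs["n_events"] == 1

    def test_noiseless_scene_recovers_true_docked_pairs_exactly(self):
        hits, truth = 0, 0
        for seed in range(3):
            spec = make_scene_spec(seed=50 + seed, n_cells=2, n_sg=4, n_pb=5,
                                   docking_fraction=0.5, cytoplasm_scale=2.5,
                                   shape=(1, 400, 400))
            stack, gt = generate_scene(spec)
            sgl, nm, cm = seg.segment_puncta(stack, "gfp")
            pbl, _, _ = seg.segment_puncta(stack, "stain", cell_mask=cm)
            ev = docking_events(sgl, pbl, max_gap_voxels=1)
            hits += ev.attrs["n_events"]
            truth += len(gt.docked_pairs)
        assert truth > 0
        assert hits == truth


class TestCountAndSize:
    def test_empty_labelmap_gives_zero_counts(self):
        t = pd.DataFrame(columns=["cell_id", "size"])
        out = count_and_size(t, n_cells=3)
        assert (out["count"] == 0).all()

    def test_isolated_spot_increments_one_cell(self):
        t = pd.DataFrame({"cell_id": [1, 1, 2], "size": [1.0, 2.0, 3.0]})
        base = count_and_size(t, n_cells=2)
        t2 = pd.concat([t, pd.DataFrame({"cell_id": [2], "size": [4.0]})],
                       ignore_index=True)
        out = count_and_size(t2, n_cells=2)
        assert out["count"].tolist() == [base["count"][0], base["count"][1] + 1]

    def test_counts_match_ground_truth_on_high_snr_scenes(self):
        exact = 0
        total = 0
        for seed in range(5):
            spec = make_scene_spec(seed=60 + seed, n_cells=2, n_sg=5,
                                   noise_sd=4.0, poisson=True)
            stack, gt = generate_scene(spec)
            labels, nm, cmask = seg.segment_puncta(stack, "gfp",
                                                   exclude_nuclear=False)
            table = seg.measure_objects(labels, stack, nuclear_mask=nm,
                                        cell_labels=gt.cell_labels)
            out = count_and_size(table, n_cells=2)
            want = gt.objects.groupby("cell_id").size()
            for cid in (1, 2):
                total += 1
                if out.set_index("cell_id")["count"].get(cid, 0) == want.get(cid, 0):
                    exact += 1
        assert exact / total >= 0.95
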