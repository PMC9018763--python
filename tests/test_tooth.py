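import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from dentseg.fields import OffsetField
from dentseg.io_core import Volume
from dentseg.oracle import OracleOffsetPredictor, OracleRoiPredictor
from dentseg.phantom import make_offset_targets
from dentseg.tooth import (
    NoDentalRoiError,
    NoTeethDetectedError,
    ToothInstance,
    VoteCloud,
    assemble_instances,
    assign_fdi_by_arch,
    build_tooth_input,
    cast_votes,
    cluster_votes,
    localize_roi,
    segment_single_tooth,
)


class _MapPredictor:
    """Returns fixed full-volume maps cropped to the requested window."""

    def __init__(self, **maps):
        self.maps = maps

    def predict(self, patch, context=None):
        w = (context or {}).get("window")
        start = np.zeros(3, dtype=int) if w is None else np.asarray(w.start)
        sl = tuple(slice(s, s + d) for s, d in zip(start, patch.shape[1:]))
        out = {}
        for name, arr in self.maps.items():
            if name == "class_logits":
                out[name] = arr
            elif arr.ndim == 4:
                out[name] = arr[(slice(None),) + sl]
            else:
                out[name] = arr[sl][None]
        return out


class TestLocalizeRoi:
    def test_margin_dilation_arithmetic(self, rng):
        prob = np.zeros((64, 64, 64), dtype=np.float32)
        prob[10:20, 10:20, 10:20] = 1.0
        v = Volume(rng.random((64, 64, 64)).astype(np.float32), spacing=(1,) * 3)
        window, _ = localize_roi(v, _MapPredictor(mask=prob), patch=(64, 64, 64),
                                 min_component_voxels=10, margin=2)
        assert window.start == (8, 8, 8)
        assert window.stop == (22, 22, 22)

    def test_empty_probability_raises(self, rng):
        v = Volume(rng.random((32, 32, 32)).astype(np.float32), spacing=(1,) * 3)
        zero = np.zeros((32, 32, 32), dtype=np.float32)
        with pytest.raises(NoDentalRoiError):
            localize_roi(v, _MapPredictor(mask=zero), patch=(32, 32, 32))

    def test_small_components_filtered_out(self, rng):
        prob = np.zeros((32, 32, 32), dtype=np.float32)
        prob[4, 4, 4] = 1.0  # single-voxel speck
        v = Volume(rng.random((32, 32, 32)).astype(np.float32), spacing=(1,) * 3)
        with pytest.raises(NoDentalRoiError):
            localize_roi(v, _MapPredictor(mask=prob), patch=(32, 32, 32),
                         min_component_voxels=10)

    def test_oracle_window_contains_all_teeth(self, phantom64):
        vol, gt = phantom64
        v = Volume(vol.voxels.astype(np.float32) / 2500.0, vol.spacing)
        window, _ = localize_roi(v, OracleRoiPredictor(gt), patch=(64, 64, 64))
        tooth_vox = np.argwhere(gt.tooth_labels > 0)
        assert (tooth_vox >= window.start).all()
        assert (tooth_vox < np.asarray(window.stop)).all()


class TestCastVotes:
    def test_zero_offsets_vote_in_place(self):
        fg = np.zeros((6, 6, 6), dtype=bool)
        fg[2:4, 2:4, 2:4] = True
        off = OffsetField(np.zeros((6, 6, 6, 3), np.float32), fg)
        cloud = cast_votes(off, fg)
        np.testing.assert_array_equal(cloud.points, cloud.sources)

    def test_empty_foreground_empty_cloud(self):
        fg = np.zeros((4, 4, 4), dtype=bool)
        cloud = cast_votes(OffsetField(np.zeros((4, 4, 4, 3), np.float32), fg), fg)
        assert len(cloud.points) == 0

    def test_gt_centroid_votes_land_on_centroids(self, phantom64):
        _, gt = phantom64
        field = make_offset_targets(gt.tooth_labels, "centroid", gt)
        cloud = cast_votes(field, field.valid)
        for f in list(gt.centroids)[:5]:
            sel = gt.tooth_labels[tuple(cloud.sources.T)] == f
            dist = np.linalg.norm(cloud.points[sel] - gt.centroids[f], axis=1)
            assert dist.max() < 0.5

    def test_shape_mismatch_rejected(self):
        fg = np.zeros((4, 4, 4), dtype=bool)
        off = OffsetField(np.zeros((4, 4, 4, 3), np.float32), fg)
        with pytest.raises(ValueError):
            cast_votes(off, np.zeros((5, 4, 4), dtype=bool))


def _blob_cloud(rng, centers, n_per=50, scale=0.5):
    pts = np.concatenate(
        [c + rng.normal(0, scale, size=(n_per, 3)) for c in np.asarray(centers, float)]
    )
    src = np.zeros((len(pts), 3), dtype=int)
    return VoteCloud(points=pts, sources=src), np.repeat(np.arange(len(centers)), n_per)


class TestClusterVotes:
    def test_two_well_separated_blobs(self, rng):
        cloud, truth = _blob_cloud(rng, [(10, 10, 10), (10, 10, 50)], n_per=50)
        labels, cents = cluster_votes(cloud, dc=2.0, peak_min_density=10, peak_min_sep=5.0)
        assert len(cents) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_blob_single_instance(self, rng):
        cloud, _ = _blob_cloud(rng, [(20, 20, 20)], n_per=80)
        labels, cents = cluster_votes(cloud, dc=2.0, peak_min_density=10, peak_min_sep=5.0)
        assert len(cents) == 1
        assert (labels == 0).all()

    def test_oracle_votes_recover_all_16_teeth(self, phantom64):
        _, gt = phantom64
        field = make_offset_targets(gt.tooth_labels, "centroid", gt)
        cloud = cast_votes(field, field.valid)
        labels, cents = cluster_votes(cloud)
        assert len(cents) == 16
        truth = gt.tooth_labels[tuple(cloud.sources.T)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_min_votes_filter_drops_stray_cluster(self, rng):
        big, _ = _blob_cloud(rng, [(10, 10, 10)], n_per=60)
        small, _ = _blob_cloud(rng, [(10, 10, 40)], n_per=8, scale=0.2)
        cloud = VoteCloud(
            points=np.concatenate([big.points, small.points]),
            sources=np.concatenate([big.sources, small.sources]),
        )
        labels, cents = cluster_votes(cloud, dc=2.0, peak_min_density=5, peak_min_sep=5.0,
                                      min_cluster_votes=30)
        assert len(cents) == 1
        assert (labels[60:] == -1).all()

    def test_empty_cloud_raises(self):
        cloud = VoteCloud(points=np.zeros((0, 3)), sources=np.zeros((0, 3), int))
        with pytest.raises(NoTeethDetectedError):
            cluster_votes(cloud)

    def test_no_center_criteria_met_raises(self, rng):
        # sparse points: nothing reaches the density threshold
        cloud = VoteCloud(points=rng.uniform(0, 100, (30, 3)), sources=np.zeros((30, 3), int))
        with pytest.raises(NoTeethDetectedError):
            cluster_votes(cloud, dc=1.0, peak_min_density=20, peak_min_sep=5.0)

    def test_permutation_invariance(self, rng):
        cloud, _ = _blob_cloud(rng, [(10, 10, 10), (10, 30, 10), (30, 10, 10)], n_per=40)
        ref_labels, ref_cents = cluster_votes(cloud, dc=2.0, peak_min_density=10,
                                              peak_min_sep=5.0)
        for _ in range(5):
            perm = rng.permutation(len(cloud.points))
            shuffled = VoteCloud(points=cloud.points[perm], sources=cloud.sources[perm])
            labels, cents = cluster_votes(shuffled, dc=2.0, peak_min_density=10,
                                          peak_min_sep=5.0)
            np.testing.assert_allclose(np.asarray(cents), np.asarray(ref_cents), atol=1e-9)
            np.testing.assert_array_equal(labels, ref_labels[perm])


class TestAssignFdiByArch:
    def test_recovers_gt_codes_full_dentition(self, phantom64):
        _, gt = phantom64
        codes = sorted(gt.centroids)
        cents = [gt.centroids[f] for f in codes]
        assert assign_fdi_by_arch(cents, gt.tooth_labels.shape) == codes

    def test_recovers_gt_codes_with_missing_teeth(self, phantom64_missing):
        _, gt = phantom64_missing
        codes = sorted(gt.centroids)
        cents = [gt.centroids[f] for f in codes]
        assert assign_fdi_by_arch(cents, gt.tooth_labels.shape) == codes

    def test_empty_input(self):
        assert assign_fdi_by_arch([], (64, 64, 64)) == []


class TestBuildToothInput:
    def test_centroid_channel_peaks_at_centroid(self, rng):
        v = Volume(rng.random((32, 32, 32)).astype(np.float32), spacing=(1,) * 3)
        inst = ToothInstance(1, None, np.array([16.0, 16.0, 16.0]), np.zeros((0, 3), int))
        patch, origin = build_tooth_input(v, inst, None, patch=(16, 16, 16))
        assert patch.shape == (3, 16, 16, 16)
        peak = np.unravel_index(np.argmax(patch[0]), patch[0].shape)
        assert tuple(np.asarray(peak) + origin) == (16, 16, 16)
        assert patch[0].max() == pytest.approx(1.0)

    def test_no_skeleton_zeroes_channel_two(self, rng):
        v = Volume(rng.random((32, 32, 32)).astype(np.float32), spacing=(1,) * 3)
        inst = ToothInstance(1, None, np.array([16.0, 16.0, 16.0]), np.zeros((0, 3), int))
        patch, _ = build_tooth_input(v, inst, None, patch=(16, 16, 16))
        assert not patch[1].any()
        assert patch[2].any()

    def test_corner_crop_clamped_inside(self, rng):
        v = Volume(rng.random((32, 32, 32)).astype(np.float32), spacing=(1,) * 3)
        inst = ToothInstance(1, None, np.array([1.0, 1.0, 30.0]), np.zeros((0, 3), int))
        _, origin = build_tooth_input(v, inst, None, patch=(16, 16, 16))
        assert origin == (0, 0, 16)

    def test_patch_larger_than_volume_rejected(self, rng):
        v = Volume(rng.random((8, 8, 8)).astype(np.float32), spacing=(1,) * 3)
        inst = ToothInstance(1, None, np.array([4.0, 4.0, 4.0]), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            build_tooth_input(v, inst, None, patch=(16, 16, 16))


class TestSegmentSingleTooth:
    def test_largest_component_survives(self):
        prob = np.zeros((16, 16, 16), dtype=np.float32)
        prob[2:10, 2:10, 2:10] = 0.9  # large blob
        prob[13:15, 13:15, 13:15] = 0.9  # small distractor

        class P:
            def predict(self, patch, context=None):
                return {"mask": prob[None]}

        mask, p, _, _, fdi = segment_single_tooth(np.zeros((3, 16, 16, 16), np.float32), P())
        assert mask[2:10, 2:10, 2:10].all()
        assert not mask[13:15, 13:15, 13:15].any()
        assert fdi is None

    def test_classifier_logits_map_through_fdi_table(self):
        logits = np.full(32, -5.0, dtype=np.float32)
        logits[31] = 5.0

        class P:
            def predict(self, patch, context=None):
                return {"mask": np.zeros((1, 8, 8, 8), np.float32), "class_logits": logits}

        *_, fdi = segment_single_tooth(np.zeros((3, 8, 8, 8), np.float32), P())
        assert fdi == 48


class TestAssembleInstances:
    @staticmethod
    def _inst(iid, fdi, origin, mask, prob):
        return ToothInstance(iid, fdi, np.zeros(3), np.zeros((0, 3), int),
                             crop_origin=origin, mask_crop=mask, prob_crop=prob)

    def test_disjoint_crops_conserve_voxel_counts(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1:3, 1:3, 1:3] = True
        p = np.full((4, 4, 4), 0.8, dtype=np.float32)
        labels, probs, ids, conflicts = assemble_instances(
            [self._inst(1, 11, (0, 0, 0), m, p), self._inst(2, 21, (0, 0, 8), m, p)],
            (16, 16, 16),
        )
        assert (labels == 11).sum() == m.sum()
        assert (labels == 21).sum() == m.sum()
        assert conflicts == []

    def test_overlap_resolved_by_probability(self):
        m = np.ones((2, 2, 2), dtype=bool)
        hi = np.full((2, 2, 2), 0.9, dtype=np.float32)
        lo = np.full((2, 2, 2), 0.6, dtype=np.float32)
        labels, probs, _, _ = assemble_instances(
            [self._inst(1, 21, (0, 0, 0), m, lo), self._inst(2, 11, (0, 0, 0), m, hi)],
            (4, 4, 4),
        )
        assert (labels[:2, :2, :2] == 11).all()
        assert probs[0, 0, 0] == pytest.approx(0.9)

    def test_probability_tie_goes_to_lower_fdi(self):
        m = np.ones((2, 2, 2), dtype=bool)
        p = np.full((2, 2, 2), 0.7, dtype=np.float32)
        labels, *_ = assemble_instances(
            [self._inst(1, 24, (0, 0, 0), m, p), self._inst(2, 13, (0, 0, 0), m, p)],
            (4, 4, 4),
        )
        assert (labels[:2, :2, :2] == 13).all()

    def test_duplicate_fdi_reported_as_conflict(self):
        m = np.ones((2, 2, 2), dtype=bool)
        p = np.full((2, 2, 2), 0.7, dtype=np.float32)
        labels, _, ids, conflicts = assemble_instances(
            [self._inst(1, 11, (0, 0, 0), m, p), self._inst(2, 11, (0, 0, 8), m, p)],
            (4, 4, 12),
        )
        assert conflicts == [(11, 2)]
        assert set(np.unique(ids)) == {0, 1, 2}

    def test_out_of_bounds_crop_rejected(self):
        m = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            assemble_instances(
                [self._inst(1, 11, (14, 0, 0), m, m.astype(np.float32))], (16, 16, 16)
            )

    def test_assembled_labels_are_legal_fdi_codes(self, phantom64):
        _, gt = phantom64
        legal = {0} | {q * 10 + p for q in (1, 2, 3, 4) for p in range(1, 9)}
        assert set(np.unique(gt.tooth_labels)).issubset(legal)
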