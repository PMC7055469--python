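"""Region extraction, silique assembly, angle splitting, counting, length."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podquant import reconstruct, siliques, synth
from podquant.reconstruct import LabelImage, BACKGROUND
from podquant.siliques import (CounterConfig, extract_regions,
                               build_candidates, pair_angle,
                               resolve_candidate, measure_length, count_image,
                               Region, BASE, BODY, STEM, TIP)


def _label_image(arr):
    arr = np.asarray(arr, dtype=np.uint8)
    votes = np.where(arr != BACKGROUND, 4, 0).astype(np.uint8)
    return LabelImage(labels=arr, votes=votes)


def _blank(rows, cols):
    return np.full((rows, cols), BACKGROUND, dtype=np.uint8)


class TestExtractRegions:
    def test_single_run_region(self):
        a = _blank(5, 5)
        a[2, 1:4] = TIP
        regs = extract_regions(_label_image(a), min_region_area=1)
        assert len(regs) == 1
        assert regs[0].cls == TIP and regs[0].area == 3

    def test_diagonal_cells_are_one_region(self):
        a = _blank(4, 4)
        a[0, 0] = TIP
        a[1, 1] = TIP
        regs = extract_regions(_label_image(a), min_region_area=1)
        assert len(regs) == 1 and regs[0].area == 2

    def test_min_area_filters_specks(self):
        a = _blank(6, 6)
        a[0, 0] = BODY          # isolated speck
        a[3, 1:4] = BODY        # real region
        regs = extract_regions(_label_image(a), min_region_area=2)
        assert len(regs) == 1 and regs[0].area == 3

    def test_classes_kept_separate(self):
        a = _blank(3, 3)
        a[1, 0], a[1, 1], a[1, 2] = BASE, BODY, TIP
        regs = extract_regions(_label_image(a), min_region_area=1)
        assert sorted(r.cls for r in regs) == [BASE, BODY, TIP]


class TestBuildCandidates:
    def test_tip_body_base_chain_is_one_candidate(self):
        a = _blank(3, 7)
        a[1, 1] = BASE
        a[1, 2:5] = BODY
        a[1, 5] = TIP
        cands = build_candidates(extract_regions(_label_image(a), 1))
        assert len(cands) == 1
        assert sorted(r.cls for r in cands[0]) == [BASE, BODY, TIP]

    def test_tip_body_without_base_is_no_candidate(self):
        a = _blank(3, 6)
        a[1, 1:4] = BODY
        a[1, 4] = TIP
        assert build_candidates(extract_regions(_label_image(a), 1)) == []

    def test_stem_terminates_growth(self):
        # two complete pods joined only through a stem column
        a = _blank(3, 11)
        a[1, 0] = TIP
        a[1, 1:3] = BODY
        a[1, 3] = BASE
        a[1, 5] = STEM
        a[1, 7] = BASE
        a[1, 8:10] = BODY
        a[1, 10] = TIP
        # bridge the gaps so only the stem separates them
        a[1, 4] = BASE
        a[1, 6] = BASE
        cands = build_candidates(extract_regions(_label_image(a), 1))
        assert len(cands) == 2

    def test_tip_base_contact_without_body_does_not_connect(self):
        a = _blank(3, 4)
        a[1, 1] = BASE
        a[1, 2] = TIP
        assert build_candidates(extract_regions(_label_image(a), 1)) == []


class TestPairAngle:
    @pytest.mark.parametrize("u,v,expected", [
        ((1, 0), (0, 1), np.pi / 2),
        ((1, 0), (1, 0), 0.0),
        ((1, 0), (1, 0.1), 0.09966865249116204),  # atan2(0.1, 1)
        ((1, 0), (-1, 0), np.pi),
    ])
    def test_reference_angles(self, u, v, expected):
        assert pair_angle(u, v) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            pair_angle((0, 0), (1, 0))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-100, 100), st.floats(-100, 100),
           st.floats(-100, 100), st.floats(-100, 100))
    def test_symmetry_and_range(self, ux, uy, vx, vy):
        u, v = np.array([ux, uy]), np.array([vx, vy])
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        a = pair_angle(u, v)
        assert 0 <= a <= np.pi
        assert a == pytest.approx(pair_angle(v, u), abs=1e-12)
        assert pair_angle(u, 3.7 * u) == pytest.approx(0.0, abs=1e-9)


def _two_tip_candidate(angle, arm=20.0):
    """Shared base at origin with two tips subtending ``angle``."""
    base = Region(BASE, ((0, 0),))
    body = Region(BODY, ((0, 1),))
    # centroids in (x, y) = (col, row): place tips on integer-free cells
    t1 = Region(TIP, ((0, int(arm)),))
    r2 = int(round(arm * np.cos(angle)))
    c2 = int(round(arm * np.sin(angle)))
    t2 = Region(TIP, ((r2, c2),))
    return [base, body, t1, t2]


class TestResolveCandidate:
    def test_single_tip_single_base(self):
        cand = [Region(BASE, ((0, 0),)), Region(BODY, ((0, 1),)),
                Region(TIP, ((0, 5),))]
        out = resolve_candidate(cand)
        assert len(out) == 1
        assert out[0].length == pytest.approx(5 * 16)

    def test_two_tips_shared_base_wide_angle_splits(self):
        out = resolve_candidate(_two_tip_candidate(0.2))
        assert len(out) == 2

    def test_two_tips_shared_base_narrow_angle_merges(self):
        cand = [Region(BASE, ((0, 0),)), Region(BODY, ((0, 1),)),
                Region(TIP, ((0, 400),)), Region(TIP, ((4, 400),))]
        # angle atan2(4, 400) ~ 0.01 rad
        out = resolve_candidate(cand)
        assert len(out) == 1
        assert out[0].merged_from == 2
        # the longer vector is retained
        assert out[0].length >= 400 * 16

    def test_threshold_monotonicity(self):
        cand = _two_tip_candidate(0.12)
        counts = [sum(1 for _ in resolve_candidate(
            cand, CounterConfig(angle_threshold=t)))
            for t in (0.01, 0.05, 0.2, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_three_fanned_tips_split_pairwise(self):
        base = Region(BASE, ((0, 0),))
        body = Region(BODY, ((1, 0),))
        tips = [Region(TIP, ((int(round(30 * np.cos(a))),
                              int(round(30 * np.sin(a)))),))
                for a in (0.3, 0.9, 1.5)]
        out = resolve_candidate([base, body, *tips])
        assert len(out) == 3


class TestMeasureLength:
    def test_three_four_five_triangle(self):
        s = resolve_candidate([Region(BASE, ((0, 0),)),
                               Region(BODY, ((0, 1),)),
                               Region(TIP, ((4, 3),))])[0]
        assert measure_length(s) == pytest.approx(5 * 16)

    def test_coincident_centroids_flagged_invalid(self):
        s = siliques.SiliqueObject(tip=Region(TIP, ((0, 0),)),
                                   base=Region(BASE, ((0, 0),)),
                                   bodies=(), vector=np.zeros(2), length=0.0)
        assert not s.valid

    def test_straight_pod_length_close_to_generator_truth(self, plain_scene):
        labels = reconstruct.downsample_mask(plain_scene.mask)
        result = count_image(labels)
        assert result.count == plain_scene.true_count
        got = sorted(s.length for s in result.siliques)
        want = sorted(plain_scene.silique_lengths)
        np.testing.assert_allclose(got, want, atol=2 * 16)


class TestCountImage:
    def test_all_background_counts_zero(self):
        assert count_image(_label_image(_blank(8, 8))).count == 0

    def test_count_on_ground_truth_labels(self, plain_scene):
        labels = reconstruct.downsample_mask(plain_scene.mask)
        assert count_image(labels).count == plain_scene.true_count

    def test_overlap_pair_at_wide_angle_counts_two(self):
        truth = synth.generate_scene(synth.SceneSpec(
            seed=31, n_siliques=2, n_overlap_pairs=1,
            overlap_angle_range=(0.2, 0.2)))
        labels = reconstruct.downsample_mask(truth.mask)
        assert count_image(labels).count == 2

    def test_monotonic_under_disjoint_pod_addition(self, plain_scene):
        labels = reconstruct.downsample_mask(plain_scene.mask)
        base_count = count_image(labels).count
        # extend the canvas and paste a complete pod into the new empty strip
        arr = np.pad(labels.labels, ((10, 0), (0, 0)), constant_values=BACKGROUND)
        arr[3, 0:2] = BASE
        arr[3, 2:6] = BODY
        arr[3, 6:8] = TIP
        assert count_image(_label_image(arr)).count == base_count + 1

    def test_rotation_robustness(self, plain_scene):
        labels = reconstruct.downsample_mask(plain_scene.mask)
        rotated = _label_image(np.rot90(labels.labels))
        assert count_image(rotated).count == count_image(labels).count

    def test_summary_schema(self, plain_scene):
        labels = reconstruct.downsample_mask(plain_scene.mask)
        summary = count_image(labels).summary()
        assert set(summary) == {"predicted_count", "mean_length_px",
                                "max_length_px", "min_length_px"}
        assert summary["min_length_px"] <= summary["mean_length_px"] \
            <= summary["max_length_px"]

    def test_detection_overlay_marks_silique_cells(self, plain_scene):
        labels = reconstruct.downsample_mask(plain_scene.mask)
        result = count_image(labels)
        overlay = siliques.detection_overlay(labels, result)
        assert overlay.shape == (labels.shape[0] * 16, labels.shape[1] * 16)
        assert set(np.unique(overlay)) <= {0, 255}
        assert overlay.any()
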