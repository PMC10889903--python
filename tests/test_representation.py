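"""Cross-set RDMs, distances, depth profiles and the framework score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from illusionprobe import (
    build_cross_rdm,
    depth_profile,
    framework_score,
    pair_distance,
    select_level_exemplars,
)
from illusionprobe.human import LEVEL_WIDTH_DEG
from illusionprobe.representation import (
    CrossRDM,
    FeatureTensor,
    diagonal_contrast,
    extract_features,
    render_level_pairs,
)
from illusionprobe.saliency import HeatMap
from illusionprobe.stimuli import render_illusion


class TestPairDistance:
    def test_matches_brute_force_loop_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(3, 4, 5))
        b = rng.normal(size=(3, 4, 5))
        sq = 0.0
        for i in range(3):
            for j in range(4):
                for k in range(5):
                    sq += (a[i, j, k] - b[i, j, k]) ** 2
        assert pair_distance(a, b, "sq_sum") == pytest.approx(sq, rel=1e-12)
        assert pair_distance(a, b, "euclidean") == pytest.approx(
            np.sqrt(sq), rel=1e-12
        )

    def test_zero_on_identical_inputs(self):
        x = np.arange(24.0).reshape(2, 3, 4)
        for mode in ("sq_sum", "euclidean"):
            assert pair_distance(x, x.copy(), mode) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        arrays(np.float64, (6,), elements=st.floats(-10, 10)),
        arrays(np.float64, (6,), elements=st.floats(-10, 10)),
        arrays(np.float64, (6,), elements=st.floats(-10, 10)),
    )
    def test_euclidean_mode_is_a_metric(self, a, b, c):
        dab = pair_distance(a, b)
        assert dab >= 0
        assert dab == pytest.approx(pair_distance(b, a))
        assert dab <= pair_distance(a, c) + pair_distance(c, b) + 1e-9

    def test_shape_layer_and_mode_mismatches_are_rejected(self):
        with pytest.raises(ValueError):
            pair_distance(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            pair_distance(np.zeros(3), np.zeros(3), mode="cosine")
        fa = FeatureTensor(np.zeros(3), "block1", "real")
        fb = FeatureTensor(np.zeros(3), "block2", "real")
        with pytest.raises(ValueError):
            pair_distance(fa, fb)


class TestExemplars:
    def test_selection_matches_nearest_bin_centre_oracle(self, strengths):
        chosen = select_level_exemplars(strengths)
        assert sorted(chosen) == list(range(1, 9))
        for level, rec in chosen.items():
            centre = (level - 0.5) * LEVEL_WIDTH_DEG
            best = min(
                (s for s in strengths if s.level == level),
                key=lambda s: abs(s.strength_deg - centre),
            )
            assert rec.strength_deg == best.strength_deg

    def test_missing_level_is_an_error(self, strengths):
        only_c2 = [s for s in strengths if s.illusion_class == "C2"]
        with pytest.raises(ValueError):
            select_level_exemplars(only_c2)

    def test_pairs_render_perceived_tilt_against_horizontal(self, strengths):
        chosen = select_level_exemplars(strengths)
        perceived, illusion = render_level_pairs(chosen)
        assert len(perceived) == len(illusion) == 8
        for p, i in zip(perceived, illusion):
            assert i.tilt is None
            assert p.tilt is not None
            # all four bars tilted by the same signed perceived angle
            assert len(set(p.tilt.angles_deg)) == 1


class TestCrossRDM:
    def test_normalisation_gives_unit_mean(self, small_model, strengths):
        chosen = select_level_exemplars(strengths)
        perceived, illusion = render_level_pairs(chosen)
        for mode in ("euclidean", "sq_sum"):
            rdm = build_cross_rdm(small_model, "block3", perceived, illusion,
                                  mode=mode)
            assert rdm.r.shape == (8, 8)
            assert (rdm.r >= 0).all()
            assert rdm.R.mean() == pytest.approx(1.0, abs=1e-9)

    def test_identical_sets_zero_the_diagonal(self, small_model, strengths):
        chosen = select_level_exemplars(strengths)
        _, illusion = render_level_pairs(chosen)
        rdm = build_cross_rdm(small_model, "block2", illusion, illusion)
        np.testing.assert_allclose(np.diag(rdm.r), 0.0, atol=1e-6)

    def test_all_zero_distances_normalise_to_ones(self, small_model, strengths):
        img = render_illusion(strengths[0].stimulus)
        same = [img] * 8
        rdm = build_cross_rdm(small_model, "block1", same, same)
        np.testing.assert_array_equal(rdm.R, np.ones((8, 8)))

    def test_wrong_set_sizes_are_rejected(self, small_model, strengths):
        img = render_illusion(strengths[0].stimulus)
        with pytest.raises(ValueError):
            build_cross_rdm(small_model, "block1", [img] * 7, [img] * 8)

    def test_feature_extraction_is_deterministic(self, small_model, strengths):
        img = render_illusion(strengths[5].stimulus)
        a = extract_features(small_model, img, "block2")
        b = extract_features(small_model, img, "block2")
        np.testing.assert_array_equal(a.values, b.values)


class TestDepthProfileAndScore:
    def test_profile_partitions_the_stimuli(self, small_model, strengths):
        subset = list(strengths)[:24]
        profile = depth_profile(small_model, subset)
        for layer, group in profile.groupby("layer_id"):
            assert group["n"].sum() == len(subset)
        valid = {"correct-C1", "correct-C2", "incorrect-C1", "incorrect-C2"}
        assert set(profile["stratum"]) <= valid
        assert (profile["mean_distance"] >= 0).all()

    def test_diagonal_contrast_hand_computed_example(self):
        R = np.full((8, 8), 1.0)
        np.fill_diagonal(R, 0.3)
        # renormalise to unit mean as build_cross_rdm would
        R = R / R.mean()
        rdm = CrossRDM(r=R.copy(), R=R, layer_id="block1", mode="euclidean")
        off = R[~np.eye(8, dtype=bool)].mean()
        diag = np.trace(R) / 8
        assert diagonal_contrast(rdm) == pytest.approx(off - diag)
        assert diagonal_contrast(rdm) > 0

    def test_score_weights_select_the_components(self):
        rng = np.random.default_rng(1)
        maps = {
            "C1": HeatMap(np.abs(rng.normal(size=(5, 17))), "block4", "C1"),
            "C2": HeatMap(np.abs(rng.normal(size=(5, 17))), "block4", "C2"),
        }
        R = np.full((8, 8), 1.1)
        np.fill_diagonal(R, 0.3)
        R = R / R.mean()
        rdm = CrossRDM(r=R.copy(), R=R, layer_id="block1", mode="euclidean")
        only_cam = framework_score(maps, [rdm], weights=(1.0, 0.0))
        only_rdm = framework_score(maps, [rdm], weights=(0.0, 1.0))
        both = framework_score(maps, [rdm])
        assert only_cam.S_DNN == pytest.approx(only_cam.components["gradcam_summary"])
        assert only_rdm.S_DNN == pytest.approx(diagonal_contrast(rdm))
        assert both.S_DNN == pytest.approx(
            0.5 * only_cam.S_DNN + 0.5 * only_rdm.S_DNN
        )

    def test_score_input_validation(self):
        hm = HeatMap(np.ones((2, 2)), "block4", "C1")
        R = np.ones((8, 8))
        rdm = CrossRDM(r=R, R=R, layer_id="block1", mode="euclidean")
        with pytest.raises(ValueError):
            framework_score({"C1": hm}, [rdm])
        with pytest.raises(ValueError):
            framework_score({"C1": hm, "C2": hm}, [])
        with pytest.raises(ValueError):
            framework_score({"C1": hm, "C2": hm}, [rdm], synthesis_name="other")
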