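"""Gating, spectral-angle filtering, fusion and slide-level diagnosis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsipath.datacube import DataCube, wavelength_axis
from hsipath.errors import StageError
from hsipath.joint_dx import (
    JointConfig,
    NearestReferenceModel,
    OVERLAY_COLORS,
    classify_pixels,
    decide_final,
    diagnose_section,
    diagnose_slide,
    filter_non_target,
    fuse,
    render_heatmap,
    render_overlay,
    spectral_angle,
    sst_gate,
)


class TestGate:
    @pytest.mark.parametrize(
        "prob,expected",
        [
            # the three undetermined patch probabilities of the worked example
            (0.826, "undetermined"),
            (0.142, "undetermined"),
            (0.730, "undetermined"),
            (0.95, "cancer"),
            (0.05, "normal"),
            (0.9, "undetermined"),  # band is inclusive; comparisons strict
            (0.1, "undetermined"),
        ],
    )
    def test_examples(self, prob, expected):
        assert sst_gate(prob) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 1))
    def test_trichotomy(self, p):
        statuses = [sst_gate(p) == s for s in ("cancer", "normal", "undetermined")]
        assert sum(statuses) == 1

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            sst_gate(0.5, hi=0.2, lo=0.4)


class TestSpectralAngle:
    def test_identical_zero_orthogonal_halfpi(self):
        a = np.array([1.0, 2.0, 3.0])
        assert spectral_angle(a, a) == pytest.approx(0.0, abs=1e-7)
        assert spectral_angle([1, 0], [0, 1]) == pytest.approx(np.pi / 2)

    def test_hand_value(self):
        # arccos(2/sqrt(6)) for (1,0,1) vs (1,1,1)
        angle = spectral_angle([1.0, 0.0, 1.0], [1.0, 1.0, 1.0])
        assert angle == pytest.approx(np.arccos(2 / np.sqrt(6)), abs=1e-9)
        assert angle == pytest.approx(0.6155, abs=1e-4)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1e-3, 1e3))
    def test_scale_invariance(self, lam):
        a = np.array([0.3, 0.9, 0.5, 0.1])
        assert spectral_angle(a, lam * a) == pytest.approx(0.0, abs=1e-6)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            spectral_angle([0.0, 0.0], [1.0, 1.0])


class TestFilterNonTarget:
    def test_all_pixels_matching_reference_removed(self, rng):
        ref = np.array([1.0, 0.2, 0.8, 0.4])
        patch = np.tile(ref[:, None, None], (1, 6, 6))
        patch = patch * rng.uniform(0.98, 1.02, size=(1, 6, 6))  # scale jitter only
        mask = filter_non_target(patch, {"red_cell": ref}, n_clusters=2)
        assert not mask.any()

    def test_two_populations_one_matching(self, rng):
        ref = np.array([1.0, 0.1, 0.9, 0.2])
        other = np.array([0.2, 1.0, 0.1, 0.9])  # nearly orthogonal: far beyond threshold
        patch = np.empty((4, 4, 6))
        patch[:, :, :3] = ref[:, None, None]
        patch[:, :, 3:] = other[:, None, None]
        patch += rng.normal(0, 0.005, size=patch.shape)
        mask = filter_non_target(patch, {"rbc": ref}, n_clusters=2, seed=0)
        expected = np.zeros((4, 6), dtype=bool)
        expected[:, 3:] = True
        np.testing.assert_array_equal(mask, expected)

    def test_zero_threshold_removes_nothing(self, rng):
        patch = rng.uniform(0.2, 1.0, size=(3, 5, 5))
        ref = rng.uniform(0.2, 1.0, size=3)
        mask = filter_non_target(patch, {"x": ref}, n_clusters=3, angle_threshold=0.0)
        assert mask.all()

    def test_validation(self, rng):
        patch = rng.uniform(0.2, 1.0, size=(3, 4, 4))
        with pytest.raises(ValueError):
            filter_non_target(patch, {}, n_clusters=2)
        with pytest.raises(ValueError):
            filter_non_target(patch, {"x": np.ones(3)}, n_clusters=1)


class _ConstantModel:
    def __init__(self, p):
        self.p = p

    def window_cancer_probs(self, windows):
        return np.full(len(windows), self.p)


class TestClassifyPixels:
    def test_always_cancer_model_gives_fraction_one(self, rng):
        patch = rng.uniform(0.2, 1.0, size=(4, 15, 15))
        mask = np.ones((15, 15), dtype=bool)
        prob_map, fraction = classify_pixels(mask, patch, _ConstantModel(0.99), window=9)
        assert fraction == 1.0
        scored = ~np.isnan(prob_map)
        assert scored.sum() == 7 * 7  # border rule leaves the interior

    def test_empty_mask_flags_fallback(self, rng):
        patch = rng.uniform(0.2, 1.0, size=(4, 12, 12))
        prob_map, fraction = classify_pixels(
            np.zeros((12, 12), dtype=bool), patch, _ConstantModel(1.0)
        )
        assert fraction is None
        assert np.isnan(prob_map).all()

    def test_oracle_model_recovers_true_fraction(self, quadrant_slide):
        spec, tran, truth = quadrant_slide
        model = NearestReferenceModel(
            truth.class_spectra["cancer"], truth.class_spectra["normal"]
        )
        # patch straddling the quadrant boundary: mixed cancer/normal nuclei
        patch = tran.values[:, 30:90, 30:90]
        from hsipath.datacube import LABEL_CODES

        lab = truth.label_map.labels[30:90, 30:90]
        mask = (lab == LABEL_CODES["cancer"]) | (lab == LABEL_CODES["normal"])
        _, fraction = classify_pixels(mask, patch, model, window=9)
        half = 4
        interior = mask.copy()
        interior[:half] = interior[-half:] = False
        interior[:, :half] = interior[:, -half:] = False
        true_frac = (lab[interior] == LABEL_CODES["cancer"]).mean()
        assert fraction == pytest.approx(true_frac, abs=0.1)


class TestFuseAndDecide:
    def test_worked_example(self):
        # patch probability 0.142 fused with pixel fraction 0.612 -> 0.377
        assert fuse(0.142, 0.612) == pytest.approx(0.377)
        assert decide_final(0.377, final_threshold=0.3) == "cancer"
        assert decide_final(0.377, final_threshold=0.5) == "normal"

    def test_fixed_point_and_degenerate_weights(self):
        assert fuse(0.4, 0.4) == pytest.approx(0.4)
        assert fuse(0.142, 0.9, weights=(1.0, 0.0)) == pytest.approx(0.142)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_fuse_monotone(self, a1, a2, b1, b2):
        lo = fuse(min(a1, a2), min(b1, b2))
        hi = fuse(max(a1, a2), max(b1, b2))
        assert lo <= hi + 1e-12

    def test_lowering_threshold_never_lowers_sensitivity(self):
        joints = np.array([0.05, 0.2, 0.35, 0.6, 0.9])
        truth = np.array([0, 1, 1, 1, 1])
        sens = []
        for thr in (0.5, 0.3, 0.1):
            calls = np.array([decide_final(j, thr) == "cancer" for j in joints])
            sens.append((calls & (truth == 1)).sum() / (truth == 1).sum())
        assert sens == sorted(sens)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            fuse(0.5, 0.5, weights=(0.7, 0.5))
        with pytest.raises(ValueError):
            decide_final(0.5, final_threshold=1.5)


class TestDiagnoseSlide:
    def _models(self, truth):
        m = NearestReferenceModel(
            truth.class_spectra["cancer"], truth.class_spectra["normal"]
        )
        return m, m, truth.non_target_references()

    def test_cancer_quadrant_localized(self, quadrant_slide):
        spec, tran, truth = quadrant_slide
        ss, spectral, refs = self._models(truth)
        config = JointConfig(patch_size=30, seed=0)
        report = diagnose_slide(tran, ss, spectral, refs, config)
        expected = truth.patch_truth_labels(30)
        assert len(report.decisions) == 16
        correct = sum(
            d.final_label == e
            for d, e in zip(report.decisions, expected)
            if e is not None
        )
        total = sum(e is not None for e in expected)
        assert correct >= 14
        assert report.prob_map.shape == tran.shape[1:]
        assert (report.prob_map >= 0).all() and (report.prob_map <= 1).all()

    def test_requires_calibrated_cube(self, quadrant_slide):
        spec, tran, truth = quadrant_slide
        ss, spectral, refs = self._models(truth)
        raw = DataCube(tran.values, tran.wavelengths, stage="raw")
        with pytest.raises(StageError):
            diagnose_slide(raw, ss, spectral, refs, JointConfig(patch_size=30))

    def test_all_background_slide_all_normal(self):
        values = np.ones((6, 60, 60))
        cube = DataCube(values, wavelength_axis(6), stage="tran")
        refs = {"rbc": np.full(6, 0.5)}
        model = NearestReferenceModel(np.full(6, 0.4), np.full(6, 0.9))
        report = diagnose_slide(cube, model, model, refs, JointConfig(patch_size=30))
        assert all(d.final_label == "normal" for d in report.decisions)

    def test_section_aggregation(self, quadrant_slide):
        spec, tran, truth = quadrant_slide
        ss, spectral, refs = self._models(truth)
        config = JointConfig(patch_size=30, seed=0)
        reports, summary = diagnose_section(
            [tran, tran], ss, spectral, refs, config
        )
        assert summary["n_cubes"] == 2
        assert summary["n_patches"] == 32
        assert 0 < summary["cancer_patch_fraction"] < 1
        assert summary["max_joint_prob"] <= 1.0


class TestRendering:
    def test_overlay_matches_decision_grid(self, quadrant_slide):
        spec, tran, truth = quadrant_slide
        model = NearestReferenceModel(
            truth.class_spectra["cancer"], truth.class_spectra["normal"]
        )
        config = JointConfig(patch_size=30, seed=0)
        report = diagnose_slide(
            tran, model, model, truth.non_target_references(), config
        )
        background = np.zeros((3, 120, 120))
        overlay = render_overlay(report, background, config, alpha=1.0)
        for dec in report.decisions:
            if abs(dec.joint_prob - config.final_threshold) <= config.suspect_band:
                expect = OVERLAY_COLORS["suspected"]
            else:
                expect = OVERLAY_COLORS[dec.final_label]
            r0, c0 = dec.origin
            np.testing.assert_allclose(overlay[:, r0 + 15, c0 + 15], expect)

    def test_all_normal_report_is_green(self):
        values = np.ones((4, 60, 60))
        cube = DataCube(values, wavelength_axis(4), stage="tran")
        model = NearestReferenceModel(np.full(4, 0.4), np.full(4, 0.9))
        report = diagnose_slide(
            cube, model, model, {"rbc": np.full(4, 0.5)}, JointConfig(patch_size=30)
        )
        overlay = render_overlay(report, np.zeros((3, 60, 60)), JointConfig(patch_size=30), alpha=1.0)
        assert (overlay[1] > overlay[0]).all() and (overlay[1] > overlay[2]).all()

    def test_heatmap_red_blue_encoding(self):
        pm = np.array([[0.0, 1.0]])
        hm = render_heatmap(pm)
        assert hm[0, 0, 1] > hm[0, 0, 0] or hm[2, 0, 0] > hm[0, 0, 0]  # low prob -> blue
        assert hm[0, 0, 1] == 1.0 and hm[2, 0, 1] == 0.0  # high prob -> red
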