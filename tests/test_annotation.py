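"""Transformation consensus and consensus-of-exemplars annotation."""

import numpy as np
import pytest

from facespace.annotation import (AnnotatedImage, ExemplarDB,
                                  SketchOracleDetector, build_exemplar_rois,
                                  coe_annotate36, consensus_annotate9,
                                  train_part_detectors, variant_grid)
from facespace.geometry import Constellation, PoseTransform, pf_length
from facespace.landmarks import C9_MIRROR_MAP
from facespace.synthetic import SketchSpec, mirror_sketch, render_face_sketch


def _annotated(seed=2):
    img, c36 = render_face_sketch(SketchSpec(seed=seed))
    return AnnotatedImage(img, truth_c9=c36.c9(), truth_c36=c36,
                          image_id=f"s{seed}"), c36


class TestConsensusAnnotate9:
    def test_default_grid_has_100_variants(self):
        assert len(variant_grid((128, 128))) == 100

    def test_noiseless_detector_recovers_truth(self):
        ann, c36 = _annotated()
        c9 = consensus_annotate9(ann, SketchOracleDetector(noise_sd=0.0))
        assert np.allclose(c9.points, c36.c9().points, atol=1e-9)

    def test_consensus_beats_single_detection(self):
        """Paired over sketches: consensus RMS < one-shot RMS (noise 3px)."""
        wins = 0
        n = 12
        for seed in range(n):
            ann, c36 = _annotated(seed)
            truth = c36.c9().points
            det = SketchOracleDetector(noise_sd=3.0, seed=seed)
            single = det.detect(ann).c9.points
            rms_single = np.sqrt(np.mean(np.sum((single - truth) ** 2, 1)))
            cons = consensus_annotate9(
                ann, SketchOracleDetector(noise_sd=3.0, seed=seed + 500))
            rms_cons = np.sqrt(np.mean(np.sum((cons.points - truth) ** 2, 1)))
            wins += rms_cons < rms_single
        assert wins >= int(0.9 * n)

    def test_detection_failure_raises(self):
        ann, _ = _annotated()
        with pytest.raises(RuntimeError, match="detection failed"):
            consensus_annotate9(
                ann, SketchOracleDetector(failure_rate=1.0))

    def test_mirror_consistency(self):
        """Annotating the mirrored sketch and un-mirroring agrees."""
        ann, c36 = _annotated()
        img_m, c36_m = mirror_sketch(ann.pixels, c36)
        ann_m = AnnotatedImage(img_m, truth_c9=c36_m.c9(), image_id="m")
        direct = consensus_annotate9(ann, SketchOracleDetector(0.5, seed=3))
        via_mirror = consensus_annotate9(ann_m,
                                         SketchOracleDetector(0.5, seed=3))
        undone = via_mirror.mirrored(img_m.shape[1])
        assert np.allclose(undone.points, direct.points, atol=1.0)


class TestExemplarROIs:
    def test_inconsistent_pair_rejected(self):
        _, c36 = _annotated()
        shifted = Constellation(c36.c9().points + 5.0, "C9")
        with pytest.raises(ValueError, match="inconsistent"):
            ExemplarDB([(shifted, c36)])

    def test_truth_in_db_centres_rois_on_truth(self):
        _, c36 = _annotated()
        db = ExemplarDB.from_c36([c36])
        rois, consensus = build_exemplar_rois(c36.c9(), db, n_sample=50,
                                              n_top=5, seed=0)
        assert np.allclose(consensus.points, c36.points, atol=1e-6)
        for roi, p in zip(rois, c36.points):
            assert np.allclose(roi.center, p, atol=1e-6)

    def test_roi_side_is_two_palpebral_fissures(self):
        _, c36 = _annotated()
        c9 = c36.c9()
        db = ExemplarDB.from_c36([c36])
        rois, _ = build_exemplar_rois(c9, db, n_sample=10, n_top=2, seed=0)
        assert rois[0].side == pytest.approx(2.0 * pf_length(c9))

    def test_similarity_transformed_db_recovers_mapped_truth(self):
        _, c36 = _annotated()
        copies = [
            PoseTransform(rotation=r, scale=s,
                          translation=(t, -t)).apply_constellation(c36)
            for r, s, t in [(0.3, 1.2, 5.0), (-0.2, 0.8, -3.0),
                            (0.1, 1.1, 2.0)]
        ]
        db = ExemplarDB.from_c36(copies)
        rois, consensus = build_exemplar_rois(c36.c9(), db, n_sample=100,
                                              n_top=10, seed=1)
        assert np.allclose(consensus.points, c36.points, atol=1e-3)

    def test_empty_db_rejected(self):
        _, c36 = _annotated()
        with pytest.raises(ValueError):
            build_exemplar_rois(c36.c9(), ExemplarDB([]))


class _PeakedBank:
    """Synthetic part-detector bank peaked exactly at given truth points."""

    def __init__(self, truth):
        self.truth = truth

    def scores(self, image, landmark, points):
        pts = np.atleast_2d(np.asarray(points, float))
        return -np.linalg.norm(pts - self.truth[landmark], axis=1)


class TestCoE:
    def test_detector_count_is_36(self, part_bank):
        assert len(part_bank.svms) == 36

    def test_too_few_training_faces_rejected(self, cohort24):
        with pytest.raises(ValueError):
            train_part_detectors(cohort24[:10])

    def test_decision_peaks_at_true_landmark(self, cohort24, part_bank):
        """Decision value at truth beats a 1-PF offset in >=90% of trials."""
        rng = np.random.default_rng(0)
        trials = wins = 0
        for img, c36 in cohort24[20:]:
            pf = pf_length(c36.c9())
            for lm in range(0, 36, 4):
                ang = rng.uniform(0, 2 * np.pi)
                off = c36.points[lm] + pf * np.array([np.cos(ang),
                                                      np.sin(ang)])
                s = part_bank.scores(img, lm,
                                     np.vstack([c36.points[lm], off]))
                wins += s[0] > s[1]
                trials += 1
        assert wins / trials >= 0.9

    def test_truth_db_with_peaked_detector_recovers_truth(self):
        img, c36 = render_face_sketch(SketchSpec(seed=9))
        db = ExemplarDB.from_c36([c36])
        bank = _PeakedBank(c36.points)
        res = coe_annotate36(img, c36.c9(), db, bank,
                             n_registrations=100, seed=0)
        err = np.linalg.norm(res.c36.points - c36.points, axis=1)
        assert err.max() <= 1.0
        assert not res.fallback_landmarks

    def test_seeded_run_is_deterministic(self, cohort24, exemplar_db,
                                         part_bank):
        img, c36 = cohort24[21]
        a = coe_annotate36(img, c36.c9(), exemplar_db, part_bank,
                           n_registrations=150, seed=7)
        b = coe_annotate36(img, c36.c9(), exemplar_db, part_bank,
                           n_registrations=150, seed=7)
        assert np.array_equal(a.c36.points, b.c36.points)

    def test_accuracy_and_improvement_over_shape_prior_alone(
            self, cohort24, exemplar_db, part_bank):
        """Held-out sketches: error below 0.6 eye-widths and CoE beats the
        ROI-centre (shape prior only) baseline on most faces."""
        better = 0
        held_out = cohort24[20:]
        for img, c36 in held_out:
            eye_width = pf_length(c36.c9())
            res = coe_annotate36(img, c36.c9(), exemplar_db, part_bank,
                                 n_registrations=300, seed=1)
            _, consensus = build_exemplar_rois(c36.c9(), exemplar_db, seed=1)
            err = np.linalg.norm(res.c36.points - c36.points, axis=1)
            base = np.linalg.norm(consensus.points - c36.points, axis=1)
            assert (err / eye_width).mean() < 0.6
            better += err.mean() <= base.mean()
        assert better >= len(held_out) - 1

    def test_outputs_lie_inside_rois(self, cohort24, exemplar_db, part_bank):
        img, c36 = cohort24[22]
        rois, _ = build_exemplar_rois(c36.c9(), exemplar_db, seed=2)
        res = coe_annotate36(img, c36.c9(), exemplar_db, part_bank,
                             n_registrations=150, seed=2, rois=rois)
        for roi, p in zip(rois, res.c36.points):
            if roi.landmark_index not in res.fallback_landmarks:
                assert roi.contains(p, slack=0.5)
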