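"""Procrustes registration, the generalized mean, and C9 measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facespace.geometry import (Constellation, PoseTransform,
                                auxiliary_points, generalized_procrustes_mean,
                                pf_length, procrustes_align)
from facespace.synthetic import make_template_constellation


def _c9(points):
    return Constellation(np.asarray(points, float), "C9")


def _random_c36(rng, scale=30.0):
    return Constellation(rng.normal(0, scale, (36, 2)), "C36")


class TestProcrustesAlign:
    def test_identity_on_self(self):
        t = make_template_constellation()
        fit = procrustes_align(t, t)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)
        assert fit.transform.scale == pytest.approx(1.0)
        assert fit.transform.rotation == pytest.approx(0.0)

    def test_recovers_constructed_similarity(self):
        t = make_template_constellation()
        pose = PoseTransform(rotation=np.pi / 2, scale=2.0,
                             translation=(11.0, -3.0))
        target = pose.apply_constellation(t)
        fit = procrustes_align(t, target)
        assert fit.transform.rotation == pytest.approx(np.pi / 2)
        assert fit.transform.scale == pytest.approx(2.0)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_reflection_excluded_by_default(self):
        tri = np.array([(0.0, 0.0), (4.0, 0.0), (1.0, 3.0)])
        # a 9-point set built from the triangle to satisfy the scheme
        pts = np.vstack([tri, tri + (10.0, 0.0), tri + (0.0, 10.0)])
        src = _c9(pts)
        dst = _c9(pts * np.array([-1.0, 1.0]))
        no_ref = procrustes_align(src, dst, allow_reflection=False)
        with_ref = procrustes_align(src, dst, allow_reflection=True)
        assert no_ref.sse > 1e-3
        assert with_ref.sse == pytest.approx(0.0, abs=1e-12)
        assert with_ref.transform.reflection

    def test_sse_symmetric(self, rng):
        a, b = _random_c36(rng), _random_c36(rng)
        f_ab = procrustes_align(a, b)
        f_ba = procrustes_align(b, a)
        # residuals are measured in the target frame; compare scale-free
        na = np.sum((a.points - a.points.mean(0)) ** 2)
        nb = np.sum((b.points - b.points.mean(0)) ** 2)
        assert f_ab.sse / nb == pytest.approx(f_ba.sse / na, rel=1e-9)

    def test_scheme_mismatch_rejected(self):
        t = make_template_constellation()
        with pytest.raises(ValueError, match="scheme"):
            procrustes_align(t, t.c9())

    def test_coincident_points_rejected(self):
        degenerate = _c9(np.zeros((9, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            procrustes_align(degenerate, degenerate)

    def test_matches_brute_force_grid_search(self, rng):
        """Optimal similarity fit agrees with exhaustive search (<=4 pts)."""
        src = rng.normal(0, 1, (4, 2))
        dst = rng.normal(0, 1, (4, 2))
        best = np.inf
        for theta in np.linspace(-np.pi, np.pi, 2000, endpoint=False):
            c, s = np.cos(theta), np.sin(theta)
            r = np.array([[c, -s], [s, c]])
            x = (src - src.mean(0)) @ r.T
            y = dst - dst.mean(0)
            # optimal scale for this rotation in closed form
            scale = max((x * y).sum() / (x ** 2).sum(), 0.0)
            best = min(best, float(np.sum((scale * x - y) ** 2)))
        got = _aligned_sse_4pt(src, dst)
        assert got == pytest.approx(best, abs=1e-3)


def _aligned_sse_4pt(src, dst):
    """Procrustes SSE of two 4-point sets via a C9 padding trick."""
    # pad both with a congruent far-away triangle pair would distort the fit;
    # instead solve directly with the same SVD code path on raw arrays
    from facespace.annotation import _similarity_fit
    a, t = _similarity_fit(src, dst)
    return float(np.sum((src @ a.T + t - dst) ** 2))


class TestGeneralizedMean:
    def test_identical_copies_return_the_shape(self):
        t = make_template_constellation()
        mean = generalized_procrustes_mean([t, t.copy(), t.copy()])
        # identical inputs: mean is the common shape, normalized
        fit = procrustes_align(t, mean)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_rotated_copies_recover_the_shape(self):
        t = make_template_constellation()
        r1 = PoseTransform(rotation=0.7).apply_constellation(t)
        r2 = PoseTransform(rotation=-1.2, scale=3.0).apply_constellation(t)
        mean = generalized_procrustes_mean([r1, r2])
        for c in (r1, r2):
            assert procrustes_align(c, mean).sse == pytest.approx(0, abs=1e-9)

    def test_invariant_to_order_and_similarity_transforms(self, rng):
        shapes = [Constellation(rng.normal(0, 20, (36, 2)), "C36")
                  for _ in range(5)]
        mean1 = generalized_procrustes_mean(shapes)
        transformed = [
            PoseTransform(rotation=rng.uniform(-3, 3),
                          scale=rng.uniform(0.5, 2.0),
                          translation=rng.normal(0, 50, 2)
                          ).apply_constellation(c)
            for c in shapes[::-1]
        ]
        mean2 = generalized_procrustes_mean(transformed)
        assert procrustes_align(mean1, mean2).sse == pytest.approx(0, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            generalized_procrustes_mean([])

    def test_normalization_convention(self, cohort_mean):
        p = cohort_mean.points
        assert np.allclose(p.mean(axis=0), 0.0, atol=1e-9)
        assert np.linalg.norm(p) == pytest.approx(1.0)


class TestC9Measures:
    SYMMETRIC = np.array([
        (-30.0, 0.0), (-10.0, 0.0), (10.0, 0.0), (30.0, 0.0),
        (-6.0, 25.0), (0.0, 26.0), (6.0, 25.0),
        (-16.0, 40.0), (16.0, 40.0),
    ])

    def test_auxiliary_points_of_symmetric_face_lie_on_axis(self):
        aux = auxiliary_points(_c9(self.SYMMETRIC))
        # nasion and mouth centre on the vertical symmetry axis
        assert aux[2, 0] == pytest.approx(0.0)
        assert aux[3, 0] == pytest.approx(0.0)
        # eye centres are canthus midpoints
        assert aux[0] == pytest.approx([-20.0, 0.0])
        assert aux[1] == pytest.approx([20.0, 0.0])

    def test_auxiliary_points_translate_with_the_face(self):
        c = _c9(self.SYMMETRIC)
        shifted = _c9(self.SYMMETRIC + (7.0, -4.0))
        assert auxiliary_points(shifted) == pytest.approx(
            auxiliary_points(c) + (7.0, -4.0))

    @pytest.mark.parametrize("left,right,expected", [
        (30.0, 30.0, 30.0),
        (20.0, 40.0, 30.0),
    ])
    def test_pf_length_is_mean_of_fissures(self, left, right, expected):
        pts = self.SYMMETRIC.copy()
        pts[0] = pts[1] - (left, 0.0)     # left fissure span
        pts[3] = pts[2] + (right, 0.0)    # right fissure span
        assert pf_length(_c9(pts)) == pytest.approx(expected)

    def test_pf_length_scales_homogeneously(self):
        c = _c9(self.SYMMETRIC)
        doubled = _c9(self.SYMMETRIC * 2.0)
        assert pf_length(doubled) == pytest.approx(2.0 * pf_length(c))

    def test_wrong_scheme_rejected(self):
        t = make_template_constellation()
        with pytest.raises(ValueError):
            pf_length(t)
        with pytest.raises(ValueError):
            auxiliary_points(t)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_alignment_residual_nonnegative_and_transform_invertible(seed):
    rng = np.random.default_rng(seed)
    a = Constellation(rng.normal(0, 10, (9, 2)), "C9")
    b = Constellation(rng.normal(0, 10, (9, 2)), "C9")
    fit = procrustes_align(a, b)
    assert fit.sse >= 0
    inv = fit.transform.inverse()
    back = inv.apply(fit.aligned.points)
    assert np.allclose(back, a.points, atol=1e-8)
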