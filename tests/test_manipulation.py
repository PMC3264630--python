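"""Affine pan/zoom laws, checked against a raw homogeneous-matrix oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slidecache import (ManipulationEvent, Rect, ViewportState, apply_event,
                        compose, identity, intermediate_states, scale_about,
                        scaling, screen_to_slide, slide_to_screen, translate,
                        uncovered_screen_region)
from slidecache.manipulation import AffineTransform, rect_difference, transform_rect

ATOL = 1e-9


# -- independent oracle: raw 3x3 matrices, no library transform code ---------

def mat_translate(dx, dy):
    return np.array([[1.0, 0.0, dx], [0.0, 1.0, dy], [0.0, 0.0, 1.0]])


def mat_scale(s):
    return np.array([[s, 0.0, 0.0], [0.0, s, 0.0], [0.0, 0.0, 1.0]])


def oracle_product(mats):
    """Matrix product for application order: first matrix applied first."""
    out = np.eye(3)
    for m in mats:
        out = m @ out
    return out


def params_to_matrix(p):
    kind, *args = p
    return mat_translate(*args) if kind == "t" else \
        oracle_product([mat_translate(-args[1], -args[2]),
                        mat_scale(args[0]), mat_translate(args[1], args[2])])


def params_to_transform(p):
    kind, *args = p
    return translate(*args) if kind == "t" else scale_about(*args)


coord = st.floats(-500, 500, allow_nan=False)
factor = st.floats(0.5, 2.0, allow_nan=False)
transform_params = st.one_of(
    st.tuples(st.just("t"), coord, coord),
    st.tuples(st.just("s"), factor, coord, coord))


class TestBasicTransforms:
    def test_translate_examples(self):
        assert translate(0, 0).almost_equals(identity())
        assert np.allclose(translate(10, 5).apply((0, 0)), (10, 5))
        assert compose([translate(3, 4), translate(-3, -4)]).almost_equals(identity())

    def test_scale_about_identity_and_origin(self):
        assert scale_about(1, 123, -7).almost_equals(identity())
        assert np.allclose(scale_about(2, 0, 0).apply((1, 1)), (2, 2))

    def test_scale_about_screen_centre(self):
        t = scale_about(2, 512, 384)
        assert np.allclose(t.apply((512, 384)), (512, 384), atol=ATOL)
        assert np.allclose(t.apply((0, 0)), (-512, -384), atol=ATOL)
        # against the hand-multiplied three-factor matrix
        expected = oracle_product([mat_translate(-512, -384), mat_scale(2),
                                   mat_translate(512, 384)])
        assert np.allclose(t.matrix, expected, atol=1e-12)

    def test_non_positive_scale_rejected(self):
        for s in (0.0, -1.0):
            with pytest.raises(ValueError):
                scale_about(s, 0, 0)
            with pytest.raises(ValueError):
                scaling(s)

    def test_rotation_matrices_rejected(self):
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError):
            AffineTransform(rot)


class TestComposition:
    def test_empty_compose_is_identity(self):
        assert compose([]).almost_equals(identity())

    def test_translations_add(self):
        assert compose([translate(10, 0), translate(0, 5)]).almost_equals(translate(10, 5))

    @given(st.lists(transform_params, max_size=6))
    @settings(derandomize=True, max_examples=60)
    def test_compose_matches_matrix_oracle(self, params):
        ours = compose([params_to_transform(p) for p in params])
        expected = oracle_product([params_to_matrix(p) for p in params])
        assert np.allclose(ours.matrix, expected, atol=ATOL)

    @given(st.lists(transform_params, max_size=6), st.data())
    @settings(derandomize=True, max_examples=60)
    def test_prefix_products(self, params, data):
        """Intermediate gesture states are prefix products; the full prefix
        equals the complete composition."""
        ts = [params_to_transform(p) for p in params]
        j = data.draw(st.integers(0, len(ts)))
        prefix = intermediate_states(ts, j)
        expected = oracle_product([params_to_matrix(p) for p in params[:j]])
        assert np.allclose(prefix.matrix, expected, atol=ATOL)
        assert intermediate_states(ts, len(ts)).almost_equals(compose(ts))
        assert intermediate_states(ts, 0).almost_equals(identity())

    def test_prefix_out_of_range(self):
        with pytest.raises(ValueError):
            intermediate_states([translate(1, 1)], 2)
        with pytest.raises(ValueError):
            intermediate_states([], -1)

    @given(factor, coord, coord, st.tuples(coord, coord))
    @settings(derandomize=True, max_examples=60)
    def test_fixed_point_law(self, s, px, py, probe):
        t = scale_about(s, px, py)
        assert np.allclose(t.apply((px, py)), (px, py), atol=ATOL)
        # decomposition law, element-wise
        dec = compose([translate(-px, -py), scaling(s), translate(px, py)])
        assert np.allclose(t.matrix, dec.matrix, atol=1e-12)
        # sanity on an arbitrary probe point via the oracle
        expected = params_to_matrix(("s", s, px, py)) @ np.array([*probe, 1.0])
        assert np.allclose(t.apply(probe), expected[:2], atol=ATOL)


class TestViewportEvents:
    def test_identity_event_is_noop(self):
        v = ViewportState()
        v2 = apply_event(v, ManipulationEvent("pan_and_zoom"))
        assert v2.cumulative.almost_equals(v.cumulative)

    def test_pure_pan_shifts_screen_points(self):
        v = apply_event(ViewportState(), ManipulationEvent("pan", dx=-300, dy=0))
        assert np.allclose(slide_to_screen(v, (500, 100)), (200, 100))

    def test_event_invariants_enforced(self):
        with pytest.raises(ValueError):
            ManipulationEvent("pan", dx=1, scale=2.0)
        with pytest.raises(ValueError):
            ManipulationEvent("zoom", dx=1, scale=2.0)
        with pytest.raises(ValueError):
            ManipulationEvent("spin")

    def test_combined_event_equals_two_step_oracle(self):
        e = ManipulationEvent("pan_and_zoom", dx=40, dy=-25, scale=1.5,
                              focal_x=512, focal_y=384)
        v = apply_event(ViewportState(), e)
        expected = oracle_product([params_to_matrix(("s", 1.5, 512, 384)),
                                   mat_translate(40, -25)])
        assert np.allclose(v.cumulative.matrix, expected, atol=ATOL)

    @given(st.lists(st.tuples(coord, coord, factor), max_size=5))
    @settings(derandomize=True, max_examples=40)
    def test_event_folding_is_associative(self, events):
        """Folding events one by one equals composing their transforms."""
        evs = [ManipulationEvent("pan_and_zoom", dx=dx, dy=dy, scale=s,
                                 focal_x=100, focal_y=50)
               for dx, dy, s in events]
        v = ViewportState()
        for e in evs:
            v = apply_event(v, e)
        composed = compose([e.transform() for e in evs])
        assert np.allclose(v.cumulative.matrix, composed.matrix, atol=ATOL)

    @given(st.tuples(coord, coord), st.lists(transform_params, min_size=1, max_size=5))
    @settings(derandomize=True, max_examples=40)
    def test_screen_slide_round_trip(self, point, params):
        v = ViewportState(compose([params_to_transform(p) for p in params]))
        there = slide_to_screen(v, point)
        back = screen_to_slide(v, there)
        assert np.allclose(back, point, atol=ATOL)


class TestUncoveredRegion:
    slide_extent = (2048, 1536)

    def test_identity_event_exposes_nothing(self):
        v = ViewportState()
        assert uncovered_screen_region(v, v, self.slide_extent) == []

    def test_left_pan_exposes_right_strip(self):
        """Panning content left by 300 px uncovers a 300 px strip on the
        right edge of a 1024x768 screen."""
        before = ViewportState()
        after = apply_event(before, ManipulationEvent("pan", dx=-300, dy=0))
        (r,) = uncovered_screen_region(before, after, self.slide_extent)
        assert (r.x0, r.y0, r.x1, r.y1) == (724.0, 0.0, 1024.0, 768.0)

    def test_zoom_in_about_centre_exposes_nothing(self):
        before = ViewportState()
        after = apply_event(before, ManipulationEvent(
            "zoom", scale=2.0, focal_x=512, focal_y=384))
        assert uncovered_screen_region(before, after, self.slide_extent) == []

    def test_mismatched_screens_rejected(self):
        with pytest.raises(ValueError):
            uncovered_screen_region(ViewportState(), ViewportState(screen_width=800),
                                    self.slide_extent)

    @given(st.floats(-800, 800), st.floats(-600, 600),
           st.floats(0.6, 1.8), coord, coord)
    @settings(derandomize=True, max_examples=40)
    def test_matches_point_sampling_oracle(self, dx, dy, s, fx, fy):
        """The rectangle set agrees with a dense point-membership oracle:
        a screen point needs refilling iff slide content should be there
        now but the old on-screen content no longer covers it."""
        before = ViewportState()
        after = apply_event(before, ManipulationEvent(
            "pan_and_zoom", dx=dx, dy=dy, scale=s, focal_x=fx, focal_y=fy))
        rects = uncovered_screen_region(before, after, self.slide_extent)

        covered_before = Rect(0, 0, 1024, 768).intersect(
            transform_rect(before.cumulative, Rect(0, 0, *self.slide_extent)))
        delta = before.cumulative.inverse().then(after.cumulative)
        moved = transform_rect(delta, covered_before)
        slide_now = transform_rect(after.cumulative, Rect(0, 0, *self.slide_extent))

        xs = np.linspace(8, 1016, 25)
        ys = np.linspace(8, 760, 19)
        for x in xs:
            for y in ys:
                in_slide = slide_now.x0 < x < slide_now.x1 and slide_now.y0 < y < slide_now.y1
                in_moved = moved.x0 < x < moved.x1 and moved.y0 < y < moved.y1
                expected = in_slide and not in_moved
                got = any(r.x0 < x < r.x1 and r.y0 < y < r.y1 for r in rects)
                # skip points within a pixel of any boundary (half-open edges)
                near_edge = any(
                    min(abs(x - e) for e in (rr.x0, rr.x1)) < 1.5 or
                    min(abs(y - e) for e in (rr.y0, rr.y1)) < 1.5
                    for rr in (moved, slide_now))
                if not near_edge:
                    assert got == expected


def test_rect_difference_partitions_area():
    outer = Rect(0, 0, 100, 80)
    inner = Rect(20, 10, 60, 50)
    parts = rect_difference(outer, inner)
    area = sum(r.width * r.height for r in parts)
    assert area == pytest.approx(100 * 80 - 40 * 40)
    # parts are pairwise disjoint
    for i, a in enumerate(parts):
        for b in parts[i + 1:]:
            assert a.intersect(b).is_empty()
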