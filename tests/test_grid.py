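"""Sampling-lattice construction: baseline, vertical lines, sites, filtering."""

import numpy as np
import pydantic
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from gmrkit.grid import (
    build_baseline,
    build_grid,
    build_vertical_lines,
    filter_attached_gingiva,
    place_sites,
)
from gmrkit.types import GeometryError, LandmarkAnnotation

from conftest import _cover_all_polygon, _tooth


class TestBaseline:
    def test_baseline_arithmetic(self, contiguous_annotation):
        # cervical y 210 at the central line of tooth 12, crown length 64
        assert build_baseline(contiguous_annotation) == pytest.approx(146.0)

    def test_zero_crown_length_rejected_at_construction(self, contiguous_annotation):
        with pytest.raises(pydantic.ValidationError):
            LandmarkAnnotation(
                image_id="x",
                teeth=contiguous_annotation.teeth,
                crown_length_12=0.0,
                attached_gingiva=contiguous_annotation.attached_gingiva,
            )

    def test_baseline_above_image_rejected(self, contiguous_annotation):
        bad = contiguous_annotation.model_copy(update={"crown_length_12": 500.0})
        with pytest.raises(GeometryError, match="baseline"):
            build_baseline(bad)


class TestVerticalLines:
    def test_interproximal_merging_yields_13_lines(self, contiguous_annotation):
        baseline = build_baseline(contiguous_annotation)
        lines = build_vertical_lines(contiguous_annotation, baseline, merge_tol=3.0)
        assert len(lines) == 13  # 18 candidates minus 5 interproximal merges
        # merged lines carry both teeth as sources
        merged = [ln for ln in lines if len(ln.source) == 2]
        assert len(merged) == 5

    def test_no_merging_with_distinct_positions(self, gapped_annotation):
        baseline = build_baseline(gapped_annotation)
        lines = build_vertical_lines(gapped_annotation, baseline, merge_tol=0.0)
        assert len(lines) == 18

    def test_single_tooth_gives_three_lines(self, single_tooth_annotation):
        baseline = build_baseline(single_tooth_annotation)
        lines = build_vertical_lines(single_tooth_annotation, baseline, merge_tol=3.0)
        assert len(lines) == 3

    def test_lines_sorted_by_x(self, contiguous_annotation):
        baseline = build_baseline(contiguous_annotation)
        lines = build_vertical_lines(contiguous_annotation, baseline)
        xs = [ln.x for ln in lines]
        assert xs == sorted(xs)
        assert [ln.line_index for ln in lines] == list(range(len(lines)))

    def test_crown_exceeding_gingival_height_rejected(self, contiguous_annotation):
        # raise tooth 13's cervical line above the baseline
        teeth = [
            _tooth("13", 40.0, 100.0, y=120.0)
            if t.tooth_id == "13"
            else t
            for t in contiguous_annotation.teeth
        ]
        bad = contiguous_annotation.model_copy(update={"teeth": teeth})
        baseline = build_baseline(bad)
        with pytest.raises(GeometryError, match="apical"):
            build_vertical_lines(bad, baseline)

    @given(
        xs=st.lists(
            st.floats(min_value=0, max_value=500, allow_nan=False),
            min_size=3,
            max_size=12,
        ),
        tol=st.floats(min_value=0, max_value=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_merging_equals_transitive_closure_oracle(self, xs, tol):
        """Merged line positions match a brute-force graph-component oracle."""
        # pad to a multiple of three so the xs fill whole teeth
        padded = list(xs) + [xs[-1]] * ((3 - len(xs) % 3) % 3)
        n = len(padded)

        # oracle: connected components of the |xi - xj| <= tol graph, by BFS
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                if abs(padded[i] - padded[j]) <= tol:
                    adj[i].add(j)
                    adj[j].add(i)
        seen, expected_xs = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            expected_xs.append(float(np.mean([padded[j] for j in comp])))
        expected_xs.sort()

        tooth_ids = ["12", "11", "21", "22"]
        teeth = [
            _tooth(tooth_ids[t], -1.0, 501.0)
            for t in range(n // 3)
        ]
        teeth = [
            t.model_copy(
                update={
                    "mesial_x": padded[3 * i],
                    "central_x": padded[3 * i + 1],
                    "distal_x": padded[3 * i + 2],
                }
            )
            for i, t in enumerate(teeth)
        ]
        ann = LandmarkAnnotation(
            image_id="x",
            teeth=teeth,
            crown_length_12=64.0,
            attached_gingiva=_cover_all_polygon(),
        )
        lines = build_vertical_lines(ann, build_baseline(ann), merge_tol=tol)
        assert [ln.x for ln in lines] == pytest.approx(expected_xs)


class TestPlaceSites:
    def test_nine_points_eight_equal_parts(self, contiguous_annotation):
        baseline = build_baseline(contiguous_annotation)
        lines = build_vertical_lines(contiguous_annotation, baseline)
        sites = place_sites(lines)
        assert len(sites) == 9 * len(lines) == 117
        one = sites[sites["line_index"] == 0]
        assert list(one["y"]) == [146, 154, 162, 170, 178, 186, 194, 202, 210]

    def test_unit_spacing_when_span_is_eight(self):
        from gmrkit.grid import VerticalLine

        line = VerticalLine(0, 5.0, 100.0, 108.0, frozenset({("12", "central")}))
        sites = place_sites([line])
        assert np.allclose(np.diff(sites["y"]), 1.0)


class TestAttachedGingivaFilter:
    def test_covering_polygon_retains_all(self, contiguous_annotation):
        grid = build_grid(contiguous_annotation)
        assert grid.retained_count == grid.candidate_count == 117

    def test_covering_none_is_an_error(self, contiguous_annotation):
        bad = contiguous_annotation.model_copy(
            update={"attached_gingiva": [(0.0, 0.0), (5.0, 0.0), (5.0, 5.0)]}
        )
        with pytest.raises(GeometryError, match="undefined"):
            build_grid(bad)

    def test_polygon_excluding_baseline_row(self, contiguous_annotation):
        # bottom of the polygon moved between k=0 (y=146) and k=1 (y=154)
        clipped = contiguous_annotation.model_copy(
            update={
                "attached_gingiva": [
                    (20.0, 150.0),
                    (420.0, 150.0),
                    (420.0, 216.0),
                    (20.0, 216.0),
                ]
            }
        )
        grid = build_grid(clipped)
        assert grid.retained_count == grid.candidate_count - len(grid.lines)
        assert not (grid.retained_sites["point_index"] == 0).any()

    def test_boundary_points_count_as_inside(self, contiguous_annotation):
        # polygon edge exactly on the k=0 row
        exact = contiguous_annotation.model_copy(
            update={
                "attached_gingiva": [
                    (20.0, 146.0),
                    (420.0, 146.0),
                    (420.0, 216.0),
                    (20.0, 216.0),
                ]
            }
        )
        grid = build_grid(exact)
        assert grid.retained_count == grid.candidate_count

    def test_retained_sites_pass_ray_casting_oracle(self, contiguous_annotation):
        """Independent even-odd ray-casting check for strictly interior points."""
        poly = contiguous_annotation.attached_gingiva

        def ray_cast(x, y):
            inside = False
            n = len(poly)
            for i in range(n):
                x1, y1 = poly[i]
                x2, y2 = poly[(i + 1) % n]
                if (y1 > y) != (y2 > y):
                    xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if x < xi:
                        inside = not inside
            return inside

        grid = build_grid(contiguous_annotation)
        for _, s in grid.retained_sites.iterrows():
            assert ray_cast(s["x"], s["y"])


class TestGridProperties:
    @given(
        dx=st.floats(min_value=-50, max_value=5000, allow_nan=False),
        dy=st.floats(min_value=-50, max_value=5000, allow_nan=False),
    )
    @settings(
        max_examples=40,
        deadline=None,
        # the annotation fixture is read-only; reuse across examples is safe
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_translation_invariance(self, dx, dy, contiguous_annotation):
        base = build_grid(contiguous_annotation)
        shifted_ann = contiguous_annotation.translated(dx, dy)
        if build_baseline(contiguous_annotation) + dy < 0:
            with pytest.raises(GeometryError):
                build_grid(shifted_ann)
            return
        shifted = build_grid(shifted_ann)
        assert shifted.retained_count == base.retained_count
        assert shifted.candidate_count == base.candidate_count
        np.testing.assert_allclose(
            shifted.retained_sites["x"], base.retained_sites["x"] + dx, atol=1e-6
        )
        np.testing.assert_allclose(
            shifted.retained_sites["y"], base.retained_sites["y"] + dy, atol=1e-6
        )

    def test_consecutive_point_indices_increase_in_y(self, contiguous_annotation):
        grid = build_grid(contiguous_annotation)
        for _, line_sites in grid.retained_sites.groupby("line_index"):
            ordered = line_sites.sort_values("point_index")
            assert (np.diff(ordered["y"]) > 0).all()
            assert ordered["x"].nunique() == 1

    def test_exclude_canines_drops_pure_canine_lines(self, gapped_annotation):
        full = build_grid(gapped_annotation, merge_tol=0.0)
        partial = build_grid(gapped_annotation, merge_tol=0.0, exclude_canines=True)
        assert len(full.lines) == 18
        assert len(partial.lines) == 12  # canines 13 and 23 contribute 3 each
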