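"""Shared fixtures: hand-constructed annotations with known lattice arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gmrkit.types import ANTERIOR_MAXILLARY_TEETH, LandmarkAnnotation, ToothLandmark
from gmrkit.grid import SiteGrid, VerticalLine
from gmrkit.types import SITE_COLUMNS

CERVICAL_Y = 210.0
CROWN_LENGTH = 64.0  # baseline at 210 - 64 = 146


def _tooth(tooth_id: str, x0: float, x1: float, y: float = CERVICAL_Y) -> ToothLandmark:
    """Tooth with a flat cervical line from (x0, y) to (x1, y)."""
    if tooth_id in ("13", "12", "11"):
        mesial, distal = x1, x0
    else:
        mesial, distal = x0, x1
    return ToothLandmark(
        tooth_id=tooth_id,
        cervical_polyline=[(x0, y), (x1, y)],
        mesial_x=mesial,
        central_x=0.5 * (x0 + x1),
        distal_x=distal,
    )


def _cover_all_polygon() -> list[tuple[float, float]]:
    return [(20.0, 140.0), (420.0, 140.0), (420.0, 216.0), (20.0, 216.0)]


@pytest.fixture
def contiguous_annotation() -> LandmarkAnnotation:
    """Six teeth of width 60 sharing edges at x = 40, 100, ..., 400.

    Interproximal mesial/distal positions of adjacent teeth coincide exactly,
    so merging collapses 18 candidate lines to 13.
    """
    teeth = [
        _tooth(tid, 40.0 + 60.0 * i, 100.0 + 60.0 * i)
        for i, tid in enumerate(ANTERIOR_MAXILLARY_TEETH)
    ]
    return LandmarkAnnotation(
        image_id="contiguous",
        teeth=teeth,
        crown_length_12=CROWN_LENGTH,
        attached_gingiva=_cover_all_polygon(),
    )


@pytest.fixture
def gapped_annotation() -> LandmarkAnnotation:
    """Six teeth with 10 px gaps, so all 18 candidate x positions are distinct."""
    teeth = [
        _tooth(tid, 45.0 + 60.0 * i, 95.0 + 60.0 * i)
        for i, tid in enumerate(ANTERIOR_MAXILLARY_TEETH)
    ]
    return LandmarkAnnotation(
        image_id="gapped",
        teeth=teeth,
        crown_length_12=CROWN_LENGTH,
        attached_gingiva=_cover_all_polygon(),
    )


@pytest.fixture
def single_tooth_annotation() -> LandmarkAnnotation:
    return LandmarkAnnotation(
        image_id="single",
        teeth=[_tooth("12", 100.0, 160.0)],
        crown_length_12=CROWN_LENGTH,
        attached_gingiva=_cover_all_polygon(),
    )


def make_toy_grid(n_lines: int = 4, points_per_line: int = 3) -> SiteGrid:
    """Small lattice built directly (no geometry) for classifier tests."""
    lines = [
        VerticalLine(line_index=i, x=10.0 * i, y_top=0.0, y_bottom=8.0, source=frozenset({("12", "central")}))
        for i in range(n_lines)
    ]
    rows = []
    for i in range(n_lines):
        for k in range(points_per_line):
            rows.append(
                {
                    "site_id": f"L{i:02d}P{k}",
                    "line_index": i,
                    "point_index": k,
                    "x": 10.0 * i,
                    "y": float(k),
                }
            )
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return SiteGrid(
        baseline_y=0.0,
        lines=lines,
        retained_sites=sites,
        candidate_count=9 * n_lines,
        retained_count=len(sites),
    )


def calls_from_pattern(grid: SiteGrid, pattern) -> "pd.DataFrame":
    """SiteCallTable for a toy grid from a flat boolean pattern."""
    from gmrkit.types import SiteCallTable

    calls = grid.retained_sites.copy()
    calls["pigmented"] = np.asarray(pattern, dtype=bool)
    return SiteCallTable(image_id="toy", calls=calls)
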