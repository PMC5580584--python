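"""Construction of the GMR sampling lattice from landmark annotations.

The lattice is built in four steps:

1. a horizontal *baseline* is drawn on the maxillary gingiva, one crown
   length of the right lateral incisor (FDI 12) apical to that tooth's
   cervical line;
2. between the right and left canines, a vertical line is dropped from the
   baseline to the cervical line of each tooth, at the mesial, central and
   distal position of every present tooth (coincident interproximal lines
   are merged);
3. nine points are plotted on each vertical line, separating it into eight
   equal parts (both endpoints included);
4. only the candidate points lying in the attached gingiva are retained as
   measurement sites.

All coordinates follow the package convention: origin top-left, y grows
downward, so "apical" means smaller y and every vertical line satisfies
``y_top < y_bottom`` (baseline above cervical line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .types import (
    GeometryError,
    LandmarkAnnotation,
    SITE_COLUMNS,
)

DEFAULT_MERGE_TOL = 3.0  # px; interproximal lines of adjacent teeth coincide
POINTS_PER_LINE = 9  # nine points separate eight equal parts, endpoints included

Position = str  # "mesial" | "central" | "distal"


@dataclass(frozen=True)
class VerticalLine:
    """One vertical measurement line, from the baseline down to the cervical line."""

    line_index: int
    x: float
    y_top: float  # baseline end (apical)
    y_bottom: float  # cervical end (coronal)
    source: frozenset  # of (tooth_id, position) pairs

    def __post_init__(self) -> None:
        if not self.y_top < self.y_bottom:
            raise GeometryError("vertical line requires y_top < y_bottom")
        if not self.source:
            raise GeometryError("vertical line must trace to at least one tooth position")


@dataclass
class SiteGrid:
    """The constructed lattice: candidate points and the retained subset."""

    baseline_y: float
    lines: list[VerticalLine]
    retained_sites: pd.DataFrame  # columns SITE_COLUMNS
    candidate_count: int
    retained_count: int

    def __post_init__(self) -> None:
        assert self.retained_count == len(self.retained_sites)
        assert self.candidate_count == POINTS_PER_LINE * len(self.lines)
        assert self.retained_count <= self.candidate_count


def build_baseline(annotation: LandmarkAnnotation) -> float:
    """Baseline y: cervical y of tooth 12 at its central line, minus one crown length."""
    t12 = annotation.tooth("12")
    cervical_y = t12.cervical_y_at(t12.central_x)
    baseline_y = cervical_y - annotation.crown_length_12
    if baseline_y < 0:
        raise GeometryError(
            f"baseline y={baseline_y} lies above the image (crown length too large)"
        )
    return float(baseline_y)


def build_vertical_lines(
    annotation: LandmarkAnnotation,
    baseline_y: float,
    merge_tol: float = DEFAULT_MERGE_TOL,
) -> list[VerticalLine]:
    """One candidate line per (tooth, mesial/central/distal); near-coincident
    candidates (|dx| <= merge_tol, transitively) merge into a single line with
    x at the member mean and the union of sources."""
    candidates: list[tuple[float, float, tuple]] = []  # (x, y_bottom, (tooth, pos))
    for tooth in annotation.teeth:
        for pos in ("mesial", "central", "distal"):
            x = getattr(tooth, f"{pos}_x")
            y_bottom = tooth.cervical_y_at(x)
            if y_bottom <= baseline_y:
                raise GeometryError(
                    f"cervical line of tooth {tooth.tooth_id} at x={x} is apical to "
                    "the baseline (crown length exceeds gingival height)"
                )
            candidates.append((x, y_bottom, (tooth.tooth_id, pos)))

    # transitive closure of the |dx| <= merge_tol relation via union-find
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(candidates[i][0] - candidates[j][0]) <= merge_tol:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    merged = []
    for members in clusters.values():
        xs = [candidates[i][0] for i in members]
        ybs = [candidates[i][1] for i in members]
        sources = frozenset(candidates[i][2] for i in members)
        merged.append((float(np.mean(xs)), float(np.mean(ybs)), sources))
    merged.sort(key=lambda m: m[0])

    return [
        VerticalLine(line_index=i, x=x, y_top=baseline_y, y_bottom=yb, source=src)
        for i, (x, yb, src) in enumerate(merged)
    ]


def place_sites(lines: list[VerticalLine]) -> pd.DataFrame:
    """Nine candidate points per line at y = y_top + k*(y_bottom - y_top)/8, k = 0..8."""
    rows = []
    for line in lines:
        for k in range(POINTS_PER_LINE):
            y = line.y_top + k * (line.y_bottom - line.y_top) / 8.0
            rows.append(
                {
                    "site_id": f"L{line.line_index:02d}P{k}",
                    "line_index": line.line_index,
                    "point_index": k,
                    "x": line.x,
                    "y": y,
                }
            )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def filter_attached_gingiva(
    candidates: pd.DataFrame,
    annotation: LandmarkAnnotation,
    lines: list[VerticalLine],
    baseline_y: float,
) -> SiteGrid:
    """Retain the candidate points inside or on the attached-gingiva polygon."""
    poly = annotation.gingiva_polygon()
    # shapely `covers` counts boundary points as inside (documented tie-break)
    keep = [
        poly.covers(Point(x, y))
        for x, y in zip(candidates["x"].to_numpy(), candidates["y"].to_numpy())
    ]
    retained = candidates.loc[keep].reset_index(drop=True)
    if retained.empty:
        raise GeometryError(
            "no candidate point lies in the attached gingiva; GMR is undefined"
        )
    return SiteGrid(
        baseline_y=baseline_y,
        lines=lines,
        retained_sites=retained,
        candidate_count=len(candidates),
        retained_count=len(retained),
    )


def build_grid(
    annotation: LandmarkAnnotation,
    merge_tol: float = DEFAULT_MERGE_TOL,
    exclude_canines: bool = False,
) -> SiteGrid:
    """Run the four lattice-construction steps on one annotation.

    ``exclude_canines`` drops lines traced exclusively to the canines
    (FDI 13/23), restricting sites to the gingiva of the incisors while the
    canines still bound the region.
    """
    baseline_y = build_baseline(annotation)
    lines = build_vertical_lines(annotation, baseline_y, merge_tol=merge_tol)
    if exclude_canines:
        lines = [
            ln
            for ln in lines
            if not all(tooth in ("13", "23") for tooth, _ in ln.source)
        ]
        lines = [
            VerticalLine(i, ln.x, ln.y_top, ln.y_bottom, ln.source)
            for i, ln in enumerate(lines)
        ]
        if not lines:
            raise GeometryError("no vertical lines remain after excluding canines")
    candidates = place_sites(lines)
    return filter_attached_gingiva(candidates, annotation, lines, baseline_y)


def grid_to_dict(grid: SiteGrid) -> dict:
    """JSON-serializable form of a SiteGrid."""
    return {
        "baseline_y": grid.baseline_y,
        "candidate_count": grid.candidate_count,
        "retained_count": grid.retained_count,
        "lines": [
            {
                "line_index": ln.line_index,
                "x": ln.x,
                "y_top": ln.y_top,
                "y_bottom": ln.y_bottom,
                "source": sorted([list(s) for s in ln.source]),
            }
            for ln in grid.lines
        ],
        "retained_sites": grid.retained_sites.to_dict(orient="records"),
    }


def grid_from_dict(d: dict) -> SiteGrid:
    lines = [
        VerticalLine(
            line_index=ln["line_index"],
            x=ln["x"],
            y_top=ln["y_top"],
            y_bottom=ln["y_bottom"],
            source=frozenset(tuple(s) for s in ln["source"]),
        )
        for ln in d["lines"]
    ]
    sites = pd.DataFrame(d["retained_sites"], columns=SITE_COLUMNS)
    return SiteGrid(
        baseline_y=d["baseline_y"],
        lines=lines,
        retained_sites=sites,
        candidate_count=d["candidate_count"],
        retained_count=d["retained_count"],
    )
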