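"""Pigmentation calling, GMR computation and Hedin 0-4 classification.

The GMR (gingival melanosis record) is the percentage of retained lattice
sites showing melanin pigmentation.  Site calls come either from image
color — melanin darkens tissue, so a site is called pigmented when the
CIELAB lightness L* of its pixel neighborhood falls at or below a threshold
— or from a manual call table standing in for a human estimator.

Hedin's classification grades the *pattern* of pigmentation on an ordinal
0-4 scale, from none through solitary pigmented units to one continuous
pigmented ribbon.  The original rubric is verbal; here it is operationalized
on the GMR lattice (see :func:`classify_hedin`).  This operationalization is
this package's own, documented mapping of the verbal descriptors onto the
lattice — not a published rubric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import ndimage
from skimage.color import rgb2lab
from skimage.filters import threshold_otsu

from .grid import SiteGrid
from .types import CALL_COLUMNS, GmrResult, OralPhotograph, SiteCallTable, ValidationError


class PigmentCallParams(BaseModel):
    """Parameters of the color-based pigmentation call.

    window_radius
        Half-width in pixels of the square neighborhood aggregated around
        each site (default 2, i.e. a 5x5 window).
    lightness_threshold
        CIELAB L* cutoff; a site is pigmented iff its aggregated L* is at or
        below this value.  Default 50, midway between typical healthy-gingiva
        (L* ~ 65-75) and melanotic (L* ~ 25-35) tissue.
    aggregation
        Statistic pooling the window pixels; median (default) is robust to
        anti-aliased edges crossing the window.
    auto_threshold
        If true, ignore ``lightness_threshold`` and derive the cutoff by
        Otsu's method from the per-site aggregated L* values (for images
        with unknown palettes; requires both tissue classes present).
    """

    window_radius: int = Field(default=2, ge=0)
    lightness_threshold: float = Field(default=50.0, gt=0, lt=100)
    aggregation: str = Field(default="median", pattern="^(median|mean)$")
    auto_threshold: bool = False


def _site_lightness(
    photo: OralPhotograph, xs: np.ndarray, ys: np.ndarray, params: PigmentCallParams
) -> np.ndarray:
    """Aggregated CIELAB L* of the window around each (x, y) site."""
    h, w = photo.pixels.shape[:2]
    r = params.window_radius
    agg = np.median if params.aggregation == "median" else np.mean
    rgb = np.empty((len(xs), 3))
    for i, (x, y) in enumerate(zip(xs, ys)):
        cx = int(round(x))
        cy = int(round(y))
        # clamp the window at image edges
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        if x0 >= x1 or y0 >= y1:
            raise ValidationError(f"site ({x}, {y}) lies outside the image")
        window = photo.pixels[y0:y1, x0:x1].reshape(-1, 3).astype(float)
        rgb[i] = agg(window, axis=0)
    lab = rgb2lab(rgb.reshape(-1, 1, 3) / 255.0).reshape(-1, 3)
    return lab[:, 0]


def call_site_pigmentation(
    photo: OralPhotograph, grid: SiteGrid, params: PigmentCallParams | None = None
) -> SiteCallTable:
    """Call pigmentation at every retained site of ``grid`` from image color."""
    params = params or PigmentCallParams()
    sites = grid.retained_sites
    if sites.empty:
        raise ValidationError("empty grid: no retained sites to call")
    lightness = _site_lightness(
        photo, sites["x"].to_numpy(), sites["y"].to_numpy(), params
    )
    if params.auto_threshold:
        threshold = float(threshold_otsu(lightness))
    else:
        threshold = params.lightness_threshold
    calls = sites.copy()
    calls["pigmented"] = lightness <= threshold
    return SiteCallTable(image_id=photo.image_id, calls=calls[CALL_COLUMNS])


def compute_gmr(calls: SiteCallTable) -> float:
    """GMR percentage: 100 x pigmented sites / all retained sites (full precision)."""
    if calls.n_sites < 1:
        raise ValidationError("GMR undefined without retained sites")
    return 100.0 * calls.n_pigmented / calls.n_sites


def classify_hedin(calls: SiteCallTable, grid: SiteGrid) -> int:
    """Hedin 0-4 class from the spatial pattern of pigmented sites.

    Pigmented sites are grouped into connected components under
    8-neighborhood adjacency on the (line_index, point_index) lattice.  A
    component is a *ribbon* when it spans at least 3 distinct lines.  Scores:

    - 0: no pigmented site;
    - 1: 1-2 components, none a ribbon (solitary units);
    - 2: more than 2 components, none a ribbon (multiple units);
    - 3: at least one ribbon, but none spanning every line;
    - 4: one component spans every line carrying retained sites
      (a continuous ribbon across the whole region).
    """
    df = calls.calls
    grid_lines = sorted(df["line_index"].unique())
    if set(grid_lines) - {ln.line_index for ln in grid.lines}:
        raise ValidationError("call table references lines absent from the grid")
    if df["pigmented"].sum() == 0:
        return 0
    n_rows = max(ln.line_index for ln in grid.lines) + 1
    lattice = np.zeros((n_rows, 9), dtype=bool)
    pig = df[df["pigmented"]]
    lattice[pig["line_index"].to_numpy(), pig["point_index"].to_numpy()] = True

    labels, n_comp = ndimage.label(lattice, structure=np.ones((3, 3), dtype=int))
    # lines that actually carry retained sites (others cannot be spanned)
    occupied_lines = set(df["line_index"].unique())
    comp_rows = [
        set(np.unique(np.nonzero(labels == comp)[0]).tolist())
        for comp in range(1, n_comp + 1)
    ]
    if any(occupied_lines <= rows for rows in comp_rows):
        return 4
    if any(len(rows) >= 3 for rows in comp_rows):
        return 3
    return 1 if n_comp <= 2 else 2


def score_photo(
    photo: OralPhotograph,
    grid: SiteGrid,
    params: PigmentCallParams | None = None,
    manual_calls: SiteCallTable | None = None,
) -> GmrResult:
    """Full scoring of one photograph: site calls, GMR percentage, Hedin class.

    A ``manual_calls`` table (e.g. a human estimator's CSV) bypasses color
    calling entirely.
    """
    calls = manual_calls if manual_calls is not None else call_site_pigmentation(
        photo, grid, params
    )
    return GmrResult(
        image_id=calls.image_id,
        pigmented_count=calls.n_pigmented,
        retained_count=calls.n_sites,
        gmr=compute_gmr(calls),
        hedin=classify_hedin(calls, grid),
    )


# Documented monotone map from a GMR percentage to a coarse Hedin-like grade,
# used where only a summary GMR (no site pattern) is available, e.g. for
# simulated subjects.  Cutpoints are package constants, not a published scale.
GMR_TO_HEDIN_CUTS = (0.0, 10.0, 25.0, 60.0)


def hedin_grade_from_gmr(gmr: float) -> int:
    if gmr < 0 or gmr > 100:
        raise ValidationError("gmr must lie in [0, 100]")
    if gmr == 0:
        return 0
    for grade, cut in enumerate(GMR_TO_HEDIN_CUTS[1:], start=1):
        if gmr <= cut:
            return grade
    return 4
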