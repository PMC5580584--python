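"""Core domain types for the GMR measurement pipeline.

Coordinate convention (used everywhere in the package): 0-based pixel
coordinates, origin at the top-left of the image, x increasing rightward,
y increasing downward.  For maxillary gingiva this means the apical
direction is *decreasing* y: the horizontal baseline sits above (smaller y
than) the cervical lines of the teeth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from shapely.geometry import Polygon

SCHEMA_VERSION = 1

#: FDI numbers of the six anterior maxillary teeth, right canine to left canine.
ANTERIOR_MAXILLARY_TEETH = ("13", "12", "11", "21", "22", "23")

#: Ten-year age bins used throughout the cohort analysis (ASCII labels).
AGE_GROUPS = ("19-29", "30-39", "40-49", "50-59", "60+")

SMOKING_STATUSES = ("former", "current")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


class GeometryError(ValueError):
    """Raised when landmark geometry makes the sampling lattice unconstructible."""


@dataclass
class OralPhotograph:
    """A frontal oral photograph as an 8-bit RGB raster."""

    image_id: str
    pixels: np.ndarray  # H x W x 3, uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError("photograph must be an HxWx3 RGB array")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValidationError("photograph must be at least 64x64 pixels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


class ToothLandmark(BaseModel):
    """Landmarks of one anterior tooth: cervical line trace and the x
    positions of its mesial / central / distal vertical measurement lines."""

    tooth_id: Literal["13", "12", "11", "21", "22", "23"]
    cervical_polyline: list[tuple[float, float]] = Field(min_length=2)
    mesial_x: float
    central_x: float
    distal_x: float

    @model_validator(mode="after")
    def _xs_within_polyline(self) -> "ToothLandmark":
        xs = [p[0] for p in self.cervical_polyline]
        lo, hi = min(xs), max(xs)
        for name in ("mesial_x", "central_x", "distal_x"):
            v = getattr(self, name)
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(
                    f"{name}={v} outside cervical polyline x-range [{lo}, {hi}]"
                )
        return self

    def cervical_y_at(self, x: float) -> float:
        """Cervical-line y at ``x`` by linear interpolation along the polyline.

        Extrapolating beyond the traced polyline is a geometry error.
        """
        pts = sorted(self.cervical_polyline, key=lambda p: p[0])
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        if not (xs[0] - 1e-9 <= x <= xs[-1] + 1e-9):
            raise GeometryError(
                f"x={x} outside cervical polyline of tooth {self.tooth_id}"
            )
        return float(np.interp(x, xs, ys))


class LandmarkAnnotation(BaseModel):
    """Per-photograph anatomical landmarks.

    ``crown_length_12`` is the crown length of the maxillary right lateral
    incisor (FDI 12) in pixels; it sets the apical offset of the horizontal
    baseline.  ``attached_gingiva`` bounds the band between the cervical side
    and the mucogingival junction — only lattice points inside it count.
    """

    schema_version: int = SCHEMA_VERSION
    image_id: str
    teeth: list[ToothLandmark]
    crown_length_12: float = Field(gt=0)
    attached_gingiva: list[tuple[float, float]] = Field(min_length=3)

    @model_validator(mode="after")
    def _check(self) -> "LandmarkAnnotation":
        ids = [t.tooth_id for t in self.teeth]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tooth_id in annotation")
        if "12" not in ids:
            raise ValueError("tooth 12 (maxillary right lateral incisor) is required")
        poly = Polygon(self.attached_gingiva)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("attached_gingiva must be a simple, non-degenerate polygon")
        return self

    def tooth(self, tooth_id: str) -> ToothLandmark:
        for t in self.teeth:
            if t.tooth_id == tooth_id:
                return t
        raise KeyError(tooth_id)

    def gingiva_polygon(self) -> Polygon:
        return Polygon(self.attached_gingiva)

    def translated(self, dx: float, dy: float) -> "LandmarkAnnotation":
        """Annotation with every landmark shifted by (dx, dy)."""
        return LandmarkAnnotation(
            schema_version=self.schema_version,
            image_id=self.image_id,
            teeth=[
                ToothLandmark(
                    tooth_id=t.tooth_id,
                    cervical_polyline=[(x + dx, y + dy) for x, y in t.cervical_polyline],
                    mesial_x=t.mesial_x + dx,
                    central_x=t.central_x + dx,
                    distal_x=t.distal_x + dx,
                )
                for t in self.teeth
            ],
            crown_length_12=self.crown_length_12,
            attached_gingiva=[(x + dx, y + dy) for x, y in self.attached_gingiva],
        )


SITE_COLUMNS = ["site_id", "line_index", "point_index", "x", "y"]
CALL_COLUMNS = SITE_COLUMNS + ["pigmented"]


@dataclass
class SiteCallTable:
    """Binary pigmentation call per retained lattice site of one photograph."""

    image_id: str
    calls: pd.DataFrame  # columns CALL_COLUMNS

    def __post_init__(self) -> None:
        df = self.calls
        missing = [c for c in CALL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"call table missing columns: {missing}")
        if df["site_id"].duplicated().any():
            raise ValidationError("site_id values must be unique")
        if ((df["point_index"] < 0) | (df["point_index"] > 8)).any():
            raise ValidationError("point_index must lie in [0, 8]")
        if df.duplicated(subset=["line_index", "point_index"]).any():
            raise ValidationError("(line_index, point_index) pairs must be unique")
        self.calls = df.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    @property
    def n_pigmented(self) -> int:
        return int(self.calls["pigmented"].sum())


@dataclass
class GmrResult:
    """GMR percentage and Hedin class for one photograph."""

    image_id: str
    pigmented_count: int
    retained_count: int
    gmr: float  # percentage, full precision
    hedin: Optional[int] = None  # 0-4

    def __post_init__(self) -> None:
        if self.retained_count < 1:
            raise ValidationError("GMR undefined for zero retained sites")
        expected = 100.0 * self.pigmented_count / self.retained_count
        if abs(self.gmr - expected) > 1e-9:
            raise ValidationError("gmr must equal 100 * pigmented / retained")
        if self.hedin is not None:
            if self.hedin not in range(5):
                raise ValidationError("hedin must be in {0..4}")
            if (self.hedin == 0) != (self.pigmented_count == 0):
                raise ValidationError("hedin == 0 iff no pigmented sites")


SUBJECT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "lifetime_cigarettes",
    "smoked_last_30_days",
    "smoking_duration",
    "cessation_duration",
    "followup_period",
    "gmr_baseline",
    "gmr_followup",
    "hedin_baseline",
    "hedin_followup",
]

DERIVED_COLUMNS = ["smoking_status", "age_group"]


@dataclass
class CohortTable:
    """Loaded cohort with derived smoking-status and age-group columns.

    ``n_excluded`` counts rows rejected because the subject met neither the
    current- nor the former-smoker definition; ``row_errors`` collects
    per-row parse problems (never silently dropped).
    """

    subjects: pd.DataFrame  # SUBJECT_COLUMNS + DERIVED_COLUMNS
    n_excluded: int = 0
    row_errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.subjects
        missing = [c for c in SUBJECT_COLUMNS + DERIVED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        bad_status = ~df["smoking_status"].isin(SMOKING_STATUSES)
        if bad_status.any():
            raise ValidationError("all loaded subjects must be current or former smokers")
        for col in ("gmr_baseline", "gmr_followup"):
            v = df[col].dropna()
            if ((v < 0) | (v > 100)).any():
                raise ValidationError(f"{col} must lie in [0, 100]")
        former = df["smoking_status"] == "former"
        if df.loc[~former, "cessation_duration"].notna().any():
            raise ValidationError("cessation_duration only defined for former smokers")
        self.subjects = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.subjects)
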