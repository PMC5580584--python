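"""Readers and writers for the pipeline's interchange formats.

Images are PNG/JPEG rasters (Pillow).  Landmark annotations travel as one
JSON document per photograph with a ``schema_version`` field.  Site-call
tables and cohorts are UTF-8 CSV with a header and "." decimal separator.
All loaders are read-only: derived columns (smoking status, age group) are
recomputed deterministically from the raw fields at load time, never stored.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .stats import assign_age_group, classify_smoking_status
from .types import (
    CALL_COLUMNS,
    CohortTable,
    LandmarkAnnotation,
    OralPhotograph,
    SiteCallTable,
    SUBJECT_COLUMNS,
    ValidationError,
)

logger = logging.getLogger("gmrkit")


def setup_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; -v raises the level to DEBUG."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gmrkit")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---- images ----------------------------------------------------------------


def read_image(path: str | Path, image_id: str | None = None) -> OralPhotograph:
    path = Path(path)
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    return OralPhotograph(image_id=image_id or path.stem, pixels=pixels)


def write_image(photo: OralPhotograph, path: str | Path) -> None:
    Image.fromarray(photo.pixels, mode="RGB").save(Path(path))


# ---- annotations (JSON) ----------------------------------------------------


def write_annotation(annotation: LandmarkAnnotation, path: str | Path) -> None:
    """Canonical JSON: sorted keys, 2-space indent, trailing newline."""
    payload = annotation.model_dump()
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )


def read_annotation(path: str | Path) -> LandmarkAnnotation:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return LandmarkAnnotation.model_validate(raw)


# ---- site-call tables (CSV) -------------------------------------------------


def write_call_table(table: SiteCallTable, path: str | Path) -> None:
    df = table.calls.copy()
    df.insert(0, "image_id", table.image_id)
    df.to_csv(Path(path), index=False)


def read_call_table(path: str | Path) -> SiteCallTable:
    df = pd.read_csv(Path(path))
    missing = [c for c in ["image_id", *CALL_COLUMNS] if c not in df.columns]
    if missing:
        raise ValidationError(f"call table CSV missing columns: {missing}")
    image_ids = df["image_id"].unique()
    if len(image_ids) != 1:
        raise ValidationError("call table CSV must describe exactly one photograph")
    df["pigmented"] = df["pigmented"].astype(bool)
    return SiteCallTable(image_id=str(image_ids[0]), calls=df[CALL_COLUMNS])


# ---- cohorts (CSV) ----------------------------------------------------------

_BOOL_STRINGS = {"true": True, "1": True, "false": False, "0": False}


def _parse_bool(value: str) -> bool:
    try:
        return _BOOL_STRINGS[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"not a boolean: {value!r}")


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write raw subject fields only; derived columns are recomputed on load."""
    cohort.subjects[SUBJECT_COLUMNS].to_csv(Path(path), index=False)


def read_cohort(path: str | Path) -> CohortTable:
    """Load a subject CSV, derive status/age-group columns, apply eligibility.

    Subjects matching neither the current- nor the former-smoker definition
    are excluded and counted (``n_excluded``); rows with unparseable fields
    are collected in ``row_errors`` — nothing is dropped silently.
    """
    raw = pd.read_csv(Path(path), dtype=str)
    missing = [c for c in SUBJECT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")

    rows = []
    row_errors: list[str] = []
    n_excluded = 0
    for i, rec in raw.iterrows():
        try:
            age = int(float(rec["age"]))
            if age < 0:
                raise ValueError("age must be >= 0")
            sex = str(rec["sex"]).strip().lower()
            if sex not in ("male", "female"):
                raise ValueError(f"unknown sex {rec['sex']!r}")
            lifetime = float(rec["lifetime_cigarettes"])
            smoked30 = _parse_bool(rec["smoked_last_30_days"])
            status = classify_smoking_status(lifetime, smoked30)
            if status == "ineligible":
                n_excluded += 1
                continue
            cess = rec.get("cessation_duration")
            cess_val = (
                float(cess) if cess not in (None, "") and not pd.isna(cess) else np.nan
            )
            if status == "former" and np.isnan(cess_val):
                raise ValueError("former smoker without cessation_duration")
            if status == "current" and not np.isnan(cess_val):
                raise ValueError("current smoker with cessation_duration")
            row = {
                "subject_id": str(rec["subject_id"]),
                "age": age,
                "sex": sex,
                "lifetime_cigarettes": int(lifetime),
                "smoked_last_30_days": smoked30,
                "smoking_duration": float(rec["smoking_duration"]),
                "cessation_duration": cess_val,
                "followup_period": float(rec["followup_period"]),
                "gmr_baseline": float(rec["gmr_baseline"]),
                "gmr_followup": float(rec["gmr_followup"]),
                "hedin_baseline": int(float(rec["hedin_baseline"])),
                "hedin_followup": int(float(rec["hedin_followup"])),
                "smoking_status": status,
                "age_group": assign_age_group(age),
            }
            rows.append(row)
        except (ValueError, KeyError) as exc:
            row_errors.append(f"row {i}: {exc}")
    if row_errors:
        logger.warning("cohort load: %d row errors (%s ...)", len(row_errors), row_errors[0])
    if n_excluded:
        logger.info("cohort load: excluded %d ineligible subjects", n_excluded)
    df = pd.DataFrame(rows, columns=SUBJECT_COLUMNS + ["smoking_status", "age_group"])
    return CohortTable(subjects=df, n_excluded=n_excluded, row_errors=row_errors)
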