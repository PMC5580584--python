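"""End-to-end orchestration: synthesize -> grid -> score -> analyze.

One :class:`RunConfig` (optionally loaded from a TOML file) drives all four
stages into a per-run output directory with fixed file names.  A manifest
records the configuration hash, package version and per-stage outputs;
identical config + seed reproduce byte-identical CSV/JSON artifacts (the
manifest's timestamps are stored in a separate field so everything else is
comparable).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .analysis import run_study_analysis
from .grid import DEFAULT_MERGE_TOL, build_grid, grid_to_dict
from .io import (
    read_annotation,
    read_cohort,
    write_annotation,
    write_call_table,
    write_cohort,
    write_image,
)
from .scoring import PigmentCallParams, call_site_pigmentation, score_photo
from .synth import CohortGenParams, PhotoGenParams, render_photograph, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the run log."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class RunConfig(BaseModel):
    """Everything needed to reproduce one end-to-end run."""

    seed: int = 0
    out_dir: str = "gmr_run"
    n_photos: int = Field(default=2, ge=0)
    photo: PhotoGenParams = Field(default_factory=PhotoGenParams)
    cohort: CohortGenParams = Field(default_factory=CohortGenParams)
    calls: PigmentCallParams = Field(default_factory=PigmentCallParams)
    merge_tol: float = DEFAULT_MERGE_TOL
    exclude_canines: bool = False
    make_plots: bool = True

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.model_validate(tomllib.load(fh))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is not part
        of what the run computes, so it is excluded)."""
        canonical = json.dumps(
            self.model_dump(exclude={"out_dir"}), sort_keys=True, default=str
        )
        return hashlib.sha256(canonical.encode()).hexdigest()


def run_end_to_end(config: RunConfig) -> dict:
    """Execute all stages; return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_photos + 1)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "gmrkit_version": __version__,
        "seed": config.seed,
        "stages": {},
        "timestamps": {"started": _dt.datetime.now().isoformat()},
    }

    # stage 1: synthesize photographs (+ ground truth) and the cohort
    stage = "synth"
    try:
        photo_files = []
        for i in range(config.n_photos):
            params = config.photo.model_copy(
                update={"seed": int(seeds[i] % 2**31), "image_id": f"photo{i:03d}"}
            )
            photo, annotation, truth = render_photograph(
                params, merge_tol=config.merge_tol
            )
            write_image(photo, out / f"{params.image_id}.png")
            write_annotation(annotation, out / f"{params.image_id}.annotation.json")
            write_call_table(truth, out / f"{params.image_id}.truth.csv")
            photo_files.append(params.image_id)
        cohort_params = config.cohort.model_copy(
            update={"seed": int(seeds[-1] % 2**31)}
        )
        cohort = simulate_cohort(cohort_params)
        write_cohort(cohort, out / "cohort.csv")
        manifest["stages"][stage] = {"photos": photo_files, "cohort": "cohort.csv"}
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc

    # stage 2: lattice construction from the written annotations
    stage = "grid"
    try:
        for image_id in photo_files:
            annotation = read_annotation(out / f"{image_id}.annotation.json")
            grid = build_grid(
                annotation,
                merge_tol=config.merge_tol,
                exclude_canines=config.exclude_canines,
            )
            (out / f"{image_id}.grid.json").write_text(
                json.dumps(grid_to_dict(grid), sort_keys=True, indent=2) + "\n"
            )
        manifest["stages"][stage] = {"grids": [f"{p}.grid.json" for p in photo_files]}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # stage 3: pigmentation calling and GMR/Hedin scoring
    stage = "score"
    try:
        from .io import read_image
        from .grid import grid_from_dict

        results = {}
        for image_id in photo_files:
            photo = read_image(out / f"{image_id}.png", image_id=image_id)
            grid = grid_from_dict(
                json.loads((out / f"{image_id}.grid.json").read_text())
            )
            calls = call_site_pigmentation(photo, grid, config.calls)
            write_call_table(calls, out / f"{image_id}.calls.csv")
            result = score_photo(photo, grid, config.calls)
            results[image_id] = {
                "gmr": result.gmr,
                "hedin": result.hedin,
                "pigmented_count": result.pigmented_count,
                "retained_count": result.retained_count,
            }
        (out / "scores.json").write_text(
            json.dumps(results, sort_keys=True, indent=2) + "\n"
        )
        manifest["stages"][stage] = {"scores": "scores.json"}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # stage 4: cohort analysis
    stage = "analyze"
    try:
        cohort = read_cohort(out / "cohort.csv")
        report = run_study_analysis(cohort, make_plots=config.make_plots)
        written = report.save(out / "report")
        manifest["stages"][stage] = {"report": [p.name for p in written]}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest["timestamps"]["finished"] = _dt.datetime.now().isoformat()
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    logger.info("run complete: %s", out)
    return manifest
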