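"""Synthetic data generators: stylized oral photographs and simulated cohorts.

The photograph generator draws a flat-shaded frontal view of the six
anterior maxillary teeth (FDI 13-23) between the canines: an alveolar-mucosa
band, the mucogingival junction, the attached-gingiva band, scalloped
cervical lines and enamel crowns.  Melanin is stamped as dark round patches
exactly at the ground-truth-pigmented lattice sites, so color-based calling
can be validated against a known truth table.  The palette is constructed so
pigmented and healthy gingiva are separated by a wide CIELAB lightness
margin; with the default calling threshold the classes cannot overlap.

The cohort simulator emulates the structure of the study population:
259 subjects in ten (smoking status x 10-year age bin) cells, baseline GMR
drawn from a moment-matched truncated normal, and follow-up GMR produced by
age-dependent multiplicative fading under cessation (weakest in the
youngest bin) or a small drift for continuing smokers.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import optimize
from scipy import stats as sps
from skimage.color import rgb2lab

from . import reference
from .grid import DEFAULT_MERGE_TOL, SiteGrid, build_grid
from .scoring import classify_hedin, hedin_grade_from_gmr
from .stats import assign_age_group, classify_smoking_status
from .types import (
    AGE_GROUPS,
    ANTERIOR_MAXILLARY_TEETH,
    CALL_COLUMNS,
    CohortTable,
    LandmarkAnnotation,
    OralPhotograph,
    SiteCallTable,
    SUBJECT_COLUMNS,
    ToothLandmark,
    ValidationError,
)

logger = logging.getLogger(__name__)

RGB = tuple[int, int, int]


def _lightness(rgb: RGB) -> float:
    arr = np.asarray(rgb, dtype=float).reshape(1, 1, 3) / 255.0
    return float(rgb2lab(arr)[0, 0, 0])


class Palette(BaseModel):
    """Flat-shading colors of the rendered scene (8-bit RGB)."""

    enamel: RGB = (243, 237, 222)
    healthy_gingiva: RGB = (232, 148, 138)
    pigmented_gingiva: RGB = (88, 58, 56)
    alveolar_mucosa: RGB = (196, 106, 108)
    background: RGB = (24, 16, 18)

    #: Minimum required L* separation between healthy and pigmented gingiva.
    LIGHTNESS_MARGIN: float = 15.0

    @model_validator(mode="after")
    def _separable(self) -> "Palette":
        healthy = _lightness(self.healthy_gingiva)
        pigmented = _lightness(self.pigmented_gingiva)
        if not pigmented < healthy - self.LIGHTNESS_MARGIN:
            raise ValueError(
                "pigmented gingiva must be darker than healthy gingiva by at "
                f"least {self.LIGHTNESS_MARGIN} L* units "
                f"(got healthy {healthy:.1f}, pigmented {pigmented:.1f})"
            )
        return self


class PhotoGenParams(BaseModel):
    """Parameters of the synthetic photograph generator."""

    image_id: str = "synthetic"
    width: int = Field(default=512, ge=120)
    height: int = Field(default=400, ge=256)
    palette: Palette = Field(default_factory=Palette)
    p_site: float = Field(default=0.25, ge=0.0, le=1.0)
    patch_radius: int = Field(default=3, ge=1)
    noise_sd: float = Field(default=0.0, ge=0.0)
    seed: int = 0


class _Layout:
    """Scene geometry derived from the image size (pixel units)."""

    def __init__(self, p: PhotoGenParams) -> None:
        w, h = p.width, p.height
        self.x_left = 0.10 * w
        self.x_right = 0.90 * w
        self.tooth_w = (self.x_right - self.x_left) / 6.0
        self.cervical_edge_y = round(0.65 * h)  # cervical line at tooth edges
        self.scallop = max(2, round(0.03 * h))  # apical rise at tooth centers
        self.crown_length_12 = round(0.16 * h)
        self.incisal_y = round(0.87 * h)
        self.baseline_y = (self.cervical_edge_y - self.scallop) - self.crown_length_12
        self.mgj_y = self.baseline_y - round(0.07 * h)
        site_spacing = self.crown_length_12 / 8.0
        if site_spacing <= p.patch_radius + 2:
            raise ValidationError(
                "image too small: lattice spacing "
                f"{site_spacing:.1f}px cannot separate patches of radius "
                f"{p.patch_radius} from neighboring call windows"
            )
        if self.mgj_y <= p.patch_radius:
            raise ValidationError("image too small to place the gingival band")

    def tooth_edges(self) -> list[float]:
        return [self.x_left + i * self.tooth_w for i in range(7)]


def _make_annotation(params: PhotoGenParams) -> LandmarkAnnotation:
    """Ground-truth landmarks geometrically consistent with the render."""
    lay = _Layout(params)
    edges = lay.tooth_edges()
    teeth = []
    for i, tooth_id in enumerate(ANTERIOR_MAXILLARY_TEETH):
        x0, x1 = edges[i], edges[i + 1]
        xc = 0.5 * (x0 + x1)
        half = 0.5 * (x1 - x0)
        # scalloped cervical line: parabola, apical (smaller y) at tooth center
        xs = np.linspace(x0, x1, 7)
        ys = lay.cervical_edge_y - lay.scallop * (1.0 - ((xs - xc) / half) ** 2)
        polyline = [(float(x), float(y)) for x, y in zip(xs, ys)]
        # mesial = toward the midline; teeth 13,12,11 sit viewer-left of it
        if tooth_id in ("13", "12", "11"):
            mesial_x, distal_x = x1, x0
        else:
            mesial_x, distal_x = x0, x1
        teeth.append(
            ToothLandmark(
                tooth_id=tooth_id,
                cervical_polyline=polyline,
                mesial_x=mesial_x,
                central_x=xc,
                distal_x=distal_x,
            )
        )
    margin = 4.0
    gingiva_polygon = [
        (lay.x_left - margin, float(lay.mgj_y)),
        (lay.x_right + margin, float(lay.mgj_y)),
        (lay.x_right + margin, float(lay.cervical_edge_y + 1)),
        (lay.x_left - margin, float(lay.cervical_edge_y + 1)),
    ]
    return LandmarkAnnotation(
        image_id=params.image_id,
        teeth=teeth,
        crown_length_12=float(lay.crown_length_12),
        attached_gingiva=gingiva_polygon,
    )


def render_photograph(
    params: PhotoGenParams,
    truth: dict[str, bool] | None = None,
    merge_tol: float = DEFAULT_MERGE_TOL,
) -> tuple[OralPhotograph, LandmarkAnnotation, SiteCallTable]:
    """Render one synthetic photograph with its annotation and truth table.

    ``truth`` maps site_id -> pigmented for every retained site; when absent,
    sites are pigmented independently with probability ``params.p_site``
    (seeded).  Returns the photograph, the landmark annotation, and the
    ground-truth call table.
    """
    lay = _Layout(params)
    annotation = _make_annotation(params)
    grid = build_grid(annotation, merge_tol=merge_tol)
    sites = grid.retained_sites

    rng = np.random.default_rng(params.seed)
    if truth is None:
        pigmented = rng.random(len(sites)) < params.p_site
    else:
        missing = set(sites["site_id"]) - set(truth)
        if missing:
            raise ValidationError(f"truth assignment missing sites: {sorted(missing)}")
        pigmented = sites["site_id"].map(truth).to_numpy(dtype=bool)

    h, w = params.height, params.width
    pal = params.palette
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = pal.background

    # per-column cervical envelope (integer row of the most coronal gingiva pixel)
    xs_all = np.arange(w, dtype=float)
    env = np.full(w, float(lay.cervical_edge_y))
    for tooth in annotation.teeth:
        pts = np.asarray(tooth.cervical_polyline)
        in_tooth = (xs_all >= pts[0, 0]) & (xs_all <= pts[-1, 0])
        env[in_tooth] = np.interp(xs_all[in_tooth], pts[:, 0], pts[:, 1])
    env_i = np.round(env).astype(int)

    yy = np.arange(h)[:, None]
    in_span = (xs_all >= lay.x_left) & (xs_all <= lay.x_right)
    img[(yy < lay.mgj_y) & np.ones(w, dtype=bool)] = pal.alveolar_mucosa
    gingiva_mask = (yy >= lay.mgj_y) & (yy <= env_i[None, :])
    img[gingiva_mask] = pal.healthy_gingiva
    enamel_mask = (yy > env_i[None, :]) & (yy < lay.incisal_y) & in_span[None, :]
    img[enamel_mask] = pal.enamel

    # melanin patches: full discs centered on pigmented sites.  With
    # patch_radius >= sqrt(2) * window_radius the whole call window of a
    # pigmented site lies inside its disc, so the median aggregate is the
    # patch color regardless of how the cervical scallops cut the window
    # (k = 8 sites straddle the gingiva/enamel boundary).
    rr = np.arange(-params.patch_radius, params.patch_radius + 1)
    dy, dx = np.meshgrid(rr, rr, indexing="ij")
    disk = dy**2 + dx**2 <= params.patch_radius**2
    for (_, site), pig in zip(sites.iterrows(), pigmented):
        if not pig:
            continue
        cx, cy = int(round(site["x"])), int(round(site["y"]))
        ys_p = cy + dy[disk]
        xs_p = cx + dx[disk]
        ok = (ys_p >= 0) & (ys_p < h) & (xs_p >= 0) & (xs_p < w)
        img[ys_p[ok], xs_p[ok]] = pal.pigmented_gingiva

    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, img.shape)
        img = np.clip(img.astype(float) + noise, 0, 255).astype(np.uint8)

    photo = OralPhotograph(image_id=params.image_id, pixels=img)
    calls = sites.copy()
    calls["pigmented"] = pigmented
    truth_table = SiteCallTable(image_id=params.image_id, calls=calls[CALL_COLUMNS])
    return photo, annotation, truth_table


def hedin_truth_from_sites(truth: SiteCallTable, grid: SiteGrid) -> int:
    """Ground-truth Hedin class of a synthetic scene.

    Delegates to the pipeline's own classifier so that truth and pipeline
    share one definition by construction.
    """
    return classify_hedin(truth, grid)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: Per-year multiplicative GMR reduction under smoking cessation, by age bin.
#: Package constants chosen to increase with age (weakest fading in the
#: youngest bin), reproducing the study's qualitative age gradient.
DEFAULT_FADE_RATE = {
    "19-29": 0.02,
    "30-39": 0.05,
    "40-49": 0.07,
    "50-59": 0.09,
    "60+": 0.10,
}

AGE_BIN_RANGES = {
    "19-29": (19, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60+": (60, 79),
}


class CohortGenParams(BaseModel):
    """Parameters of the longitudinal cohort simulator.

    Defaults reproduce the published cell structure (ten status x age-bin
    cells, 259 subjects) and summary moments: baseline GMR mean 26.7 / sd
    19.8 (%), follow-up period means 4.50 (former) and 3.79 (current) years.
    ``onset_age_sd`` (years) is calibrated so the population Spearman
    correlation between age and smoking duration is ~0.85, the study's
    reported value; see the methods note for the calibration.
    """

    n_per_cell: dict[str, tuple[int, int, int, int, int]] = Field(
        default_factory=lambda: dict(reference.SUBGROUP_N)
    )
    males_per_cell: dict[str, tuple[int, int, int, int, int]] = Field(
        default_factory=lambda: dict(reference.SUBGROUP_MALES)
    )
    gmr_mean: float = Field(default=26.7, ge=0, le=100)
    gmr_sd: float = Field(default=19.8, ge=0)
    onset_age_mean: float = 18.0
    onset_age_sd: float = Field(default=11.0, ge=0)
    fade_rate: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_FADE_RATE))
    current_smoker_drift: float = -0.01
    followup_mean: dict[str, float] = Field(
        default_factory=lambda: {"former": 4.50, "current": 3.79}
    )
    followup_sd: dict[str, float] = Field(
        default_factory=lambda: {"former": 2.15, "current": 1.17}
    )
    cessation_mean: tuple[float, float, float, float, float] = reference.SUBGROUP_CESSATION
    cessation_sd: float = Field(default=1.95, ge=0)
    seed: int = 0

    @field_validator("n_per_cell", "males_per_cell")
    @classmethod
    def _nonneg_counts(cls, v):
        for status, counts in v.items():
            if status not in ("former", "current"):
                raise ValueError(f"unknown smoking status {status!r}")
            if any(c < 0 for c in counts):
                raise ValueError("cell counts must be non-negative")
        return v

    @field_validator("fade_rate")
    @classmethod
    def _fade_in_unit(cls, v):
        for bin_, rate in v.items():
            if bin_ not in AGE_GROUPS:
                raise ValueError(f"unknown age group {bin_!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("fade_rate must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _males_fit(self) -> "CohortGenParams":
        for status, counts in self.n_per_cell.items():
            males = self.males_per_cell.get(status, (0,) * 5)
            if any(m > n for m, n in zip(males, counts)):
                raise ValueError("males_per_cell cannot exceed n_per_cell")
        return self


@lru_cache(maxsize=8)
def _matched_truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu0, sigma0) such that the [0, 100]-truncated normal has
    the requested mean and sd.  At the defaults (26.7, 19.8) the unique root
    is mu0 ~ 0.84, sigma0 ~ 33.4: a strongly right-skewed shape, matching
    how pigmentation scores pile up near zero."""

    def moments(p):
        mu, sig = p
        a, b = (0.0 - mu) / sig, (100.0 - mu) / sig
        d = sps.truncnorm(a, b, loc=mu, scale=sig)
        return [d.mean() - mean, d.std() - sd]

    sol, info, ier, msg = optimize.fsolve(moments, [mean, sd], full_output=True)
    if ier != 1:
        raise ValueError(f"cannot moment-match truncated normal: {msg}")
    return float(sol[0]), float(sol[1])


def _draw_baseline_gmr(rng: np.random.Generator, n: int, mean: float, sd: float):
    if sd == 0:
        return np.full(n, mean)
    mu0, sig0 = _matched_truncnorm_params(mean, sd)
    a, b = (0.0 - mu0) / sig0, (100.0 - mu0) / sig0
    return sps.truncnorm(a, b, loc=mu0, scale=sig0).rvs(n, random_state=rng)


def simulate_cohort(params: CohortGenParams | None = None) -> CohortTable:
    """Simulate one longitudinal cohort with the study's cell structure.

    Per subject: age uniform within its bin (60+ bin: 60-79), smoking onset
    age normal, smoking duration = age - onset truncated to [0, age - 10],
    baseline GMR from the moment-matched truncated normal, and follow-up GMR

    - former smokers:  baseline x (1 - fade_rate(age bin)) ** cessation_years
    - current smokers: baseline x (1 + current_smoker_drift) ** followup_years

    clamped to [0, 100].  Deterministic under a fixed seed.
    """
    params = params or CohortGenParams()
    rng = np.random.default_rng(params.seed)
    rows = []
    idx = 0
    for status in ("former", "current"):
        counts = params.n_per_cell.get(status, (0,) * 5)
        males = params.males_per_cell.get(status, (0,) * 5)
        for age_group, n, n_males in zip(AGE_GROUPS, counts, males):
            if n == 0:
                continue
            lo, hi = AGE_BIN_RANGES[age_group]
            ages = rng.integers(lo, hi + 1, size=n)
            sexes = np.array(["male"] * n_males + ["female"] * (n - n_males))
            rng.shuffle(sexes)
            onset = rng.normal(params.onset_age_mean, params.onset_age_sd, size=n)
            duration = np.clip(ages - onset, 0.0, ages - 10.0)
            followup = np.clip(
                rng.normal(
                    params.followup_mean[status], params.followup_sd[status], size=n
                ),
                0.1,
                None,
            )
            baseline = _draw_baseline_gmr(rng, n, params.gmr_mean, params.gmr_sd)
            cigs_per_day = rng.uniform(5, 25, size=n)
            lifetime = (101 + duration * 365.25 * cigs_per_day).astype(int)
            if status == "former":
                bin_i = AGE_GROUPS.index(age_group)
                cessation = np.clip(
                    rng.normal(params.cessation_mean[bin_i], params.cessation_sd, n),
                    0.0,
                    followup,
                )
                fade = params.fade_rate[age_group]
                follow_gmr = baseline * (1.0 - fade) ** cessation
            else:
                cessation = np.full(n, np.nan)
                follow_gmr = baseline * (1.0 + params.current_smoker_drift) ** followup
            follow_gmr = np.clip(follow_gmr, 0.0, 100.0)
            n_clamped = int(np.sum((follow_gmr == 0.0) | (follow_gmr == 100.0)))
            if n_clamped:
                logger.debug(
                    "cell (%s, %s): clamped %d follow-up GMR values", status, age_group, n_clamped
                )
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"S{idx:04d}",
                        "age": int(ages[i]),
                        "sex": sexes[i],
                        "lifetime_cigarettes": int(lifetime[i]),
                        "smoked_last_30_days": status == "current",
                        "smoking_duration": float(duration[i]),
                        "cessation_duration": float(cessation[i])
                        if status == "former"
                        else np.nan,
                        "followup_period": float(followup[i]),
                        "gmr_baseline": float(baseline[i]),
                        "gmr_followup": float(follow_gmr[i]),
                        "hedin_baseline": hedin_grade_from_gmr(float(baseline[i])),
                        "hedin_followup": hedin_grade_from_gmr(float(follow_gmr[i])),
                    }
                )
                idx += 1
    df = pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
    df["smoking_status"] = [
        classify_smoking_status(c, s)
        for c, s in zip(df["lifetime_cigarettes"], df["smoked_last_30_days"])
    ]
    df["age_group"] = df["age"].map(assign_age_group)
    return CohortTable(subjects=df)
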