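# Methods

## The GMR measurement model

The gingival melanosis record treats pigmentation measurement as sampling
on a landmark-anchored lattice. All geometry lives in raster coordinates
(origin top-left, y downward), so for maxillary gingiva "apical" means
decreasing y and every vertical measurement line runs from the baseline
(`y_top`) down to a cervical line (`y_bottom`), with `y_top < y_bottom`.

- **Baseline.** `baseline_y = (cervical y of tooth 12 at its central
  line) − crown_length_12`. The crown length of the maxillary right
  lateral incisor is the study's internal length scale; it makes the
  lattice height proportional to tooth size rather than image resolution.
- **Vertical lines.** Each of the six anterior maxillary teeth (FDI
  13–23) contributes candidate lines at its mesial, central and distal
  x-positions: 18 candidates. Adjacent teeth share interproximal
  positions; candidates whose x differ by at most `merge_tol` (default
  3 px, transitively closed) merge into one line at the mean x with the
  union of source positions. With contiguous teeth this yields 13 lines.
  Cervical y at a line's x is linearly interpolated along the annotated
  cervical polyline; extrapolating beyond the traced polyline is an error,
  as is a cervical line apical to the baseline (crown length exceeding the
  gingival height).
- **Sites.** Nine points at `y = y_top + k·(y_bottom − y_top)/8`,
  k = 0…8. "Nine points separating eight equal parts" forces inclusive
  endpoints, so both the baseline point and the cervical point are
  candidates; they are then filtered like any other point.
- **Attached-gingiva filter.** A site is retained iff it lies inside *or
  on the boundary of* the annotated attached-gingiva polygon (the band
  between the mucogingival junction and the free gingiva). Boundary
  inclusion is a deterministic tie-break (shapely `covers`); an independent
  ray-casting oracle in the test suite checks the interior decisions.
  Zero retained sites is a hard error: the GMR is undefined without sites.

GMR is kept at full precision internally (`100 × pigmented / retained`);
rounding to one decimal happens only at presentation.

### Pigmentation calling

Melanin darkens tissue, so the color decision uses CIELAB lightness only:
a site is pigmented iff the aggregated L* of the `(2r+1)²` pixel window
around it (default r = 2, median aggregation) is ≤ `lightness_threshold`
(default 50, midway between typical healthy gingiva at L* ≈ 65–75 and
melanotic tissue at L* ≈ 25–35). Median aggregation makes the call robust
to anti-aliased edges crossing the window; windows are clamped at image
borders. For images with unknown palettes an Otsu threshold over the
per-site L* values can replace the fixed cutoff (`auto_threshold`).
Manual call tables (CSV) bypass color calling entirely, mirroring a
human-estimator workflow.

### Hedin grading — an operationalization

The classical Hedin scale is verbal (0 none, 1–2 solitary units, 3–4
ribbon-like bands). **The lattice rules used here are this package's own
operationalization, not a published rubric**: pigmented sites are grouped
into connected components under 8-neighborhood adjacency on the
(line_index, point_index) lattice; a component is a *ribbon* if it spans
≥ 3 distinct lines; grade 0 = no pigmented site, 1 = ≤ 2 components with
no ribbon, 2 = > 2 components with no ribbon, 3 = at least one ribbon,
4 = one component spans every line that carries retained sites. Lines
that lost all their sites to the attached-gingiva filter cannot be
spanned and are excluded from the "every line" requirement, so a fully
pigmented region always grades 4. The classifier is verified against an
independent flood-fill oracle on all 4096 patterns of a 4 × 3 toy
lattice. Hedin grading uses the same canine-to-canine region as the GMR.
Where only a summary GMR exists (simulated subjects), a documented
monotone map (cuts at 0, 10, 25, 60 %) provides a coarse Hedin-like
grade; these cutpoints are package constants.

## Synthetic photographs

The renderer draws a flat-shaded scene: background, alveolar-mucosa band,
mucogingival junction, attached-gingiva band, scalloped (parabolic)
cervical lines, and enamel crowns for the six teeth spanning the central
80 % of the image width. Layout is proportional to image size (crown
length of tooth 12 = 0.16 H, so the lattice spacing is H/50). Melanin is
stamped as full discs (default radius 3 px) centered on the
ground-truth-pigmented sites.

Separability is guaranteed by construction, not by luck:

- the palette validator requires pigmented gingiva to be ≥ 15 L* darker
  than healthy gingiva (defaults: ≈ 30 vs ≈ 70, threshold 50 between);
- `patch_radius ≥ √2 × window_radius` puts a pigmented site's whole call
  window inside its own disc — this matters at k = 8 sites, which sit on
  the gingiva/enamel boundary where the cervical scallops would otherwise
  cut the window;
- the lattice spacing check (`spacing > patch_radius + 2`) keeps discs out
  of neighboring sites' windows, else rendering refuses with a parameter
  error.

Consequently color calling with default parameters reproduces the
ground-truth call table *exactly*, which the acceptance suite checks over
50 seeds. What the renderer does **not** emulate: illumination gradients,
specular highlights, camera noise beyond optional flat Gaussian noise,
lip/cheek occlusion, tooth rotation or absence, and continuous pigment
intensity. Passing tests therefore demonstrate correctness of the
measurement given clean separable color classes, not robustness to
clinical photography.

## Simulated cohorts

One cohort = ten (smoking status × age bin) cells with the published cell
sizes and sex counts (133 former / 126 current, 259 total). Per subject,
with a single seeded generator stream:

- age ~ uniform integers within the bin (60+ bin: 60–79);
- smoking onset age ~ Normal(18, 11) years; smoking duration =
  age − onset, truncated to [0, age − 10];
- follow-up period ~ Normal(4.50, 2.15) (former) or Normal(3.79, 1.17)
  (current) years, floored at 0.1;
- cessation duration (former only) ~ Normal(bin mean 2.62–3.67, 1.95)
  years, clipped to [0, follow-up];
- baseline GMR ~ truncated normal on [0, 100] **moment-matched** so the
  truncated distribution itself has mean 26.7 and sd 19.8 % (underlying
  parameters μ₀ ≈ 0.84, σ₀ ≈ 33.4 — a strongly right-skewed shape,
  realistic for pigmentation scores piling up near zero). Matching the
  observed moments directly is what makes the parameter-recovery check
  (grand mean within ±3 SE of 26.7 over 200 replicates) meaningful;
  a naive truncation of Normal(26.7, 19.8) would have mean ≈ 30.2.
- follow-up GMR: former smokers fade multiplicatively,
  `baseline × (1 − fade_rate(bin))^cessation_years` with fade rates
  0.02 / 0.05 / 0.07 / 0.09 / 0.10 per year from youngest to oldest bin
  (package constants, ordered so the cessation effect is weakest in the
  20s, the study's qualitative age gradient); current smokers drift by
  −1 %/year over the follow-up. Both are clamped to [0, 100] with the
  clamping fraction logged.

### Calibration of the onset-age spread

`onset_age_sd` is the one free dispersion parameter without a published
counterpart; it controls how tightly smoking duration tracks age, i.e. the
population Spearman ρ(age, duration). It was calibrated once, by
large-sample simulation over a grid of candidate values under the exact
duration mechanics above (400 replicate cohorts of n = 259 per candidate),
to reproduce the study's reported ρ = 0.85; the calibrated default is
**11.0 years** (mean ρ ≈ 0.849), and it was frozen before the acceptance
checks were written. Smaller spreads give markedly higher correlations
(e.g. ρ ≈ 0.90 at sd 7.8) because the truncation at 0 and age − 10
compresses the noise.

Known rounding tensions in the published tables are left as-is rather
than reconciled: pooling the printed age cells gives 45.7 vs the printed
45.9; pooling former-smoker cessation cells gives ≈ 3.20 vs the printed
3.14; pooling former-smoker smoking-duration cells gives 27.25, which
rounds to 27.2 vs the printed 27.3. No generator target or acceptance
quantity is set on these three.

## Statistics

All test statistics are computed from closed-form mean-squares / rank
formulas (scipy supplies only the F- and t-distribution tails):

- one-way fixed-effects ANOVA, F = MS_between/MS_within, df (g−1, N−g);
  zero within-group variance with non-zero between-group variance is
  reported as infinite F with p = 0 and a `degenerate` flag;
- paired t on d = follow-up − baseline, df n−1, two-sided; sd(d) = 0
  yields t = 0 (p = 1) when mean(d) = 0, else a degenerate infinite t;
- Spearman ρ as the Pearson correlation of mid-rank vectors, p via the
  t-approximation with n−2 df (an exact permutation p for n ≤ 10 serves
  as the small-sample oracle in tests); zero rank variance is an error;
- ICC(1,1) = (BMS − WMS)/(BMS + (k−1)WMS) and ICC(2,1) =
  (BMS − EMS)/(BMS + (k−1)EMS + k(JMS − EMS)/n), the Shrout–Fleiss
  single-rater forms from the one-/two-way mean-squares decompositions;
  constant matrices are an error.

p-values are two-sided, uncorrected for multiplicity, read at α = 0.05 —
the study's reporting conventions. The suite ties every statistic to an
independent path (scipy's `f_oneway`/`ttest_rel`/`spearmanr`, pingouin's
ICC, and hand-written mean-squares oracles) at 1e-10, and checks the
paired-t type-I error empirically (2000 null replicates of n = 30,
rejection rate required in [0.04, 0.06]).

The cohort report mirrors the study's outputs: group and subgroup
summary tables (empty cells reported with n = 0, never dropped), baseline
ANOVA across the five age bins, former-vs-current baseline/follow-up
comparison, per-bin paired t within the former group, ρ(age, duration),
and three figures (baseline GMR by age; GMR by status and visit; former
smokers' change by age with significance stars).

## Problem sizes and determinism

Replicate-based checks use 200 cohorts of n = 259 (Spearman calibration,
GMR mean recovery), 2000 reps of n = 30 (type-I error), 50 rendered scenes
(call-vs-truth identity), and exhaustive enumeration of the 4096 toy
Hedin patterns — sizes at which every Monte-Carlo band in the suite is
comfortably narrower than the tolerance it checks. Every random draw in
the package flows from one `numpy` `default_rng` stream per operation,
seeded explicitly; the pipeline derives per-stage child seeds from the run
seed via `SeedSequence`, and identical config + seed reproduce
byte-identical CSV/JSON artifacts.

## Limitations

- Landmark annotations are *inputs*: there is no automatic landmark
  detection, no camera calibration or color management, and no DICOM.
- The Hedin lattice rules are an operationalization (above); absolute
  grades are comparable within this package, not across graders.
- The cohort simulator reproduces published summary structure, not
  individual-level covariance (e.g. baseline GMR is age-independent by
  construction, so the study's observed peak in the 30s is not emulated,
  and the real cohort's p-values are out of reach by design).
- Missing anterior teeth are representable in the schema (except tooth
  12, which anchors the baseline) and reduce the lattice accordingly;
  the canines can be excluded from site-bearing lines (`exclude_canines`)
  while still bounding the region.
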