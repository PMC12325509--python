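# Methods

## Scope and model

The package quantifies low pulmonary attenuation on Hounsfield-calibrated
thoracic CT. All endpoints are functionals of the empirical distribution of
HU values inside a lung-parenchyma mask:

- `LAA(c) = 100 · |{v : v < c}| / N` with strict inequality. At integer HU
  the strict/non-strict choice only matters for voxels exactly at the
  cutoff; strict is the package default and a plain reading of "below".
- `Perc15` is the nearest-rank inverse empirical CDF at fraction 0.15 — the
  order statistic at rank `⌈0.15·N⌉` (1-indexed), i.e. the smallest value
  whose empirical CDF reaches the fraction. A linearly interpolated
  convention (`convention="linear"`) exists for sensitivity analyses; the
  two differ by at most one HU step on large populations.
- `PD15 = Perc15 + 1000` (g/L), exact by definition.
- Histograms use half-open uniform bins anchored at a multiple of the bin
  width. With 1-HU bins on integer HU every value coincides with its bin's
  left edge, so the histogram route reproduces both endpoints exactly; this
  identity is tested, not assumed.

## Input handling

Volumes are held in `(x, y, z)` order with `z` cranio-caudal; files are
reoriented at read time (NIfTI via the closest canonical RAS transform).
NIfTI values are trusted as HU — the common convention for derived research
data — while DICOM stored values are always mapped through
`HU = stored × RescaleSlope + RescaleIntercept`. DICOM directories must hold
exactly one series; slices are sorted by position and slice gaps deviating
more than 10 % from the median gap raise a geometry error rather than
silently producing a distorted volume. HU are natively integral on
scanners, but float inputs (e.g. synthetic volumes) are used as given; no
rounding or clamping window is applied before densitometry.

## Segmentation

The reference workflow this replaces is semi-automatic with manual editing;
for reproducibility the package is fully automatic, with an external-mask
override instead of interactive correction:

1. **Body**: largest 26-connected component above −500 HU; its filled
   interior defines "inside the body".
2. **Candidate air**: voxels ≤ −300 HU inside the body whose component does
   not touch the volume border (excludes ambient air).
3. **Selection**: keep components ≥ 50 mL, at most the two largest (one if
   the lungs merge through the airway tree).
4. **Closing** with a 2 mm ball recovers vessels and partial-volume boundary
   voxels.

Airway removal seeds a 6-connected breadth-first region growing at the
trachea and subtracts the grown tree (dilated by 2 mm) from the mask. The
trachea is found as a near-midline (±20 mm) air column in the most cranial
mask slices with a tubular cross-section (15–600 mm²) that persists ≥ 10 mm
with per-slice area growth ≤ 1.5×; lung apex caps fail both the growth-rate
and midline tests. Growth proceeds in wavefronts through voxels ≤ −300 HU;
since parenchyma also satisfies that threshold, a leak is detected as a
wavefront exceeding 3× the median tubular wave size (established over the
first ten waves) and growth halts there. If no trachea candidate exists the
mask is returned unchanged with a warning — a soft condition, since the
trachea may lie outside the scanned range. Thresholds follow common
quantitative-CT practice and are all exposed in `SegmentationParams`.
Connectivity is 26-neighbour for components and 6-neighbour for airway
growing (the tighter connectivity resists leakage). Lungs are analysed as
one pooled voxel population; vessels are not explicitly removed and lobes
are not separated.

## Statistics

- Normality gate: Shapiro–Wilk at α = 0.05 per group (an automatable
  replacement for visual QQ-plot inspection); the route taken is logged.
  n < 3 or constant data default to nonparametric with a warning.
- `compare_groups(auto)` uses Student's t (pooled variance by default,
  Welch by flag) only when both groups pass the gate, otherwise the
  Wilcoxon rank-sum test. Rank-sum p-values are exact (full null
  distribution) when min(n) ≤ 8 with no ties, else normal approximation with
  tie and continuity corrections. Exactness is validated against full
  enumeration of all group-label assignments up to n₁ + n₂ = 12.
- `ttest_from_summary` reproduces printed-table comparisons from
  (mean, SD, n) triples; the published age row (48.1 ± 15.2, n = 20 vs
  46.9 ± 12.4, n = 21) yields p = 0.783 against the printed 0.79, the
  difference being rounding of the printed summaries. Other printed
  demographic rows are not used as anchors because the per-row test choice
  in the source table is not stated (its PMI row is not reproducible from
  its printed summaries by any summary t-test).
- Quartiles/IQR use numpy's linear-interpolation convention ("type 7");
  SD uses the n−1 denominator.
- Subgroup tables are descriptive only (n, median, IQR) — no p-values are
  emitted for the small asphyxia subtypes, mirroring standard practice of
  not testing groups of n ≤ 9.
- No multiple-testing correction is applied, matching the study design the
  pipeline mirrors.

## Synthetic data

### Voxel phantoms

A phantom is a body ellipsoid (+40 HU) in a −1000 HU background, two lung
ellipsoids whose voxels are i.i.d. draws from a Gaussian mixture (default
`0.2·N(−980, 15) + 0.8·N(−850, 60)` — a low-attenuation mode over a
parenchymal mode, the simplest family producing the bimodal histogram shape
seen in lung CT), an optional walled airway (tracheal stem plus two
bronchial branches; lumen −1000 HU, 2.5 mm soft-tissue wall — without a wall
a region-growing removal would be ill-posed because the lumen would touch
parenchyma along its entire length), an optional linear ventro-dorsal
density gradient emulating hypostasis (default off), and global N(0, 5 HU)
noise. Defaults: 128³ voxels at 1 mm isotropic spacing (slice thickness
matching thin-slice densitometry protocols; in-plane spacing is an
assumption, as reconstruction matrices vary), chosen to keep the full suite
at desk-scale runtime. The generator validates that lungs keep a ≥ 2-voxel
soft-tissue shell to the body surface, otherwise the pleural cavity would
connect to ambient air and any air-based segmentation becomes ill-posed.

Ground truth is analytic: the lung HU distribution is the specified mixture
convolved with the noise (`effective_lung_mixture`), for which
`analytic_mixture_laa` evaluates the closed-form CDF and
`analytic_mixture_percentile` solves the quantile by bracketed root-finding
(tolerance 1e−6 HU; the mixture CDF is strictly increasing when any
component has positive sd, so the root is unique). Degenerate (sd = 0)
components contribute step functions. The analytic-recovery check uses a
176×176×208 grid so that the lung ellipsoids genuinely contain ≥ 10⁶ voxels
(two lung ellipsoids inside a body ellipsoid cannot reach 10⁶ voxels on a
128³ grid, whose inscribed body ellipsoid holds at most ~1.1·10⁶ voxels
in total); at that size the 3σ binomial bound on an LAA of ~20 % is about
0.12 pp, well inside the 0.5 pp acceptance band.

### Case-level cohorts

The cohort generator emulates a 20-asphyxia (subtypes allocated 9 hanging,
3 choking, 1 ligature strangulation, 4 manual strangulation, 3 smothering)
vs 21-control comparison. LAA endpoints are log-normal — LAA is bounded
below by zero and strongly right-skewed across subjects — calibrated to
published group statistics by matching the median exactly
(`μ = ln median`) and taking σ from the upper quartile. The lower quartile
is deliberately not used: the published quartiles are symmetric about the
median (no log-normal matches all three), and a lower quartile near the
zero bound (0.15 % for controls) is unstable on the log scale. Perc15 is
normal with mean = published median and sd from the IQR width; the choking
subtype carries a denser-lung Perc15 override (−605 HU median). Within a
case the endpoints are drawn comonotonically — one uniform per case, LAA
quantiles increasing, Perc15 quantile decreasing — which reflects their
physical coupling and enforces `LAA(−910) ≥ LAA(−950)` per case.
Demographics are truncated normals with published group means/SDs (age
truncated to the study's 16–80 inclusion window, PMI to (0, 5] days so the
default cohort passes its own inclusion filter). These distributional forms
are generator conventions, not claims about the source data.

What phantoms do **not** model: anatomy beyond ellipsoids and cylinders,
scanner physics, reconstruction kernels, inter-scanner variability, pleural
fluid, intrapulmonary vessels, or spatially correlated noise. Passing tests
therefore demonstrate correctness of the algorithms under the stated
distributional model, not segmentation robustness on real postmortem
anatomy — on real data the external-mask override exists precisely because
automatic thresholds can fail on pathology.

## Cohort filtering

Exclusion reasons are evaluated in a fixed priority order (PMI > 5 days;
age above 80; age below 16; penetrating chest injury; lung disease; severe
putrefaction; control-specific: causes of death that severely affect lung
density — exsanguination, burns, cold exposure, opioid intoxication — and
death following hospitalization/intensive care) and the first match is
logged per excluded case. The filter is idempotent.

## Determinism and reproducibility

All generators are pure functions of their spec (including an integer
seed) via `numpy.random.default_rng`; segmentation is deterministic; the
pipeline writes no timestamps into result files, so a fixed config and seed
reproduce byte-identical outputs. The run log records package version,
a hash of the scientific config (output paths excluded), the seed, and
per-case segmentation provenance (automatic vs supplied mask).

## Problem sizes used in validation

Chosen as the package's own test design: 1000 random arrays (lengths up to
10⁴) for oracle equivalence; one 176×176×208 phantom (~1.06·10⁶ lung
voxels) for analytic recovery; twenty randomized 128³ phantoms for
segmentation quality; all 66 group-size splits with n₁ + n₂ ≤ 12 for exact
rank-sum enumeration; 1000 replicates for type-I calibration; 500
replicates for cohort-generator calibration; six coarse phantoms for the
end-to-end reproducibility run.

## Known limitations

- The automatic segmentation assumes air-filled lungs surrounded by a
  watertight soft-tissue shell; severe consolidation, pneumothorax
  communicating with ambient air, or heavily putrefied anatomy will defeat
  it (use the mask override).
- The airway wavefront guard is tuned for tubular trees; extremely dilated
  airways could be truncated early, leaving lumen voxels in the mask.
- LAA/Perc15 conventions (strict cutoff, nearest-rank) match the package's
  documented definitions; other software may use non-strict cutoffs or
  interpolated percentiles, so absolute values can differ by up to one HU
  or the mass at the cutoff value.
- Cohort-level synthetic endpoints are drawn directly from calibrated
  distributions; they are not derived from the voxel phantoms, so
  cross-level consistency is only enforced where tested (the full-pipeline
  phantom runs).
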