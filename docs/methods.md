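# Methods

This note records the models implemented in `rsomskin`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical conventions. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Imaging model and conventions

Volumes are nonnegative scalar intensity fields on a regular grid with axis
order (depth, fast, slow), 0-based indices, and default spacing
(3, 12, 12) µm. Two co-registered bands are carried per subject: low
(10–40 MHz, large vessels) and high (40–120 MHz, small vessels). A "full
band" volume, where needed (surface detection, EP density, TBV), is the
unweighted sum of the two — the true 10–120 MHz reconstruction is not
recoverable from band volumes, and the sum preserves relative intensities,
which is all the 20 %-of-max TBV rule needs. The red/green display composite
(low → red, high → green) uses per-band max normalization and a high-band
weight; the default weight matches the two bands' 95th percentiles. The
composite never feeds biomarkers.

All depth intervals are half-open `[top, bottom)`. Flattening uses
integer-voxel shifts only, so intensities are exact and relative-intensity
thresholds are unaffected; flattening is idempotent and preserves total
intensity up to zero-fill at the borders.

## Surface detection

Per A-line: smooth along depth (5-voxel uniform filter), take the first depth
where the smoothed line exceeds f = 0.5 of its own maximum, then median
filter the lateral map (3 × 3). All-zero columns are filled with the lateral
median. The detector is a declared stand-in — the study delegates surface
detection to earlier system papers without parameters — and is validated only
on phantoms (flat and tilted surfaces recovered within one depth voxel).

## Epidermis segmentation

The low-band volume is split into four stacks along the slow axis (equal
counts of ⌈n/4⌉ slices, remainder shortening the last stack: 167 → 42, 42,
42, 41; exactly 0.5 mm each when the extent is 2.0 mm). Each stack's sagittal
MIP is segmented by an exact shortest path over columns: one node per pixel,
edges to the next column within ±1 row, edge cost `2 − (g(a)+g(b)) + ε` with
ε = 1e−5 and `g` the per-column min–max-normalized vertical gradient. Virtual
zero-cost start/end columns leave the endpoints free. The gradient is a
*backward difference*, so the dark→bright cost peak sits on the first
epidermis row and the bright→dark peak on the first dermis row: the epidermis
is exactly `[top, bottom)` and the dermis MIP starts on true dermis — with a
centered-difference gradient the bottom boundary lands on the last epidermis
row and the bright, ridged epidermis leaks into the dermis projection,
flooding the vessel analysis. The bottom path is searched ≥2 rows below the
top path to avoid degenerate coincidence. Boundaries are smoothed with an
11-column moving average and re-clamped to bottom ≥ top.

EP thickness is the mean over stacks of the mean per-column (bottom − top)
separation; EP signal density is summed epidermis intensity over epidermis
voxel count. The dynamic program is verified against exhaustive path
enumeration on 6 × 6 images.

## Dermis and vessels

The dermis slab is `[EP bottom, EP bottom + 1.5 mm)` per lateral position,
clipped with a warning on shallow grids. TBV is computed in 3D on this slab;
everything else runs on the per-band coronal dermis MIPs (junction markers in
the study are displayed on coronal projections, and 2D analysis is
deterministic); a consequence is that vessels crossing in projection create
junctions absent from the 3D truth.

Matched filter: zero-mean line kernels with Gaussian cross-section
σ = s/2.355/2 (kernel FWHM = half the nominal scale), length 3s, at 12
orientations over 180°, scales (15, 30, 45, 60, 90) µm; each kernel is scaled
so its positive lobe sums to 1, making responses comparable across scales
(≈ tube intensity at a matched center). The response is the max over scales
and orientations and is verified against dense correlation at sampled pixels.

Mask: Otsu on the positive responses detects components; each component's
boundary is then refined at the *image's* local half-maximum (background
median + 0.5 × (component peak − background), within a 2-pixel dilation of
the component). The refinement exists because the zero-mean response decays
faster than the intensity near tube edges and Otsu alone widens or narrows
masks by 1–3 pixels depending on vessel size; intensity half-max tracks the
blurred tube edge, keeping distance-transform diameters within one lateral
voxel for tubes ≥ 36 µm (verified over 36–90 µm at 0°, 22.5°, 45°). A
1-pixel closing follows; border components are kept.

Skeletons come from Lee's thinning — Zhang–Suen collapses some stair-stepped
diagonal tube masks to a point. Isolated skeleton components shorter than 5
pixels *with no junction* are removed; spurs attached to larger structures
stay (the rule targets isolated noise specks). The study text also mentions a
"~7 pixel" aside; the operative 5-pixel rule is implemented and exposed in
config. Junctions are skeleton pixels with ≥3 neighbours (8-connectivity),
with adjacent junction pixels merged into one cluster (thinning artifacts
otherwise double-count). Junction-free components do not add to the counts by
default (the literal junction-count rule); diameters are 2 × Euclidean
distance transform at the centerline (over- or under-reading up to half a
pixel per side with orientation). A junction is classified small/large by
the length-weighted mean diameter of its incident segments against the 40 µm
cutoff. Cohort-level counts mirror the band-to-size mapping: SVN from the
high-band network, LVN from the low-band network, TVN = SVN + LVN by default
(preserving svn + lvn = tvn exactly) with a config switch to count junctions
on the summed full-band MIP instead.

## Phantom generator

The phantom states a world: a flat or tilted skin surface (default 120 µm),
an epidermis slab of default thickness 105 µm with a cosmetic sinusoidal
intensity ridge (period 150 µm, relative amplitude 0.2 — excluded from all
biomarkers), and vessels as hard cylinders swept along polylines, rasterized
by point-in-cylinder tests against voxel centers, band-assigned by size.
Volumes are blurred by an anisotropic Gaussian PSF with σ = FWHM/2.355 of
the stated system resolutions (axial 4.5 µm, lateral 18.4 µm) and corrupted
by additive Gaussian noise clipped at zero (reconstructed intensities are
nonnegative; the study does not characterize its noise). Ground truth
(boundary surfaces, per-band masks, branch points as polyline vertices of
degree ≥ 3, TBV from rasterized counts over the analytic dermis slab) is
frozen *before* blur and noise. The ridge amplitude is dimensionless
(intensity modulation), a deliberate reading of the texture parameter. The
relative high/low band intensity scaling in real data is unknown and exposed
as `high_band_scale` (default 1).

What a green phantom test establishes: geometric recovery under the package's
own forward model. What it does not: performance under real speckle,
reconstruction artifacts, motion, melanin shadowing, or vessel networks of
realistic density.

## Synthetic cohorts

Healthy and pooled-diabetic biomarker distributions are the published
means ± SD. The severity subgroups (NC, LN, HN, NA) have no published
per-group values; their defaults were fixed once, before testing, by a normal
approximation power calculation so that (a) the published significance ladder
(healthy/NC at p < 0.01, NC/LN at p < 0.05, LN/HN at p < 0.001 for SVN) has
≥ 95 % power at the published group sizes (48/45/13/12), and (b) the
subgroup mixture stays near the published pooled diabetic values (e.g. SVN
mixture mean 2.94 vs published 3.45; TBV 1.48 vs 1.58). SVN defaults:
NC 5.2 ± 2.8, LN 2.4 ± 1.2, HN 0.35 ± 0.35, NA 0.3 ± 0.5. Biomarkers are
drawn untruncated by default (an optional clip-at-zero flag exists). One
published inconsistency is noted: the pooled diabetic EP thickness
(81.03 ± 23.06 µm) cannot arise from any mixture in which the NC majority
subgroup is *thicker* than healthy (the +7.2 % histology the study cites);
the generator follows the subgroup structure, so its pooled diabetic EP
thickness marginal sits near 97 µm. Covariates follow the published
Table-1-style summaries; healthy HbA1c is synthetic (N(5.4, 0.4), the normal
clinical range) because it was not recorded, keeping adjusted models
estimable. Group sizes use the grouping text (NA = 25, diabetic total 95)
over the figure caption's 24.

## Statistics

Two-sample comparisons gate on Shapiro–Wilk normality at α = 0.05 in both
groups: unpaired (equal-variance) t test if both pass, two-sided
Mann–Whitney U otherwise (exact null distribution when n₁n₂ ≤ 64 and no
ties, asymptotic with tie/continuity correction otherwise; verified against
exhaustive enumeration up to 8 vs 8). Stars: * p < 0.05, ** p < 0.01,
*** p < 0.001, exact at the boundaries. Identical constant samples return
p = 1. Spearman correlations use tie-corrected ranks; constant columns
report missing. Adjusted logistic regression is a statsmodels ML fit with
Wald tests; constant covariates are dropped with a warning and (quasi-)
perfect separation raises a diagnostic instead of diverging. The threshold
classifier predicts "diabetic" below the accuracy-maximizing threshold
(polarity fixed by the direction of the diabetes effect) and reports AUC by
the rank identity U/(n₁n₂) with midrank ties, verified against trapezoidal
ROC integration. Covariate selection for the multivariate models is exposed
as configuration (the study included univariately significant covariates,
which is data-dependent). No multiple-testing correction is applied,
matching the study. Type-I error of the adjusted logistic and Spearman
pipelines is checked by null simulation (rejection rate within [0.02, 0.09]
at α = 0.05).

## Known limitations

- 2D vessel analysis merges depth-separated vessels that cross in
  projection; TVN can exceed the 3D branch count.
- Diameter estimates are quantized to the 12 µm lateral grid (±1 voxel);
  sub-24 µm vessels are detected but their widths saturate at 1–2 pixels.
- The TBV threshold rule counts PSF-widened tube voxels, so phantom TBV
  reads high by up to ~2× for thin vessels; the rule is intensity-scale
  invariant but not blur invariant.
- The surface detector and the DP edge-cost constants stand in for cited
  system papers whose parameters are not public; all constants live in
  `PipelineConfig`.
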