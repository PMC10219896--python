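# Methods

## Signal model and estimators

The package assumes mono-exponential transverse decay of the spin-echo
magnitude signal,

    S(TE) = ρ · exp(−TE / T2_app),

sampled at two echo times (TE₁ = 14 ms, TE₂ = 86 ms by default).  Inverting
the model at two points gives the two-point estimators

    T2_app = (TE₂ − TE₁) / ln( SI(TE₁) / SI(TE₂) )        [ms]
    ρ      = SI(TE₁) / exp(−TE₁ / T2_app)                 [a.u.]

`T2_app` is "apparent" because two-point estimation over a heterogeneous
voxel population folds multi-compartment decay, stimulated echoes and B1
effects into a single effective constant; none of those are modeled here.

**ROI-first estimation.**  `SI(TE)` is the arithmetic mean of the masked
nerve pixels of a slice, computed *before* the formulas are applied.  At
the in-plane resolution nerve imaging requires (≈0.33 mm), single-pixel SNR
is too low for stable pixel-wise maps; averaging first makes the log-ratio
estimator operate at ROI-level SNR.  A pixel-wise mode (estimate per pixel,
then average) exists for testing; on a noise-free homogeneous ROI the two
agree to floating point, which the suite asserts.

**Non-physical slices.**  Under noise a slice can yield
`SI(TE₁) ≤ SI(TE₂)`, for which no positive T2 exists.  Such slices are
flagged (`valid = False`, T2/ρ = NaN), excluded from region denominators,
and counted; they are never silently dropped.  Regions with more than 20%
flagged slices emit a warning, and a region with no valid slice raises.
With the default noise level flagged slices are essentially absent (nerve
ROI SNR ≈ 50 at TE₁, ≈ 16 at TE₂).

**Morphometry.**  CSA is foreground pixel count × pixel spacing², with no
sub-pixel contour integration: the mask's boundary convention (epineurium)
is the segmentation's responsibility, not the measurement's.

## Slab layout and aggregation

The default protocol covers the left leg with four contiguous slabs of 35
axial slices (140 slices, proximal thigh → tibiotalar joint), 3.5 mm thick
with a 0.35 mm gap, 170 mm FOV on a 512 matrix (pixel spacing
170/512 ≈ 0.332 mm; a nominal 0.3 mm voxel quoted for such protocols is
this value rounded).  Slice indices are 0-based and increase proximal →
distal; slab k owns the half-open range [35(k−1), 35k).  A fifth slab
mirrors slab 2 on the right leg for side comparisons.

Regions: thigh = slabs 1–2, lower leg = slabs 3–4 (disjoint, jointly
covering all 140 slices), left/right mid-thigh = slab 2 / slab 5.  Region
means are unweighted arithmetic means over the region's valid slices —
not slab-then-region nesting; with equal slab sizes and no flagged slices
the two readings coincide, and the flat mean is the simpler contract.
The proximal-to-distal gradient of a marker is the signed thigh-minus-lower
difference of region means.

## Synthetic cohort generator

The generator exists so every downstream stage can be exercised, and its
defaults *are* the study conditions the package targets: 35 cases (RRMS)
vs 30 healthy controls, with per-group region-level means

| marker | cases thigh / lower | controls thigh / lower |
|---|---|---|
| T2_app (ms) | 66.1 / 62.1 | 69.9 / 67.5 |
| ρ (a.u.) | 473.2 / 461.2 | 410.1 / 418.0 |
| CSA (mm²) | 17.3 / 9.1 | 15.1 / 8.5 |

i.e. lower T2_app and higher ρ in cases at both locations, a positive
T2_app gradient in both groups, no consistent ρ gradient, and a thigh-only
CSA increase.  Between-participant SDs are back-computed from group
standard errors as SEM × √n (3.3–5.5 ms for T2, 33–72 a.u. for ρ,
1.6–2.4 mm² for CSA).  Only the SEM is observable at the group level, so
this back-computation assumes between-participant variance dominates
within-participant slice scatter; the generator accordingly draws one value
per participant × region and keeps it constant across that region's slices
(a piecewise-constant profile — the simplest shape whose region mean equals
the drawn value exactly, which is what makes exact mean recovery testable).
The contralateral slab 5 is an independent draw from the same thigh
distribution, so side differences are null by construction.

**Geometry.**  The nerve is a filled disc on a homogeneous muscle-like
background (T2 = 35 ms, ρ = 380 a.u.; fat suppression is assumed perfect,
so no fat compartment).  The disc center sits at a fixed *generic*
sub-pixel offset from the FOV center (plus optional per-participant
jitter, ±4 mm by default).  A generic center breaks the square lattice's
symmetry, making all pixel-center distances distinct, so the rasterizer
can realize any integer pixel count; the radius for a drawn CSA is found
by sorting pixel-center distances and cutting between the k-th and
(k+1)-th, which matches the rendered area to the drawn CSA within half a
pixel (0.055 mm² at the full matrix).  A symmetry-aligned center can only
change the count in jumps of 4–8 pixels (worst-case area error
≈ 0.45 mm²).  The recorded ground-truth CSA is the drawn value; the mask
is exactly the rendered disc.

**Noise.**  Magnitude images get Rician noise: each pixel v becomes
√((v+g₁)² + g₂²) with independent zero-mean Gaussians of scale σ.  The
default σ = 8 a.u. puts per-pixel SNR near 50 at TE₁ in nerve (≈ 16 at
TE₂), where the Rician bias of the ROI-mean estimator is negligible
(σ²/2v ≈ 0.25 a.u. at TE₂).  σ = 0 bypasses the sampler entirely, giving
bit-exact noise-free runs.

**Clinical covariates** mirror the two groups' demographics (age ≈ 37,
balanced sex, matched weight/height), and for cases only: EDSS (drawn on
the half-point grid, truncated to [0, 10]), symptom duration in months
(log-normal with median 60 and log-SD 1, truncated to [5, 330] — mean
≈ 98 months with ≈ 29% of cases under 3 years), and ten nerve-conduction
values (tibial/peroneal CMAP, NCV, F-wave, DML; sural SNAP, NCV),
truncated positive.  Covariates are drawn independently of the imaging
markers, so all marker–covariate correlations are null in synthetic
cohorts; correlation machinery is therefore tested for calibration, not
for effect recovery.

**What the generator does not emulate:** real nerve anatomy (fascicles,
vessels, bone), B1/coil inhomogeneity, k-space effects, motion, partial
volume at the nerve boundary, within-participant slice-to-slice biological
variation, and any true marker–covariate coupling.  Passing recovery tests
therefore demonstrate the correctness of the estimators and plumbing under
the stated model — not robustness to those real-data effects.

## Statistical plan

Two-group comparisons use the Mann-Whitney U test, two-tailed: exact
distribution when the smaller group has ≤ 8 observations and the pooled
sample is tie-free, otherwise the normal approximation with tie and
continuity corrections (scipy).  The reported U is the smaller of the two
group statistics.  When U₁ = U₂ the two-sided p is exactly 1 by symmetry;
this is special-cased because the continuity-corrected approximation
returns p < 1 there.  Proximal-vs-distal comparisons reuse the unpaired
Mann-Whitney test even though the data are participant-paired, mirroring
common practice in this literature; a paired Wilcoxon signed-rank
alternative is available behind `paired_locations=True`.

Correlations are Pearson product-moment coefficients with two-tailed p via
the t transform; sex is coded 0/1 (point-biserial).  They are computed
within the case group, where the clinical and electrophysiologic
covariates exist.  The duration-split analysis partitions cases at 36
months ("less than 3 years" is strict: exactly 36 months is long) and runs
a one-way fixed-effects ANOVA per marker × region over
{controls, short-duration cases, long-duration cases}, with Tukey HSD post
hoc pairs — a conventional default, recorded in the output metadata.  No
multiple-testing correction is applied; the total number of tests is
reported instead.  Descriptives are mean ± SEM throughout.

## Numerical and design choices

- Two-point inversion is exact algebra; the suite requires < 1e-10
  relative round-trip error through full image rendering, which in
  practice comes out near machine precision.  Volumes are float64 for this
  reason.
- The T2w signal is defined as the ROI mean of the TE₂ image (the
  T2-weighted contrast of the pair); values land in the same ~110–130 a.u.
  range as reported semiquantitative nerve signal.
- Region means bound their inputs (mean containment) and are permutation
  invariant; both are property-tested.
- Degenerate statistics: empty groups, < 3 correlation pairs, zero
  variance, and missing case durations raise typed errors; zero rank
  variance in Mann-Whitney yields p = 1.
- Determinism: every stochastic element flows from one integer seed
  through `numpy.random.SeedSequence` spawning (one child per
  participant), so cohorts are bit-reproducible and participants are
  independent of cohort size ordering.
- Problem sizes in the test suite are scaled to keep the full run around a
  minute of compute: recovery and calibration tests use 64–128 matrices
  and 1–2 slices per slab (the estimators are resolution-independent on
  homogeneous ROIs), CSA recovery uses the full 512 matrix where one pixel
  is 0.11 mm², and the power Monte-Carlo runs 200 seeded cohorts at the
  default 35-vs-30 group sizes on the reduced grid.

## Known limitations

- Two echoes determine the mono-exponential fit exactly, so goodness of
  fit is unobservable; multi-echo relaxometry is out of scope.
- CSA at coarse simulation matrices is heavily quantized (one pixel at a
  64 matrix is 7 mm²); CSA-sensitive work should use the full matrix.
- The side-comparison unit is the participant's slab mean; summed (rather
  than averaged) per-slab CSA conventions reported elsewhere are not
  implemented.
- The generator's homogeneous background makes segmentation trivially
  easy; it cannot be used to validate segmentation algorithms.
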