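# Methods

## DOPU and depolarizing-RPE segmentation

The per-pixel Stokes components (Q, U, V) are divided by the intensity I,
averaged over a rectangular window confined to each B-scan, and DOPU is the
Euclidean norm of the averaged vector, clamped to [0, 1]. Averaging is an
unweighted mean of the intensity-normalized components, not an
intensity-weighted mean; with fully polarized per-pixel states the
normalized vectors are unit vectors and DOPU is the resultant length of a
set of directions — exactly 1 for a uniform set, tending to ~N^(-1/2) for N
independent random directions. Windows are truncated at image edges (no
synthetic padding); pixels with zero intensity do not contribute, and a
voxel whose whole window is dark is invalid (NaN) and never classified.

A voxel is depolarizing RPE when it is valid, its intensity reaches the
noise floor, and DOPU < 0.8 **strictly**. The floor defaults to the mean
plus two standard deviations of the top (vitreous-side) 10% of each B-scan,
because DOPU computed from noise-level signal is meaningless; the floor is
exposed as a parameter.

Defaults: window 9 px (axial) x 9 px (lateral) at the full acquisition
sampling (512 A-scans x 128 B-scans x 256 depth, 6.2 x 6.7 mm). No
averaging across B-scans: the slow axis is sampled too sparsely for a
cross-B-scan window to be meaningful. For the down-sampled simulation
profile (128 x 64 x 128, same field of view) the window is scaled with the
sampling to 3 x 3 so its physical footprint stays comparable; this is the
profile used throughout the test suite and the acceptance script, chosen so
a full 31-eye cohort runs in well under a minute on one CPU.

**Window convolution.** Because DOPU mixes a window of pixels, the
segmented band is systematically wider than the true depolarizing layer
(about half a window on each axial side) and atrophic gaps are narrower
(about one lateral pixel per side at the 3 x 3 profile). This is a real
property of DOPU imaging, not an artifact of the phantom; it is why
measured GA areas sit a few percent below planted truth and why a lesion
planted exactly at the 0.1 mm² detection floor may fall below it.

## Evaluation band and GA quantification

The evaluation band reproduces the semi-automated exclusion of
sub-RPE/choroidal depolarization. Automatically, each A-line's band is the
depth centroid of the depolarizing mask ± margins (default 12 px up and
down at 128-depth sampling — wide enough to cover a 3x-thickened band,
narrow enough to exclude planted choroidal speckle), with the centroid
profile smoothed by a 31-A-line running median and holes (fully atrophic
A-lines) interpolated from flanking A-lines. Manual per-B-scan overrides
are supplied as an explicit YAML file, keeping "semi-automated" runs
reproducible.

The thickness map counts depolarizing pixels per A-line within
[upper, lower). A cell is atrophic when its count is at most
`atrophy_count_max` (default 0: atrophy is the absence of depolarizing
RPE). Smoothing is a 3 x 3 median filter followed by closing then opening
with a disc of radius 1 px; the binarization cutoff, smoothing operator and
connectivity are design choices, since only "binarized and smoothed" is
specified by the imaging protocol. GA lesions are 8-connected atrophic
patches with area = pixel count x en-face pixel area (anisotropic pixels
used as-is, ~12 x 52 um at full sampling); patches below the 0.1 mm² floor
are retained as sub-threshold components for the focal-atrophy rule rather
than discarded.

## Lesion rules

Per B-scan, on the thickness-map row, with `normal` = median of non-zero
counts (median is robust to a few percent of thickened or thinned cells):

* gap — run of ≥ 3 consecutive A-lines with count ≤ `atrophy_count_max`;
* porosity — ≥ 3 gaps, ≥ 2 interleaved residual runs, cumulative gap width
  ≥ 20% of the B-scan ("series of gaps" is operationalized as a count of 3
  and 2 residuals; cumulative rather than contiguous width, both
  configurable);
* focal atrophy — a gap whose en-face A-lines intersect a sub-threshold
  atrophic component;
* thinning — contiguous run with 0 < count < 0.5 x normal over ≥ 10% of the
  B-scan (strictly below half; count 0 is a gap, not thinning);
* accumulation — contiguous run with count ≥ 2 x normal over ≥ 5 A-lines.

Width thresholds flip exactly at ceil(fraction x n_ascans), computed with a
tolerance so that printed-percentage boundaries are exact despite binary
floats. Ectopic foci are 26-connected depolarizing components lying
entirely ≥ 5 px above the band's upper bound with ≥ 3 voxels; sharing any
connected path with an in-band component disqualifies them. An eye-visit is
positive for a type when any B-scan is positive (ectopic and GA are
volume-level). The pixel minima (3/5/5/3) suppress single-pixel noise and
are configurable.

## Cohort statistics

Prevalence is exact counts and percentages per visit and type. GA-area
summaries run only over eyes with detected GA; a visit without GA is
reported as absent, not zero. Paired t is the classical two-sided test on
per-eye differences (identical samples give t = 0, p = 1; a non-zero
constant difference is rejected as degenerate). Cohen's κ is computed on
the 2 x 2 presence table with a Fleiss-type large-sample standard error and
a normal-approximation 95% CI clipped to [-1, 1]; the all-agree
single-category case returns κ = 1 with a degeneracy flag. κ on presence
tables is used throughout; Spearman correlation (mid-ranks) compares graded
GA areas between parameterizations.

## The phantom

Each voxel is fully polarized per pixel; depolarization arises from spatial
randomness of the polarization direction, which is the physical mechanism
in melanin-bearing tissue. Non-RPE tissue carries a common incident Stokes
direction; RPE voxels carry a direction slerped from the incident direction
towards an independent uniform random direction with weight
`depol_strength` (default 0.9), the simplest model whose window-averaged
DOPU decreases monotonically with the weight. Additive Gaussian noise
(default sd 0.005) on Q, U, V is followed by rescaling so that
sqrt(Q²+U²+V²) ≤ I everywhere. The axial intensity profile is vitreous 0.05
/ retina & RPE 1.0 / choroid 0.4, enough contrast for the vitreous-based
noise floor; the choroid is polarization-preserving by default (choroidal
depolarization is planted explicitly where a test needs it).

Lesions are planted as en-face footprints with known geometry: GA patches
are circular in mm (elliptical in the anisotropic pixel grid) with analytic
area pi r²; focal atrophy, thinning (thickness factor 0.25) and thickening
(factor 3, grown symmetrically about the band center) are rectangles; gap
series plant n gaps of fixed width separated by residuals; ectopic foci are
3 px cubes planted 25 px above the band. A thickening factor of 3 is used
in cohorts so that the ≥ 2x rule fires on the measured counts despite the
additive window widening (which inflates thin and normal bands by the same
amount and would otherwise defeat a planted exact-2x lesion). Ground truth
(label map, per-B-scan expected grades obtained by applying the same rule
definitions to the true thickness rows, lesion records) is a function of
the phantom specification alone and is bit-for-bit invariant to the noise
seed.

What the phantom does **not** emulate: speckle statistics and the optical
point-spread function, nerve-fiber-layer birefringence, pigment-epithelial
detachment curvature (beyond a configurable band offset), eye motion and
inter-visit registration error, and the raw-signal statistics of the
instrument (unpublished). Passing tests therefore demonstrate correctness
of the algorithm chain under idealized optics, not clinical performance on
patient data.

## The month-24 cohort fixture

`fixtures/cohort_month24.yaml` defines 31 eyes at a single month-24 visit
whose manifests encode the study's reported prevalence: 19 eyes with a GA
patch (61%), 20 with porosity (65%), 30 with focal atrophy (97%), 3 with
thinning (10%), 8 with thickening (26%), 16 with ectopic foci (52%), one
eye fully unaffected. The GA areas (`fixtures/ga_areas_month24.txt`) hit
the printed mean 1.10 mm² and range 0.14–2.58 mm² exactly, with sample SD
1.10 (printed: 1.09); all but the smallest lesion are kept at ≥ 0.30 mm² so
they stay comfortably detectable on the down-sampled grid, and a single
lesion sits at the printed 0.14 mm² minimum, at the algorithm's detection
floor. CRT and BCVA values are drawn once around the study's month-24
means (323.9 um, 56.3 letters) and shipped as static data. Everything in
the fixture is synthetic; no patient data exist in this repository.

Recovered quantities at the 3 x 3 window profile: porosity 20/31 = 64.5%
(printed 65%), focal atrophy/thinning/accumulation/ectopic prevalence exact,
GA 18/31 = 58% with the 0.14 mm² lesion lost to the floor (printed 61%),
mean detected GA area ~1.05 mm² (printed 1.10), the shortfall being the
~1-pixel margin erosion discussed above.

## Numerical choices and degenerate inputs

* Truncated window means are computed as box-sum / valid-pixel count via a
  constant-padded uniform filter; agreement with an explicit loop oracle is
  within 1e-6 (float32 inputs).
* Band bounds are clipped to the axial range; an empty mask with no manual
  override is an error, as is a zero-length grading row, an all-zero
  thickness map, or fewer than 5% of cells for the normal-thickness
  estimate.
* Lesion ordering: area descending, ties by top-left-most pixel, so outputs
  are deterministic.
* Cohort generation derives one child seed per (eye, visit) from the cohort
  seed via a seed sequence; identical (spec, seed) reproduce volumes
  byte-for-byte.

## Known limitations

Measured GA areas carry a systematic negative bias of roughly one lateral
pixel of margin erosion per side (window convolution); lesions within one
pixel-perimeter of the 0.1 mm² floor may drop below it. The band fit
assumes one dominant depolarizing layer per A-line; a bright ectopic focus
column is handled by the running median but pathologies dominating whole
B-scans would need manual overrides. Agreement statistics between two
parameterizations of the same pipeline are a reproducibility check of the
chain, not a model of human inter-grader disagreement.
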