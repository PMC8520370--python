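# Methods

## Model and procedure

### Tsallis threshold selection

The segmentation core treats an image as a sample from a discrete
gray-level distribution on L levels (default 256) and selects the
threshold maximizing the combined Tsallis entropy of the two classes it
induces. For q ≠ 1 the entropy of a distribution p is
S_q(p) = (1 − Σ pᵢ^q)/(q − 1); within a numerical tolerance |q − 1| < 1e−9
the implementation switches to the Shannon form −Σ pᵢ ln pᵢ, which is the
analytic limit. Zero-probability entries contribute nothing.

At a candidate threshold t, class A (levels 0…t) and class B (levels
t+1…L−1) are renormalized by their masses P_A and P_B and their entropies
combined. The default combination is the pseudo-additive Tsallis
composition S_A + S_B + (1 − q)·S_A·S_B — the form under which Tsallis
entropy composes for independent systems and the standard total-entropy
objective in non-extensive thresholding. A `plain_sum` rule is available
for comparison; at q = 1 the two coincide.

Thresholds leaving either class empty are *inadmissible* and skipped
rather than assigned −∞, keeping the objective curve well defined.
Admissibility is decided from integer occupancy counts, not from floating
class masses, so an empty class can never appear occupied through
cumulative-sum rounding. Ties in the objective (within a relative 1e−12)
break toward the smallest threshold, making outputs deterministic.

### The 2D variant

The 1D objective uses no spatial information and degrades under voxelwise
noise. The 2D variant histograms each pixel jointly with the rounded
arithmetic mean of its w×w neighborhood (default w = 3, reflect-padded;
w×w×w in 3D). Homogeneous-region pixels concentrate near the diagonal
i = j; noise spikes and boundary pixels fall off it. The search maximizes
the combined entropy of quadrant A = {i ≤ s, j ≤ t} and quadrant
B = {i > s, j > t} over all pairs (s, t), using 2D cumulative-sum tables so
the sweep is O(L²) after O(L²) setup. The two off-diagonal quadrants are
ignored under the default policy, each class being renormalized within its
own quadrant; an alternative `joint` policy renormalizes both classes by
the total retained mass. The local-mean second axis and the
ignore-off-diagonal policy are the canonical constructions in
two-dimensional entropy thresholding; both are exposed as configuration.

Mask generation requires a foreground pixel to exceed both thresholds
(value > s and neighborhood mean > t). Polarity follows hyperintense
lesions (T2/DWI); `invert` selects hypointense targets.

### Entropic index q

q is a free parameter of the method ("non-extensiveness"); no canonical
value exists for brain MRI. The package default is q = 0.8 — a mildly
sub-extensive choice that weights low-probability histogram tails more
than Shannon entropy and is a common operating point in Tsallis
thresholding practice. On the synthetic phantoms used in the test suite
the selected threshold is insensitive to q across {0.5, 0.8, 1, 2, 4};
the default is therefore not load-bearing for the shipped results, and it
is exposed everywhere (`TsallisThresholder(q=...)`, `--q`).

### Segmentation pipeline

The full pipeline is: quantize → select threshold(s) → binarize →
suppress foreground components smaller than `min_size` (default 5 voxels)
→ label components (default full connectivity: 8-connected in 2D,
26-connected in 3D) → shape descriptors. Speck suppression is part of the
default output because maximum-entropy thresholds on noisy images sit
partway into the background tail, leaving isolated suprathreshold pixels
that are not lesions under any reading; `min_size=0` disables it. The
phantom-recovery checks in the test suite accordingly evaluate the
pipeline output, while the 1D-versus-2D noise-robustness comparison is
made on raw threshold masks so that post-filtering does not confound the
contrast between the two selection methods.

Circularity is 4π·area/perimeter² with the Crofton 4-direction perimeter
estimator, which is near-exact on digital disks and does not collapse on
one-pixel-wide shapes the way exposed-edge counting does; in 3D the
sphericity analog π^(1/3)(6V)^(2/3)/A uses exposed-face surface area.
Elongation is the square root of the ratio of principal second moments,
with each voxel contributing a unit-cube self-moment (1/12 per axis) so
single voxels and one-voxel-wide bars remain well defined (both examples
are exercised in the tests). Single-voxel components are defined as
circularity 1, elongation 1.

## Quantification layer

### ADC

ADC maps use the two-point mono-exponential decay
ADC = ln(S_low/S_high)/(b_high − b_low), the universal clinical estimate
for a paired b = 0 / b = 1000 s/mm² acquisition, reported in 10⁻³ mm²/s.
Voxels with non-positive signal are invalid (NaN) and excluded from ROI
statistics; negative ADC values from noise (S_high > S_low) are returned
as computed but are physically suspect. ROI statistics use the sample SD
(n − 1).

### Mann-Whitney U

The group comparison is a two-sided Mann-Whitney U test with midranks for
ties. The exact method defines the p-value as the proportion of all
C(n₁+n₂, n₁) group labelings whose U deviates from the null mean n₁n₂/2
at least as far as observed. For tie-free data this distribution is
evaluated by the classical rank-sum dynamic program (cached per sample
size); with ties the labelings are enumerated directly. Both routes are
limited to n₁+n₂ ≤ 20; beyond that the tie-corrected normal approximation
with continuity correction applies. For tie-free data the exact p-value
agrees with scipy's exact implementation to machine precision, which the
test suite uses as an independent cross-check; identical pooled samples
return U = n₁n₂/2, p = 1. Two-sided testing at α = 0.05 throughout.

### Reference cohort

The packaged cohort encodes a 15-patient posterior-fossa PCNSL case
series: 11 M / 4 F, 12 DLBCL / 3 Burkitt, 10 single- and 5 multiple-lesion
patients, 25 lesions with location counts (15 cerebellar
hemisphere/vermis pooled, 2 midbrain, 2 cerebellopontine angle, 1 fourth
ventricle, 5 supratentorial), enhancement 17 mass/nodular, 4 striped,
3 patchy, 1 ring, 24 solid / 1 cystic, paired radiological signs on 8
lesions, peritumoral edema on 12, T1 22 low-or-slightly-low / 3
intermediate, T2 20 / 3 / 2, DWI 5 homogeneous-high / 2 uneven-high /
3 intermediate among 10 scanned, and MRS lipid peak 2 present / 2 absent
among 4 examined. Only these marginal counts are contractual: the source
tabulations do not cross-tabulate attributes, so the assignment of
attributes to individual records (and the hemisphere/vermis split within
the pooled 15) is a deterministic but arbitrary choice. Per-patient ADC
values were never published — only group summaries (tumor 0.62 ± 0.095,
contralateral 0.73 ± 0.038 × 10⁻³ mm²/s, n = 10) — so patient records
carry no individual ADC values and the group test on real data is not
reproducible at the individual level; the acceptance computation instead
simulates individuals from the group parameters.

## Synthetic data

Phantoms are piecewise-constant lesion-on-background rasters. The four
morphologies operationalize the cohort's qualitative vocabulary as test
fixtures, not clinical claims: *round* is a digital ball; *irregular* a
ball with a seeded smooth radial perturbation (2–5-cycle Fourier modes,
5–18% amplitude); *nodular* a cluster of 2–4 small balls; *patchy* a union
of 4–7 overlapping anisotropic blobs. Ground truth is the noiseless union
of lesion supports. Noise is additive Gaussian or Rician — the magnitude
of (signal + complex Gaussian), the correct MRI magnitude-noise model,
which biases dark regions upward. Defaults (128×128 raster, background
60, one round lesion of radius 20, contrast 80) give a lesion fraction of
about 8%, comparable to a conspicuous cerebellar lesion on a single
slice. The noise conditions exercised by the tests are contrast/σ = 8
(σ = 10) for recovery and contrast/σ = 4 (σ = 20) for the 1D-vs-2D
robustness comparison.

ADC cohort simulation draws independent normals per group with the
reference group parameters as defaults, truncated at zero by redrawing
(negligible at these parameters, but avoids the point mass clipping would
create). Randomized cohort tables honor a marginal-count specification
exactly while shuffling assignments by seed.

What passing phantom tests do *not* show: performance on real MRI with
bias fields, partial-volume boundaries, anatomy-correlated intensity
structure, or multi-class histograms; the phantoms are two-class by
construction. No claim is made that the thresholds selected on phantoms
transfer to clinical images without tuning.

## Numerical choices

- Quantization is global min–max onto [0, L−1] with round-half-even;
  constant inputs map to all zeros and are flagged. An optional percentile
  clip (p_low, p_high) is available because MRI intensity outliers
  otherwise compress the histogram; it defaults to off.
- The Shannon branch activates at |q − 1| < 1e−9; continuity at the
  boundary is verified to 1e−4 in the tests.
- Probability-vector contracts tolerate |Σp − 1| ≤ 1e−9 at the entropy
  level and 1e−12 at the histogram level.
- Tie-breaks: smallest t (1D), lexicographically smallest (s, t) (2D),
  within a relative 1e−12 tolerance; component ids follow raster-scan
  order of first voxel.
- Degenerate inputs: constant images raise a no-threshold error rather
  than returning an arbitrary cut; empty ROIs and all-invalid ADC regions
  raise statistics errors.

## Problem sizes

The shipped tests and the acceptance computation run at deliberately
modest sizes chosen to exercise the method's regimes: 128×128 phantoms
(10 seeds at 8σ recovery, 50 at the 4σ comparison), random histograms at
L ≤ 64 (1D) and L ≤ 16 (2D) against brute-force references, 1000
replicates of the n = 10 + 10 ADC simulation, and 2000 permutation-null
replicates at n₁ = n₂ = 6 for type-I validity.

## Known limitations

- Two-class thresholding only; multi-level extension is out of scope.
- The 2D search is exhaustive (with cumulative-sum acceleration), not
  metaheuristic; L = 65536 inputs should use the histogram bin-reduction
  path (quantize to fewer levels) first.
- The exact Mann-Whitney route is capped at n₁+n₂ ≤ 20 by enumeration
  cost; the normal approximation beyond that is standard but approximate.
- DICOM series, registration, and bias-field correction are explicitly
  not handled; inputs are PNG (2D) or NIfTI (3D).
- The reference cohort's record-level attribute assignments are arbitrary
  beyond their marginals, and the multiplicity/ADC structure of the
  original series constrains only what is encoded here.
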