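# tsallisseg

Maximum-Tsallis-entropy threshold segmentation and lesion quantification for
MRI-like grayscale images.

Primary central nervous system lymphoma (PCNSL) in the posterior cranial
fossa is rare, frequently misdiagnosed, and reads on MRI as hyperintense,
diffusion-restricted lesions against brain parenchyma. This package provides
the computational side of that workflow for researchers working with such
images (or any two-class grayscale segmentation problem): entropy-based
threshold selection to delineate lesions, connected-component quantification
of their number and shape, ADC (apparent diffusion coefficient) maps from
paired diffusion-weighted acquisitions, and the nonparametric group
comparison of tumor versus contralateral-parenchyma ADC values. Because no
images from the motivating case series are publicly deposited, the package
ships a synthetic-phantom generator and a fully encoded reference cohort so
every component is testable end to end.

## Method

For a gray-level histogram {p₁, …, p_L}, the Tsallis (non-extensive)
entropy with entropic index q > 0 is

    S_q(p) = (1 − Σᵢ pᵢ^q) / (q − 1),

recovering Shannon entropy −Σ pᵢ ln pᵢ as q → 1. A threshold t splits the
histogram into target A (levels ≤ t) and background B (levels > t) with
class masses P_A = Σ_{i≤t} pᵢ and P_B = 1 − P_A; each class is renormalized
and its entropy S_q^A, S_q^B computed. The selected threshold maximizes the
pseudo-additive total

    S_q(t) = S_q^A + S_q^B + (1 − q) · S_q^A · S_q^B,

swept exhaustively over all t leaving both classes non-empty (a plain sum
is available as an alternative combination rule; default q = 0.8).

The 1D criterion is sensitive to voxelwise noise, so a 2D variant
thresholds the joint histogram of (gray level i, 3×3-neighborhood mean j)
at a pair (s, t): class A is the quadrant {i ≤ s, j ≤ t}, class B is
{i > s, j > t}, and the off-diagonal quadrants — mostly noise spikes and
region-boundary pixels — are excluded from both classes. Cumulative-sum
tables keep the full (s, t) sweep at O(L²). A foreground voxel must then be
bright *and* locally bright (value > s and neighborhood mean > t), which
rejects isolated noise.

Downstream, ADC maps follow the standard two-point mono-exponential model
ADC = ln(S_b0 / S_b1000) / (b₁ − b₀) (reported in 10⁻³ mm²/s), and group
comparison uses an exact two-sided Mann-Whitney U test: the permutation
p-value over all C(n₁+n₂, n₁) group labelings, with midranks for ties and a
tie-corrected normal approximation for larger samples.

## Worked example

```python
from tsallisseg import (
    PhantomSpec, TsallisThresholder, dice, generate_phantom,
    quantize, suppress_specks,
)

raw, truth = generate_phantom(PhantomSpec(sigma=10.0, seed=1))  # noisy disk lesion
img = quantize(raw, 256)

est = TsallisThresholder(method="2d", q=0.8).fit(img)
print(est.threshold_, est.mean_threshold_)      # 130 126
mask = suppress_specks(est.predict(img))
print(round(dice(mask, truth), 4))              # 0.9992
```

The estimator selects gray-level threshold 130 and neighborhood-mean
threshold 126 on the 256-level quantized phantom; the resulting mask
overlaps the ground-truth lesion with Dice 0.9992. The same run from the
shell:

```sh
tsallisseg segment --input demo.png --output mask.png --method 2d --report report.json
```

writes the mask and a JSON report containing the thresholds, the entropy
objective, and one row per detected component — here a single lesion of
1255 pixels with circularity 0.991 and elongation 1.000, i.e. a round
lesion in the cohort's morphology vocabulary.

The packaged reference cohort reproduces the case series' tabulations:

```sh
tsallisseg summarize --fixture reference
# ... "n_patients": 15, "n_lesions": 25, "enhancement": {"mass_nodular": 17, ...}
```

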