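# Methods

This note documents the model behind `dopaquant`, the conventions chosen
where the procedure leaves details open, what the synthetic phantoms do and
do not establish, and the package's known limitations.

## Problem and assumptions

The package computes tumor-to-normal (`t_n`) and tumor-to-striatum (`t_s`)
uptake ratios from [18F]F-DOPA PET of pediatric diffuse gliomas, mimicking
the manual SUVr routine but with data-driven reference regions. Three
assumptions underpin the design and are required of the input:

* the glioma shows **increased** F-DOPA uptake relative to parenchyma;
* the lesion volume is **small** relative to the brain, so lobe-level
  intensity statistics of the contralateral hemisphere represent healthy
  tissue;
* the lesion is **monolateral**, so one hemisphere can serve as reference.

Inputs are PET, FLAIR and an integer label atlas (five lobes + striatum per
hemisphere, pons, background) on one shared grid. Registration into that
space is an external precondition: it is mature standard tooling, and
nothing in it is specific to this method. Intensities are treated as
relative activities; both scores are ratios, so dose/weight calibration and
global scanner scaling cancel exactly (verified to 1e-12 relative in the
tests).

## Lateralization

FLAIR is parcelled into ~`k_districts` (default 300) districts with SLIC
supervoxels — a K-means in (intensity, position) with deterministic grid
initialization — followed by a 26-connected-component split so districts
are guaranteed connected, and a merge of sub-2-voxel fragments. A plain
intensity-only K-means was considered and rejected: its clusters are not
spatial, and splitting them into components yields either a handful of
districts (clean images) or thousands of noise speckles, never a stable
~300; the supervoxel formulation is the established way to make an
intensity-based K-means spatial.

Each district is summarized by 14 intensity statistics (in fixed order:
mean, SD, variance, mean/median absolute deviation, skewness, kurtosis,
max, min, median, mode, range, IQR, entropy). Conventions, since names
alone do not fix formulas: SD/variance use n−1; skewness and excess
kurtosis are the plain moment (Fisher–Pearson / Fisher) estimators, defined
for districts as small as 2 voxels and set to 0 for constant districts;
entropy is the Shannon entropy (bits) of a 32-bin histogram over the
district's own range; the mode is the mean of the values in the most
populated of those bins, smallest bin on ties.

A linear-kernel SVM (C = 1) over z-scored features classifies districts as
healthy/pathological; classes are balanced by seeded subsampling to the
minority count before fitting. The classifier is intentionally coarse —
the union of pathological districts (`V_t`) is only used to pick the
affected hemisphere, not to segment the tumor. The affected side maximizes
the fraction of `V_t` it contains. The decision is refused as *ambiguous*
when the fractions differ by less than 1% **or** when the minority
hemisphere still holds more than 25% of `V_t`. The second clause is what
actually enforces monolaterality in practice: a district-level mask of a
truly bilateral lesion never splits exactly 50/50 (phantom experiments give
0.41/0.59 noisy, 0.49/0.51 noiseless, versus ≤ 0.07 minority share for
monolateral lesions), so a pure tie test would never fire.

The classifier must be trained on data resembling the deployment domain.
The test fixtures train on both noisy and noiseless phantoms with lesions
on either side; a model trained only on noisy cases misclassifies the
zero-variance districts of noiseless images wholesale — an instructive
reminder that the SVM learns the feature distribution, not "lesionness".

## Reference extraction: the quantile-histogram conformity filter

Each contralateral lobe `V_i` supplies a reference histogram: its PET
intensities are split at K = 10 quantiles. The reference proportions `e_j`
are measured empirically from the lobe's own bin assignment rather than
fixed at 1/K: on continuous data they are 1/K to within 1/n, while with
heavily tied intensities quantile edges collapse, bins merge, and the
empirical masses keep the statistic well defined (every bin mass positive).

For every brain voxel `p`, the proportions `o_j` of the (2l+1)³ cubic
window (l = 3) falling into the reference bins give the conformity
statistic

    Y(p) = Σ_j (o_j − e_j)² / e_j ,

zero iff the window reproduces the reference distribution. Voxels with
`Y ≤ threshold` are accepted into the lobe mask `M_i`. Implementation uses
exact integer window counts (3-D integral images), and the test suite
checks the sliding-window mask voxel-for-voxel against a brute-force
re-count on 20³ volumes. Window values outside the reference range are
clipped into the extreme bins. Windows are evaluated only where fully
inside the grid; centers closer than l to the boundary are excluded and
counted in the diagnostics — truncated windows would have biased
histograms. A fully degenerate reference (a single distinct intensity)
switches to the natural limit of the filter: a window conforms iff every
voxel equals that value.

**Threshold.** The fixed default is 1e-3, but the statistic has a sampling
floor: with N = 343 window voxels and K = 10 bins, `E[Y] ≈ (K−1)/N ≈
0.026` under pure multinomial sampling, so 1e-3 rejects essentially every
voxel of any noisy image and empties the reference mask. The default mode
therefore *calibrates* the threshold per reference histogram as the 95th
percentile of Y under seeded multinomial simulation at the window size
(taking the larger of that and the fixed value); `y_threshold_mode =
"fixed"` restores the literal fixed threshold. Both behaviors are logged in
the report.

The five lobe masks are averaged and thresholded at 0.5 — i.e., a voxel
joins `M_n` when at least 3 of 5 lobes accept it ("averaging" five binary
masks needs a rule; majority is the neutral one). The filter runs over the
whole brain so that its *rejected* set is defined on both sides; `M_n` is
the accepted set restricted to the non-affected hemisphere (a
`per_lobe_search` switch instead unions each lobe's accepted voxels within
that lobe). `c_n` is the arithmetic mean of PET over `M_n`, and the
normalized image P/c_n has mean exactly 1 over `M_n` (asserted every run).
On phantoms the accepted-region intensity distribution is mono-modal
(kernel-density single mode, tested), consistent with hyper- and
hypo-intense structures having been removed.

**Striatal reference.** The striatum is hyperintense on F-DOPA, so the
filter discards it; the discarded component around the contralateral
striatum label becomes `M_s`. One refinement: the filter also discards a
window-reach-thick *halo* of background-level voxels around any bright
structure (their windows overlap it), and folding the halo into `M_s`
would dilute `c_s` toward the background. Components are therefore gated
at the midpoint between `c_n` and the striatal estimate before extraction;
discarded voxels inside the atlas label are always kept. On a noiseless
phantom this recovers the striatal mean exactly; with 5% noise, `M_s`
covers ≥ 90% of the true striatum. If nothing is discarded at the striatum
(pathologically low striatal uptake), the atlas label itself is used and
the case flagged (`striatal_fallback`).

## Lesion maxima and selection

`M_c = brain − M_n − M_s` contains the glioma *and* the ipsilateral
striatum, whose physiological uptake can rival the tumor's — distinguishing
the two from PET alone is not possible, which is why two maxima are
reported instead of one. The ipsilateral striatal mask `M_c,s` starts from
the filter-discarded component at the striatum label (gated as above) and
grows by 26-neighbor accretion: a frontier voxel joins while its activity
is at least `rho_grow` (default 0.8) of the current region mean, until the
atlas label is fully covered or `grow_max_iter` (default 50) iterations.
The growth parameters are config-exposed; the values give tight masks on
sharp phantom boundaries (no growth beyond the bright ball) while still
following deformed or infiltrated anatomy — by design the mask may
incorporate contiguous affected tissue of similar uptake. Coverage of the
label is enforced by union at the end; hitting the iteration cap first is
flagged (`incomplete striatal coverage`).

`m_in` and `m_out` are the highest (2l+1)³ window means (l = 2, roughly
the manual ROI size) over centers in `M_c,s` and `M_c,n = M_c − M_c,s`.
Window centers are restricted to the mask but the averaged window is taken
as-is — gliomas peak centrally and decline outward, so the local mean at
the center is a noise-robust stand-in for the single hottest voxel. Ties
resolve to the smallest lexicographic voxel index for reproducibility.
Selection: `m_out ≥ m_in` → `m_out`; otherwise `m_in` only when striatal
infiltration is established (`infiltration_assumed`), else `m_out` with a
`clinician review required` flag — infiltration is a human/MRI judgement,
not something this method decides.

Scores: `t_n = m_sel/c_n`, `t_s = m_sel/c_s`, reported to 3 decimals in
the JSON report (full precision is included for lossless round-trips).
The identity `t_n/t_s = c_s/c_n` and the mask partition invariants
(`M_n ∩ M_s = ∅`; `M_c,s ∪ M_c,n = M_c`, disjoint) are asserted on every
run.

## Synthetic phantoms

The phantom emulates exactly the features the method consumes: an
ellipsoidal "brain" split into two hemispheres with five antero-posterior
lobe slabs, one striatal sphere each (2.5× background uptake), and a pons;
a spherical lesion (default 2.0× background on PET, 1.5× on FLAIR) with a
flat plateau core wider than the maxima window and a linear ramp to
background; additive Gaussian noise (default σ = 5% of the background
mean) clipped at zero, on brain voxels only. Defaults represent a clearly
hyperintense monolateral glioma on quiet parenchyma. Expected scores are
analytic — `t_n = peak/background`, `t_s = peak/striatum` — because the
plateau exceeds the 5³ maxima window, making the best window mean equal
the plateau value.

What the phantom does *not* emulate: scanner point-spread and
partial-volume effects, anatomy (lobe slabs are not lobes), spatially
correlated or Poisson-like noise, registration error, FLAIR artifacts.
Passing phantom tests therefore demonstrates the correctness of the
algorithmic chain (parcellation → classification → conformity filtering →
mask algebra → maxima → scores) under the method's own assumptions, not
clinical performance. The published cohort-level agreement of automated
and manual scores cannot be reproduced without the original image sets,
which were never deposited; the cohort table packaged here supports only
the score-table statistics (grade t-tests, cut-offs, survival analysis).

Problem sizes were chosen for fast, deterministic test runs: 64³ grids,
~53k brain voxels, 20 noisy seeds for the recovery property, 10 for the
acceptance script, classifier training on 5 phantoms (~1450 districts).
Noisy recovery errors on these grids stay below 1% against the ±5%
contract.

## Evaluation statistics

The 18-patient cohort ships as a typed fixture (9 low-grade, 9 high-grade;
the survival event is death of disease, everything else censored at last
follow-up). Pearson correlation and the unpaired t-test come from
scipy.stats (pooled-variance Student's by default, Welch behind a flag —
the grade comparison only says "unpaired"); residual dispersion is the
sample SD (n−1) of OLS residuals; Kaplan–Meier and log-rank come from
lifelines and are cross-checked in the tests against independent
product-limit and O/E/V computations on random cohorts. The
sensitivity-maximizing cut-off is the smallest score among deceased
patients: every death lands in the `score ≥ cutoff` group, so the
low-score group has zero events by construction, and its KM curve stays
flat at 1. On the packaged table the cut-offs are 1.73 (T_N) and 1.14
(T_S) and both log-rank splits give p ≈ 3.4e-4. When the cut-off equals
the overall minimum the split is degenerate (empty low group); the split
is then flagged and the log-rank p set to 1 by convention.

## Known limitations

* Striatal infiltration is a clinical input, not an output: with
  `m_in > m_out` the method cannot itself decide which maximum represents
  the tumor.
* A lesion contiguous with the striatum at similar uptake is (by design)
  partly absorbed into `M_c,s`, which can depress `m_out`.
* The conformity filter assumes the contralateral hemisphere is healthy;
  bilateral disease violates the model and is only caught at the
  lateralization stage.
* The district classifier generalizes only to images resembling its
  training distribution; it must be retrained per protocol/scanner.
* Lobe masks here are atlas labels; no attempt is made at anatomically
  faithful parcellation, partial-volume correction, or absolute SUV.
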