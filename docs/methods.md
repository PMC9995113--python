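# Methods

`glymphokit` re-implements, as a tested pipeline over synthetic data with
known ground truth, the computational stages of a multi-modal MRI study of
glymphatic function in AQP4-knockout mice: CSF-space segmentation from
CISS-like cisternography, ADC and segmented IVIM diffusion fitting, rank-sum
DCE tracer-kinetic scoring, variable-TR T1 mapping with dual-angle B1
correction, and free-fluid estimation in microbead phantoms. This note
records the models, the parameter choices that matter, and the places where
the original method description is ambiguous and a concrete reading had to
be fixed.

## Synthetic phantoms (`glymphokit.synthetic`)

Every generator is a pure function of its seed: one `numpy.random.Generator`
per call, no global state, bit-reproducible output.

**Rician noise.** Magnitude MRI noise is simulated as
`|signal + g1 + i g2|` with per-channel SD σ. "SNR" is defined as foreground
(parenchyma) mean divided by σ, matching the convention of measuring noise in
a background VOI of a magnitude image; the observable background SD is then
`σ·sqrt(2 − π/2)` (Rayleigh).

**CISS phantom.** A brain ellipsoid (parenchyma mean 3 a.u.) carries seven
CSF compartments — paired lateral ventricles, third and fourth ventricles,
and four families of perivascular tubes — at CSF mean 9 a.u. (3× parenchyma,
the contrast regime of heavily T2-weighted cisternography), modulated by a
low-order polynomial bias field (±5%, unit mean over the brain; real scans
retain residual inhomogeneity even after bias correction, and a perfectly
flat phantom makes percentile thresholds degenerate). The default grid is
96³ with compartment radii scaled to the grid, so the thinnest tubes are 2–3
voxels in radius — comparable to the structure-to-voxel ratio of the real
33 µm acquisition. CSF occupies ≈4.7% of the brain, consistent with the
method's premise that CSF intensities occupy roughly the top 5% of the
aggregated brain distribution (the in-vivo CSF/brain ratio is 2.4–4.4%).
Default SNR is 3.5, the reported CISS operating point.

**DWI phantom.** Voxel-wise signals follow the IVIM biexponential
`S(b) = S0(Fp e^{−bD*} + (1−Fp) e^{−bD})` over the 17-b scheme
(40…3081 s/mm², first value doubling as the "b0"). Parameter maps are
blockwise-constant (4 regions by default, one of them purely
monoexponential) so ROI statistics have known truth; levels span
Fp 0–0.15, D 6–9·10⁻⁴ mm²/s, D* 0.8–1.5·10⁻² mm²/s. b-values ≥ 1057 are
generated as the mean of two independent Rician magnitudes, mirroring the
protocol's doubled averages.

**DCE cohort.** The original analysis defines its metrics operationally
(arrival, time-to-peak, peak, duration) without a curve model, so the
generator uses a piecewise gamma-variate with an explicit plateau and a hard
return to baseline, which makes every metric well-defined by construction.
All kinetic parameters are minutes **relative to the infusion start** (the
scan after the third baseline volume), the same convention in which the
metrics are reported; the curve onset is placed half a sample before the
arrival time so the sample *at* the arrival minute is the first enhanced one
and the maximum falls exactly on the time-to-peak sample.

**Variable-TR stack.** `S(TR) = S0·sin(κ·90°)·(1 − e^{−TR/T1})` over the 13
printed TRs (12000…15 ms), plus the dual-angle pair at the maximal TR with
`S(α) ∝ sin(κα)`. A flip-angle scaling κ therefore biases only the
amplitude, not the recovery rate — see the B1 discussion below.

**Bead phantom.** Non-overlapping low-HU spheres in a high-HU contrast bath.
Below 0.25 nominal packing the spheres are placed by random sequential
adsorption; denser packs use a jittered simple-cubic lattice (limit ≈0.52),
approximating a packed Sephadex bed. The exact voxel fraction outside the
beads is the ground-truth free-fluid fraction. Within-mode HU spread (SD 3)
emulates 8-bit reconstruction noise.

## CSF segmentation (`glymphokit.ciss`)

Axis order is (sagittal, coronal, axial); plane *p* slices along its axis.
The chain: bounding box → solitary-region removal → adaptive seeding →
region growing (dilate, then erode, in sagittal → axial → coronal order) →
median filter → intersection with the brain mask.

* **Statistics.** Over positive brain voxels: mean µ_d, population SD σ_d,
  threshold-correcting factor `f_c = σ_d/(µ_d + σ_d)`, SNR `µ_d/σ_d`.
* **Bounding box.** Per axis, the longest contiguous run of slices whose
  intensity variance is ≥10% of the peak slice variance (the original pipeline states the objective — variance maximization —
  but no concrete rule; the threshold is exposed).
* **Solitary regions.** Slice-wise sagittal, 8-connected: components with
  ellipse-moment eccentricity ≥ 0.5, roundness `4πA/P²` ≥ 0.5 **and**
  perimeter < 0.005% of the brain voxel count are dropped; survivors are
  re-dilated with an 11-pixel disk.
* **Seeding.** Intensities are rescaled `I_r = (I − 1.33σ_d)/σ_d`, negatives
  zeroed; the seed keeps voxels strictly above the 95.5th percentile of the
  positive rescaled distribution (95.5 + f_c for SNR > 4, capped at the
  97th). Percentiles use linear interpolation; ties resolve toward
  exclusion.
* **Boundary contrast.** For a candidate voxel v, direction u and window n:
  `|I_v − mean(n preceding)| / (I_v + mean(n following)) × 100%`, with the
  *preceding* side oriented toward the mask. The original description of the contrast is
  asymmetric in exactly this way; a symmetric variant is available
  (`symmetric_contrast=True`) but the asymmetric form is the default. The
  contrast is evaluated **at the candidate** — the inclusion rule attaches
  the contrast to the voxel being considered for inclusion; evaluating it at
  the boundary voxel instead makes growth fire into flat parenchyma
  (measured ≈3000 false positives on a noiseless phantom).
* **Dilation.** Boundary voxels must have original intensity ≥ µ_d + 2σ_d —
  the stated meaning of the (97.5 − f_c)th-percentile criterion. On strongly bimodal
  phantom distributions the empirical percentile lands *inside* the CSF mode
  and disables growth entirely, so the µ+2σ form is the default and the
  percentile form a config option. Candidates at distance n (1–4 sagittal,
  1–3 axial/coronal) along horizontal/vertical/diagonal directions join when
  their contrast is < 2%.
* **Erosion.** Recomputed boundary; mask voxels at distance n (1–2 sagittal,
  1–3 axial/coronal) are removed when their intensity is at/below the
  (95.5 − f_c)th percentile and the contrast exceeds 2.5% — strict/non-strict
  per plane exactly as originally specified (≤ and > sagittal; < and ≥
  elsewhere).
* **Median filter.** Default is a 3×3 median per sagittal slice. The
  original account calls for a three-dimensional median filtration with a
  3×3-voxel kernel, which is ambiguous; a
  3×3×3 majority erases structures of 1–2 voxel radius (perivascular tubes),
  measurably degrading noiseless Dice from 0.98 to 0.94 and volume error
  from ~4% to 6–9%, against the filter's stated purpose of removing single
  voxels and closing small openings. The 3×3×3 variant is
  `median_mode="3d"`.
* **Volumetry.** Compartment ratio = compartment volume / (brain volume −
  whole segmented CSF volume) × 100; invariant to voxel-size rescaling.

Measured on the default phantoms: Dice 0.976 noiseless (volume error 4.1%),
0.94–0.95 at SNR 3.5 over five seeds.

## Diffusion fitting (`glymphokit.dwi`)

* **Normalization.** `DWI_norm = DWI − (µ_noise − 6σ_noise)` per b-volume,
  a constant shift from a 704-voxel half-ball background VOI (auto-placed in
  a FOV corner by default, position configurable).
* **Brain mask.** Threshold at mean + 0.5 SD of the b0 image, diamond
  dilation (2 px), slice-wise hole filling.
* **ADC.** Nonlinear least squares of `S = S0 e^{−b·ADC}` over all 17
  b-values, initialized from the log-linear solution.
* **Segmented IVIM.** Step 1 regresses ln S over b ≥ 238 s/mm² (the acquired
  value closest to 250; ties break toward lower b) to get D and the
  intercept S0_lin; the raw perfusion fraction is
  `Fp = (S_b0 − S0_lin)/S_b0`. The regression is signal²-weighted by
  default — the standard log-domain approximation of least squares on the
  untransformed signals; the unweighted fit over-weights the Rician-floor-
  dominated top b-values and biases D down ~5% at D = 9·10⁻⁴, SNR 30.
  Step 2 fits D* (bounds [D, 1] mm²/s, start 10·D) with Fp and D fixed,
  refining S0.
* **b0 ≠ 0 correction.** Because "b0" is 40 s/mm², the raw Fp is biased low
  (≈0.05 at Fp = 0.1, D* = 10⁻²: e^{−40·D*} ≈ 0.67 is far from 1). After
  each D* fit, Fp is re-derived from the closed form
  `Fp = (S_b0 − S0_lin e^{−b0·D}) / (S_b0 + S0_lin(e^{−b0·D*} − e^{−b0·D}))`
  and step 2 repeated (3 iterations) — exact on noiseless data and reducing
  to the raw formula as b0 → 0. The uncorrected estimate is kept in
  `fp_raw`; `correct_b0_offset=False` restores the plain two-step method.
* **ROI statistics.** Mean/SD after excluding negative values and values
  above the within-ROI 99th percentile.
* **D\*** is ill-conditioned at these SNRs; its tolerance is 50% on the
  region median and voxels with Fp ≤ 0 leave it undefined.

Measured: noiseless ADC recovered to <10⁻⁷ relative, Fp within 0.01,
D within 0.5%; at SNR 30 (100 voxels/region) the region-median D is within
~2%, Fp within ~0.01 absolute.

## DCE scoring (`glymphokit.dce`)

Within one group, each subject's ROI curve is ranked across time (midranks);
`score(t) = mean_rank(baseline) − mean_rank(t)`, so enhancement gives
negative scores. Dunn's `z = |score| / sqrt(k(k+1)/(6n))` compares each time
point against the baseline reference only, Bonferroni-corrected over the
k − 1 comparisons at α = 0.05 — not all pairwise contrasts, matching the design of comparing
every time point to the pre-infusion baseline only.

* **Arrival**: first post-baseline time with `−score ≥ 3·B`, where B is the
  maximum baseline |score| floored at one midrank unit (the three-times-baseline
  rule is degenerate when baseline scores are exactly 0; the floor
  keeps it defined and the multiplier is a parameter).
* **Time-to-peak**: most negative score, earliest tie, minus infusion start.
* **Peak intensity**: group-*mean* enhancement at the peak sample
  (config-switchable to median; the original report does not say which).
* **Duration**: last minus first significant time point; 0 when fewer than
  two. On a noiseless cohort the significant window is *not* the full
  above-baseline support — with 88 time points and n = 6 the critical
  mean-rank shift is ≈50 — so recovery tests compare the duration against an
  independent recomputation of the Dunn flags, while arrival and
  time-to-peak equal the generator truth exactly at 1-minute resolution.
* **AUC**: plain sum of amplitudes over time points (no trapezoid).
* **Group comparison**: per-time two-sample t-tests with Bonferroni over
  time points — the per-time contrast of the repeated-measures two-way
  design as statistics packages implement it.

All rank-derived metrics are invariant under strictly monotone transforms of
the enhancement values (property-tested).

## T1 mapping and free fluid (`glymphokit.relaxometry`)

T1 is fitted per voxel by log-free nonlinear least squares of
`S(TR) = S0(1 − e^{−TR/T1})`, initialized at the median TR (robust across
the 3-decade TR range); voxels with T1 below min(TR)/5 are flagged as
saturated/degenerate. The dual-angle map solves
`S45/S90 = sin(45κ)/sin(90κ)` by Brent root finding on κ ∈ (0, 2)
(tolerance 10⁻⁶; the ratio is monotone from 0.5 upward, out-of-range ratios
clamp and flag). With ideal refocusing a flip-angle scaling multiplies the
saturation-recovery signal by sin(κ·90°) without touching the recovery
rate, so the correction rescales S0 and carries T1 over — the original
description cites the dual-angle method without a formula, and this is the
reading adopted.

The free-fluid estimator counts ROI voxels above the 75th, 80th and 85th
percentile of the ROI's own HU distribution and averages the three
fractions. By construction `count(I > P_p)/count ≤ (100 − p)/100` for
continuous distributions (≤0.25 at p = 75), so the estimator is a
*comparative* score across phantoms, not an absolute porosity: phantoms with
true free fractions of 0.65–0.75 all score ≈0.20. It is monotone
non-decreasing in the true fraction (property-tested) and exact only below
~0.15 true fraction with tightly quantized bead intensities.

## Group statistics (`glymphokit.stats`)

Water content `(W_wet − W_dry)/W_dry` (ml/g dry weight); the ±1.5 SD
single-pass retention filter (sample SD, no iteration; SD = 0 retains all);
Mann-Whitney U (exact null for tie-free groups under 20, normal
approximation with tie correction otherwise — all study groups are ≤20); Pearson/Spearman correlation with the regression line for the
"|r| > 0.5, p < 0.05, non-zero slope" significance convention. Spreadsheet
ingestion (`load_source_table`) maps arbitrary column layouts onto a tidy
(subject, genotype, region, measurement, value) frame, since per-animal
source files differ in internal layout.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in a few minutes on one core: 96³ CISS grids (six segmentations
≈ 40 s), 400-voxel DWI maps (100 per parameter region), 6-subject 90-minute
DCE cohorts, 8×8 T1 maps, 48³ bead phantoms. All are parameters; nothing in
the algorithms depends on these sizes.

## Known limitations

* The phantoms contain no banding artifacts, EPI distortion, ghosting,
  motion, or partial-volume ramps — passing tests show the algorithms invert
  their stated forward models, not that they are robust to every artifact of
  real acquisitions (the original pipeline handled those with external motion-correction and
  bias-field tools, which are out of scope here).
* The segmented IVIM D* estimate is ill-conditioned below SNR ≈ 50 at b0;
  only order-of-magnitude recovery is claimed (50% tolerance).
* The free-fluid percentile estimator saturates at 0.25 (see above).
* Dunn significance needs n ≥ 3 subjects; with fewer, scores are returned
  but flags are undefined.
* The brain mask threshold (mean + 0.5 SD) assumes a roughly bimodal b0
  histogram; a uniform image degenerately keeps every voxel.
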