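# Methods

## Problem and model

After lobectomy or segmentectomy for lung cancer, guidelines require a
preoperative estimate of residual lung function. `walppo` implements two
estimators of predicted postoperative (ppo) FEV1 and %DLCO, both of which
rescale the preoperative value by the functional share of the tissue to be
removed:

* **Anatomical segment counting (ASC).** Each of the 19 bronchopulmonary
  segments (RUL 3, RML 2, RLL 5, LUL 4, LLL 5) is assumed to contribute
  equally:

  `ppo = pre × [1 − S × 0.0526]`,

  where `S` is the number of resected segments. The coefficient 0.0526
  (≈ 1/19) is used literally, never recomputed, so the formula reproduces
  published arithmetic bit for bit.

* **Well-aerated-lung (WAL) ratio.** The functional share of the resected
  lobe is measured on CT as its share of the well-aerated lung volume:

  `ppo = pre × [1 − WAL_lobe / WAL_total]`.

WAL is defined by a density mask: voxels with attenuation in the **closed**
window **[−950, −750] HU** inside the segmented lung. Voxels **strictly
below −950 HU** are low-attenuation areas (LAA, the emphysema surrogate);
%LAA is the LAA share of whole-lung volume. The boundary convention is a
declared choice: a voxel at exactly −950 HU counts once, as WAL, and a voxel
at −750 HU counts as WAL; −951 and −749 count as neither. Commercial
densitometry packages do not document their boundary handling, so the
convention here is explicit and tested at the boundary voxels.

All densitometry is integer arithmetic on voxel counts; volumes in liters
are `count × voxel volume`, with the voxel volume the product of the header
spacing (mm³ → L via 10⁻⁶). Whole-lung quantities are exact sums of
per-lobe counts. Display rounding (4 decimals in tables) never enters the
arithmetic.

## Agreement battery

Two methods are compared (WAL vs ASC, and each vs the measured
postoperative value) with:

* **Spearman rho**, tie-corrected (Pearson on average ranks), two-sided p
  from the t approximation on n−2 df. An exact permutation p is available
  for n ≤ 10 and serves as a small-sample oracle.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measures — from the two-way ANOVA decomposition, with the F-based 95% CI.
  Absolute agreement is the deliberate variant: the question is whether the
  methods are interchangeable, so a systematic offset must lower the index
  (a consistency ICC would forgive it; this asymmetry is tested). Bands:
  < 0.40 poor, 0.40–0.54 weak, 0.55–0.69 moderate, 0.70–0.84 good,
  0.85–1.00 excellent, with band edges belonging to the higher band.
  Perfect agreement (`b` identical to `a`) returns exactly 1.0 rather than
  propagating a 0/0 ANOVA; zero total variance raises an undefined-statistic
  error.
* **Bland–Altman limits of agreement**: bias ± 1.96 × SD of the paired
  differences, with the sample SD (n−1) and 1.96 applied literally rather
  than a t quantile.
* **Wilcoxon signed-rank** for paired location shift: zero differences
  dropped, average ranks for tied absolute differences, statistic
  min(W⁺, W⁻). The two-sided p is exact for effective n ≤ 25 — computed by
  a subset-sum recursion over doubled ranks, which enumerates the 2ⁿ sign
  assignments even in the presence of ties — and a tie-corrected normal
  approximation (no continuity correction) above. SciPy cannot produce
  exact p values with ties, which is why this statistic is implemented
  in-package; SciPy's approximation is used as a cross-check in the no-tie
  regime.

Tests are two-sided with significance at p < 0.05 and no multiple-testing
correction. The report always contains the same six comparisons (FEV1 in
liters and %DLCO; WAL vs ASC, WAL vs measured, ASC vs measured).

## Synthetic phantoms

Phantoms exist to make the densitometry testable to the last voxel.
Geometry: two ellipsoidal lungs inside an ellipsoidal soft-tissue body
(+40 HU) surrounded by background air (−1000 HU); the right lung is cut
into three axial slabs (RUL/RML/RLL, superior to inferior), the left into
two (LUL/LLL). A one-voxel soft-tissue shell is guaranteed around the lungs
so threshold segmentation (< −300 HU inside the body, two largest
26-connected interior components) recovers exactly the lobe union.
Anatomical realism — fissures, airways, vessels, gravity gradients — is a
non-goal; none of it affects density-mask arithmetic.

Each lobe is composed of three compartments matching the density-mask
windows: emphysema (< −950 HU), WAL ([−950, −750]), non-aerated (> −750,
capped at −400 HU so lungs stay below the segmentation threshold).
Compartment assignment partitions the lobe's shuffled voxel list exactly —
`floor(f·n)` voxels to emphysema and non-aerated, remainder to WAL — rather
than sampling per-voxel Bernoullis, so the recorded ground truth
(`PhantomTruth`) is exact, not approximate, and recovery tests can demand
equality instead of tolerance. HU values are normal draws, rounded to
integers *first* and then clipped into the compartment interval, so the
boundary contracts survive int16 casting. Default compartment distributions:
emphysema N(−980, 15), WAL N(−860, 40), non-aerated N(−600, 60) HU.

## Synthetic cohorts

The cohort generator emulates a 40-patient early-stage resection cohort.
Marginals are log-normal with medians at the targets and log-scale spreads
derived from the target interquartile ranges via
`s = ln(q75/q25) / (2 × 0.6745)`:

| quantity | median | IQR target |
|---|---|---|
| pre-FEV1 | 2.33 L | 1.68–2.76 L |
| pre-FEV1 %pred | 85% | 67–101% |
| pre-%DLCO | 71% | 58–83% |
| WAL RUL / LUL | 1.20 L | 1.08–1.33 / 1.06–1.35 L |
| WAL RML | 0.45 L | 0.39–0.57 L |
| WAL RLL / LLL | 1.42 / 1.32 L | 1.11–1.58 / 1.12–1.51 L |

Resection sites are drawn with upper-lobe predominance (RUL 0.45, LUL 0.27,
RLL 0.12, LLL 0.16, RML 0 — middle-lobe resections are rare enough to be
absent from a cohort of this size); 22.5% of patients get a segmentectomy of
one or two segments, the rest a lobectomy. FEV1 and %DLCO are drawn
independently: no inter-trait correlation structure is imposed because none
is identifiable from cohort marginals alone.

Measured postoperative values are generated from the WAL prediction with
multiplicative log-normal noise, `post = wal_ppo × exp(ε)`,
ε ~ N(0, σ²). This choice keeps values positive and makes σ the single
interpretable agreement knob: σ = 0 closes the pipeline exactly (rho = 1,
ICC = 1, LoA = [0, 0]), and mean ICC decreases monotonically in σ — both
properties are tested. The default σ = 0.12. Because the generative truth
*is* the WAL formula, simulated agreement statistics are optimistic relative
to clinical data (ICC ≈ 0.95 for FEV1 at default σ and n = 40): real
postoperative function also carries position effects at CT acquisition,
inspiration-level variability and genuine physiological divergence from the
density-mask surrogate, none of which the noise model represents. Passing
tests therefore validate the arithmetic and the statistical machinery, not
clinical accuracy.

**Segmentectomy under the WAL formula.** No canonical sub-lobar rule
exists; the lobe's WAL is scaled proportionally by `S / segments(lobe)` —
the minimal assumption — and such rows carry a `wal_lobe_scaled` flag so
users can exclude them. The generator and the predictor share this rule,
which the σ = 0 closure tests depend on.

## Numerical and design choices

* Noise reduction (unspecified by densitometry vendors) is a 3D median
  filter, default radius 1, **off by default**; median filtering preserves
  the HU range, so window monotonicity survives it.
* Lobe label maps are an *input* (phantom truth or external segmentation);
  fissure-based lobar segmentation of real CT is out of scope.
* NIfTI volumes are reoriented to closest-RAS on load; HU round-trips as
  int16 bit-identically. Cohort CSVs are parsed with round-trip float
  precision so write→read is bit-exact (the closure tests need this).
* ICC CI quantiles use Satterthwaite degrees of freedom; the CI is clamped
  to contain the point estimate and to [−1, 1].
* Exact Wilcoxon enumeration is O(n · Σ2r) via the subset-sum recursion,
  cheap up to n = 25; beyond that the normal approximation is standard.
* `run-all` outputs (cohort, predictions, report CSV/JSON, manifest) are a
  pure function of config + seed; the manifest deliberately excludes
  timestamps so repeated runs are byte-identical.

## Problem sizes in the test suite

Phantom recovery is exercised on twenty random 64³ phantoms (≈ 260k voxels
each) and smaller fixtures; statistical oracles on vectors of length 5–20
(full 2ⁿ enumeration for the Wilcoxon oracle); the σ-monotonicity property
on 200 replicate cohorts of n = 40 per grid point σ ∈ {0.02, 0.05, 0.1,
0.2}. These sizes give stable Monte-Carlo means while keeping the whole
suite in the tens of seconds.

## Known limitations

* The phantom's slab-lobe geometry cannot test fissure-related segmentation
  errors, partial-volume effects at lobe boundaries, or scanner noise
  textures; its HU histograms are truncated normals, not reconstructions.
* The cohort noise model induces no bias between WAL prediction and
  measured outcome, so Bland–Altman bias on simulated data centers on zero;
  clinical data show systematic underestimation by CT-based prediction.
* The exact permutation option for Spearman is factorial in n and intended
  only as a small-n oracle.
* %predicted values are taken as given; reference-equation modeling is out
  of scope.
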