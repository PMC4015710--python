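# Methods

## Scope and model

Air trapping on expiratory CT is the failure of lung regions to gain
attenuation (and lose volume) between inspiration and expiration. The
package quantifies it densitometrically and compares the resulting
criteria against the single-breath nitrogen washout test (SBNT), whose
phase-III slope dN₂ is the accepted functional marker of small airway
obstruction (cutoff 2.5 %N₂/L, strict inequality — a boundary value is
classified negative). Because no suitable public dataset pairs expiratory
CT with SBNT, validation is built on synthetic data with known ground
truth; the simulation layer is therefore first-class, tested code.

## Lung segmentation and densitometry

Segmentation is deliberately the simplest method that satisfies the
stated behaviour: threshold to the parenchymal window [−1024, −500] HU,
label connected components (6-connectivity), discard components touching
the lateral (x/y) image border (outside-body air), remove every
low-attenuation component (≤ `airway_hu_max`, default −970 HU) that
reaches the most cranial slice — only the trachea can do that — and keep
components of at least `min_component_voxels` (default 100). One retained
component is a warning (single lung), zero is an error. Commercial
densitometry tools do not publish their algorithms; nothing here depends
on more than thresholds plus connectivity.

All three HU ranges are **inclusive at both ends**, which makes the
nesting LAA%[−910,−850] ≤ LAA%[−1024,−850] exact even at integer HU. The
narrow range's −910 floor excludes very low densities that would reflect
emphysematous or cystic lesions rather than trapping.

Left and right lungs are pooled at the voxel level when summarising a
level ("combining both sides"); the across-level summary is the
**unweighted mean of the four level values**, since no area weighting is
implied by single-slice sampling. Level positions are caller-supplied
slice indices (index 0 = most cranial): matching expiratory to
inspiratory levels is an anatomical judgement, not something the package
can automate.

Ratios in the paired criteria use **raw signed HU**. On the MLD basis
both E and I are negative, so E/I is positive and approaches 1 as
trapping increases; discrimination thresholds like E/I_MLD ≈ 0.9 only
make sense on this signed scale. (E−I)/I is computed as E/I − 1, making
the identity exact to machine precision. E−I carries HU on the MLD basis
and percentage points on LAA bases; the fields are never mixed.

## Washout analysis

- **Flow QC**: the manoeuvre should be exhaled at 0.3–0.5 L/s; the check
  passes when ≥ 90% of mid-expiration samples (25–75% of expired VC) are
  in band. Missing flow → "not assessed" (None), not a failure.
- **Closing volume**: a continuous two-segment line `y = a + b·v +
  c·(v−v_b)₊` is fitted over the terminal window (≥ 50% of VC expired) at
  every candidate breakpoint (exhaustive search, ≥ 3 samples per side);
  the best-SSE breakpoint is accepted as phase-IV onset only when the
  terminal slope exceeds the first-segment slope by ≥ 2× (configurable).
  The gate prevents spurious phase-IV detection on noisy linear tails;
  rejection means CV = 0.
- **dN₂**: OLS slope of N₂% vs expired volume over [30% of VC, phase-IV
  onset]. The 30% start is conventional SBNT practice; commercial
  analyzers do not document their window, so both ends are configurable.
  Intervals shorter than 0.5 L are refused. R² uses a scale-aware floor so
  an exactly flat plateau reads as a perfect fit rather than 0/0.
- Closing capacity (CV + residual volume) is not computed: residual
  volume is not measured by this module.

## Statistics

- **Spearman** (scipy, mid-ranks, two-sided p) with constant columns
  flagged undefined rather than raised.
- **Dendrogram**: distance 1 − |ρ_Spearman|, average linkage. Correlation
  distance is the natural metric for "how close is a criterion to dN₂";
  the linkage is configurable. Closest branches are read off cophenetic
  distances.
- **ROC**: empirical curve over all observed thresholds; AUC by
  trapezoid (= Mann–Whitney); 95% CI by the DeLong structural-components
  estimator (implemented here; no installed package provides it);
  direction auto-chosen so AUC ≥ 0.5 and reported. Optimal threshold by
  Youden J, ties broken toward higher specificity.
- **ICC**: two-way random-effects, absolute-agreement, single-measure
  ICC(2,1) from the ANOVA decomposition — it penalises systematic
  between-reader bias, which is what inter-reader agreement should do.
  ICC(3,1) and one-way ICC(1) are exposed as alternatives. Cross-checked
  against pingouin's ICC(A,1) in the test suite.
- **Across-level heterogeneity**: Friedman test. For small instances the
  p-value is exact, enumerating all k!ⁿ within-subject orderings
  (vectorised dynamic programming; the tie pattern is permutation
  invariant, so the uncorrected rank statistic induces the same ordering
  as the tie-corrected χ²). Larger samples use the tie-corrected
  chi-square approximation, which matches scipy's.

`run_comparison` chains these the way a criterion-selection study
proceeds: prevalence → Spearman table → dendrogram → ROC of the k = 3
branches closest to dN₂, ranked by AUC. Single-class labels skip ROC with
a message instead of failing.

## Synthetic data: what it emulates, and what it does not

**Phantom.** A body cylinder (N(40, 15) HU) in surrounding air, two lung
ellipsoids, and a vertical near −1000 HU airway tube entering at the apex
slice. Lung voxels are Gaussian: N(−880, 20) at inspiration, N(−750, 20)
at expiration, except trapped voxels which stay at N(−880, 15). Trapped
regions are carved by thresholding a smoothed Gaussian random field
(σ = 3 voxels) at the quantile matching the requested fraction — focal,
spatially coherent blobs with the realised fraction exact to one voxel,
and independent of the HU noise, so expiratory attenuation is an exact
two-Gaussian mixture. An optional caudal gradient biases trapping toward
dependent lung without changing the overall fraction. Volumes are
bitwise-deterministic functions of (spec, seed), identical outside the
lungs across the paired acquisitions.

Not emulated: realistic lung texture, vessels/bronchi within lung,
partial-volume edges, respiratory motion, scanner noise spectra, DICOM
metadata. Passing tests show the measurement chain is correct on its
stated model, not that segmentation would survive pathological anatomy.

**Washout curves.** Phase I at 0 %N₂ to 0.3 L; phase II a logistic rise
(rescaled to hit its endpoints exactly — the schematic shape of the
transition is not otherwise constrained) to 25 %N₂ at 0.8 L; phase III
exactly linear at the requested slope; phase IV linear and steeper, with
pointwise Gaussian noise (default 0.05 %N₂) and constant 0.4 L/s flow.
Defaults: VC 4 L, CV 0.8 L. The spec-level constraint is relaxed to
phase4 ≥ phase3 so a degenerate flat curve is constructible; the
slope-ratio gate then correctly reports CV = 0 for it.

**Cohorts.** Each subject has a latent trapped fraction f ~ U(0.05,
0.75); the nine criteria at four levels are the two-Gaussian-mixture
closed forms of f (times per-level factors 0.85/0.95/1.05/1.15 for
cranio-caudal heterogeneity) plus Gaussian measurement noise, and
dN₂ = 0.5 + 5·f + N(0, 0.4). The link is centred so ≈ half the cohort
exceeds the 2.5 cutoff. Measurement noise is scaled per criterion as
`index_noise_sd × relative × (dynamic range over f ∈ [0,1])`, default
`index_noise_sd = 0.3` with relative noise 0.1 for E/I_MLD and 1.2 for
the rest. These defaults were chosen by a power analysis, not to mimic
any observed cohort: the construction must make exactly one criterion
the strongest-linked so that ranking tests have a defined truth, and
because label noise on dN₂ compresses AUC differences between criteria
that are all monotone in f, a 3–4× noise separation is needed before the
intended winner is identifiable in ≥ 95% of 50-subject cohorts.

**Reader pairs.** Shared subject effects N(0, σs²) plus independent
reader noise N(0, σe²) and optional reader bias, giving population
ICC(2,1) = σs²/(σs² + σe²) minus the bias penalty — closed forms the
estimator tests check against.

## Numerical choices and degenerate inputs

- LAA/parenchyma range bounds inclusive; HU kept as floats (quantisation
  optional at export).
- Empty masks, single-class labels, constant columns, zero inspiratory
  LAA (ratio undefined, difference still valid), zero total variance in
  ICC: all flagged or raised explicitly rather than propagating NaN.
- Breakpoint candidates keep ≥ 3 samples per segment; < 10 samples in
  the search window is an error.
- Exact Friedman enumeration is capped at 10⁶ arrangements ("auto" falls
  back to chi-square beyond that).
- Problem sizes in the validation suite — a 256³ phantom (≈ 2.4 M lung
  voxels), 100 washout curves per condition, 10⁵-per-class binormal ROC,
  5 000-subject reader pairs, 100 cohort seeds at n = 50 — were chosen so
  every Monte-Carlo check has comfortable statistical margin while the
  whole suite runs in well under a minute of compute.

## Known limitations

- Segmentation is threshold-based: it will fail on consolidated lung or
  dense pleural disease, and its airway exclusion assumes the trachea is
  the only air column reaching the most cranial slice.
- Registration-free pairing: E and I are compared at caller-matched
  levels; no deformable registration or voxel-wise difference maps.
- No lobe segmentation, no emphysema index at −950 HU, no
  multiple-breath washout indices.
- The cohort simulator works at the index level (closed forms + noise),
  not by generating a phantom per subject — a deliberate speed choice;
  a small end-to-end test runs full phantoms for 5 subjects through the
  on-disk pipeline.
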