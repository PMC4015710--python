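# airtrap

Quantitative assessment of **air trapping** — gas retained in the lung on
expiration because small airways close or narrow — from paired
inspiratory/expiratory chest CT, validated against the **single-breath
nitrogen washout test** (SBNT) as functional reference, with a
digital-phantom simulation layer so every stage can be tested against
known ground truth.

The package is aimed at researchers in quantitative chest imaging and
pulmonary physiology who need a transparent, fully scriptable alternative
to closed commercial densitometry tools.

## What it computes

**CT densitometry.** Lung parenchyma is segmented by thresholding
(attenuation in [−1024, −500] HU) plus connected components, excluding
everything continuous with the lateral image border and the
tracheal/bronchial air column reaching the apex slice. On the segmented
voxels it measures, per anatomical level and pooled over both lungs:

- MLD — mean lung density (HU);
- LAA%[−1024, −850] — percentage of low-attenuation voxels;
- LAA%[−910, −850] — same with a floor that excludes emphysema-like
  densities below −910 HU.

**Paired criteria.** With E the expiratory and I the inspiratory value of
a basis (MLD or either LAA%), the nine air-trapping criteria are

    E/I,   E − I,   (E − I)/I        for each of the three bases,

with ratios on raw signed HU, so (E−I)/I ≡ E/I − 1 exactly.

**Washout analysis.** From an SBNT trace (N₂ concentration vs expired
volume) it recovers the phase-III slope dN₂ (%N₂/L, by OLS over the
alveolar plateau), the closing volume CV (continuous two-segment fit with
exhaustive breakpoint search over the terminal window), expiratory-flow
quality control, and the obstruction label dN₂ > 2.5 %N₂/L.

**Statistics.** Spearman correlation of each criterion with dN₂, an
average-linkage dendrogram on distance 1 − |ρ|, ROC analysis (AUC with
DeLong 95% CI, Youden-optimal threshold) of the branches closest to dN₂,
inter-reader ICC(2,1), and a Friedman test for heterogeneity across the
four sampling levels (exact permutation p on small samples).

**Simulation.** Digital thorax phantoms (two-Gaussian lung mixture with
focal trapped regions, airway tube, body cylinder), four-phase washout
curves, reader pairs with known variance components, and cohorts in which
dN₂ is a noisy monotone function of the true trapped fraction.

## Worked example

```python
import airtrap as at

spec = at.PhantomSpec(grid_shape=(128, 128, 96), spacing=(1.5, 1.5, 1.5),
                      lung_exp_mean=-750.0, trapped_exp_mean=-880.0,
                      trapped_fraction=0.30, seed=1)
insp, exp, truth = at.generate_phantom(spec)
mask = at.segment_lung(exp)
print(at.mean_lung_density(exp, mask))          # -789.02
print(at.laa_percent(exp, mask, (-1024, -850))) #  29.32
```

The expiratory lung is a 70/30 mixture of N(−750, 20) and N(−880, 15) HU,
so MLD lands on the mixture mean 0.7·(−750) + 0.3·(−880) = −789 HU and
LAA% on the mixture mass below −850 HU (29.32%). Running
`python examples/phantom_densitometry.py` prints exactly this check:

```
segmented 221340 lung voxels in 2 components (Jaccard vs truth: 1.0000)
expiratory MLD  :  -789.02 HU   (mixture closed form -789.00)
expiratory LAA% :    29.32 %    (mixture closed form 29.32)
```

`examples/cohort_comparison.py` runs the full statistics layer on a
simulated 89-subject cohort and ends with the criterion ranking:

```
ROC against the dN2 > 2.5 %N2/L label:
  e_over_i_mld_mean            AUC 0.986 (95% CI 0.971-1.000) threshold 0.910 sens 0.96 spec 0.93
  e_minus_i_mld_mean           AUC 0.905 (95% CI 0.843-0.967) threshold 82.356 sens 0.92 spec 0.76
  e_minus_i_laa850_910_mean    AUC 0.877 (95% CI 0.806-0.948) threshold -48.357 sens 0.83 spec 0.78
```

The expiratory/inspiratory MLD ratio, generated with the strongest link
to the latent trapped fraction, heads the ranking — the package
recovering by measurement what the simulation put in.

Other examples: `washout_analysis.py` (dN₂/CV recovery from a noisy
trace), `air_trapping_indices.py` (the nine criteria at four levels),
`full_pipeline.py` (the on-disk pipeline end to end).

## Command line

A thin CLI wraps the same functions:

```bash
airtrap simulate --out study/ --n 5 --seed 1
airtrap run --inputs study/ --out report/
airtrap sbnt curve.csv --vc 4.0
airtrap quantify --insp i.nii.gz --exp e.nii.gz --levels 14,21,28,36
airtrap analyze cohort.csv --out report/
```

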