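# sporemorph

Outline-based geometric morphometrics of fungal spores: from binary
micrographs to elliptic Fourier shape spaces, linear size traits, and a
cross-validated answer to the question *do shape descriptors, size
descriptors, or their combination identify species best?*

Spore morphology is central to fungal taxonomy, yet spore **shape** is
usually reduced to qualitative terms or to the length/width ratio Q,
while **size** is captured as linear measurements. This package treats
both quantitatively, for microscopic propagules whose outlines carry no
landmarks — the situation of basidiospores seen in lateral projection,
with the hilar appendix (apiculus) as the only orientation anchor.

## What it computes

For each spore outline, parameterized by arc length t over one period T:

```
x(t) = A0 + Σ_n a_n cos(2πnt/T) + b_n sin(2πnt/T)
y(t) = C0 + Σ_n c_n cos(2πnt/T) + d_n sin(2πnt/T)
```

The elliptic Fourier descriptors (a_n, b_n, c_n, d_n), n = 1…20, are
normalized using the first-harmonic ellipse (removing size, rotation,
translation and starting point), which fixes a₁ = 1, b₁ = c₁ = 0: of the
80 stored coefficients, 77 remain as shape variables (NEFDs). The
{a_n, d_n} block carries mirror-symmetric shape variation about the
major axis; {b_n, c_n} carries asymmetric variation (bowing, unequal
ends). Three covariance PCAs — symmetric, asymmetric, global — give the
shape spaces; components with above-mean eigenvalues are "effective",
and each is visualized as the mean outline ± 2 SD. Size traits are the
max Feret length L, the perpendicular caliper width W, Q = L/W and the
integrated size √(L·W). Traits are averaged per image (the observation
unit), correlated by Spearman's ρ, and compared as feature sets via
flexible discriminant analysis (optimal scoring; with the default
linear basis exactly equivalent to classical LDA) under repeated
stratified 70/30 cross-validation.

Because real micrograph collections are external, the package ships a
first-class synthetic generator: bent-capsule spores with species-level
differences in length, width, bowing, end curvature, taper and
apiculus, plus specimen- and spore-level random effects — every
downstream stage is testable against known ground truth.

## Worked example

```python
from sporemorph import PipelineConfig, run_pipeline

cfg = PipelineConfig(mode="polygons", outdir="demo_run", seed=11, n_reps=200)
res = run_pipeline(cfg)
print(res.comparison.table.head(4).to_string(index=False))
```

prints (10 synthetic species, 285 image observations):

```
model  mean_accuracy       sd  n_reps  train_frac       seed
 SALW       0.944405 0.023482     200         0.7 1388763434
  GLW       0.908452 0.029917     200         0.7 1388763434
   LW       0.886964 0.028568     200         0.7 1388763434
  QLW       0.868214 0.030996     200         0.7 1388763434
```

Read: the model combining symmetric + asymmetric shape PCs with length
and width (SALW, 94.4% correct test identifications on average) beats
both the best pure-shape model and length+width alone — the package's
synthetic panels reproduce the shape-plus-size advantage. The `examples/`
directory walks through every stage (simulation, chain coding, EFA,
shape spaces, trait correlations, discrimination, full pipeline); each
script prints the numbers it computes and what they mean.

A thin CLI covers the shell workflows:

```bash
sporemorph simulate --n-species 10 --n-specimens 3 --out panel/
sporemorph run-all --outdir run/ --seed 1 --reps 1000
sporemorph compare --traits run/traits.csv --models S,G,LW,SALW --reps 1000 --seed 1 --out cv.csv
```

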