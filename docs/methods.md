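# Methods

## Problem setting

`parkmvpa` implements a multi-class probabilistic pattern-recognition
pipeline for discriminating Parkinsonian disorders — progressive
supranuclear palsy (PSP), idiopathic Parkinson's disease (IPD), multiple
system atrophy (MSA, with parkinsonian MSA-P and cerebellar MSA-C variants)
— and healthy controls (HC) from structural-MRI-derived morphometric
features, masked to anatomical regions of interest. Because no patient data
are available, the package ships a synthetic cohort generator that
reproduces the *statistical* structure of such features (class-specific
regional atrophy, spatially correlated noise, per-subject global scaling)
on a desk-scale grid, so that every downstream stage is fully testable.

## Synthetic cohort model

The atlas is a 32³ voxel grid holding a spherical "brain" (radius 15
voxels) containing six disjoint spheres standing for the bilateral
subcortical motor network: cerebellum (radius 4), brainstem, caudate,
putamen, pallidum (radius 3 each) and accumbens (radius 2). Remaining brain
tissue is labelled `cortex_background`. Three masks are exposed:
`whole_brain` (all labelled tissue), `subcortical_network` (union of the
six regions) and `region:<name>`.

Each subject is a two-channel volume (grey- and white-matter components of
a morphometric map, e.g. scalar-momentum-like features). For subject *i*
of class *c*, each channel is

    scale_i · (baseline − effect[c, r] · σ  inside region r)  +  ε

where σ is the per-voxel noise SD (default 1.0, arbitrary units),
`baseline` = 1.0, `scale_i` = 1 + N(0, 0.05) is a subject-level
multiplicative factor shared by both channels, and ε is white Gaussian
noise smoothed with a Gaussian of FWHM 2 voxels and rescaled to per-voxel
SD σ (smoothing mimics the spatial correlation of registered morphometric
maps; the rescaling keeps effect sizes interpretable in SD units).
Atrophy is encoded as a *negative* mean shift applied to both channels
with independent noise per channel; the sign convention is internal.

The default effect matrix mirrors the disease topography the classifier is
meant to exploit: PSP loads on all six regions (1.5 σ); MSA-P on brainstem
and cerebellum (1.5 σ) and putamen (1.0 σ); MSA-C most strongly on
cerebellum (2.0 σ) then brainstem (1.5 σ); IPD only weakly on the
brainstem/midbrain (0.75 σ); HC is exactly null (enforced). The source
study does not report per-region effect sizes, so these magnitudes are
modelling choices, selected once to give a qualitatively faithful
difficulty ordering (IPD hardest, MSA easiest), not estimates. Default
group sizes are the study's: 19 HC, 17 PSP, 14 IPD, 12 MSA-P, 7 MSA-C.

What the generator does **not** emulate: anatomy, diffeomorphic
registration and template building, scanner artifacts, bias fields,
age/sex confounds, and within-class heterogeneity beyond the global
scaling factor. Passing tests therefore demonstrate correctness of the
statistical machinery under a known generative model, not clinical
performance on real MRI.

## Features and kernels

Images are masked and both channels concatenated into one row per subject
(grey voxels first, then white, each in ascending linear voxel index).
The per-fold preprocessor is column centering on the training mean
(optional variance scaling, off by default). It stands in for the original
pipeline's fold-wise template construction; the preserved contract is that
*no statistic crosses the train/test boundary*. Channels are concatenated
unweighted — whether the original analysis rescaled the tissue channels
relative to one another is unstated, so no rescaling is applied.

The kernel is linear (required for voxel weight maps). Trace
normalisation is on by default: all kernels of a fold are divided by the
training set's mean self-similarity, which decouples sampler behaviour
from mask size. Linear kernels are block-additive over disjoint masks, a
property the tests exploit (network kernel = sum of region kernels).

## Multinomial probit classifier

For m classes, each class carries an independent latent function with
prior f_c ~ N(0, s·(K + jitter·I)) — the symmetric m-function
parameterisation rather than m−1 contrasts, because the weight maps read
one latent per class. Labels follow the multinomial probit link
y_n = argmax_c(f_c(x_n) + ε_nc), ε standard normal.

Inference is Albert–Chib-style auxiliary-variable Gibbs sampling: one scan
of truncated-normal draws for the noisy latents (the true class's value
sampled above the best other, the rest below it), then a joint Gaussian
draw of all latent functions. Since the prior covariance S commutes with
I, the conditional is N(M·a, M) with M = S(S+I)⁻¹, precomputed once per
fit. Defaults: 500 burn-in, 2000 retained draws, jitter 10⁻⁶ × mean kernel
diagonal, s = 1 on the trace-normalised kernel. Hyperparameters are fixed,
not sampled — a deliberate divergence from a fully Bayesian treatment that
keeps LOO × permutation loops tractable.

Prediction: per posterior draw, the test latents' conditional mean is
computed per class; because the conditional variance v is shared across
classes, the Gaussian test latents are marginalised analytically by
inflating the probit noise to 1 + v, leaving the one-dimensional integral
P(c) = E_u[∏_{j≠c} Φ(u + (μ_c−μ_j)/√(1+v))], evaluated by 32-node
Gauss–Hermite quadrature. This makes prediction deterministic given the
draws and bit-identical for duplicated test rows. For m = 2 the whole
construction reduces to the binary probit GP, which the test suite checks
against dense numerical quadrature at small n (agreement within 0.02 at
2000 draws). Rows are renormalised to sum to one (quadrature residual
~10⁻¹⁰); exact argmax ties break toward the lowest class index with a
logged warning.

## Evaluation

Leave-one-out CV re-fits the preprocessor, kernels and sampler inside
every fold; per-fold sampler seeds derive deterministically from the
classifier seed. A class with a single member is rejected before compute
(its only fold would leave it untrained). The confusion matrix is fixed as
rows = true, columns = predicted; this orientation is forced by defining
sensitivity as a row share. Per-class predictive value is 0 (with a
warning) when a class is never predicted, keeping the OPV a mean over a
fixed class set. Two chance conventions are exposed side by side: the
aggregate chance level is 1/m, while per-class chance bars use training
proportions; they are never merged.

Significance is Monte Carlo label permutation: each of N permutations
reruns the *full* LOO pipeline; p = (1 + #{perm ≥ obs})/(1 + N) (add-one,
so p > 0). Default N = 999; the calibration test uses N = 99 over 200
null cohorts at a reduced size (two classes of four subjects, one region,
20 retained draws) — the permutation p-value is valid for any statistic
computed identically across permutations, so the small sampler does not
bias the test, it only adds variance shared by observed and permuted runs.

The balanced-accuracy interval gives each class an independent
Beta(C_ii+1, n_i−C_ii+1) posterior (uniform prior), averages draws across
classes and reports the central interval. It is a pragmatic, seeded
construction — the exact multi-class interval method of the source
analysis is not reproduced and the reported study intervals are not
validated against it.

The Pearson chi-square helper (for demographic contingency tables) wraps
the standard uncorrected test.

## Weight maps

For the linear kernel the dual-to-primal identity gives per-class voxel
weights w_c = Xᵀα_c with α_c = S⁻¹·f̄_c, where f̄_c is the posterior-mean
latent vector and S the jittered prior covariance. Solving the posterior
mean once is equivalent in expectation to per-draw solves averaged, and
cheaper; the cheaper path is used. Maps are scattered back to the two
channel volumes, are exactly zero outside the mask, and are exported
unthresholded (one NIfTI per class per channel) with a JSON sidecar
carrying per-class L2 norms so unit-norm variants can be reconstructed.
Because subject order enters the sampler's random-variate stream, maps are
invariant to training-subject permutation only up to Monte Carlo error of
the posterior mean.

## Class-structure contrasts

Four diagnostic contrasts are configuration-level label mappings:
I = PSP/IPD/MSA (controls dropped, MSA variants pooled; chance 33%),
II = PSP/IPD/HC/MSA (chance 25%), III = PSP/IPD/MSA-P/MSA-C (chance 25%),
IV = all five groups (chance 20%).

## Numerical choices and degenerate inputs

- Truncated normals are drawn by inverse-CDF with probabilities clipped to
  [10⁻¹², 1−10⁻¹²]; extreme separation therefore saturates rather than
  overflows.
- Kernels must be positive definite after jitter (Cholesky check; failure
  raises rather than silently regularising further).
- Kernel trace-normalisation falls back to 1 when the training matrix is
  identically zero.
- The posterior covariance Cholesky adds 10⁻¹² to the diagonal.
- All randomness flows from named integer seeds; stage and fold seeds are
  derived via `numpy.random.SeedSequence` and kept below 2³¹.

## Problem sizes

Simulation-based checks run at reduced sizes chosen to keep the full suite
desk-scale while leaving clear statistical margins: separable-cohort
recovery uses 3 classes × 8 subjects with 3 σ effects; the permutation
calibration uses 200 replicates × 99 permutations on 8-subject null
cohorts; weight-map localisation uses a 36-subject five-class cohort on
the whole-brain mask; the study-sized (50-prediction) three-class run uses
a reduced sampler (200 draws). Default sampler settings (500/2000) are
intended for single analyses.

## Known limitations

- Spherical regions on a 32³ grid; no anatomical realism.
- Fixed kernel hyperparameters; no model selection.
- The companion inference scheme of the original analysis is not fully
  specified publicly; the sampler here is the closest standard reading
  (multinomial probit, auxiliary-variable Gibbs) and is documented on its
  own terms.
- Real-data accuracies cannot be reproduced without the patient cohort;
  tests validate machinery and statistical behaviour, not clinical claims.
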