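# parkmvpa

Multi-class probabilistic pattern recognition for Parkinsonian disorders
from region-masked volumetric MRI features.

Clinical differentiation of progressive supranuclear palsy (PSP),
idiopathic Parkinson's disease (IPD) and multiple system atrophy (MSA;
parkinsonian MSA-P and cerebellar MSA-C variants) is hard, especially
early in the disease course. This package implements the full analysis
pipeline for discriminating these disorders (and healthy controls, HC)
*simultaneously* — rather than pair-wise — from two-channel morphometric
feature maps masked to a subcortical motor network (bilateral cerebellum,
brainstem, caudate, putamen, pallidum, accumbens), its component regions,
or the whole brain.

The core classifier is a multinomial probit Gaussian-process model over a
linear kernel: per class c a latent function f_c ~ N(0, s·(K + λI)), with
observed diagnosis y_n = argmax_c (f_c(x_n) + ε_nc), ε ~ N(0,1).
Inference is auxiliary-variable Gibbs sampling; predictions are posterior
class probabilities — quantitative diagnostic confidence, not just hard
labels. Around it:

- a **synthetic cohort generator** (spherical-region atlas, class-specific
  regional atrophy, smooth spatial noise) standing in for patient data;
- **leave-one-out cross-validation** with every preprocessing statistic
  re-estimated inside each training fold;
- **balanced multi-class metrics**: per-class sensitivity Sens_i =
  C_ii/Σ_j C_ij and predictive value PV_i = C_ii/Σ_j C_ji from the
  confusion matrix C (rows = true), with balanced accuracy = mean_i Sens_i
  and overall predictive value (OPV) = mean_i PV_i;
- **Monte Carlo permutation tests** for metric significance, and Beta
  posterior intervals for the balanced accuracy;
- **voxel weight maps** per class via the linear-kernel dual-to-primal
  identity w_c = Xᵀ(S⁻¹ f̄_c).

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

```bash
# simulate a study-sized cohort: 19 HC, 17 PSP, 14 IPD, 12 MSA-P, 7 MSA-C
parkmvpa simulate --out cohort/ --seed 1

# three-class disease contrast (PSP vs IPD vs MSA) on the motor network
parkmvpa run --cohort cohort/ --out results/ --contrast I --seed 1
```

which prints (the synthetic default effects make the three disease
classes fully separable):

```
balanced accuracy 100.0%, OPV 100.0% (50 predictions)
```

and `parkmvpa report --out results/` shows the per-class table:

```
classes: PSP, IPD, MSA
confusion (rows=true, cols=predicted):
     PSP [17, 0, 0]
     IPD [0, 14, 0]
     MSA [0, 0, 19]
     PSP  sens 100.0%  pv 100.0%
     IPD  sens 100.0%  pv 100.0%
     MSA  sens 100.0%  pv 100.0%
balanced accuracy 100.0%  OPV 100.0%  chance 33.3%
```

Each subject receives a row of posterior class probabilities
(`results/cv_result.json`); the hard labels above are row-wise argmax.
`parkmvpa permute` attaches a permutation p-value to the balanced
accuracy, and `parkmvpa maps` exports per-class voxel weight volumes.
The same pipeline is available as a library:

```python
import parkmvpa as pk
from parkmvpa.probit import ClassifierConfig

atlas = pk.build_atlas()
images, labels = pk.generate_cohort(atlas, pk.default_design(seed=1))
keep, mapped, classes = pk.apply_contrast(labels["class"], "I")
fm = pk.extract_features([images[i] for i in keep], atlas, "subcortical_network")
res = pk.loo_cross_validate(fm, mapped,
                            ClassifierConfig(n_classes=3, seed=1),
                            class_names=classes)
print(res.metrics.balanced_accuracy, res.confusion.counts)
```

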