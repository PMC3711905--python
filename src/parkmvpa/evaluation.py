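"""Cross-validated assessment: LOO harness, balanced multi-class metrics,
chance levels, Monte Carlo significance, interval estimates and small
cohort-summary statistics.

Confusion matrices are oriented rows = true class, columns = predicted class.
Sensitivity of class i is its diagonal share of row i; predictive value its
diagonal share of column i; balanced accuracy and overall predictive value
(OPV) are unweighted class means of the two, which makes the aggregate
metrics insensitive to class imbalance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    FeatureMatrix,
    apply_preprocessor,
    build_fold_kernels,
    fit_fold_preprocessor,
)
from .probit import (
    ClassifierConfig,
    PredictiveDistribution,
    assign_class,
    fit_classifier,
    predict_probabilities,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Confusion matrices and metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray                # (m, m) ints, rows=true, cols=predicted
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        m = len(self.class_names)
        if c.shape != (m, m):
            raise ValueError("counts must be m x m for m class names")
        if np.any(c < 0):
            raise ValueError("negative counts")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: np.ndarray
    predictive_value: np.ndarray
    balanced_accuracy: float
    overall_predictive_value: float
    chance_accuracy: float
    per_class_chance: np.ndarray
    class_names: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "sensitivity": self.sensitivity.tolist(),
            "predictive_value": self.predictive_value.tolist(),
            "balanced_accuracy": self.balanced_accuracy,
            "overall_predictive_value": self.overall_predictive_value,
            "chance_accuracy": self.chance_accuracy,
            "per_class_chance": self.per_class_chance.tolist(),
        }


def confusion_matrix(
    true_labels: Sequence, predicted_labels: Sequence, class_names: Sequence[str]
) -> ConfusionMatrix:
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) == 0:
        raise ValueError("no predictions to tabulate")
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true/predicted length mismatch")
    index = {c: i for i, c in enumerate(class_names)}
    m = len(class_names)
    counts = np.zeros((m, m), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class_names: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class sensitivity / predictive value and their unweighted means.

    A class that is never predicted gets predictive value 0 (with a warning)
    rather than being dropped, so the OPV stays a mean over a fixed class set
    and degenerate classifiers are penalised.
    """
    C = np.asarray(cm.counts, dtype=float)
    if C.sum() == 0:
        raise ValueError("all-zero confusion matrix")
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    m = len(cm.class_names)
    sens = np.zeros(m)
    pv = np.zeros(m)
    for i in range(m):
        if row[i] > 0:
            sens[i] = C[i, i] / row[i]
        else:
            logger.warning("class %r has no true cases; sensitivity set to 0",
                           cm.class_names[i])
        if col[i] > 0:
            pv[i] = C[i, i] / col[i]
        else:
            logger.warning("class %r never predicted; predictive value set to 0",
                           cm.class_names[i])
    return MetricsReport(
        sensitivity=sens,
        predictive_value=pv,
        balanced_accuracy=float(sens.mean()),
        overall_predictive_value=float(pv.mean()),
        chance_accuracy=1.0 / m,
        per_class_chance=row / row.sum(),
        class_names=cm.class_names,
    )


def chance_levels(training_labels: Sequence, m: int) -> tuple[float, dict]:
    """Uninformed-guessing accuracy (1/m) and per-class training proportions.

    The aggregate chance level is 1/m; the per-class chance bars are the
    proportion of each class in the training labels.  Both conventions are in
    circulation, so both are returned rather than silently merged.
    """
    if m < 2:
        raise ValueError("need at least two classes")
    labels = list(training_labels)
    n = len(labels)
    per_class = {c: labels.count(c) / n for c in dict.fromkeys(labels)} if n else {}
    return 1.0 / m, per_class


# ---------------------------------------------------------------------------
# LOO cross-validation with fold-local preprocessing

@dataclass(frozen=True)
class CVResult:
    probabilities: np.ndarray         # (n, m) held-out predictive probabilities
    predicted: np.ndarray             # (n,) hard labels (class-name strings)
    true: np.ndarray                  # (n,)
    class_names: tuple[str, ...]
    confusion: ConfusionMatrix
    metrics: MetricsReport
    config: dict

    @property
    def n_predictions(self) -> int:
        return len(self.true)

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "probabilities": self.probabilities.tolist(),
            "predicted": self.predicted.tolist(),
            "true": self.true.tolist(),
            "confusion": self.confusion.counts.tolist(),
            "metrics": self.metrics.to_dict(),
            "config": self.config,
        }


def fold_seed(base_seed: int, fold: int) -> int:
    """Deterministic per-fold sampler seed below 2**31."""
    return int(np.random.SeedSequence([base_seed, fold]).generate_state(1)[0] % (2**31))


def loo_cross_validate(
    features: FeatureMatrix,
    labels: Sequence[str],
    classifier_config: ClassifierConfig,
    with_scaling: bool = False,
    normalize_kernel: bool = True,
    class_names: Sequence[str] | None = None,
) -> CVResult:
    """Leave-one-out CV with all preprocessing embedded in the loop.

    Each fold re-fits the feature preprocessor on the training subjects only,
    rebuilds the (trace-normalised) kernels from the transformed matrices,
    runs the sampler with a fold-specific seed derived from the classifier
    seed, and predicts the single held-out subject.
    """
    labels = np.asarray(list(labels), dtype=object)
    n = len(labels)
    if features.n_subjects != n:
        raise ValueError("labels length must match feature rows")
    if class_names is None:
        class_names = tuple(dict.fromkeys(labels))
    class_names = tuple(class_names)
    code = {c: i for i, c in enumerate(class_names)}
    m = len(class_names)
    y = np.array([code[c] for c in labels])
    counts = np.bincount(y, minlength=m)
    if np.any(counts < 2):
        bad = [class_names[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(
            f"each class needs at least 2 subjects for LOO; too few in {bad}"
        )

    probs = np.zeros((n, m))
    cfg = replace(classifier_config, n_classes=m)
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        train = features.rows(train_idx)
        test = features.rows([i])
        prep = fit_fold_preprocessor(train, with_scaling=with_scaling)
        train = apply_preprocessor(prep, train)
        test = apply_preprocessor(prep, test)
        K_train, K_cross, k_diag = build_fold_kernels(
            train, test, normalize=normalize_kernel
        )
        fold_cfg = replace(cfg, seed=fold_seed(cfg.seed, i))
        post = fit_classifier(K_train, y[train_idx], fold_cfg)
        pred = predict_probabilities(post, K_cross, k_diag)
        probs[i] = pred.probabilities[0]

    hard_idx = assign_class(PredictiveDistribution(probabilities=probs))
    predicted = np.array([class_names[k] for k in hard_idx], dtype=object)
    cm = confusion_matrix(labels, predicted, class_names)
    return CVResult(
        probabilities=probs,
        predicted=predicted,
        true=labels,
        class_names=class_names,
        confusion=cm,
        metrics=compute_metrics(cm),
        config={
            "n_classes": m,
            "n_samples": cfg.n_samples,
            "n_burnin": cfg.n_burnin,
            "seed": cfg.seed,
            "kernel_jitter": cfg.kernel_jitter,
            "latent_prior_scale": cfg.latent_prior_scale,
            "with_scaling": with_scaling,
            "normalize_kernel": normalize_kernel,
        },
    )


# ---------------------------------------------------------------------------
# Monte Carlo significance

@dataclass(frozen=True)
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    seed: int


def permutation_test(
    features: FeatureMatrix,
    labels: Sequence[str],
    metric: Callable[[CVResult], float],
    n_permutations: int,
    seed: int,
    classifier_config: ClassifierConfig | None = None,
    **loo_kwargs,
) -> PermutationResult:
    """Label-permutation null for any CV metric.

    Each permutation reruns the full LOO pipeline (preprocessing included) on
    shuffled labels; the add-one estimator p = (1 + #{perm >= obs}) / (1 + N)
    avoids zero p-values.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    labels = np.asarray(list(labels), dtype=object)
    cfg = classifier_config or ClassifierConfig(n_classes=len(set(labels)))
    class_names = tuple(dict.fromkeys(labels))
    observed = metric(
        loo_cross_validate(features, labels, cfg, class_names=class_names, **loo_kwargs)
    )
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        shuffled = labels[rng.permutation(len(labels))]
        try:
            permuted[b] = metric(
                loo_cross_validate(
                    features, shuffled, cfg, class_names=class_names, **loo_kwargs
                )
            )
        except Exception as exc:
            raise RuntimeError(f"metric failed on permutation {b}: {exc}") from exc
    p = (1.0 + np.sum(permuted >= observed)) / (1.0 + n_permutations)
    return PermutationResult(
        observed=float(observed), permuted=permuted, p_value=float(p), seed=seed
    )


def significance_marker(p: float) -> str:
    """Report markers: '*' p<0.01, '#' p<0.05, '+' p<0.1, '' otherwise."""
    if p < 0.01:
        return "*"
    if p < 0.05:
        return "#"
    if p < 0.1:
        return "+"
    return ""


def balanced_accuracy_interval(
    cm: ConfusionMatrix, level: float = 0.95, n_draws: int = 20000, seed: int = 0
) -> tuple[float, float]:
    """Central posterior interval for the balanced accuracy.

    Each class's accuracy gets an independent Beta(C_ii + 1, n_i - C_ii + 1)
    posterior (uniform prior on the per-class accuracy); draws are averaged
    across classes and the central ``level`` interval of the mean reported.
    """
    C = np.asarray(cm.counts, dtype=float)
    row = C.sum(axis=1)
    diag = np.diag(C)
    rng = np.random.default_rng(seed)
    draws = rng.beta(diag + 1.0, row - diag + 1.0, size=(n_draws, len(row)))
    mean = draws.mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(mean, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence for an r x c contingency table."""
    T = np.asarray(table, dtype=float)
    if T.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(T < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(T, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# Class-structure contrasts (which diagnostic groups form the classes)

#: The four diagnostic contrasts: whether healthy controls are included and
#: whether the MSA variants are pooled into one class or kept distinct.
CONTRASTS: Mapping[str, dict] = {
    "I": {"include_hc": False, "split_msa": False,
          "classes": ("PSP", "IPD", "MSA")},
    "II": {"include_hc": True, "split_msa": False,
           "classes": ("PSP", "IPD", "HC", "MSA")},
    "III": {"include_hc": False, "split_msa": True,
            "classes": ("PSP", "IPD", "MSA-P", "MSA-C")},
    "IV": {"include_hc": True, "split_msa": True,
           "classes": ("PSP", "IPD", "HC", "MSA-P", "MSA-C")},
}


def apply_contrast(
    labels: Sequence[str], contrast: str
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Map raw group labels (HC/PSP/IPD/MSA-P/MSA-C) to a contrast's classes.

    Returns (kept row indices, mapped labels, class names).  Pooling maps
    MSA-P and MSA-C to a single MSA class; contrasts without HC drop the
    control subjects.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected I-IV")
    spec = CONTRASTS[contrast]
    labels = np.asarray(list(labels), dtype=object)
    mapped = []
    keep = []
    for i, lab in enumerate(labels):
        if lab == "HC" and not spec["include_hc"]:
            continue
        if lab in ("MSA-P", "MSA-C") and not spec["split_msa"]:
            lab = "MSA"
        if lab not in spec["classes"]:
            raise ValueError(f"unexpected group label {labels[i]!r}")
        keep.append(i)
        mapped.append(lab)
    return np.asarray(keep), np.asarray(mapped, dtype=object), spec["classes"]
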