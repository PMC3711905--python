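import logging

import numpy as np
import pytest

import parkmvpa as pk
from parkmvpa.probit import ClassifierConfig

# keep the never-predicted / tie warnings out of test output noise
logging.getLogger("parkmvpa").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def atlas():
    return pk.build_atlas()


@pytest.fixture(scope="session")
def separable_cohort(atlas):
    """Three well-separated classes (3 SD regional effects), 8 per class."""
    design = pk.default_design(
        seed=11,
        class_names=("HC", "C1", "C2"),
        n_per_class={"HC": 8, "C1": 8, "C2": 8},
        effects={"HC": {}, "C1": {"cerebellum": 3.0}, "C2": {"putamen": 3.0}},
    )
    images, labels = pk.generate_cohort(atlas, design)
    fm = pk.extract_features(images, atlas, "subcortical_network")
    return fm, list(labels["class"])


@pytest.fixture(scope="session")
def null_cohort(atlas):
    """Zero-effect cohort: labels carry no information about the images."""
    design = pk.default_design(
        seed=12,
        class_names=("HC", "C1", "C2"),
        n_per_class={"HC": 8, "C1": 8, "C2": 8},
        effects={"HC": {}, "C1": {}, "C2": {}},
    )
    images, labels = pk.generate_cohort(atlas, design)
    fm = pk.extract_features(images, atlas, "subcortical_network")
    return fm, list(labels["class"])


@pytest.fixture
def fast_config():
    """Small sampler adequate for smoke-level checks."""
    return ClassifierConfig(n_classes=2, n_samples=100, n_burnin=50, seed=0)


def chance_band(true_labels, predicted_labels, n_mc=2000, level=0.95, seed=0):
    """Central Monte Carlo band of the balanced accuracy under chance.

    Shuffles the predicted labels relative to the true ones, which preserves
    the predicted-class frequencies while destroying any association.
    """
    rng = np.random.default_rng(seed)
    true = np.asarray(list(true_labels), dtype=object)
    pred = np.asarray(list(predicted_labels), dtype=object)
    class_names = tuple(dict.fromkeys(true))
    vals = np.empty(n_mc)
    for b in range(n_mc):
        cm = pk.confusion_matrix(true, pred[rng.permutation(len(pred))], class_names)
        vals[b] = pk.compute_metrics(cm).balanced_accuracy
    alpha = (1 - level) / 2
    return tuple(np.quantile(vals, [alpha, 1 - alpha]))
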