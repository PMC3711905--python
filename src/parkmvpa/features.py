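"""Masked feature matrices and linear kernels.

Images become a subjects × voxels-within-mask matrix with the grey channel's
voxels first and the white channel's second, exactly as the kernel classifier
consumes them.  All preprocessing statistics (the fold preprocessor) are
estimable from a training subset only, so a cross-validation harness can keep
train and test strictly independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import RegionAtlas, SubjectImage


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects × features matrix plus the voxel/channel index per column."""

    values: np.ndarray            # (n_subjects, n_features) float64
    subject_ids: tuple[str, ...]
    channel_index: np.ndarray     # (n_features,) 0 = grey, 1 = white
    voxel_index: np.ndarray       # (n_features,) linear voxel index (C order)
    mask_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != len(self.subject_ids):
            raise ValueError("values must be (n_subjects, n_features)")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.channel_index) != v.shape[1] or len(self.voxel_index) != v.shape[1]:
            raise ValueError("feature index length mismatch")
        pairs = np.stack([self.channel_index, self.voxel_index], axis=1)
        if len(np.unique(pairs, axis=0)) != v.shape[1]:
            raise ValueError("duplicate (channel, voxel) feature index entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def rows(self, idx) -> "FeatureMatrix":
        """Row subset preserving the feature index."""
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            subject_ids=tuple(np.asarray(self.subject_ids, dtype=object)[idx]),
        )

    def same_feature_index(self, other: "FeatureMatrix") -> bool:
        return (
            self.values.shape[1] == other.values.shape[1]
            and np.array_equal(self.channel_index, other.channel_index)
            and np.array_equal(self.voxel_index, other.voxel_index)
        )


def extract_features(
    images: Sequence[SubjectImage], atlas: RegionAtlas, mask_name: str
) -> FeatureMatrix:
    """Mask both channels and concatenate them into one row per subject.

    Columns are channel-0 (grey) voxels then channel-1 (white) voxels, each in
    ascending linear (C-order) voxel index.
    """
    mask = atlas.mask(mask_name)
    lin = np.flatnonzero(mask.ravel())
    if lin.size == 0:
        raise ValueError(f"mask {mask_name!r} is empty")
    rows = []
    for img in images:
        for ch in img.channels:
            if ch.shape != atlas.grid_dims:
                raise ValueError(
                    f"grid mismatch for {img.subject_id}: {ch.shape} vs {atlas.grid_dims}"
                )
        rows.append(np.concatenate([ch.ravel()[lin] for ch in img.channels]))
    values = np.asarray(rows, dtype=np.float64)
    return FeatureMatrix(
        values=values,
        subject_ids=tuple(img.subject_id for img in images),
        channel_index=np.repeat([0, 1], lin.size),
        voxel_index=np.tile(lin, 2),
        mask_name=mask_name,
    )


@dataclass(frozen=True)
class FoldPreprocessor:
    """Per-feature centering (and optional scaling) fit on training rows only.

    Stands in for the study-specific template building of the original
    pipeline: the preserved contract is that no statistic crosses the
    train/test boundary.
    """

    training_mean: np.ndarray
    training_scale: np.ndarray | None = None


def fit_fold_preprocessor(train: FeatureMatrix, with_scaling: bool = False) -> FoldPreprocessor:
    if train.n_subjects == 0:
        raise ValueError("empty training matrix")
    mean = train.values.mean(axis=0)
    scale = None
    if with_scaling:
        scale = train.values.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
    return FoldPreprocessor(training_mean=mean, training_scale=scale)


def apply_preprocessor(prep: FoldPreprocessor, fm: FeatureMatrix) -> FeatureMatrix:
    if prep.training_mean.shape[0] != fm.n_features:
        raise ValueError("preprocessor/feature dimension mismatch")
    values = fm.values - prep.training_mean
    if prep.training_scale is not None:
        values = values / prep.training_scale
    return replace(fm, values=values)


@dataclass(frozen=True)
class KernelMatrix:
    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("kernel shape does not match id lists")


def mean_self_similarity(fm: FeatureMatrix) -> float:
    """Mean squared row norm — the trace-normalisation constant."""
    return float(np.mean(np.einsum("ij,ij->i", fm.values, fm.values)))


def linear_kernel(
    A: FeatureMatrix, B: FeatureMatrix | None = None, scale: float | None = None
) -> KernelMatrix:
    """Gram matrix of inner products, optionally divided by ``scale``.

    For consistent train/test geometry pass the *training* mean
    self-similarity as ``scale`` for both the training and the cross kernel
    (see :func:`build_fold_kernels`).
    """
    if B is None:
        B = A
    if not A.same_feature_index(B):
        raise ValueError("feature index mismatch between kernel inputs")
    values = A.values @ B.values.T
    if scale is not None:
        values = values / scale
    return KernelMatrix(values=values, row_ids=A.subject_ids, col_ids=B.subject_ids)


def build_fold_kernels(
    train: FeatureMatrix, test: FeatureMatrix, normalize: bool = True
) -> tuple[KernelMatrix, KernelMatrix, np.ndarray]:
    """(K_train, K_cross, k_test_diag) with a shared training-derived scale.

    Trace normalisation (on by default) divides every kernel by the training
    set's mean self-similarity, decoupling sampler step sizes from mask size.
    """
    scale = mean_self_similarity(train) if normalize else None
    if scale is not None and scale <= 0:
        scale = 1.0
    K_train = linear_kernel(train, scale=scale)
    K_cross = linear_kernel(test, train, scale=scale)
    diag = np.einsum("ij,ij->i", test.values, test.values)
    if scale is not None:
        diag = diag / scale
    return K_train, K_cross, diag


# ---------------------------------------------------------------------------
# Simple on-disk round trip: .npy payload + JSON sidecar.

def save_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), fm.values)
    sidecar = {
        "subject_ids": list(fm.subject_ids),
        "channel_index": fm.channel_index.tolist(),
        "voxel_index": fm.voxel_index.tolist(),
        "mask_name": fm.mask_name,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return FeatureMatrix(
        values=values,
        subject_ids=tuple(sidecar["subject_ids"]),
        channel_index=np.asarray(sidecar["channel_index"]),
        voxel_index=np.asarray(sidecar["voxel_index"]),
        mask_name=sidecar["mask_name"],
    )
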