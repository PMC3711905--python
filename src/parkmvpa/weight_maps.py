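"""Multi-class voxel weight maps for the linear-kernel classifier.

For a linear kernel the classifier's discriminative pattern can be pulled
back from dual to primal space: with posterior-mean latent values f_bar_c for
class c, the dual coefficients are the conditional-mean solve against the
jittered prior covariance, alpha_c = S^{-1} f_bar_c, and the voxel weights
are w_c = X^T alpha_c, scattered back to the two channel volumes.  Maps are
descriptive: unthresholded, no multiple-comparison correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import nibabel as nib
from scipy.linalg import cho_solve

from .cohort import CHANNEL_NAMES, RegionAtlas
from .features import FeatureMatrix
from .probit import PosteriorSamples


@dataclass(frozen=True)
class WeightMap:
    """Per-class, per-channel weight volumes on the atlas grid."""

    volumes: np.ndarray               # (m, 2, *grid)
    class_names: tuple[str, ...]
    mask_name: str
    affine: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.volumes.shape[0]

    def class_volume(self, name: str, channel: str) -> np.ndarray:
        c = self.class_names.index(name)
        ch = CHANNEL_NAMES.index(channel)
        return self.volumes[c, ch]

    def flat_weights(self, train: FeatureMatrix) -> np.ndarray:
        """(m, n_features) weights in the training feature-column order."""
        out = np.empty((self.n_classes, train.n_features))
        for c in range(self.n_classes):
            for ch in (0, 1):
                cols = train.channel_index == ch
                out[c, cols] = self.volumes[c, ch].ravel()[train.voxel_index[cols]]
        return out


def compute_weight_maps(
    post: PosteriorSamples,
    train: FeatureMatrix,
    atlas: RegionAtlas,
    class_names: Sequence[str] | None = None,
) -> WeightMap:
    """Recover voxel weights from a classifier fit on ``train``'s linear kernel.

    ``post`` must have been fit on the linear kernel of ``train`` (subject
    ids are checked).  The posterior-mean latents are solved against the
    jittered prior covariance once (rather than per draw and averaged — the
    two agree in expectation and the single solve is cheaper).
    """
    if tuple(post.kernel.row_ids) != tuple(train.subject_ids):
        raise ValueError("posterior kernel subjects do not match training matrix")
    m = post.config.n_classes
    if class_names is None:
        class_names = tuple(str(c) for c in range(m))
    if len(class_names) != m:
        raise ValueError("class_names length must equal number of classes")

    f_bar = post.latent_draws.mean(axis=0)                  # (n, m)
    alpha = cho_solve(post.prior_cov_cho, f_bar)            # S^{-1} f_bar
    W = train.values.T @ alpha                              # (p, m)

    grid = atlas.grid_dims
    vols = np.zeros((m, 2) + grid)
    for ch in (0, 1):
        cols = np.flatnonzero(train.channel_index == ch)
        for c in range(m):
            flat = np.zeros(int(np.prod(grid)))
            flat[train.voxel_index[cols]] = W[cols, c]
            vols[c, ch] = flat.reshape(grid)
    return WeightMap(
        volumes=vols,
        class_names=tuple(class_names),
        mask_name=train.mask_name,
        affine=atlas.affine,
    )


def export_weight_maps(maps: WeightMap, atlas: RegionAtlas, directory: str | Path) -> list[Path]:
    """One NIfTI per class per channel plus a JSON sidecar.

    The sidecar records the class order and each class's L2 norm so unit-norm
    variants can be reconstructed from the raw volumes.
    """
    if maps.volumes.shape[2:] != atlas.grid_dims:
        raise ValueError("weight-map grid does not match atlas grid")
    if not np.allclose(maps.affine, atlas.affine):
        raise ValueError("weight-map affine does not match atlas affine")
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    norms = {}
    for c, cls in enumerate(maps.class_names):
        norms[cls] = float(np.linalg.norm(maps.volumes[c]))
        for ch, ch_name in enumerate(CHANNEL_NAMES):
            path = out / f"weights_{cls}_{ch_name}.nii.gz"
            nib.save(
                nib.Nifti1Image(maps.volumes[c, ch].astype(np.float32), atlas.affine),
                path,
            )
            written.append(path)
    sidecar = {
        "class_names": list(maps.class_names),
        "channels": list(CHANNEL_NAMES),
        "mask_name": maps.mask_name,
        "normalization": "raw; per-class L2 norms below",
        "l2_norms": norms,
    }
    (out / "weights.json").write_text(json.dumps(sidecar, indent=2))
    return written
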