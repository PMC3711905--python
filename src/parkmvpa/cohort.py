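"""Synthetic cohorts of two-channel volumetric morphometry maps.

The real study material — diffeomorphically registered structural MRI with
grey-/white-matter "scalar momentum" components — is emulated here by a
desk-scale simulator: a small integer-labelled atlas of spherical subcortical
regions inside a spherical "brain", and per-subject two-channel volumes in
which disease classes express tissue loss as a negative mean shift inside
their affected regions, on top of spatially smoothed Gaussian noise and a
subject-level global scaling factor.

Only the *statistical* structure of the features is emulated (class-specific
regional effects, spatial noise correlation, per-subject scaling); anatomy
and registration are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import nibabel as nib
import yaml
from scipy.ndimage import gaussian_filter

#: The six bilateral regions making up the subcortical motor network.
NETWORK_REGIONS = (
    "cerebellum",
    "brainstem",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
)

#: Label given to brain tissue outside the six network regions.
BACKGROUND_REGION = "cortex_background"

#: FWHM of a Gaussian in units of its standard deviation.
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

CHANNEL_NAMES = ("grey", "white")


@dataclass(frozen=True)
class RegionAtlas:
    """Integer-labelled 3D volume naming subcortical regions.

    ``labels`` holds 0 outside the brain, the label of one of the six
    network regions inside that region, and the ``cortex_background`` label
    for remaining brain tissue.  ``affine`` maps 0-based voxel indices to
    world mm coordinates, with voxel (0,0,0) centred at the world origin.
    """

    labels: np.ndarray
    region_names: Mapping[int, str]
    affine: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        present = set(np.unique(labels)) - {0}
        unnamed = present - set(self.region_names)
        if unnamed:
            raise ValueError(f"unnamed atlas labels: {sorted(unnamed)}")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    def label_of(self, name: str) -> int:
        for lab, nm in self.region_names.items():
            if nm == name:
                return lab
        raise KeyError(f"unknown region name: {name!r}")

    def mask(self, mask_name: str) -> np.ndarray:
        """Boolean mask for ``whole_brain``, ``subcortical_network`` or
        ``region:<name>``."""
        if mask_name == "whole_brain":
            return self.labels > 0
        if mask_name == "subcortical_network":
            net = [self.label_of(n) for n in NETWORK_REGIONS
                   if any(nm == n for nm in self.region_names.values())]
            return np.isin(self.labels, net)
        if mask_name.startswith("region:"):
            return self.labels == self.label_of(mask_name.split(":", 1)[1])
        raise ValueError(f"unknown mask name: {mask_name!r}")

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)


@dataclass(frozen=True)
class SubjectImage:
    """One subject's two-channel (grey/white) morphometric feature map."""

    channels: tuple[np.ndarray, np.ndarray]
    subject_id: str
    class_label: str

    def __post_init__(self) -> None:
        if len(self.channels) != 2:
            raise ValueError("expected exactly two channels (grey, white)")
        shape = self.channels[0].shape
        for ch in self.channels:
            if ch.shape != shape:
                raise ValueError("channel grids differ")
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"non-finite voxels in {self.subject_id}")


@dataclass(frozen=True)
class CohortDesign:
    """Generative design of a synthetic cohort.

    ``effects`` maps class name -> region name -> mean tissue-loss shift in
    units of the per-voxel noise SD (positive numbers mean atrophy, i.e. a
    *negative* shift of the stored intensity).  A class named ``HC`` must
    have no effects.
    """

    class_names: tuple[str, ...]
    n_per_class: Mapping[str, int]
    effects: Mapping[str, Mapping[str, float]]
    noise_sd: float = 1.0
    smoothing_fwhm: float = 2.0
    subject_scale_sd: float = 0.05
    baseline: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_names:
            raise ValueError("at least one class required")
        for c in self.class_names:
            if self.n_per_class.get(c, 0) < 1:
                raise ValueError(f"class {c!r} needs at least one subject")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        hc = self.effects.get("HC", {})
        if any(abs(v) > 0 for v in hc.values()):
            raise ValueError("HC effects must all be zero")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_class[c] for c in self.class_names)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_names"] = list(self.class_names)
        d["n_per_class"] = dict(self.n_per_class)
        d["effects"] = {c: dict(r) for c, r in self.effects.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortDesign":
        d = dict(d)
        d["class_names"] = tuple(d["class_names"])
        return cls(**d)


# Default effect pattern, mirroring the disease topography the classifier is
# meant to pick up: PSP affects all six regions; MSA-P loads on brainstem,
# cerebellum and putamen; MSA-C most strongly on cerebellum then brainstem;
# IPD shows only a weak brainstem (midbrain) effect; HC is null.  Magnitudes
# are modelling choices in units of the voxel noise SD.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "PSP": {r: 1.5 for r in NETWORK_REGIONS},
    "MSA-P": {"brainstem": 1.5, "cerebellum": 1.5, "putamen": 1.0},
    "MSA-C": {"cerebellum": 2.0, "brainstem": 1.5},
    "IPD": {"brainstem": 0.75},
    "HC": {},
}

#: Study-sized cohort: 19 HC, 17 PSP, 14 IPD, 19 MSA (12 MSA-P + 7 MSA-C).
DEFAULT_N_PER_CLASS = {"HC": 19, "PSP": 17, "IPD": 14, "MSA-P": 12, "MSA-C": 7}


def default_design(seed: int = 0, **overrides) -> CohortDesign:
    """The package's reference cohort design (study-sized, default effects)."""
    kw = dict(
        class_names=("HC", "PSP", "IPD", "MSA-P", "MSA-C"),
        n_per_class=dict(DEFAULT_N_PER_CLASS),
        effects={c: dict(e) for c, e in DEFAULT_EFFECTS.items()},
        seed=seed,
    )
    kw.update(overrides)
    return CohortDesign(**kw)


DEFAULT_REGION_SPEC: dict[str, tuple[tuple[int, int, int], float]] = {
    BACKGROUND_REGION: ((16, 16, 16), 15.0),
    "cerebellum": ((16, 8, 9), 4.0),
    "brainstem": ((16, 16, 9), 3.0),
    "caudate": ((10, 20, 16), 3.0),
    "putamen": ((22, 20, 16), 3.0),
    "pallidum": ((10, 12, 20), 3.0),
    "accumbens": ((22, 12, 20), 2.0),
}


def _sphere(grid: tuple[int, int, int], center, radius: float) -> np.ndarray:
    ax = [np.arange(n) for n in grid]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    c = np.asarray(center, dtype=float)
    return (dx - c[0]) ** 2 + (dy - c[1]) ** 2 + (dz - c[2]) ** 2 <= radius**2


def build_atlas(
    grid_dims: Sequence[int] = (32, 32, 32),
    region_spec: Mapping[str, tuple[Sequence[int], float]] | None = None,
    voxel_size_mm: float = 1.0,
) -> RegionAtlas:
    """Build a spherical-region atlas on a small grid.

    ``region_spec`` maps region name -> (center voxel, radius in voxels).
    An entry named ``cortex_background`` is painted first and stands for
    brain tissue outside the named regions; the named network regions must be
    pairwise disjoint and fit inside the grid.
    """
    grid = tuple(int(n) for n in grid_dims)
    if len(grid) != 3 or any(n <= 0 for n in grid):
        raise ValueError("grid_dims must be three positive integers")
    spec = dict(region_spec if region_spec is not None else DEFAULT_REGION_SPEC)

    named = [n for n in spec if n != BACKGROUND_REGION]
    masks: dict[str, np.ndarray] = {}
    for name in spec:
        center, radius = spec[name]
        if radius <= 0:
            raise ValueError(f"region {name!r} has non-positive radius")
        lo = np.floor(np.asarray(center, float) - radius)
        hi = np.ceil(np.asarray(center, float) + radius)
        if name != BACKGROUND_REGION and (np.any(lo < 0) or np.any(hi > np.asarray(grid) - 1)):
            raise ValueError(f"region {name!r} does not fit inside the grid")
        masks[name] = _sphere(grid, center, radius)

    for i, a in enumerate(named):
        for b in named[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"regions overlap: {a!r} and {b!r}")

    labels = np.zeros(grid, dtype=np.int16)
    region_names: dict[int, str] = {}
    next_label = 1
    for name in named:
        if not masks[name].any():
            raise ValueError(f"region {name!r} is empty")
        labels[masks[name]] = next_label
        region_names[next_label] = name
        next_label += 1
    if BACKGROUND_REGION in spec:
        bg = masks[BACKGROUND_REGION] & (labels == 0)
        labels[bg] = next_label
        region_names[next_label] = BACKGROUND_REGION

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    return RegionAtlas(labels=labels, region_names=region_names, affine=affine)


def _smooth_noise(rng: np.random.Generator, grid, fwhm: float, sd: float) -> np.ndarray:
    """White Gaussian noise, Gaussian-smoothed, rescaled to per-voxel SD ``sd``."""
    noise = rng.standard_normal(grid)
    if fwhm > 0:
        noise = gaussian_filter(noise, sigma=fwhm / _FWHM_PER_SIGMA)
        noise /= noise.std()
    return sd * noise


def generate_cohort(
    atlas: RegionAtlas, design: CohortDesign
) -> tuple[list[SubjectImage], pd.DataFrame]:
    """Draw a cohort of two-channel subject volumes from ``design``.

    Subject i of class c gets, per channel,

        scale_i * (baseline - effects[c][r] * noise_sd  inside region r)
        + smoothed noise (per-voxel SD = noise_sd, independent per channel)

    with scale_i = 1 + N(0, subject_scale_sd) shared across channels.
    Fully reproducible from ``design.seed``.
    """
    for c, regs in design.effects.items():
        for r in regs:
            try:
                atlas.label_of(r)
            except KeyError:
                raise ValueError(f"unknown region name in effects: {r!r} (class {c!r})")

    rng = np.random.default_rng(design.seed)
    grid = atlas.grid_dims
    images: list[SubjectImage] = []
    rows = []
    idx = 0
    for cls in design.class_names:
        signal = np.full(grid, design.baseline, dtype=float)
        for region, eff in design.effects.get(cls, {}).items():
            signal[atlas.region_mask(region)] -= eff * design.noise_sd
        for _ in range(design.n_per_class[cls]):
            idx += 1
            sid = f"sub-{idx:03d}"
            scale = 1.0 + rng.normal(0.0, design.subject_scale_sd)
            chans = tuple(
                scale * signal
                + _smooth_noise(rng, grid, design.smoothing_fwhm, design.noise_sd)
                for _ in CHANNEL_NAMES
            )
            images.append(SubjectImage(channels=chans, subject_id=sid, class_label=cls))
            rows.append({"subject_id": sid, "class": cls})
    return images, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Disk round trip: NIfTI volumes + CSV labels + JSON manifest + YAML design.

def save_cohort(
    images: Sequence[SubjectImage],
    labels: pd.DataFrame,
    atlas: RegionAtlas,
    directory: str | Path,
    design: CohortDesign | None = None,
) -> dict:
    """Write a cohort to ``directory``; returns the manifest dict."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict[str, str]] = {}
    for img in images:
        entry = {}
        for ch_name, vol in zip(CHANNEL_NAMES, img.channels):
            fname = f"{img.subject_id}_{ch_name}.nii.gz"
            nib.save(
                nib.Nifti1Image(vol.astype(np.float32), atlas.affine), out / fname
            )
            entry[ch_name] = fname
        files[img.subject_id] = entry
    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine),
        out / "atlas.nii.gz",
    )
    labels.to_csv(out / "labels.csv", index=False)
    manifest = {
        "files": files,
        "atlas": "atlas.nii.gz",
        "labels": "labels.csv",
        "region_names": {str(k): v for k, v in atlas.region_names.items()},
        "seed": design.seed if design is not None else None,
        "design": design.to_dict() if design is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if design is not None:
        (out / "design.yaml").write_text(yaml.safe_dump(design.to_dict()))
    return manifest


def load_cohort(
    directory: str | Path,
) -> tuple[list[SubjectImage], pd.DataFrame, RegionAtlas, CohortDesign | None]:
    """Inverse of :func:`save_cohort`."""
    src = Path(directory)
    mpath = src / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"missing manifest: {mpath}")
    manifest = json.loads(mpath.read_text())

    atlas_img = nib.load(src / manifest["atlas"])
    atlas = RegionAtlas(
        labels=np.asarray(atlas_img.dataobj, dtype=np.int16),
        region_names={int(k): v for k, v in manifest["region_names"].items()},
        affine=np.asarray(atlas_img.affine),
    )
    labels = pd.read_csv(src / manifest["labels"], dtype={"subject_id": str, "class": str})
    by_id = dict(zip(labels["subject_id"], labels["class"]))

    images = []
    for sid, entry in manifest["files"].items():
        chans = []
        for ch_name in CHANNEL_NAMES:
            fpath = src / entry[ch_name]
            if not fpath.exists():
                raise FileNotFoundError(f"missing image file: {fpath}")
            vol = np.asarray(nib.load(fpath).dataobj, dtype=np.float64)
            if vol.shape != atlas.grid_dims:
                raise ValueError(
                    f"grid mismatch for {fpath.name}: {vol.shape} vs atlas {atlas.grid_dims}"
                )
            chans.append(vol)
        images.append(
            SubjectImage(channels=tuple(chans), subject_id=sid, class_label=by_id[sid])
        )
    design = (
        CohortDesign.from_dict(manifest["design"]) if manifest.get("design") else None
    )
    return images, labels, atlas, design
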