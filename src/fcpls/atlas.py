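"""Probabilistic-atlas handling and seed-mask construction.

A probabilistic subregion atlas assigns every voxel a probability of
belonging to each structure (here: left/right centromedial, basolateral
and superficial amygdala).  Seed masks are built by the maximum-probability
rule: a voxel is labeled with the structure of highest probability provided
that probability exceeds a cutoff (default 10%) and strictly beats every
competitor, so the resulting subregion masks are pairwise disjoint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ProbabilisticAtlas",
    "SubregionMask",
    "GreyMatterMask",
    "VoxelIndexMap",
    "load_volume",
    "save_volume",
    "build_subregion_masks",
    "mask_voxel_index",
]


def load_volume(path):
    """Load a 3D or 4D NIfTI volume.

    Returns ``(data, affine, voxel_size_mm)`` with the time axis last for
    4D images.  Raises ``FileNotFoundError`` for missing files and
    ``ValueError`` for non-NIfTI payloads or dimensionality other than
    3 or 4.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises ImageFileError subclasses
        raise ValueError(f"not a readable NIfTI file: {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D image, got {data.ndim}D: {path}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine), voxel_size


def save_volume(path, data, affine=None):
    """Write ``data`` as NIfTI; identity affine by default."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


@dataclass
class ProbabilisticAtlas:
    """Per-structure probability volumes on a shared grid.

    ``prob`` is stacked (n_structures, x, y, z).  Probabilities supplied
    as percentages (any value > 1) are rescaled to [0, 1] with a log
    message, since atlas distributions ship both conventions.
    """

    structures: list
    prob: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.prob = np.asarray(self.prob, dtype=np.float64)
        if len(self.structures) == 0:
            raise ValueError("atlas needs at least one structure")
        if len(set(self.structures)) != len(self.structures):
            raise ValueError("structure names must be unique")
        if self.prob.ndim != 4 or self.prob.shape[0] != len(self.structures):
            raise ValueError(
                "prob must be (n_structures, x, y, z) matching the structure list"
            )
        if np.nanmax(self.prob) > 1.0:
            logger.info("atlas probabilities exceed 1; rescaling from percent to [0, 1]")
            self.prob = self.prob / 100.0
        if np.nanmin(self.prob) < 0.0 or np.nanmax(self.prob) > 1.0:
            raise ValueError("probabilities must lie in [0, 1] (or [0, 100] as percent)")

    @property
    def grid_shape(self):
        return self.prob.shape[1:]

    @classmethod
    def from_files(cls, structure_files):
        """Build from an ordered ``{name: nifti_path}`` mapping."""
        names = list(structure_files)
        vols, affine, zooms = [], None, None
        for name in names:
            data, aff, vox = load_volume(structure_files[name])
            if data.ndim != 3:
                raise ValueError(f"probability map for {name} must be 3D")
            if vols and data.shape != vols[0].shape:
                raise ValueError(f"grid mismatch for structure {name}")
            vols.append(data)
            affine, zooms = aff, vox
        return cls(structures=names, prob=np.stack(vols), voxel_size_mm=zooms, affine=affine)


@dataclass
class SubregionMask:
    """Nonoverlapping label volume: 0 = unassigned, k = structures[k-1]."""

    labels: np.ndarray
    threshold: float
    structures: list
    n_ties: int = 0

    def structure_mask(self, name):
        """Boolean mask of one structure's voxels."""
        k = self.structures.index(name) + 1
        return self.labels == k

    def label_codes(self):
        return {name: k + 1 for k, name in enumerate(self.structures)}


@dataclass
class GreyMatterMask:
    """Boolean grey-matter search volume for seed-to-voxel maps."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("grey-matter mask must be 3D")
        if not self.mask.any():
            raise ValueError("grey-matter mask is empty")

    @property
    def n_voxels(self):
        return int(self.mask.sum())


def build_subregion_masks(atlas: ProbabilisticAtlas, threshold: float = 0.10) -> SubregionMask:
    """Maximum-probability labeling with a strict probability cutoff.

    A voxel is assigned to the structure with the highest probability iff
    that probability is strictly greater than ``threshold`` and strictly
    greater than every other structure's probability.  Exact ties above
    threshold are resolved in favor of the structure declared earliest and
    a warning is emitted, so label volumes stay deterministic.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    prob = atlas.prob
    winner = np.argmax(prob, axis=0)  # first max wins -> earliest structure
    winning_p = np.take_along_axis(prob, winner[None], axis=0)[0]
    labels = np.where(winning_p > threshold, winner + 1, 0).astype(np.int32)
    # detect ties among structures at the winning probability
    n_at_max = (prob == winning_p[None]).sum(axis=0)
    ties = (labels > 0) & (n_at_max > 1)
    n_ties = int(ties.sum())
    if n_ties:
        warnings.warn(
            f"{n_ties} voxel(s) had tied maximum probabilities; "
            "assigned to the earliest declared structure",
            stacklevel=2,
        )
    return SubregionMask(labels=labels, threshold=threshold,
                         structures=list(atlas.structures), n_ties=n_ties)


class VoxelIndexMap:
    """Deterministic bijection between in-mask voxels and feature indices.

    Coordinates are visited in row-major (C) order, so feature ``i``
    always refers to the same voxel regardless of how the mask was built.
    """

    def __init__(self, mask):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not mask.any():
            raise ValueError("cannot index an empty mask")
        self.shape = mask.shape
        self.mask = mask
        self.flat_indices = np.flatnonzero(mask.ravel(order="C"))
        self.coords = np.column_stack(np.nonzero(mask))

    @property
    def n_voxels(self):
        return self.flat_indices.size

    def vectorize(self, volume):
        """Volume -> 1D feature vector over in-mask voxels."""
        volume = np.asarray(volume)
        if volume.shape[:3] != self.shape:
            raise ValueError("volume grid does not match the index map")
        flat = volume.reshape(-1, *volume.shape[3:])
        return flat[self.flat_indices]

    def unvectorize(self, vector, fill=0.0):
        """Feature vector -> volume, with ``fill`` outside the mask."""
        vector = np.asarray(vector)
        if vector.shape[0] != self.n_voxels:
            raise ValueError("vector length does not match the index map")
        out = np.full(self.shape + vector.shape[1:], fill, dtype=np.result_type(vector, type(fill)))
        out.reshape(-1, *vector.shape[1:])[self.flat_indices] = vector
        return out


def mask_voxel_index(mask) -> VoxelIndexMap:
    """Build the row-major voxel/feature index map for a boolean mask."""
    return VoxelIndexMap(mask)
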