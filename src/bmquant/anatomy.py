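"""Skeletal and reference-organ masks.

The threshold-based quantification needs an anatomical scaffold: the axial
skeleton (vertebrae, ribs, sternum, pelvis, ...), the extremity bones (humeri,
femora), the skull (excluded from analysis because of the intense physiological
brain uptake next to it), and the reference organs (liver, muscle, lumbar
spine, mediastinal blood pool).

Two routes produce that scaffold:

* real CT: Hounsfield thresholding plus morphological closing
  (:func:`segment_skeleton_from_ct`) followed by :func:`partition_regions`
  against an anatomical label map;
* digital phantoms: the ground-truth label map directly
  (:func:`masks_from_labels`).

:func:`refine_bone_mask` then applies the spillover mitigation (erosion and an
optional exclusion margin around high-uptake organs) before any SUV threshold
is applied.

All morphology uses 26-connectivity and voxel-indexed coordinates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid

__all__ = [
    "LABELS",
    "RegionMaskSet",
    "segment_skeleton_from_ct",
    "partition_regions",
    "masks_from_labels",
    "refine_bone_mask",
]

log = logging.getLogger(__name__)


def _load_labels() -> dict[str, int]:
    with resources.files("bmquant.data").joinpath("labels.json").open() as fh:
        return json.load(fh)["labels"]


#: Closed label vocabulary (name -> integer) shipped with the package.
LABELS: dict[str, int] = _load_labels()

_STRUCT26 = ndimage.generate_binary_structure(3, 3)  # full 3x3x3 neighbourhood


@dataclass
class RegionMaskSet:
    """Named binary masks over one voxel lattice.

    ``axial_bone`` includes the lumbar spine (vertebrae belong to the axial
    skeleton); ``lumbar_spine`` is additionally kept separate because the
    diffuse bone-marrow Deauville score is read there. ``skull`` is disjoint
    from the analysis bone masks by construction.
    """

    axial_bone: np.ndarray
    extremity_bone: np.ndarray
    skull: np.ndarray
    liver: np.ndarray
    muscle: np.ndarray
    lumbar_spine: np.ndarray
    mediastinum: np.ndarray
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        names = ["axial_bone", "extremity_bone", "skull", "liver", "muscle",
                 "lumbar_spine", "mediastinum"]
        shape = np.asarray(self.axial_bone).shape
        for name in names:
            mask = np.asarray(getattr(self, name), dtype=bool)
            if mask.shape != shape:
                raise ValueError(f"mask {name!r} has shape {mask.shape}, expected {shape}")
            setattr(self, name, mask)
        if np.any(self.skull & (self.axial_bone | self.extremity_bone)):
            raise ValueError("skull mask overlaps analysis bone masks")

    @property
    def bone(self) -> np.ndarray:
        """Analysis skeleton: axial plus extremities, skull excluded."""
        return self.axial_bone | self.extremity_bone


def segment_skeleton_from_ct(ct: VoxelGrid, hu_threshold: float = 150.0,
                             closing_radius_mm: float = 0.0) -> np.ndarray:
    """Bone mask from CT by Hounsfield thresholding plus morphological closing.

    A deliberately simple stand-in for a learned organ segmentation: cortical
    and trabecular bone sit well above soft tissue on CT, so ``HU >=
    hu_threshold`` (default 150) captures the skeleton on phantom-grade data;
    closing with the given radius fills marrow-space holes.

    Returns an empty mask (with a logged warning) when nothing exceeds the
    threshold.
    """
    mask = ct.values >= hu_threshold
    if closing_radius_mm > 0:
        iterations = max(1, int(np.ceil(closing_radius_mm / min(ct.spacing_mm))))
        mask = ndimage.binary_closing(mask, structure=_STRUCT26, iterations=iterations)
    if not mask.any():
        log.warning("skeleton segmentation at %.0f HU produced an empty mask", hu_threshold)
    return mask


def partition_regions(bone_mask: np.ndarray, label_map: np.ndarray) -> RegionMaskSet:
    """Split a bone mask into axial / extremity / skull and copy organ masks.

    Bone voxels take the compartment of their label; lumbar-spine labels count
    as axial skeleton. Bone voxels carrying no bone label (partial-volume
    edges, segmentation spill) are assigned to the nearest bone-labelled voxel
    and counted in ``diagnostics['unlabeled_bone_voxels']``.
    """
    bone_mask = np.asarray(bone_mask, dtype=bool)
    label_map = np.asarray(label_map)
    if bone_mask.shape != label_map.shape:
        raise ValueError("bone mask and label map shapes differ")

    bone_label_values = {LABELS[k] for k in ("axial_bone", "extremity_bone", "skull",
                                             "lumbar_spine")}
    labeled_bone = np.isin(label_map, list(bone_label_values))
    effective = label_map.copy()

    stray = bone_mask & ~labeled_bone
    n_stray = int(stray.sum())
    if n_stray and labeled_bone.any():
        # nearest-label rule via Euclidean feature transform on the labelled set
        _, idx = ndimage.distance_transform_edt(~labeled_bone, return_indices=True)
        effective[stray] = label_map[tuple(i[stray] for i in idx)]

    def bone_of(*names: str) -> np.ndarray:
        return bone_mask & np.isin(effective, [LABELS[n] for n in names])

    skull = bone_of("skull")
    masks = RegionMaskSet(
        axial_bone=bone_of("axial_bone", "lumbar_spine") & ~skull,
        extremity_bone=bone_of("extremity_bone") & ~skull,
        skull=skull,
        liver=label_map == LABELS["liver"],
        muscle=label_map == LABELS["muscle"],
        lumbar_spine=label_map == LABELS["lumbar_spine"],
        mediastinum=label_map == LABELS["mediastinum"],
        diagnostics={"unlabeled_bone_voxels": n_stray},
    )
    return masks


def masks_from_labels(label_map: np.ndarray) -> RegionMaskSet:
    """Region masks straight from a ground-truth label map (phantom route)."""
    label_map = np.asarray(label_map)
    bone = np.isin(label_map, [LABELS["axial_bone"], LABELS["extremity_bone"],
                               LABELS["skull"], LABELS["lumbar_spine"]])
    return partition_regions(bone, label_map)


def refine_bone_mask(masks: RegionMaskSet, suv: VoxelGrid,
                     erosion_radius_voxels: int = 1,
                     exclusion_margin_mm: float = 0.0) -> RegionMaskSet:
    """Spillover mitigation: erode the bone masks and carve out an exclusion
    margin around high-uptake non-skeletal organs.

    PET's limited spatial resolution lets tracer signal from hot neighbours
    (liver, mediastinal blood pool) bleed into the bone mask; eroding the mask
    and dropping bone voxels within ``exclusion_margin_mm`` of those organs is
    a conservative, contractive counter-measure. The refined set is always a
    subset of the input set.
    """
    if erosion_radius_voxels < 0:
        raise ValueError("erosion radius must be >= 0")

    def shrink(mask: np.ndarray) -> np.ndarray:
        out = mask
        if erosion_radius_voxels > 0 and out.any():
            out = ndimage.binary_erosion(out, structure=_STRUCT26,
                                         iterations=erosion_radius_voxels)
        if exclusion_margin_mm > 0:
            hot = masks.liver | masks.mediastinum
            if hot.any():
                dist = ndimage.distance_transform_edt(~hot, sampling=suv.spacing_mm)
                out = out & (dist > exclusion_margin_mm)
        if mask.any() and not out.any():
            warnings.warn("refinement emptied a bone mask", stacklevel=2)
        return out

    return RegionMaskSet(
        axial_bone=shrink(masks.axial_bone),
        extremity_bone=shrink(masks.extremity_bone),
        skull=masks.skull,
        liver=masks.liver,
        muscle=masks.muscle,
        lumbar_spine=masks.lumbar_spine,
        mediastinum=masks.mediastinum,
        diagnostics=dict(masks.diagnostics),
    )
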