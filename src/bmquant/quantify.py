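"""SUV-threshold quantification of bone-marrow metabolism.

Ten threshold approaches define "pathological" FDG uptake in the skeleton.
Each approach assigns one rule to the axial skeleton and one to the
extremities; a rule is either a multiple of a reference-organ statistic
(liver SUVmedian, liver SUVmean, muscle SUVmedian) or an absolute SUV value:

====  ==============================  ==========================
id    axial skeleton                  extremities
====  ==============================  ==========================
1     liver SUVmedian x 1.1           muscle SUVmedian x 4
2     liver SUVmedian x 1.5           muscle SUVmedian x 4
3     SUV 2.5                         SUV 2.5
4     SUV 2.5                         SUV 2.0
5     liver SUVmedian                 liver SUVmedian
6     liver SUVmedian                 muscle SUVmedian x 4
7     liver SUVmedian x 1.2           liver SUVmedian x 1.2
8     liver SUVmedian x 1.2           muscle SUVmedian x 4
9     liver SUVmean                   liver SUVmean
10    SUV 3.0                         SUV 3.0
====  ==============================  ==========================

A voxel is segmented when its SUV is **greater than or equal to** the
threshold of its compartment. The metabolic tumor volume MTV (mL) is the
volume of segmented voxels; total lesion glycolysis TLG (g) is
``SUVmean(segmented) x MTV``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import RegionMaskSet
from .grids import VoxelGrid

__all__ = [
    "ReferenceStats",
    "ThresholdRule",
    "ApproachSpec",
    "QuantResult",
    "APPROACHES",
    "compute_reference_stats",
    "approach_thresholds",
    "segment_bm_uptake",
    "compute_mtv_tlg",
    "quantify_all_approaches",
]


@dataclass(frozen=True)
class ReferenceStats:
    """Reference-organ SUV statistics the relative thresholds are built on."""

    liver_suv_median: float
    liver_suv_mean: float
    muscle_suv_median: float

    def __post_init__(self) -> None:
        for name in ("liver_suv_median", "liver_suv_mean", "muscle_suv_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ThresholdRule:
    """One compartment's rule: ``reference`` in {'liver_median', 'liver_mean',
    'muscle_median', 'absolute'}; for 'absolute' the multiplier IS the SUV."""

    reference: str
    multiplier: float

    _REFS = ("liver_median", "liver_mean", "muscle_median", "absolute")

    def __post_init__(self) -> None:
        if self.reference not in self._REFS:
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")

    def evaluate(self, refs: ReferenceStats) -> float:
        base = {
            "liver_median": refs.liver_suv_median,
            "liver_mean": refs.liver_suv_mean,
            "muscle_median": refs.muscle_suv_median,
            "absolute": 1.0,
        }[self.reference]
        return base * self.multiplier

    def describe(self) -> str:
        if self.reference == "absolute":
            return f"SUV >= {self.multiplier:g}"
        label = {"liver_median": "liver SUVmedian", "liver_mean": "liver SUVmean",
                 "muscle_median": "muscle SUVmedian"}[self.reference]
        if self.multiplier == 1.0:
            return f"SUV >= {label}"
        return f"SUV >= {label} x {self.multiplier:g}"


@dataclass(frozen=True)
class ApproachSpec:
    id: int
    axial_rule: ThresholdRule
    extremity_rule: ThresholdRule

    def describe(self) -> str:
        if self.axial_rule == self.extremity_rule:
            return f"axial+extremities: {self.axial_rule.describe()}"
        return (f"axial: {self.axial_rule.describe()}; "
                f"extremities: {self.extremity_rule.describe()}")


def _rule(ref: str, mult: float) -> ThresholdRule:
    return ThresholdRule(ref, mult)


#: The ten published approach presets, keyed by id.
APPROACHES: dict[int, ApproachSpec] = {
    1: ApproachSpec(1, _rule("liver_median", 1.1), _rule("muscle_median", 4.0)),
    2: ApproachSpec(2, _rule("liver_median", 1.5), _rule("muscle_median", 4.0)),
    3: ApproachSpec(3, _rule("absolute", 2.5), _rule("absolute", 2.5)),
    4: ApproachSpec(4, _rule("absolute", 2.5), _rule("absolute", 2.0)),
    5: ApproachSpec(5, _rule("liver_median", 1.0), _rule("liver_median", 1.0)),
    6: ApproachSpec(6, _rule("liver_median", 1.0), _rule("muscle_median", 4.0)),
    7: ApproachSpec(7, _rule("liver_median", 1.2), _rule("liver_median", 1.2)),
    8: ApproachSpec(8, _rule("liver_median", 1.2), _rule("muscle_median", 4.0)),
    9: ApproachSpec(9, _rule("liver_mean", 1.0), _rule("liver_mean", 1.0)),
    10: ApproachSpec(10, _rule("absolute", 3.0), _rule("absolute", 3.0)),
}


@dataclass(frozen=True)
class QuantResult:
    """Whole-body quantification under one approach.

    ``tlg_g == suv_mean_segmented * mtv_ml`` and ``mtv_ml == voxel_count *
    voxel_volume_ml`` by construction; an empty segmentation yields zeros.
    """

    approach_id: int
    mtv_ml: float
    tlg_g: float
    suv_mean_segmented: float
    voxel_count: int
    mtv_axial_ml: float = 0.0
    mtv_extremity_ml: float = 0.0


def compute_reference_stats(suv: VoxelGrid, masks: RegionMaskSet) -> ReferenceStats:
    """Median/mean liver SUV and median muscle SUV over the full organ masks.

    Raises ``ValueError`` naming the offending mask when liver or muscle is
    empty — relative thresholds are meaningless without references.
    """
    for name in ("liver", "muscle"):
        if not getattr(masks, name).any():
            raise ValueError(f"reference mask {name!r} is empty")
    liver = suv.values[masks.liver]
    muscle = suv.values[masks.muscle]
    return ReferenceStats(
        liver_suv_median=float(np.median(liver)),
        liver_suv_mean=float(np.mean(liver)),
        muscle_suv_median=float(np.median(muscle)),
    )


def approach_thresholds(spec: ApproachSpec | int,
                        refs: ReferenceStats) -> tuple[float, float]:
    """Evaluate one approach's rules into (axial, extremity) SUV thresholds."""
    if isinstance(spec, int):
        if spec not in APPROACHES:
            raise ValueError(f"unknown approach id {spec}; valid ids are 1..10")
        spec = APPROACHES[spec]
    return spec.axial_rule.evaluate(refs), spec.extremity_rule.evaluate(refs)


def segment_bm_uptake(suv: VoxelGrid, masks: RegionMaskSet,
                      thresholds: tuple[float, float]) -> np.ndarray:
    """Binary pathological-uptake mask: SUV >= threshold within each bone
    compartment (inclusive comparison; a voxel exactly at the threshold is
    segmented)."""
    axial_thr, ext_thr = thresholds
    return ((masks.axial_bone & (suv.values >= axial_thr))
            | (masks.extremity_bone & (suv.values >= ext_thr)))


def compute_mtv_tlg(segmented: np.ndarray, suv: VoxelGrid,
                    spacing_mm: tuple[float, float, float] | None = None,
                    approach_id: int = 0,
                    masks: RegionMaskSet | None = None) -> QuantResult:
    """MTV (mL), SUVmean over segmented voxels, and TLG = SUVmean x MTV.

    An empty segmentation is a valid outcome and reports MTV = TLG = 0.
    """
    segmented = np.asarray(segmented, dtype=bool)
    if segmented.shape != suv.shape:
        raise ValueError("segmentation and SUV grid shapes differ")
    spacing = suv.spacing_mm if spacing_mm is None else tuple(spacing_mm)
    vox_ml = float(np.prod(spacing)) / 1000.0
    count = int(segmented.sum())
    mtv = count * vox_ml
    suv_mean = float(suv.values[segmented].mean()) if count else 0.0
    axial = float((segmented & masks.axial_bone).sum() * vox_ml) if masks is not None else 0.0
    ext = float((segmented & masks.extremity_bone).sum() * vox_ml) if masks is not None else 0.0
    return QuantResult(approach_id=approach_id, mtv_ml=mtv, tlg_g=suv_mean * mtv,
                       suv_mean_segmented=suv_mean, voxel_count=count,
                       mtv_axial_ml=axial, mtv_extremity_ml=ext)


def quantify_all_approaches(suv: VoxelGrid, masks: RegionMaskSet,
                            approach_ids: list[int] | None = None) -> list[QuantResult]:
    """Run the selected approaches (default: all ten) on refined masks."""
    ids = sorted(APPROACHES) if approach_ids is None else list(approach_ids)
    refs = compute_reference_stats(suv, masks)
    results = []
    for i in ids:
        thr = approach_thresholds(i, refs)
        seg = segment_bm_uptake(suv, masks, thr)
        results.append(compute_mtv_tlg(seg, suv, approach_id=i, masks=masks))
    return results
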