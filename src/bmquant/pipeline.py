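"""Orchestration and tabular I/O.

Wires phantom generation, anatomy, quantification, IMPeTUs reading and the
survival stage into seeded end-to-end runs, and owns the CSV/JSON table
conventions (every written table gets a provenance sidecar recording package
version, seed and a config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anatomy import masks_from_labels, partition_regions, refine_bone_mask, \
    segment_skeleton_from_ct
from .grids import VoxelGrid, read_volume, write_volume
from .impetus import ImpetusParams, assemble_impetus_report
from .quantify import APPROACHES, approach_thresholds, compute_reference_stats, \
    quantify_all_approaches
from .survival import cox_fit, dichotomize_at_median, km_estimate, log_rank_test, \
    median_followup_inverse_km, roc_at_horizon
from .synthetic import PhantomConfig, generate_phantom

__all__ = [
    "RunConfig",
    "run_quantification",
    "run_survival_study",
    "read_table",
    "write_table",
    "write_phantom",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration.

    Either file paths (PET + CT + labels) or a list of phantom configs feed
    the imaging stage; the survival stage consumes a cohort table.
    """

    pet_path: str | None = None
    ct_path: str | None = None
    labels_path: str | None = None
    phantoms: tuple[PhantomConfig, ...] = ()
    approach_ids: tuple[int, ...] = tuple(range(1, 11))
    hu_threshold: float = 150.0
    closing_radius_mm: float = 0.0
    erosion_radius_voxels: int = 1
    exclusion_margin_mm: float = 0.0
    impetus_params: ImpetusParams = field(default_factory=ImpetusParams)
    horizon_months: float = 24.0
    roc_method: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.approach_ids) - set(APPROACHES)
        if bad:
            raise ValueError(f"unknown approach ids {sorted(bad)}; valid ids are 1..10")
        object.__setattr__(self, "phantoms", tuple(self.phantoms))
        object.__setattr__(self, "approach_ids", tuple(self.approach_ids))

    def hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.ndarray, tuple)):
                return list(o)
            return str(o)
        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config_hash: str, seed: int) -> dict:
    return {
        "package": "bmquant",
        "version": __version__,
        "config_hash": config_hash,
        "seed": seed,
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a CSV table with an optional ``<name>.provenance.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if provenance is not None:
        path.with_suffix(path.suffix + ".provenance.json").write_text(
            json.dumps(provenance, indent=2))


def read_table(path: str | Path, required_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, erroring with the name of any missing mandatory column."""
    df = pd.read_csv(path)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    return df


def write_phantom(ct: VoxelGrid, suv: VoxelGrid, truth, out_dir: str | Path,
                  stem: str = "phantom") -> dict[str, Path]:
    """Persist a phantom as paired NIfTI volumes plus a JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct": out / f"{stem}_ct.nii.gz",
        "suv": out / f"{stem}_suv.nii.gz",
        "labels": out / f"{stem}_labels.nii.gz",
        "truth": out / f"{stem}_truth.json",
    }
    write_volume(ct, str(paths["ct"]), dtype=np.float32)
    write_volume(suv, str(paths["suv"]), dtype=np.float32)
    write_volume(suv.with_values(truth.label_map), str(paths["labels"]), dtype=np.int16)
    sidecar = {
        "lesion_volumes_ml": list(truth.lesion_volumes_ml),
        "compartment_volumes_ml": truth.compartment_volumes_ml,
        "infiltration_fraction": truth.infiltration_fraction,
        "liver_suv": truth.liver_suv,
        "muscle_suv": truth.muscle_suv,
        "mediastinum_suv": truth.mediastinum_suv,
        "diffuse_bm_suv": truth.diffuse_bm_suv,
        "fracture_present": truth.fracture_present,
    }
    paths["truth"].write_text(json.dumps(sidecar, indent=2))
    return paths


def _subject_masks(config: RunConfig, ct: VoxelGrid, label_map: np.ndarray | None):
    if label_map is not None:
        masks = masks_from_labels(label_map)
    else:
        bone = segment_skeleton_from_ct(ct, config.hu_threshold, config.closing_radius_mm)
        masks = partition_regions(bone, np.zeros(ct.shape, dtype=np.int16))
    return masks


def _iter_subjects(config: RunConfig):
    if config.phantoms:
        for i, ph in enumerate(config.phantoms, start=1):
            ct, suv, truth = generate_phantom(ph)
            yield f"phantom_{i:03d}", ct, suv, truth.label_map, truth
    else:
        if not (config.pet_path and config.labels_path):
            raise ValueError("run config needs either phantoms or pet+labels paths")
        suv = read_volume(config.pet_path)
        ct = read_volume(config.ct_path) if config.ct_path else suv.with_values(
            np.zeros(suv.shape))
        labels = read_volume(config.labels_path).values.astype(np.int16)
        yield "subject_001", ct, suv, labels, None


def run_quantification(config: RunConfig) -> pd.DataFrame:
    """One row per (subject, approach) with thresholds, MTV and TLG.

    Per-subject failures are logged and reported in an ``error`` column; the
    run continues with the remaining subjects.
    """
    rows = []
    for subject, ct, suv, label_map, truth in _iter_subjects(config):
        try:
            masks = _subject_masks(config, ct, label_map)
            refined = refine_bone_mask(masks, suv, config.erosion_radius_voxels,
                                       config.exclusion_margin_mm)
            refs = compute_reference_stats(suv, refined)
            for res in quantify_all_approaches(suv, refined, list(config.approach_ids)):
                ax_thr, ext_thr = approach_thresholds(res.approach_id, refs)
                rows.append({
                    "subject_id": subject,
                    "approach": res.approach_id,
                    "threshold_rule": APPROACHES[res.approach_id].describe(),
                    "axial_threshold_suv": round(ax_thr, 6),
                    "extremity_threshold_suv": round(ext_thr, 6),
                    "mtv_ml": res.mtv_ml,
                    "tlg_g": res.tlg_g,
                    "suv_mean_segmented": res.suv_mean_segmented,
                    "voxel_count": res.voxel_count,
                    "mtv_axial_ml": res.mtv_axial_ml,
                    "mtv_extremity_ml": res.mtv_extremity_ml,
                    "infiltration_fraction": (truth.infiltration_fraction
                                              if truth is not None else np.nan),
                    "error": "",
                })
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.error("subject %s failed: %s", subject, exc)
            rows.append({"subject_id": subject, "approach": -1, "error": str(exc)})
    return pd.DataFrame(rows)


def run_impetus(config: RunConfig) -> pd.DataFrame:
    """One IMPeTUs report row per subject."""
    rows = []
    for subject, ct, suv, label_map, truth in _iter_subjects(config):
        masks = masks_from_labels(label_map) if label_map is not None else \
            _subject_masks(config, ct, None)
        report = assemble_impetus_report(
            suv, ct, masks, label_map, config.impetus_params,
            fracture_present=bool(truth.fracture_present) if truth is not None else False)
        row = {"subject_id": subject}
        row.update(report.to_dict())
        row["lesion_locations"] = ";".join(report.lesion_locations)
        rows.append(row)
    return pd.DataFrame(rows)


def run_survival_study(cohort: pd.DataFrame, marker_cols: list[str] | None = None,
                       adjust_cols: list[str] | None = None,
                       horizon_months: float = 24.0, roc_method: str = "binary",
                       time_col: str = "time_months", event_col: str = "event",
                       ties: str = "efron") -> dict:
    """The full statistical stage over a cohort table.

    Returns a dict with keys ``followup`` (median follow-up, months),
    ``km`` (per-marker median-dichotomized KM medians and log-rank p),
    ``cox_univariable`` and ``cox_multivariable`` DataFrames, and ``roc``
    (per-marker AUC/cut at the horizon). Analyses with insufficient events
    are skipped with an explicit notice in ``skipped``.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    for col in (time_col, event_col):
        if col not in cohort.columns:
            raise ValueError(f"cohort table missing mandatory column {col!r}")
    marker_cols = marker_cols or ["mtv_ml", "tlg_g"]
    adjust_cols = adjust_cols if adjust_cols is not None else \
        [c for c in ("infiltration_pct", "high_risk_cyto") if c in cohort.columns]

    time = cohort[time_col].to_numpy(float)
    event = cohort[event_col].to_numpy(int)
    out: dict = {"skipped": []}
    out["followup"] = {
        "median_followup_months": median_followup_inverse_km(time, event),
        "km_median_months": km_estimate(time, event).median_months,
        "n": len(cohort), "n_events": int(event.sum()),
    }

    km_rows, uni_rows, multi_rows, roc_rows = [], [], [], []
    for marker in marker_cols:
        values = cohort[marker].to_numpy(float)
        groups = dichotomize_at_median(values)
        try:
            chi2, p = log_rank_test(time, event, groups)
            km_rows.append({
                "marker": marker,
                "median_low_months": km_estimate(time[groups == 0], event[groups == 0]).median_months,
                "median_high_months": km_estimate(time[groups == 1], event[groups == 1]).median_months,
                "logrank_chi2": chi2, "logrank_p": p,
            })
        except ValueError as exc:
            out["skipped"].append(f"log-rank[{marker}]: {exc}")
        try:
            fit = cox_fit(cohort, [marker], time_col, event_col, ties=ties)
            uni_rows.append({"marker": marker, "hr": fit.hazard_ratios[marker],
                             "ci_lower": fit.ci_lower[marker],
                             "ci_upper": fit.ci_upper[marker],
                             "p": fit.p_values[marker], "n_events": fit.n_events})
        except ValueError as exc:
            out["skipped"].append(f"cox_uni[{marker}]: {exc}")
        if adjust_cols:
            try:
                fit = cox_fit(cohort, [marker] + adjust_cols, time_col, event_col, ties=ties)
                for cov in [marker] + adjust_cols:
                    multi_rows.append({"marker": marker, "covariate": cov,
                                       "hr": fit.hazard_ratios[cov],
                                       "ci_lower": fit.ci_lower[cov],
                                       "ci_upper": fit.ci_upper[cov],
                                       "p": fit.p_values[cov]})
            except ValueError as exc:
                out["skipped"].append(f"cox_multi[{marker}]: {exc}")
        try:
            roc = roc_at_horizon(cohort, marker, horizon_months, time_col,
                                 event_col, method=roc_method)
            roc_rows.append({"marker": marker, "auc": roc.auc,
                             "auc_ci_lower": roc.auc_ci[0], "auc_ci_upper": roc.auc_ci[1],
                             "p": roc.p_value, "cut_point": roc.cut_point,
                             "sensitivity": roc.sensitivity,
                             "specificity": roc.specificity})
        except ValueError as exc:
            out["skipped"].append(f"roc[{marker}]: {exc}")

    out["km"] = pd.DataFrame(km_rows)
    out["cox_univariable"] = pd.DataFrame(uni_rows)
    out["cox_multivariable"] = pd.DataFrame(multi_rows)
    out["roc"] = pd.DataFrame(roc_rows)
    return out
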