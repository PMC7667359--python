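"""End-to-end orchestration: cohort in, accuracy report out.

``run_patient`` performs the complete single-lesion procedure (slice
selection, calipers, slice count, voxel volumetry, both estimators, all
four classifications).  ``run_cohort`` drives it over a synthetic or
on-disk cohort, evaluates the classifications against voxel volumetry,
and writes the per-patient table, the accuracy report and a run manifest
with seed and exclusion accounting.  Patients with empty masks are
flagged and excluded from evaluation, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators as est
from . import evaluation as ev
from . import geometry as geo
from . import synthetic as syn

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "patient_id", "a_cm", "b_cm", "slice_index", "n_slices", "thickness_cm",
    "od_value", "od_volume_ml", "abc2_volume_ml", "manual_volume_ml",
    "od_class_70", "od_class_100", "abc2_class_70", "abc2_class_100",
    "truth_70", "truth_100", "excluded", "exclusion_reason",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run.

    Exactly one input mode is active: ``mode='synthetic'`` generates a
    phantom cohort from ``cohort``; ``mode='masks'`` reads NIfTI masks
    listed in ``catalog`` (CSV with a ``mask_path`` column, resolved
    relative to the catalog) or all ``*.nii``/``*.nii.gz`` under
    ``mask_dir``.
    """

    mode: str = "synthetic"
    cohort: syn.CohortConfig = field(default_factory=syn.CohortConfig)
    thresholds: est.ThresholdConfig = field(default_factory=est.ThresholdConfig)
    catalog: str | None = None
    mask_dir: str | None = None
    slice_axis: int | None = None
    thickness_mm_override: float | None = None
    ci_level: float = 0.95
    ci_method: str = "clopper-pearson"
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "masks"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "masks" and not (self.catalog or self.mask_dir):
            raise ValueError("mode='masks' requires a catalog or mask_dir")


def _excluded_row(patient_id: str, reason: str) -> dict:
    row = {c: np.nan for c in RESULT_COLUMNS}
    row.update(patient_id=patient_id, excluded=True, exclusion_reason=reason)
    return row


def run_patient(
    source,
    thickness_cm: float | None = None,
    thresholds: est.ThresholdConfig = est.DEFAULT_THRESHOLDS,
    slice_axis: int | None = None,
) -> dict:
    """Measure one patient and return the full results row (a dict).

    ``source`` is a NIfTI path or a :class:`~strokevol.geometry.LesionImage`.
    Slice thickness defaults to the slice-axis spacing from the header;
    pass ``thickness_cm`` to override (e.g. when thickness is catalogued
    separately from slice spacing).  An empty mask yields a flagged
    exclusion row rather than an error.
    """
    if isinstance(source, geo.LesionImage):
        image = source
    else:
        image = geo.load_mask(source, slice_axis=slice_axis)
    if not image.mask.any():
        logger.warning("patient %s excluded: empty mask", image.patient_id)
        return _excluded_row(image.patient_id, "empty mask")
    meas = geo.select_measurement_slice(image)
    n_slices = geo.count_lesion_slices(image)
    manual_ml = geo.volumetric_volume(image)
    if thickness_cm is None:
        thickness_cm = image.slice_thickness_mm / geo.MM_PER_CM
    od = est.od_value(meas.a_cm, meas.b_cm)
    estimates = est.VolumeEstimates(
        od_value=od,
        od_volume_ml=est.od_to_volume(od, thresholds),
        abc2_volume_ml=est.abc2_volume(meas.a_cm, meas.b_cm, n_slices, thickness_cm),
        manual_volume_ml=manual_ml,
        n_slices=n_slices,
        slice_thickness_cm=thickness_cm,
    )
    row = {
        "patient_id": image.patient_id,
        "a_cm": meas.a_cm,
        "b_cm": meas.b_cm,
        "slice_index": meas.slice_index,
        "n_slices": n_slices,
        "thickness_cm": thickness_cm,
        "od_value": estimates.od_value,
        "od_volume_ml": estimates.od_volume_ml,
        "abc2_volume_ml": estimates.abc2_volume_ml,
        "manual_volume_ml": estimates.manual_volume_ml,
        "excluded": False,
        "exclusion_reason": "",
    }
    for method, col in (("od_cutoff", "od_class"), ("abc2", "abc2_class")):
        for label, suffix in (("70ml", "70"), ("100ml", "100")):
            row[f"{col}_{suffix}"] = est.classify_large_lesion(
                estimates, thresholds, method, label
            )
    row["truth_70"] = est.true_large_lesion(estimates, thresholds, "70ml")
    row["truth_100"] = est.true_large_lesion(estimates, thresholds, "100ml")
    return row


def measure_cohort(
    mask_paths,
    thickness_cm=None,
    thresholds: est.ThresholdConfig = est.DEFAULT_THRESHOLDS,
    slice_axis: int | None = None,
) -> pd.DataFrame:
    """Per-patient results table for a list of mask paths (or images).

    ``thickness_cm`` may be a scalar override or a per-patient sequence.
    """
    rows = []
    for i, src in enumerate(mask_paths):
        t = thickness_cm[i] if isinstance(thickness_cm, (list, tuple)) else thickness_cm
        try:
            rows.append(run_patient(src, t, thresholds, slice_axis))
        except (OSError, ValueError) as exc:
            pid = getattr(src, "patient_id", str(src))
            logger.warning("patient %s excluded: %s", pid, exc)
            rows.append(_excluded_row(pid, str(exc)))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@dataclass(frozen=True)
class RunResult:
    results: pd.DataFrame
    evaluation: ev.CohortEvaluation
    manifest: dict


def _resolve_mask_inputs(config: RunConfig):
    if config.catalog:
        cat = pd.read_csv(config.catalog)
        base = Path(config.catalog).parent
        paths = [base / p for p in cat["mask_path"]]
        thickness = None
        if config.thickness_mm_override is not None:
            thickness = config.thickness_mm_override / geo.MM_PER_CM
        elif "slice_thickness_mm" in cat.columns:
            thickness = [t / geo.MM_PER_CM for t in cat["slice_thickness_mm"]]
        return paths, thickness
    paths = sorted(Path(config.mask_dir).glob("*.nii*"))
    if not paths:
        raise FileNotFoundError(f"no NIfTI masks found under {config.mask_dir}")
    thickness = (
        config.thickness_mm_override / geo.MM_PER_CM
        if config.thickness_mm_override is not None
        else None
    )
    return paths, thickness


def run_cohort(config: RunConfig) -> RunResult:
    """Run the full analysis and (optionally) write all outputs.

    Returns the per-patient table, the cohort evaluation and a manifest
    recording the seed, the configuration and the inclusion/exclusion
    counts (n_input = n_evaluated + n_excluded, always).
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if config.mode == "synthetic":
        cohort = dataclasses.replace(config.cohort, seed=config.seed)
        specs = syn.sample_cohort(cohort)
        if out_dir is not None:
            catalog = syn.write_cohort(specs, out_dir / "masks")
            cat = pd.read_csv(catalog)
            paths = [catalog.parent / p for p in cat["mask_path"]]
            results = measure_cohort(paths, None, config.thresholds, config.slice_axis)
        else:
            images = [syn.rasterize_lesion(s) for s in specs]
            results = measure_cohort(images, None, config.thresholds, config.slice_axis)
    else:
        paths, thickness = _resolve_mask_inputs(config)
        results = measure_cohort(paths, thickness, config.thresholds, config.slice_axis)

    included = results[~results["excluded"].astype(bool)]
    if len(included) == 0:
        raise ValueError("no valid patients: every mask was excluded")
    evaluation = ev.evaluate_cohort(
        included, config.thresholds, config.ci_level, config.ci_method
    )
    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "n_input": int(len(results)),
        "n_evaluated": int(len(included)),
        "n_excluded": int(results["excluded"].astype(bool).sum()),
        "excluded_patients": results.loc[
            results["excluded"].astype(bool), ["patient_id", "exclusion_reason"]
        ].to_dict("records"),
        "ci_level": config.ci_level,
        "ci_method": config.ci_method,
        "thresholds": dataclasses.asdict(config.thresholds),
        "cohort": dataclasses.asdict(config.cohort) if config.mode == "synthetic" else None,
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "results.csv", index=False, float_format="%.10g")
        evaluation.to_frame().to_csv(
            out_dir / "evaluation.csv", index=False, float_format="%.10g"
        )
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(results=results, evaluation=evaluation, manifest=manifest)
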