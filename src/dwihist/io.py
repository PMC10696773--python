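"""Readers and writers for every on-disk format the pipeline touches.

Volumes and masks are NIfTI (via nibabel); b-values live in a single-line
whitespace-separated text file with one entry per 4th-axis volume (the
de-facto diffusion-toolchain convention), with an optional companion file
for per-b averaging counts.  Cohort manifests and feature/result tables are
CSV; reports carry a JSON sidecar with provenance (tool version, options,
seeds, statistic conventions).  Diffusion coefficients are stored in
mm**2/s inside NIfTI data; the conventional 1e-3 mm**2/s display scaling is
applied only in report tables.

All writers are deterministic for fixed inputs; the timestamp is isolated
to a single provenance field.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .containers import DwiSeries, ParameterMaps, VoiMask
from .signal_models import AcquisitionScheme
from .stats import CohortAnalysis

__all__ = [
    "read_bvals", "write_bvals", "read_dwi", "write_dwi", "read_mask",
    "write_mask", "write_parameter_maps", "read_parameter_maps",
    "write_manifest", "read_manifest", "write_report", "display_scale",
]

#: metrics reported in the 1e-3 mm**2/s display convention
_DIFFUSIVITY_METRICS = {"ADC", "D", "Dstar", "DDC"}
_UNITLESS_STATS = {"kurtosis", "skewness"}


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def read_bvals(path) -> np.ndarray:
    values = np.loadtxt(path, ndmin=1, dtype=float)
    if values.ndim != 1:
        raise ValueError(f"{path}: expected a single line of b-values")
    if np.any(values < 0):
        raise ValueError(f"{path}: negative b-value")
    return values


def write_bvals(b_values, path) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in b_values) + "\n")


def read_dwi(nifti_path, bval_path, nex_path=None) -> DwiSeries:
    """Load a 4-D DWI volume plus its b-value file.

    The scheme is canonicalized to ascending b order (data reordered to
    match); the on-disk volume order is recorded in ``meta``.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    bvals = read_bvals(bval_path)
    if data.ndim != 4 or bvals.size != (data.shape[3] if data.ndim == 4
                                        else -1):
        n_vols = data.shape[3] if data.ndim == 4 else 1
        raise ValueError(
            f"{nifti_path}: b-value count {bvals.size} does not match "
            f"volume count {n_vols} of a {data.ndim}-D image")
    if nex_path is not None:
        nex = np.loadtxt(nex_path, ndmin=1, dtype=int)
        if nex.size != bvals.size:
            raise ValueError(f"{nex_path}: NEX count mismatch")
    else:
        nex = np.ones(bvals.size, dtype=int)
    order = np.argsort(bvals, kind="stable")
    scheme = AcquisitionScheme(tuple(bvals[order]), tuple(nex[order]))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DwiSeries(data=data[..., order], scheme=scheme,
                     voxel_size=voxel_size,
                     meta={"source": str(nifti_path),
                           "disk_b_order": [int(i) for i in order]})


def write_dwi(series: DwiSeries, nifti_path, bval_path,
              nex_path=None) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32),
                          _affine(series.voxel_size))
    nib.save(img, str(nifti_path))
    write_bvals(series.scheme.b_values, bval_path)
    if nex_path is not None:
        Path(nex_path).write_text(
            " ".join(str(n) for n in series.scheme.nex) + "\n")


def read_mask(nifti_path, reference: DwiSeries) -> VoiMask:
    """Load a binary VOI mask and validate it against a reference series.

    Nonzero voxels become True.  A shape mismatch is an error; an affine
    mismatch beyond 1e-3 only warns (masks are assumed co-registered), as
    does an all-zero mask (which errors later, at analysis time).
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj)
    if data.shape != reference.spatial_shape:
        raise ValueError(
            f"{nifti_path}: mask shape {data.shape} does not match DWI "
            f"spatial shape {reference.spatial_shape}")
    ref_affine = _affine(reference.voxel_size)
    if not np.allclose(img.affine, ref_affine, atol=1e-3):
        warnings.warn(f"{nifti_path}: mask affine differs from reference "
                      "beyond 1e-3; assuming co-registration", stacklevel=2)
    mask = VoiMask(data != 0)
    if mask.n_voxels == 0:
        warnings.warn(f"{nifti_path}: mask is empty", stacklevel=2)
    return mask


def write_mask(mask: VoiMask, nifti_path, voxel_size=(1.25, 1.25, 5.0)):
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(voxel_size))
    nib.save(img, str(nifti_path))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_parameter_maps(maps: ParameterMaps, out_dir, subject_id: str,
                         voxel_size=(1.25, 1.25, 5.0)) -> dict:
    """One NIfTI per metric plus a JSON sidecar with fit provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    aff = _affine(voxel_size)
    for metric, vol in maps.maps.items():
        p = out_dir / f"{subject_id}_{maps.model_name}_{metric}.nii"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), str(p))
        paths[metric] = p
    valid_path = out_dir / f"{subject_id}_{maps.model_name}_valid.nii"
    nib.save(nib.Nifti1Image(maps.valid_mask.astype(np.uint8), aff),
             str(valid_path))
    sidecar = out_dir / f"{subject_id}_{maps.model_name}_fit.json"
    sidecar.write_text(json.dumps(_jsonable(
        {"model": maps.model_name, "metrics": list(maps.maps),
         **maps.meta}), indent=2, sort_keys=True) + "\n")
    paths["valid"] = valid_path
    paths["sidecar"] = sidecar
    return paths


def read_parameter_maps(out_dir, subject_id: str, model: str) -> ParameterMaps:
    out_dir = Path(out_dir)
    sidecar = out_dir / f"{subject_id}_{model}_fit.json"
    meta = json.loads(sidecar.read_text())
    maps = {}
    for metric in meta["metrics"]:
        p = out_dir / f"{subject_id}_{model}_{metric}.nii"
        maps[metric] = np.asarray(nib.load(str(p)).dataobj, dtype=float)
    valid = np.asarray(nib.load(
        str(out_dir / f"{subject_id}_{model}_valid.nii")).dataobj) != 0
    return ParameterMaps(model_name=model, maps=maps, valid_mask=valid,
                         meta=meta)


MANIFEST_COLUMNS = ["subject_id", "label", "dwi_path", "mask_path", "seed"]


def write_manifest(rows, path) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in manifest")
    bad = ~df["label"].isin(["soft", "hard", "unknown"])
    if bad.any():
        raise ValueError(f"invalid labels: {df['label'][bad].tolist()}")
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return df


def display_scale(feature_name: str) -> tuple:
    """(scale, units) used to display a feature or its cutoff in reports."""
    metric, _, stat = feature_name.partition("_")
    if metric in _DIFFUSIVITY_METRICS and stat not in _UNITLESS_STATS:
        return 1.0e3, "1e-3 mm^2/s"
    return 1.0, ""


def _comparison_frame(analysis: CohortAnalysis) -> pd.DataFrame:
    rows = []
    for gc in analysis.comparisons:
        rows.append({
            "feature": gc.feature_name, "test_used": gc.test_used,
            "p_value": gc.p_value,
            "soft_mean": gc.group_summaries["soft"]["mean"],
            "soft_sd": gc.group_summaries["soft"]["sd"],
            "soft_median": gc.group_summaries["soft"]["median"],
            "soft_iqr": gc.group_summaries["soft"]["iqr"],
            "hard_mean": gc.group_summaries["hard"]["mean"],
            "hard_sd": gc.group_summaries["hard"]["sd"],
            "hard_median": gc.group_summaries["hard"]["median"],
            "hard_iqr": gc.group_summaries["hard"]["iqr"],
            "significant": gc.p_value < analysis.alpha,
        })
    return pd.DataFrame(rows, columns=[
        "feature", "test_used", "p_value", "soft_mean", "soft_sd",
        "soft_median", "soft_iqr", "hard_mean", "hard_sd", "hard_median",
        "hard_iqr", "significant"])


def _diagnostics_frame(analysis: CohortAnalysis) -> pd.DataFrame:
    rows = []
    for d in analysis.diagnostics:
        scale, units = display_scale(d.feature_name)
        rows.append({
            "feature": d.feature_name, "auc": d.auc,
            "auc_ci_low": d.auc_ci_low, "auc_ci_high": d.auc_ci_high,
            "cutoff": d.cutoff * scale, "cutoff_units": units,
            "sensitivity_pct": 100.0 * d.sensitivity,
            "specificity_pct": 100.0 * d.specificity,
            "youden": d.youden, "accuracy_pct": 100.0 * d.accuracy,
            "ppv_pct": 100.0 * d.ppv, "npv_pct": 100.0 * d.npv,
            "orientation": d.orientation,
        })
    return pd.DataFrame(rows, columns=[
        "feature", "auc", "auc_ci_low", "auc_ci_high", "cutoff",
        "cutoff_units", "sensitivity_pct", "specificity_pct", "youden",
        "accuracy_pct", "ppv_pct", "npv_pct", "orientation"])


def _delong_frame(analysis: CohortAnalysis) -> pd.DataFrame:
    rows = [{"feature_a": d.feature_a, "feature_b": d.feature_b,
             "auc_a": d.auc_a, "auc_b": d.auc_b, "z": d.z,
             "p_value": d.p_value} for d in analysis.delong]
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "auc_a",
                                       "auc_b", "z", "p_value"])


def write_report(analysis: CohortAnalysis, out_dir, provenance=None,
                 agreement=None) -> dict:
    """Write the group-comparison, diagnostics and DeLong CSVs plus a JSON
    report with embedded provenance; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "group_comparison": out_dir / "group_comparison.csv",
        "diagnostics": out_dir / "diagnostics.csv",
        "delong": out_dir / "delong.csv",
        "report": out_dir / "report.json",
    }
    _comparison_frame(analysis).to_csv(paths["group_comparison"], index=False)
    _diagnostics_frame(analysis).to_csv(paths["diagnostics"], index=False)
    _delong_frame(analysis).to_csv(paths["delong"], index=False)
    report = {
        "provenance": {
            "tool": "dwihist", "version": __version__,
            "timestamp": datetime.datetime.now(
                datetime.timezone.utc).isoformat(),
            **(provenance or {}),
        },
        "n_features_tested": analysis.n_features_tested,
        "alpha": analysis.alpha,
        "positive_label": analysis.positive_label,
        "comparisons": [dataclasses.asdict(c) for c in analysis.comparisons],
        "diagnostics": [dataclasses.asdict(d) for d in analysis.diagnostics],
        "delong": [dataclasses.asdict(d) for d in analysis.delong],
    }
    if agreement is not None:
        report["agreement"] = [dataclasses.asdict(a) for a in agreement]
        agree_df = pd.DataFrame(
            [{"feature": a.feature_name, "icc": a.icc, "band": a.icc_band,
              "bias": a.bland_altman_bias, "loa_low": a.loa_low,
              "loa_high": a.loa_high, "icc_form": a.icc_form}
             for a in agreement],
            columns=["feature", "icc", "band", "bias", "loa_low",
                     "loa_high", "icc_form"])
        paths["agreement"] = out_dir / "agreement.csv"
        agree_df.to_csv(paths["agreement"], index=False)
    paths["report"].write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return paths
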