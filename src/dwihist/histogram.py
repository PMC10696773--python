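"""First-order histogram features of a parameter map inside a VOI.

Six statistics per metric: mean, median, 10th percentile, 90th percentile,
kurtosis and skewness, computed over all valid in-mask voxel values.
Percentiles use linear interpolation between closest ranks.  Kurtosis is
Pearson-normalized (normal = 3) by default and skewness is the classical
population third standardized moment; both conventions are configurable and
recorded in the output so downstream tables are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ParameterMaps, VoiMask

__all__ = ["STATISTICS", "HistogramOptions", "FeatureRecord",
           "voi_statistics", "extract_features", "merge_records",
           "records_to_frame"]

STATISTICS = ("mean", "median", "p10", "p90", "kurtosis", "skewness")


@dataclass(frozen=True)
class HistogramOptions:
    """Estimator conventions for the shape statistics.

    kurtosis: "pearson" (normal = 3) or "excess" (normal = 0).
    skewness: "population" (biased moment estimator) or "adjusted"
        (adjusted Fisher-Pearson).
    """

    kurtosis: str = "pearson"
    skewness: str = "population"

    def __post_init__(self):
        if self.kurtosis not in ("pearson", "excess"):
            raise ValueError("kurtosis must be 'pearson' or 'excess'")
        if self.skewness not in ("population", "adjusted"):
            raise ValueError("skewness must be 'population' or 'adjusted'")

    @property
    def kurtosis_normal_reference(self) -> float:
        return 3.0 if self.kurtosis == "pearson" else 0.0


@dataclass
class FeatureRecord:
    """One subject's histogram statistics, keyed ``<metric>_<statistic>``.

    Missing statistics (too few voxels for shape estimates) are NaN;
    ``degenerate`` flags zero-variance metrics, for which skewness is 0 and
    kurtosis the convention's normal-reference value.
    """

    subject_id: str
    label: str
    features: dict
    n_voxels: int
    degenerate: tuple = ()
    conventions: dict = field(default_factory=dict)


def voi_statistics(values, opts: HistogramOptions | None = None):
    """Six first-order statistics of a 1-D value multiset.

    Returns ``(stats_dict, degenerate)`` where ``degenerate`` is True for a
    zero-variance input.  With fewer than 4 values, kurtosis and skewness
    are NaN (marked missing).
    """
    opts = opts or HistogramOptions()
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    values = np.sort(values)   # exact permutation invariance
    out = {
        "mean": float(values.mean()),
        "median": float(np.percentile(values, 50)),
        "p10": float(np.percentile(values, 10)),
        "p90": float(np.percentile(values, 90)),
    }
    degenerate = bool(values.size > 0 and np.ptp(values) == 0.0)
    if values.size < 4:
        out["kurtosis"] = float("nan")
        out["skewness"] = float("nan")
    elif degenerate:
        out["kurtosis"] = opts.kurtosis_normal_reference
        out["skewness"] = 0.0
    else:
        fisher = opts.kurtosis == "excess"
        out["kurtosis"] = float(sps.kurtosis(values, fisher=fisher,
                                             bias=True))
        out["skewness"] = float(sps.skew(values,
                                         bias=opts.skewness == "population"))
    return out, degenerate


def extract_features(maps: ParameterMaps, mask: VoiMask, subject_id: str,
                     label: str = "unknown",
                     opts: HistogramOptions | None = None) -> FeatureRecord:
    """Histogram features of every metric of one model over valid VOI voxels.

    The VOI is intersected with the fit validity mask; ``n_voxels`` reports
    the resulting count so masks can be audited.
    """
    opts = opts or HistogramOptions()
    if mask.data.shape != maps.valid_mask.shape:
        raise ValueError("mask shape does not match parameter maps")
    select = mask.data & maps.valid_mask
    n = int(select.sum())
    if n == 0:
        raise ValueError(
            f"subject {subject_id}: no valid voxels inside the VOI")
    features = {}
    degenerate = []
    for metric, vol in maps.maps.items():
        stats_dict, degen = voi_statistics(vol[select], opts)
        if degen:
            degenerate.append(metric)
        for stat, value in stats_dict.items():
            features[f"{metric}_{stat}"] = value
    return FeatureRecord(subject_id=subject_id, label=label,
                         features=features, n_voxels=n,
                         degenerate=tuple(degenerate),
                         conventions={"kurtosis": opts.kurtosis,
                                      "skewness": opts.skewness,
                                      "percentile": "linear"})


def merge_records(*records: FeatureRecord) -> FeatureRecord:
    """Merge one subject's records from several models into one row.

    ``n_voxels`` becomes the minimum across models (the most conservative
    audit count); conventions must agree.
    """
    if not records:
        raise ValueError("no records")
    first = records[0]
    features = {}
    degenerate = []
    for rec in records:
        if rec.subject_id != first.subject_id or rec.label != first.label:
            raise ValueError("records belong to different subjects")
        if rec.conventions != first.conventions:
            raise ValueError("records use different conventions")
        features.update(rec.features)
        degenerate.extend(rec.degenerate)
    return FeatureRecord(subject_id=first.subject_id, label=first.label,
                         features=features,
                         n_voxels=min(r.n_voxels for r in records),
                         degenerate=tuple(degenerate),
                         conventions=dict(first.conventions))


def records_to_frame(records) -> pd.DataFrame:
    """Cohort feature table: one row per subject, columns metric_statistic."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    feature_cols = sorted({k for r in records for k in r.features})
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "label": r.label,
               "n_voxels": r.n_voxels}
        for c in feature_cols:
            row[c] = r.features.get(c, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "label", "n_voxels"]
                        + feature_cols)
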