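"""Shared in-memory containers for volumes, masks and fitted parameter maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_models import AcquisitionScheme

__all__ = ["DwiSeries", "VoiMask", "ParameterMaps", "MODEL_METRICS"]

#: map names produced by each signal model
MODEL_METRICS = {
    "mem": ("ADC",),
    "bem": ("D", "Dstar", "f"),
    "sem": ("DDC", "alpha"),
}


@dataclass
class DwiSeries:
    """4-D magnitude DWI volume indexed (x, y, z, b) with its scheme."""

    data: np.ndarray
    scheme: AcquisitionScheme
    voxel_size: tuple = (1.25, 1.25, 5.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, b)")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"4th axis length {self.data.shape[3]} does not match "
                f"scheme length {len(self.scheme)}")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class VoiMask:
    """3-D boolean volume-of-interest mask."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ParameterMaps:
    """Per-voxel fitted maps for one model plus a validity mask.

    ``maps`` holds one 3-D float volume per metric (NaN outside
    ``valid_mask``); ``valid_mask`` marks voxels with a converged, in-bounds
    fit.  ``meta`` records the model name, bounds, options and convergence
    counts for provenance.
    """

    model_name: str
    maps: dict
    valid_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.valid_mask = np.asarray(self.valid_mask).astype(bool)
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError("all maps must share one shape")
        if shapes and self.valid_mask.shape not in shapes:
            raise ValueError("valid_mask shape must match maps")

    @property
    def metrics(self) -> tuple:
        return tuple(self.maps)
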