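"""Closed-form diffusion signal-decay models.

Three models of the magnitude DWI signal as a function of the diffusion
weighting b (s/mm**2) are provided:

* mono-exponential (MEM):        S(b) = S0 * exp(-b * ADC)
* bi-exponential / IVIM (BEM):   S(b) = S0 * [f * exp(-b * D*) + (1 - f) * exp(-b * D)]
* stretched-exponential (SEM):   S(b) = S0 * exp(-(b * DDC)**alpha)

All diffusion coefficients are carried in mm**2/s so that b*D products are
dimensionless; reports display them in the conventional 1e-3 mm**2/s scale.
The default acquisition scheme is a 12-b-value trace-weighted protocol from
b = 0 to 3000 s/mm**2 with per-b signal averaging (NEX) increasing at high b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_B_VALUES",
    "DEFAULT_NEX",
    "AcquisitionScheme",
    "MonoExpParams",
    "BiExpParams",
    "StretchedExpParams",
    "mem_signal",
    "bem_signal",
    "sem_signal",
]

#: 12-b-value acquisition: b in s/mm**2 and the number of excitations averaged per b.
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 150.0, 200.0, 300.0, 500.0, 800.0,
                    1000.0, 1500.0, 2000.0, 3000.0)
DEFAULT_NEX = (1, 1, 1, 1, 1, 1, 1, 2, 2, 3, 4, 6)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered diffusion weightings with per-b averaging counts.

    Parameters
    ----------
    b_values : tuple of float
        Diffusion weightings in s/mm**2; strictly increasing, starting at 0.
    nex : tuple of int
        Number of excitations averaged for each b; same length as ``b_values``.
    """

    b_values: tuple = DEFAULT_B_VALUES
    nex: tuple = DEFAULT_NEX

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        n = np.asarray(self.nex)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("scheme needs at least two b-values")
        if b[0] != 0:
            raise ValueError("first b-value must be 0")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if n.shape != b.shape:
            raise ValueError("nex must match b_values in length")
        if np.any(n <= 0) or not np.issubdtype(n.dtype, np.integer):
            raise ValueError("nex must be positive integers")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        object.__setattr__(self, "nex", tuple(int(x) for x in n))

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def nex_array(self) -> np.ndarray:
        return np.asarray(self.nex, dtype=float)

    def __len__(self) -> int:
        return len(self.b_values)

    def index_of(self, b: float) -> int:
        """Index of an exact b-value; raises if absent."""
        b_arr = self.b
        hits = np.flatnonzero(np.isclose(b_arr, b))
        if hits.size == 0:
            raise ValueError(f"b={b} not in scheme {self.b_values}")
        return int(hits[0])

    def subset(self, b_max: float) -> "AcquisitionScheme":
        """Scheme restricted to b <= b_max."""
        keep = self.b <= b_max
        if keep.sum() < 2:
            raise ValueError("b_max leaves fewer than two b-values")
        return AcquisitionScheme(tuple(np.asarray(self.b_values)[keep]),
                                 tuple(np.asarray(self.nex)[keep]))


@dataclass(frozen=True)
class MonoExpParams:
    """Mono-exponential parameters: baseline signal and ADC (mm**2/s)."""

    s0: float
    adc: float

    def __post_init__(self):
        if not (self.s0 > 0):
            raise ValueError("s0 must be > 0")
        if not np.isfinite(self.adc) or self.adc < 0:
            raise ValueError("adc must be finite and >= 0")


@dataclass(frozen=True)
class BiExpParams:
    """IVIM parameters: tissue diffusion d, pseudo-diffusion d_star (mm**2/s)
    and perfusion fraction f in [0, 1]."""

    s0: float
    d: float
    d_star: float
    f: float

    def __post_init__(self):
        if not (self.s0 > 0):
            raise ValueError("s0 must be > 0")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must be in [0, 1]")
        if self.d < 0 or self.d_star < self.d:
            raise ValueError("require 0 <= d <= d_star")


@dataclass(frozen=True)
class StretchedExpParams:
    """Stretched-exponential parameters: distributed diffusion coefficient ddc
    (mm**2/s) and heterogeneity exponent alpha in (0, 1]."""

    s0: float
    ddc: float
    alpha: float

    def __post_init__(self):
        if not (self.s0 > 0):
            raise ValueError("s0 must be > 0")
        if self.ddc < 0:
            raise ValueError("ddc must be >= 0")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")


def _check_b(b):
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    return b


def mem_signal(p: MonoExpParams, b) -> np.ndarray:
    """Mono-exponential decay S(b) = s0 * exp(-b * adc)."""
    b = _check_b(b)
    return p.s0 * np.exp(-b * p.adc)


def bem_signal(p: BiExpParams, b) -> np.ndarray:
    """Bi-exponential (IVIM) decay
    S(b) = s0 * [f * exp(-b * d_star) + (1 - f) * exp(-b * d)]."""
    b = _check_b(b)
    return p.s0 * (p.f * np.exp(-b * p.d_star) + (1.0 - p.f) * np.exp(-b * p.d))


def sem_signal(p: StretchedExpParams, b) -> np.ndarray:
    """Stretched-exponential decay S(b) = s0 * exp(-(b * ddc)**alpha).

    alpha = 1 reduces to the mono-exponential model with adc = ddc; alpha < 1
    expresses a continuous distribution of intravoxel diffusion rates.
    """
    b = _check_b(b)
    return p.s0 * np.exp(-np.power(b * p.ddc, p.alpha))


def _bem_signal_raw(b, s0, d, d_star, f):
    """Unvalidated BEM forward model on raw floats (fitting hot path)."""
    return s0 * (f * np.exp(-b * d_star) + (1.0 - f) * np.exp(-b * d))


def _sem_signal_raw(b, s0, ddc, alpha):
    """Unvalidated SEM forward model on raw floats (fitting hot path)."""
    return s0 * np.exp(-np.power(b * ddc, alpha))
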