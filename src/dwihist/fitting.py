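"""Voxelwise estimation of diffusion-model parameters from multi-b signals.

The mono-exponential ADC is a two-point closed form over b = 0 and
1000 s/mm**2.  The bi-exponential (IVIM) and stretched-exponential models are
estimated by bounded nonlinear least squares (trust-region reflective) with
analytic Jacobians; the IVIM fit is initialized from a segmented estimate
(log-linear tissue diffusion over the high-b regime, perfusion fraction from
the intercept gap, pseudo-diffusion from a coarse grid), which stabilizes the
notoriously ill-conditioned D* estimate.  Residuals are weighted by
sqrt(NEX) by default so b-values acquired with more averaging count more.

Fits are deterministic: no random restarts, identical inputs give identical
maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .containers import MODEL_METRICS, DwiSeries, ParameterMaps, VoiMask
from .signal_models import (AcquisitionScheme, BiExpParams, MonoExpParams,
                            StretchedExpParams, _bem_signal_raw,
                            _sem_signal_raw)

__all__ = ["FitOptions", "FitResult", "fit_mem", "fit_bem", "fit_sem",
           "fit_volume"]

# physiological parameter bounds (diffusivities in mm**2/s)
D_BOUNDS = (0.0, 3.0e-3)
DSTAR_BOUNDS = (0.0, 0.5)
F_BOUNDS = (0.0, 1.0)
DDC_BOUNDS = (0.0, 10.0e-3)
ALPHA_BOUNDS = (0.01, 1.0)

_TINY_D = 1.0e-8  # below this a decay rate is treated as "no decay"


@dataclass(frozen=True)
class FitOptions:
    """Options shared by the nonlinear fitters.

    weighting : "nex" weights each b-value's residual by sqrt(NEX);
        "none" uses unweighted residuals.
    b_max : restrict BEM/SEM fits to b <= b_max (None = use all b-values).
    b_split : b-value above which the signal is treated as perfusion-free
        for the segmented IVIM initialization (s/mm**2).
    """

    weighting: str = "nex"
    b_max: float | None = None
    b_split: float = 200.0
    max_nfev: int = 400

    def __post_init__(self):
        if self.weighting not in ("nex", "none"):
            raise ValueError("weighting must be 'nex' or 'none'")


@dataclass(frozen=True)
class FitResult:
    params: object
    converged: bool
    residual_norm: float
    n_iter: int


def _invalid(params=None) -> FitResult:
    return FitResult(params=params, converged=False,
                     residual_norm=math.nan, n_iter=0)


def _weights(scheme: AcquisitionScheme, opts: FitOptions) -> np.ndarray:
    if opts.weighting == "nex":
        return np.sqrt(scheme.nex_array)
    return np.ones(len(scheme))


def _apply_subset(sig, scheme, opts):
    sig = np.asarray(sig, dtype=float)
    if sig.shape != (len(scheme),):
        raise ValueError("signal length must match scheme")
    if opts.b_max is not None:
        keep = scheme.b <= opts.b_max
        scheme = scheme.subset(opts.b_max)
        sig = sig[keep]
    return sig, scheme


def fit_mem(sig, scheme: AcquisitionScheme | None = None) -> FitResult:
    """Two-point closed-form ADC from b = 0 and b = 1000 s/mm**2.

    ADC = ln(S(0)/S(1000)) / 1000.  Voxels with a nonpositive signal at
    either b, or with S(1000) > S(0) (negative implied ADC, noise-dominated),
    come back with ``converged=False`` rather than raising.
    """
    scheme = scheme or AcquisitionScheme()
    sig = np.asarray(sig, dtype=float)
    if sig.shape != (len(scheme),):
        raise ValueError("signal length must match scheme")
    i0 = scheme.index_of(0.0)
    i1 = scheme.index_of(1000.0)
    s_0, s_1000 = sig[i0], sig[i1]
    if not (s_0 > 0 and s_1000 > 0):
        return _invalid()
    adc = math.log(s_0 / s_1000) / 1000.0
    if adc < 0:
        return _invalid()
    return FitResult(params=MonoExpParams(s0=float(s_0), adc=adc),
                     converged=True, residual_norm=0.0, n_iter=0)


def _bem_residual_jac(b, sig, w):
    def resid(x):
        s0, d, ds, f = x
        return w * (sig - _bem_signal_raw(b, s0, d, ds, f))

    def jac(x):
        s0, d, ds, f = x
        e_fast = np.exp(-b * ds)
        e_slow = np.exp(-b * d)
        j = np.empty((b.size, 4))
        j[:, 0] = f * e_fast + (1.0 - f) * e_slow
        j[:, 1] = -s0 * (1.0 - f) * b * e_slow
        j[:, 2] = -s0 * f * b * e_fast
        j[:, 3] = s0 * (e_fast - e_slow)
        return -w[:, None] * j

    return resid, jac


def _segmented_init(b, sig, w, opts):
    """Segmented IVIM initialization: (s0, d, d_star, f) start point."""
    s_0 = sig[0]
    high = b >= opts.b_split
    if high.sum() >= 2:
        # weighted log-linear fit of the perfusion-free tail
        coef = np.polyfit(b[high], np.log(sig[high]), 1, w=w[high])
        d0 = float(np.clip(-coef[0], _TINY_D, D_BOUNDS[1]))
        f0 = float(np.clip(1.0 - math.exp(coef[1]) / s_0, 0.0, 0.95))
    else:
        d0 = float(np.clip(math.log(sig[0] / sig[-1]) / max(b[-1], 1.0),
                           _TINY_D, D_BOUNDS[1])) if sig[-1] > 0 else 1e-3
        f0 = 0.1
    # coarse grid over the pseudo-diffusion rate
    grid = np.geomspace(1e-3, 0.2, 25)
    ssr = [float(np.sum((w * (sig - _bem_signal_raw(b, s_0, d0, ds, f0))) ** 2))
           for ds in grid]
    ds0 = float(grid[int(np.argmin(ssr))])
    return np.array([s_0, d0, ds0, f0])


def fit_bem(sig, scheme: AcquisitionScheme | None = None,
            opts: FitOptions | None = None) -> FitResult:
    """Joint 4-parameter bounded IVIM fit with segmented initialization."""
    scheme = scheme or AcquisitionScheme()
    opts = opts or FitOptions()
    sig, scheme = _apply_subset(sig, scheme, opts)
    if np.sum(sig > 0) < 4 or sig[0] <= 0 or not np.all(np.isfinite(sig)):
        return _invalid()
    b = scheme.b
    w = _weights(scheme, opts)
    x0 = _segmented_init(b, sig, w, opts)
    lb = [1e-9, D_BOUNDS[0], DSTAR_BOUNDS[0], F_BOUNDS[0]]
    ub = [5.0 * float(sig.max()), D_BOUNDS[1], DSTAR_BOUNDS[1], F_BOUNDS[1]]
    x0 = np.clip(x0, lb, ub)
    resid, jac = _bem_residual_jac(b, sig, w)
    res = least_squares(resid, x0, jac=jac, bounds=(lb, ub),
                        max_nfev=opts.max_nfev, method="trf")
    s0, d, ds, f = (float(v) for v in res.x)
    ok = res.status > 0
    # degenerate-fit policy: ordering violated, pseudo-diffusion pinned at
    # its ceiling (noise-chasing runaway), or no decay at all
    if ds < d:
        ok = False
    if ds >= 0.999 * DSTAR_BOUNDS[1]:
        ok = False
    if d <= _TINY_D and f <= 0.01:
        ok = False
    params = None
    if ok:
        params = BiExpParams(s0=s0, d=d, d_star=ds, f=f)
    return FitResult(params=params, converged=ok,
                     residual_norm=float(2.0 * res.cost),
                     n_iter=int(res.nfev))


def _sem_residual_jac(b, sig, w):
    def resid(x):
        s0, ddc, alpha = x
        return w * (sig - _sem_signal_raw(b, s0, ddc, alpha))

    def jac(x):
        s0, ddc, alpha = x
        u = b * ddc
        with np.errstate(divide="ignore"):
            ua = np.power(u, alpha)
            logu = np.where(u > 0, np.log(np.maximum(u, 1e-300)), 0.0)
        m = s0 * np.exp(-ua)
        j = np.empty((b.size, 3))
        j[:, 0] = np.exp(-ua)
        j[:, 1] = np.where(u > 0, -m * alpha * ua / max(ddc, 1e-300), 0.0)
        j[:, 2] = np.where(u > 0, -m * ua * logu, 0.0)
        return -w[:, None] * j

    return resid, jac


def fit_sem(sig, scheme: AcquisitionScheme | None = None,
            opts: FitOptions | None = None) -> FitResult:
    """Bounded stretched-exponential fit; alpha in (0.01, 1], ddc >= 0.

    Initialized at alpha = 0.9 with ddc at the two-point ADC estimate when
    b = 0/1000 are present, otherwise at a global log-linear slope.
    """
    scheme = scheme or AcquisitionScheme()
    opts = opts or FitOptions()
    sig, scheme = _apply_subset(sig, scheme, opts)
    if np.sum(sig > 0) < 2 or sig[0] <= 0 or not np.all(np.isfinite(sig)):
        return _invalid()
    if np.sum(sig > 0) == 2:
        # alpha is unidentifiable from two points: report the alpha = 1
        # (mono-exponential) boundary sub-model in closed form
        j = int(np.flatnonzero(sig > 0)[1])
        ddc = math.log(sig[0] / sig[j]) / scheme.b[j]
        if ddc <= _TINY_D:
            return _invalid()
        return FitResult(params=StretchedExpParams(s0=float(sig[0]),
                                                   ddc=ddc, alpha=1.0),
                         converged=True, residual_norm=0.0, n_iter=0)
    b = scheme.b
    w = _weights(scheme, opts)
    try:
        mem = fit_mem(sig, scheme)
        ddc0 = mem.params.adc if mem.converged else 1e-3
    except ValueError:
        ddc0 = 1e-3
    ddc0 = float(np.clip(ddc0, 1e-5, DDC_BOUNDS[1]))
    x0 = np.array([sig[0], ddc0, 0.9])
    lb = [1e-9, DDC_BOUNDS[0], ALPHA_BOUNDS[0]]
    ub = [5.0 * float(sig.max()), DDC_BOUNDS[1], ALPHA_BOUNDS[1]]
    resid, jac = _sem_residual_jac(b, sig, w)
    res = least_squares(resid, np.clip(x0, lb, ub), jac=jac, bounds=(lb, ub),
                        max_nfev=opts.max_nfev, method="trf")
    s0, ddc, alpha = (float(v) for v in res.x)
    ok = res.status > 0 and ddc > _TINY_D
    params = None
    if ok:
        params = StretchedExpParams(s0=s0, ddc=ddc, alpha=alpha)
    return FitResult(params=params, converged=ok,
                     residual_norm=float(2.0 * res.cost),
                     n_iter=int(res.nfev))


_SCALAR_FITTERS = {"mem": fit_mem, "bem": fit_bem, "sem": fit_sem}

_PARAM_ATTR = {
    "mem": {"ADC": "adc"},
    "bem": {"D": "d", "Dstar": "d_star", "f": "f"},
    "sem": {"DDC": "ddc", "alpha": "alpha"},
}


def fit_volume(dwi: DwiSeries, mask: VoiMask, model: str,
               opts: FitOptions | None = None) -> ParameterMaps:
    """Fit every in-mask voxel independently and assemble parameter maps.

    Equivalent to looping the scalar fitter over mask voxels; voxels whose
    fit does not converge (or lands out of bounds) are excluded from
    ``valid_mask`` and set to NaN in the maps.
    """
    if model not in _SCALAR_FITTERS:
        raise ValueError(f"unknown model '{model}' (expected mem/bem/sem)")
    opts = opts or FitOptions()
    if mask.data.shape != dwi.spatial_shape:
        raise ValueError("mask shape does not match DWI spatial shape")
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    shape = dwi.spatial_shape
    metric_names = MODEL_METRICS[model]
    maps = {m: np.full(shape, np.nan) for m in metric_names}
    valid = np.zeros(shape, dtype=bool)
    fitter = _SCALAR_FITTERS[model]
    attr = _PARAM_ATTR[model]
    n_converged = 0
    voxels = np.argwhere(mask.data)
    for idx in voxels:
        i, j, k = idx
        if model == "mem":
            result = fitter(dwi.data[i, j, k, :], dwi.scheme)
        else:
            result = fitter(dwi.data[i, j, k, :], dwi.scheme, opts)
        if result.converged:
            n_converged += 1
            valid[i, j, k] = True
            for name, a in attr.items():
                maps[name][i, j, k] = getattr(result.params, a)
    return ParameterMaps(
        model_name=model, maps=maps, valid_mask=valid,
        meta={
            "model": model,
            "options": {"weighting": opts.weighting, "b_max": opts.b_max,
                        "b_split": opts.b_split},
            "bounds": {"d": D_BOUNDS, "d_star": DSTAR_BOUNDS, "f": F_BOUNDS,
                       "ddc": DDC_BOUNDS, "alpha": ALPHA_BOUNDS},
            "n_mask_voxels": int(len(voxels)),
            "n_converged": int(n_converged),
        })
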