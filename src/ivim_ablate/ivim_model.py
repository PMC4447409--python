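"""Bi-exponential intravoxel incoherent motion (IVIM) modelling.

The signal model is

    S(b) = S0 * (f * exp(-b * D_star) + (1 - f) * exp(-b * D))

with perfusion fraction ``f``, true diffusion coefficient ``D`` and
pseudodiffusion coefficient ``D_star`` (both in mm^2/s, with
``D_star > D``).  Fitting proceeds in two stages: a segmented fit
(log-linear high-b estimate of ``D``, intercept-based ``f``, bounded
one-dimensional search for ``D_star``) followed by a bounded four-parameter
nonlinear least-squares refinement seeded from the segmented result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import FitError, ParameterError

__all__ = [
    "IVIMParams",
    "FitQuality",
    "ParameterMaps",
    "F_BOUNDS",
    "D_BOUNDS",
    "DSTAR_BOUNDS",
    "DEFAULT_B_THRESHOLD",
    "ivim_signal",
    "fit_ivim_segmented",
    "fit_ivim_full",
    "fit_ivim",
    "fit_ivim_volume",
    "fit_ivim_roi",
]

#: Hard box constraints applied by every fitting routine.
F_BOUNDS = (0.0, 1.0)
D_BOUNDS = (1e-6, 3e-3)  # mm^2/s
DSTAR_BOUNDS = (3e-3, 0.5)  # mm^2/s

#: b-value (s/mm^2) separating the diffusion-dominated segment; the
#: pseudodiffusion compartment with D_star >= 0.06 mm^2/s has decayed by
#: exp(-12) at b = 200.
DEFAULT_B_THRESHOLD = 200.0

_REL_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class IVIMParams:
    """One voxel's (or ROI's) bi-exponential decay parameters."""

    S0: float
    f: float
    D: float
    D_star: float

    def validate(self) -> None:
        if not (self.S0 > 0 and math.isfinite(self.S0)):
            raise ParameterError(f"S0 must be finite and > 0, got {self.S0}")
        if not (0.0 <= self.f <= 1.0):
            raise ParameterError(f"f must lie in [0, 1], got {self.f}")
        if not (self.D > 0 and math.isfinite(self.D)):
            raise ParameterError(f"D must be finite and > 0, got {self.D}")
        if not (self.D_star > self.D):
            raise ParameterError(
                f"D_star ({self.D_star}) must exceed D ({self.D})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.S0, self.f, self.D, self.D_star], dtype=float)


@dataclass
class FitQuality:
    """Goodness-of-fit bookkeeping attached to every fit result."""

    rss: float
    n_points: int
    converged: bool
    algorithm: str  # "SEGMENTED" or "FULL"


@dataclass
class ParameterMaps:
    """Voxelwise parameter maps; values are NaN outside ``mask``."""

    f_map: np.ndarray
    D_map: np.ndarray
    Dstar_map: np.ndarray
    S0_map: np.ndarray
    mask: np.ndarray


def ivim_signal(b, params: IVIMParams) -> np.ndarray:
    """Evaluate the bi-exponential decay at one or many b-values."""
    params.validate()
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ParameterError("b-values must be non-negative")
    out = params.S0 * (
        params.f * np.exp(-b_arr * params.D_star)
        + (1.0 - params.f) * np.exp(-b_arr * params.D)
    )
    return out if out.ndim else float(out)


def _check_series(signals, b_values) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(signals, dtype=float).ravel()
    b = np.asarray(b_values, dtype=float).ravel()
    if s.shape != b.shape:
        raise FitError(
            f"signal/b-value length mismatch: {s.size} signals vs {b.size} b-values"
        )
    if not np.all(np.isfinite(s)):
        raise FitError("signals contain non-finite values")
    if np.any(s <= 0):
        raise FitError("all signals must be positive for IVIM fitting")
    return s, b


def _clamp(value: float, bounds: tuple[float, float]) -> tuple[float, bool]:
    lo, hi = bounds
    clamped = value < lo or value > hi
    return min(max(value, lo), hi), clamped


def fit_ivim_segmented(
    signals, b_values, b_threshold: float = DEFAULT_B_THRESHOLD
) -> tuple[IVIMParams, FitQuality]:
    """Segmented fit: high-b log-linear D, intercept f, 1-D search for D_star.

    Requires at least three b-values at or above ``b_threshold`` and two
    below.  Degenerate decays (flat or rising signal) return parameters
    clamped to the box constraints with ``converged=False``.
    """
    s, b = _check_series(signals, b_values)
    hi = b >= b_threshold
    lo = ~hi
    if hi.sum() < 3 or lo.sum() < 2:
        raise FitError(
            f"need >=3 points at b>={b_threshold} and >=2 below; "
            f"got {int(hi.sum())} and {int(lo.sum())}"
        )

    # Step 1: log-linear diffusion-segment fit.
    slope, log_intercept = np.polyfit(b[hi], np.log(s[hi]), 1)
    D, d_clamped = _clamp(-slope, D_BOUNDS)
    s_int = math.exp(log_intercept)

    # Step 2: perfusion fraction from the b=0 estimate.
    zero = b == 0
    if zero.any():
        s0_est = float(s[zero].mean())
    else:
        lo_slope, lo_int = np.polyfit(b[lo], np.log(s[lo]), 1)
        s0_est = math.exp(lo_int)
    f, f_clamped = _clamp(1.0 - s_int / s0_est, F_BOUNDS)

    # Step 3: bounded 1-D fit of D_star with S0, f, D held fixed.
    tissue = (1.0 - f) * np.exp(-b * D)

    def cost(d_star: float) -> float:
        model = s0_est * (f * np.exp(-b * d_star) + tissue)
        return float(np.sum((model - s) ** 2))

    ds_converged = True
    if f <= 1e-12:
        d_star = max(DSTAR_BOUNDS[0], 5.0 * D)
        ds_converged = False
    else:
        res = minimize_scalar(
            cost, bounds=DSTAR_BOUNDS, method="bounded",
            options={"xatol": 1e-14},
        )
        d_star = float(res.x)
        ds_converged = bool(res.success)

    if d_star <= D:  # touching bounds, e.g. D clamped to its upper limit
        d_star = D * (1.0 + 1e-6) + 1e-12
        ds_converged = False

    params = IVIMParams(S0=s0_est, f=f, D=D, D_star=d_star)
    rss = float(np.sum((np.asarray(ivim_signal(b, params)) - s) ** 2))
    converged = ds_converged and not d_clamped and not f_clamped
    return params, FitQuality(rss, s.size, converged, "SEGMENTED")


def _residual_and_jac(x: np.ndarray, b: np.ndarray, s: np.ndarray):
    s0, f, d, ds = x
    e_star = np.exp(-b * ds)
    e_d = np.exp(-b * d)
    model = s0 * (f * e_star + (1.0 - f) * e_d)
    r = model - s
    jac = np.empty((b.size, 4))
    jac[:, 0] = f * e_star + (1.0 - f) * e_d
    jac[:, 1] = s0 * (e_star - e_d)
    jac[:, 2] = -s0 * (1.0 - f) * b * e_d
    jac[:, 3] = -s0 * f * b * e_star
    return r, jac


def fit_ivim_full(
    signals, b_values, init: IVIMParams
) -> tuple[IVIMParams, FitQuality]:
    """Bounded 4-parameter refinement; never returns a worse fit than ``init``.

    If the optimizer fails to improve on the initial point the initial
    parameters are returned with ``converged=False``.
    """
    s, b = _check_series(signals, b_values)
    if s.size < 4:
        raise FitError("full IVIM fit needs at least 4 points")
    init.validate()

    lower = np.array([1e-12, F_BOUNDS[0], D_BOUNDS[0], DSTAR_BOUNDS[0]])
    upper = np.array([np.inf, F_BOUNDS[1], D_BOUNDS[1], DSTAR_BOUNDS[1]])
    x0 = np.clip(init.as_array(), lower, upper)

    rss_init = float(np.sum((np.asarray(ivim_signal(b, init)) - s) ** 2))
    try:
        res = least_squares(
            lambda x: _residual_and_jac(x, b, s)[0],
            x0,
            jac=lambda x: _residual_and_jac(x, b, s)[1],
            bounds=(lower, upper),
            method="trf",
            x_scale=[max(x0[0], 1.0), 0.25, 1e-3, 0.05],
            ftol=1e-15,
            xtol=1e-15,
            gtol=1e-15,
            max_nfev=200,
        )
    except Exception:
        q = FitQuality(rss_init, s.size, False, "FULL")
        return init, q

    rss_full = float(2.0 * res.cost)
    if not np.isfinite(rss_full) or rss_full > rss_init * (1 + _REL_CLAMP_TOL):
        return init, FitQuality(rss_init, s.size, False, "FULL")

    s0, f, d, ds = res.x
    if ds <= d:
        ds = d * (1.0 + 1e-6) + 1e-12
    params = IVIMParams(S0=float(s0), f=float(f), D=float(d), D_star=float(ds))
    converged = bool(res.status > 0)
    return params, FitQuality(rss_full, s.size, converged, "FULL")


_DSTAR_RESTARTS = (0.01, 0.03, 0.1, 0.3)


def fit_ivim(
    signals, b_values, b_threshold: float = DEFAULT_B_THRESHOLD
) -> tuple[IVIMParams, FitQuality]:
    """Segmented initialization followed by the full bounded refinement.

    When the refined fit leaves a residual that is large relative to machine
    precision *and* the segmented stage flagged trouble, a small set of
    deterministic D_star restarts guards against a bad initial basin.
    """
    seg_params, seg_q = fit_ivim_segmented(signals, b_values, b_threshold)
    params, quality = fit_ivim_full(signals, b_values, seg_params)

    s = np.asarray(signals, dtype=float).ravel()
    scale = float(np.sum(s**2))
    if quality.rss > 1e-16 * scale and not seg_q.converged:
        best = (params, quality)
        for ds0 in _DSTAR_RESTARTS:
            if ds0 <= seg_params.D:
                continue
            alt = replace(seg_params, D_star=ds0, f=min(max(seg_params.f, 0.05), 0.95))
            cand, cand_q = fit_ivim_full(signals, b_values, alt)
            if cand_q.rss < best[1].rss:
                best = (cand, cand_q)
        params, quality = best
    return params, quality


_DEGENERATE = IVIMParams(
    S0=1.0, f=0.0, D=D_BOUNDS[0], D_star=DSTAR_BOUNDS[0]
)


def fit_ivim_volume(
    dwi: np.ndarray,
    b_values,
    mask: np.ndarray,
    b_threshold: float = DEFAULT_B_THRESHOLD,
) -> ParameterMaps:
    """Voxel-by-voxel fitting over a boolean mask.

    Degenerate voxels (e.g. non-positive signal) yield bound-clamped
    parameters with ``converged=False`` instead of aborting the volume.
    """
    dwi = np.asarray(dwi, dtype=float)
    b = np.asarray(b_values, dtype=float).ravel()
    if dwi.ndim != 4 or dwi.shape[3] != b.size:
        raise FitError(
            f"dwi 4th dimension ({dwi.shape[-1] if dwi.ndim == 4 else 'n/a'}) "
            f"must match number of b-values ({b.size})"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape[:3]:
        raise FitError(
            f"mask shape {mask.shape} does not match spatial dims {dwi.shape[:3]}"
        )

    shape = dwi.shape[:3]
    maps = ParameterMaps(
        f_map=np.full(shape, np.nan),
        D_map=np.full(shape, np.nan),
        Dstar_map=np.full(shape, np.nan),
        S0_map=np.full(shape, np.nan),
        mask=mask.copy(),
    )
    for idx in zip(*np.nonzero(mask)):
        series = dwi[idx]
        try:
            params, _ = fit_ivim(series, b, b_threshold)
        except FitError:
            params = replace(_DEGENERATE, S0=max(float(series.max()), 1e-12))
        maps.f_map[idx] = params.f
        maps.D_map[idx] = params.D
        maps.Dstar_map[idx] = params.D_star
        maps.S0_map[idx] = params.S0
    return maps


def fit_ivim_roi(
    dwi: np.ndarray,
    labels: np.ndarray,
    code: int,
    b_values,
    b_threshold: float = DEFAULT_B_THRESHOLD,
) -> tuple[IVIMParams, FitQuality]:
    """Fit the mean signal over all voxels carrying ``code`` in ``labels``."""
    labels = np.asarray(labels)
    sel = labels == code
    if not sel.any():
        raise FitError(f"label code {code} absent from label volume")
    mean_signal = np.asarray(dwi, dtype=float)[sel].mean(axis=0)
    return fit_ivim(mean_signal, b_values, b_threshold)
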