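"""Standard Tofts two-compartment DCE quantification at the ROI level.

Tissue concentration follows

    Ct(t) = Ktrans * integral_0^t Cp(tau) * exp(-Kep * (t - tau)) dtau

with ``Kep = Ktrans / Ve`` enforced as an identity.  The convolution is
evaluated with an exact trapezoidal recursion on the acquisition grid, and
fitting is a bounded two-parameter (Ktrans, Ve) nonlinear least squares.
Times are minutes, concentrations mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ParameterError
from .ivim_model import FitQuality

__all__ = [
    "DCEParams",
    "InputFunction",
    "ConcentrationCurve",
    "population_aif",
    "tofts_concentration",
    "kep_from",
    "fit_tofts",
    "DEFAULT_AIF_ONSET_MIN",
    "DEFAULT_AIF_ALPHA",
    "DEFAULT_AIF_BETA_MIN",
    "DEFAULT_AIF_PEAK_MM",
]

DEFAULT_AIF_ONSET_MIN = 0.25  # bolus arrival after 5 x 3 s baseline frames
DEFAULT_AIF_ALPHA = 3.0
DEFAULT_AIF_BETA_MIN = 0.15
DEFAULT_AIF_PEAK_MM = 5.0

KTRANS_BOUNDS = (0.0, 5.0)  # 1/min
VE_BOUNDS = (1e-3, 1.0)


def kep_from(ktrans: float, ve: float) -> float:
    """Reflux constant Kep = Ktrans / Ve (1/min)."""
    if ve <= 0:
        raise ParameterError(f"Ve must be > 0, got {ve}")
    if ktrans < 0:
        raise ParameterError(f"Ktrans must be >= 0, got {ktrans}")
    return ktrans / ve


@dataclass(frozen=True)
class DCEParams:
    ktrans: float  # 1/min
    ve: float  # fraction
    kep: float  # 1/min

    def __post_init__(self):
        if self.ktrans < 0:
            raise ParameterError(f"Ktrans must be >= 0, got {self.ktrans}")
        if not (0.0 < self.ve <= 1.0):
            raise ParameterError(f"Ve must lie in (0, 1], got {self.ve}")
        expected = self.ktrans / self.ve
        if abs(self.kep - expected) > 1e-9 * max(1.0, abs(self.kep)):
            raise ParameterError(
                f"Kep ({self.kep}) inconsistent with Ktrans/Ve ({expected})"
            )

    @classmethod
    def from_ktrans_ve(cls, ktrans: float, ve: float) -> "DCEParams":
        return cls(ktrans=ktrans, ve=ve, kep=kep_from(ktrans, ve))


def _check_grid(times: np.ndarray, name: str) -> None:
    if times.ndim != 1 or times.size < 2:
        raise ParameterError(f"{name} grid needs >=2 samples")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ParameterError(f"{name} grid must be strictly increasing and >=0")


@dataclass
class InputFunction:
    """Plasma concentration Cp(t); times in minutes, cp in mM."""

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        _check_grid(self.times, "AIF time")
        if self.cp.shape != self.times.shape:
            raise ParameterError("AIF times and cp must have equal length")
        if np.any(self.cp < 0):
            raise ParameterError("AIF concentrations must be >= 0")


@dataclass
class ConcentrationCurve:
    """Tissue concentration Ct(t) on the same grid as its input function."""

    times: np.ndarray
    ct: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        _check_grid(self.times, "curve time")
        if self.ct.shape != self.times.shape:
            raise ParameterError("curve times and ct must have equal length")
        if not np.all(np.isfinite(self.ct)):
            raise ParameterError("curve contains non-finite values")


def population_aif(
    times_min,
    onset_min: float = DEFAULT_AIF_ONSET_MIN,
    alpha: float = DEFAULT_AIF_ALPHA,
    beta_min: float = DEFAULT_AIF_BETA_MIN,
    peak_mm: float = DEFAULT_AIF_PEAK_MM,
) -> InputFunction:
    """Gamma-variate bolus ``A * (t-t0)^alpha * exp(-(t-t0)/beta)``.

    ``A`` is scaled so the analytic peak (at ``t0 + alpha*beta``) equals
    ``peak_mm``; the curve is zero up to the onset.
    """
    times = np.asarray(times_min, dtype=float)
    _check_grid(times, "AIF time")
    if alpha <= 0 or beta_min <= 0 or peak_mm <= 0:
        raise ParameterError("alpha, beta and peak must all be > 0")
    if not (times[0] <= onset_min <= times[-1]):
        raise ParameterError(
            f"onset {onset_min} outside time grid [{times[0]}, {times[-1]}]"
        )
    amplitude = peak_mm / ((alpha * beta_min) ** alpha * math.exp(-alpha))
    dt = np.clip(times - onset_min, 0.0, None)
    cp = np.where(dt > 0, amplitude * dt**alpha * np.exp(-dt / beta_min), 0.0)
    return InputFunction(times=times, cp=cp)


def tofts_concentration(
    aif: InputFunction, ktrans: float, ve: float
) -> ConcentrationCurve:
    """Forward Tofts model via an exact trapezoidal convolution recursion."""
    if ktrans < 0:
        raise ParameterError(f"Ktrans must be >= 0, got {ktrans}")
    if ve <= 0:
        raise ParameterError(f"Ve must be > 0, got {ve}")
    kep = ktrans / ve
    t, cp = aif.times, aif.cp
    ct = np.zeros_like(cp)
    # I_i = e^{-kep dt} I_{i-1} + dt/2 (cp_i + e^{-kep dt} cp_{i-1}):
    # the trapezoid rule applied to cp(tau) e^{-kep (t_i - tau)}.
    integral = 0.0
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        decay = math.exp(-kep * dt)
        integral = integral * decay + 0.5 * dt * (cp[i] + decay * cp[i - 1])
        ct[i] = ktrans * integral
    return ConcentrationCurve(times=t, ct=ct)


def _check_shared_grid(curve: ConcentrationCurve, aif: InputFunction) -> None:
    if curve.times.shape != aif.times.shape or not np.allclose(
        curve.times, aif.times, rtol=0, atol=1e-9
    ):
        raise FitError("concentration curve and AIF must share one time grid")


def fit_tofts(
    curve: ConcentrationCurve, aif: InputFunction
) -> tuple[DCEParams, FitQuality]:
    """Bounded (Ktrans, Ve) least squares against the forward Tofts model."""
    _check_shared_grid(curve, aif)
    ct = curve.ct
    n = ct.size

    cum = np.concatenate(([0.0], np.cumsum(
        0.5 * np.diff(aif.times) * (aif.cp[1:] + aif.cp[:-1])
    )))
    exposure = float(cum[-1])
    if exposure <= 0:
        raise FitError("AIF carries no contrast (zero integral)")

    def resid(x):
        model = tofts_concentration(aif, x[0], x[1]).ct
        return model - ct

    ktrans0 = min(max(float(np.max(ct, initial=0.0)) / exposure, 1e-3), 1.0)
    best = None
    for x0 in ((ktrans0, 0.3), (0.1, 0.2), (0.5, 0.6)):
        res = least_squares(
            resid,
            x0,
            bounds=([KTRANS_BOUNDS[0], VE_BOUNDS[0]], [KTRANS_BOUNDS[1], VE_BOUNDS[1]]),
            method="trf",
            x_scale=[0.1, 0.25],
            ftol=1e-15,
            xtol=1e-15,
            gtol=1e-15,
            max_nfev=300,
        )
        if best is None or res.cost < best.cost:
            best = res
        if best.cost <= 1e-20 * max(1.0, float(np.sum(ct**2))):
            break

    ktrans, ve = (float(v) for v in best.x)
    params = DCEParams.from_ktrans_ve(max(ktrans, 0.0), ve)
    quality = FitQuality(
        rss=float(2.0 * best.cost),
        n_points=n,
        converged=bool(best.status > 0),
        algorithm="FULL",
    )
    return params, quality
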