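"""CT perfusion quantification from time-density curves.

A deliberately self-consistent scheme: the forward model

    tissue(t) = (BV/100) * cp(t) + (PMB * BF / 100) * integral_0^t cp dtau

(leakage constant per minute) is paired with a max-slope blood-flow
estimator and a Patlak linearization, so that simulation and estimation
share one documented model.  Times are seconds, enhancements HU
(baseline-subtracted), BF in mL/100 mL/min, BV in mL/100 mL, PMB a
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, ParameterError

__all__ = [
    "TimeDensityCurve",
    "CTPerfusionParams",
    "PatlakFit",
    "ct_aif",
    "ct_forward",
    "estimate_bf_maxslope",
    "fit_patlak",
    "estimate_ct_params",
    "DEFAULT_CT_AIF_ONSET_S",
    "DEFAULT_CT_AIF_BETA_S",
    "DEFAULT_CT_AIF_PEAK_HU",
]

DEFAULT_CT_AIF_ONSET_S = 10.0  # 10 x 1 s baseline frames
DEFAULT_CT_AIF_ALPHA = 3.0
DEFAULT_CT_AIF_BETA_S = 6.0
DEFAULT_CT_AIF_PEAK_HU = 300.0

_SMOOTH_WINDOW = 3


@dataclass
class TimeDensityCurve:
    """Baseline-subtracted enhancement versus time."""

    times: np.ndarray  # seconds
    hu: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.hu = np.asarray(self.hu, dtype=float)
        if self.times.ndim != 1 or self.times.size < 3:
            raise ParameterError("time grid needs >=3 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("time grid must be strictly increasing")
        if self.hu.shape != self.times.shape:
            raise ParameterError("times and hu must have equal length")
        if not np.all(np.isfinite(self.hu)):
            raise ParameterError("curve contains non-finite values")


@dataclass(frozen=True)
class CTPerfusionParams:
    bf: float  # mL/100 mL/min
    bv: float  # mL/100 mL
    pmb: float  # fraction

    def __post_init__(self):
        if self.bf < 0 or self.bv < 0 or self.pmb < 0:
            raise ParameterError("BF, BV and PMB must all be >= 0")
        if self.pmb > 1:
            raise ParameterError(f"PMB is a fraction, got {self.pmb}")

    @property
    def leakage(self) -> float:
        """Leakage rate constant PMB * BF / 100, per minute."""
        return self.pmb * self.bf / 100.0


@dataclass
class PatlakFit:
    bv: float
    leakage: float  # per minute
    r_squared: float


def ct_aif(
    times_s,
    onset_s: float = DEFAULT_CT_AIF_ONSET_S,
    alpha: float = DEFAULT_CT_AIF_ALPHA,
    beta_s: float = DEFAULT_CT_AIF_BETA_S,
    peak_hu: float = DEFAULT_CT_AIF_PEAK_HU,
) -> TimeDensityCurve:
    """Gamma-variate arterial enhancement, zero through the baseline frames."""
    times = np.asarray(times_s, dtype=float)
    if alpha <= 0 or beta_s <= 0 or peak_hu <= 0:
        raise ParameterError("alpha, beta and peak must all be > 0")
    amplitude = peak_hu / ((alpha * beta_s) ** alpha * np.exp(-alpha))
    dt = np.clip(times - onset_s, 0.0, None)
    hu = np.where(dt > 0, amplitude * dt**alpha * np.exp(-dt / beta_s), 0.0)
    return TimeDensityCurve(times=times, hu=hu)


def _cumtrapz_minutes(curve: TimeDensityCurve) -> np.ndarray:
    """Running integral of the curve, in HU * minutes."""
    dt = np.diff(curve.times) / 60.0
    seg = 0.5 * dt * (curve.hu[1:] + curve.hu[:-1])
    return np.concatenate(([0.0], np.cumsum(seg)))


def ct_forward(aif: TimeDensityCurve, params: CTPerfusionParams) -> TimeDensityCurve:
    """Blood-pool term plus unidirectional leakage of the running AIF integral."""
    tissue = (params.bv / 100.0) * aif.hu + params.leakage * _cumtrapz_minutes(aif)
    return TimeDensityCurve(times=aif.times.copy(), hu=tissue)


def _smooth(values: np.ndarray) -> np.ndarray:
    kernel = np.ones(_SMOOTH_WINDOW) / _SMOOTH_WINDOW
    padded = np.pad(values, _SMOOTH_WINDOW // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _check_shared(tissue: TimeDensityCurve, aif: TimeDensityCurve) -> None:
    if tissue.times.shape != aif.times.shape or not np.allclose(
        tissue.times, aif.times, rtol=0, atol=1e-9
    ):
        raise FitError("tissue curve and AIF must share one time grid")


def estimate_bf_maxslope(tissue: TimeDensityCurve, aif: TimeDensityCurve) -> float:
    """BF = 100 * 60 * max(dTissue/dt) / max(cp), slope from the smoothed curve."""
    _check_shared(tissue, aif)
    peak = float(aif.hu.max())
    if peak <= 0:
        raise FitError("AIF peak must be positive for max-slope estimation")
    slope = np.gradient(_smooth(tissue.hu), tissue.times)
    bf = 100.0 * 60.0 * float(slope.max()) / peak
    return max(bf, 0.0)


def fit_patlak(
    tissue: TimeDensityCurve, aif: TimeDensityCurve, t_start: float
) -> PatlakFit:
    """OLS of tissue/cp against (running AIF integral)/cp for t >= t_start.

    Intercept*100 is BV; the slope is the leakage constant (per minute).
    """
    _check_shared(tissue, aif)
    cum = _cumtrapz_minutes(aif)
    sel = (tissue.times >= t_start) & (aif.hu > 1e-12)
    if sel.sum() < 5:
        raise FitError(
            f"Patlak fit needs >=5 frames after t_start={t_start}s with cp>0, "
            f"got {int(sel.sum())}"
        )
    x = cum[sel] / aif.hu[sel]
    y = tissue.hu[sel] / aif.hu[sel]
    if np.ptp(x) <= 1e-12:
        raise FitError("Patlak design is singular (constant regressor)")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot <= 1e-30 else 1.0 - ss_res / ss_tot
    return PatlakFit(bv=float(intercept * 100.0), leakage=float(slope), r_squared=r2)


def estimate_ct_params(
    tissue: TimeDensityCurve,
    aif: TimeDensityCurve,
    t_start: float | None = None,
) -> tuple[CTPerfusionParams, PatlakFit]:
    """Max-slope BF plus Patlak BV/leakage; PMB recovered as leakage*100/BF.

    ``t_start`` defaults to the AIF peak time (leakage-dominated phase).
    All returned parameters are clamped to their non-negative ranges.
    """
    if t_start is None:
        t_start = float(aif.times[int(np.argmax(aif.hu))])
    bf = estimate_bf_maxslope(tissue, aif)
    patlak = fit_patlak(tissue, aif, t_start)
    bv = max(patlak.bv, 0.0)
    leak = max(patlak.leakage, 0.0)
    pmb = min(leak * 100.0 / bf, 1.0) if bf > 1e-12 else 0.0
    return CTPerfusionParams(bf=bf, bv=bv, pmb=pmb), patlak
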