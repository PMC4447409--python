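"""ROI-level summaries, before/after paired tests and cross-modality correlations.

Statistics operate on a tidy table of subject-level ROI values with columns
``subject, tissue_class, phase, parameter, value``.  The paired t and
Pearson statistics are computed from first principles (p-values via the t
distribution), so they can be audited against independent reference
implementations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import InsufficientSubjectsError, ParameterError
from .synthetic_cohort import IVIM_PARAMETERS, PERFUSION_PARAMETERS, TimePoint

__all__ = [
    "TTestResult",
    "roi_mean",
    "paired_t_test",
    "pearson_r",
    "significance_flag",
    "build_parameter_tables",
    "build_correlation_table",
    "CORRELATION_IVIM_PARAMETERS",
]

#: IVIM parameters entered into the cross-modality correlation grid.
CORRELATION_IVIM_PARAMETERS = ("D_star", "f")

FIT_COLUMNS = ("subject", "tissue_class", "phase", "parameter", "value")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def roi_mean(
    volume: np.ndarray, labels: np.ndarray, code: int
) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and count over one label code."""
    volume = np.asarray(volume, dtype=float)
    labels = np.asarray(labels)
    if volume.shape != labels.shape:
        raise ParameterError(
            f"volume shape {volume.shape} != labels shape {labels.shape}"
        )
    values = volume[labels == code]
    if values.size == 0:
        raise ParameterError(f"label code {code} absent from label volume")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd, int(values.size)


def paired_t_test(before, after) -> TTestResult:
    """Two-sided paired t-test on d = before - after with df = n - 1."""
    b = np.asarray(before, dtype=float).ravel()
    a = np.asarray(after, dtype=float).ravel()
    if b.shape != a.shape:
        raise ParameterError("before/after must have equal length")
    n = b.size
    if n < 2:
        raise InsufficientSubjectsError(f"paired t-test needs n >= 2, got {n}")
    d = b - a
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0)
        warnings.warn(
            "zero-variance nonzero differences: degenerate paired t-test",
            RuntimeWarning,
            stacklevel=2,
        )
        return TTestResult(t=math.copysign(math.inf, mean_d), df=df, p=0.0)
    t = mean_d / (sd_d / math.sqrt(n))
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.shape != yv.shape:
        raise ParameterError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise InsufficientSubjectsError(f"Pearson correlation needs n >= 3, got {n}")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ParameterError("zero variance in correlation input")
    r = float(xc @ yc / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * _sps.t.sf(abs(t), n - 2))
    return r, p


def significance_flag(p: float) -> str:
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"p-value out of range: {p}")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _check_fits(fits: pd.DataFrame) -> pd.DataFrame:
    missing = set(FIT_COLUMNS) - set(fits.columns)
    if missing:
        raise ParameterError(f"fit table lacks columns: {sorted(missing)}")
    return fits


def build_parameter_tables(
    fits: pd.DataFrame, parameters: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per class x parameter before/after comparison with significance flags.

    Every subject must carry both phases for each class x parameter cell;
    rows mirror the published summary-table layout.
    """
    fits = _check_fits(fits)
    rows = []
    for (cls, param), group in fits.groupby(
        ["tissue_class", "parameter"], sort=False
    ):
        if parameters is not None and param not in parameters:
            continue
        wide = group.pivot_table(
            index="subject", columns="phase", values="value", aggfunc="first"
        )
        for phase in (TimePoint.BEFORE.value, TimePoint.AFTER.value):
            if phase not in wide.columns or wide[phase].isna().any():
                raise ParameterError(
                    f"missing phase '{phase}' for class {cls}, parameter {param}"
                )
        before = wide[TimePoint.BEFORE.value].to_numpy()
        after = wide[TimePoint.AFTER.value].to_numpy()
        result = paired_t_test(before, after)
        rows.append(
            {
                "tissue_class": cls,
                "parameter": param,
                "mean_before": float(before.mean()),
                "sd_before": float(before.std(ddof=1)),
                "mean_after": float(after.mean()),
                "sd_after": float(after.std(ddof=1)),
                "t_statistic": result.t,
                "df": result.df,
                "p_value": result.p,
                "flag": significance_flag(result.p),
            }
        )
    return pd.DataFrame(rows)


def build_correlation_table(
    fits: pd.DataFrame,
    phase: TimePoint | str = TimePoint.BEFORE,
    perfusion_parameters: tuple[str, ...] = PERFUSION_PARAMETERS,
    ivim_parameters: tuple[str, ...] = CORRELATION_IVIM_PARAMETERS,
) -> pd.DataFrame:
    """Perfusion-vs-IVIM Pearson grid per tissue class, across subjects."""
    fits = _check_fits(fits)
    phase = TimePoint(phase)
    sub = fits[fits["phase"] == phase.value]
    rows = []
    for cls in sorted(sub["tissue_class"].unique()):
        cls_data = sub[sub["tissue_class"] == cls]
        wide = cls_data.pivot_table(
            index="subject", columns="parameter", values="value", aggfunc="first"
        )
        for perf in perfusion_parameters:
            for ivim in ivim_parameters:
                for name in (perf, ivim):
                    if name not in wide.columns:
                        raise ParameterError(
                            f"parameter {name} missing for class {cls}"
                        )
                pair = wide[[perf, ivim]].dropna()
                r, p = pearson_r(pair[perf].to_numpy(), pair[ivim].to_numpy())
                rows.append(
                    {
                        "tissue_class": cls,
                        "perfusion_parameter": perf,
                        "ivim_parameter": ivim,
                        "n": int(len(pair)),
                        "r": r,
                        "p_value": p,
                        "flag": significance_flag(p),
                    }
                )
    return pd.DataFrame(rows)


def ivim_parameter_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Comparison table restricted to the diffusion-model parameters."""
    return build_parameter_tables(fits, parameters=IVIM_PARAMETERS)


def perfusion_parameter_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Comparison table restricted to the DCE and CT perfusion parameters."""
    return build_parameter_tables(fits, parameters=PERFUSION_PARAMETERS)
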