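"""Synthetic phantom cohort generator.

Builds simulated animals with four tissue classes (ablated necrosis,
residual viable tumor, contralateral untreated tumor, normal muscle) imaged
at two time points (before/after ablation).  Each subject carries a label
volume, a multi-b diffusion stack with Rician magnitude noise, ROI-level
DCE concentration curves driven by a population arterial input function,
and CT time-density curves from the leakage forward model — all
parameterized by a per-class/per-phase ground-truth table of published
group means and SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

from . import ct_perfusion, dce_tofts
from .errors import GeometryError, ParameterError
from .ivim_model import IVIMParams, ivim_signal

__all__ = [
    "TissueClass",
    "TimePoint",
    "SamplingMode",
    "ParamStat",
    "GroundTruthTable",
    "AcquisitionProtocol",
    "EllipsoidSpec",
    "SubjectDataset",
    "PARAMETER_NAMES",
    "IVIM_PARAMETERS",
    "PERFUSION_PARAMETERS",
    "default_ground_truth",
    "default_protocol",
    "default_geometry",
    "make_label_volume",
    "rician",
    "sample_parameter",
    "simulate_subject",
    "simulate_cohort",
]


class TissueClass(IntEnum):
    """ROI classes and their integer mask codes."""

    T_RFA = 1  # ablation-zone coagulation necrosis
    T_RESIDUAL = 2  # residual viable tumor rim
    T_CONTROL = 3  # contralateral untreated tumor
    NORMAL = 4  # normal muscle


class TimePoint(str, Enum):
    BEFORE = "before"
    AFTER = "after"


class SamplingMode(str, Enum):
    FIXED_MEAN = "FIXED_MEAN"
    SAMPLED = "SAMPLED"


PARAMETER_NAMES = ("f", "D", "D_star", "Ktrans", "Ve", "Kep", "BF", "BV", "PMB")
IVIM_PARAMETERS = ("f", "D", "D_star")
DCE_PARAMETERS = ("Ktrans", "Ve", "Kep")
CT_PARAMETERS = ("BF", "BV", "PMB")
PERFUSION_PARAMETERS = CT_PARAMETERS + DCE_PARAMETERS

#: Validity ranges used to clip per-subject Gaussian draws.
FRACTION_RANGE = (0.001, 0.999)
POSITIVE_RANGE = (1e-6, np.inf)
_CLIP_RANGES = {
    "f": FRACTION_RANGE,
    "Ve": FRACTION_RANGE,
    "PMB": FRACTION_RANGE,
    "D": (1e-6, 3e-3),
    "D_star": (3e-3, 0.5),
    "Ktrans": POSITIVE_RANGE,
    "Kep": POSITIVE_RANGE,
    "BF": POSITIVE_RANGE,
    "BV": POSITIVE_RANGE,
}

TUMOR_CLASSES = (TissueClass.T_RFA, TissueClass.T_RESIDUAL, TissueClass.T_CONTROL)


@dataclass(frozen=True)
class ParamStat:
    """Published group mean and standard deviation of one parameter."""

    mean: float
    sd: float


@dataclass
class GroundTruthTable:
    """Per-(class, phase) parameter means/SDs driving the simulator."""

    entries: dict[tuple[TissueClass, TimePoint], dict[str, ParamStat]]

    def validate(self) -> None:
        expected = {(c, p) for c in TissueClass for p in TimePoint}
        if set(self.entries) != expected:
            raise ParameterError("ground truth must cover all 8 class x phase cells")
        for key, params in self.entries.items():
            if set(params) != set(PARAMETER_NAMES):
                raise ParameterError(f"missing parameters in entry {key}")
            for name, stat in params.items():
                if not np.isfinite(stat.mean) or not np.isfinite(stat.sd):
                    raise ParameterError(f"non-finite stat for {name} in {key}")
            for name in ("f", "Ve", "PMB"):
                if not (0.0 <= params[name].mean <= 1.0):
                    raise ParameterError(
                        f"{name} mean must lie in [0,1] in {key}, got {params[name].mean}"
                    )
            if params["Kep"].mean <= 0:
                raise ParameterError(f"Kep mean must be > 0 in {key}")
            if key[0] in TUMOR_CLASSES and params["D_star"].mean <= params["D"].mean:
                raise ParameterError(f"D_star mean must exceed D mean in {key}")

    def stat(self, cls: TissueClass, phase: TimePoint, name: str) -> ParamStat:
        return self.entries[(cls, phase)][name]

    def means(self, cls: TissueClass, phase: TimePoint) -> dict[str, float]:
        return {k: v.mean for k, v in self.entries[(cls, phase)].items()}


def _entry(f, D, Dstar, ktrans, ve, kep, bf, bv, pmb):
    return {
        "f": ParamStat(*f),
        "D": ParamStat(D[0] * 1e-3, D[1] * 1e-3),  # table rows are x1e-3 mm^2/s
        "D_star": ParamStat(*Dstar),
        "Ktrans": ParamStat(*ktrans),
        "Ve": ParamStat(*ve),
        "Kep": ParamStat(*kep),
        "BF": ParamStat(*bf),
        "BV": ParamStat(*bv),
        # published PMB values are percentages; stored as fractions
        "PMB": ParamStat(pmb[0] / 100.0, pmb[1] / 100.0),
    }


def default_ground_truth() -> GroundTruthTable:
    """Published group means/SDs for all four classes at both time points."""
    B, A = TimePoint.BEFORE, TimePoint.AFTER
    entries = {
        (TissueClass.T_RFA, B): _entry(
            (0.29, 0.05), (0.61, 0.15), (0.13, 0.03),
            (0.13, 0.05), (0.29, 0.08), (0.50, 0.14),
            (33.48, 18.12), (5.61, 1.10), (17.72, 7.97),
        ),
        (TissueClass.T_RFA, A): _entry(
            (0.15, 0.04), (0.92, 0.04), (0.06, 0.02),
            (0.02, 0.02), (0.06, 0.71), (0.12, 0.22),
            (0.87, 1.87), (0.93, 1.10), (0.68, 1.2),
        ),
        (TissueClass.T_RESIDUAL, B): _entry(
            (0.29, 0.04), (0.75, 0.15), (0.12, 0.09),
            (0.11, 0.05), (0.28, 0.06), (0.49, 0.12),
            (33.31, 9.92), (4.91, 1.17), (15.53, 3.22),
        ),
        (TissueClass.T_RESIDUAL, A): _entry(
            (0.42, 0.03), (0.79, 0.40), (0.11, 0.08),
            (0.14, 0.09), (0.49, 0.02), (0.51, 0.09),
            (35.91, 3.33), (8.03, 2.72), (16.23, 6.57),
        ),
        (TissueClass.T_CONTROL, B): _entry(
            (0.31, 0.03), (0.70, 0.01), (0.11, 0.07),
            (0.13, 0.12), (0.31, 0.14), (0.53, 0.20),
            (34.20, 16.34), (5.66, 1.88), (17.37, 7.30),
        ),
        (TissueClass.T_CONTROL, A): _entry(
            (0.30, 0.02), (0.71, 0.01), (0.10, 0.08),
            (0.11, 0.10), (0.30, 0.16), (0.49, 0.18),
            (33.10, 8.54), (5.88, 1.49), (16.18, 6.29),
        ),
        (TissueClass.NORMAL, B): _entry(
            (0.12, 0.04), (0.94, 0.03), (0.11, 0.06),
            (0.05, 0.01), (0.18, 0.02), (0.20, 0.05),
            (0.56, 0.15), (3.98, 0.67), (1.06, 0.75),
        ),
        (TissueClass.NORMAL, A): _entry(
            (0.12, 0.02), (0.90, 0.02), (0.11, 0.04),
            (0.04, 0.02), (0.17, 0.04), (0.24, 0.27),
            (0.03, 0.27), (3.41, 0.57), (0.91, 0.43),
        ),
    }
    table = GroundTruthTable(entries=entries)
    table.validate()
    return table


DEFAULT_B_VALUES = (
    0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0,
    400.0, 450.0, 500.0, 550.0, 600.0, 650.0, 700.0, 800.0,
)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition grids and noise levels for all three modalities."""

    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    dce_times: tuple[float, ...] = tuple(np.arange(75) * 3.0)  # seconds
    dce_baseline_frames: int = 5
    ct_times: tuple[float, ...] = tuple(np.arange(90) * 1.0)  # seconds
    ct_baseline_frames: int = 10
    snr_dwi: float = 50.0
    noise_sd_dce: float = 0.005  # mM
    noise_sd_ct: float = 2.0  # HU

    def validate(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 4 or b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ParameterError("b-values must start at 0 and strictly increase")
        for name, grid, baseline in (
            ("dce", self.dce_times, self.dce_baseline_frames),
            ("ct", self.ct_times, self.ct_baseline_frames),
        ):
            g = np.asarray(grid, dtype=float)
            if g.size < 2 or np.any(np.diff(g) <= 0):
                raise ParameterError(f"{name} time grid must strictly increase")
            if not (0 <= baseline < g.size):
                raise ParameterError(f"{name} baseline frame count out of range")
        if not self.snr_dwi > 0:
            raise ParameterError(f"snr_dwi must be > 0, got {self.snr_dwi}")
        if self.noise_sd_dce < 0 or self.noise_sd_ct < 0:
            raise ParameterError("noise SDs must be >= 0")


def default_protocol() -> AcquisitionProtocol:
    protocol = AcquisitionProtocol()
    protocol.validate()
    return protocol


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid carrying one tissue class."""

    tissue_class: TissueClass
    center: tuple[float, float, float]
    radii: tuple[float, float, float]


DEFAULT_SHAPE = (32, 32, 16)


def default_geometry() -> list[EllipsoidSpec]:
    """Four disjoint ellipsoids of ~200 voxels each in the default grid."""
    radii = (4.0, 4.0, 3.0)
    centers = [(8, 8, 8), (24, 8, 8), (8, 24, 8), (24, 24, 8)]
    return [
        EllipsoidSpec(cls, tuple(map(float, c)), radii)
        for cls, c in zip(TissueClass, centers)
    ]


def make_label_volume(
    shape: tuple[int, int, int], geometry: list[EllipsoidSpec]
) -> np.ndarray:
    """Rasterize class ellipsoids into an integer label volume.

    Raises :class:`GeometryError` if an ellipsoid leaves the grid or two
    ellipsoids claim the same voxel.
    """
    if len(shape) != 3 or any(int(s) <= 0 for s in shape):
        raise GeometryError(f"shape must be 3 positive integers, got {shape}")
    labels = np.zeros(shape, dtype=np.int16)
    grids = np.indices(shape, dtype=float)
    for spec in geometry:
        center = np.asarray(spec.center, dtype=float)
        radii = np.asarray(spec.radii, dtype=float)
        if np.any(radii <= 0):
            raise GeometryError(f"radii must be positive: {spec}")
        if np.any(center - radii < -0.5) or np.any(
            center + radii > np.asarray(shape) - 0.5
        ):
            raise GeometryError(f"ellipsoid leaves the volume: {spec}")
        dist = sum(
            ((grids[ax] - center[ax]) / radii[ax]) ** 2 for ax in range(3)
        )
        inside = dist <= 1.0
        if np.any(labels[inside] != 0):
            raise GeometryError(f"ellipsoid overlaps an earlier one: {spec}")
        labels[inside] = int(spec.tissue_class)
    return labels


def rician(signal, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + n1) + i*n2 with iid Gaussian(0, sigma) noise."""
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    s = np.asarray(signal, dtype=float)
    if np.any(s < 0):
        raise ParameterError("signal must be non-negative")
    if sigma == 0:
        return s.copy()
    n1 = rng.normal(0.0, sigma, size=s.shape)
    n2 = rng.normal(0.0, sigma, size=s.shape)
    return np.sqrt((s + n1) ** 2 + n2**2)


def sample_parameter(
    name: str, stat: ParamStat, rng: np.random.Generator
) -> float:
    """One Gaussian(mean, sd) draw clipped to the parameter's validity range."""
    lo, hi = _CLIP_RANGES[name]
    return float(np.clip(rng.normal(stat.mean, stat.sd), lo, hi))


@dataclass
class SubjectDataset:
    """One simulated animal across both imaging time points."""

    subject_id: str
    labels: np.ndarray
    b_values: np.ndarray
    dwi: dict[TimePoint, np.ndarray]  # (x, y, z, b) per phase
    dce_curves: dict[tuple[TissueClass, TimePoint], dce_tofts.ConcentrationCurve]
    ct_curves: dict[tuple[TissueClass, TimePoint], ct_perfusion.TimeDensityCurve]
    aif_mr: dce_tofts.InputFunction
    aif_ct: ct_perfusion.TimeDensityCurve
    truth: dict[tuple[TissueClass, TimePoint], dict[str, float]] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        for phase, vol in self.dwi.items():
            if vol.shape[-1] != self.b_values.size:
                raise ParameterError(
                    f"dwi {phase} has {vol.shape[-1]} volumes for "
                    f"{self.b_values.size} b-values"
                )
            if np.any(vol < 0):
                raise ParameterError("dwi magnitudes must be >= 0")
        present = set(np.unique(self.labels)) - {0}
        for code in present:
            cls = TissueClass(int(code))
            for phase in TimePoint:
                if (cls, phase) not in self.truth:
                    raise ParameterError(f"missing truth for {cls}, {phase}")


def _realize_params(
    truth: GroundTruthTable,
    mode: SamplingMode,
    rng: np.random.Generator | None,
) -> dict[tuple[TissueClass, TimePoint], dict[str, float]]:
    realized = {}
    for key, stats in truth.entries.items():
        if mode is SamplingMode.FIXED_MEAN:
            vals = {k: float(np.clip(v.mean, *_CLIP_RANGES[k])) for k, v in stats.items()}
        else:
            vals = {
                k: sample_parameter(k, stats[k], rng)
                for k in PARAMETER_NAMES
                if k != "Kep"
            }
        # the reflux constant is tied to Ktrans/Ve as an identity
        vals["Kep"] = vals["Ktrans"] / vals["Ve"]
        if vals["D_star"] <= vals["D"]:
            vals["D_star"] = vals["D"] * (1.0 + 1e-6) + 1e-12
        realized[key] = vals
    return realized


def simulate_subject(
    truth: GroundTruthTable | None = None,
    protocol: AcquisitionProtocol | None = None,
    sampling_mode: SamplingMode | str = SamplingMode.FIXED_MEAN,
    seed: int | None = None,
    subject_id: str = "sub-01",
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    geometry: list[EllipsoidSpec] | None = None,
    s0: float = 1000.0,
) -> SubjectDataset:
    """Simulate one animal at both time points.

    In ``FIXED_MEAN`` mode every class carries exactly the table means; in
    ``SAMPLED`` mode per-subject parameters are Gaussian draws (clipped to
    validity ranges), which requires a seed.  DWI noise is Rician with
    ``sigma = s0 / snr_dwi``; curve noise is additive Gaussian, clipped at
    zero.
    """
    truth = truth if truth is not None else default_ground_truth()
    truth.validate()
    protocol = protocol if protocol is not None else default_protocol()
    protocol.validate()
    try:
        mode = SamplingMode(sampling_mode)
    except ValueError:
        raise ParameterError(f"unknown sampling mode: {sampling_mode!r}") from None
    if mode is SamplingMode.SAMPLED and seed is None:
        raise ParameterError("SAMPLED mode requires a seed")
    rng = np.random.default_rng(seed)

    realized = _realize_params(truth, mode, rng)
    geometry = geometry if geometry is not None else default_geometry()
    labels = make_label_volume(shape, geometry)
    b = np.asarray(protocol.b_values, dtype=float)

    sigma = 0.0 if np.isinf(protocol.snr_dwi) else s0 / protocol.snr_dwi
    dce_times_min = np.asarray(protocol.dce_times, dtype=float) / 60.0
    onset_min = float(protocol.dce_times[protocol.dce_baseline_frames]) / 60.0
    aif_mr = dce_tofts.population_aif(dce_times_min, onset_min=onset_min)
    ct_times = np.asarray(protocol.ct_times, dtype=float)
    onset_ct = float(protocol.ct_times[protocol.ct_baseline_frames])
    aif_ct = ct_perfusion.ct_aif(ct_times, onset_s=onset_ct)

    dwi: dict[TimePoint, np.ndarray] = {}
    dce_curves = {}
    ct_curves = {}
    for phase in TimePoint:
        clean = np.zeros(labels.shape + (b.size,), dtype=float)
        for cls in TissueClass:
            sel = labels == int(cls)
            if not sel.any():
                continue
            vals = realized[(cls, phase)]
            params = IVIMParams(
                S0=s0, f=vals["f"], D=vals["D"], D_star=vals["D_star"]
            )
            clean[sel] = np.asarray(ivim_signal(b, params))
        dwi[phase] = rician(clean, sigma, rng)

        for cls in TissueClass:
            vals = realized[(cls, phase)]
            dce = dce_tofts.tofts_concentration(aif_mr, vals["Ktrans"], vals["Ve"])
            noisy_ct_conc = dce.ct + rng.normal(
                0.0, protocol.noise_sd_dce, size=dce.ct.shape
            )
            dce_curves[(cls, phase)] = dce_tofts.ConcentrationCurve(
                times=dce.times, ct=np.clip(noisy_ct_conc, 0.0, None)
            )
            ctp = ct_perfusion.ct_forward(
                aif_ct,
                ct_perfusion.CTPerfusionParams(
                    bf=vals["BF"], bv=vals["BV"], pmb=vals["PMB"]
                ),
            )
            noisy_hu = ctp.hu + rng.normal(
                0.0, protocol.noise_sd_ct, size=ctp.hu.shape
            )
            ct_curves[(cls, phase)] = ct_perfusion.TimeDensityCurve(
                times=ctp.times, hu=np.clip(noisy_hu, 0.0, None)
            )

    dataset = SubjectDataset(
        subject_id=subject_id,
        labels=labels,
        b_values=b,
        dwi=dwi,
        dce_curves=dce_curves,
        ct_curves=ct_curves,
        aif_mr=aif_mr,
        aif_ct=aif_ct,
        truth=realized,
    )
    dataset.validate()
    return dataset


def subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Deterministic per-subject seeds derived from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_subjects, np.uint64)
    return [int(v) for v in state]


def simulate_cohort(
    n_subjects: int = 10,
    master_seed: int = 0,
    truth: GroundTruthTable | None = None,
    protocol: AcquisitionProtocol | None = None,
    sampling_mode: SamplingMode | str = SamplingMode.SAMPLED,
    **subject_kwargs,
) -> list[SubjectDataset]:
    """Simulate ``n_subjects`` independent animals from one master seed."""
    if n_subjects < 1:
        raise ParameterError(f"n_subjects must be >= 1, got {n_subjects}")
    seeds = subject_seeds(master_seed, n_subjects)
    return [
        simulate_subject(
            truth=truth,
            protocol=protocol,
            sampling_mode=sampling_mode,
            seed=seeds[i],
            subject_id=f"sub-{i + 1:02d}",
            **subject_kwargs,
        )
        for i in range(n_subjects)
    ]
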