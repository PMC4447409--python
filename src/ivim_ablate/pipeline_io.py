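"""Orchestration and on-disk formats: simulate -> fit -> stats as one run.

Formats: NIfTI-1 for volumes (label masks, 4D diffusion stacks, parameter
maps), FSL-style plain-text b-value sidecars, tidy CSV for ROI curves and
fitted parameters, YAML run configuration and a JSON manifest with
per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__, ct_perfusion, dce_tofts, ivim_model, roi_statistics
from .errors import FormatError, InsufficientSubjectsError, ParameterError
from .synthetic_cohort import (
    AcquisitionProtocol,
    SamplingMode,
    SubjectDataset,
    TimePoint,
    TissueClass,
    default_protocol,
    simulate_cohort,
)

logger = logging.getLogger("ivim_ablate")

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_dwi",
    "write_dwi",
    "write_maps",
    "read_curves",
    "write_curves",
    "run_pipeline",
]

CURVE_COLUMNS = ("subject", "tissue_class", "phase", "time_s", "value")
ALL_STAGES = ("simulate", "fit", "stats")


# ---------------------------------------------------------------------------
# volume + sidecar I/O

def write_volume(volume: np.ndarray, path: Path | str, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def read_volume(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float32), img.affine


def write_bvals(b_values, path: Path | str) -> None:
    Path(path).write_text("\n".join(f"{b:g}" for b in b_values) + "\n")


def read_bvals(path: Path | str) -> np.ndarray:
    text = Path(path).read_text().split()
    try:
        return np.array([float(v) for v in text], dtype=float)
    except ValueError as exc:
        raise FormatError(f"malformed b-value file {path}: {exc}") from None


def write_dwi(dwi: np.ndarray, b_values, path: Path | str, bval_path: Path | str) -> None:
    write_volume(dwi, path)
    write_bvals(b_values, bval_path)


def read_dwi(path: Path | str, bval_path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    """4D stack plus b-values; the counts must agree."""
    vol, _ = read_volume(path)
    b = read_bvals(bval_path)
    if vol.ndim != 4:
        raise FormatError(f"{path} is not a 4D volume (ndim={vol.ndim})")
    if vol.shape[3] != b.size:
        raise FormatError(
            f"volume count {vol.shape[3]} in {path} does not match "
            f"{b.size} b-values in {bval_path}"
        )
    return vol, b


def write_maps(maps: ivim_model.ParameterMaps, out_dir: Path | str, affine=None) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, vol in (
        ("f", maps.f_map),
        ("D", maps.D_map),
        ("Dstar", maps.Dstar_map),
        ("S0", maps.S0_map),
    ):
        path = out_dir / f"{name}_map.nii.gz"
        write_volume(vol, path, affine)
        written.append(path)
    mask_path = out_dir / "mask.nii.gz"
    write_volume(maps.mask.astype(np.float32), mask_path, affine)
    written.append(mask_path)
    return written


# ---------------------------------------------------------------------------
# tidy-CSV curve I/O

_VALID_CLASSES = {cls.name for cls in TissueClass}
_VALID_PHASES = {p.value for p in TimePoint}


def write_curves(curves: pd.DataFrame, path: Path | str) -> None:
    missing = set(CURVE_COLUMNS) - set(curves.columns)
    if missing:
        raise FormatError(f"curve table lacks columns: {sorted(missing)}")
    curves.to_csv(path, index=False, float_format="%.10g")


def read_curves(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path} lacks columns: {sorted(missing)}")
    bad = set(df["tissue_class"].unique()) - _VALID_CLASSES
    if bad:
        raise FormatError(
            f"{path} contains unknown class labels {sorted(bad)}; "
            f"valid labels: {sorted(_VALID_CLASSES)}"
        )
    bad_phase = set(df["phase"].unique()) - _VALID_PHASES
    if bad_phase:
        raise FormatError(
            f"{path} contains unknown phases {sorted(bad_phase)}; "
            f"valid phases: {sorted(_VALID_PHASES)}"
        )
    return df.astype({"time_s": float, "value": float})


def curves_to_frame(subject: SubjectDataset, modality: str) -> pd.DataFrame:
    """Flatten one subject's per-ROI curves into the tidy schema."""
    rows = []
    source = subject.dce_curves if modality == "dce" else subject.ct_curves
    for (cls, phase), curve in source.items():
        times = curve.times * 60.0 if modality == "dce" else curve.times
        values = curve.ct if modality == "dce" else curve.hu
        for t, v in zip(times, values):
            rows.append(
                {
                    "subject": subject.subject_id,
                    "tissue_class": cls.name,
                    "phase": phase.value,
                    "time_s": float(t),
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows, columns=list(CURVE_COLUMNS))


def aif_to_frame(subject: SubjectDataset, modality: str) -> pd.DataFrame:
    if modality == "dce":
        times, values = subject.aif_mr.times * 60.0, subject.aif_mr.cp
    else:
        times, values = subject.aif_ct.times, subject.aif_ct.hu
    return pd.DataFrame(
        {
            "subject": subject.subject_id,
            "tissue_class": "AIF",
            "phase": "na",
            "time_s": times.astype(float),
            "value": values.astype(float),
        }
    )


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Single entry point for a reproducible pipeline run."""

    master_seed: int
    n_subjects: int = 10
    sampling_mode: str = "SAMPLED"
    output_dir: Path = Path("ivim_ablate_run")
    stages: tuple[str, ...] = ALL_STAGES
    protocol: AcquisitionProtocol = field(default_factory=default_protocol)
    s0: float = 1000.0
    b_threshold: float = ivim_model.DEFAULT_B_THRESHOLD
    write_voxel_maps: bool = False

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        SamplingMode(self.sampling_mode)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ParameterError(f"unknown stages: {sorted(unknown)}")
        self.protocol.validate()

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        protocol_raw = raw.pop("protocol", None)
        config = cls(**raw)
        if protocol_raw:
            config.protocol = AcquisitionProtocol(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in protocol_raw.items()
                }
            )
        config.output_dir = Path(config.output_dir)
        config.stages = tuple(config.stages)
        config.validate()
        return config

    def canonical(self) -> dict:
        d = {
            "master_seed": self.master_seed,
            "n_subjects": self.n_subjects,
            "sampling_mode": self.sampling_mode,
            "stages": list(self.stages),
            "s0": self.s0,
            "b_threshold": self.b_threshold,
            "write_voxel_maps": self.write_voxel_maps,
            "protocol": {
                "b_values": list(self.protocol.b_values),
                "dce_times": list(self.protocol.dce_times),
                "dce_baseline_frames": self.protocol.dce_baseline_frames,
                "ct_times": list(self.protocol.ct_times),
                "ct_baseline_frames": self.protocol.ct_baseline_frames,
                "snr_dwi": self.protocol.snr_dwi,
                "noise_sd_dce": self.protocol.noise_sd_dce,
                "noise_sd_ct": self.protocol.noise_sd_ct,
            },
        }
        return d


@dataclass
class RunManifest:
    config_hash: str
    version: str
    files: dict[str, str]
    timestamps: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "files": self.files,
                "timestamps": self.timestamps,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline stages

def write_subject(subject: SubjectDataset, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    labels_path = out_dir / "labels.nii.gz"
    write_volume(subject.labels.astype(np.float32), labels_path)
    written.append(labels_path)

    bval_path = out_dir / "dwi.bval"
    write_bvals(subject.b_values, bval_path)
    written.append(bval_path)
    for phase in TimePoint:
        dwi_path = out_dir / f"dwi_{phase.value}.nii.gz"
        write_volume(subject.dwi[phase], dwi_path)
        written.append(dwi_path)

    for modality in ("dce", "ct"):
        curve_path = out_dir / f"{modality}_curves.csv"
        write_curves(curves_to_frame(subject, modality), curve_path)
        written.append(curve_path)
        aif_path = out_dir / f"{modality}_aif.csv"
        aif_to_frame(subject, modality).to_csv(
            aif_path, index=False, float_format="%.10g"
        )
        written.append(aif_path)

    truth_path = out_dir / "truth.json"
    truth_payload = {
        f"{cls.name}/{phase.value}": values
        for (cls, phase), values in subject.truth.items()
    }
    truth_path.write_text(json.dumps(truth_payload, indent=2, sort_keys=True))
    written.append(truth_path)
    return written


def fit_subject(
    subject: SubjectDataset,
    b_threshold: float = ivim_model.DEFAULT_B_THRESHOLD,
) -> pd.DataFrame:
    """ROI-level fits of all three modalities for one subject."""
    rows = []

    def add(cls, phase, parameter, value):
        rows.append(
            {
                "subject": subject.subject_id,
                "tissue_class": cls.name,
                "phase": phase.value,
                "parameter": parameter,
                "value": float(value),
            }
        )

    for phase in TimePoint:
        for cls in TissueClass:
            params, _ = ivim_model.fit_ivim_roi(
                subject.dwi[phase], subject.labels, int(cls),
                subject.b_values, b_threshold,
            )
            add(cls, phase, "f", params.f)
            add(cls, phase, "D", params.D)
            add(cls, phase, "D_star", params.D_star)

            dce_params, _ = dce_tofts.fit_tofts(
                subject.dce_curves[(cls, phase)], subject.aif_mr
            )
            add(cls, phase, "Ktrans", dce_params.ktrans)
            add(cls, phase, "Ve", dce_params.ve)
            add(cls, phase, "Kep", dce_params.kep)

            ct_params, _ = ct_perfusion.estimate_ct_params(
                subject.ct_curves[(cls, phase)], subject.aif_ct
            )
            add(cls, phase, "BF", ct_params.bf)
            add(cls, phase, "BV", ct_params.bv)
            add(cls, phase, "PMB", ct_params.pmb)
    return pd.DataFrame(rows)


def run_stats(fits: pd.DataFrame, out_dir: Path) -> list[Path]:
    n_subjects = fits["subject"].nunique()
    if n_subjects < 2:
        raise InsufficientSubjectsError(
            f"statistics need >=2 subjects, got {n_subjects}"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    table2 = roi_statistics.perfusion_parameter_table(fits)
    table3 = roi_statistics.ivim_parameter_table(fits)
    table4 = roi_statistics.build_correlation_table(fits)
    for name, table in (("table2", table2), ("table3", table3), ("table4", table4)):
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    report = {
        "n_subjects": int(n_subjects),
        "significant_comparisons": [
            f"{row.tissue_class}/{row.parameter}"
            for row in pd.concat([table2, table3]).itertuples()
            if row.flag
        ],
        "max_abs_correlation": float(table4["r"].abs().max()),
    }
    report_path = out_dir / "stats_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    written.append(report_path)
    return written


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages; returns a manifest of written files."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timestamps: dict[str, float] = {}

    cohort = None
    fits_path = out_dir / "fits.csv"
    stage = "simulate"
    try:
        if "simulate" in config.stages or "fit" in config.stages:
            logger.info("stage simulate: %d subjects, seed %d",
                        config.n_subjects, config.master_seed)
            cohort = simulate_cohort(
                n_subjects=config.n_subjects,
                master_seed=config.master_seed,
                sampling_mode=config.sampling_mode,
                protocol=config.protocol,
                s0=config.s0,
            )
            timestamps["simulate"] = time.time()
            if "simulate" in config.stages:
                for subject in cohort:
                    written.extend(
                        write_subject(subject, out_dir / subject.subject_id)
                    )

        if "fit" in config.stages:
            stage = "fit"
            logger.info("stage fit: ROI-level fits for %d subjects", len(cohort))
            frames = []
            for subject in cohort:
                try:
                    frames.append(fit_subject(subject, config.b_threshold))
                except Exception as exc:
                    raise RuntimeError(
                        f"fit stage failed for subject {subject.subject_id}: {exc}"
                    ) from exc
                if config.write_voxel_maps:
                    for phase in TimePoint:
                        maps = ivim_model.fit_ivim_volume(
                            subject.dwi[phase], subject.b_values,
                            subject.labels > 0, config.b_threshold,
                        )
                        written.extend(
                            write_maps(
                                maps,
                                out_dir / subject.subject_id / f"maps_{phase.value}",
                            )
                        )
            fits = pd.concat(frames, ignore_index=True)
            fits.to_csv(fits_path, index=False, float_format="%.10g")
            written.append(fits_path)
            timestamps["fit"] = time.time()

        if "stats" in config.stages:
            stage = "stats"
            if not fits_path.exists():
                raise FormatError(f"stats stage needs {fits_path}")
            fits = pd.read_csv(fits_path)
            written.extend(run_stats(fits, out_dir))
            timestamps["stats"] = time.time()
    except InsufficientSubjectsError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    config_blob = json.dumps(config.canonical(), sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_blob).hexdigest(),
        version=__version__,
        files={
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(set(written))
        },
        timestamps=timestamps,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
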