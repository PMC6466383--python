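"""Readers, writers, configuration and the end-to-end pipeline.

File formats are plain text: raw recordings as ``time_s,x_mg,y_mg,z_mg`` CSV,
epoch features as ``epoch_index,epoch_start_s,filtered_mg,unfiltered_mg,ratio,class``
CSV, equation sets as JSON, and activity profiles as YAML. Floats are
serialized at 6 significant digits. Every pipeline run writes a manifest
(config snapshot, package version, input digests, timestamp) sufficient to
reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import SubjectCovariates, two_regression_predict
from .classify import ActivityClass, CutoffSpec, classify_epochs
from .equations import load_equation_set
from .signal import EpochFeatures, FilterSpec, RawTriaxialRecording, compute_epoch_features
from .simulate import ActivityProfile

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_raw_csv",
    "write_raw_csv",
    "read_epochs_csv",
    "write_epochs_csv",
    "load_activity_profiles",
    "run_pipeline",
]

_FLOAT_FMT = "%.6g"

RAW_COLUMNS = ["time_s", "x_mg", "y_mg", "z_mg"]
EPOCH_COLUMNS = ["epoch_index", "epoch_start_s", "filtered_mg", "unfiltered_mg", "ratio", "class"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated knobs of the process -> classify -> predict pipeline."""

    sampling_rate_hz: Optional[float] = None  # None: infer from time_s
    epoch_length_s: float = 60.0
    cutoff_hz: float = 0.7
    filter_order: int = 2
    zero_phase: bool = True
    ratio_cutoff: float = 1.16
    ratio_floor_mg: float = 3.0
    equation_set: Optional[str] = None  # path; None -> bundled young-children set
    sex: Optional[int] = None
    age: Optional[float] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sampling_rate_hz is not None and self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        if self.ratio_floor_mg < 0:
            raise ValueError("ratio_floor_mg must be non-negative")
        # cutoff_hz / filter_order / ratio_cutoff are validated by FilterSpec
        # and CutoffSpec at use time
        self.filter_spec()
        self.cutoff_spec()

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.cutoff_hz, self.filter_order, self.zero_phase)

    def cutoff_spec(self) -> CutoffSpec:
        return CutoffSpec(self.ratio_cutoff)

    def covariates(self) -> Optional[SubjectCovariates]:
        if self.sex is None and self.age is None:
            return None
        return SubjectCovariates(sex=self.sex, age=self.age)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    """Reproducibility record emitted with every pipeline run."""

    config: dict
    package_version: str
    inputs: dict[str, str]  # path -> sha256
    outputs: list[str]
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_raw_csv(path, rate: Optional[float] = None) -> RawTriaxialRecording:
    """Read a ``time_s,x_mg,y_mg,z_mg`` recording CSV.

    The sampling rate is inferred from the median time step unless ``rate``
    overrides it. Malformed cells and non-monotonic time are reported with
    their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must name {RAW_COLUMNS}")
    df = df[RAW_COLUMNS]
    bad = df.index[df.isna().any(axis=1) | ~df.map(np.isreal).all(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric or missing value at data line {bad[0] + 2}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0))
            raise ValueError(f"{path}: non-monotonic time_s at data line {row + 3}")
        inferred = 1.0 / float(np.median(dt))
    else:
        inferred = None
    fs = rate if rate is not None else inferred
    if fs is None:
        raise ValueError(f"{path}: cannot infer sampling rate from a single sample; pass rate")
    return RawTriaxialRecording(
        df["x_mg"].to_numpy(float),
        df["y_mg"].to_numpy(float),
        df["z_mg"].to_numpy(float),
        sampling_rate_hz=float(fs),
        start_time=float(t[0]) if len(t) else None,
    )


def write_raw_csv(recording: RawTriaxialRecording, path) -> None:
    t0 = recording.start_time or 0.0
    t = t0 + np.arange(recording.n_samples) / recording.sampling_rate_hz
    df = pd.DataFrame(
        {
            "time_s": t,
            "x_mg": recording.samples_x,
            "y_mg": recording.samples_y,
            "z_mg": recording.samples_z,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_epochs_csv(
    epochs: Sequence[EpochFeatures],
    path,
    classes: Optional[Sequence[ActivityClass]] = None,
) -> None:
    rows = []
    for i, e in enumerate(epochs):
        rows.append(
            {
                "epoch_index": e.epoch_index,
                "epoch_start_s": e.epoch_index * e.epoch_length_s,
                "filtered_mg": e.filtered_synthetic_mg,
                "unfiltered_mg": e.unfiltered_synthetic_mg,
                "ratio": e.ratio if e.ratio is not None else "",
                "class": str(classes[i]) if classes is not None else "",
                "activity_label": e.activity_label or "",
                "measured_met": e.measured_met if e.measured_met is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_epochs_csv(path) -> tuple[list[EpochFeatures], list[Optional[ActivityClass]]]:
    df = pd.read_csv(path)
    missing = [c for c in EPOCH_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    epochs: list[EpochFeatures] = []
    classes: list[Optional[ActivityClass]] = []
    # epoch length back out of start spacing; single-epoch files default to 60 s
    starts = df["epoch_start_s"].to_numpy(float)
    idx = df["epoch_index"].to_numpy()
    if len(df) > 1 and idx[1] != idx[0]:
        epoch_len = float((starts[1] - starts[0]) / (idx[1] - idx[0]))
    else:
        epoch_len = 60.0
    for _, row in df.iterrows():
        ratio = row["ratio"]
        ratio = None if (isinstance(ratio, float) and math.isnan(ratio)) or ratio == "" else float(ratio)
        label = row.get("activity_label")
        if isinstance(label, float) and math.isnan(label):
            label = None
        met = row.get("measured_met")
        met = None if met is None or (isinstance(met, float) and math.isnan(met)) else float(met)
        epochs.append(
            EpochFeatures(
                epoch_index=int(row["epoch_index"]),
                epoch_length_s=epoch_len,
                filtered_synthetic_mg=float(row["filtered_mg"]),
                unfiltered_synthetic_mg=float(row["unfiltered_mg"]),
                ratio=ratio,
                activity_label=label if label else None,
                measured_met=met,
            )
        )
        cls = row.get("class")
        classes.append(ActivityClass(cls) if isinstance(cls, str) and cls else None)
    return epochs, classes


def load_activity_profiles(path=None) -> list[ActivityProfile]:
    """Load activity profiles from YAML (default: the bundled ten-activity table)."""
    if path is None:
        raw = resources.files("metcalib").joinpath("data/table2_profiles.yaml").read_text()
    else:
        raw = Path(path).read_text(encoding="utf-8")
    d = yaml.safe_load(raw)
    return [
        ActivityProfile(
            label=p["label"],
            met_mean=p["met_mean"],
            met_sd=p["met_sd"],
            filtered_mean=p["filtered_mean"],
            filtered_sd=p["filtered_sd"],
            ratio_mean=p["ratio_mean"],
            ratio_sd=p["ratio_sd"],
            n_subjects=p["n_subjects"],
            class_truth=ActivityClass(p["class_truth"]),
        )
        for p in d["profiles"]
    ]


def run_pipeline(config: PipelineConfig, raw_path, out_dir) -> RunManifest:
    """process -> classify -> predict on one raw CSV; write epochs, METs, summary.

    Outputs ``epochs.csv``, ``mets.csv``, ``summary.json`` and
    ``manifest.json`` under ``out_dir``. On any stage failure the partial
    outputs are removed and the error re-raised with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read"
    try:
        recording = read_raw_csv(raw_path, rate=config.sampling_rate_hz)
        stage = "process"
        epochs = compute_epoch_features(
            recording, config.filter_spec(), config.epoch_length_s, config.ratio_floor_mg
        )
        stage = "classify"
        classes = classify_epochs(epochs, config.cutoff_spec())
        stage = "predict"
        nonamb_eq, amb_eq, _pop = load_equation_set(config.equation_set)
        pred = two_regression_predict(
            epochs, nonamb_eq, amb_eq, config.cutoff_spec(), config.covariates()
        )
        stage = "write"
        epochs_path = out / "epochs.csv"
        write_epochs_csv(epochs, epochs_path, classes)
        written.append(epochs_path)
        mets_path = out / "mets.csv"
        pd.DataFrame(
            {
                "epoch_index": [e.epoch_index for e in epochs],
                "class": [str(c) for c in classes],
                "met": pred.mets,
                "negative_flag": pred.negative.astype(int),
            }
        ).to_csv(mets_path, index=False, float_format=_FLOAT_FMT)
        written.append(mets_path)

        summary = {
            "n_epochs": len(epochs),
            "epoch_length_s": config.epoch_length_s,
            "mean_met": float(np.mean(pred.mets)),
            "class_time_s": {
                c.value: config.epoch_length_s * sum(1 for k in classes if k is c)
                for c in ActivityClass
            },
            "class_fraction": {
                c.value: sum(1 for k in classes if k is c) / len(classes)
                for c in ActivityClass
            },
        }
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2) + "\n")
        written.append(summary_path)
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        package_version=__version__,
        inputs={str(raw_path): _sha256(raw_path)},
        outputs=[p.name for p in written],
    )
    manifest.write(out / "manifest.json")
    return manifest
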