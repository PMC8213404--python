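"""Reading and writing airflow / integrated-signal time series.

Storage is plain delimited text: a two-column CSV ``time_s,flow_ml_s``
(or ``time_s,signal_au`` for integrated nerve signals) plus a JSON
sidecar ``<name>.meta.json`` holding the condition metadata (and, for
integrated signals, the epoch table).  Airflow follows the
inspiration-negative convention: inspiratory flow is < 0 mL/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError

GENOTYPES = ("+/+", "+/-", "-/-")
DRUGS = ("saline", "morphine")
GASES = ("normoxic", "hypercapnic")

#: relative tolerance on time-stamp uniformity (fraction of the period)
_UNIFORMITY_RTOL = 1e-6

BREATH_TABLE_COLUMNS = (
    "animal_id",
    "drug",
    "gas",
    "onset_s",
    "duration_s",
    "inst_freq_hz",
    "pif_ml_s",
    "insp_volume_ml",
)


@dataclass(frozen=True)
class RecordingMetadata:
    """Condition labels attached to one plethysmography recording."""

    animal_id: str
    genotype: str
    drug: str
    gas: str
    session_day: int = 1

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise MetadataError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        if self.drug not in DRUGS:
            raise MetadataError(f"unknown drug {self.drug!r}; expected one of {DRUGS}")
        if self.gas not in GASES:
            raise MetadataError(f"unknown gas {self.gas!r}; expected one of {GASES}")


@dataclass
class AirflowRecording:
    """Uniformly sampled airflow trace (mL/s, inspiration negative)."""

    samples: np.ndarray
    sample_rate: float
    metadata: RecordingMetadata | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite (no NaN/Inf)")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    def validate_for_analysis(self) -> None:
        """Recordings shorter than 2 s carry too few breaths to analyze."""
        if self.samples.size < 2 * self.sample_rate:
            raise ValueError("recording shorter than 2 s; too short for breath analysis")


@dataclass
class IntegratedSignal:
    """Integrated (rectified, smoothed) nerve-root signal in arbitrary units.

    ``epochs`` is an ordered list of ``(label, start_s, end_s)``, e.g. one
    entry per DAMGO dose.
    """

    samples: np.ndarray
    sample_rate: float
    epochs: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite (no NaN/Inf)")
        self.epochs = [(str(l), float(a), float(b)) for l, a, b in self.epochs]
        dur = self.samples.size / self.sample_rate
        tol = 0.5 / self.sample_rate  # absorb sample-rate round-off on re-read
        prev_end = 0.0
        for label, a, b in self.epochs:
            if a >= b:
                raise ValueError(f"epoch {label!r} has non-positive length")
            if a < prev_end - tol:
                raise ValueError(f"epoch {label!r} overlaps the previous epoch")
            if b > dur + tol:
                raise ValueError(f"epoch {label!r} extends past the signal end")
            prev_end = b

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.stem + ".meta.json")


def _check_uniform(times: np.ndarray) -> float:
    """Return the sample rate, raising FormatError on non-uniform stamps."""
    if times.size < 2:
        raise FormatError("need at least two samples to establish a sample rate")
    diffs = np.diff(times)
    period = float(np.median(diffs))
    if period <= 0:
        raise FormatError("time stamps must be strictly increasing")
    if np.any(np.abs(diffs - period) > _UNIFORMITY_RTOL * period):
        raise FormatError("non-uniform time stamps (gap or jitter in the time column)")
    return 1.0 / period


def read_trace(path: str | Path, metadata_path: str | Path | None = None,
               sample_rate: float | None = None,
               require_metadata: bool = False) -> AirflowRecording:
    """Read an airflow CSV (``time_s,flow_ml_s`` or single ``flow_ml_s``
    column with a declared *sample_rate*), merging the JSON sidecar if found."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if "flow_ml_s" not in cols:
        raise FormatError(f"{path}: missing 'flow_ml_s' column (found {cols})")
    flow = df["flow_ml_s"].to_numpy(dtype=float)
    if "time_s" in cols:
        rate = _check_uniform(df["time_s"].to_numpy(dtype=float))
    elif sample_rate is not None:
        rate = float(sample_rate)
    else:
        raise FormatError(f"{path}: no 'time_s' column and no declared sample_rate")

    meta = None
    mpath = Path(metadata_path) if metadata_path is not None else _sidecar_path(path)
    if mpath.exists():
        raw = json.loads(mpath.read_text())
        if raw.get("flow_sign", "inspiration_negative") != "inspiration_negative" \
                and not raw.get("flip_sign", False):
            raise MetadataError(
                "metadata declares a non inspiration-negative sign convention; "
                "set flip_sign to accept after inverting")
        if raw.get("flip_sign", False):
            flow = -flow
        try:
            meta = RecordingMetadata(
                animal_id=raw["animal_id"], genotype=raw["genotype"],
                drug=raw["drug"], gas=raw["gas"],
                session_day=int(raw.get("session_day", 1)))
        except KeyError as exc:
            raise MetadataError(f"{mpath}: missing metadata field {exc}") from exc
    elif require_metadata:
        raise MetadataError(f"no metadata sidecar found for {path}")
    return AirflowRecording(flow, rate, meta)


def write_trace(recording: AirflowRecording, path: str | Path) -> Path:
    """Write an airflow recording as full-precision CSV + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": recording.times, "flow_ml_s": recording.samples})
    df.to_csv(path, index=False, float_format="%.17g")
    if recording.metadata is not None:
        side = dict(asdict(recording.metadata))
        side["flow_sign"] = "inspiration_negative"
        _sidecar_path(path).write_text(json.dumps(side, indent=1))
    return path


def read_integrated_signal(path: str | Path,
                           metadata_path: str | Path | None = None) -> IntegratedSignal:
    """Read an integrated-signal CSV (``time_s,signal_au``) with its epoch sidecar."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "signal_au" not in df.columns:
        raise FormatError(f"{path}: missing 'signal_au' column")
    rate = _check_uniform(df["time_s"].to_numpy(dtype=float))
    epochs: list[tuple[str, float, float]] = []
    mpath = Path(metadata_path) if metadata_path is not None else _sidecar_path(path)
    if mpath.exists():
        raw = json.loads(mpath.read_text())
        epochs = [(e["label"], float(e["start_s"]), float(e["end_s"]))
                  for e in raw.get("epochs", [])]
    return IntegratedSignal(df["signal_au"].to_numpy(dtype=float), rate, epochs)


def write_integrated_signal(signal: IntegratedSignal, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": signal.times, "signal_au": signal.samples}) \
        .to_csv(path, index=False, float_format="%.17g")
    _sidecar_path(path).write_text(json.dumps(
        {"epochs": [{"label": l, "start_s": a, "end_s": b} for l, a, b in signal.epochs]},
        indent=1))
    return path


def write_breath_table(breaths: pd.DataFrame | Sequence, path: str | Path,
                       metadata: RecordingMetadata | None = None) -> Path:
    """Write one row per breath as TSV.

    Accepts either a DataFrame with the canonical columns or a sequence of
    :class:`~oirdkit.segmentation.Breath` objects plus *metadata* for the
    identifying columns.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(breaths, pd.DataFrame):
        df = breaths
    else:
        rows = []
        for b in breaths:
            rows.append({
                "animal_id": metadata.animal_id if metadata else "",
                "drug": metadata.drug if metadata else "",
                "gas": metadata.gas if metadata else "",
                "onset_s": b.insp_onset_s,
                "duration_s": b.duration_s,
                "inst_freq_hz": b.inst_freq_hz,
                "pif_ml_s": b.pif_ml_s,
                "insp_volume_ml": b.insp_volume_ml,
            })
        df = pd.DataFrame(rows, columns=BREATH_TABLE_COLUMNS)
    unknown = set(df.columns) - set(BREATH_TABLE_COLUMNS)
    if unknown:
        raise FormatError(f"unknown breath-table columns: {sorted(unknown)}")
    df = df.reindex(columns=BREATH_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_breath_table(path: str | Path) -> pd.DataFrame:
    """Read a breath TSV; column order is free but names are fixed."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    unknown = set(df.columns) - set(BREATH_TABLE_COLUMNS)
    if unknown:
        raise FormatError(f"unknown breath-table columns: {sorted(unknown)}")
    missing = set(BREATH_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing breath-table columns: {sorted(missing)}")
    return df.reindex(columns=BREATH_TABLE_COLUMNS)
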