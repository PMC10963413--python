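"""Core containers shared across the pipeline.

A :class:`Recording` is one modality's multichannel time series; a
:class:`BlockDesign` row localises one task block (subject, task, session,
easy/hard condition) on the recording clock.  Detected point events
(R-peaks, pulses, saccades, fixations) are small dataclasses collected in
plain lists.  The long-format feature table that links the signal layer to
the statistics layer is an ordinary :class:`pandas.DataFrame` with the
column set in :data:`FEATURE_COLUMNS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MODALITIES = (
    "fnirs_730",
    "fnirs_850",
    "eeg",
    "ecg",
    "ppg",
    "eog_h",
    "eog_v",
    "gaze_x",
    "gaze_y",
    "pupil",
)

TASKS = (
    "WorkingMemory",
    "Vigilance",
    "RiskAssessment",
    "ShiftingAttention",
    "SituationAwareness",
    "InhibitoryControl",
)

CONDITIONS = ("easy", "hard")

#: long-format feature table columns (one row per block x measure)
FEATURE_COLUMNS = (
    "subject_id",
    "task_name",
    "task_session",
    "condition",
    "block_index",
    "modality",
    "measure_name",
    "value",
)


@dataclass
class Recording:
    """One modality's multichannel time series.

    ``samples`` is a (channels, time) float array.  Units by modality:
    fNIRS raw intensity a.u.; EEG/EOG microvolt; ECG millivolt; PPG a.u.;
    gaze degrees; pupil millimetre.  NaN marks explicit dropouts (blinks).
    """

    modality: str
    sample_rate_hz: float
    channel_labels: list[str]
    samples: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz

    def copy(self, samples: np.ndarray | None = None) -> "Recording":
        return Recording(
            modality=self.modality,
            sample_rate_hz=self.sample_rate_hz,
            channel_labels=list(self.channel_labels),
            samples=self.samples.copy() if samples is None else samples,
            t0_s=self.t0_s,
        )

    def index_of(self, t_s: float) -> int:
        """Sample index of recording-clock time ``t_s`` (clipped)."""
        i = int(round((t_s - self.t0_s) * self.sample_rate_hz))
        return int(np.clip(i, 0, self.n_samples))

    def slice(self, t_start_s: float, t_end_s: float) -> np.ndarray:
        """Samples within [t_start_s, t_end_s) as a view (channels x time)."""
        return self.samples[:, self.index_of(t_start_s): self.index_of(t_end_s)]

    # -- CSV + JSON sidecar interchange ---------------------------------
    def save(self, path: str | Path) -> None:
        """Write ``<path>.csv`` (time_s + one column per channel) and
        ``<path>.json`` ({modality, sample_rate_hz, channel_labels, t0_s})."""
        path = Path(path)
        df = pd.DataFrame(self.samples.T, columns=self.channel_labels)
        df.insert(0, "time_s", self.times)
        df.to_csv(path.with_suffix(".csv"), index=False, float_format="%.8g")
        meta = {
            "modality": self.modality,
            "sample_rate_hz": self.sample_rate_hz,
            "channel_labels": list(self.channel_labels),
            "t0_s": self.t0_s,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        try:
            df = pd.read_csv(path.with_suffix(".csv"))
        except pd.errors.ParserError as exc:  # surface file context
            raise ValueError(f"corrupted recording CSV {path}: {exc}") from exc
        return cls(
            modality=meta["modality"],
            sample_rate_hz=float(meta["sample_rate_hz"]),
            channel_labels=list(meta["channel_labels"]),
            samples=df[meta["channel_labels"]].to_numpy().T,
            t0_s=float(meta.get("t0_s", 0.0)),
        )


@dataclass
class BlockDesign:
    """One task block: who/what/when plus its interval on the recording clock."""

    subject_id: str
    task_name: str
    task_session: int  # 1-3: nth time this subject sees this task
    condition: str  # easy | hard
    block_index: int
    t_start_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.t_end_s <= self.t_start_s:
            raise ValueError("t_end_s must exceed t_start_s")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.t_start_s, self.t_end_s)

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


def check_nonoverlapping(design: Sequence[BlockDesign]) -> None:
    """Raise ValueError if any two block intervals overlap."""
    ordered = sorted(design, key=lambda b: b.t_start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.t_start_s < a.t_end_s:
            raise ValueError(
                f"overlapping blocks: [{a.t_start_s}, {a.t_end_s}) and "
                f"[{b.t_start_s}, {b.t_end_s})"
            )


def design_to_frame(design: Sequence[BlockDesign]) -> pd.DataFrame:
    return pd.DataFrame([asdict(b) for b in design])


def design_from_frame(df: pd.DataFrame) -> list[BlockDesign]:
    return [
        BlockDesign(
            subject_id=str(r.subject_id),
            task_name=str(r.task_name),
            task_session=int(r.task_session),
            condition=str(r.condition),
            block_index=int(r.block_index),
            t_start_s=float(r.t_start_s),
            t_end_s=float(r.t_end_s),
        )
        for r in df.itertuples()
    ]


@dataclass
class SaccadeEvent:
    onset_s: float
    duration_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    source: str = "eog"  # eog | gaze


@dataclass
class FixationEvent:
    onset_s: float
    duration_ms: float
    centroid_x_deg: float
    centroid_y_deg: float
    dispersion_deg: float


@dataclass
class BeatSeries:
    """Detected heartbeat (R-peak or pulse-peak) times and RR intervals."""

    event_times_s: np.ndarray
    source: str  # ecg | ppg
    corrected_flags: np.ndarray = field(default=None)  # per RR interval

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        if self.event_times_s.size and np.any(np.diff(self.event_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.corrected_flags is None:
            self.corrected_flags = np.zeros(
                max(self.event_times_s.size - 1, 0), dtype=bool
            )

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.event_times_s) * 1000.0

    @property
    def n_beats(self) -> int:
        return int(self.event_times_s.size)

    def within(self, t_start_s: float, t_end_s: float) -> "BeatSeries":
        m = (self.event_times_s >= t_start_s) & (self.event_times_s < t_end_s)
        idx = np.flatnonzero(m)
        flags = (
            self.corrected_flags[idx[0]: idx[-1]]
            if idx.size > 1
            else np.zeros(0, dtype=bool)
        )
        return BeatSeries(self.event_times_s[m], source=self.source,
                          corrected_flags=flags)


def empty_feature_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        FEATURE_COLUMNS,
        [str, str, int, str, int, str, str, float],
    )})


def feature_rows(
    block: BlockDesign, modality: str, values: dict[str, float]
) -> list[dict]:
    """Expand a {measure_name: value} dict into long-format table rows."""
    return [
        {
            "subject_id": block.subject_id,
            "task_name": block.task_name,
            "task_session": block.task_session,
            "condition": block.condition,
            "block_index": block.block_index,
            "modality": modality,
            "measure_name": name,
            "value": value,
        }
        for name, value in values.items()
    ]
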