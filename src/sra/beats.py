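"""Beat-level containers shared by the detector, feature and pipeline layers.

A Holter recording, once QRS detection and morphology typing have run, is
reduced to a :class:`BeatSeries`: a time-ordered list of beats, each carrying
a label (``N`` normal, ``V`` ventricular, ``A`` atrial-premature, ``X``
artifact) and the morphology metrics the beat classifier uses.  All times are
milliseconds from the start of the record; amplitudes are millivolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Valid beat labels: normal, ventricular, atrial-premature, artifact.
BEAT_LABELS = ("N", "V", "A", "X")

#: Minimum spacing between two accepted beats (physiological refractoriness).
REFRACTORY_MS = 200.0


@dataclass
class Beat:
    """One detected heartbeat.

    ``shape_corr`` is the Pearson correlation of the beat's waveform against
    the running normal-beat template (dimensionless, in [-1, 1]); it is NaN
    when no waveform was available (beat tables imported from CSV).
    """

    time_ms: float
    label: str = "N"
    width_ms: float = float("nan")
    amplitude_mv: float = float("nan")
    shape_corr: float = float("nan")

    def __post_init__(self) -> None:
        if self.time_ms < 0:
            raise ValueError("beat time must be non-negative")
        if self.label not in BEAT_LABELS:
            raise ValueError(f"unknown beat label {self.label!r}")


@dataclass
class BeatSeries:
    """Time-ordered beats of one record plus a global signal-quality figure.

    ``quality_fraction`` is the fraction of the record judged clean signal
    (1.0 when unknown inputs are assumed clean).
    """

    record_id: str = ""
    beats: list[Beat] = field(default_factory=list)
    quality_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.quality_fraction <= 1.0:
            raise ValueError("quality_fraction must lie in [0, 1]")
        times = self.times_ms
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def times_ms(self) -> np.ndarray:
        return np.asarray([b.time_ms for b in self.beats], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([b.label for b in self.beats], dtype=object)

    @property
    def duration_ms(self) -> float:
        t = self.times_ms
        return float(t[-1] - t[0]) if len(t) >= 2 else 0.0

    def slice(self, start_ms: float, end_ms: float) -> "BeatSeries":
        """Beats with start_ms <= t < end_ms (labels and metrics kept)."""
        kept = [b for b in self.beats if start_ms <= b.time_ms < end_ms]
        return BeatSeries(self.record_id, kept, self.quality_fraction)

    # -- CSV interchange (columns fixed by the tool's file contract) --------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": [b.time_ms for b in self.beats],
                "label": [b.label for b in self.beats],
                "width_ms": [b.width_ms for b in self.beats],
                "amplitude_mv": [b.amplitude_mv for b in self.beats],
                "shape_corr": [b.shape_corr for b in self.beats],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, record_id: str = "", quality_fraction: float | None = None
    ) -> "BeatSeries":
        beats = [
            Beat(
                time_ms=float(row.time_ms),
                label=str(row.label),
                width_ms=float(getattr(row, "width_ms", float("nan"))),
                amplitude_mv=float(getattr(row, "amplitude_mv", float("nan"))),
                shape_corr=float(getattr(row, "shape_corr", float("nan"))),
            )
            for row in df.itertuples(index=False)
        ]
        if quality_fraction is None:
            n = len(beats)
            n_x = sum(b.label == "X" for b in beats)
            quality_fraction = 1.0 - n_x / n if n else 0.0
        return cls(record_id, beats, quality_fraction)

    @classmethod
    def from_csv(cls, path, record_id: str = "") -> "BeatSeries":
        return cls.from_frame(pd.read_csv(path), record_id=record_id)


def beat_series_from_intervals(
    intervals_ms: np.ndarray,
    labels=None,
    record_id: str = "",
    t0_ms: float = 0.0,
    quality_fraction: float = 1.0,
    width_ms: float = 90.0,
    amplitude_mv: float = 1.0,
    shape_corr: float = 1.0,
) -> BeatSeries:
    """Build a BeatSeries from inter-beat intervals.

    ``labels`` has one entry per beat (= len(intervals) + 1); defaults to all
    normal.  Width/amplitude/shape defaults describe a clean narrow QRS and can
    be overridden per-beat downstream.
    """
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    times = t0_ms + np.concatenate([[0.0], np.cumsum(intervals_ms)])
    if labels is None:
        labels = ["N"] * len(times)
    if len(labels) != len(times):
        raise ValueError("need one label per beat (len(intervals)+1)")
    beats = [
        Beat(t, lab, width_ms=width_ms, amplitude_mv=amplitude_mv, shape_corr=shape_corr)
        for t, lab in zip(times, labels)
    ]
    return BeatSeries(record_id, beats, quality_fraction)
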