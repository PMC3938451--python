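"""QRS detection, lead selection and morphology-based beat typing.

The detector follows the Pan–Tompkins recipe: band-pass 5–25 Hz, squared
derivative, 150 ms moving-window integration, adaptive per-block threshold,
200 ms refractory period.  Detection runs on the two best leads (ranked by
agreement between two independent single-lead detectors) and the two beat
streams are fused: a beat is kept if either lead saw it, duplicates within a
100 ms merge window collapse to the earlier detection.

Beat typing is template-based: a running normal-QRS template is formed from
the record itself; beats that are wider than the widened-QRS threshold
(default 120 ms) or correlate poorly with the template (shape_corr < 0.8) are
labeled ventricular.  Saturated or flat stretches are flagged artifact and
excluded, and their share of the record is reported as 1 − quality_fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .beats import Beat, BeatSeries, REFRACTORY_MS

__all__ = [
    "EcgRecord",
    "DetectorConfig",
    "select_best_leads",
    "detect_qrs",
    "classify_beats",
]


@dataclass
class EcgRecord:
    """Multi-lead ECG: equal-length sample sequences (mV) at one rate (Hz)."""

    leads: list[np.ndarray]
    sampling_rate: float
    start_time_s: float = 0.0  # clock seconds since midnight
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.leads:
            raise ValueError("no signal")
        self.leads = [np.asarray(ch, dtype=float) for ch in self.leads]
        n = len(self.leads[0])
        if any(len(ch) != n for ch in self.leads):
            raise ValueError("all leads must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.leads[0])

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sampling_rate

    @classmethod
    def from_csv(cls, path, sampling_rate: float, **kw) -> "EcgRecord":
        """Read `lead1..leadN` columns from plain CSV."""
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c.startswith("lead")]
        if not cols:
            raise ValueError("no leadN columns found")
        return cls([df[c].to_numpy(float) for c in cols], sampling_rate, **kw)


@dataclass
class DetectorConfig:
    band_low_hz: float = 5.0
    band_high_hz: float = 25.0
    morph_low_hz: float = 1.0      # wider band preserves true QRS width
    morph_high_hz: float = 40.0
    integration_ms: float = 150.0
    refractory_ms: float = REFRACTORY_MS
    merge_ms: float = 100.0
    agree_ms: float = 150.0        # detector-agreement window for lead quality
    quality_window_s: float = 10.0
    artifact_window_s: float = 1.0
    saturation_mv: float = 4.5
    flat_std_mv: float = 1e-4
    wide_qrs_ms: float = 120.0
    shape_corr_min: float = 0.8
    template_min_beats: int = 30


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(2, [lo, hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _artifact_mask(x: np.ndarray, fs: float, cfg: DetectorConfig) -> np.ndarray:
    """Per-sample artifact mask: saturated or flat 1 s windows."""
    w = max(1, int(cfg.artifact_window_s * fs))
    mask = np.zeros(len(x), dtype=bool)
    for s in range(0, len(x), w):
        seg = x[s : s + w]
        if len(seg) == 0:
            continue
        if np.max(np.abs(seg)) >= cfg.saturation_mv or np.std(seg) < cfg.flat_std_mv:
            mask[s : s + w] = True
    return mask


def _detect_single(x: np.ndarray, fs: float, cfg: DetectorConfig) -> np.ndarray:
    """Pan–Tompkins-style detection on one lead -> R times (ms)."""
    if len(x) < int(2 * fs):
        return np.empty(0)
    mask = _artifact_mask(x, fs, cfg)
    xc = np.where(mask, 0.0, x - np.median(x))
    bp = _bandpass(xc, fs, cfg.band_low_hz, cfg.band_high_hz)
    energy = np.gradient(bp) ** 2
    w = max(1, int(cfg.integration_ms / 1000.0 * fs))
    integ = np.convolve(energy, np.ones(w) / w, mode="same")
    # adaptive threshold per 10 s block, floored by a global noise estimate
    block = max(1, int(cfg.quality_window_s * fs))
    thr = np.empty_like(integ)
    global_floor = 4.0 * np.median(integ[~mask]) if (~mask).any() else 0.0
    for s in range(0, len(integ), block):
        seg = integ[s : s + block]
        thr[s : s + block] = max(0.25 * seg.max(), global_floor) if len(seg) else 0.0
    peaks, _ = sps.find_peaks(
        integ, height=None, distance=max(1, int(cfg.refractory_ms / 1000.0 * fs))
    )
    peaks = peaks[integ[peaks] >= thr[peaks]]
    peaks = peaks[~mask[peaks]]
    # refine to the local absolute maximum of the band-passed waveform
    half = int(0.06 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    times = np.asarray(sorted(set(refined)), dtype=float) * 1000.0 / fs
    # enforce refractoriness after refinement
    keep = []
    last = -np.inf
    for t in times:
        if t - last >= cfg.refractory_ms:
            keep.append(t)
            last = t
    return np.asarray(keep)


def _detect_alt(x: np.ndarray, fs: float, cfg: DetectorConfig) -> np.ndarray:
    """Independent second detector (different band, amplitude-based)."""
    if len(x) < int(2 * fs):
        return np.empty(0)
    mask = _artifact_mask(x, fs, cfg)
    xc = np.where(mask, 0.0, x - np.median(x))
    bp = np.abs(_bandpass(xc, fs, 8.0, 35.0))
    if bp.max() == 0:
        return np.empty(0)
    height = 0.4 * np.percentile(bp, 99.5)
    peaks, _ = sps.find_peaks(bp, height=height, distance=max(1, int(0.25 * fs)))
    peaks = peaks[~mask[peaks]]
    return peaks.astype(float) * 1000.0 / fs


def _match_count(a: np.ndarray, b: np.ndarray, tol_ms: float) -> int:
    """Greedy one-to-one matches between two sorted event-time lists."""
    i = j = matches = 0
    while i < len(a) and j < len(b):
        d = a[i] - b[j]
        if abs(d) <= tol_ms:
            matches += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return matches


def _lead_quality(x: np.ndarray, fs: float, cfg: DetectorConfig) -> float:
    """Fraction of 10 s windows where the two detectors agree within 150 ms."""
    t1 = _detect_single(x, fs, cfg)
    t2 = _detect_alt(x, fs, cfg)
    total_ms = len(x) * 1000.0 / fs
    win_ms = cfg.quality_window_s * 1000.0
    n_win = max(1, int(np.ceil(total_ms / win_ms)))
    good = 0
    for k in range(n_win):
        lo, hi = k * win_ms, (k + 1) * win_ms
        a = t1[(t1 >= lo) & (t1 < hi)]
        b = t2[(t2 >= lo) & (t2 < hi)]
        if len(a) == 0 or len(b) == 0:
            continue
        if _match_count(a, b, cfg.agree_ms) / max(len(a), len(b)) >= 0.7:
            good += 1
    return good / n_win


def select_best_leads(
    record: EcgRecord, n: int = 2, cfg: DetectorConfig | None = None
) -> list[int]:
    """Indices of the ``n`` leads with the highest signal-quality score.

    Quality is the agreement rate between two independent single-lead
    detectors; ties break toward the lower lead index, so the result is
    deterministic and permutation-equivariant.
    """
    cfg = cfg or DetectorConfig()
    if n > len(record.leads):
        raise ValueError("n exceeds the number of leads")
    scores = [_lead_quality(ch, record.sampling_rate, cfg) for ch in record.leads]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return sorted(order[:n])


def _morphology(
    bp: np.ndarray,
    fs: float,
    sample: int,
    cfg: DetectorConfig,
    template: np.ndarray | None,
    noise_mv: float = 0.0,
) -> tuple[float, float, float, np.ndarray]:
    """Width (ms), amplitude (mV), template correlation, and the segment."""
    half = int(0.15 * fs)
    lo, hi = sample - half, sample + half + 1
    if lo < 0 or hi > len(bp):
        # clipped window at the record edge: no trustworthy morphology
        seg_src = bp[max(0, lo) : min(len(bp), hi)]
        amp = float(seg_src.max() - seg_src.min()) if len(seg_src) else 0.0
        return (math_nan, amp, math_nan, np.zeros(2 * half + 1))
    seg = bp[lo:hi].copy()
    peak = np.abs(seg).max()
    if peak == 0:
        return (math_nan, 0.0, math_nan, seg)
    # QRS duration = onset to offset across all deflections in the window.
    # The quarter-max threshold is floored at 5x the robust noise level of
    # the window (MAD of the mostly-baseline samples), and only runs of >=2
    # consecutive above-threshold samples count, so noise cannot stretch the
    # span at low SNR
    thr = max(0.25 * peak, 5.0 * noise_mv)
    above = np.abs(seg) > thr
    runs = above[:-1] & above[1:]
    idx = np.flatnonzero(runs)
    if len(idx) == 0:
        width_ms = 1000.0 / fs
    else:
        width_ms = (idx[-1] + 1 - idx[0] + 1) * 1000.0 / fs
    amp = float(seg.max() - seg.min())
    if template is None:
        corr = 1.0
    else:
        s0 = seg - seg.mean()
        t0 = template - template.mean()
        denom = np.linalg.norm(s0) * np.linalg.norm(t0)
        corr = float(s0 @ t0 / denom) if denom > 0 else 0.0
    return (width_ms, amp, corr, seg)


math_nan = float("nan")


def detect_qrs(
    record: EcgRecord, leads: list[int] | None = None, cfg: DetectorConfig | None = None
) -> BeatSeries:
    """Detect beats on the selected leads and fuse the two streams.

    A detection is kept if seen on either lead; detections within the 100 ms
    merge window collapse.  Flat or all-artifact signal yields an empty series
    with quality_fraction 0 rather than an exception.
    """
    cfg = cfg or DetectorConfig()
    fs = record.sampling_rate
    if record.duration_ms < 10_000:
        raise ValueError("record shorter than 10 s")
    if leads is None:
        leads = select_best_leads(record, min(2, len(record.leads)), cfg)
    if any(i < 0 or i >= len(record.leads) for i in leads):
        raise ValueError("invalid lead index")

    streams = [_detect_single(record.leads[i], fs, cfg) for i in leads]
    merged: list[float] = []
    for t in sorted(np.concatenate(streams)) if streams else []:
        if not merged or t - merged[-1] > cfg.merge_ms:
            merged.append(float(t))
    # drop fused beats violating refractoriness
    fused: list[float] = []
    for t in merged:
        if not fused or t - fused[-1] >= cfg.refractory_ms:
            fused.append(t)

    masks = [_artifact_mask(record.leads[i], fs, cfg) for i in leads]
    joint_mask = np.logical_and.reduce(masks) if masks else np.ones(record.n_samples, bool)
    quality = float(1.0 - joint_mask.mean())
    if not fused:
        return BeatSeries(str(record.metadata.get("id", "")), [], 0.0)

    primary = record.leads[leads[0]]
    bp = _bandpass(primary - np.median(primary), fs, cfg.morph_low_hz, cfg.morph_high_hz)
    # global robust noise level of the morphology band (QRS occupies a small
    # duty cycle, so the overall MAD tracks the baseline noise)
    noise_mv = 1.4826 * float(np.median(np.abs(bp - np.median(bp))))
    segs = []
    beats = []
    for t in fused:
        s = int(round(t / 1000.0 * fs))
        width, amp, _, seg = _morphology(bp, fs, s, cfg, None, noise_mv)
        segs.append(seg if not np.isnan(width) else None)
        beats.append(Beat(time_ms=t, label="N", width_ms=width, amplitude_mv=amp))
    # running-template shape correlation (template = median of early segments)
    usable = [s for s in segs if s is not None]
    if usable:
        template = np.median(np.stack(usable[: cfg.template_min_beats]), axis=0)
        t0 = template - template.mean()
        for beat, seg in zip(beats, segs):
            if seg is None:
                continue
            s0 = seg - seg.mean()
            denom = np.linalg.norm(s0) * np.linalg.norm(t0)
            beat.shape_corr = float(s0 @ t0 / denom) if denom > 0 else 0.0
    return BeatSeries(str(record.metadata.get("id", "")), beats, quality)


def classify_beats(beats: BeatSeries, cfg: DetectorConfig | None = None) -> BeatSeries:
    """Label beats normal vs ventricular from morphology.

    A beat is ventricular when wider than the widened-QRS threshold or when
    its template correlation falls below the shape threshold.  With fewer
    than ``template_min_beats`` beats no template is trustworthy: every beat
    is labeled X (artifact) instead.
    """
    cfg = cfg or DetectorConfig()
    out = [Beat(b.time_ms, b.label, b.width_ms, b.amplitude_mv, b.shape_corr) for b in beats.beats]
    if len(out) < cfg.template_min_beats:
        for b in out:
            b.label = "X"
        return BeatSeries(beats.record_id, out, beats.quality_fraction)
    for b in out:
        if b.label == "X":
            continue
        wide = not np.isnan(b.width_ms) and b.width_ms > cfg.wide_qrs_ms
        dissimilar = not np.isnan(b.shape_corr) and b.shape_corr < cfg.shape_corr_min
        b.label = "V" if (wide or dissimilar) else "N"
    return BeatSeries(beats.record_id, out, beats.quality_fraction)
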