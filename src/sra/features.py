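"""RR-interval features for AF detection and paroxysmal-AF risk scoring.

From a beat series the tool derives, per snip, the feature set driving the
risk classifier:

* Poincaré descriptors SD1, SD2 and their ratio — dispersion of the lag-1
  return map (R_i, R_{i+1}) along its minor/major axes.  SD1 captures
  beat-to-beat irregularity, SD2 longer-range variability.
* Normalized successive differences d_i = (R_i - R_{i+1}) / (R_i + R_{i+1}) —
  a scale-free irregularity measure; its SD and 95th percentile of |d_i| are
  strongly elevated during AF.
* Extreme-window ratio — min/max interval within the contiguous run of
  ``window_len`` (default 6) intervals whose sum is maximal, i.e. the
  slowest stretch of the snip.  Near 1 in steady rhythm, depressed by pauses.
* A premature-atrial-complex (PAC) census typed by coupling interval (CI) and
  post-extrasystolic pause (P) against the local sinus cycle length (NN):
  sinus-node reset, interpolated, full compensatory pause, or delayed reset.
  Only PACs *without* sinus-node reset count toward the risk score.
* Approximate entropy ApEn(m, r) of the interval series — low for regular or
  strictly periodic rhythm, high for the irregularly irregular AF response.

NN (normal-to-normal) intervals are those bounded by two N-labeled beats;
intervals touching ventricular, atrial-premature or artifact beats are
excluded from every NN-based statistic.  Missing features are carried as NaN,
never as silent zeros; the classifier treats a missing core feature as a
not-analyzable trigger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .beats import BeatSeries

__all__ = [
    "RRSeries",
    "FeatureConfig",
    "FeatureVector",
    "PacRecord",
    "PAC_TYPES",
    "build_rr",
    "poincare_descriptors",
    "normalized_rr_differences",
    "extreme_window_ratio",
    "approximate_entropy",
    "pac_census",
    "feature_vector",
]

PAC_TYPES = ("SINUS_RESET", "INTERPOLATED", "FULL_COMPENSATORY", "DELAYED_RESET")


@dataclass
class RRSeries:
    """Consecutive inter-beat intervals R_i (ms) with NN flags.

    ``is_nn[i]`` is True iff both beats bounding interval i are labeled N.
    ``beat_labels`` keeps the source labels (length = len(intervals) + 1).
    """

    intervals_ms: np.ndarray
    is_nn: np.ndarray
    beat_labels: np.ndarray

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.is_nn = np.asarray(self.is_nn, dtype=bool)
        self.beat_labels = np.asarray(self.beat_labels, dtype=object)
        if np.any(self.intervals_ms <= 0):
            raise ValueError("all RR intervals must be positive")
        if len(self.is_nn) != len(self.intervals_ms):
            raise ValueError("is_nn must align with intervals")
        if len(self.beat_labels) != len(self.intervals_ms) + 1:
            raise ValueError("need one beat label per bounding beat")

    def __len__(self) -> int:
        return len(self.intervals_ms)

    @property
    def nn_intervals(self) -> np.ndarray:
        return self.intervals_ms[self.is_nn]

    @property
    def nn_count(self) -> int:
        return int(self.is_nn.sum())


@dataclass
class FeatureConfig:
    """Tunable constants of the feature layer.

    apen_m / apen_r_factor: ApEn embedding dimension and tolerance as a
    multiple of the series SD (classic convention m=2, r=0.2·SD).
    window_len: extreme-window length in intervals.
    prematurity_factor: a beat is premature when its coupling interval is
    below this fraction of the local NN cycle.
    pause_rel_tol: relative tolerance when matching CI+P against NN or 2·NN
    (strict inequality).  delayed_pause_min / delayed_sum_max bound the
    delayed-reset type: P > delayed_pause_min·NN and CI+P < delayed_sum_max·NN.
    local_nn_window: number of neighboring NN intervals whose median defines
    the local cycle length; also the minimum context for the PAC census.
    apen_min_nn: minimum NN intervals for ApEn to be defined.
    """

    apen_m: int = 2
    apen_r_factor: float = 0.2
    window_len: int = 6
    prematurity_factor: float = 0.85
    pause_rel_tol: float = 0.10
    delayed_pause_min: float = 1.15
    delayed_sum_max: float = 1.8
    local_nn_window: int = 10
    apen_min_nn: int = 50
    apen_max_nn: int = 1000

    def __post_init__(self) -> None:
        if self.apen_m < 1:
            raise ValueError("apen_m >= 1")
        if self.apen_r_factor <= 0:
            raise ValueError("apen_r_factor > 0")
        if self.window_len < 2:
            raise ValueError("window_len >= 2")


@dataclass
class PacRecord:
    """One detected premature atrial complex.

    coupling_ms (CI): interval from the preceding beat to the premature beat.
    pause_ms (P): interval from the premature beat to the next one.
    local_nn_ms (NN): median surrounding NN cycle length.
    countable: True for every type except SINUS_RESET (only PACs that do not
    reset the sinus node feed the risk score).
    """

    index: int
    coupling_ms: float
    pause_ms: float
    local_nn_ms: float
    type: str
    countable: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.type not in PAC_TYPES:
            raise ValueError(f"unknown PAC type {self.type!r}")
        self.countable = self.type != "SINUS_RESET"


# Snip-level feature vector; NaN marks a feature whose preconditions failed.
@dataclass
class FeatureVector:
    sd1_ms: float = math.nan
    sd2_ms: float = math.nan
    sd_ratio: float = math.nan
    dnorm_mean: float = math.nan
    dnorm_sd: float = math.nan
    dnorm_p95: float = math.nan
    extreme_window_ratio: float = math.nan
    pac_countable: int = 0
    pac_total: int = 0
    apen: float = math.nan
    nn_count: int = 0
    artifact_fraction: float = math.nan
    v_count: int = 0
    duration_ms: float = math.nan

    #: features whose absence gates the snip as not analyzable
    CORE = ("sd1_ms", "sd2_ms", "dnorm_sd", "extreme_window_ratio", "apen")

    def missing_core(self) -> list[str]:
        return [name for name in self.CORE if math.isnan(getattr(self, name))]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureVector":
        names = {f for f in cls.__dataclass_fields__ if f != "CORE"}
        return cls(**{k: v for k, v in d.items() if k in names})

    @property
    def pac_countable_per_hour(self) -> float:
        if math.isnan(self.duration_ms) or self.duration_ms <= 0:
            return math.nan
        return self.pac_countable / (self.duration_ms / 3_600_000.0)

    @property
    def v_per_hour(self) -> float:
        if math.isnan(self.duration_ms) or self.duration_ms <= 0:
            return math.nan
        return self.v_count / (self.duration_ms / 3_600_000.0)


def build_rr(beats: BeatSeries) -> RRSeries:
    """Materialize the RR list from a beat series.

    Raises ValueError("no intervals") with fewer than 2 beats.  An interval is
    NN only when both bounding beats are labeled N.
    """
    if len(beats) < 2:
        raise ValueError("no intervals")
    times = beats.times_ms
    labels = beats.labels
    intervals = np.diff(times)
    normal = labels == "N"
    is_nn = normal[:-1] & normal[1:]
    return RRSeries(intervals, is_nn, labels)


def _nn_pairs(rr: RRSeries) -> tuple[np.ndarray, np.ndarray]:
    """Lag-1 pairs (R_i, R_{i+1}) where both intervals are NN."""
    ok = rr.is_nn[:-1] & rr.is_nn[1:]
    x = rr.intervals_ms[:-1][ok]
    y = rr.intervals_ms[1:][ok]
    return x, y


def poincare_descriptors(rr: RRSeries) -> tuple[float, float, float]:
    """SD1, SD2 (ms) and SD1/SD2 of the Poincaré return map.

    Computed as the principal axes of the exchange-symmetrized covariance
    matrix of the return-map cloud (the axis variances are averaged, which
    makes the eigenvectors exactly the ±45° diagonals); equivalently
    SD1 = SD((x−y)/√2), SD2 = SD((x+y)/√2) with the population (1/N)
    variance convention.  The ratio is +inf when SD2 = 0 (undefined).
    Returns (nan, nan, nan) with fewer than 3 usable pairs.
    """
    x, y = _nn_pairs(rr)
    if len(x) < 3:
        return (math.nan, math.nan, math.nan)
    sd1 = float(np.std((x - y) / math.sqrt(2.0)))
    sd2 = float(np.std((x + y) / math.sqrt(2.0)))
    # snap float-cancellation residue on degenerate (constant) axes to zero
    eps = 1e-10 * float(np.mean(x + y))
    sd1 = 0.0 if sd1 < eps else sd1
    sd2 = 0.0 if sd2 < eps else sd2
    ratio = sd1 / sd2 if sd2 > 0 else math.inf
    return (sd1, sd2, ratio)


def normalized_rr_differences(rr: RRSeries) -> tuple[np.ndarray, dict]:
    """Normalized successive differences (R_i − R_{i+1})/(R_i + R_{i+1}).

    Returns the per-pair sequence over NN-adjacent pairs and summary stats
    {mean, sd, p95} where p95 is the 95th percentile of absolute values.
    All values lie in (−1, 1) for positive intervals.
    """
    x, y = _nn_pairs(rr)
    if len(x) < 1:
        return np.empty(0), {"mean": math.nan, "sd": math.nan, "p95": math.nan}
    d = (x - y) / (x + y)
    stats = {
        "mean": float(np.mean(d)),
        "sd": float(np.std(d)),
        "p95": float(np.percentile(np.abs(d), 95)),
    }
    return d, stats


def extreme_window_ratio(rr: RRSeries, window_len: int = 6) -> float:
    """Min/max interval inside the max-sum contiguous NN window.

    Scans every run of consecutive NN intervals for the length-``window_len``
    window with the largest sum (ties broken toward the earliest window) and
    returns shortest/longest within it.  NaN when no run is long enough.
    """
    best_sum = -math.inf
    best: np.ndarray | None = None
    n = len(rr.intervals_ms)
    i = 0
    while i < n:
        if not rr.is_nn[i]:
            i += 1
            continue
        j = i
        while j < n and rr.is_nn[j]:
            j += 1
        run = rr.intervals_ms[i:j]
        if len(run) >= window_len:
            sums = np.convolve(run, np.ones(window_len), mode="valid")
            k = int(np.argmax(sums))  # argmax takes the first maximum: earliest
            if sums[k] > best_sum:
                best_sum = sums[k]
                best = run[k : k + window_len]
        i = j
    if best is None:
        return math.nan
    return float(best.min() / best.max())


def _apen_raw(x: np.ndarray, m: int, r: float) -> float:
    """ApEn Φ^m − Φ^{m+1}, Pincus convention, self-matches included.

    The n×n Chebyshev match structure is built once at lag 0 and embedded
    match matrices follow by AND-ing diagonal shifts, so cost stays O(m·n²)
    boolean operations.
    """
    n = len(x)
    match = np.empty((n, n), dtype=bool)
    block = max(1, int(4_000_000 / n))
    for s in range(0, n, block):
        e = min(s + block, n)
        match[s:e] = np.abs(x[s:e, None] - x[None, :]) <= r
    emb = match
    for k in range(1, m):
        emb = emb[:-1, :-1] & match[k:, k:]
    n_m = n - m + 1
    phi_m = float(np.mean(np.log(emb.sum(axis=1) / n_m)))
    emb = emb[:-1, :-1] & match[m:, m:]
    n_m1 = n - m
    phi_m1 = float(np.mean(np.log(emb.sum(axis=1) / n_m1)))
    return phi_m - phi_m1


def approximate_entropy(rr: RRSeries, cfg: FeatureConfig | None = None) -> float:
    """ApEn(m, r) of the NN intervals, classic Pincus convention.

    Chebyshev distance, self-matches included, r = apen_r_factor × population
    SD of the NN series.  Zero-SD series give 0 by convention; NaN when fewer
    than ``apen_min_nn`` NN intervals are available.  The estimate carries a
    finite-sample bias that grows with series length, so it is evaluated on
    at most the first ``apen_max_nn`` NN intervals — snips of different
    durations then yield comparable values.
    """
    cfg = cfg or FeatureConfig()
    x = rr.nn_intervals
    if len(x) < max(cfg.apen_min_nn, cfg.apen_m + 2):
        return math.nan
    x = x[: cfg.apen_max_nn]
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = cfg.apen_r_factor * sd
    return max(0.0, _apen_raw(x, cfg.apen_m, r))


def _classify_pac(ci: float, p: float, nn: float, cfg: FeatureConfig) -> str:
    """Type a premature narrow-QRS beat from CI, pause and local cycle length.

    Tolerance comparisons are strict so that boundary cases (CI+P exactly 10%
    away from 2·NN) fall through to the sinus-reset default.
    """
    s = ci + p
    if abs(s - nn) < cfg.pause_rel_tol * nn:
        return "INTERPOLATED"
    if abs(s - 2.0 * nn) < cfg.pause_rel_tol * 2.0 * nn:
        return "FULL_COMPENSATORY"
    if p > cfg.delayed_pause_min * nn and s < cfg.delayed_sum_max * nn:
        return "DELAYED_RESET"
    return "SINUS_RESET"


def pac_census(beats: BeatSeries, cfg: FeatureConfig | None = None) -> list[PacRecord]:
    """Detect and type premature atrial complexes from beat timing.

    A narrow-QRS beat (label N or A) is a PAC candidate when its coupling
    interval is shorter than ``prematurity_factor`` times the local NN cycle
    length (median of the nearest ``local_nn_window`` NN intervals, excluding
    the coupling and pause intervals themselves).  Candidates without enough
    surrounding NN context are skipped.  Returns records in beat order; the
    empty list when no PAC is found.
    """
    cfg = cfg or FeatureConfig()
    if len(beats) < 3:
        return []
    rr = build_rr(beats)
    labels = beats.labels
    n_int = len(rr)
    nn_idx = np.flatnonzero(rr.is_nn)
    out: list[PacRecord] = []
    for b in range(1, len(beats) - 1):
        if labels[b] not in ("N", "A"):
            continue
        ci_i, p_i = b - 1, b  # interval indices around beat b
        pos = int(np.searchsorted(nn_idx, b))
        lo = max(0, pos - cfg.local_nn_window - 2)
        cand = [j for j in nn_idx[lo : pos + cfg.local_nn_window + 2] if j not in (ci_i, p_i)]
        if len(cand) < cfg.local_nn_window:
            continue
        cand.sort(key=lambda j: abs(j - b))
        nearest = cand[: cfg.local_nn_window]
        local_nn = float(np.median(rr.intervals_ms[nearest]))
        ci = float(rr.intervals_ms[ci_i])
        if ci >= cfg.prematurity_factor * local_nn:
            continue
        # the preceding beat must be narrow too, else the short CI reflects
        # the neighbor's ectopy rather than an atrial premature beat
        if labels[b - 1] not in ("N", "A"):
            continue
        p = float(rr.intervals_ms[p_i])
        kind = _classify_pac(ci, p, local_nn, cfg)
        out.append(PacRecord(index=b, coupling_ms=ci, pause_ms=p, local_nn_ms=local_nn, type=kind))
    return out


def feature_vector(beats: BeatSeries, cfg: FeatureConfig | None = None) -> FeatureVector:
    """Assemble the full per-snip feature vector.

    Missing features (failed preconditions) are NaN; counts are exact.
    ``artifact_fraction`` is the larger of the series' flagged-artifact beat
    fraction and 1 − quality_fraction of the detector.
    """
    cfg = cfg or FeatureConfig()
    fv = FeatureVector()
    n = len(beats)
    labels = beats.labels if n else np.empty(0, dtype=object)
    x_frac = float((labels == "X").sum() / n) if n else 1.0
    fv.artifact_fraction = max(x_frac, 1.0 - beats.quality_fraction)
    fv.v_count = int((labels == "V").sum())
    fv.duration_ms = beats.duration_ms
    if n < 2:
        return fv
    rr = build_rr(beats)
    fv.nn_count = rr.nn_count
    fv.sd1_ms, fv.sd2_ms, fv.sd_ratio = poincare_descriptors(rr)
    _, stats = normalized_rr_differences(rr)
    fv.dnorm_mean, fv.dnorm_sd, fv.dnorm_p95 = stats["mean"], stats["sd"], stats["p95"]
    fv.extreme_window_ratio = extreme_window_ratio(rr, cfg.window_len)
    fv.apen = approximate_entropy(rr, cfg)
    pacs = pac_census(beats, cfg)
    fv.pac_total = len(pacs)
    fv.pac_countable = sum(p.countable for p in pacs)
    return fv


def features_to_frame(rows: list[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame([fv.to_dict() for fv in rows])


def features_from_frame(df: pd.DataFrame) -> list[FeatureVector]:
    return [FeatureVector.from_dict(rec) for rec in df.to_dict("records")]
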