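"""Seeded synthetic Holter generator with ground-truth annotations.

Emulates the three study-style populations — paroxysmal-AF patients, chronic
AF, and healthy controls — at the beat level:

* Sinus rhythm: NN = mean + AR(1) colored noise + sinusoidal respiratory
  modulation.  Defaults (mean 800 ms, SDNN 40 ms, 0.25 Hz respiration) are
  ordinary resting adult values.
* AF: serially uncorrelated gamma-distributed intervals with a shorter mean
  and coefficient of variation ≥ 0.15 — the irregularly irregular ventricular
  response.  No AV-node refractory modeling; this is a deliberate
  simplification sufficient to exercise every feature.
* Ectopy: premature atrial complexes inserted with coupling interval and
  pause constructed mid-tolerance for each of the four types (sinus-node
  reset / interpolated / full compensatory / delayed reset), ventricular
  ectopy with a compensatory pattern and wide-QRS morphology, and artifact
  bursts.
* Risk signature: paroxysmal patients carry an elevated countable-PAC rate
  and extra beat-to-beat jitter in sinus rhythm; after an AF episode both are
  boosted and decay exponentially over ``decay_hours`` — the mechanism behind
  falling post-episode detection sensitivity.

Everything is reproducible from (spec, seed); per-patient seeds are spawned
from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .beats import Beat, BeatSeries, beat_series_from_intervals
from .features import PacRecord, PAC_TYPES

__all__ = [
    "SinusParams",
    "AfParams",
    "EctopySpec",
    "RiskSignature",
    "Segment",
    "RhythmTimeline",
    "CohortSpec",
    "PatientRecord",
    "gen_sinus_rr",
    "gen_af_rr",
    "insert_pacs",
    "insert_vpcs",
    "mark_artifacts",
    "gen_patient",
    "gen_cohort",
    "gen_ecg_waveform",
    "healthy_timeline",
    "chronic_timeline",
    "paroxysmal_timeline",
]

MS_PER_HOUR = 3_600_000.0


@dataclass
class SinusParams:
    mean_nn_ms: float = 800.0
    sdnn_ms: float = 40.0
    resp_freq_hz: float = 0.25
    resp_frac: float = 0.4      # share of SDNN carried by respiration
    ar_phi: float = 0.9         # AR(1) pole of the slow HRV component
    jitter_ms: float = 0.0      # extra white beat-to-beat jitter
    min_nn_ms: float = 300.0


@dataclass
class AfParams:
    mean_nn_ms: float = 600.0
    cv: float = 0.2             # coefficient of variation of the gamma model
    min_nn_ms: float = 250.0


@dataclass
class EctopySpec:
    pac_per_hour: float = 2.0
    pac_type_mix: dict = field(
        default_factory=lambda: {
            "SINUS_RESET": 0.25,
            "INTERPOLATED": 0.25,
            "FULL_COMPENSATORY": 0.25,
            "DELAYED_RESET": 0.25,
        }
    )
    vpc_per_hour: float = 0.0
    artifact_fraction: float = 0.0
    artifact_burst_beats: int = 20


@dataclass
class RiskSignature:
    present: bool = False
    pac_per_hour: float = 25.0   # baseline countable-PAC rate while at risk
    dnorm_jitter_ms: float = 25.0
    post_boost: float = 3.0      # multiplier right after an AF episode
    decay_hours: float = 1.0


@dataclass
class Segment:
    kind: str                    # SINUS | AF
    duration_ms: float

    def __post_init__(self) -> None:
        if self.kind not in ("SINUS", "AF"):
            raise ValueError("segment kind must be SINUS or AF")
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")


@dataclass
class RhythmTimeline:
    segments: list[Segment]
    sinus: SinusParams = field(default_factory=SinusParams)
    af: AfParams = field(default_factory=AfParams)
    ectopy: EctopySpec = field(default_factory=EctopySpec)
    risk: RiskSignature = field(default_factory=RiskSignature)


@dataclass
class CohortSpec:
    n_paroxysmal: int = 10
    n_chronic: int = 3
    n_healthy: int = 15
    duration_hours: tuple[float, float] = (6.0, 6.0)
    paroxysmal_burden: tuple[float, float] = (0.05, 0.3)
    master_seed: int = 0


@dataclass
class PatientRecord:
    patient_id: str
    group: str                   # PAROXYSMAL | CHRONIC | HEALTHY
    start_clock_time_s: float
    beats: BeatSeries
    annotations: list[dict]      # {start_ms, end_ms, kind}
    pac_truth: list[PacRecord] = field(default_factory=list)

    @property
    def af_intervals(self) -> list[tuple[float, float]]:
        return [(a["start_ms"], a["end_ms"]) for a in self.annotations if a["kind"] == "AF"]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_sinus_rr(duration_ms: float, params: SinusParams | None = None, seed=0) -> np.ndarray:
    """Sinus NN intervals (ms) covering ``duration_ms``.

    AR(1) noise plus respiratory sinus arrhythmia; realized mean tracks the
    spec within ~2% and SD within ~15% for half-hour-or-longer stretches.
    """
    p = params or SinusParams()
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    n = int(np.ceil(duration_ms / p.mean_nn_ms)) + 16
    if p.sdnn_ms == 0 and p.jitter_ms == 0:
        iv = np.full(n, p.mean_nn_ms)
    else:
        resp_amp = p.resp_frac * p.sdnn_ms * np.sqrt(2.0)
        ar_sd = p.sdnn_ms * np.sqrt(max(0.0, 1.0 - p.resp_frac**2))
        x = np.empty(n)
        x[0] = rng.normal(0.0, ar_sd) if ar_sd > 0 else 0.0
        eps_sd = ar_sd * np.sqrt(1.0 - p.ar_phi**2)
        eps = rng.normal(0.0, eps_sd, n) if eps_sd > 0 else np.zeros(n)
        for i in range(1, n):
            x[i] = p.ar_phi * x[i - 1] + eps[i]
        # respiration phase advances with elapsed (approximate) time
        t = np.cumsum(np.full(n, p.mean_nn_ms)) / 1000.0
        iv = p.mean_nn_ms + x + resp_amp * np.sin(2 * np.pi * p.resp_freq_hz * t)
        if p.jitter_ms > 0:
            iv = iv + rng.normal(0.0, p.jitter_ms, n)
        iv = np.clip(iv, p.min_nn_ms, None)
    cut = np.searchsorted(np.cumsum(iv), duration_ms)
    return iv[: max(cut, 2)]


def gen_af_rr(duration_ms: float, params: AfParams | None = None, seed=0) -> np.ndarray:
    """Serially uncorrelated gamma RR intervals emulating manifest AF."""
    p = params or AfParams()
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    n = int(np.ceil(duration_ms / p.mean_nn_ms)) + 16
    shape = 1.0 / p.cv**2
    iv = rng.gamma(shape, p.mean_nn_ms / shape, n)
    iv = np.clip(iv, p.min_nn_ms, None)
    cut = np.searchsorted(np.cumsum(iv), duration_ms)
    return iv[: max(cut, 2)]


# Mid-tolerance (CI, P) construction per PAC type, as fractions of local NN.
# INTERPOLATED splits a single cycle; the others replace two cycles.
_PAC_PLANS = {
    "SINUS_RESET": (0.70, 1.00),
    "FULL_COMPENSATORY": (0.70, 1.30),
    "DELAYED_RESET": (0.55, 1.20),
    "INTERPOLATED": (0.50, 0.50),
}


def insert_pacs(
    intervals_ms: np.ndarray,
    labels: list[str] | None,
    rate_per_hour: float,
    type_mix: dict | None = None,
    seed=0,
    min_gap_intervals: int = 12,
) -> tuple[np.ndarray, list[str], list[PacRecord], int]:
    """Insert typed premature atrial complexes into an interval series.

    Returns (intervals, beat labels, ground-truth PAC records, n_skipped).
    Inserted beats are labeled ``A``; CI and P are placed mid-tolerance for
    the requested type so the census typing rules recover them exactly.
    Infeasible sites (intervals too short) are skipped and counted.
    """
    if rate_per_hour < 0:
        raise ValueError("rate must be non-negative")
    mix = type_mix or {t: 0.25 for t in PAC_TYPES}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("type_mix must sum to 1")
    iv = list(np.asarray(intervals_ms, dtype=float))
    labs = list(labels) if labels is not None else ["N"] * (len(iv) + 1)
    if len(labs) != len(iv) + 1:
        raise ValueError("labels must have len(intervals)+1 entries")
    rng = _rng(seed)
    duration_h = float(np.sum(iv)) / MS_PER_HOUR
    n_pac = int(rng.poisson(rate_per_hour * duration_h))
    if n_pac == 0:
        return np.asarray(iv), labs, [], 0

    margin = 6
    eligible = [j for j in range(margin, len(iv) - margin - 1)]
    rng.shuffle(eligible)
    sites: list[int] = []
    for j in eligible:
        if len(sites) == n_pac:
            break
        if all(abs(j - s) >= min_gap_intervals for s in sites):
            sites.append(j)
    types = list(rng.choice(list(mix.keys()), size=len(sites), p=list(mix.values())))

    records: list[tuple[int, str, float, float, float]] = []
    skipped = 0
    for j, kind in sorted(zip(sites, types), reverse=True):
        nn = float(np.median(iv[max(0, j - 5) : j + 5]))
        ci_f, p_f = _PAC_PLANS[kind]
        if kind == "INTERPOLATED":
            base = iv[j]
            ci, p = ci_f * base, base - ci_f * base
            if ci < 250 or p < 250:
                skipped += 1
                continue
            iv[j : j + 1] = [ci, p]
            labs.insert(j + 1, "A")
            records.append((j, kind, ci, p, nn))
        else:
            ci, p = ci_f * nn, p_f * nn
            if ci < 250 or p < 250:
                skipped += 1
                continue
            iv[j : j + 2] = [ci, p]
            labs[j + 1] = "A"
            records.append((j, kind, ci, p, nn))

    interp_sites = sorted(j for j, kind, *_ in records if kind == "INTERPOLATED")
    out_records = []
    for j, kind, ci, p, nn in sorted(records):
        shift = int(np.searchsorted(interp_sites, j))  # interpolations before j
        out_records.append(
            PacRecord(index=j + 1 + shift, coupling_ms=ci, pause_ms=p, local_nn_ms=nn, type=kind)
        )
    return np.asarray(iv), labs, out_records, skipped


def insert_vpcs(
    intervals_ms: np.ndarray, labels: list[str], rate_per_hour: float, seed=0
) -> tuple[np.ndarray, list[str]]:
    """Replace cycles with a premature wide-QRS beat plus compensatory pause."""
    iv = list(np.asarray(intervals_ms, dtype=float))
    labs = list(labels)
    rng = _rng(seed)
    n_vpc = int(rng.poisson(rate_per_hour * float(np.sum(iv)) / MS_PER_HOUR))
    if n_vpc == 0:
        return np.asarray(iv), labs
    eligible = [j for j in range(6, len(iv) - 7) if labs[j + 1] == "N" and labs[j] == "N"]
    rng.shuffle(eligible)
    sites = []
    for j in eligible:
        if len(sites) == n_vpc:
            break
        if all(abs(j - s) >= 12 for s in sites):
            sites.append(j)
    for j in sorted(sites, reverse=True):
        nn = float(np.median(iv[max(0, j - 5) : j + 5]))
        iv[j : j + 2] = [0.6 * nn, 1.4 * nn]
        labs[j + 1] = "V"
    return np.asarray(iv), labs


def mark_artifacts(
    labels: list[str], fraction: float, burst_beats: int = 20, seed=0
) -> list[str]:
    """Relabel contiguous bursts of beats as artifact, totaling ~fraction."""
    if fraction <= 0:
        return list(labels)
    labs = list(labels)
    rng = _rng(seed)
    target = int(round(fraction * len(labs)))
    marked = 0
    guard = 0
    while marked < target and guard < 1000:
        guard += 1
        start = int(rng.integers(0, max(1, len(labs) - burst_beats)))
        run = min(burst_beats, target - marked, len(labs) - start)
        for k in range(start, start + run):
            if labs[k] != "X":
                labs[k] = "X"
                marked += 1
    return labs


def _sinus_block(
    duration_ms: float,
    base: SinusParams,
    ectopy: EctopySpec,
    risk: RiskSignature,
    hours_since_af: float | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str], list[tuple[str, float]]]:
    """One sinus block with the risk signature applied at its current decay."""
    pac_rate = ectopy.pac_per_hour
    jitter = base.jitter_ms
    if risk.present:
        boost = 1.0
        if hours_since_af is not None:
            boost += (risk.post_boost - 1.0) * np.exp(-hours_since_af / risk.decay_hours)
        pac_rate = risk.pac_per_hour * boost
        jitter = max(jitter, risk.dnorm_jitter_ms * min(boost, risk.post_boost) / 1.0)
    p = SinusParams(**{**asdict(base), "jitter_ms": jitter})
    iv = gen_sinus_rr(duration_ms, p, seed=rng.integers(2**31))
    labs = ["N"] * (len(iv) + 1)
    mix = {"SINUS_RESET": 0.25, "INTERPOLATED": 0.25, "FULL_COMPENSATORY": 0.25,
           "DELAYED_RESET": 0.25}
    if risk.present:
        # countable types dominate while the risk substrate is active
        mix = {"SINUS_RESET": 0.1, "INTERPOLATED": 0.3, "FULL_COMPENSATORY": 0.4,
               "DELAYED_RESET": 0.2}
    iv, labs, pac_truth, _ = insert_pacs(
        iv, labs, pac_rate, ectopy.pac_type_mix if not risk.present else mix,
        seed=rng.integers(2**31),
    )
    if ectopy.vpc_per_hour > 0:
        iv, labs = insert_vpcs(iv, labs, ectopy.vpc_per_hour, seed=rng.integers(2**31))
    return iv, labs, pac_truth


def gen_patient(timeline: RhythmTimeline, seed=0, patient_id: str = "p0") -> PatientRecord:
    """Render a rhythm timeline into beats plus ground-truth annotations.

    Sinus segments are generated in ≤1 h blocks so the post-episode risk
    decay applies blockwise; AF segments are annotated with exact episode
    boundaries.
    """
    rng = _rng(seed)
    all_iv: list[float] = []
    all_labs: list[str] = ["N"]
    annotations: list[dict] = []
    pac_truth: list[PacRecord] = []
    t = 0.0
    last_af_end_ms: float | None = None
    for seg in timeline.segments:
        seg_start = t
        if seg.kind == "AF":
            iv = gen_af_rr(seg.duration_ms, timeline.af, seed=rng.integers(2**31))
            labs = ["N"] * (len(iv) + 1)
            offset = len(all_iv)
            all_iv.extend(iv)
            all_labs.extend(labs[1:])
            t += float(np.sum(iv))
            annotations.append({"start_ms": seg_start, "end_ms": t, "kind": "AF"})
            last_af_end_ms = t
        else:
            remaining = seg.duration_ms
            while remaining > 0:
                block_ms = min(remaining, MS_PER_HOUR)
                since = None
                if last_af_end_ms is not None:
                    since = (t - last_af_end_ms) / MS_PER_HOUR
                iv, labs, pacs = _sinus_block(
                    block_ms, timeline.sinus, timeline.ectopy, timeline.risk, since, rng
                )
                offset = len(all_iv)
                for p in pacs:
                    pac_truth.append(
                        PacRecord(p.index + offset, p.coupling_ms, p.pause_ms,
                                  p.local_nn_ms, p.type)
                    )
                all_iv.extend(iv)
                all_labs.extend(labs[1:])
                t += float(np.sum(iv))
                remaining -= block_ms
            annotations.append({"start_ms": seg_start, "end_ms": t, "kind": "SINUS"})
    if timeline.ectopy.artifact_fraction > 0:
        all_labs = mark_artifacts(
            all_labs, timeline.ectopy.artifact_fraction,
            timeline.ectopy.artifact_burst_beats, seed=rng.integers(2**31),
        )
    quality = 1.0 - sum(l == "X" for l in all_labs) / max(1, len(all_labs))
    beats = []
    times = np.concatenate([[0.0], np.cumsum(all_iv)])
    for tt, lab in zip(times, all_labs):
        if lab == "V":
            beats.append(Beat(tt, lab, width_ms=180.0, amplitude_mv=1.4, shape_corr=0.3))
        else:
            beats.append(Beat(tt, lab, width_ms=90.0, amplitude_mv=1.0, shape_corr=0.98))
    series = BeatSeries(patient_id, beats, quality)
    return PatientRecord(patient_id, "UNSPECIFIED", 0.0, series, annotations, pac_truth)


def healthy_timeline(duration_hours: float = 6.0) -> RhythmTimeline:
    return RhythmTimeline(
        segments=[Segment("SINUS", duration_hours * MS_PER_HOUR)],
        ectopy=EctopySpec(pac_per_hour=1.0, artifact_fraction=0.02),
    )


def chronic_timeline(duration_hours: float = 6.0) -> RhythmTimeline:
    return RhythmTimeline(
        segments=[Segment("AF", duration_hours * MS_PER_HOUR)],
        ectopy=EctopySpec(pac_per_hour=0.0, artifact_fraction=0.02),
    )


def paroxysmal_timeline(
    duration_hours: float = 6.0,
    burden: float = 0.15,
    episode_start_hour: float | None = 2.0,
) -> RhythmTimeline:
    """Sinus rhythm carrying the risk signature, with one AF episode.

    ``burden`` is the fraction of the recording spent in AF (0 → no episode,
    only the persistent risk substrate).
    """
    if not 0.0 <= burden < 1.0:
        raise ValueError("burden in [0,1)")
    risk = RiskSignature(present=True)
    ectopy = EctopySpec(pac_per_hour=2.0, artifact_fraction=0.02)
    total = duration_hours * MS_PER_HOUR
    if burden == 0:
        segs = [Segment("SINUS", total)]
    else:
        af_ms = burden * total
        start = (episode_start_hour if episode_start_hour is not None else 2.0) * MS_PER_HOUR
        start = min(start, total - af_ms)
        segs = []
        if start > 0:
            segs.append(Segment("SINUS", start))
        segs.append(Segment("AF", af_ms))
        tail = total - start - af_ms
        if tail > 0:
            segs.append(Segment("SINUS", tail))
    return RhythmTimeline(segments=segs, ectopy=ectopy, risk=risk)


def gen_cohort(spec: CohortSpec | None = None) -> list[PatientRecord]:
    """Generate a study-shaped cohort, reproducible from the master seed."""
    spec = spec or CohortSpec()
    ss = np.random.SeedSequence(spec.master_seed)
    n_total = spec.n_paroxysmal + spec.n_chronic + spec.n_healthy
    children = ss.spawn(max(n_total, 1))
    records: list[PatientRecord] = []
    k = 0
    lo, hi = spec.duration_hours

    def draw(rng_seed):
        rng = _rng(rng_seed)
        dur = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        clock = float(rng.integers(0, 24 * 3600))
        return rng, dur, clock

    for i in range(spec.n_paroxysmal):
        rng, dur, clock = draw(children[k])
        blo, bhi = spec.paroxysmal_burden
        burden = float(rng.uniform(blo, bhi)) if bhi > blo else float(blo)
        ep_start = float(rng.uniform(1.0, max(1.5, dur - max(0.5, burden * dur) - 1.0)))
        tl = paroxysmal_timeline(dur, burden, ep_start)
        rec = gen_patient(tl, seed=children[k].spawn(1)[0], patient_id=f"par{i:03d}")
        rec.group, rec.start_clock_time_s = "PAROXYSMAL", clock
        records.append(rec)
        k += 1
    for i in range(spec.n_chronic):
        _, dur, clock = draw(children[k])
        rec = gen_patient(chronic_timeline(dur), seed=children[k].spawn(1)[0],
                          patient_id=f"chr{i:03d}")
        rec.group, rec.start_clock_time_s = "CHRONIC", clock
        records.append(rec)
        k += 1
    for i in range(spec.n_healthy):
        _, dur, clock = draw(children[k])
        rec = gen_patient(healthy_timeline(dur), seed=children[k].spawn(1)[0],
                          patient_id=f"hea{i:03d}")
        rec.group, rec.start_clock_time_s = "HEALTHY", clock
        records.append(rec)
        k += 1
    return records


def write_cohort(records: list[PatientRecord], out_dir) -> Path:
    """Write beats/annotations CSVs plus a manifest JSON for the pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": []}
    for rec in records:
        beats_path = out / f"{rec.patient_id}_beats.csv"
        ann_path = out / f"{rec.patient_id}_annotations.csv"
        rec.beats.to_csv(beats_path)
        with open(ann_path, "w") as fh:
            fh.write("start_ms,end_ms,kind\n")
            for a in rec.annotations:
                fh.write(f"{a['start_ms']},{a['end_ms']},{a['kind']}\n")
        manifest["patients"].append(
            {
                "id": rec.patient_id,
                "group": rec.group,
                "start_clock_time_s": rec.start_clock_time_s,
                "beats_csv": beats_path.name,
                "annotations_csv": ann_path.name,
            }
        )
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def gen_ecg_waveform(
    beats: BeatSeries,
    fs: float = 250.0,
    seed=0,
    snr_db: float = 20.0,
    lead_gains: tuple = (1.0, 0.8, 0.6),
):
    """Template-based ECG synthesis from a beat series.

    Each beat contributes Gaussian P-QRS-T deflections; ventricular beats use
    a wide, P-less template.  Additive white noise is scaled to the requested
    SNR per lead.  R-peak times land on the sample grid within one sample.
    Returns an :class:`~sra.ecg.EcgRecord`.
    """
    from .ecg import EcgRecord

    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    rng = _rng(seed)
    t_end = (beats.times_ms[-1] if len(beats) else 0.0) + 500.0
    n = int(np.ceil(t_end / 1000.0 * fs))
    t_ms = np.arange(n) * 1000.0 / fs
    sig = np.zeros(n)

    def bump(center_ms, amp, sigma_ms):
        lo = np.searchsorted(t_ms, center_ms - 4 * sigma_ms)
        hi = np.searchsorted(t_ms, center_ms + 4 * sigma_ms)
        sig[lo:hi] += amp * np.exp(-0.5 * ((t_ms[lo:hi] - center_ms) / sigma_ms) ** 2)

    for b in beats.beats:
        if b.label == "X":
            continue
        # QRS sigma chosen so the quarter-max width matches the beat's
        # nominal width (2*sqrt(2 ln 4) ~ 3.33 sigma)
        if b.label == "V":
            # biphasic slurred complex: broad R lobe plus deep offset S lobe
            w = b.width_ms if not np.isnan(b.width_ms) else 180.0
            bump(b.time_ms, 1.2, 0.22 * w)
            bump(b.time_ms + 0.35 * w, -0.9, 0.28 * w)
            bump(b.time_ms + 300.0, -0.25, 70.0)
        else:
            w = b.width_ms if not np.isnan(b.width_ms) else 90.0
            bump(b.time_ms - 160.0, 0.12, 25.0)
            bump(b.time_ms, 1.0, 0.3 * w)
            bump(b.time_ms + 45.0, -0.15, 12.0)
            bump(b.time_ms + 250.0, 0.3, 60.0)
    p_signal = float(np.mean(sig**2))
    noise_sd = np.sqrt(p_signal / 10 ** (snr_db / 10.0)) if p_signal > 0 else 0.0
    leads = [g * sig + rng.normal(0.0, noise_sd, n) for g in lead_gains]
    return EcgRecord(leads, fs, metadata={"id": beats.record_id, "synthetic": True})
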