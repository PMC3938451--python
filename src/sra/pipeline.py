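"""Snip segmentation and per-patient orchestration.

A 20–24 h recording is cut into clock-aligned 1-hour snips: snip 0 runs from
the start of recording to the next full clock hour (hence always ≤60 min and
usually shorter), subsequent snips are full clock hours, and the trailing
incomplete hour is discarded.  Each snip is feature-extracted and classified
independently; patient-level flags aggregate the per-snip readouts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .beats import BeatSeries
from .classifier import GateConfig, RiskModel, SnipClassification, classify_snip
from .features import FeatureConfig, FeatureVector, feature_vector

__all__ = [
    "Snip",
    "PatientResult",
    "segment_recording",
    "pseudonymize",
    "run_patient",
    "run_manifest",
]

log = logging.getLogger(__name__)

MS_PER_HOUR = 3_600_000.0

#: identifier-carrying metadata keys removed by pseudonymization
IDENTIFYING_KEYS = frozenset(
    {
        "initials",
        "name",
        "birth_date",
        "patient_number",
        "patient_id",
        "id",
        "file_id",
        "device_id",
        "recording_date",
        "recording_time",
    }
)


@dataclass
class Snip:
    patient_id: str
    index: int
    start_ms: float
    duration_ms: float
    beats: BeatSeries
    ground_truth: str | None = None          # SINUS | AF | MIXED
    truth_af_intervals: list = field(default_factory=list)
    features: FeatureVector | None = None
    classification: SnipClassification | None = None

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms


@dataclass
class PatientResult:
    pseudonym: str
    group: str
    snips: list[Snip]
    assessable: bool = True

    @property
    def first_hour_class(self) -> str | None:
        return self.snips[0].classification.category if self.snips else None

    @property
    def any_hour_flag(self) -> bool:
        return any(
            s.classification is not None and s.classification.category in ("PAF_RISK", "AF")
            for s in self.snips
        )

    @property
    def holter_af_overall(self) -> bool:
        return any(s.ground_truth in ("AF", "MIXED") for s in self.snips)

    @property
    def holter_af_first_hour(self) -> bool:
        return bool(self.snips) and self.snips[0].ground_truth in ("AF", "MIXED")


def segment_recording(
    beats: BeatSeries,
    start_clock_time_s: float,
    duration_ms: float | None = None,
    patient_id: str = "",
    truncate_offset_to_minutes: bool = False,
) -> list[Snip]:
    """Clock-aligned snips: offset first hour, full hours, tail discarded.

    ``start_clock_time_s`` is the recording start as seconds since midnight
    (a date ordinal offset, being a multiple of 24 h, cannot change the
    result).  With ``truncate_offset_to_minutes`` the start time is floored
    to the minute, emulating an acquisition system that reports the offset
    without seconds.  A recording shorter than the first-hour remainder plus
    one full hour yields only snip 0, with a warning.
    """
    if duration_ms is None:
        duration_ms = beats.duration_ms
    clock = start_clock_time_s % 86400.0
    if truncate_offset_to_minutes:
        clock = 60.0 * int(clock // 60.0)
    rem_s = 3600.0 - (clock % 3600.0)  # exactly on the hour -> full 60 min snip 0
    first_ms = rem_s * 1000.0
    snips: list[Snip] = []
    if duration_ms < first_ms:
        warnings.warn("recording shorter than the first-hour remainder; single truncated snip")
        snips.append(Snip(patient_id, 0, 0.0, duration_ms, beats.slice(0.0, duration_ms)))
        return snips
    snips.append(Snip(patient_id, 0, 0.0, first_ms, beats.slice(0.0, first_ms)))
    t = first_ms
    idx = 1
    while t + MS_PER_HOUR <= duration_ms:
        snips.append(Snip(patient_id, idx, t, MS_PER_HOUR, beats.slice(t, t + MS_PER_HOUR)))
        t += MS_PER_HOUR
        idx += 1
    if len(snips) == 1:
        warnings.warn("recording holds no full hour beyond the offset snip")
    return snips


def pseudonymize(metadata: dict, key: int | str = 0) -> tuple[dict, str, dict]:
    """Strip identifiers, returning (clean metadata, pseudonym, mapping).

    The pseudonym is a stable keyed hash of the patient identifier, so the
    same patient under the same key always maps to the same pseudonym, and
    the operation is idempotent (a pseudonym passes through unchanged).  The
    mapping {pseudonym: original id} is returned separately and must be
    stored apart from the data.
    """
    ident = metadata.get("pseudonym")
    if ident is not None and not (IDENTIFYING_KEYS & set(metadata)):
        return dict(metadata), str(ident), {}
    source = str(
        metadata.get("patient_id") or metadata.get("id") or metadata.get("patient_number") or ""
    )
    digest = hashlib.sha256(f"{key}:{source}".encode()).hexdigest()[:10]
    pseudonym = f"P{digest}"
    clean = {k: v for k, v in metadata.items() if k not in IDENTIFYING_KEYS}
    clean["pseudonym"] = pseudonym
    mapping = {pseudonym: source}
    return clean, pseudonym, mapping


def _snip_truth(snip: Snip, af_intervals) -> None:
    overlap = 0.0
    hits = []
    for a, b in af_intervals:
        lo, hi = max(a, snip.start_ms), min(b, snip.end_ms)
        if hi > lo:
            overlap += hi - lo
            hits.append((lo, hi))
    if overlap <= 0:
        snip.ground_truth = "SINUS"
    elif overlap >= snip.duration_ms - 1e-6:
        snip.ground_truth = "AF"
    else:
        snip.ground_truth = "MIXED"
    snip.truth_af_intervals = hits


def run_patient(
    beats: BeatSeries,
    model: RiskModel | None,
    start_clock_time_s: float = 0.0,
    group: str = "UNSPECIFIED",
    af_intervals=None,
    feature_cfg: FeatureConfig | None = None,
    gate_cfg: GateConfig | None = None,
    pseudonym_key: int | str = 0,
    truncate_offset_to_minutes: bool = False,
) -> PatientResult:
    """Segment, extract features, classify and aggregate one recording.

    ``af_intervals`` (ground-truth episode boundaries, ms from record start)
    enables benchmark mode: per-snip truth labels and the patient-level
    Holter-AF booleans.  A patient whose snips are all NOT_ANALYZABLE is
    flagged not assessable.
    """
    feature_cfg = feature_cfg or FeatureConfig()
    gate_cfg = gate_cfg or GateConfig()
    _, pseudonym, _ = pseudonymize({"patient_id": beats.record_id}, pseudonym_key)
    snips = segment_recording(
        beats,
        start_clock_time_s,
        patient_id=pseudonym,
        truncate_offset_to_minutes=truncate_offset_to_minutes,
    )
    for snip in snips:
        # times inside a snip are kept relative to the recording, so features
        # that depend only on intervals are unaffected by the offset
        snip.features = feature_vector(snip.beats, feature_cfg)
        snip.classification = classify_snip(snip.features, model, gate_cfg)
        if af_intervals is not None:
            _snip_truth(snip, af_intervals)
    assessable = any(s.classification.category != "NOT_ANALYZABLE" for s in snips)
    if not assessable:
        log.warning("patient %s: no analyzable snip", pseudonym)
    return PatientResult(pseudonym, group, snips, assessable)


def run_manifest(
    manifest_path,
    model: RiskModel | None,
    out_dir=None,
    feature_cfg: FeatureConfig | None = None,
    gate_cfg: GateConfig | None = None,
) -> list[PatientResult]:
    """Run every patient listed in a cohort manifest JSON.

    The manifest holds, per patient: id, group, start clock time and the
    beats/annotations CSV paths (relative to the manifest).  Writes per-snip
    and per-patient summary CSVs when ``out_dir`` is given.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    results = []
    for entry in manifest["patients"]:
        beats = BeatSeries.from_csv(base / entry["beats_csv"], record_id=entry["id"])
        af_intervals = None
        ann_name = entry.get("annotations_csv")
        if ann_name:
            ann = pd.read_csv(base / ann_name)
            af_intervals = [
                (row.start_ms, row.end_ms) for row in ann.itertuples() if row.kind == "AF"
            ]
        results.append(
            run_patient(
                beats,
                model,
                start_clock_time_s=float(entry.get("start_clock_time_s", 0.0)),
                group=entry.get("group", "UNSPECIFIED"),
                af_intervals=af_intervals,
                feature_cfg=feature_cfg,
                gate_cfg=gate_cfg,
            )
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results_frame(results).to_csv(out / "snips.csv", index=False)
        patients_frame(results).to_csv(out / "patients.csv", index=False)
    return results


def results_frame(results: list[PatientResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for s in res.snips:
            rows.append(
                {
                    "pseudonym": res.pseudonym,
                    "group": res.group,
                    "snip_index": s.index,
                    "start_ms": s.start_ms,
                    "duration_ms": s.duration_ms,
                    "category": s.classification.category if s.classification else "",
                    "reasons": ";".join(s.classification.reasons) if s.classification else "",
                    "ground_truth": s.ground_truth or "",
                }
            )
    return pd.DataFrame(rows)


def patients_frame(results: list[PatientResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pseudonym": [r.pseudonym for r in results],
            "group": [r.group for r in results],
            "assessable": [r.assessable for r in results],
            "first_hour_class": [r.first_hour_class for r in results],
            "any_hour_flag": [r.any_hour_flag for r in results],
            "holter_af_overall": [r.holter_af_overall for r in results],
            "holter_af_first_hour": [r.holter_af_first_hour for r in results],
        }
    )
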