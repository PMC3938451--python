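"""Diagnostic-accuracy statistics for snip- and patient-level readouts.

Sensitivities and specificities are kept as exact rationals (numerator and
denominator retained) and rounded half-up only at the presentation layer.
Packaged fixture CSVs transcribe the study-style per-patient outcome counts
(first-hour and all-snip contingency tables, post-episode sensitivities,
Holter detection rates) with the schema ``group,stratum,positive,total``;
they let every printed statistic be replayed without patient-level raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib.resources import files

import numpy as np
import pandas as pd

from .pipeline import PatientResult

__all__ = [
    "ConfusionTable",
    "DiagnosticSummary",
    "confusion_from_labels",
    "sensitivity_specificity",
    "first_hour_patient_stats",
    "post_episode_hour_sensitivity",
    "holter_detection_rate",
    "load_fixture",
    "confusion_from_fixture",
    "FIXTURE_TABLES",
]

FIXTURE_TABLES = ("table2", "table3", "table4", "table5")

POSITIVE_CLASSES = ("PAF_RISK", "AF")


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 predicted × truth counts."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def transpose(self) -> "ConfusionTable":
        """Swap the roles of prediction and truth."""
        return ConfusionTable(self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity/specificity with their exact fractions retained."""

    sensitivity: float
    specificity: float
    sens_num: int = 0
    sens_den: int = 0
    spec_num: int = 0
    spec_den: int = 0

    def rounded(self, decimals: int = 2) -> tuple[float, float]:
        """Half-up rounding as in printed tables (0.585 -> 0.59)."""

        def r(v: float) -> float:
            if math.isnan(v):
                return v
            return float(Decimal(repr(v)).quantize(Decimal(10) ** -decimals, ROUND_HALF_UP))

        return r(self.sensitivity), r(self.specificity)


def confusion_from_labels(pred, truth) -> ConfusionTable:
    """Cross-tabulate binary predicted vs true labels."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return ConfusionTable(
        tp=int(np.sum(pred & truth)),
        fn=int(np.sum(~pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def sensitivity_specificity(t: ConfusionTable) -> DiagnosticSummary:
    """Sensitivity tp/(tp+fn), specificity tn/(fp+tn); NaN on empty margins."""
    sens_den = t.tp + t.fn
    spec_den = t.fp + t.tn
    sens = t.tp / sens_den if sens_den else math.nan
    spec = t.tn / spec_den if spec_den else math.nan
    return DiagnosticSummary(sens, spec, t.tp, sens_den, t.tn, spec_den)


def _first_hour_positive(res: PatientResult) -> bool:
    return res.first_hour_class in POSITIVE_CLASSES


def first_hour_patient_stats(
    results: list[PatientResult],
    positive_groups=("PAROXYSMAL", "CHRONIC"),
    control_group: str = "HEALTHY",
    assessable_only: bool = True,
) -> DiagnosticSummary:
    """Patient-level first-hour sensitivity/specificity.

    A patient counts positive when the first snip reads PAF_RISK or AF;
    patients in ``positive_groups`` contribute to sensitivity, controls to
    specificity.  Not-assessable patients are excluded by default, mirroring
    exclusion from a study's accuracy analysis.
    """
    pool = [r for r in results if r.assessable or not assessable_only]
    cases = [r for r in pool if r.group in positive_groups]
    controls = [r for r in pool if r.group == control_group]
    tp = sum(_first_hour_positive(r) for r in cases)
    fp = sum(_first_hour_positive(r) for r in controls)
    return sensitivity_specificity(
        ConfusionTable(tp=tp, fn=len(cases) - tp, fp=fp, tn=len(controls) - fp)
    )


def post_episode_hour_sensitivity(results: list[PatientResult], hour_offset: int = 1) -> float:
    """Fraction of eligible patients flagged in the k-th sinus hour after AF.

    Eligible: at least one AF episode and at least ``hour_offset`` complete
    sinus snips after the last snip touching the episode.  NaN when nobody is
    eligible.
    """
    if hour_offset < 1:
        raise ValueError("hour_offset >= 1")
    hits = 0
    eligible = 0
    for res in results:
        af_snips = [s.index for s in res.snips if s.ground_truth in ("AF", "MIXED")]
        if not af_snips:
            continue
        last_af = max(af_snips)
        target = last_af + hour_offset
        chain = [s for s in res.snips if last_af < s.index <= target]
        if len(chain) < hour_offset or any(s.ground_truth != "SINUS" for s in chain):
            continue
        snip = chain[-1]
        if snip.classification is None or snip.classification.category == "NOT_ANALYZABLE":
            continue
        eligible += 1
        if snip.classification.category in POSITIVE_CLASSES:
            hits += 1
    return hits / eligible if eligible else math.nan


def holter_detection_rate(
    results: list[PatientResult], group: str, window: str = "full"
) -> float:
    """Fraction of a group with a confirmed AF episode in the window.

    ``window`` is ``full`` (whole recording) or ``first_hour``.  Requires
    ground-truth annotations; NaN for an empty group.
    """
    if window not in ("full", "first_hour"):
        raise ValueError("window must be 'full' or 'first_hour'")
    members = [r for r in results if r.group == group]
    if not members:
        return math.nan
    if window == "full":
        return sum(r.holter_af_overall for r in members) / len(members)
    return sum(r.holter_af_first_hour for r in members) / len(members)


# -- packaged study-style fixtures ------------------------------------------


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture CSV (schema group,stratum,positive,total)."""
    path = files("sra.fixtures").joinpath(f"{name}.csv")
    return pd.read_csv(path.open())


def confusion_from_fixture(name: str) -> ConfusionTable:
    """Rebuild a 2×2 table from a two-row contingency fixture.

    Row 0 holds the condition-positive margin (test-positives / total), row 1
    the condition-negative margin.
    """
    if name not in FIXTURE_TABLES:
        raise ValueError(f"not a contingency fixture: {name}")
    df = load_fixture(name)
    pos, neg = df.iloc[0], df.iloc[1]
    return ConfusionTable(
        tp=int(pos.positive),
        fn=int(pos.total - pos.positive),
        fp=int(neg.positive),
        tn=int(neg.total - neg.positive),
    )


def fixture_proportion(name: str, group: str, stratum: str) -> tuple[int, int]:
    """(positive, total) for one row of a counts fixture."""
    df = load_fixture(name)
    row = df[(df.group == group) & (df.stratum == stratum)]
    if len(row) != 1:
        raise KeyError(f"{group}/{stratum} not found in {name}")
    return int(row.positive.iloc[0]), int(row.total.iloc[0])
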