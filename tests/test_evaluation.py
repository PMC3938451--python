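"""Diagnostic accuracy arithmetic and printed-table fixture replay."""

import math

import numpy as np
import pytest

from sra.evaluation import (
    ConfusionTable,
    confusion_from_fixture,
    confusion_from_labels,
    first_hour_patient_stats,
    fixture_proportion,
    load_fixture,
    sensitivity_specificity,
)


# ------------------------------------------------------------ cross-tabs


def test_perfect_agreement():
    t = confusion_from_labels([1, 1, 0, 0], [1, 1, 0, 0])
    assert (t.tp, t.fn, t.fp, t.tn) == (2, 0, 0, 2)


def test_perfect_disagreement():
    t = confusion_from_labels([0, 0, 1, 1], [1, 1, 0, 0])
    assert t.tp == 0 and t.tn == 0 and t.fn == 2 and t.fp == 2


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion_from_labels([1, 0], [1])


def test_margin_conservation_random():
    rng = np.random.default_rng(0)
    pred = rng.integers(0, 2, 500).astype(bool)
    truth = rng.integers(0, 2, 500).astype(bool)
    t = confusion_from_labels(pred, truth)
    assert t.tp + t.fn == truth.sum()
    assert t.fp + t.tn == (~truth).sum()
    assert t.total == 500


def test_swapping_pred_truth_transposes():
    rng = np.random.default_rng(1)
    pred = rng.integers(0, 2, 100).astype(bool)
    truth = rng.integers(0, 2, 100).astype(bool)
    assert confusion_from_labels(pred, truth).transpose == confusion_from_labels(truth, pred)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionTable(-1, 0, 0, 0)


# -------------------------------------------------- sensitivity/specificity


def test_exact_fractions_retained():
    s = sensitivity_specificity(ConfusionTable(tp=1, fn=0, fp=0, tn=1))
    assert s.sensitivity == 1.0 and s.specificity == 1.0


def test_zero_denominator_undefined_not_raising():
    s = sensitivity_specificity(ConfusionTable(tp=0, fn=0, fp=1, tn=9))
    assert math.isnan(s.sensitivity)
    assert s.specificity == 0.9


def test_rounding_half_up_matches_print_convention():
    s = sensitivity_specificity(ConfusionTable(tp=117, fn=83, fp=0, tn=1))  # 0.585
    assert s.rounded(2)[0] == 0.59


# -------------------------------------------------------- fixture replay


def test_first_hour_table_counts():
    t = confusion_from_fixture("table2")
    assert (t.tp, t.fn, t.fp, t.tn) == (50, 35, 1, 99)
    s = sensitivity_specificity(t)
    assert (s.sens_num, s.sens_den) == (50, 85)
    assert s.rounded(2) == (0.59, 0.99)


def test_no_holter_af_table_counts():
    t = confusion_from_fixture("table3")
    s = sensitivity_specificity(t)
    assert (s.sens_num, s.sens_den) == (19, 47)
    assert s.rounded(2) == (0.40, 0.99)


def test_all_snips_table_counts():
    t = confusion_from_fixture("table4")
    assert (t.tp, t.fn, t.fp, t.tn) == (1164, 766, 134, 2102)
    assert sensitivity_specificity(t).rounded(2) == (0.60, 0.94)


def test_af_episode_snips_table_counts():
    t = confusion_from_fixture("table5")
    assert (t.tp, t.fn, t.fp, t.tn) == (500, 4, 24, 2797)
    s = sensitivity_specificity(t)
    assert s.rounded(2) == (0.99, 0.99)
    assert round(100 * s.sensitivity, 1) == 99.2
    assert round(100 * s.specificity, 1) == 99.1


@pytest.mark.parametrize(
    "group,stratum,expected",
    [
        ("paroxysmal_af", "sra_first_hour", (37, 70)),
        ("paroxysmal_af", "sra_first_hour_sinus_rhythm", (23, 54)),
        ("paroxysmal_af", "post_episode_hour_1", (7, 9)),
        ("paroxysmal_af", "post_episode_hour_2", (5, 7)),
        ("paroxysmal_af", "post_episode_hour_3", (3, 7)),
        ("paroxysmal_af", "holter_af_full", (19, 70)),
        ("chronic_af", "holter_af_full", (16, 19)),
        ("healthy", "holter_af_full", (0, 100)),
    ],
)
def test_ancillary_fixture_counts(group, stratum, expected):
    assert fixture_proportion("ancillary", group, stratum) == expected


def test_fixture_schema():
    for name in ("table2", "table3", "table4", "table5", "ancillary"):
        df = load_fixture(name)
        assert list(df.columns) == ["group", "stratum", "positive", "total"]
        assert (df.positive <= df.total).all()
        assert (df.positive >= 0).all()


# ------------------------------------------------- patient-level statistics


class _FakeSnip:
    def __init__(self, index, category, truth="SINUS"):
        self.index = index
        self.ground_truth = truth
        self.classification = type("C", (), {"category": category, "reasons": []})()


class _FakeResult:
    def __init__(self, group, cats, truths=None, assessable=True):
        truths = truths or ["SINUS"] * len(cats)
        self.group = group
        self.assessable = assessable
        self.snips = [_FakeSnip(i, c, t) for i, (c, t) in enumerate(zip(cats, truths))]
        self.pseudonym = "x"

    @property
    def first_hour_class(self):
        return self.snips[0].classification.category

    @property
    def any_hour_flag(self):
        return any(s.classification.category in ("PAF_RISK", "AF") for s in self.snips)

    @property
    def holter_af_overall(self):
        return any(s.ground_truth in ("AF", "MIXED") for s in self.snips)

    @property
    def holter_af_first_hour(self):
        return self.snips[0].ground_truth in ("AF", "MIXED")


def test_all_negative_controls_give_full_specificity():
    results = [_FakeResult("HEALTHY", ["NO_RISK"] * 3) for _ in range(10)]
    s = first_hour_patient_stats(results)
    assert s.specificity == 1.0
    assert math.isnan(s.sensitivity)  # no cases present


def test_first_hour_counts_positive_cases():
    results = [
        _FakeResult("PAROXYSMAL", ["PAF_RISK", "NO_RISK"]),
        _FakeResult("PAROXYSMAL", ["NO_RISK", "PAF_RISK"]),
        _FakeResult("CHRONIC", ["AF", "AF"]),
        _FakeResult("HEALTHY", ["NO_RISK", "NO_RISK"]),
    ]
    s = first_hour_patient_stats(results)
    assert (s.sens_num, s.sens_den) == (2, 3)
    assert (s.spec_num, s.spec_den) == (1, 1)


def test_post_episode_sensitivity_on_constructed_results():
    from sra.evaluation import post_episode_hour_sensitivity

    results = [
        _FakeResult(
            "PAROXYSMAL",
            ["NO_RISK", "AF", "PAF_RISK", "NO_RISK"],
            ["SINUS", "AF", "SINUS", "SINUS"],
        ),
        _FakeResult(
            "PAROXYSMAL",
            ["NO_RISK", "AF", "NO_RISK", "PAF_RISK"],
            ["SINUS", "AF", "SINUS", "SINUS"],
        ),
    ]
    assert post_episode_hour_sensitivity(results, 1) == 0.5
    assert post_episode_hour_sensitivity(results, 2) == 0.5
    assert math.isnan(post_episode_hour_sensitivity(results, 3))


def test_holter_detection_rate_windows():
    from sra.evaluation import holter_detection_rate

    results = [
        _FakeResult("PAROXYSMAL", ["NO_RISK"] * 3, ["SINUS", "AF", "SINUS"]),
        _FakeResult("PAROXYSMAL", ["NO_RISK"] * 3, ["SINUS", "SINUS", "SINUS"]),
        _FakeResult("CHRONIC", ["AF"] * 3, ["AF", "AF", "AF"]),
    ]
    assert holter_detection_rate(results, "PAROXYSMAL", "full") == 0.5
    assert holter_detection_rate(results, "PAROXYSMAL", "first_hour") == 0.0
    assert holter_detection_rate(results, "CHRONIC", "first_hour") == 1.0
    assert math.isnan(holter_detection_rate(results, "HEALTHY", "full"))
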