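"""RR feature layer: worked examples, independent oracles, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sra.beats import beat_series_from_intervals
from sra.features import (
    FeatureConfig,
    approximate_entropy,
    build_rr,
    extreme_window_ratio,
    feature_vector,
    normalized_rr_differences,
    pac_census,
    poincare_descriptors,
)


def series(intervals, labels=None):
    return build_rr(beat_series_from_intervals(np.asarray(intervals, float), labels))


# ---------------------------------------------------------------- build_rr


def test_build_rr_intervals_and_nn_flags():
    rr = series([800, 800])
    assert rr.intervals_ms.tolist() == [800, 800]
    assert rr.is_nn.tolist() == [True, True]


def test_build_rr_non_normal_neighbor_clears_nn():
    rr = series([600, 1000], labels=["N", "V", "N"])
    assert rr.is_nn.tolist() == [False, False]


def test_build_rr_single_beat_raises():
    with pytest.raises(ValueError, match="no intervals"):
        build_rr(beat_series_from_intervals(np.empty(0)))


# ---------------------------------------------------------------- Poincaré


def _poincare_oracle(x, y):
    """Brute-force oracle: eigendecomposition of the exchange-symmetrized
    covariance matrix of the return-map cloud (population convention).

    Eigenvalues are resolved by eigenvector: SD1 belongs to the (1,-1)/sqrt(2)
    (difference) axis and SD2 to the (1,1)/sqrt(2) (identity-line) axis.
    """
    cov = np.cov(np.vstack([x, y]), bias=True)
    sym = np.array(
        [[(cov[0, 0] + cov[1, 1]) / 2, cov[0, 1]], [cov[0, 1], (cov[0, 0] + cov[1, 1]) / 2]]
    )
    evals, evecs = np.linalg.eigh(sym)
    diff_axis = np.array([1.0, -1.0]) / math.sqrt(2.0)
    # whichever eigenvector aligns with the difference axis carries SD1
    idx1 = int(np.argmax(np.abs(evecs.T @ diff_axis)))
    idx2 = 1 - idx1
    return math.sqrt(max(evals[idx1], 0.0)), math.sqrt(max(evals[idx2], 0.0))


def test_poincare_constant_series_degenerate():
    sd1, sd2, ratio = poincare_descriptors(series([800.0] * 100))
    assert sd1 == 0.0 and sd2 == 0.0
    assert math.isinf(ratio)


def test_poincare_alternating_series():
    # strict alternans: all dispersion lies on the minor axis, SD1 = 200/sqrt(2)
    # 99 successive differences split 50/49 between the signs, so the
    # mean-centered SD sits just below the balanced-case value 200/sqrt(2)
    iv = [600.0, 800.0] * 50
    sd1, sd2, _ = poincare_descriptors(series(iv))
    assert sd1 == pytest.approx(200.0 / math.sqrt(2.0), abs=0.01)
    assert sd2 == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_poincare_matches_eigendecomposition_oracle(seed):
    rng = np.random.default_rng(seed)
    rr = series(rng.uniform(500, 1100, 50))
    sd1, sd2, ratio = poincare_descriptors(rr)
    x, y = rr.intervals_ms[:-1], rr.intervals_ms[1:]
    o1, o2 = _poincare_oracle(x, y)
    assert sd1 == pytest.approx(o1, rel=1e-9)
    assert sd2 == pytest.approx(o2, rel=1e-9)
    assert ratio == pytest.approx(o1 / o2, rel=1e-9)


@given(st.lists(st.floats(300, 2000), min_size=4, max_size=60))
@settings(max_examples=100, deadline=None)
def test_poincare_sd1_closed_form(iv):
    # SD1 equals the population SD of successive differences / sqrt(2)
    rr = series(iv)
    sd1, _, _ = poincare_descriptors(rr)
    d = (rr.intervals_ms[:-1] - rr.intervals_ms[1:]) / math.sqrt(2.0)
    assert sd1 == pytest.approx(float(np.std(d)), rel=1e-9, abs=1e-9)


def test_poincare_scaling_linearity():
    rng = np.random.default_rng(3)
    iv = rng.uniform(600, 1000, 80)
    sd1, sd2, ratio = poincare_descriptors(series(iv))
    s1, s2, r = poincare_descriptors(series(iv * 2.5))
    assert s1 == pytest.approx(2.5 * sd1, rel=1e-9)
    assert s2 == pytest.approx(2.5 * sd2, rel=1e-9)
    assert r == pytest.approx(ratio, rel=1e-9)


# ----------------------------------------------------- normalized ΔRR plot


def test_dnorm_equal_intervals_zero():
    d, stats = normalized_rr_differences(series([800, 800, 800]))
    assert np.all(d == 0.0)
    assert stats["sd"] == 0.0


def test_dnorm_hand_computed_value():
    d, _ = normalized_rr_differences(series([600, 800]))
    assert d[0] == pytest.approx((600 - 800) / (600 + 800), abs=1e-12)  # -1/7


@given(st.lists(st.floats(1, 5000), min_size=3, max_size=50))
@settings(max_examples=100, deadline=None)
def test_dnorm_bounded_open_unit_interval(iv):
    d, _ = normalized_rr_differences(series(iv))
    assert np.all(d > -1.0) and np.all(d < 1.0)


def test_dnorm_scale_invariance():
    rng = np.random.default_rng(4)
    iv = rng.uniform(500, 900, 60)
    d1, _ = normalized_rr_differences(series(iv))
    d2, _ = normalized_rr_differences(series(iv * 3.0))
    np.testing.assert_allclose(d1, d2, rtol=1e-9)


# ------------------------------------------------------- extreme window


def test_extreme_window_constant_is_one():
    assert extreme_window_ratio(series([700.0] * 20)) == 1.0


def test_extreme_window_worked_example():
    rr = series([600, 900, 1000, 950, 980, 1000, 900, 600])
    # max-sum window of 6 starts at index 1; min/max = 900/1000
    assert extreme_window_ratio(rr, 6) == pytest.approx(0.9, rel=1e-12)


def _exhaustive_window_oracle(iv, w):
    sums = [sum(iv[i : i + w]) for i in range(len(iv) - w + 1)]
    k = int(np.argmax(sums))
    win = iv[k : k + w]
    return min(win) / max(win)


@pytest.mark.parametrize("seed", range(8))
def test_extreme_window_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    rr = series(rng.uniform(400, 1200, 60))
    got = extreme_window_ratio(rr, 6)
    assert got == pytest.approx(_exhaustive_window_oracle(list(rr.intervals_ms), 6), rel=1e-12)


def test_extreme_window_bounds_and_missing():
    rng = np.random.default_rng(9)
    iv = rng.uniform(400, 1200, 30)
    assert 0.0 < extreme_window_ratio(series(iv), 6) <= 1.0
    assert math.isnan(extreme_window_ratio(series(iv[:4]), 6))


# ------------------------------------------------------------------- ApEn


def naive_apen(x, m=2, r_factor=0.2):
    """O(N²) double-loop reference, Pincus convention with self-matches."""
    x = np.asarray(x, float)
    n = len(x)
    r = r_factor * np.std(x)

    def phi(mm):
        n_m = n - mm + 1
        total = 0.0
        for i in range(n_m):
            c = 0
            for j in range(n_m):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            total += math.log(c / n_m)
        return total / n_m

    return phi(m) - phi(m + 1)


def test_apen_constant_series_zero():
    assert approximate_entropy(series([800.0] * 120)) == 0.0


@pytest.mark.parametrize("n,seed", [(60, 0), (100, 1), (150, 2), (200, 3)])
def test_apen_matches_naive_oracle(n, seed):
    rng = np.random.default_rng(seed)
    iv = rng.normal(800, 60, n)
    got = approximate_entropy(series(iv))
    assert got == pytest.approx(naive_apen(iv), abs=1e-10)


def test_apen_af_more_complex_than_sinus():
    # compared at the feature layer's evaluation window (1000 intervals);
    # much shorter windows censor both rhythms at the match-count ceiling
    from sra import synthetic as syn

    wins = 0
    for seed in range(20):
        sinus = syn.gen_sinus_rr(1100 * 800.0, syn.SinusParams(), seed=seed)
        af = syn.gen_af_rr(1100 * 600.0, syn.AfParams(), seed=seed + 1000)
        a_s = approximate_entropy(series(sinus[:1000]))
        a_a = approximate_entropy(series(af[:1000]))
        wins += a_a > a_s
    assert wins == 20


def test_apen_requires_minimum_length():
    assert math.isnan(approximate_entropy(series([800.0] * 30)))


# ------------------------------------------------------------- PAC census


def _pac_context(pattern):
    iv = [800.0] * 12 + [float(v) for v in pattern] + [800.0] * 12
    return beat_series_from_intervals(np.asarray(iv))


@pytest.mark.parametrize(
    "pattern,expected_type,countable",
    [
        ((560, 1040), "FULL_COMPENSATORY", True),   # CI+P = 2*NN
        ((560, 880), "SINUS_RESET", False),          # P ~ NN: node reset
        ((400, 400), "INTERPOLATED", True),          # CI+P = NN
        ((440, 960), "DELAYED_RESET", True),         # P > 1.15 NN, CI+P < 1.8 NN
    ],
)
def test_pac_typing_rules(pattern, expected_type, countable):
    records = pac_census(_pac_context(pattern))
    premature = [r for r in records if r.index == 13]
    assert len(premature) == 1
    assert premature[0].type == expected_type
    assert premature[0].countable is countable


def test_pac_census_empty_on_regular_rhythm():
    assert pac_census(beat_series_from_intervals(np.full(50, 800.0))) == []


def test_pac_census_needs_local_context():
    # too few surrounding NN intervals: candidate skipped, not mistyped
    short = beat_series_from_intervals(np.asarray([800.0, 560.0, 1040.0, 800.0]))
    assert pac_census(short) == []


# --------------------------------------------------------- feature vector


def test_feature_vector_clean_sinus_hour():
    from sra import synthetic as syn

    iv = syn.gen_sinus_rr(3_600_000, seed=21)
    fv = feature_vector(beat_series_from_intervals(iv))
    for name in fv.CORE:
        assert not math.isnan(getattr(fv, name))
    assert fv.pac_countable == 0
    assert fv.nn_count == len(iv)
    assert fv.missing_core() == []


def test_feature_vector_short_fragment_apen_missing():
    fv = feature_vector(beat_series_from_intervals(np.full(29, 800.0)))
    assert fv.nn_count == 29
    assert math.isnan(fv.apen)
    assert "apen" in fv.missing_core()


def test_feature_vector_artifact_fraction_tracks_labels():
    from sra import synthetic as syn

    iv = syn.gen_sinus_rr(3_600_000, seed=22)
    labels = syn.mark_artifacts(["N"] * (len(iv) + 1), 0.10, seed=5)
    fv = feature_vector(beat_series_from_intervals(iv, labels, quality_fraction=0.9))
    assert fv.artifact_fraction == pytest.approx(0.10, abs=0.02)


def test_features_invariant_under_time_translation():
    rng = np.random.default_rng(8)
    iv = rng.uniform(600, 1000, 200)
    a = feature_vector(beat_series_from_intervals(iv))
    b = feature_vector(beat_series_from_intervals(iv, t0_ms=123456.0))
    for name in ("sd1_ms", "sd2_ms", "dnorm_sd", "extreme_window_ratio", "apen"):
        assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9)
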