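"""Snip gating and four-way readout classification.

Every snip is first gated for analyzability (enough NN intervals, acceptable
artifact load, no dominant pathological QRS); failing snips read
NOT_ANALYZABLE with machine-readable reasons.  Analyzable snips are mapped to
AF / PAF_RISK / NO_RISK by a linear support-vector margin classifier over the
RR feature set, trained on the synthetic generator and shipped as a versioned
JSON fixture.  A rule-based manifest-AF fallback (dual threshold on the
normalized-ΔRR SD and approximate entropy) is selectable in the config for
model-free operation.  An ApEn regularity guard keeps strictly periodic
rhythms (e.g. bigeminy, whose alternating pattern is highly "irregular" by
ΔRR dispersion but maximally regular by entropy) out of the AF class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .features import FeatureVector

__all__ = [
    "CATEGORIES",
    "GateConfig",
    "SnipClassification",
    "RiskModel",
    "analyzability_check",
    "detect_manifest_af",
    "classify_snip",
    "train_risk_model",
    "default_model",
]

#: readout categories in precedence order
CATEGORIES = ("NOT_ANALYZABLE", "AF", "PAF_RISK", "NO_RISK")

#: gating reason codes
GATE_REASONS = ("NN_TOO_LOW", "BAD_SIGNAL", "PATHOLOGICAL_QRS", "FEATURE_MISSING")

#: feature columns fed to the risk model (order is part of the model format)
MODEL_FEATURES = (
    "sd1_ms",
    "sd2_ms",
    "sd_ratio",
    "dnorm_sd",
    "dnorm_p95",
    "extreme_window_ratio",
    "apen",
    "pac_countable_per_hour",
)

_SD_RATIO_CAP = 10.0  # +inf sentinel (SD2=0) is capped before normalization


@dataclass
class GateConfig:
    nn_min: int = 1800                 # NN intervals per snip
    artifact_fraction_max: float = 0.20
    v_per_hour_max: float = 30.0       # mirrors the >30 VES/hour exclusion
    use_rule_fallback: bool = False    # manifest AF by dual threshold, no model
    af_dnorm_sd_min: float = 0.06
    af_apen_guard: float = 0.6         # regularity guard for the AF class


@dataclass
class SnipClassification:
    category: str
    reasons: list[str] = field(default_factory=list)
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        gate = [r for r in self.reasons if r in GATE_REASONS]
        if (self.category == "NOT_ANALYZABLE") != bool(gate):
            raise ValueError("NOT_ANALYZABLE iff gating reasons present")


def analyzability_check(fv: FeatureVector, cfg: GateConfig | None = None) -> list[str]:
    """Gating reasons for a snip; empty list means the snip passes."""
    cfg = cfg or GateConfig()
    reasons = []
    if fv.nn_count < cfg.nn_min:
        reasons.append("NN_TOO_LOW")
    if not math.isnan(fv.artifact_fraction) and fv.artifact_fraction > cfg.artifact_fraction_max:
        reasons.append("BAD_SIGNAL")
    v_rate = fv.v_per_hour
    if not math.isnan(v_rate) and v_rate > cfg.v_per_hour_max:
        reasons.append("PATHOLOGICAL_QRS")
    return reasons


def _model_row(fv: FeatureVector) -> np.ndarray:
    vals = []
    for name in MODEL_FEATURES:
        v = fv.pac_countable_per_hour if name == "pac_countable_per_hour" else getattr(fv, name)
        if name == "sd_ratio" and math.isinf(v):
            v = _SD_RATIO_CAP
        vals.append(v)
    return np.asarray(vals, dtype=float)


@dataclass
class RiskModel:
    """Linear margin classifier over the RR feature set.

    Stored as standardization constants plus one weight row and intercept per
    class; the decision is the argmax of class scores.  JSON serialization
    round-trips doubles exactly, so save/load preserves predictions bitwise.
    """

    kind: str = "linear_svm"
    classes: list[str] = field(default_factory=lambda: ["AF", "NO_RISK", "PAF_RISK"])
    feature_names: list[str] = field(default_factory=lambda: list(MODEL_FEATURES))
    scale_mean: list[float] = field(default_factory=list)
    scale_sd: list[float] = field(default_factory=list)
    coef: list[list[float]] = field(default_factory=list)
    intercept: list[float] = field(default_factory=list)
    seed: int = 0
    version: str = "1"

    def decision_scores(self, fv: FeatureVector) -> dict:
        x = _model_row(fv)
        z = (x - np.asarray(self.scale_mean)) / np.asarray(self.scale_sd)
        raw = np.asarray(self.coef) @ z + np.asarray(self.intercept)
        return dict(zip(self.classes, raw.tolist()))

    def predict(self, fv: FeatureVector) -> str:
        scores = self.decision_scores(fv)
        return max(scores, key=lambda c: (scores[c], c))

    # -- persistence --------------------------------------------------------

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RiskModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)


def detect_manifest_af(
    fv: FeatureVector, model: RiskModel | None, cfg: GateConfig | None = None
) -> bool:
    """True when the snip's irregularity signature crosses the AF surface.

    Requires the analyzability gate to have passed; a missing core feature
    raises.  The ApEn guard vetoes strictly periodic rhythm regardless of the
    ΔRR dispersion.
    """
    cfg = cfg or GateConfig()
    if fv.missing_core():
        raise ValueError("not analyzable: missing core feature")
    guard_ok = fv.apen >= cfg.af_apen_guard
    if cfg.use_rule_fallback or model is None:
        return bool(fv.dnorm_sd >= cfg.af_dnorm_sd_min and guard_ok)
    return bool(model.predict(fv) == "AF" and guard_ok)


def classify_snip(
    fv: FeatureVector, model: RiskModel | None, cfg: GateConfig | None = None
) -> SnipClassification:
    """Four-way snip readout with precedence NOT_ANALYZABLE > AF > PAF_RISK > NO_RISK."""
    cfg = cfg or GateConfig()
    reasons = analyzability_check(fv, cfg)
    if not reasons and fv.missing_core():
        reasons = ["FEATURE_MISSING"]
    if reasons:
        return SnipClassification("NOT_ANALYZABLE", reasons)
    if model is None and not cfg.use_rule_fallback:
        raise ValueError("no model loaded")
    if detect_manifest_af(fv, model, cfg):
        scores = model.decision_scores(fv) if model is not None else {}
        return SnipClassification("AF", [], scores)
    if cfg.use_rule_fallback or model is None:
        # without a model, risk flagging falls back to the countable-PAC rate
        risky = fv.pac_countable_per_hour >= 10.0
        return SnipClassification("PAF_RISK" if risky else "NO_RISK")
    scores = model.decision_scores(fv)
    pred = model.predict(fv)
    if pred == "AF":
        # AF call vetoed by the regularity guard: flag for review, not AF
        pred = "PAF_RISK"
    return SnipClassification(pred, [], scores)


def train_risk_model(features, labels, seed: int = 0) -> RiskModel:
    """Fit the linear margin classifier on labeled feature vectors.

    ``features`` is a sequence of FeatureVector (or a DataFrame of their
    fields); ``labels`` the per-row category (AF / PAF_RISK / NO_RISK).
    Requires at least 2 classes and 50 examples per class.  Rows are sorted
    canonically before fitting, so training is invariant to input order, and
    the solver seed derives from ``seed``: identical inputs give an identical
    model file.
    """
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    if hasattr(features, "iterrows"):
        from .features import features_from_frame

        features = features_from_frame(features)
    X = np.stack([_model_row(fv) for fv in features])
    y = np.asarray([str(l) for l in labels])
    if X.shape[0] != len(y):
        raise ValueError("features and labels must align")
    if np.isnan(X).any():
        raise ValueError("training rows must have complete features")
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 50:
        raise ValueError("need at least 50 examples per class")

    # canonical row order: lexicographic by feature values, then label
    order = sorted(range(len(y)), key=lambda i: (tuple(X[i]), y[i]))
    X, y = X[order], y[order]

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    svc = LinearSVC(C=1.0, random_state=int(seed) % (2**31), max_iter=20000, tol=1e-6)
    svc.fit(Xs, y)
    classes = [str(c) for c in svc.classes_]
    coef = svc.coef_
    intercept = svc.intercept_
    if len(classes) == 2:  # sklearn stores a single row for binary problems
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.asarray([-intercept[0], intercept[0]])
    return RiskModel(
        kind="linear_svm",
        classes=classes,
        feature_names=list(MODEL_FEATURES),
        scale_mean=scaler.mean_.tolist(),
        scale_sd=scaler.scale_.tolist(),
        coef=coef.tolist(),
        intercept=intercept.tolist(),
        seed=int(seed),
        version="1",
    )


def training_snips(n_per_class: int = 100, seed: int = 0, minutes: float = 16.0):
    """Labeled synthetic feature vectors for model training.

    Draws ``n_per_class`` snips per readout class with physiological spread:
    NO_RISK from healthy sinus rhythm, PAF_RISK from risk-signature sinus
    rhythm, AF from the gamma AF model.  Snips are long enough to reach the
    ApEn evaluation cap, and the remaining model features are rates or
    scale-free statistics, so training and hour-long classification see the
    same feature geometry while training stays cheap.
    """
    from .beats import beat_series_from_intervals
    from .features import feature_vector, FeatureConfig
    from . import synthetic as syn

    rng = np.random.default_rng(seed)
    dur = minutes * 60_000.0
    cfg = FeatureConfig()
    out_fv, out_y = [], []
    for _ in range(n_per_class):
        p = syn.SinusParams(
            mean_nn_ms=rng.uniform(700, 950), sdnn_ms=rng.uniform(25, 60),
            resp_freq_hz=rng.uniform(0.2, 0.3),
        )
        iv = syn.gen_sinus_rr(dur, p, seed=rng.integers(2**31))
        iv, labs, _, _ = syn.insert_pacs(iv, None, rng.uniform(0, 4), seed=rng.integers(2**31))
        fv = feature_vector(beat_series_from_intervals(iv, labs), cfg)
        out_fv.append(fv)
        out_y.append("NO_RISK")
    for _ in range(n_per_class):
        p = syn.SinusParams(
            mean_nn_ms=rng.uniform(700, 950), sdnn_ms=rng.uniform(25, 60),
            jitter_ms=rng.uniform(15, 35),
        )
        iv = syn.gen_sinus_rr(dur, p, seed=rng.integers(2**31))
        mix = {"SINUS_RESET": 0.1, "INTERPOLATED": 0.3, "FULL_COMPENSATORY": 0.4,
               "DELAYED_RESET": 0.2}
        iv, labs, _, _ = syn.insert_pacs(
            iv, None, rng.uniform(15, 45), mix, seed=rng.integers(2**31)
        )
        fv = feature_vector(beat_series_from_intervals(iv, labs), cfg)
        out_fv.append(fv)
        out_y.append("PAF_RISK")
    for _ in range(n_per_class):
        p = syn.AfParams(mean_nn_ms=rng.uniform(500, 700), cv=rng.uniform(0.15, 0.3))
        iv = syn.gen_af_rr(dur, p, seed=rng.integers(2**31))
        fv = feature_vector(beat_series_from_intervals(iv), cfg)
        out_fv.append(fv)
        out_y.append("AF")
    return out_fv, out_y


_DEFAULT_MODEL_SEED = 42


def build_default_model() -> RiskModel:
    """Train the shipped fixture model from scratch (fixed seed)."""
    fvs, ys = training_snips(n_per_class=100, seed=_DEFAULT_MODEL_SEED)
    return train_risk_model(fvs, ys, seed=_DEFAULT_MODEL_SEED)


def default_model() -> RiskModel:
    """Load the versioned fixture model shipped with the package."""
    from importlib.resources import files

    return RiskModel.from_json(files("sra.fixtures").joinpath("default_model.json").read_text())
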