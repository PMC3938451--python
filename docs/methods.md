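# Methods

This note records the model choices, parameter conventions and known
limitations of the package, in the spirit of a statistical software appendix.

## Problem setting

Paroxysmal atrial fibrillation (AF) is intermittent; a 20–24 h Holter
recording from an affected patient frequently contains no episode. The tool
therefore operates at the level of 1-hour ECG snips and produces a four-way
readout per snip: not analyzable, no risk, risk of paroxysmal AF, or
manifest AF. The scientific premise is that an AF-prone atrium alters
heart-rate dynamics — more frequent non-resetting atrial ectopy and elevated
beat-to-beat irregularity — and that these changes persist for some time
after an episode terminates.

## Beat detection and typing

QRS detection is Pan–Tompkins-style: 5–25 Hz band-pass, squared derivative,
150 ms moving-window integration, per-10 s adaptive threshold with a global
noise floor, 200 ms refractory period. Detection runs on the best two leads
and streams are fused with a 100 ms merge window. Lead quality is the
fraction of 10 s windows in which two methodologically independent detectors
(the integrator above, and an amplitude detector on an 8–35 Hz band) agree
within 150 ms; ties between leads break toward the lower index, which makes
selection deterministic and permutation-equivariant.

Morphology is measured on a wider 1–40 Hz band, which preserves QRS
duration: width is the onset-to-offset span of samples above a quarter of
the peak envelope (floored at five times the global in-band noise MAD, and
requiring two consecutive samples, so noise cannot stretch the span), and
shape is the Pearson correlation against a running normal-beat template
(median of the first 30 usable complexes). A beat is ventricular when wider
than 120 ms or correlating below 0.8 — conventional figures, both
configurable. With fewer than 30 beats no template is trustworthy and all
beats are labeled artifact. Beats at the record edge carry NaN morphology
and default to normal.

## RR feature layer

All NN-based statistics use intervals whose two bounding beats are labeled
normal; intervals touching ventricular, atrial-premature or artifact beats
are excluded. Missing features are NaN, never silent zeros, and any missing
core feature gates the snip to not-analyzable.

* **Poincaré SD1/SD2.** Defined as SD((Ri−Ri+1)/√2) and SD((Ri+Ri+1)/√2)
  with the population (1/N) variance convention — equivalently, the
  eigendecomposition of the exchange-symmetrized covariance matrix of the
  return-map cloud, whose principal axes are exactly the ±45° diagonals.
  Plain PCA of the raw cloud differs at order 1/n (the two marginal
  variances differ by endpoint effects) and was deliberately not used, so
  that the closed form is exact for any series. SD1/SD2 is reported as +inf
  when SD2 = 0; SDs below 1e-10 of the mean cycle are snapped to zero to
  absorb float cancellation on constant series.
* **Normalized ΔRR.** d_i = (Ri − Ri+1)/(Ri + Ri+1) over NN-adjacent pairs;
  summarized by mean, SD and the 95th percentile of |d_i|. Values are
  algebraically confined to (−1, 1) and scale-invariant.
* **Extreme-window ratio.** The contiguous window of six intervals with
  maximal sum (earliest on ties) within a run of NN intervals; the statistic
  is min/max inside that window. "Window of the six largest consecutive
  intervals" is read as the maximal-sum contiguous window — the alternative
  reading (six individually largest values that happen to be adjacent) is
  ill-defined on real data.
* **PAC census.** A narrow-QRS beat is premature when its coupling interval
  CI is below 0.85 × the local cycle length NN (median of the ten nearest NN
  intervals, excluding the coupling and pause intervals; candidates without
  ten context intervals are skipped rather than guessed). Typing compares
  CI + P against NN and 2·NN with a strict ±10 % relative tolerance:
  interpolated (≈ NN), full compensatory pause (≈ 2·NN), delayed sinus-node
  reset (P > 1.15·NN and CI + P < 1.8·NN), otherwise sinus-node reset.
  Strictness of the tolerance places exact boundary cases with the reset
  default. Only non-resetting PACs are countable for risk. Typing is purely
  timing-based, so the beat that ends an interpolated PAC's second
  half-interval can itself appear premature; it types as a non-countable
  sinus reset and does not bias the risk count.
* **Approximate entropy.** Classic convention: embedding m = 2, tolerance
  r = 0.2 × population SD of the series, Chebyshev distance, self-matches
  included. The estimator's finite-sample bias grows with series length, so
  ApEn is evaluated on at most the first 1000 NN intervals; snips of
  different durations (the offset first snip versus full hours) then yield
  comparable values, and training snips are sized to reach the same cap.
  Zero-SD series give 0 by convention; fewer than 50 NN intervals give NaN.
  The implementation builds the n×n lag-0 match matrix once and ANDs
  diagonal shifts (O(m·n²) boolean work), and equals the naive double-loop
  definition to 1e-10.

## Classifier

The snip gate requires ≥1800 NN intervals, ≤20 % artifact fraction and ≤30
ventricular beats per hour-equivalent (mirroring the usual screening
exclusion of frequent ventricular ectopy); each failure carries a
machine-readable reason, and NOT_ANALYZABLE holds exactly when a gating
reason is present, taking precedence over every rhythm class.

Rhythm classification (AF / PAF risk / no risk) is a linear support-vector
margin classifier (standardization + one-vs-rest linear SVM) over eight
features: SD1, SD2, SD1/SD2 (+inf capped at 10 before standardization),
ΔRR-SD, ΔRR-p95, extreme-window ratio, ApEn, and countable PACs per hour.
Counts enter as rates so snip duration cancels. Training rows are sorted
canonically before fitting, making training invariant to input order; the
model serializes to JSON (doubles round-trip exactly via repr, so save/load
preserves predictions bitwise). The shipped default model is trained on 100
synthetic snips per class with a fixed seed and is rebuildable with
`sra.classifier.build_default_model()`.

A manifest-AF call additionally requires ApEn ≥ 0.6: strictly periodic
rhythms such as bigeminy show large ΔRR dispersion but near-zero entropy and
must not read as AF; a model AF vote vetoed by this guard downgrades to PAF
risk (flag-for-review is the conservative clinical reading). A model-free
fallback (ΔRR-SD ≥ 0.06 and the same ApEn guard, with a 10 countable-PACs/h
risk threshold) is selectable in the gate config.

## Snip segmentation and patient aggregation

Snip 0 runs from recording start to the next full clock hour (a recording
started exactly on the hour gets a full 60 min snip 0); subsequent snips are
full clock hours; the trailing incomplete hour is discarded. Durations are
conserved exactly. Offsets are kept at second resolution; a
truncate-to-minutes compatibility flag emulates acquisition systems that
report the offset without seconds. A snip 0 too short to pass the gate is
reported not-analyzable rather than merged into hour 1, keeping "first
hour" semantics intact. Patient-level "at risk" means any snip reads PAF
risk or AF; a patient with no analyzable snip is flagged not assessable.
Pseudonymization strips identifier-bearing metadata and replaces it with a
stable keyed hash; the pseudonym→identity mapping is returned separately.

## Synthetic generator

The generator is the package's ground-truth substrate and defines the
conditions under which all self-tests run:

* **Sinus rhythm:** NN = mean + AR(1) noise + respiratory sinusoid. Defaults
  mean 800 ms, SDNN 40 ms (40 % carried by 0.25 Hz respiration), AR pole
  0.9 — ordinary resting adult values. Realized mean tracks within ~2 % and
  SD within ~15 % for ≥30 min stretches.
* **AF:** i.i.d. gamma intervals, mean 600 ms, CV 0.2. No AV-nodal
  refractory or autonomic modeling — a documented simplification; it
  reproduces the irregularly irregular, serially uncorrelated response that
  the feature set measures, which is what the tests require.
* **Ectopy:** PACs are inserted with CI and P constructed mid-tolerance for
  the requested type, so census round-trips are exact by design; ventricular
  beats use a premature-plus-compensatory cycle pattern and a biphasic wide
  template. Artifact bursts relabel contiguous beats.
* **Risk signature:** paroxysmal patients carry an elevated countable-PAC
  rate (25/h vs ~1/h in health) and 25 ms of extra white beat-to-beat
  jitter during sinus rhythm; after an episode both are boosted ×3 with a
  1 h exponential decay. The true magnitude and duration of such
  post-episode dynamics are unknown; these are free knobs, so tests assert
  qualitative trends (monotone non-increasing post-episode flag rate), not
  magnitudes.
* **Waveforms:** Gaussian P-QRS-T synthesis per beat with additive white
  noise at a configurable SNR; R peaks stay on the sample grid. The QRS
  sigma is 0.3 × nominal width so the measured quarter-max duration matches
  the label.

Cohort defaults are 10 paroxysmal / 3 chronic / 15 healthy patients at 6 h
per recording — chosen to keep the full self-test suite and the acceptance
script at desk scale (minutes on one CPU) while leaving every statistic
well-determined; larger cohorts and 20–24 h recordings are one
`CohortSpec` away.

## What the synthetic results do and do not show

Passing round-trip benchmarks (AF-snip sensitivity/specificity ≥ 0.95,
PAC-type recovery ≥ 95 %) demonstrates internal consistency: the features
measure what the generator encodes, and the classifier separates the
generator's populations. They do not establish clinical performance; real
ECG carries morphologies, artifacts and rhythm disorders the generator does
not emulate (bundle-branch block, atrial flutter with variable block, sick
sinus, electrode motion artifact that mimics ectopy). Patient-level
accuracies from real screening populations are therefore carried as packaged
contingency-count fixtures and replayed through the evaluation module rather
than re-derived from signals. The printed-count fixtures also carry two
transcription quirks of their source tables: one table's marginal totals are
internally inconsistent (the fixture keeps the consistent cell counts) and
one specificity is quoted one rounding step above what its own cells give
(2797/2821 = 99.1 %); the evaluation reports what the counts compute.

## Numerical conventions

Population (1/N) variance throughout the feature layer; half-up rounding at
the presentation layer only (matching printed two-decimal tables), with
exact numerator/denominator fractions retained. Times are ms from record
start; clock times are seconds since midnight. Interval series recovered
from cumulative beat times differ from the generating intervals at ~1e-12
relative (float summation), so cross-implementation checks compare at 1e-9
rather than bit-exactly, while determinism checks (same seed, same code
path) are bit-exact.
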