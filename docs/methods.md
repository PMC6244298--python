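# Methods

`cortiwave` analyses multichannel surface field potentials (micro-ECoG)
recorded on a rectangular electrode grid — by default the 8 × 8, 500 µm
pitch, 64-channel layout — and asks two linked questions about epileptic
activity: *how do high-amplitude spike events propagate across the cortex*
(directional plane waves, rotating spirals, or stationary synchrony), and
*do the functional network states of the underlying circuits co-vary with
those propagation patterns*. This note describes the models, the estimators,
the synthetic data the package is validated on, and the numerical choices.

## Conventions

Channels are 0-based and row-major from the top-left of the array as drawn;
`x = col · pitch` (rightward), `y = row · pitch` (downward), in µm.
Direction labels such as "right-to-left" are array-frame, not anatomical:
nothing in a recording file says how the array was oriented on the cortex.
Voltages are µV, delays ms, phases radians. Channels flagged bad (e.g. high
electrode impedance) are excluded from every statistic — never interpolated,
so no value is fabricated for a dead contact.

## Stationary-wave diagnosis

Theta-band activity (5–9 Hz) is isolated with an order-4 Butterworth
band-pass, and instantaneous phase φₖ(t) is taken from the analytic signal
(Hilbert transform) of each channel. Synchrony at time t is the circular
resultant length

R(t) = | (1/N) Σₖ exp(i φₖ(t)) | ∈ [0, 1],

which is exactly 1 when all channels share one phase — the signature of a
global stationary oscillation — and 0 for a balanced phase spread. The first
and last 5 % of samples (or one oscillation period, whichever is longer) are
flagged unreliable because the Hilbert transform wraps circularly; event
windows are cut with margins so edges never enter statistics.

All filters are applied zero-phase (forward–backward, `sosfiltfilt`):
the delay estimation downstream must not inherit filter group delay. The
effective order is therefore twice the design order; presets are named by
their design order (theta 5–9 Hz order 4; spike low-pass 120 Hz order 6;
high-gamma 80–120 Hz order 4 — the high-gamma order is a package default,
chosen to match the other band-pass).

## Spike events

Epileptic "spikes" here are millivolt-scale ictal / inter-ictal field
transients, not single-unit action potentials. Detection runs on the
120 Hz-low-passed recording: the across-channel maximum of |v| is scanned
for peaks above a fixed threshold (default 500 µV), with a refractory
distance (default 200 ms) larger than one wave's cross-array sweep so one
propagating spike yields one event. Applying the threshold to the
across-channel max (rather than one channel) catches waves entering at any
edge at their first strong channel. Window length depends on context —
100 ms for ictal spikes, 500 ms inter-ictal, one spike per window — and
context is assigned from a sliding 10 s spike-rate estimate (default
cutoff 1 spike/s), a reproducible surrogate for manual seizure-stage
labelling. Windows are centred on the event peak and never overlap (the
larger-peak event wins a collision). Detected event count is non-increasing
in the threshold by construction of the peak picker.

## Delay estimation and propagation features

For two channels the delay is the integer-sample lag τ ∈ [−L, L] maximizing
the Pearson-normalized cross-correlation of the overlapping samples;
normalization makes the lag choice invariant to per-channel amplitude
scaling. Ties break toward the smallest |τ|, then toward the negative lag —
deterministic and documented. Sub-sample parabolic refinement of the
correlation peak exists behind a flag but is off by default (delay maps are
reported on the sample grid). The default lag bound is half the event
window. An equivalent cheap cross-check, the difference of per-channel
global peak times, is provided as `peak_time_delay`.

The event's delay matrix D (D[i][j] = lag of j relative to i, antisymmetric
with zero diagonal because each unordered pair is computed once) yields:

* the **delay map** — one row of D on the grid, the propagation portrait of
  the event (plane waves appear as a monotone ramp along the travel
  direction; spirals wind around their centre);
* the **delay features** — the column of D against a fixed reference channel
  (default: first good channel). The full matrix is redundant by
  antisymmetry, and a 64-dimensional feature already separates the
  propagation types; using one column avoids the curse of dimensionality in
  the clustering that follows.

A plane wave with speed v and unit direction d produces the delay field
(p · d)/v at electrode position p — affine in position — so all plane waves
together span ≤ 2 feature directions and spirals add roughly one more.
PCA on the feature matrix therefore concentrates nearly all variance in the
first 3 components (≥ 95 % on noiseless synthetic sets; integer-sample
quantization contributes the remainder). Component signs are fixed so each
component's largest-magnitude coefficient is positive, making component
maps reproducible across runs.

Events are clustered by k-means (k-means++ seeding) on the 3-component
projection, best of `n_init` = 50 seeded restarts by within-cluster sum of
squares — k-means is seed-dependent, and restarts plus logged seeds make
runs reproducible. The cluster count is inspected with the elbow of W_k:
the suggested k maximizes the successive-decrease ratio
(W_{k−1} − W_k)/(W_k − W_{k+1}), a scale-free reading of "the decrease
flattens sharply here" (a raw second difference is dominated by whichever
single drop is largest and misses elbows that follow a much larger earlier
drop). When no k flattens markedly more than the rest (max ratio < 2 × the
median ratio) the suggestion is flagged low-confidence.

Clusters are then named from their centroid delay map: a least-squares
planar fit with R² ≥ 0.8 names the cardinal direction of the gradient
(delay grows along the travel direction); otherwise a rotational fit —
delay linear in polar angle about a centre, searched over a coarse grid of
candidate centres and branch cuts — names a `spiral` at the same R²
threshold (a good angle-linear fit is precisely a unit-winding arrival
field); anything else is `other`. An all-zero map has no gradient and no
winding and is `other`.

## Network states

Each electrode is a node sensing the population beneath it. Per event, the
recording is common-average referenced (subtracting the mean over good
channels at each sample, which exactly annihilates any component shared
identically across channels — the volume-conduction surrogate), band-passed
to high gamma (80–120 Hz, a proxy for local population firing), and cut at
the event window. Connectivity between channels i and j is the maximum over
lags |τ| ≤ 20 ms of the normalized cross-correlation of their amplitude
envelopes (analytic-signal magnitudes): a power-based measure, deliberately
robust to the propagation delays the waves themselves introduce, so the
comparison of network states against propagation types is not circular.
A raw-signal (non-envelope) variant is available for sensitivity analysis.
The 20 ms lag bound and the envelope choice are package defaults exposed in
the API.

Two events are similar when their connection matrices correlate: Pearson
correlation over the vectorized strict upper triangles (the matrices are
symmetric with unit diagonal, so full-matrix vectorization would
double-count). The event-by-event similarity matrix is an undirected
weighted graph; its communities are the network states.

Communities maximize the weighted Newman–Girvan modularity
Q = Σ_c [e_c/m − γ(d_c/2m)²] (resolution γ = 1, classic modularity; the
all-in-one partition scores exactly 0). Negative similarity edges are
clipped to zero first — modularity is defined for non-negative weights —
with the clip count logged; self-loops are dropped. Optimization is greedy
and seeded: each of `n_init` = 50 restarts combines a Louvain pass with
greedy single-node-move local searches, one polishing the Louvain result
and one started from a random partition. The mixed restarts matter: pure
Louvain (and even Leiden) can lock into a local optimum that a flat local
search from a different start escapes; with mixed restarts the optimizer
attains the exhaustively enumerated maximum-Q partition on all random
graphs of ≤ 8 nodes we test.

## Association between states and types

With 3 network states and 3 wave types the contingency table is 3 × 3 and
the Pearson chi-squared test of independence has df = (3−1)(3−1) = 4.
No continuity correction is applied (it is a 2 × 2 adjustment). Effect size
is Cramér's V = √(χ²/(n·(min(r,c)−1))) ∈ [0, 1].

Because k-means type labels vary with the seed, the test is repeated
(default 1000 runs; 100 000 available via `--runs`): each run re-clusters
the projected delay features with a fresh single k-means initialization —
run-to-run k-means variability is exactly the quantity being integrated
over — and records χ² and V against the fixed network states. Chance level
is a label-permutation null (network-state labels shuffled per run with the
run's seed), the standard chance model preserving both marginals; a
one-sided Wilcoxon rank-sum test compares the observed V distribution
against the null. The distributional conclusions are robust to the run
count, which is why the desk-scale default is 1000.

## The synthetic generator

All validation rests on recordings whose structure is planted by
construction; the generator is deliberately phenomenological (no neural-mass
or cable biophysics). Defaults describe a realistic drug-induced-seizure
session on the 8 × 8 array:

| parameter | default | meaning |
|---|---|---|
| spike amplitude | 2000 µV | "several mV" ictal transients over a tens-of-µV background |
| spike template | 40 ms biphasic | half-sine depolarization, 30 % opposite rebound; shape configurable |
| plane-wave speed | 50 µm/ms | 70 ms sweep across the 3.5 mm array — tens of ms |
| spiral angular speed | 0.1 rad/ms | ~63 ms per turn; spirals show the longest delays |
| white noise | 50 µV sd | per-channel sensor/background noise |
| common mode | 50 µV sd, 1–10 Hz | volume-conduction surrogate, added identically to all channels |
| high-gamma bursts | 50 µV RMS, 80–120 Hz | per-event planted connectivity substrate |

The spiral model is a pure rotating-phase field: arrival time depends only
on the polar angle about the centre, so the arrival field winds by exactly
±2π per turn — the minimal model with the spiral delay-map signature.
Channels at equal angle but different radius arrive together; real spirals
also have a radial wave number, which this model omits.

Planted network states deserve a note. A naive plant — one shared waveform
per channel block — is destroyed by the analysis itself: common-average
referencing turns two complementary block latents into a single ± shared
signal, and envelope correlation is sign-blind, so the structure vanishes.
The generator instead plants *power co-modulation*: every channel carries an
independent band-limited carrier, and the channels of one block share a slow
(≤ 8 Hz) bounded amplitude envelope 1 + depth·tanh(s(t)), depth 0.9.
This is precisely the kind of coupling the envelope connectivity estimator
measures, it survives re-referencing, and the bounded form keeps bursts from
ever crossing the spike-detection threshold. The burst is padded ± 0.3 s
around the spike so the full analysis window carries the state. Under these
conditions the measured event-similarity contrast is about 0.3
within-state versus 0.0 across — enough for exact state recovery across
seeds at 60 events.

All randomness flows from a single seed through named substreams
(background / events / high-gamma), so recordings are bit-reproducible and
components independently reproducible.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: anatomical inhomogeneity (speeds and
amplitudes varying across cortex), waveform variability between spikes,
drifting or broken electrodes mid-session, movement and breathing
artifacts, true biophysical coupling between propagation and connectivity
(here they co-vary because the schedule says so), and the empirical
proportions of wave types in any animal. Proportions in a synthetic
schedule are configurable inputs, not predictions.

## Numerical choices and degenerate inputs

* Zero-variance signals make correlation undefined: whole-signal flatness is
  a hard error naming the channel pair; per-lag flat overlaps simply cannot
  win the argmax; flat channels are excluded from connectivity with a
  warning and flagged in phase extraction.
* Delay-matrix cells touching bad channels are NaN; the diagonal stays 0.
* The correlation-vs-oracle agreement is exact (same argmax) rather than
  approximate because both scan the same integer lag grid with the same tie
  rule; peak correlations agree to 1e-9 (different but algebraically equal
  formulas).
* χ² drops zero-marginal rows/columns (with a warning) before computing df;
  expected counts below 5 warn but do not fail.
* Degenerate k-means runs (an empty cluster) inside the repeated
  association are re-seeded and counted; sizes used here make them rare.
* Problem sizes in the test-suite and in `scripts/acceptance.py` are desk
  scale: 300 events for wave classification, 60 for network states, 1000
  association runs, 100 graphs for the modularity oracle, 1 kHz sampling
  for synthetic recordings (the estimators only assume the band of interest
  is below Nyquist; 10 kHz acquisition data is handled identically).

## Known limitations

* Direction labels are array-frame; anatomical interpretation needs the
  surgical orientation, which no file format here carries.
* The spiral detector tests a coarse grid of candidate centres; spirals
  centred far outside the array will fall back to `other`.
* Modularity on the clipped graph ignores the information in negative
  similarities; a signed-modularity extension is out of scope.
* The ictal/inter-ictal context rule is a rate heuristic, not a clinical
  stage label.
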