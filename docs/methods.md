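# Methods

`preictal-scout` searches multichannel scalp EEG recorded before an
epileptic seizure for a *preictal* signature — a cluster of feature
windows, inside the 120 min before onset, that separates from the
surrounding interictal activity — without using any labels. This note
documents the procedure, its assumptions, the tunable parameters, and
what the synthetic-data studies do and do not demonstrate.

## Analysis windows

A seizure qualifies for analysis when it is a **lead seizure**: at least
4.5 h of seizure-free recording precede its onset (gap measured from the
previous seizure's offset to the current onset). For each lead seizure
the analysis window covers up to 4.5 h before onset, minus

- the **seizure prediction horizon** (SPH): the final 10 min before
  onset, and
- the **postictal tail**: any overlap with the 30 min following the
  previous seizure's offset.

An isolated seizure therefore contributes 4.33 h of usable signal; a
seizure exactly 4.5 h after the previous offset contributes 3.83 h
(4.5 − 0.5 − 1/6). Time is referenced to onset: window timestamps are
negative seconds, half-open windows `[t, t + 5 s)`.

**Matched control intervals** span `[onset − 28.5 h, onset − 24 h)` —
the same 4.5 h of clock time on the previous day — and are emitted only
when at least 33 h before onset are seizure-free, which also separates
the control from the previous seizure by ≥ 4.5 h. Controls run through
the identical pipeline.

## Preprocessing

Signals are band-pass filtered 0.5–100 Hz (4th-order Butterworth) and
notch filtered at 50 Hz (2nd-order IIR, Q = 30). Both filters are
applied forward-backward (zero phase): the timing of putative preictal
transitions is an output of this analysis, so phase distortion is
unacceptable; the cost is a doubled effective order.

A rule-based detector flags artifact samples on any channel: flatlines
(|first difference| < 10⁻³ µV for ≥ 2 s), rail saturation (|x| ≥ 500 µV
for ≥ 0.5 s), and abnormal peaks (|z| > 8 per channel), with a 1-s guard
margin dilated around every hit. These thresholds are configuration, not
science; an externally produced artifact mask (e.g. from an ICA-based
classifier) can be OR-ed in through `run_seizure(extra_artifact_mask=…)`.
The window is split into 10-min segments (a trailing partial segment is
kept and flagged) and each segment is re-referenced to the instantaneous
channel average.

## Features

All features are computed on 5-s non-overlapping windows. Windows
overlapping an artifact or excluded interval are kept as rows with
`validity = False` so the time axis never shifts. Three groups:

**Univariate linear** (per channel): absolute and relative spectral
power in delta [0.5, 4), theta [4, 8), alpha [8, 13), beta [13, 30) and
gamma [30, 47) Hz, total power, spectral edge frequencies (50%, 90%),
peak and intensity-weighted mean frequency, spectral bandwidth and
entropy; time-domain mean, variance, skewness, kurtosis, RMS, line
length, zero crossings, Hjorth activity/mobility/complexity,
decorrelation time (first autocorrelation lag below 1/e) and energy.
Spectra use Welch with 1-s Hann segments and 50% overlap. Relative band
powers are normalized per window by the summed power of the five bands,
so they sum to exactly 1.

**Univariate nonlinear** (per channel): sample entropy (m = 2,
r = 0.2·SD), approximate entropy, permutation entropy (orders 3–5),
Higuchi, Katz and Petrosian fractal dimensions, DFA exponent, R/S Hurst
exponent, Hjorth complexity of the differenced series, and Lempel–Ziv
complexity of the median-binarized window. Entropy parameters are fixed
and logged; estimators that cannot run on a window return NaN.

**Multivariate**: for each band, a channels × channels connectivity
matrix (default: absolute Pearson correlation of the band-filtered
window; coherence and phase-locking value available), proportionally
thresholded (top q = 0.3 of off-diagonal edges, weights kept) and
summarized by global graph measures: mean strength, mean weighted
clustering, transitivity, characteristic path length and global
efficiency (lengths = 1/weight; largest component with a flag if
disconnected), mean local efficiency, mean/max betweenness,
assortativity, greedy modularity, and density. The feature count is
bands × estimators × measures and is configuration-dependent by design.

The exact feature inventory is a configurable registry; counts are not
contractual.

## Preparation

Per seizure and per group: invalid rows are removed; remaining NaN
entries are median-imputed per feature (counts logged); features whose
values are all equal (constant) or whose modal value exceeds half the
rows (quasi-constant, strict) are dropped, comparing values after
rounding to 12 significant digits; the rest are z-scored with the n−1
SD. Normalization is per seizure, matching the seizure-specific design.

## Embedding, clustering, selection

Each prepared matrix is reduced to 3-D with UMAP over a grid of ten
neighbour values (10, 20, …, 100) × nine minimum distances (0.1–0.9) —
90 embeddings. We run UMAP with `n_epochs = 200` (measured
indistinguishable cluster geometry at half the cost of the library's
auto setting at these sizes) and a fixed `random_state`.

Every embedding receives ten clustering solutions: k-means,
Ward-linkage agglomerative, and full-covariance Gaussian mixtures for
k = 2, 3, 4, plus HDBSCAN (noise label allowed). Each solution is
scored with the classical **Dunn's Index**: minimum single-linkage
inter-cluster Euclidean distance divided by maximum intra-cluster
diameter, noise points excluded; undefined unless at least two
non-noise clusters of size ≥ 2 exist. The grid-wide maximum DI selects
the final (embedding, solution); ties resolve to grid order then method
order. If no solution has a defined DI, a DBSCAN sweep (ten ε values
between the 1st and 50th percentile of 4-NN distances) re-selects, and
if that also fails the seizure is flagged `unclustered`.

## Categorization

A deterministic rule cascade replaces the expert vote of the original
study design; every threshold is explicit configuration and every
verdict carries a rule trace.

A cluster passes the **preictal test** when, after trimming temporal
outliers, ≥ 90% of its retained members lie within the 120-min search
window and its within-span density (members / valid windows between its
first and last member) is ≥ 0.5. Outlier trimming uses Tukey fences on
member times (outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` removed): a
percentile-based trim would shave a fixed fraction off every clean
cluster and bias the registered start and duration by construction,
whereas fences leave compact clusters untouched and still discard
isolated stragglers.

The cascade: (a) ≥ 3 clusters with a passing cluster → **category 6**
(preictal = passing cluster nearest onset, by median member time);
(b) exactly two clusters with size ratio ≥ 0.8 and neither passing →
**category 2**; (c) exactly two clusters, ratio < 0.8, smaller passes →
**category 3**; (d) time-coherent trajectory → **category 4**;
(e) a 10–120-min time-contiguous suffix block with silhouette-like
compactness ≥ 0.25 against the rest → **category 5** (an intrinsically
soft notion; this rule is one defensible operationalization and is
marked experimental); else **category 1**.

The trajectory statistic for (d) is `1 − (mean consecutive-in-time step
length) / (mean distance over all point pairs)`, thresholded at 0.9. A
naive per-coordinate rank correlation with time misses periodic paths
(a helix has two uncorrelated coordinates), and any cumulative
arc-length parameter is monotone in time for arbitrary data; the step
ratio is small exactly when temporally adjacent windows stay adjacent
in the embedding, which is the property category 4 describes.

For categories 3/6 the preictal interval is registered after the same
trimming: start = earliest retained member (minutes before onset),
duration = earliest-to-latest span plus one window, density as above,
plus an `ends_at_onset` flag (reaching the last pre-SPH window is
reported, not required).

**Sleep-wake association**: for categories 2, 3 and 6 the phi
(Matthews) coefficient is computed between a binary cluster vector
(preictal membership, or either-cluster membership for category 2) and
a binary wake vector, from the 2×2 contingency table. phi equals the
Pearson correlation of the two binary vectors; constant vectors make it
undefined and are reported as such.

## Synthetic data

The generator produces the statistical structure the analysis assumes —
not biophysical EEG. Background is per-channel colored noise shaped
into the five bands (amplitude weights 1.0/0.6/0.5/0.3/0.15,
1/f-like), plus a shared alpha-band common source with per-channel
mixing (uniform 0.5–1.5 × 0.4) so baseline connectivity is nonzero and
survives average re-referencing; channels are scaled to ≈ 20 µV SD. The
preictal regime multiplies alpha amplitude by (1 + 0.25·effect) and
beta by (1 − 0.20·effect) and scales common-source coupling by
(1 + 0.25·effect) on a chosen set of 5-s windows inside
`[−start, −start + duration]`, realizing a requested window density.
`effect_size` is therefore an approximate z-shift of the interictal
feature distribution, calibrated through band gains. Sleep-wake
modulation alternates delta up / alpha down with a configurable period;
artifacts (4-s flatlines, 1.5-s rail clipping, 1-s spike bursts) are
placed in a configurable fraction of 10-min segments. One integer seed
drives everything; identical seeds give bit-identical outputs.

What passing synthetic tests shows: the pipeline detects and localizes
a genuine distributional regime change of the stated size, does not
invent one from stationary noise, and attributes periodic band
modulation to an even two-cluster split rather than a preictal cluster.
What it does not show: performance on real EEG, whose artifacts,
nonstationarities and preictal physiology are far richer than the
generator's three-parameter regime model.

## Study problem sizes

The end-to-end suites run 8 channels, 2-h pre-onset windows (3 h for
the sleep-wake study, two full 90-min periods, so both vigilance states
get near-even window counts), a reduced 3 × 3 embedding grid, and the
univariate-linear feature group, with effect size 3 z (recovery), 0
(null), and sleep-wake 2 z — six seizures per condition in the test
suite and eight in `scripts/acceptance.py`, with success thresholds at
the same rates as the full-size design (e.g. ≥ 5/6 recoveries ≈ the
90% criterion). The nonlinear and multivariate groups are exercised by
their own unit and oracle tests; they are too slow per window to sweep
in every end-to-end batch and their detection path through the pipeline
is identical.

## Numerical choices and edge cases

- SD convention: n−1 throughout; quasi-constant ties compared at 12
  significant digits.
- DI degenerate cases: zero inter-cluster distance → 0; zero diameter
  with positive separation → ∞; otherwise undefined cases propagate as
  NaN, never exceptions.
- Clustering failures (non-convergence) are recorded as unscored
  solutions; the sweep never aborts.
- All-zero or constant windows yield NaN features and invalid rows;
  zero-variance channels yield NaN connectivity rows/columns.
- EDF output is 16-bit with per-channel physical scaling; quantization
  error is bounded by (range/2¹⁶) per sample and checked against an
  independent reader in tests.

## Known limitations

- The ICA + classifier artifact-removal stage of a clinical pipeline is
  out of scope; the hook accepts an external mask instead.
- Category 5 and the trajectory threshold encode judgment calls; both
  are exposed as configuration and traced in every report.
- The DI maximum can select a different embedding than a human would;
  no visual verification step exists by design.
- Sleep-wake vectors must be supplied (or taken from synthetic ground
  truth); no sleep-staging model is included.
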