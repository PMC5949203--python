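# Methods

## Pipeline model and assumptions

The package treats a subject as one continuous multichannel recording with
stimulus event markers, and reduces it to a single averaged event-related
waveform before any connectivity is computed. All synchrony measures are
therefore measures of *evoked, stimulus-locked* co-variation: activity that
is not phase-locked to the stimulus is attenuated by trial averaging in
proportion to 1/√(n trials). This is a deliberate modeling choice — the
classification claim rests on the synchrony structure of the evoked
response, not on ongoing oscillations.

Stage order: band-pass filter → epoch → amplitude rejection → average
reference → bad-channel removal → average reference again → trial average.
Rereferencing is applied on both sides of bad-channel removal so the
zero-mean-across-channels property holds on the final channel set.
Ocular channels participate only in rejection decisions; they are excluded
from the average reference, from the scalp amplitude threshold, and from
the averaged waveform.

## Preprocessing parameters

| Parameter | Default | Notes |
|---|---|---|
| band edges | 0.3–30 Hz | zero-phase (forward–backward) Butterworth, order 4; zero phase preserves event-locked latencies at the cost of doubling the effective order |
| epoch window | 100 ms pre / 600 ms post | 700 samples at 1 kHz; onset at sample ⌊pre·rate⌋ |
| scalp rejection | 75 µV absolute | applied to the filtered, baseline-uncorrected signal; no baseline correction by default (a prestimulus-mean option exists) |
| eye blink / movement | 140 µV / 55 µV | on designated ocular channels |
| flat channel | std < 0.1 µV | over accepted trials |
| extreme channel | std > 5 × median scalp std | a reproducible automatic stand-in for manual bad-channel screening; a manual list is also accepted |
| trial averaging | pooled | both stimulus conditions pooled; a "balanced" mode averages the two condition means instead (differs only by trial-count weighting) |

Rejection only clears per-trial accept flags; it never deletes data.
Lowering any threshold can only shrink the accepted set (monotonicity is
property-tested).

## Synchrony measures

Normalisation follows the classical textbook forms exactly: population
standard deviations (divisor N), prefactor 1/N for COR and PLV and
1/(N−τ) for XCOR, so self-correlation is exactly 1. Consequences worth
knowing:

* XCOR at τ≠0 uses the full-series mean/std, so |r(τ)| can marginally
  exceed 1 (bound N/(N−τ)); entries are reported as computed, not clipped.
* The XCOR pair value is direction-dependent at τ≠0
  (r(τ; x, y) = r(−τ; y, x)); the connectivity matrix defines the
  unordered-pair value by channel order (i < j) and mirrors it. The
  diagonal carries the τ-lagged autocorrelation. Default τ = 1 sample:
  τ = 0 would duplicate COR, and accuracy on lag-structured couplings is
  empirically flat for small |τ|.
* PLV is the modulus of the complex mean of per-sample phase differences —
  the resultant length — making it a real index in [0, 1], invariant to
  amplitude scaling and to any constant phase offset.
* COH must be estimated by Welch segment averaging: with a single averaged
  waveform per subject, single-segment coherence is identically 1 and is
  refused (`DegenerateCoherenceError`).

### Coherence resolution vs. segment count

A 700-sample epoch forces a hard trade-off: 128-sample segments give ≥9
averaging segments (needed for a meaningful coherence) but a 7.8 Hz natural
bin grid — too coarse for the 1–4 Hz and 8–10 Hz analysis bands, which
would then contain no bins at all. The estimator therefore zero-pads each
segment (default nfft = 1024, ~0.98 Hz bin spacing). Padding interpolates
the segment spectrum without adding resolution, but it guarantees every
analysis band contains evaluation bins; the band value is the mean of
c(f) over bins in the half-open interval [f_low, f_high). The 13–14 Hz gap
between the alpha-2 and beta band definitions belongs to no band, and the
25–45 Hz band extends past the 30 Hz filter cutoff — its upper half
carries attenuated signal, which is logged when the band sweep runs.

### PLV null level

For N *independent* uniform phase differences the expected resultant is
√(π/(4N)) (≈0.034 at N = 700). Sample phases extracted via the Hilbert
transform are weakly dependent — the unit-phasor autocovariance at lag k
is ≈ 1/(4k²), summing to ≈0.62 — which inflates the white-noise PLV null
mean by an N-independent factor √(1.62) ≈ 1.27 (≈1.30 measured by Monte
Carlo at N = 700 and N = 2800). The unit tests assert this measured level
and the 1/√N scaling; any analysis comparing PLV against an iid-phase
Rayleigh baseline should apply this correction.

## Regions of interest

Two bundled partitions (YAML data files, editable without touching code):
the classical 10-region layout with 7 electrodes per region (70 of 128
channels), and a bilateral functional layout (left/right prefrontal,
premotor, auditory, visual, somatosensory; 68 channels). The published
electrode-to-region assignments exist only as figures, so the bundled
configs place electrodes by standard HydroCel GSN-128 scalp geography
under the published cardinality constraints; users with exact layouts
should edit the YAML. Channels removed as bad are dropped from their
region and the denominators use surviving counts (Nₖ(Nₖ−1)/2 within,
Nₖ·Nₗ across); a region left with fewer than 2 channels raises an error
rather than producing a feature from too little data. Feature order is
fixed — 10 intra values in partition order, then 45 inter values for
pairs k < l — so vectors are comparable across subjects.

## Classification and evaluation

* KNN: Euclidean distance, k = 1 (odd k enforced; small cohorts make
  larger k counterproductive).
* SVM: soft margin, RBF kernel, C = 1, bandwidth by the median heuristic
  γ = 1/(2·median²) over pairwise training distances.
* Features are standardized to zero mean / unit variance with
  **training-set statistics only** (disable with `standardize=False` for a
  strict raw-feature mode). Standardization matters when measures with
  different scales are swapped in; note it also gives uninformative
  features unit weight, which is why classifier power grows with the trial
  count even after the informative features have converged.
* Hold-out: each repeat draws 3 positives + 3 negatives uniformly without
  replacement (balanced test sets keep chance level at exactly 0.5 despite
  the 17:8 class imbalance), trains on the remainder, and scores accuracy,
  recall, precision, F1. Positive = implanted. Zero-denominator metrics
  are defined as 0. A single seed spawns independent per-repeat
  substreams, so reports are bit-reproducible. Both the per-repeat std and
  variance are reported.

## Synthetic cohorts

The generator emulates the recording design end to end: 128-channel
montage at 1 kHz (4 designated ocular channels), 100 trials per stimulus
condition plus 10 catch trials, 1 s picture + 1.2–1.7 s blank between
onsets, and injected artifacts (half-sine excursions: 150 µV scalp, 250 µV
eye blink, 90 µV eye movement; default 12% of trials, which lands the
accepted count in the 80–90 per condition range after rejection).

Coupling is realised by shared-source mixing with stimulus-locked latent
sources that are sinusoids on the epoch's exact Fourier grid (distinct
bins, subject-random phases), making distinct sources orthogonal by
construction. Planted correlations are therefore analytic: the expected
averaged-waveform correlation is base_intra within a region,
base_intra·base_inter across regions, and base_intra·(base_inter + δ)
across the coupled pairs in the positive group. Defaults: base_intra 0.9,
base_inter 0.2, two coupled region pairs at δ = 0.5, 6 Hz carrier for the
coupled-pair sources (inside theta and the filter passband; the remaining
sources spread over 2–26 Hz), 10 µV amplitude scale, and a fixed 4 µV
half-sine evoked deflection 80–300 ms post-onset added identically to all
scalp channels and both groups — so classification must come from
connectivity, not waveform shape.

What the generator does **not** emulate: volume conduction and the common
spatial mixing it induces, realistic blink morphology and topography,
1/f background spectra, non-stationarity across the session, or
between-subject montage variation. Passing tests therefore demonstrate
that the pipeline recovers region-structured evoked coupling under clean
conditions, not that it would achieve any particular accuracy on clinical
recordings.

Recordings are generated in float32 (~266 MB per full-scale subject);
the pipeline drivers generate and preprocess one subject at a time, so a
25-subject cohort never holds more than one continuous recording in
memory. The 0.3–30 Hz forward-backward filter was verified stable in
single precision (relative RMS deviation from float64 ≈ 0.5%).

## Numerical choices and degenerate inputs

* Constant signals: correlation-family measures raise
  `UndefinedCorrelationError`; constancy is detected by zero peak-to-peak
  range (exact), not a float-std threshold.
* Connectivity matrices are made exactly symmetric by mirroring the upper
  triangle; diagonals are set to exactly 1 (COR/COH/PLV) or the lagged
  autocorrelation (XCOR).
* Empty frequency bands (no bins) raise rather than returning NaN.
* Events without full epoch support are dropped with a warning; an
  epochless or all-rejected set raises `EmptyEpochSetError` at the stage
  that needs trials.
* All randomness flows through `numpy` `SeedSequence` spawning, so every
  pipeline output is reproducible from (inputs, config, seed).

## Problem sizes used by the test suite and acceptance script

Unit tests run on small fixtures (tens of channels, hundreds of samples,
≤10 trials). The cohort-level checks use the full default design — 25
subjects × 210 trials × 128 channels at 1 kHz — generated fresh
(~2 minutes per cohort on one CPU, two cohorts: planted effect and
no-effect control). Parameter sweeps reuse the per-subject averaged
waveforms and run 30 hold-out repeats per sweep point on an 8-point lag
grid and the six analysis bands; single-point runs use 100 repeats. Monte
Carlo nulls use 200 replicates.

## Known limitations

* EDF support is read-only via mne plus a minimal built-in 16-bit EDF
  writer (plain EDF, 1 s records, events in a sidecar text file); EDF+
  annotations are not parsed.
* The delimited text fixture format is meant for fixtures and small
  exports; a full-scale continuous recording as text is hundreds of MB.
* Sensor space only: no source localisation, leakage correction, or
  anatomical atlas mapping.
* The repeated hold-out draws test sets independently per repeat, so
  repeats are not independent samples of generalisation error; reported
  stds describe the repeat distribution, not a confidence interval.
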