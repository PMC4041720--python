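# Methods and modelling notes

## The feature and why it works

The quantity tracked by every downstream stage is, per analysis window,
per pattern length, the number of unique pattern clusters found by the
multiresolution N-gram scan. Irregular background activity produces
almost maximal diversity — at 60 s × 256 Hz a window holds 15 345
overlapping 16-grams, nearly all distinct — whereas pseudo-periodic ictal
discharge repeats the same handful of symbol patterns over and over, so
the count collapses by orders of magnitude. Detection and prediction
reduce to spotting departures of this count series from its interictal
baseline.

Two consequences shape the implementation:

* **The collapse requires synchronization, not just amplitude.** If a
  rhythm is merely *added* on top of independent background noise whose
  amplitude spans a quantization step, every 16-gram stays unique no
  matter how large the rhythm: per-symbol jitter destroys exact repeats.
  Real ictal discharges recruit the local network — the irregular
  background largely disappears into the rhythm. The synthetic generator
  models this with an `ictal_sync` factor (default 0.9) that suppresses
  the background in proportion to the ictal envelope.
* **Quantization coarseness sets the noise tolerance.** With 8-bit
  symbols over a 16-bit range one symbol step is 256 codes; residual
  noise well below a step leaves periodic symbol patterns intact, noise
  above a step randomizes them. The study regime (below) is chosen so
  interictal background spans a few steps (high diversity) while the
  synchronized discharge is an order of magnitude larger.

## Signal conditioning

* Butterworth band-stop of overall order 4 (scipy `butter` with N = 2 for
  a band filter), ±1 Hz around the mains frequency, applied zero-phase
  (`sosfiltfilt`) so alarm timing is not smeared. The stop-band edge must
  stay below Nyquist. Steady-state attenuation at the mains frequency
  exceeds 60 dB; the first/last second carries the forward–backward edge
  transient.
* Smooth-and-subtract: `savgol_filter`, window 101 samples (50 each
  side), polynomial order 2, mirror padding, subtracted from the input.
  It exactly annihilates polynomial trends up to order 2 in the window
  interior, removes >90 % of a saturation plateau's amplitude, and passes
  ≥90 % of the variance of a 100 Hz oscillation. At 256 Hz its cutoff is
  ≈3 Hz, so it also acts as a gentle high-pass on the 1/f background.
* Order: notch first, then smooth-subtract, applied per channel.

## Symbolization

Acquisition codes are signed 16-bit by convention; `requantize` shifts
them by 2^15 before truncating least-significant bits (a `signed` switch
covers already-unsigned code streams, inferred from the data when not
given). Filtered (real-valued) signals re-digitize through the reference
span with floor rounding and clamping; on integer input this coincides
exactly with bit truncation. A non-binary level count is supported for
finer-than-power-of-two resolution. Symbols are fixed-width uppercase
hex (⌈b/4⌉ digits). Windows are consecutive, non-overlapping, exactly
`window_s × sampling_rate` symbols; a trailing partial window is dropped.

## Pattern engine

Methods: (1) tiled single length — ⌊W/n⌋ patterns; (2) sliding single
length — W−n+1 patterns; (3) = (1) per length independently; (4) sliding
multi-length with dominance. In method 4 the scan pointer always
advances one symbol; "skip the smaller ones" is per position: once a
longer length matches an existing cluster, shorter lengths at that
position are not tested, and a position matching nothing inserts its
substring at *every* configured length. With a single length, method 4
reduces exactly to method 2 — a property the tests assert.

Clustering: a candidate joins the first cluster (insertion order) whose
*representative* (first-seen pattern) is at least τ similar; ties go to
the earlier cluster; τ = 1 recovers exact matching. Inverse Hamming
distance is the working metric; Needleman–Wunsch (match +2, mismatch 0,
gap −1, symbols absent from the other pattern removed first, score
normalized by the sum of the original lengths, negative scores clamped
to 0) handles unequal lengths. Cluster counts are conserved: every
scanned position increments exactly one cluster or creates one, so the
single-length totals above hold for any τ.

Complexity note: exact matching runs through a hash table (a packed
numba kernel when available, a bytes-keyed dictionary otherwise) at
O(W·L) per window. Sub-unit τ clustering must compare each candidate
against existing representatives — O(clusters²) per window, which at
~15 000 clusters per 60 s window is ~10⁹ symbol comparisons. The
packaged studies therefore run with τ = 1 and count all unique clusters
(k_sig = 0); similarity clustering is exercised on short windows in the
test suite. k_sig = 0 rather than the repeated-pattern rule (count > 1)
because under exact matching interictal windows may contain *no*
repeated long pattern at all, which would degenerate the normalization.

## Thresholds, voting, scoring

Counts are normalized per length against a reference interictal period:
x̂ = (x − μ_ref)/max_ref, with σ_ref the SD of the normalized reference
(a 10⁻⁴ floor guards zero-variance references). Static marker:
|x̂| ≥ c·σ_ref (two-sided by default — large-pattern counts fall while
small-pattern counts can rise at onset; one-sided directions are
available). Dynamic marker: deviation from the mean of the previous m
windows (default 10), first m windows are warm-up. Voting: alarm when at
least fraction p of selected lengths carry a marker; multi-channel mode
ORs channels; refractory de-bouncing keeps the first alarm of a burst.

Prediction scoring follows the IT/SOP framework: alarm at t is correct
iff an onset lies in [t+IT, t+IT+SOP). The default refractory equals
IT+SOP — one pending forecast at a time; with a shorter refractory a
predictor re-alarms inside its own pending horizon and each extra alarm
is a guaranteed false prediction. Alarms raised during a seizure are
dropped (prediction is moot once the event has begun), and both scorers
accept a post-ictal exclusion window; the interictal hours in the FPR
denominator exclude the same ictal, preictal-horizon and post-ictal
time, keeping numerator and denominator consistent. Strict literal
scoring (every non-predicting alarm counts) remains available via flags.

Random predictor: Poisson alarms at FPR_max give per-seizure hit chance
P = 1 − exp(−FPR_max·SOP); chance of ≥ k of K via the binomial tail;
d independent features correct the tail by 1 − (1 − tail)^d; σ_upper is
the smallest k/K whose corrected chance falls below α = 0.05 (σ_lower
analogously on the lower tail). Monotonicity in FPR_max, SOP and d, and
agreement with Monte-Carlo simulation of the Poisson alarm process, are
asserted in the acceptance tests.

## Training

Leave-one-seizure-in: for each seizure, grid-search {threshold kind,
multiplier c, pattern-length subset, vote fraction, channel (singletons
plus OR of all), IT} on that seizure plus one seeded, randomly placed
interictal reference hour (which doubles as the normalization
reference; the seed and chosen hour are recorded). Objective:
lexicographic — training seizure hit, then fewest false events in the
reference hour, then smallest c, then candidate enumeration order. The
winner is applied to the remaining seizures and interictal data; the
training seizure and hour never enter their own test aggregate.
Candidate multipliers default to (4, 6, 8, 12): normalized interictal
count series show a noise floor of ≈3 reference SDs, so smaller
multipliers alarm on background fluctuations that a single training hour
is too short to veto. Per-IT bests are kept so summaries can report
min-FPR and max-sensitivity selections across ITs alongside first-case
(seizure #1) and best-case (highest held-out sensitivity, then lowest
false rate, then earliest seizure) choices. Channel "combination" means
OR-ing per-channel alarms, not summing counts.

## Synthetic data: what it does and does not emulate

The generator produces 16-bit, 256 Hz, 3-channel recordings:
1/f^α Gaussian background (α = 1) with RMS 400 codes (≈1.2 % of the ADC
span — a gain setting that leaves headroom for discharges an order of
magnitude larger); seizures of mean 108 s (clipped to 0.5–2 min) as a
3 Hz rhythm with decaying harmonics, peak amplitude 8× background RMS,
raised-cosine 5 s edges, and ictal synchronization 0.9; optional
50 Hz mains and rail-clipped saturation episodes; all randomness from
one seed (bit-identical reruns).

The preictal regime is *not* characterized by the clinical literature
this method targets; whether preictal dynamics exist at all is the open
question of the field. The generator therefore makes it explicit and
optional: a linear amplitude ramp of the ictal rhythm over the 20 min
before onset, reaching half the ictal amplitude (off by default;
enabled in the prediction-study fixtures). Passing prediction tests on
this fixture demonstrates that the pipeline *recovers a planted preictal
signature* — it says nothing about whether clinical EEG carries one.
Similarly the canonical study patient uses clean interictal background;
saturation artifacts (tested separately) leave a count signature that
the thresholds will flag, as artifacts notoriously do in practice.

Study sizes: the packaged studies use 15 000 s patients (3 seizures,
~3 h of plain interictal, ~1 h of FPR-countable interictal after the
horizon/reference/post-ictal exclusions), 20 seeds in the test suite and
5 (prediction) + 3 (detection) seeds in the acceptance script, with
false rates aggregated over seeds before comparison.

## Numerical choices and degenerate inputs

* Window boundaries, annotations and alarm windows are half-open
  [start, stop); alarms are stamped at window start.
* All-zero normalization references raise; σ_ref has a 10⁻⁴ floor.
* A pattern length longer than its window yields an empty table, not an
  error; an empty window set yields an empty series.
* Equal-scoring grid candidates resolve by enumeration order
  (kind, c, subset, fraction, channel, IT as listed).
* The exact-matching kernel packs ≤16-symbol patterns of a ≤8-bit
  alphabet into two 64-bit words; anything else takes the generic path.
  Both paths are asserted equal in the tests.

## Known limitations

* No cross-window pattern persistence; tables reset at window
  boundaries.
* No cross-patient training; no joint multi-seizure training objective.
* Sub-unit similarity thresholds are impractical at full window length
  (quadratic clustering); a locality-sensitive scheme would be needed.
* The evaluation assumes seizures are independent events, as the
  binomial chance model requires.
* EDF support is read-only and depends on the optional `mne` backend.
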