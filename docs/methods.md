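# Methods

This note documents the models and procedures implemented in `thalamostate`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generators do and do not emulate.

## Scientific setting

Thalamic relay neurons fire in two modes. In *tonic* mode they emit single
spikes at rates that track behavioral state (highest during locomotion and
wake, lowest in deep NREM sleep). In *burst* mode, de-inactivation of
low-voltage-activated (T-type, Ca_v_3.1) calcium channels after membrane
hyperpolarization produces clusters of 2–5 spikes at very short (< 10 ms)
inter-spike intervals, each cluster riding a low-threshold calcium spike and
preceded by a stretch of silence. Animals lacking Ca_v_3.1 lose burst firing
entirely while retaining tonic discharge.

The package quantifies both phenomena from standard inputs — spike timestamp
tables, labeled brain-state epochs, and head-mounted accelerometer (or video
motion) traces — and scores sedation behaviorally as *loss of movement*
(LOM), the continuous analog of loss of righting reflex, on a forced walking
task: a mouse walks a treadmill for a ~10 min baseline, receives an i.p.
injection, and its subsequent immobility episodes are detected and timed.

## Loss-of-movement scoring

1. **Filtering.** 3-axis acceleration is band-passed at 0.5–20 Hz with a
   5th-order Butterworth filter applied forward and backward
   (`scipy.signal.sosfiltfilt`), removing the gravity/DC component with zero
   phase shift. Video-derived motion (per-frame displaced-pixel counts after
   frame differencing and 3×3 median filtering) skips this stage.
2. **Instantaneous activity** is the per-sample RMS over the three filtered
   axes.
3. **Windowed index.** In 4 s windows advancing by 2 s (50% overlap), the
   index is mean × standard deviation of instantaneous activity — sustained
   activity times its variability. Windows are anchored at the trace start;
   all episode boundaries snap to this 2 s grid, which bounds boundary error
   at one step.
4. **Normalization** is affine: `norm = (raw − floor) / (baseline_mean −
   floor)`, clipped at 0, where the floor is the 1st percentile of the raw
   index over the whole recording and the baseline mean is taken over windows
   fully inside the pre-injection walking interval. Complete cessation then
   maps near 0 and the walking baseline averages exactly 1. A low percentile
   was chosen as the cessation estimator because it is robust when no true
   zero-motion segment exists; because the map is affine, the entire
   downstream pipeline is invariant to any positive gain on the raw trace.
5. **Classification.** Windows are *walking* by default. Maximal runs below
   the empirical 2.5th percentile of baseline window values (a
   distribution-free lower bound of the baseline's 95% band, chosen over a
   parametric mean ± 1.96 SD bound because the index is positive and skewed)
   lasting ≥ 60 s become *non-walking*; within those, maximal runs held below
   0.25 for ≥ 30 s become *LOM*. The 0.25 threshold applies to the
   normalized index directly; both the threshold and the two minimum
   durations are arguments. Adjacent LOM runs separated by a single
   supra-threshold window are deliberately not merged: determinism is
   preferred over emulating manual video curation.
6. **Metrics.** Latency to the first LOM episode with onset at or after the
   injection, that episode's duration, and total LOM time clipped to a 60 min
   horizon. When no LOM occurs all three are NaN, never 0.

## Burst detection and indices

A burst is a maximal run of ≥ 2 spikes whose consecutive inter-spike
intervals are all ≤ 10 ms and whose first spike is preceded by ≥ 50 ms of
silence (the first spike of a train trivially qualifies). All three
parameters are exposed; the defaults cohere with the analysis windows used by
the correlogram indices below (early peak 0–10 ms, baseline 40–50 ms, ratio
< 10 ms vs > 50 ms). Detection partitions every spike exactly into burst or
tonic, and the implementation is property-tested against an exhaustive
brute-force criterion scan.

The one-sided spike autocorrelogram uses 1 ms bins centered on integer lags
with zero-lag self-pairs excluded and raw (unnormalized) counts — the two
indices are count ratios, so normalization cancels. The *burst index*
subtracts the mean count over the 40–50 ms bins (baseline) from the maximum
single-bin count over 1–10 ms (peak; earliest lag on ties), normalizing
positive amplitudes to the peak and negative ones to the baseline, giving a
value in [−1, 1] with 0 for a flat correlogram. The *bursting ratio index* is
the total count at lags < 10 ms over the total count at lags > 50 ms
(infinity sentinel when the denominator is empty). Both are provided as
distinct operations because they answer slightly different questions (peak
shape vs mass ratio).

Per-state metrics use the summed occupied duration of each state as the
denominator: tonic rate (non-burst spikes/s), burst spike rate (spikes inside
bursts/s), burst event rate (onsets/min, an event belonging to the epoch
containing its onset), their sum (total rate), and the burst-to-total spike
ratio. A unit is *bursting* in a state when it exceeds 1 burst event per
10 min (strict inequality; configurable). States with zero occupied time are
omitted rather than reported as zero. Units are split into regular-spiking
(RS) and narrow-spiking (NS) by peak-to-valley waveform width with a strict
threshold at 250 μs (exactly 250 μs is NS).

Wake-referenced Z-scores discretize home-cage wake firing into 10 s bins
(≥ 10 bins required); the target state's overall rate is expressed in SD
units of those bins. The bin size makes the SD well defined — the analysis
this mirrors states neither a bin size nor an SD basis, so both are
arguments. Labels use the two-sided p = 0.05 bounds: increase above +1.96,
decrease below −1.96, no change between, with an explicit sentinel when the
wake SD is zero.

Peristimulus analysis histograms spike latencies around pulse onsets (1 ms
bins over ±window) and reports fidelity (fraction of pulses with ≥ 1 spike
in the post-onset window), the median first-spike latency, and its SD
(jitter).

## Stimulation protocols

Three pulse-train constructors return validated, non-overlapping protocols
starting at t = 0 of their own clock (callers shift into session time):
tonic-like regular pulses (default 50 ms inter-pulse interval = 20 Hz,
6.25 ms optogenetic pulse width), burst-like clusters (4 pulses at 4 ms
intervals = 250 Hz within the cluster, repeated every 1 s, default 100 μs
electric pulse width), and phasic ON-OFF alternation (1 s ON / 1 s OFF, 50%
duty cycle). Pulse width is always an explicit argument because the same
paradigm was driven with different widths on different hardware.

## Synthetic data

`gen_spike_train` draws, per scheduled state epoch, a tonic spike stream and
a stream of burst events, then plants each burst as 2–5 spikes with 3–5 ms
intra-burst intervals and an enforced 100 ms silent window before the onset
(tonic spikes falling in a burst's surround are removed). Both streams are
*dead-time renewal processes*: Poisson streams thinned by a minimum interval,
with the driving rate calibrated (`λ' = r/(1 − r·d)`) so the realized rate
equals the requested one. For burst onsets the dead time is one pre-burst
silence plus the longest possible burst, so bursts never collide. For tonic
spikes the dead time (default 20 ms) encodes the defining feature of
tonic-mode — and knockout — thalamic firing: the absence of short
inter-spike intervals. A memoryless tonic process would produce chance
ISI ≤ 10 ms pairs at rates that no burst detector could distinguish from real
events (about 4.6 "bursts"/min at just 3 Hz), which is neither biologically
right for tonic mode nor usable for recovery testing. The calibration breaks
down at rates approaching 1/dead-time (50 Hz at the default), where the
generator raises rather than silently under-delivering.

Default per-state parameters: burst event rates of 0.16 (wake, walk), 0.5
(REM), 5.76 (NREM) and 0.79 (fLOM/LOM) events/min — the wake, NREM and fLOM
values being the reported group means for wild-type regular-spiking
mediodorsal units, REM a low intermediate free choice — and tonic rates of
20 (walk/wake), 8 (REM), 3 (NREM), 5 (fLOM) spikes/s. The tonic rates are
free parameters chosen only to reproduce the qualitative ordering of firing
across states; no per-state absolute tonic rates are published as text.
Knockout mode forces every burst event rate to zero and changes nothing
else. Every generator returns its latent truth (burst onsets and sizes,
planted episode intervals) so downstream recovery is assertable.

`gen_motion_trace` produces a walking baseline at a stable positive level
with positive, autocorrelated fluctuations (white noise boxcar-smoothed over
0.5 s, coefficient of variation 0.3), then planted episodes at a quiescent
level defaulting to 2% of baseline (a sensor-noise floor). Accelerometer
mode spreads the scalar envelope over three axes via a slowly rotating unit
vector (carrier ≈ 3 Hz, inside the analysis passband) scaled by √3, plus a
1 g gravity offset on z, so the per-sample RMS over channels reproduces the
scalar truth exactly before filtering. What this emulates is the *contrast
structure* the mean × STD index needs (stable baseline, near-zero quiescence,
sharp transitions); what it does not emulate is real gait periodicity,
posture changes, sensor drift, or gradual sedation onset — so passing
recovery tests demonstrate correctness of the rule pipeline, not field
performance on real mice.

## Statistics layer

Rank correlation between the consciousness-ordered state code (walk 1 <
wake 2 < REM 3 < NREM 4) and firing rate uses Spearman's rho (Pearson
available as an option). Variance homogeneity uses the classic mean-centered
two-sample Levene test. Families of two-sample rank-sum (or paired
signed-rank) comparisons are corrected with Holm's step-down procedure via
`statsmodels`. The firing-feature state space (tonic rate, burst spike rate,
burst event rate; columns standardized) is embedded in 2-D with UMAP under a
fixed `random_state`, making embeddings reproducible at the cost of
single-threaded execution. Repeated-measures ANOVA is deliberately left to
standard statistical packages and carries no weight in this package's own
guarantees.

## Numerical choices and degenerate inputs

* Epochs are half-open `[start, end)`; an event exactly at an epoch end
  belongs to the next interval. All times are seconds from recording start.
* Results tables are TSV with 6-significant-digit floats; absolute event
  times (spike times, motion timestamps) are written with 10 significant
  digits because millisecond structure must survive hours into a recording.
* Degenerate cases return sentinels with diagnostics rather than silently
  producing numbers: empty burst-index windows → 0 with a warning, zero wake
  variance → undefined Z, empty ratio denominator → infinity, absent LOM →
  NaN metrics.
* Problem sizes used by the verification suites — 200 ten-minute trains per
  state for rate recovery, 50 planted-episode traces, 1000 random trains for
  the detector/oracle equivalence, 1000 replicates for Levene calibration —
  were chosen so that Monte-Carlo standard errors are small relative to the
  effects asserted while the whole suite stays interactive.

## Known limitations

* The generator's tonic process is a renewal process with a hard dead time —
  more regular than cortical Poisson-like firing and less structured than
  real thalamic discharge (no rate adaptation, no theta/spindle modulation).
* LOM scoring assumes a clean pre-injection walking baseline; a mouse that
  freezes during baseline will inflate the non-walking threshold.
* Burst detection near epoch boundaries assigns the whole event to the
  epoch containing its onset; bursts straddling boundaries contribute spikes
  to both sides' spike rates but only one side's event rate.
* The waveform-width RS/NS split uses a single fixed threshold; no
  uncertainty is attached to classifications near 250 μs.
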