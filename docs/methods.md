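# Methods

This note documents the models, estimators and numerical choices behind
`ipsckit`, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Signal conventions

IPSCs are inward currents at a −70 mV hold, but all amplitudes are stored and
reported as positive magnitudes in pA; file readers apply the declared
polarity (`sign` header) on read.  Times are seconds from record start;
analysis windows are half-open.  Continuous recordings default to 10 kHz
sampling, train sweeps to 50 kHz.

## Synthetic data: what it emulates

`simulate_trace` draws event onsets from a homogeneous Poisson process
(default 1.7 Hz — a typical spontaneous IPSC rate in juvenile cortex),
amplitudes from a Gaussian (default 30 ± 6 pA) truncated at the 5 pA quantal
analysis floor, renders each event as an exponential-activation ×
biexponential-decay waveform (rise tau 0.5 ms; decay 5/15 ms mixed 70/30,
weighted tau ≈ 8 ms), and adds white Gaussian baseline noise.  Trace events
are *deterministic* waveforms: they carry no channel-gating fluctuations, so
peak-scaled noise analysis applied to such traces correctly reports a
non-converged fit (flat variance).  Noise analysis is exercised on the
dedicated gating generator instead.

`simulate_channel_events` models a synapse with N independent channels of
unit current i.  At the aligned peak, the open count is Binomial(N, p0)
(default p0 = 1); during the decay each peak-open channel remains open at
each sample independently with probability exp(−t/tau), so the marginal open
probability is p0·exp(−t/tau) and the across-event current variance at any
decay lag obeys N p_t (1−p_t) i².  Under this model the peak-scaled residual
variance is exactly i·I − I²/(N p0) + σ_b², so the parabola fit recovers the
*mean number of channels open at the peak* — the quantity the analysis is
meant to estimate.  A fully per-sample-independent gating model (channels
re-drawn each sample with no peak conditioning) would leave peak-count
variance in the residuals and bias N by 1/(2 − 1/p0); the conditioned model
was chosen because it is the minimal generator for which the peak-scaled
procedure is consistent.  Gating is uncorrelated between samples, which is
unrealistic microscopically but irrelevant to the variance identities the
analysis uses.

`simulate_tm_sweeps` renders five-pulse trains plus a 500 ms recovery pulse
at 5/20/50/100 Hz: deterministic Tsodyks–Markram amplitudes, multiplied by
unit-mean lognormal trial noise (coefficient of variation `trial_cv`,
default 0.2), per-pulse Bernoulli failures, waveform rendering as above, and
2 pA baseline noise.  With `trial_cv = 0` the per-sweep amplitude matrix
reproduces the TM prediction to machine precision.

`simulate_blot_table` draws lane totals lognormal around 100 a.u. (CV 0.2)
and band intensities as group-mean × lane-total × unit-mean lognormal noise
(CV 0.25, eight samples per group), so the lane-corrected ratio has the group
mean as expectation and `cv = 0` gives exact fold changes.

None of the generators simulate series-resistance filtering, baseline drift,
seal instabilities, action-potential contamination or correlated noise, so
passing tests demonstrate the estimators' correctness under the stated
models, not robustness to every pathology of real recordings.

## Event detection

Pipeline: moving-median baseline subtraction (200 ms window), 0.5 ms boxcar
smoothing, `scipy.signal.find_peaks` with height = threshold (default 15 pA)
and prominence = threshold, then two merge passes — hysteresis (a later peak
is the same event unless the signal dipped below 0.4 × threshold in between)
and a 5 ms minimum interval.  Merged events are overlap-flagged, as are
events whose decay has not fallen below 20% of peak before the next event;
flagged events are excluded from decay fits and noise analysis but retained
for frequency and amplitude statistics.  The 200 ms baseline window (rather
than a shorter one) keeps the running median from riding up on the events
themselves at physiological rates; with ~30 ms events at ~2 Hz the median
bias is well under 1 pA.

**Amplitude estimator.**  Reading the current at the detected peak sample
overestimates amplitudes by several percent at signal-to-noise 5, because the
argmax selects wherever smoothed noise is largest.  Amplitudes are therefore
measured by template regression: each event window is aligned on its
mid-rise (50%) crossing — the steepest point of the waveform, whose location
is nearly noise-free — baseline-centered on its pre-rise segment, and the
per-event amplitude is the least-squares coefficient against the unit-peak
mean waveform of the non-overlapping events.  On simulated ground truth at
SNR 5 this estimator is unbiased to within ~2% (slight residual attenuation
from alignment smear); the raw peak readout remains available with
`refine_amplitudes=False`.

Rise times are 10–90% crossings by linear interpolation on the unsmoothed
baseline-subtracted signal.  Biexponential decay fits use four starts
spanning fast:slow tau ratios 1:2–1:20, bounded nonneg amplitudes, best RSS
wins with ties to the smaller slow tau; the weighted tau is asserted to lie
between the component taus on every fit.  Per-cell decay statistics follow
the convention of fitting a random subset of up to 400 clean events and
keeping fits with R² ≥ 0.5.

The default summary window is the final two thirds of the record, mirroring
the practice of discarding the first minutes of a recording while the patch
stabilizes.

## Quantal analysis

Histograms span 5–150 pA at 2 pA bins (half-open; the last bin truncated at
150).  The k-component model is fitted by variable projection: for trial
values of (q, offset, σ) the per-component bin masses are exact Gaussian CDF
differences and the non-negative weights are solved by NNLS, so the
equidistance of the means is structural, not a post-hoc constraint.  The
outer optimization multi-starts over a spacing grid of 6–26 pA and two
offset guesses (the histogram mode and q itself).  Components share a common
width by default; a σ√k mode is available, and the offset can be forced to
equal q for a strict quantal reading — both conventions appear in the
quantal literature and neither is asserted as canonical.  The component
count is chosen by BIC on the Poisson likelihood of the binned counts
(penalty `(3 + k) ln n_events`), an objective, reproducible replacement for
by-eye confirmation of fits; ties go to the smaller k.  On equidistant
mixtures with ≥ 2.5 σ separation and 2000 events the true count is selected
in ≥ 95% of seeds and q is recovered within ~1%.

## Peak-scaled noise analysis

Event matrices take 50–500 non-overlapping events (windows 10 ms before to
50 ms after the peak; per-row baseline from the pre-window excluding a 3 ms
rise guard).  Residuals are `row − mean × (row_peak / mean_peak)`, which is
identically zero at the peak column — the defining property, asserted at run
time.  The decay phase ends where the mean waveform falls below 5% of its
peak; its amplitude range is split into 25 equal-width bins (the literal
reading of "divided into 25 bins"; equal-count binning is not implemented),
empty bins dropped, and the across-event residual variance at each time
point is averaged per bin.

The parabola σ²(I) = iI − I²/N + σ_b² is linear in (i, 1/N, σ_b²) and is
solved by bounded linear least squares (i > 0, 1/N > 0, σ_b² ≥ 0);
baseline variance is fitted as a free parameter rather than pre-subtracted.
The fit is reported non-converged when the unconstrained curvature is
non-positive, statistically unresolved (below twice its standard error), or
contributes less than 10⁻³ of the mean variance across the amplitude range —
flat variance data carry no saturation information and must not yield a
receptor count.

Unitary conductance divides the fitted single-channel current by the
chloride driving force |V_hold − E_Cl| with E_Cl = −(RT/F) ln([Cl]_out /
[Cl]_in); defaults are 70 mM internal chloride (from the KCl-based internal
solution), 132 mM external (125 NaCl + 3 KCl + 2×2 CaCl₂ — chloride-bearing
salts only), 32 °C (RT/F ≈ 26.3 mV) and −70 mV, giving E_Cl ≈ −16.7 mV and
a ≈ 53.3 mV driving force.

## Short-term plasticity

Per-pulse responses are measured on 0.5 ms box-smoothed sweeps as the
baseline-subtracted maximum between the pulse and min(inter-pulse interval,
20 ms), with the baseline the median of the 2 ms before the pulse — at
100 Hz this limits contamination by the preceding, still-decaying response.
A pulse is a failure when its response is below 4 × the smoothed pre-train
baseline SD: the measurement is a maximum over ~40 effectively independent
smoothed samples, so a 3 × single-sample criterion would misclassify a few
percent of genuine responses as detections and vice versa; 4 × keeps the
false-failure rate below ~0.5% while catching true failures, whose residual
signal at these intervals is well under the threshold.  The evoked-train
policy drops sweeps containing any failure; the unitary-pair policy keeps
all sweeps and averages failures as zeros.

The TM model is fitted jointly across frequencies (equal weight per
frequency) on the normalized trains including the recovery ratio, by
multi-start bounded least squares over U ∈ (0.001, 1] and tau_rec ∈ [1, 10⁴]
ms (tau_facil optionally free); A is recovered afterwards from the mean
un-normalized first-pulse amplitude as A = amp₁/U.  A fit is flagged
non-identifiable when the trains show less than 5% depression (flat trains
constrain neither U nor tau_rec), when parameters sit at bounds, or when the
normal-equations covariance is singular.  The depression-only mode is the
default; whether the original analyses included facilitation is not
restated anywhere authoritative, so both modes exist and neither is claimed
canonical.  Normalization uses ratio-of-means across sweeps; a
mean-of-ratios variant was considered and not implemented because it is
noise-biased at small first responses.

## Immunoblot normalization

Lane correction divides each band by its lane's total-protein intensity;
WT-ratio normalization divides every lane-corrected value by the WT group
mean, making the WT mean exactly 1 and the KO mean the fold change.  Outlier
exclusion is a single pass per group at |x − mean| > 2 SD (SD with n−1;
switchable), never iterated — iterative trimming at n = 8 over-excludes.
Whether reported group means were recomputed after exclusion is ambiguous
(published WT means slightly off 1 suggest not); both orderings are
implemented, with post-exclusion renormalization the default.

## Pipeline and reproducibility

`run_pipeline` executes configured stages in order from one JSON config;
per-stage seeds derive from the master seed as CRC-32 of `"<seed>:<stage>"`
mod 2³¹, so any stage can be reproduced in isolation.  All generators use
`numpy.random.default_rng`; identical config and seed give byte-identical
output files (HDF5 datasets are written without modification-time tracking
for this reason).

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to give
stable statistics: 100–120 s traces at 10 kHz (~170–200 events) with 20
seeds for detection fidelity; 400 gating events × 10 seeds for noise
analysis; 25 sweeps per frequency × 10 seeds for TM recovery; 2000
amplitudes × 25 seeds per mixture for component selection; 300 Monte-Carlo
tables for blot unbiasedness.

## Known limitations

- The detector is a threshold/prominence design; template-matching or
  deconvolution detectors would outperform it at very high event rates or
  SNR < 3, and heavily overlapping events are flagged rather than resolved.
- The rise phase of real IPSCs is not specified by the decay model; the
  single-exponential activation used here is the minimal form with a finite
  10–90% rise time, and rise-time statistics depend on that choice.
- PSnSN assumes peak-conditioned gating and no series-resistance filtering;
  recovered N is the number of receptors open at peak, not the receptor
  complement of the synapse.
- TM fitting assumes depression dominated by resource use; strongly
  facilitating synapses need the facilitation mode and multi-frequency data
  for identifiability.
- Group comparisons (t-tests, ANOVA and friends) are out of scope: the
  package emits tidy per-cell/per-sample tables for standard statistical
  software.
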