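# Methods

`alphadrift` quantifies slow, systematic drifts of the two defining
parameters of the human alpha rhythm — peak frequency and band power —
across an experimental session, and dissects whether the two drifts are one
process or several. This note records the models, estimators, numerical
choices and their rationale. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The measurement model

Scalp EEG in the alpha band is treated as a superposition of a small number
of oscillatory generators plus 1/f background noise:

    x_c(t, i) = Σ_s  a_s(i) · m_s(t, i) · sin(2π f_s(i) t + φ_{s,i}) · w_{s,c}  +  ε_c(t, i)

for channel c, trial i, source s, with unit-norm scalp map `w_s`,
per-trial amplitude `a_s(i)` and frequency `f_s(i)`, a waxing-and-waning
within-trial envelope `m_s`, and noise `ε` with a 1/f^γ power spectrum.
Session drifts are linear in the session fraction `u = i/(N−1)`:

    f_s(i) = f0_s + Δf_s · u + jitter,      a_s(i) = a0_s · (1 + Δp_s · u)

`Δf_s` is the total frequency change over the session in Hz and `Δp_s` the
total fractional amplitude change. A source's drift class follows directly:
*mixed* (Δf ≠ 0 and Δp ≠ 0), *unique-power*, *unique-frequency*, or
*stationary*.

### Synthetic-data generator (`synthgen`)

The generator exists so that every downstream statistic can be validated by
parameter recovery against planted ground truth. Defaults describe a
session of the kind the pipeline targets: 750 trials (an ~1 h session at
700–800 trials), 60 channels, 250 Hz, 2 s epochs with a [−1, 0) s
pre-stimulus baseline, trial-to-trial frequency jitter SD 0.5 Hz, 1/f
noise with exponent 1 and unit SD. What it deliberately does **not**
emulate: artifacts (blinks, muscle), non-sinusoidal waveform shape,
volume-conduction head modelling (maps are phenomenological Gaussian bumps
on a spherical cap), and channel-correlated noise. A green recovery test
therefore establishes correctness of the estimators under the model above,
not robustness to every property of real recordings.

Design choices worth recording:

- **Burst envelope (`burst_modulation`, default 0.2).** Real alpha waxes
  and wanes; a smooth (~0.1 s kernel) multiplicative envelope reproduces
  this. It also matters statistically: a constant-envelope sinusoid is
  nearly Gaussian over time, leaving ICA's rotation weakly identified.
  Moderate modulation keeps the amplitude distribution distinctly
  non-Gaussian and distinct generators separable — mirroring why ICA works
  on real EEG. Depths ≳0.5 over-Gaussianise the mixture (envelope noise
  swamps the sub-Gaussian carrier) and degrade separation; 0.2 is the
  default.
- **Scenario presets.** `A`: one 10 Hz source with Δf = −0.25 Hz and
  Δp = +20% (the single drifting oscillator). `B`: a 9.5 Hz source with
  Δp = +30% and a dominant 11.5 Hz source with Δf = −0.30 Hz, both with
  broad (8 cm) overlapping maps so a single peak electrode sees both
  generators — necessary for the sensor-level coexistence of both drifts
  that the stratification analysis dissects. `C`: two assemblies with
  *no* frequency drift sharing one scalp map (spectrally offset
  populations in the same cortical patch, inseparable at the sensor): an
  initially dominant 11 Hz source (amplitude 2.1) and a 9 Hz source
  (amplitude 1.5) growing by +80%, so the low/high power ratio crosses 1
  mid-session and the summed-spectrum peak migrates decisively downward
  although no generator changes frequency. An early equal-amplitude
  variant of `C` produced a nearly flat summed-spectrum summit whose
  argmax was noise-dominated; the preset was redesigned so the mechanism
  it exists to demonstrate has clear margins.
- **Coupling hooks.** `amplitude_jitter_frac` gives per-trial amplitude
  variability, and `freq_power_coupling_hz` makes frequency a function of
  the realised amplitude — the "one process" world in which equalising
  power must abolish the frequency trend.
- Amplitude units are arbitrary throughout; analyses z-score or rank, so
  only ratios matter.

## Spectral split-half analysis (`spectral`)

Each 1 s baseline is Hamming-windowed, zero-padded to `fs/0.1` samples
(0.1 Hz grid) and Fourier transformed; power spectra are averaged over the
first- and second-half trials (ascending acquisition order; odd counts give
the first half the extra trial). The individual alpha frequency (IAF) is
the argmax of power within 8–13 Hz (band edges inclusive; frequency ties
take the lower bin) at the electrode with the highest mean alpha power.
Group drift tests are paired t-tests on the second-minus-first deltas, with
paired Cohen's d = mean(Δ)/SD(Δ) and a Spearman correlation between the
frequency and power deltas. A proportional-change variant divides deltas by
the first-half value.

A planted linear drift of Δf Hz/session produces a split-half delta of
Δf/2, because the two half-means sit at 1/4 and 3/4 of the session; the
recovery tests therefore report `2·Δ` as the session-drift estimate.

For component selection a second peak-extraction mode smooths the spectrum
with an 11-point, 3rd-order Savitzky–Golay filter and requires a strict
local maximum strictly inside (8, 13) Hz that also rises above the smoothed
power at both band edges; without the band-edge prominence requirement
every smoothed 1/f wiggle would count as a peak.

## Instantaneous alpha frequency (`instfreq`)

The instantaneous frequency is the temporal derivative of the phase of the
analytic signal of the band-limited waveform, scaled by `fs/2π` (forward
difference; one sample shorter than the input; samples with vanishing
envelope are NaN). Phase-slip spikes are suppressed by a bank of ten median
filters with windows linearly spaced 10–400 ms (odd sample counts), whose
outputs are combined by a pointwise median. The denoiser is an order
statistic: it cannot move an estimate outside the local range of the raw
derivative. Its 400 ms maximum window means estimates within ~0.2 s of an
epoch edge are partially determined by shrinking windows; accuracy
statements exclude 0.3 s margins.

**Band-pass realisation.** The conceptual filter is zero-phase with a flat
8–13 Hz passband and raised-cosine transition zones spanning 15% of each
edge (6.8→8 and 13→14.95 Hz). Realising a 1.2 Hz transition exactly
requires an impulse response of ~1 s, which at 2 s epochs would let edge
transients reach everywhere and smear time-varying frequency content;
conversely a ~0.4 s least-squares design carries ±20% passband ripple,
which converts frequency drift into spurious measured-power drift through
gain slope. The compromise adopted: window design (`firwin2`) of the
raised-cosine target at ~0.48 s order with a Kaiser β=3 window, scaled to
unit gain at the band centre. Realised two-pass properties (verified in the
test suite from the designed coefficients): mid-band gain within 1%,
3 Hz attenuated by ~90 dB, an 8→12 Hz chirp tracked within 0.1 Hz away
from edges. The response does sag towards the upper band edge (~0.87 at
12 Hz); a frequency drift of a source sitting above ~11.5 Hz therefore
leaks slightly into its measured Hilbert-power trend. This artifact is
inherent to any realisable band-pass of this shape and is the reason the
component-level recovery fixtures place frequency-drifting sources mid-band.

Sliding-window power uses 0.5 s Hanning-tapered segments stepped every
20 ms, zero-padded to 1 Hz resolution over 1–40 Hz; bins whose window
does not fit inside the epoch are NaN. The 20 ms output grids of the
instantaneous-frequency and power paths are identical, enabling pointwise
pairing.

## Trend statistics (`trendstats`)

Per (electrode, 20 ms bin), the trial series of a measure is correlated
with trial order by Spearman rank correlation (average ranks for ties;
constant series → NaN). Group inference on the rho maps uses a
spatio-temporal cluster-based permutation test:

- one-sample t against 0 across subjects at every sample;
- per sign, samples beyond the one-sided `cluster_alpha` (default .05)
  t-quantile form candidates; a candidate must have at least one
  suprathreshold neighbour in space (≤5 cm adjacency) *and* one in time
  (adjacent 20 ms bin) to enter a cluster; clusters are connected
  components under the combined adjacency and score the summed t;
- the null flips the sign of whole subjects' maps (2000 iterations by
  default), retaining each iteration's most extreme cluster mass per tail;
  a cluster is significant when its mass exceeds the 97.5th percentile of
  its tail's null; p-values use (b+1)/(n+1).

Two numerical conventions deserve note. First, the per-tail (rather than
two-tailed) cluster-forming threshold: with the stricter |t| threshold and
the space-AND-time neighbour rule, the null almost never forms clusters at
all, the null distribution degenerates to an atom at zero, and the
familywise error of the two-tailed decision falls to ~2.5%; the per-tail
threshold keeps null cluster formation frequent and the test calibrates at
its nominal 5% (verified by simulation in the acceptance suite). Second,
channels with no spatial neighbours at all are exempted from the spatial
requirement, so degenerate montages do not silently suppress every cluster.

The inverted-U test of the frequency–power relationship fits, per subject,
separate OLS slopes of z-scored power on z-scored instantaneous frequency
for negative and positive frequency z-values (the split at 0 is fixed by
the z-scoring), and requires opposite-signed, individually significant
group slopes. Polynomial trend fits (degrees 1–3) use OLS on a
standardised predictor; a degree is "supported" iff its highest
coefficient's 95% CI excludes zero (with a numerical-magnitude floor so a
perfect lower-order fit does not spuriously support higher degrees).

## Stratification (`stratify`)

To ask whether the frequency and power drifts are one process, the trial
distribution of one measure (baseline-averaged over [−1, 0) and all
electrodes) is equalised between session halves: 100 equal-width bins over
the pooled range; within each bin the larger half is randomly subsampled to
the smaller count, making the retained per-bin histograms identical. The
split-half spectral analysis is then recomputed on the retained trials —
the peak electrode is re-selected per iteration from the retained trials —
and averaged over (default) 100 random iterations. If the other measure's
drift survives, the two drifts are not redundant descriptions of one
process. Reported alongside: mean retained counts and the achieved
half-wise mean difference of the equalised measure in pooled-SD units.

## ICA components (`components`)

Epochs are 5–15 Hz filtered, the baselines concatenated, and an ICA
(scikit-learn FastICA after PCA reduction, default 20 components) estimates
spatial filters; the *unfiltered* epochs are projected through the filters
so component spectra retain the broadband background. Components without a
validated interior alpha peak (Savitzky–Golay criterion above) are
discarded. Anatomical dipole fitting is deliberately not implemented —
component selection is purely spectral — so component counts are not
comparable to dipole-based selections.

Per component, baseline-averaged Hilbert power and instantaneous frequency
trends against trial order get permutation z-scores and two-sided p-values
from (default) 10 000 trial-order shuffles (z uses the null's mean and SD;
p uses (b+1)/(n+1)). Classification at uncorrected α = .05: both trends
significant → *mixed*; one → *unique-power* / *unique-frequency*; neither →
*none*. Note the false-positive floor this implies: a genuinely
unique-drift component is classified *mixed* in ~5% of runs by
construction.

The drift-direction cloud over components is summarised in the
(power-z, frequency-z) plane: angles `atan2(f_z, p_z)` are tested for
non-uniformity with the Rayleigh test (z = n·R̄², Zar's p approximation) and
the circular mean gets a dispersion-based 95% CI. Because angles discard
magnitude, the centroid is additionally tested against the origin with the
T²circ statistic for bivariate (complex-valued) samples:
T² = |z̄|²/s² with s² = Σ|z_i − z̄|²/(n−1), referred to F = n·T² on
F(2, 2n−2); centroid coordinates get BCa bootstrap 95% CIs (1000
resamples). Class-wise peak-frequency comparisons use independent
two-sample t-tests, optionally on peaks recomputed from the first quarter
of trials only (excluding the drifts themselves as the source of spectral
differences).

## Runtime and test-design notes

- Simulation-based checks that pin their design (the familywise-error
  calibration: 500 cohorts × 10 subjects × 8 channels × 20 bins × 200
  trials × 500 permutations) run exactly as stated. Checks that leave the
  cohort open use reduced, session-like configurations (6–20 subjects,
  300–750 trials, 12–60 channels) chosen for CI-scale runtime; the
  reductions are noted in the test docstrings.
- Acceptance-scale cohorts are streamed subject-by-subject
  (`split_half_analysis` accepts a generator); a materialised 20-subject ×
  60-channel cohort is ~3.6 GB.
- Component-label recovery is scored per (source, reseed) pair; with
  uncorrected 5% tests, requiring all labels jointly correct per reseed
  would fail even a perfect implementation (expected joint rate
  ≤ 0.95² × detection²).
- The permutation RNG, ICA seed and all generator draws derive from
  user-supplied seeds; identical (config, seed) reproduce results bitwise.

## Known limitations

- The band-pass gain slope near the band edges converts large frequency
  drifts of edge-adjacent sources into small apparent power trends
  (quantified above); sensor-level FFT analyses are unaffected (they are
  unfiltered).
- The 0.1 Hz spectral grid quantises IAF deltas; single-subject split-half
  deltas are multiples of 0.1 Hz, and recovery accuracy statements hold for
  cohort means.
- Rayleigh and T²circ treat components as exchangeable; components from
  the same subject are correlated in real data, so those p-values are
  anti-conservative there (full-cohort analyses of real data share this
  property).
- `ft_stratify`-style histogram equalisation matches distributions only up
  to bin resolution; the achieved mean difference is reported rather than
  assumed zero.
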