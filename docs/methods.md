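# Methods

This note documents the analysis conventions, the simulator model, the
numerical choices, and the known limitations of `autoregkit`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal-processing conventions

**Units and grids.** Time in seconds, pressures in mmHg throughout. PEEP
values are configured in cmH2O and converted with the physical constant
1 cmH2O = 0.7355 mmHg where a pressure is needed. Raw ABP/ICP waveforms are
expected near 100 Hz, the DCS flow index near 1 Hz; all derived channels
live on one 5 Hz grid.

**MAP and CPP.** Systolic/diastolic pressures are per-window extrema over
non-overlapping 2-s windows (≥ 2 cardiac cycles at the heart rates the
simulator emits), held to the waveform grid. MAP uses the clinical
2/3 diastolic + 1/3 systolic rule; CPP = MAP − ICP, never clipped.

**Alignment and down-sampling.** The common origin is the latest channel
start; channels must overlap for at least half of the longest channel span.
Channels faster than 5 Hz are block-averaged (boxcar) over each 0.2-s
output interval — for the ≤ 0.06 Hz analysis band this doubles as an
anti-aliasing filter; slower channels (DCS) are held constant between
samples. 10-s binning is left-aligned and non-overlapping with the trailing
partial bin dropped: partial bins would re-admit the respiratory/cardiac
content binning exists to suppress.

**Quality control.** DCS samples are rejected when |z(β)| > 0.5 (z over the
whole recording) *or* β < median(β) − 0.01; both rules run because the
instability signature includes both fluctuation and depression of β. The
rejection propagates to co-timed flow-index samples before binning; after
binning, 10-s CBF means with |z| > 2 are rejected. All threshold
comparisons are strict (> not ≥), and a zero-variance series is assigned
z = 0 so constant inputs reject nothing. The β baseline-flow reference for
ΔCBF is the mean over the first 60 s of unmasked samples.

## Static CA (Lassen curve)

Per subject, quality-controlled 10-s flow-index means are averaged within
half-open 1-mmHg CPP bins [k, k+1); a bin with no data is missing, never
zero-filled. Normalization (v → (v − m)/m, m the unweighted mean over
non-missing bins) operates on the raw flow-index bin means, so the
normalized curve is a dimensionless fractional deviation with exact zero
mean. Group curves are unweighted per-bin means across subjects; the SD is
reported only where ≥ 2 subjects contribute (a one-subject group average
equals that subject's curve with missing SD).

**Plateau estimation.** The LLA/ULA estimator fits a continuous
three-segment piecewise-linear model — rising arm, flat middle (slope
pinned to 0), rising arm — by exhaustive search of breakpoint pairs on the
1-mmHg bin grid with an exact least-squares solve of the three remaining
linear parameters per candidate; arm slopes are constrained ≥ 0 by refit.
Ties in residual break toward the narrower plateau, so a globally linear
(pressure-passive) curve collapses to width ≈ 0 and is flagged degenerate
(width < 10 mmHg). The search is O(bins²) with a 3-column solve per
candidate: negligible for the ≤ 150-bin curves this package produces.

**Group tests.** The Mann–Whitney rank-sum test uses midranks and the
exact permutation distribution of U whenever the combined sample is ≤ 20
(every label assignment enumerated; two-sided p = P(|U − n₁n₂/2| ≥
|U_obs − n₁n₂/2|)), and the tie-corrected normal approximation otherwise.
To avoid pseudo-replication the test consumes per-subject means of
CPP/MAP/ICP, not pooled samples; the pooled histograms are descriptive
only.

## Pseudo-dynamic CA (PRx)

MAP, ICP and CPP are reduced to 0.1 Hz by 10-s block means (this mean *is*
the smoothing of the underlying traces; no separate moving average is
applied first). PRx windows are 5 min long (30 points) on a 60-s sliding
step — the window length is canonical, the step is a package choice since
"moving" implies overlap; both are configurable. Windows with missing
points or zero variance in either channel are skipped and counted. Window
correlations pool across subjects of a group into 150 half-open CPP groups
of exactly 180/150 = 1.2 mmHg over [0, 180); out-of-range windows are
dropped and counted. Group means use the Fisher-Z transform
(tanh(mean(atanh r))), with |r| clipped at 1 − 1e-12 first because
noise-free fixtures legitimately reach ±1; the group SD stays on the r
scale. Windows spanning protocol-segment boundaries are kept, matching a
whole-recording PRx.

## Dynamic CA (phase lag)

**Filter design.** For each protocol frequency f₀ ∈ {0.009, 0.017, 0.025,
0.033, 0.059} Hz a linear-phase (odd-length, type-I) equiripple bandpass is
designed at 5 Hz. The protocol frequencies sit as little as 0.008 Hz
apart, and the phase estimate is only meaningful if each filter rejects
every *other* protocol frequency and DC; the band edges are therefore
derived from the spacing: passband half-width hw = min(0.03, f₀/2, 0.35·d)
and transition width 0.55·d, where d is the distance to the nearest other
protocol frequency. This keeps stopband edges strictly inside the
neighbouring frequency while the passband still covers the ~1/T main lobe
of a 4-cycle segment. Parks–McClellan (Remez) design is attempted first; if
the exchange iteration fails to converge at these extreme band ratios, a
Kaiser-window design with the same edges is substituted. Either way the
result is validated against the specification — gain within 1% at f₀,
≤ 0.01 (−40 dB) at DC and at every other protocol frequency — and designs
run to 905–2935 taps (3–10 min of impulse response at 5 Hz), which is why
phase analysis requires recordings of at least three filter lengths.

**Phase extraction.** The *same* filter is applied once to both channels
(centered convolution; the symmetric linear phase cancels exactly in the
subtraction), the analytic signal is built over the whole series (FFT
padded to a fast length), and the per-segment delay is the circular
(unit-vector) mean of the unwrapped instantaneous phase difference over the
segment minus one oscillation cycle at each end, where the filter rings.
Delays are mapped to (−180°, 180°]; magnitudes are median analytic
envelopes over the same window, and a delay whose envelope falls below a
0.5 mmHg noise floor is flagged unreliable and excluded from group
statistics. Within-subject repeats (same frequency, different ICP
baselines) are circularly averaged first, then subjects are circularly
averaged into the group mean with circular SD √(−2 ln R) — arithmetic
averaging of wrapped angles is simply wrong near ±180°.

## The simulator

`synthetic_data` is a lumped-parameter model stepped at 100 Hz whose only
purpose is to emulate the *measurement situation*: two anesthesia groups
with known autoregulation state, the induced-oscillation protocol, and
realistic noise. All stochastic draws come from one seeded generator, so
identical configurations are bit-reproducible.

State equations (per step, Δt = 10 ms):

1. **Systemic pressure.** MAP_sys = baseline (optionally ramped) +
   0.2·(low-passed ICP, τ = 60 s) [slow Cushing-type response] +
   0.25·(ICP − ICP₀) [fast mechanical transmission] + 2.0·ΔPEEP
   (mmHg/cmH2O) + Ornstein–Uhlenbeck fluctuations (SD 3 mmHg, τ = 60 s).
   The fast transmission term exists because a purely low-passed coupling
   would impose a ~70° lag on the ABP response to ICP oscillations,
   contradicting the near-zero lag a passive preparation shows; a fast
   component (upstream pressure rises as the cerebrovascular bed is
   compressed) is the physiologically plausible resolution.
2. **Static flow target.** A piecewise-linear Lassen shape (plateau 1.0
   between LLA = 60 and ULA = 100 mmHg, slopes 0.02 and 0.01 per mmHg
   below/above) blended with the pressure-passive proportional line through
   the 80 mmHg plateau point: curve(g) = g·intact + (1−g)·passive, with
   g = `ca_gain`.
3. **Vascular tone.** The radius implied by the target flow
   (Poiseuille: R ∝ r⁻⁴, so r_target = (anchor·CBF_t/(CBF₀·CPP))^¼,
   additionally divided by the passive-compliance factor raised to g so
   that intact steady-state flow equals the target exactly) is tracked
   through the *complement of a third-order Butterworth high-pass* at
   f_c = 0.03 Hz: the regulator follows every pressure component it can and
   leaves the high-passed residual unregulated. A first-order relaxation at
   the same cutoff was rejected because its atan(f/f_c) phase lag (17–30°
   at 0.009–0.017 Hz) would forbid the flat ≈180° antiphase plateau that an
   intact preparation demonstrably produces below cutoff; the third-order
   complement has near-zero phase error in the regulated band and the same
   cutoff semantics. With g = 0 the target is constant and tone stays
   frozen. A small instantaneous passive compliance (5·10⁻⁴ fractional
   radius per mmHg CPP) distends vessels with pressure.
4. **ICP.** A reservoir state equilibrates toward the protocol set-point
   (baseline staircase 3–40 mmHg plus 5 mmHg oscillation segments) with
   τ = 5 s; blood-volume coupling adds elastance·(CBV − CBV_buffered) with
   CBV ∝ r² and elastance 80 mmHg per unit fractional CBV. The buffer
   tracks CBV with τ = 180 s: slow volume loads drain through the open
   reservoir (CSF displacement), fast ones raise ICP — without this the
   staircase would be distorted by steady-state CBV shifts of tens of mmHg.
5. **Outputs.** CBF = CPP·r⁴/R₀. The emitted ABP waveform adds a skewed
   cardiac pulse (half-sine systole, 30 mmHg peak-to-trough at 2 Hz) whose
   beat extrema satisfy MAP = 2/3·dia + 1/3·sys *exactly* — a pure
   sinusoid would bias the estimated MAP by −amplitude/3 (≈5 mmHg) and
   shift every CPP-keyed result — plus respiration (0.25 Hz, 1.5 mmHg) and
   white noise. ICP adds sinusoidal pulsatility, slow OU sensor noise
   (0.2 mmHg, τ = 20 s) and white noise. The DCS index is
   α·D_b = α·D_b₀ · CBF/CBF₀ at 1 Hz with 5% multiplicative noise;
   β = 0.5 ± 0.003, and optional Poisson laser-instability events
   (5–30 s) depress β by ≥ 0.05 with high-variance jitter while corrupting
   the flow index with 50% noise. Vitals (heart rate, ETCO2 ≈ 38 mmHg with
   slow drift) are logged at 2 samples/min.

**Group presets.** "fentanyl" = intact (g = 1, ABP baseline 95 mmHg, CPP
spanning the plateau across the ICP staircase); "isoflurane" =
pressure-passive (g = 0, ABP baseline 72 mmHg, CPP mostly 40–75 mmHg),
mirroring the hypotensive, vasodilated deep-volatile-anesthesia state. The
Grubb exponent (0.38) is carried as a reference parameter only; the
simulator's volume–flow coupling is the geometric Poiseuille/cylinder
mapping, which near the plateau implies a much smaller volume-per-flow
exponent — a documented divergence, acceptable because no analysis in this
package consumes the exponent.

**Problem sizes.** The validation suite and the acceptance script use
desk-scale versions of the study: 5 subjects per scenario, one or two ICP
baselines, 1400–3600 s per recording (phase scenarios must exceed three
filter lengths ≈ 1760 s), chosen as the smallest sizes at which the
group-level contrasts are stable across seeds. The 100 Hz loop is
numba-compiled when available and falls back to pure Python (~0.16 M
steps/s) transparently.

## What the synthetic validation does and does not show

The simulator reproduces the *mechanistic couplings* the three indices are
built on (tone-mediated CBV antiphase, passive transmission, Lassen
plateau) with realistic noise floors, so passing tests demonstrate that the
pipelines recover known ground truth through the full raw-data path —
waveforms in, group statistics out. They do not demonstrate performance on
real neuromonitoring data: real ABP/ICP have non-sinusoidal pulsatility
with harmonics, slow drifts and artifacts the generator does not emulate
(probe displacement, suction events, drug boluses), real CA has
distributed, nonlinear and CO2-dependent dynamics rather than a single
cutoff, and real DCS noise is heavier-tailed than the multiplicative model
used here. The QC thresholds are exercised by the injected β-artifact
model only.

## Known limitations

* The plateau estimator assumes exactly one flat segment; curves with a
  tilted plateau or two quasi-linear regimes resolve to whichever
  three-segment fit has lower residual, and only the width flags
  degeneracy.
* PRx windows that straddle oscillation segments are kept (whole-recording
  convention); segment-restricted PRx is available by filtering markers
  upstream but is not the default.
* Phase analysis needs long recordings (≥ 3 filter lengths); short
  protocols at 0.009–0.033 Hz are rejected rather than estimated badly.
* The exact rank-sum enumeration is O(C(n, n₁)) and is capped at combined
  n = 20 before switching to the tie-corrected normal approximation.
* `estimate_beat_pressures` is a windowed-extrema stand-in, not a beat
  detector; it is accurate for the simulator's waveforms and for any
  waveform whose systole/diastole dominate 2-s windows.
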