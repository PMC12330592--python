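# Methods

This note records the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## Electrode model (`synth_electrode`)

The synthetic electrochemical cell is a Randles circuit: solution
resistance R_s in series with a charge-transfer resistance R_ct in
parallel with a constant-phase element Z_CPE(ω) = 1/(Q·(jω)^α),
0 < α ≤ 1.  The Randles form is a modelling choice for generating test
inputs with known ground truth, not a claim about any particular
electrode chemistry; α = 1 (ideal double-layer capacitor) is the
default because every pipeline oracle has a closed form there.

*Impedance spectra* are evaluated exactly:
Z(ω) = R_s + R_ct / (1 + R_ct·Q·(jω)^α).  |Z| → R_s as f → ∞ and
|Z| → R_s + R_ct at DC.

*Voltage transients* integrate the interface state with the exact
piecewise-constant-current exponential update per sample.  For α < 1
the interface branch is replaced by a 5-element series Foster RC
ladder, fitted by non-negative least squares to the branch impedance
over the stimulation band with 1/|Z| row weighting so the fit
minimizes relative error (≤ ~10% across three decades at α = 0.8).
This keeps the spectra faithful without fractional-calculus machinery.

Default transient sampling is 1 MHz so the 0.6 ms pulse edges occupy a
single sample, matching the near-instantaneous access-voltage step the
isolation procedure assumes.  Additive Gaussian measurement noise is
off by default and seeded when enabled.

The default pulse protocol is a burst of 5 cathodic-first biphasic
charge-balanced pulses, 0.6 ms per phase, 200 μs interphase gap, at a
500 Hz within-burst pulse rate (the period must exceed the biphasic
pulse itself).  A zero-amplitude train is accepted as a null-stimulus
probe.

## Stimulation characterization (`cic`)

The pipeline follows the standard transient-isolation recipe:

1. first derivative by finite central differences (one-sided at the
   endpoints; exact for quadratics);
2. edge detection at local extrema of |dv/dt| above an adaptive
   threshold of 10× the median absolute derivative of the pre-pulse
   baseline.  Two robustness guards: the threshold is never below 5% of
   the global derivative peak (slow intra-pulse charging must not
   cross it), and supra-threshold runs closer than half the interphase
   gap are merged (noisy post-edge RC transients land within a few
   samples of the true edge).  A biphasic pulse with a gap yields 4
   edges; the expected count is checked against the pulse descriptor;
3. E_ipp = mean of the pre-pulse baseline (≥ 10 samples), subtracted;
4. the access voltage at each edge is the step between the samples at
   ±1 sample (configurable guard) around the edge — the interface
   polarization is continuous across an edge, so the step is the Ohmic
   i·R_s term.  The cumulative steps are subtracted and the smeared
   guard samples held at the pre-edge level, leaving V_μE;
5. E_mc = min(V_μE), E_ma = max(V_μE); compliance is the closed
   interval window.lower ≤ E_mc ∧ E_ma ≤ window.upper against the
   PEDOT:PSS water window (−0.9 to +0.6 V by default);
6. the amplitude ramp stops at the first non-compliant amplitude;
   Q_inj = I·pw_c/GSA at the last compliant amplitude, in mC/cm².

Accuracy: each edge step absorbs one sample of interface drift, about
2Δt/τ of I·R_ct.  At the default 1 MHz sampling and τ ≥ 0.3 ms, the
recovered access voltage and the V_μE extrema agree with closed-form
RC charging to well under 2%; the residual after a 20-edge burst stays
under 2% of the V_μE swing.  Faster cells (τ ~ 0.1 ms) approach that
bound.  Analysis is performed on one burst; the reported cathodic and
anodic access voltages follow the cathodic-first convention
(configurable through the pulse descriptor).

Known discrepancy: for a 20 μm disc at 50 μA and 0.6 ms the formula
gives Q_inj = 9.549 mC/cm²; a published figure of 8.754 mC/cm² for a
comparable electrode implies an effective GSA or pulse width that is
not stated.  The toolkit implements the formula as defined.

## Electrode analytics (`eis`)

R = |Z|·cos(θ·π/180) with capacitive phase negative (cos is symmetric
in the sign, so either convention works).  Nearest-frequency lookup
tolerates 1% relative grid mismatch.  Population SD is the sample
(n−1) estimator, matching how measured electrode populations are
reported.  "Working channel" has no standard definition; the default
criterion is |Z|@1 kHz within [1 kΩ, 1 MΩ] and is configurable.  The
deposition cutoff is density × π(d/2)² with the integer report
truncated toward zero.  Note that 20·log₁₀(150 μV/3.382 μV) ≈ 32.9 dB;
the SNR formula is implemented exactly as defined, and claims of
~75 dB for those inputs are not reproducible from it.

## Optics (`optics`)

Transmission through a layer stack is the product of (1 − R) over
successive interfaces at normal incidence, with optional Beer-Lambert
absorption.  Multiple partial reflections (Fabry-Perot etalon
interference) are deliberately excluded — a simplification appropriate
for incoherent broadband illumination — so predicted improvements
(e.g. replacing an air interface with water/CSF) are upper-bound
estimates relative to coherent treatments.

Optical access is 1 − blocked/window area.  Features live in
millimeters with the origin at the window center; circles (electrodes,
trace caps) are 64-gon approximations (area error < 0.2% of each
feature), traces are buffered polylines with flat caps, tapers are
explicit polygons (whether published blocked-area figures counted
tapers separately is unknowable, so they are first-class features
here).  The union is computed exactly with shapely and clipped to the
window; the denominator is the analytic disc area.  Traces narrower
than a configurable threshold can be neglected — thin (~10 μm) traces
are effectively transparent when imaging below them — and access is
monotone non-decreasing in that threshold.  Exact published access
percentages for fabricated arrays are not reproducible because the
actual trace routing is not published; the geometry engine is instead
validated against a Monte-Carlo rasterization oracle (10⁶ uniform
points, agreement within 3 binomial SE).

Spectrometer processing: T(λ) = (sample − dark)/(reference − dark),
with all readings linearly interpolated onto the sample grid and
wavelengths where the reference does not exceed the dark reading
masked with a warning.

## Mechanics (`mechanics`)

Effective modulus is the thickness-weighted (Voigt) average — for the
250 μm PDMS (2 MPa) + 10 μm Parylene C (2.8 GPa) design stack,
109.62 MPa, in the range of native dura.  Flexural rigidity uses the
transformed-section method with E/(1−ν²) plane-strain weighting about
the computed neutral axis; it reduces to E·t³/(12(1−ν²)) for one layer
and matches brute-force through-thickness integration to ~1e−9
relative on random stacks.

Center deflection of the clamped, uniformly loaded circular laminate
solves the Föppl interpolation

    P = (64D/R⁴)·w₀ + (8·E_eff·t/(3(1−ν_eff)·R⁴))·w₀³

for its unique positive root, with ν_eff thickness-averaged.  The
cubic stretching term extends validity beyond w₀ ≈ t, where the design
stack operates at CSF pressures (1–10 mmHg).  This is an analytic
small-strain surrogate, not a hyperelastic FEM: absolute deflections
are design-stage estimates, and only orderings (thicker stiff layer ⇒
smaller deflection) and the small-pressure plate limit
w₀ = PR⁴/(64D) are asserted.  Assumed Poisson ratios: PDMS 0.49,
Parylene C 0.40.

## Synthetic recordings (`synth_ephys`)

Background is Gaussian noise shaped to a 1/f^1 power spectrum
(configurable slope), 50 μV RMS per channel by default, plus 60/120/180
Hz line components (5 μV at 60 Hz, harmonics falling as 1/k, random
phase per channel).  Optional artifacts are decaying exponentials at
≥ 10 background SD to exercise the rejection rule; off by default.
Sessions are bit-reproducible from the mandatory seed.

Evoked effects are additive band-limited Gaussian components gated to
event-locked windows.  The component is calibrated against the band
measure itself: its re-filtered, in-window power is scaled to
(multiplier − 1) times the channel's own background band power, so the
expected task/baseline band-power ratio equals the multiplier despite
the spectral leakage a rectangular gate introduces.  Spike trains are
Poisson with a 1 ms refractory hold-off; the biphasic template
(trough-dominant, 1.4 ms) is scaled so its peak-to-trough amplitude is
σ_b·10^(SNR_dB/20), with an error if the requested SNR exceeds the
clip limit.

What the generator does **not** emulate: volume conduction and
inter-channel correlation, nonstationary background, behavioral
variability, spike-LFP coupling, electrode drift.  Passing tests
demonstrate that the statistics recover what was planted under the
stated noise model — they do not certify performance on real
recordings with correlated noise.

## Analysis pipeline (`ephys`)

Power convention: band-pass, then sum of squares over duration in
seconds (a unit in-band sinusoid gives ≈ f_s/2 regardless of length).
Filters are zero-phase (forward-backward) Butterworth, 4th order for
band/high-pass; the 250 Hz LFP anti-alias low-pass is 8th order
because a 4th-order forward-backward skirt only reaches ~14.5 dB one
fifth of an octave above the cutoff, short of the ≥ 20 dB wanted
before decimation to 1 kHz.  Notches are IIR, Q = 30.  Band names
carry both gamma conventions in use (behavior: 30–70 Hz; stimulation
analysis: 30–59 and 60–150 Hz); no reconciliation is imposed.

Spike detection thresholds at −6× a robust background SD
(median(|x|)/0.6745, insensitive to the spikes themselves) after
250 Hz high-pass filtering, with trough alignment and a 1 ms
refractory hold-off.  A_spike defaults to the peak-to-trough amplitude
of the mean waveform (configurable to trough depth).  Sorting is
K-means on the first 3 principal components of the aligned waveforms,
seeded for determinism.

Statistics: paired t-tests across trials (task vs baseline windows,
half-open [start, end) in seconds relative to event timestamps, which
are authoritative), two-sample t-tests for pre/post designs, and
one-sample plus paired t-tests for the block design (signals
normalized to the first baseline period, artifact samples zeroed and
the power duration reduced accordingly).  Multiple-comparison control
is Bonferroni across channels within each analysis at FWER 0.05; no
hierarchical correction across analyses.  Artifact "normalized signal"
is z-scored per analysis period (the normalization window is
configurable).  Multitaper spectrograms use DPSS tapers with
time-bandwidth 3 and 5 tapers; z-scoring is per frequency row against
the baseline-interval windows of the trial average.  Heatmap
interpolation is linear barycentric on the layout positions.

## Problem sizes

Statistical validations run on sessions generated at 500 Hz (LFP-band
content only; Nyquist 250 Hz) rather than a 30 kHz raw rate, a choice
that changes nothing about the band-power statistics below 250 Hz:
planted-effect recovery uses 32 channels × 800 trials; family-wise
error calibration uses 200 null replicates of 16 channels × 20 trials;
spike-train validations stay at 30 kHz (60 s, 5 Hz rate).  The
Monte-Carlo optics oracle uses 10⁶ points per layout.

## Known limitations

- The transient pipeline assumes edges are single-sample relative to
  the interface time constant; heavily smoothed acquisitions need a
  wider edge guard.
- The Foster ladder is fitted over the stimulation band only; CPE
  behavior far outside that band is not matched.
- The membrane model has no residual stress term and no hyperelastic
  stiffening; it is for design comparison, not FEM replication.
- t-tests treat per-trial band powers as approximately normal; with
  very few trials (< 10) the block and map procedures lose calibration.
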