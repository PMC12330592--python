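# durakit

A characterization and analysis toolkit for transparent micro-ECoG
(μECoG) surface electrode arrays of the kind built into silicone
artificial-dura implants for non-human-primate electrophysiology.  It
covers the four quantitative questions that qualify such a device:

1. **Can it record?**  Electrochemical impedance spectroscopy (EIS)
   analytics: electrode impedance Z = V_ref / I_C, Johnson thermal noise
   V_rms = √(4 k_B T R Δf) with R = |Z| cos θ, theoretical SNR
   20 log₁₀(V_signal / V_noise,rms), impedance population statistics,
   electrodeposition charge cutoffs, and channel yield.
2. **Can it stimulate safely?**  Voltage-transient analysis of
   charge-balanced biphasic pulse bursts: isolation of the
   electrode–electrolyte interface voltage V_μE from the raw trace
   (removing the polarization bias E_ipp and the Ohmic access steps V_a),
   water-window compliance of E_mc/E_ma, and the charge-injection
   capacity Q_inj = I·pw_c / GSA from an amplitude ramp.
3. **Can you see through it?**  Normal-incidence Fresnel reflectance
   ((n₁−n₂)/(n₁+n₂))², incoherent multilayer transmission, spectrometer
   dark/reference/sample processing, and exact polygon-union accounting
   of the window area blocked by opaque metal features.
4. **Does it move with the brain?**  Bilayer laminate mechanics: Voigt
   effective modulus, composite flexural rigidity, and the center
   deflection of a clamped circular membrane under CSF-range pressure.

Because no public recordings exist for this device class, the package
ships two first-class synthetic generators with complete ground truth —
a Randles-cell electrode simulator (`synth_electrode`) and a
trial-structured multichannel LFP/spike generator (`synth_ephys`) — and
an analysis pipeline (`ephys`) implementing the standard in-vivo
recipes: LFP extraction (250 Hz low-pass, 60/120/180 Hz notches,
decimation to 1 kHz), −6 SD threshold spike detection with K-means
sorting and empirical SNR A_spike/σ_b, band-power change maps with
paired t-tests and Bonferroni correction, z-scored multitaper
spectrograms, artifact rejection at 10 SD, and the block-design and
pre/post-stimulus statistical procedures.

## Worked example

Simulate a PEDOT-like electrode (R_s = 10 kΩ, R_ct = 20 kΩ, τ = 0.3 ms)
driven by the standard burst of 5 charge-balanced biphasic pulses
(0.6 ms phases, 200 μs interphase gap) at 50 μA, then run the
stimulation characterization:

```sh
durakit simulate-electrode --rs 10e3 --rct 20e3 --cap 1.5e-8 \
    --amplitude 50e-6 --seed 1 --out demo
durakit cic --trace demo/transient.csv --window pedot --diameter 20
```

which writes `demo/transient.cic.json`:

```json
{
  "eipp_v": 0.0,
  "va_cathodic_v": 0.5066444937449657,
  "va_anodic_v": 0.5095942082239074,
  "emc_v": -0.8580202230184253,
  "ema_v": 0.7958898543111188,
  "compliance": {
    "compliant": false,
    "margin_low": 0.041979776981574735,
    "margin_high": -0.19588985431111883
  },
  "qinj_mc_per_cm2": 9.54929658551372
}
```

Reading: the recovered access voltage (≈0.507 V) matches the planted
I·R_s = 0.5 V to ~1%; the interface excursion reaches −0.858 V/+0.796 V,
so at 50 μA this synthetic electrode exceeds the PEDOT:PSS water window
(−0.9 to 0.6 V) on the anodic side and a lower amplitude is needed; at
50 μA and 0.6 ms a compliant 20 μm disc would inject
Q_inj ≈ 9.55 mC/cm².  `durakit eis summarize --freq 1000 --in
demo/spectra.csv` reports the same cell's 1 kHz impedance (16.6 kΩ) and
its thermal-noise floor over a 30 kHz bandwidth (2.67 μV_rms).

The optical and mechanical design numbers are one-liners:

```python
>>> from durakit.optics import fresnel_reflectance
>>> 100 * fresnel_reflectance(1.64, 1.00)   # Parylene C | air
5.88...
>>> 100 * fresnel_reflectance(1.64, 1.33)   # Parylene C | water (CSF)
1.09...
>>> from durakit.mechanics import PDMS, PARYLENE_C, effective_modulus
>>> effective_modulus([PDMS(250.0), PARYLENE_C(10.0)])   # MPa
109.615...
```

## Layout

```
src/durakit/
  synth_electrode.py   Randles-cell simulator (EIS spectra, transients)
  eis.py               impedance analytics, noise, SNR, yield, cutoffs
  cic.py               transient isolation and charge-injection capacity
  optics.py            Fresnel/stack transmission, optical access
  mechanics.py         bilayer modulus, rigidity, membrane deflection
  synth_ephys.py       ground-truth LFP/spike session generator
  ephys.py             LFP/spike pipeline and paradigm statistics
  cli.py               the `durakit` command-line entry point
docs/methods.md        model assumptions, parameter choices, limitations
```
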