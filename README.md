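# zeobench

A synthetic model system for benchmarking fluorescence bioimaging.

Comparing fluorescent probes, staining protocols and microscopes across
labs is hard because every result is entangled with local hardware,
settings and analysis. A practical way out is a fully reproducible
benchmark sample: lanthanide(III)-doped Linde Type A zeolite particles
dispersed in a dye-stained polyvinyl-alcohol (PVA) film. The dyed film
provides a homogeneous "stain" with broad emission; the zeolites carry
Eu³⁺ or Tb³⁺ ions whose uniquely narrow f–f emission lines make them
spectrally unmistakable fiducials.

`zeobench` implements that benchmark entirely in software, for people who
analyze (or plan) such experiments:

* a **synthetic scene generator** emulating the model system — a 10 × 10
  pixel, 5 × 5 µm raster scan at 1 s/pixel, four laser lines
  (465/488/560/633 nm) imaged in four quadrants around one zeolite,
  shot + read noise, and per-dye photobleaching kinetics;
* **virtual filter channels**: any bandpass emission filter is emulated by
  integrating the per-pixel emission spectra over its transmission window;
* the **two-pixel fluorescent-signal statistic** with background
  subtraction from a dye-free reference sample, and contrast;
* **crosstalk analysis**: cross-excitation spectra and emission
  bleed-through matrices over (dye × excitation × channel), with flags
  where an off-target pairing outshines a channel's designated dye;
* **photobleaching analysis**: windowed traces, min–max normalization,
  bi-exponential decay fits, fraction-lost metrics;
* packaged **photophysical constants** for F18 (an octadecanoyl
  fluorescein), MitoTracker Red, ATTO647N, Eu³⁺ and Tb³⁺.

## The core quantities

For an emitter with quantum yield *QY* and molar absorptivity *ε(λ)*,

* **brightness** B(λ) = QY · ε(λ)  [M⁻¹cm⁻¹],
* **photon-budget ratio** of emitter a over b:
  (B_a/B_b) · (τ_b/τ_a), with τ the excited-state lifetime,
* **fluorescent signal**: net = signal pixel − mean(background pixels),
  reported as mean ± sd over (by default two) pixels,
* **bleach trace**: I(t) = Σᵢ aᵢ·exp(−t/τᵢ) + b, fit by bounded nonlinear
  least squares.

The forward model behind every simulated pixel is linear:
background + Σ_species k · c · ε(λ_exc) · QY · P · t · bleach(t) ·
shape(λ), with the emission long-pass filter of each laser line applied
as a hard cutoff.

## Worked example

```bash
python examples/brightness_and_photon_budget.py
```

prints

```
Brightness at the designated laser lines (M^-1 cm^-1):
  F18              @ 488 nm :    6.923e+04
  MitoTracker Red  @ 560 nm :    2.355e+04
  ATTO647N         @ 633 nm :    6.728e+04
  Eu               @ 465 nm :      0.01924
  Tb               @ 488 nm :      0.01917

Per-molecule photon-budget advantage, F18@488 over Eu@465: 3.6e+11

Film molarity ratio F18 : MitoTracker Red = 1500
```

F18 and ATTO647N are ~70 000 M⁻¹cm⁻¹ bright at their laser lines and
MitoTracker Red ~23 000, while the directly excited lanthanides sit near
0.02 — yet on a real microscope their measured intensities end up the
same order of magnitude, which is exactly the kind of discrepancy the
benchmark exposes. `examples/crosstalk_matrix.py` shows the flip side of
unequal loading (150 µM F18 vs 0.1 µM red dyes):

```
Bleed-through flags (off-target pair brighter than designated):
  channel TexasRed : F18@465 nm (6758 a.u.) exceeds MitoTracker Red@560 nm (1220 a.u.)
  channel TexasRed : F18@488 nm (50431 a.u.) exceeds MitoTracker Red@560 nm (1220 a.u.)
```

i.e. the F18 emission tail in the red channel beats the red dye's own
designated signal — a false-positive hazard in co-localization — while
the Cy5 channel stays clean (only ATTO647N@633 dominates there).
`examples/bleaching_kinetics.py` reproduces the photobleaching ranking
(F18 loses ~75 % of its intensity within 10 s; MitoTracker Red's signal
is essentially gone by 40 s; ATTO647N survives toward 100 s), and
`examples/filter_channels.py` and `examples/wavelength_calibration.py`
cover channel images/contrast and neon-line wavelength calibration.

A thin CLI wraps the same library surface:

```bash
zeobench simulate --seed 1 --out-dir out/      # full pipeline
zeobench brightness --dye F18 --excitation 488
zeobench channels --cubes out/manifest.json --filterset chroma --out table.tsv
```

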