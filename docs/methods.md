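# Methods

## The model system being emulated

The benchmark sample is a thin polyvinyl-alcohol film stained with one or
more fluorophores, carrying micron-scale Linde Type A zeolite particles
whose exchangeable cations host Eu³⁺ or Tb³⁺. The film dyes have broad
emission bands; the lanthanide ions emit sharp f–f lines (ms-scale
excited-state lifetimes), so zeolite pixels are spectrally identifiable
and serve as fiducials and instrument benchmarks. Imaging is raster-scan
confocal with a spectrometer behind a pinhole: a full emission spectrum
per pixel, 10 × 10 pixels over 5 × 5 µm, 1 s dwell. Four laser lines —
465 nm (2 µW), 488 nm (7.2 µW), 560 nm (1.2 µW), 633 nm (2.9 µW) — are
used in four separate quadrants around one zeolite, whose centre sits at
a corner of each image so the shared region is imaged four times while
each film area is only exposed once.

## Forward model

Expected counts per wavelength sample at a pixel:

    I(λ) = background + Σ_species k · c · ε(λ_exc) · QY · P · t · bleach(elapsed) · shape(λ)

* `c` — stain concentration in µM (defaults 150 µM F18, 0.1 µM
  MitoTracker Red, 0.1 µM ATTO647N), or for a zeolite pixel the dopant
  loading (5 × 10⁵ µM-equivalent by default: local lanthanide
  concentrations in an exchanged zeolite are of order 1 M; the constant
  also absorbs the unknown collection efficiency) times an annular
  weight — 1 within 0.5 µm of the particle surface, 0.25 in the core —
  which renders the bright-rim/dark-centre appearance of doped particles.
* `ε(λ_exc)` — tabulated molar absorptivity at the four laser lines;
  elsewhere eps_max × a peak-normalised excitation shape.
* `k` — global scale constant mapping the arbitrary photophysical units
  to pseudo-counts; default 1.0. Intensities are arbitrary units
  throughout; no detector-efficiency correction is applied anywhere.
* `shape(λ)` — unit-area emission density (below).
* The emission long-pass filter paired with each laser line is a hard
  cutoff on the *emitted* light: nothing below 539 nm for the 465/488 nm
  lines (the 532 nm long-pass becomes transparent around 539 nm), below
  566 nm for 560 nm, below 652 nm for 633 nm. The last two edges are
  package choices for the corresponding commercial long-pass filters.
  The detector-side `background` (default 2 counts/sample) is unfiltered.

Noise is Poisson on the expected counts followed by additive Gaussian
read noise (σ = 1 count). Stored counts are *not* clipped at zero:
clipping the read noise would bias replicate means upward, and
offset-subtracted CCD counts do dip below zero. Raw `EmissionSpectrum`
objects are nonnegative by contract, so the bleach-series generator clips
its (high-count) frames at zero; the bias there is negligible.

## Emission and excitation shapes

Dye emission uses the log-normal peak function of Siano & Metzler
parameterised by mode, FWHM and asymmetry ρ (red/blue half-width ratio):
F18 517 nm / 35 nm, MitoTracker Red 598 nm / 45 nm, ATTO647N
664 nm / 50 nm, all with ρ = 1.4. The peaks are the packaged emission
maxima; widths and asymmetry were chosen once to mimic typical
fluorescein/rhodamine/carborhodamine bands. Lanthanide emission is a sum
of 8 nm-FWHM Gaussian lines at the standard transition positions — Eu³⁺
592/616/650/700 nm (616 dominant, the ⁵D₀→⁷F₂ line; the packaged
constant uses the tabulated 616 nm although 615 nm also appears in the
literature), Tb³⁺ 490/544/585/620 nm (544 dominant). In-zeolite relative
line intensities are not published; the shipped ratios are plausible
defaults and configurable. Excitation shapes are broad blue-tailed bands
for the dyes and narrow lines for the lanthanides whose relative heights
reproduce the tabulated laser-line absorptivities.

## Band integration

Filters are ideal top-hats (constant in-band transmission, zero
outside). Integration is trapezoidal on the stored grid with window
endpoints snapped by linear interpolation of the integrand, implemented
as a quadrature weight vector; this makes integrals exactly additive
over adjacent windows and lets channel images be computed as a single
matrix–vector product, identical by construction to per-pixel
integration. The default wavelength grid is 400–820 nm at 1 nm; the
spectrometer's true range is instrument-specific, and 820 nm covers the
817 nm upper limit used in the bleaching analysis windows.

## Bleaching

Each dye bleaches bi-exponentially, `a₁e^(−t/τ₁) + a₂e^(−t/τ₂) + b`,
with shipped defaults F18 (0.7, 4 s, 0.3, 25 s, 0), MitoTracker Red
(0.5, 7 s, 0.5, 15 s, 0) and ATTO647N (0.5, 7 s, 0.5, 40 s, 0),
calibrated once to the qualitative behaviour of these dyes under
continuous illumination: F18 loses ~70 % of its intensity in the first
10 s and levels out at the background; the two red dyes lose ~50 % in a
fast 5–10 s component, MitoTracker Red is essentially gone by ~40 s and
ATTO647N survives toward 100 s. Lanthanide ions do not bleach in the
model.

Scans apply the bleach factor at each pixel's *own* exposure: a
point-scanning confocal only illuminates a pixel during its dwell, and
the quadrant scheme exists precisely to keep imaged regions fresh.
Setting `SceneConfig.cumulative_scan_bleaching = True` instead advances
the bleach clock by 1 s per raster pixel (a continuous-illumination
worst case). Single-pixel bleach series always accumulate exposure at
the frame interval.

The decay fit is bounded nonlinear least squares (lmfit/MINPACK) with
fixed, documented initialisation for determinism: τ guesses log-spaced
over (t_max/50, t_max/2), equal amplitudes sharing the observed dynamic
range, baseline at the trace minimum plus 1 % of the range — strictly
inside the bounds, because the bound transform has zero gradient exactly
at a bound and would silently freeze the fit. Components are reported
sorted by increasing τ. Fits should be run on *raw* traces (the constant
detector background is absorbed by the baseline); a min–max normalized
trace lies slightly outside the nonnegative-baseline model class (its
true baseline is negative by the subtracted minimum), so normalization
is used only for presentation and for fraction-lost metrics, whose
reference I(0) is the first recorded frame.

## Signal statistics and classification

The fluorescent signal subtracts the mean of (by default two) background
pixels — taken at the same positions in a scan of a dye-free reference
sample — from each of two signal pixels; mean and sample standard
deviation (n−1; for n = 2 this is |net₁−net₂|/√2) of the nets are
reported. Default signal pixels are the two film pixels geometrically
farthest from any zeolite; without scene knowledge a data-driven
fallback takes pixels farthest from the brightest pixel of the
total-intensity image. Which pixels a real analysis would pick is a free
choice, so the selector is fully overridable.

Zeolite/film classification computes max(spectrum − running median over
a 31 nm window) / total integrated intensity and labels a pixel
`zeolite` above 0.05 (units 1/nm). Window and threshold are package
choices: 31 nm comfortably brackets the 8 nm lines while sitting inside
the ≥ 35 nm dye bands, and 0.05 sits between the statistic of pure line
spectra (≈ 0.06–0.07) and pure dye bands (≤ 0.03, including the sharp
long-pass truncation edges). Accuracy degrades monotonically as line
width approaches dye width, which the property suite checks.

## Crosstalk

Single-dye scenes are scanned at all four lines; the background-
subtracted mean film spectrum per excitation gives the cross-excitation
panel, and channel integration gives the bleed-through matrix. Each
channel's designated pair (FITC ← F18@488, TexasRed/mCherry ←
MitoTracker Red@560, Cy5/ATTO647N ← ATTO647N@633) is compared against
every off-target entry; ratios clip negative (noise-dominated) nets to
zero and carry a flag. With the default unequal staining the F18 tail
dominates the red channels — the benchmark's central cautionary result —
while the far-red channels remain specific to ATTO647N.

## Packaged filter sets

"edmund": FITC 539–556, TexasRed 604–644, Cy5 672–712 nm; "chroma":
FITC 539–550, mCherry 593–667, ATTO647N 669–741 nm. The green windows
start at 539 nm (not the kits' nominal 513/500 nm) because the 532 nm
long-pass in the emission path only opens there.

## What the synthetic data does and does not capture

The generator reproduces the *structure* of the experiment — geometry,
excitation plan, filter physics, concentration/brightness/power
linearity, shot and read noise, bleaching kinetics — so the analysis
code can be validated against known ground truth, and qualitative
orderings (which dye wins which channel) are meaningful. It does not
model the point-spread function or diffraction (pixels are independent),
film thickness or focal depth, detector spectral efficiency,
self-quenching or pH effects at high dye loading, or the true in-zeolite
line ratios. Absolute simulated intensities are therefore not
comparable to any particular instrument's counts, and passing tests say
nothing about PSF-limited resolution or absolute radiometry. Notably,
real measured intensities correlate poorly with brightness × loading —
that mismatch is the benchmark's point, and the simulation reproduces
its mechanisms (bleaching, crosstalk, window truncation) only to the
extent they are modelled.

## Numerical and design choices

* Wavelength axes are strictly increasing; windows partially outside the
  axis integrate over the intersection; empty intersections warn and
  return zero rather than raising.
* Diagonal profiles use the integer main diagonal of square images
  (matching 10 × 10 data); non-square input raises.
* Lifetimes not tabulated anywhere (MitoTracker Red 1.8 ns, ATTO647N
  3.5 ns, Tb³⁺ 1.5 ms) are typical literature-scale values,
  configurable; only F18 (≈5 ns) and Eu³⁺ (≈0.5 ms) enter the headline
  photon-budget arithmetic.
* All randomness flows from a single integer seed; identical
  configuration + seed gives bit-identical cubes and byte-identical
  pipeline tables.
* Pipeline and test problem sizes are the experiment's own: 10 × 10
  pixel scans, 100-frame bleach series, 10–20 seed replicate studies.

## Known limitations

* The factor (~300) by which zeolite dopant loading may favour the
  lanthanides over a 150 µM film stain is a documented constant of the
  system description, not something the package derives.
* The classifier is per-pixel spectral only; no spatial segmentation.
* No spectral unmixing: species are identified by windows and narrow
  peaks, as in a filter-based experiment.
* Crosstalk is quantified, not corrected; compensation/unmixing is out
  of scope.
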