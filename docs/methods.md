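# Methods

This note documents the models, parameter choices and numerical decisions
behind `colortsfg`, and what the synthetic-data tests do and do not
establish about real data.

## Signal model

Pulses are Gaussian in time, `I(t) = (I0/√2π)(T/τ) exp(−t²/2τ²)`, with τ
the Gaussian σ (all user-facing FWHM values are converted on input via the
factor 2√(2 ln 2); the reference configurations use 240 fs FWHM for the
pump and 140–180 fs for the OPO/OPA). Time-integrating the cubed
intensity per period gives the single-beam law `(T/τ)² P³`; the
mixed-beam integrals give the `9√3 T²/(τ₁τ₂√((τᵢ/τⱼ)²+2)) Pᵢ²Pⱼ` law.
The combinatorial factor 9 is the squared multinomial weight of drawing
(2,1) photons from two distinguishable fields; for identical beams the
TSFG/THG rate ratio is exactly 9, which the tests confirm against
brute-force numeric overlap integrals.

The delay factors `exp(−Δ²/(τᵢ²+2τⱼ²))` are the closed forms of the
Gaussian overlap integrals `∫I₁²(t)I₂(t−Δ)dt` (and the mirror case),
normalized to zero delay. They are not taken from any printed source;
they are derived for Gaussian pulses and locked in by an oracle test that
integrates the pulse products numerically on a fine grid (agreement to
1e-6 relative over Δ ∈ [−500, 500] fs).

Signals are monotonically decreasing in every pulse duration that enters
a channel; a single-beam channel is exactly flat in the other beam's
duration. The claim that mixed signals are maximized by *equal* durations
holds only under specific constraints (e.g. fixed τ₁τ₂ product) and is
deliberately not asserted.

### Resonant susceptibility

The resonant χ⁽³⁾ is a product of three detuning factors with one-, two-
and three-photon transition energies and dephasing rates. The microscopic
numerator (number density × four transition dipoles / ħ³) is collapsed
into a single non-negative amplitude, because only |χ⁽³⁾|² is observable
here. Defaults:

| parameter | oxy | deoxy | rationale |
| --- | --- | --- | --- |
| 3P transition (emission) | 415 nm | 430 nm | Soret band positions |
| γ_da | 0.12 rad/fs | 0.12 rad/fs | see below |
| 1P/2P transitions | 4.54 / 4.60 rad/fs | same | far from the 1.0–1.5 rad/fs excitation band, so the 3P factor dominates |
| amplitude | normalized to unit peak | same | arbitrary units; only ratios are meaningful |
| non-resonant χ⁽³⁾ (cell) | 0.05 | 0.05 | small real background |

γ_da = 0.12 rad/fs was chosen, together with the 0.05 background, so that
the closed-form on/off-resonance signal ratio of a default oxygenated
cell (1240 vs 1120 nm excitation, single-beam THG) lands mid-range of the
observed 10–20× enhancement window; this was computed analytically from
the susceptibility before any image was rendered. A possible two-photon
contribution to the deoxy spectrum is left off by default (its amplitude
is not quantified); the parameters are exposed for users who want it.

Partial oxygenation mixes the two resonant terms linearly,
χ(s) = χ_nr + s·χ_res,oxy + (1−s)·χ_res,deoxy, which follows from the
additivity of χ⁽³⁾ in species concentration.

## Synthetic scenes

THG/TSFG contrast is interface-localized; the generator represents this
phenomenologically: each object contributes a one-pixel boundary shell
weighted by |χ_object − χ_surround|², and hemoglobin-filled cytoplasm
additionally radiates an interior term (weight 0.5) proportional to the
squared resonant part, since the resonant enhancement appears throughout
hemoglobin-rich areas. No phase-matching/Green's-function field
computation is performed — mixed-beam signals are treated as harmonic
generation at a shifted wavelength, which matches the observed similarity
of THG and TSFG contrast at these wavelengths and numerical apertures.

Geometry is conventional morphology: human RBC = 7.5 µm disc (the
biconcave dimple is not modeled; the footprint is what the analysis
sees); zebrafish RBC = 11×7 µm ellipse with a 5×3 µm central nucleus
carrying only non-resonant χ⁽³⁾ (hence a wavelength-flat nucleus signal).
Embryonic trunk vessels are straight tubes of 4 µm radius — barely wider
than the cells — with non-resonant walls (χ = 0.15).

Motion: the scan acquires rows sequentially (row time = pixels-per-row ×
dwell), so a cell moving along the fast axis is sheared across the rows
it spans; pulsatile arterial flow modulates speed sinusoidally (default
amplitude 0.5, period 0.5 s) through an analytically integrated
displacement. Default train speeds (213.7/107.3 µm/s for artery/vein) are
slower than peak embryonic systole so that shear stays a fraction of a
cell length and neighbouring cells remain resolvable; they are chosen
non-commensurate with round frame intervals so the wrapped cell train
samples many lumen positions across a time series. Cells wrap around the
field (period = width + 2×6 µm margin), emulating continuous flow past a
fixed field of view at constant census; ground-truth masks use the same
rasterizer, so scoring is self-consistent.

Photometry: expected counts = dwell × detection efficiency ×
signal_intensity with the local |χ|². The calibration scalar anchors an
oxygenated-cell boundary pixel in the 433 nm channel of the reference
configuration at ~2×10⁶ photons/s, the observed per-cell signal scale;
absolute χ magnitudes are arbitrary and only ratios are meaningful.
Detection efficiencies default to 1.0 except the UV-side channels (0.5 at
~373 nm, 0.3 at ~348 nm, reflecting reduced optics transmission). The
pump power of the reference pair defaults to half the OPO power: the
mixed channels grow faster with power, and attenuating the pump balances
the simultaneous channel levels while keeping the brightest pixels below
the photon pile-up bound (1 detected photon per 4 pulses). Pile-up is
flagged, never corrected — the model is pure Poisson counting.

Randomness: one integer seed per render; Poisson streams are split per
(frame, channel) with the channel keyed by its canonical identity, so the
order of channels in a set does not change the draws.

Depth: z-stacks scale the surface frame by (P₁(z)/P₁)ⁿ¹(P₂(z)/P₂)ⁿ²·
exp(−3z/EAL) per channel before Poisson sampling.

What the generator does *not* emulate: optical PSF blur (an isotropic
Gaussian can be added but is off), chromatic focal mismatch across the
field (available as an optional radial efficiency falloff, default off),
fluorescence channels, mosaic tiling, detector afterpulsing, and
biconcave shading. Passing tests therefore demonstrate correctness of the
analysis chain under Poisson statistics and the stated contrast model,
not robustness to optical artifacts absent from the model.

## Spectroscopy

Images are normalized by their power/duration factors — ×τ²/P³ for
single-beam harmonics, or division by the full channel-specific mixing
factor — so normalized values are proportional to |χ⁽³⁾|². Both options
exist because either convention is defensible for mixed-beam scans; the
default spectrum extraction uses the single-beam factor of the scanned
beam. Spectra are means over a region mask with per-pixel standard
deviations; an optional background region's median is subtracted first.
Default scan steps are 10 nm (oxygenated) and 20 nm (deoxygenated, to
halve acquisition time before cells reoxygenate).

## Segmentation

Enhancement variants: (S₄₀₁+S₄₃₃)/S₃₇₃ (default), (S₄₀₁+S₄₃₃)−S₃₇₃,
S₄₀₁−S₃₇₃, and the deep-imaging variants S₄₄₀/(S₄₀₂+S₃₇₀), S₄₄₀−S₄₀₂.
Ratio denominators carry ε = 1 count against division blow-ups in the
weak 373 nm channel. The vessel mask thresholds the time maximum
projection and fills small holes; the RBC mask restricts the map to the
vessel, Gaussian-smooths (σ = 1 px), thresholds, then applies a 3×3
morphological closing and removes components under 9 px. Thresholds
default to Otsu's method — automatic and parameter-free — with an
absolute override; the original processing may have used manual
per-dataset thresholds, and this divergence is intentional. The
"dilation–erosion" cleanup is implemented as closing + small-object
removal, consistent with its stated purpose of removing isolated pixels.
Note that with Otsu, a lone extreme pixel in an otherwise empty map is
still detected (any automatic threshold must); the minimum-size rule
removes isolated noise whenever genuine signal sets the threshold scale.

Scoring is pixel-wise (precision/recall/Jaccard) and object-wise (greedy
one-to-one centroid matching within 3 µm); components below the
pipeline's own 9-px detection size are excluded from both sides of the
object match.

## Oximetry

R is the slope of S₄₀₁ against S₄₃₃ over a cell's segmented pixels,
through the origin by default (with background removed, zero signal at
433 nm implies zero at 401 nm); a free intercept and pixel weighting are
available but off. Cells need ≥5 pixels. Frame summaries average per-cell
R; window summaries divide by the control-window median, so the control
value is 1 by construction. Group comparisons use Welch's
unequal-variance t test (two-tailed); the degenerate zero-variance
equal-mean case returns p = 1. The cross-subject mixed-effects analysis
of repeated hypoxia assays is out of scope; per-run Welch tests and
descriptive summaries are provided instead.

The default sealed-chamber schedule holds saturation at 1 for 30 min,
decays exponentially toward a floor of s = 0.72 over 2.5 h (time constant
= one third of the sealed period), and steps back to 1 at reopening. The
floor was chosen from the closed-form R(s) mixing curve so that the
normalized R drop at full hypoxia is ~40%, the typical observed drop
after 3 h; it was fixed before any stochastic test was run.

## Depth attenuation

The fit is linear least squares of log(S/P³) against z with slope
−3/EAL; the exponent 3 is fixed by the photon order (a joint fit of the
order exists for diagnostics only). Per-plane powers may be scalars
(both beams stepped together) or (P₁, P₂) pairs, in which case the
channel's process orders give the factor P₁ⁿ¹P₂ⁿ². Slopes above −1e-6/µm
are reported as EAL = ∞ (no measurable attenuation); planes with
non-positive summaries are excluded with a warning, and fewer than four
usable planes is an error.

The per-plane summary defaults to the 99th-percentile pixel value — a
robust bright-structure statistic on dark backgrounds — computed after a
3×3 uniform pre-filter. The pre-filter matters: upper quantiles of raw
Poisson count images are inflated by shot noise by an amount that varies
with the signal level, which biases the fitted slope by several percent;
averaging a few neighbouring pixels is linear (the summary still scales
exactly with the plane's signal) and suppresses the inflation. S₀ is
fitted per channel, not per structure.

Stitching of successive power-stepped sub-stacks normalizes each plane by
its power factor, concatenates in z and averages overlapping planes;
gaps wider than 1.5 z-steps are an error.

## Problem sizes

The default test/demo problem sizes are deliberately desk-scale: 128×256
px fields (64×128 µm at 0.5 µm/px), 30-frame time series, 14-plane
z-stacks, ~18 cells per frame, 20-seed recovery studies, ≥100 cells per
saturation level. They are large enough for the recovery claims made
(e.g. EAL within 5%, enhancement within 10%) and small enough to run the
whole suite in well under a minute of rendering time.

## Known limitations

- The contrast model is phenomenological; absolute signal levels and the
  boundary/interior weighting are calibrated, not derived from field
  propagation.
- R is a relative oxygenation index; no absolute SO₂ calibration is
  attempted, and the s ↦ R map depends on the default resonance
  parameters.
- Enhancement-map thresholds are automatic (Otsu); highly unbalanced
  scenes may need the absolute-threshold override.
- Signal reabsorption by overlying blood, laser noise, and vectorial
  focal fields are not modeled.
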