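# colortsfg

Forward modeling and image analysis for **color third-order sum-frequency
generation (TSFG) microscopy of red blood cells** — a label-free nonlinear
imaging modality in which two overlapped femtosecond pulse trains
(λ₁ ≈ 1045 nm, λ₂ ≈ 1300 nm) generate four simultaneous third-order
signals whose emission wavelengths straddle the Soret absorption band of
hemoglobin. The three-photon resonance with that band makes red blood
cells (RBCs) dramatically brighter than non-resonant tissue structures,
and the oxy/deoxy shift of the Soret peak makes the signal ratio between
channels a label-free reporter of RBC oxygenation.

The package is aimed at microscopists and image analysts who want to
simulate, understand, or process this kind of multichannel χ⁽³⁾ data: it
provides the physical forward model, a seeded synthetic-image generator
with ground truth, and the full analysis pipeline (spectral
normalization, ratiometric segmentation, oximetry, depth-attenuation
correction).

## The model

**Wavelength mixing.** Beams at λ₁, λ₂ emit third harmonics at λ₁/3 and
λ₂/3 plus two sum-frequency signals at 1/(2/λ₁+1/λ₂) and 1/(1/λ₁+2/λ₂).
For 1045/1300 nm these are 348, 373, 401 and 433 nm.

**Power/duration dependence.** For Gaussian pulses of average power P,
duration τ (σ of the intensity profile) and repetition period T,

    S_THG  ∝ (T/τ)² ⟨P⟩³
    S_TSFG1 ∝ 9√3 T² / (τ₁τ₂ √((τ₁/τ₂)² + 2)) ⟨P₁⟩² ⟨P₂⟩
    S_TSFG2 ∝ 9√3 T² / (τ₁τ₂ √((τ₂/τ₁)² + 2)) ⟨P₁⟩ ⟨P₂⟩²

with an inter-pulse-delay factor exp(−Δ²/(τᵢ²+2τⱼ²)) for the mixed
channels (THG channels are delay-independent).

**Resonant susceptibility.** χ⁽³⁾ = χ⁽³⁾_nr + χ⁽³⁾_res with

    χ⁽³⁾_res ∝ A / {[(ω_da−3ω) − iγ_da][(ω_ca−2ω) − iγ_ca][(ω_ba−ω) − iγ_ba]}

The three-photon transition ω_da sits at the Soret band: emission 415 nm
for oxyhemoglobin, 430 nm for deoxyhemoglobin. A mixed oxygenation state
s ∈ [0,1] mixes the two resonant terms linearly (χ⁽³⁾ is additive in
number density).

**Analysis.** "Enhancement" maps such as (S₄₀₁+S₄₃₃)/S₃₇₃ isolate
resonant contrast for vessel/RBC segmentation; the per-cell slope
R = S₄₀₁/S₄₃₃ (regression through the origin over the cell's pixels)
reports oxygenation; power-stepped z-series are fitted with
S = S₀·P³·exp(−3z/EAL) to estimate the effective attenuation length and
renormalize deep stacks.

## Worked example

```python
import numpy as np
from colortsfg import mix_wavelengths, scenes, segmentation, oximetry

channels = mix_wavelengths(1045, 1300)
print("emission lines (nm):",
      {c.label: round(c.emission_wavelength) for c in channels})

beams = scenes.reference_beams()                  # 1045/1300 nm, 80 MHz
detected = channels.subset(["TSFG1", "TSFG2", "THG2"])
spec = scenes.embryo_scene(seed=1)                # two vessels, ~18 RBCs
stack = scenes.render_timeseries(spec, beams, detected, n_frames=30,
                                 frame_interval=300.0, seed=1)

seg = segmentation.segment_timeseries(stack)
truth = scenes.ground_truth_masks(spec, times=stack.plane_positions)
score = segmentation.score_segmentation(seg, truth, pixel_size_um=0.5)
print(f"object recall {score['object_recall']:.3f}, "
      f"precision {score['object_precision']:.3f}, "
      f"vessel Jaccard {score['vessel_jaccard']:.3f}")

result = oximetry.timeseries_R(stack, seg)
print(f"mean R over {len(result.table)} frames: "
      f"{result.table['mean_R'].mean():.2f} "
      f"(sd {result.table['mean_R'].std():.2f})")
```

Output:

```
emission lines (nm): {'THG1': 348, 'TSFG1': 373, 'TSFG2': 401, 'THG2': 433}
object recall 1.000, precision 1.000, vessel Jaccard 0.911
mean R over 30 frames: 4.20 (sd 0.04)
```

The emission lines are the four simultaneous signals of the 1045/1300 nm
pair (the 348 nm harmonic is poorly transmitted by standard optics and is
not used by the analysis). Every flowing cell in the 30-frame series is
detected against ground truth, and the frame-averaged oxygenation
parameter R is stable to ~1% for fully oxygenated cells — deoxygenated
cells give a several-fold lower R.

A command-line interface mirrors the library:

```bash
colortsfg simulate --seed 1 --out ts.tif
colortsfg segment ts.tif --recipe ratio_sum --sigma 1.0 --min-size 9
colortsfg oximetry ts.tif --control 0:30
colortsfg depthfit zstack.tif --summary p99 --channel all
colortsfg run --config run.yaml --seed 1 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `colortsfg.physics` | wavelength mixing, power/duration/delay laws, resonant χ⁽³⁾ |
| `colortsfg.scenes` | seeded synthetic frames, time series, z-stacks + ground truth |
| `colortsfg.stack` | the `ImageStack` container (pixels + acquisition metadata) |
| `colortsfg.spectroscopy` | power/duration normalization, excitation spectra |
| `colortsfg.segmentation` | Enhancement maps, vessel/RBC masks, scoring |
| `colortsfg.oximetry` | per-cell R, time courses, Welch tests |
| `colortsfg.attenuation` | EAL fits, z-stack renormalization and stitching |
| `colortsfg.io` / `colortsfg.cli` | TIFF+sidecar I/O, run configs, workflows, CLI |

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
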