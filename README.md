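# condyn

Quantitative imaging analysis for nuclear protein condensates: FRAP
(fluorescence recovery after photobleaching) kinetics, two-channel
colocalization statistics with a rotation-randomized control, and
condensate/fiber morphology metrics — together with a synthetic-data
generator that emulates the underlying microscopy, so the entire pipeline
can be exercised and validated without any external data.

The package is aimed at cell biologists and image analysts studying
liquid–liquid phase separation (LLPS) in the nucleus: proteins such as
MPRIP form micrometre-scale condensates and actin-associated fibers whose
liquid-like character is assayed by FRAP mobility, whose association with
nuclear lipid structures (e.g. PIP2-rich islets) is assayed by
pixel-intensity colocalization, and whose shape phenotypes (diffuse /
condensed / fibrous) and fiber thickness are measured from confocal and
STED images.

## What it computes

**FRAP** (`condyn.frap`). An ROI-mean intensity trace is corrected for
general acquisition photobleaching against an unbleached reference region,

```
corrected(t) = target(t) / ( reference(t) / mean(reference_pre) ),
```

then normalized full-scale, f(t) = (F(t) − F₀) / (F_pre − F₀), so the
pre-bleach mean maps to 1 and the first post-bleach frame to 0. Recovery is
fitted by nonlinear least squares to

```
single:  f(t) = A (1 − e^{−kt})
biexp :  f(t) = A₁ (1 − e^{−k₁t}) + A₂ (1 − e^{−k₂t}),  k₁ > k₂
```

with half-times t½ = ln 2 / k, mobile fraction = plateau (ΣAᵢ), and model
choice by small-sample-corrected AIC. For diffusion-dominated recovery in a
circular bleach spot of radius r, the diffusion coefficient follows the
uniform-disk (Soumpasis) relation

```
f(t) = e^{−2τ/t} [ I₀(2τ/t) + I₁(2τ/t) ],   τ = r² / 4D
D ≈ 0.224 · r² / t½
```

with I₀, I₁ modified Bessel functions of the first kind.

**Colocalization** (`condyn.coloc`). Per cell, under a nuclear mask:
Manders split coefficients (M_A = fraction of channel-2 intensity where
channel 1 is above threshold, and conversely M_B) and Spearman rank
correlation. The randomized control rotates one channel 90°, preserving
each channel's texture while destroying spatial correspondence; real and
randomized groups (≥ 5 cells) are compared with a two-sided Student's
t test, flagged at p ≤ 0.05 (\*) and p ≤ 0.007 (\*\*).

**Morphology** (`condyn.morphology`). Otsu segmentation of condensates
with per-object area, equivalent diameter and circularity (4πA/P²);
multi-scale tubeness (Sato) detection of curvilinear fibers with thickness
measured as the full width at half maximum (FWHM) of intensity profiles
perpendicular to the skeleton; and a rule-based classifier of the three
overexpression phenotypes from ridge- and condensate-area evidence.

**Synthetic data** (`condyn.simulate`). Seeded generators for FRAP movies
(explicit finite-difference reaction–diffusion with reflective boundaries
and an immobile pool, or well-mixed exchange kinetics with exactly
(bi)exponential recovery), the closed-form disk-recovery oracle,
two-channel spot-pattern pairs with a controllable truly-colocalized
fraction, and the three phenotype image classes — each emitted with its
ground truth.

## Worked example

```python
from condyn import (frap_config_for_design, simulate_frap_movie,
                    process_movie, fit_single_exponential,
                    diffusion_coefficient)

cfg = frap_config_for_design("full", seed=42, noise_sd=0.05)
movie, truth = simulate_frap_movie(cfg)          # 1020-frame movie, 23 ms/frame
curve = process_movie(movie, cfg.bleach_roi)     # corrected + normalized
fit = fit_single_exponential(curve)
print(f"half-time      : {fit.half_times[0]:.2f} s   (truth {truth.half_times[0]:.2f} s)")
print(f"mobile fraction: {fit.mobile_fraction:.3f}  (truth {truth.mobile_fraction:.2f})")
d = diffusion_coefficient(fit.half_times[0], cfg.bleach_roi.radius)
print(f"diffusion coeff: {d:.3f} um^2/s (uniform-disk relation)")
```

prints

```
half-time      : 3.59 s   (truth 3.60 s)
mobile fraction: 0.600  (truth 0.60)
diffusion coeff: 0.140 um^2/s (uniform-disk relation)
```

The "full" design bleaches a 3 µm-diameter circle covering a whole
condensate; the recovered half-time (~3.6 s) and mobile fraction (~60%)
characterise molecular exchange between condensate and nucleoplasm, and the
uniform-disk relation converts them into an effective diffusion
coefficient. The other designs (`inner`, `nucleoplasmic`, `fiber`) cover
the 1 µm inner-condensate, 6 µm nucleoplasmic and 0.5 µm fiber bleach
geometries; fiber recovery is bi-exponential (a fast free-diffusion
component plus a slower fiber-bound component).

A full demo pipeline — simulate movies for all four designs, fit them,
run a colocalization experiment and classify phenotype images — runs in
seconds:

```sh
condyn run --seed 1 --out demo_run
```

and writes per-curve CSVs, fit JSONs, a condition-level summary table, a
manifest with output hashes, and a plain-text report.

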