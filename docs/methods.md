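# Methods

This note documents the models behind `condyn`, the choices made where the
experimental literature leaves the procedure open, and what the synthetic
data do and do not establish about real microscopy.

## FRAP model

A FRAP experiment here is a movie of `n_pre` pre-bleach frames, `n_bleach`
bleach frames and `n_post` post-bleach frames at a fixed frame interval
(defaults 10 / 10 / 1000 at 0.0232 s, matching a resonant-scanner confocal
protocol). The fluorophore population is split into a mobile and an
immobile pool; during each bleach frame both pools inside the bleach ROI
are scaled by `1 − bleach_depth` (default 0.206 per frame, i.e. ~90%
cumulative over ten frames — the instrument's true bleach depth is rarely
reported, and the full-scale normalization removes any dependence on it).
Imaging itself bleaches the whole field: every acquired frame is scaled by
`exp(−acq_bleach_rate · t)`.

### Two kinetic regimes in the generator

* **Diffusion kinetics.** The mobile pool evolves by the 2-D diffusion
  equation, discretized with an explicit scheme built from a flux-form
  five-point Laplacian. The flux form conserves total intensity to machine
  precision and implements reflective (zero-flux) boundaries, representing
  a closed nucleoplasm; conservation is a tested invariant (relative drift
  < 1e−9 with noise off). The scheme is sub-stepped with an integer number
  of steps per frame so that each step satisfies dt ≤ 0.5·h²/(4D) — half
  the formal stability bound, for accuracy; a configuration that would need
  more than 10⁵ sub-steps per frame is refused with an explanatory error
  rather than run badly.

* **Exchange kinetics.** The bleached region relaxes toward the level of an
  effectively infinite surrounding reservoir as a sum of one or two
  exponential components. This is the reaction-dominant limit of FRAP
  (binding/unbinding or exchange much slower than mixing), and it is the
  regime in which recovery is *exactly* (bi)exponential — the model family
  the fitting stage assumes. Condensate-exchange FRAP with single- or
  bi-exponential empirical recovery is the standard description for
  nuclear condensates, so parameter-recovery validation uses this mode: the
  generator's half-times and mobile fraction are the ground truth the
  fitted values are compared against. The diffusion mode cannot serve that
  purpose: an exponential fitted to the closed-form uniform-disk recovery
  misestimates the half-time by ~25% for the full-FRAP window (a model-
  mismatch bias, not a fitting defect), which is why the closed-form oracle
  is compared against the *simulation* directly instead.

Four named bleach-ROI designs mirror the experimental geometries:
full (3 µm diameter, covering a whole condensate), inner (1 µm, inside a
condensate), nucleoplasmic (6 µm) and fiber (0.5 µm). Their reference
recovery regimes, used as simulation ground truth, are single-exponential
t½ = 3.6 s / 60% mobile (full), 1.6 s / 85% (inner), 0.5 s / 96%
(nucleoplasmic), and bi-exponential 0.2 s + 1.6 s with 45% mobile split
0.25/0.20 fast/slow (fiber).

### Curve processing

Acquisition bleaching is corrected by dividing the target trace by a
same-nucleus unbleached reference trace normalized to its own pre-bleach
mean. A shared multiplicative decay cancels exactly up to one constant
factor — the mean reference decay over the pre-bleach phase — which the
subsequent normalization removes; the corrected *normalized* curve is
therefore identical to the bleach-free case. A reference trace that
*increases* over time (slope > 3 standard errors) triggers a warning, since
it suggests the reference region overlaps the recovering bleached area.

Normalization is full-scale: f(t) = (F(t) − F₀)/(F_pre − F₀) with F_pre the
pre-bleach mean and F₀ the first post-bleach value, so f is exactly 1 over
the pre-phase mean and exactly 0 at the first post-bleach frame, and the
fitted plateau is directly the mobile fraction on a 0–1 scale.
Bleach-phase frames are excluded; time zero is the first post-bleach
acquisition. Equal pre-bleach mean and first post-bleach value means no
bleach was achieved and is an error. An optional annular "coast" band at
the ROI boundary is available for quantifying recovery at the interface
with the unbleached surround.

### Fitting

Nonlinear least squares (`scipy.optimize.curve_fit`) with analytic-free
initialization: A ← mean of the last decile of the curve; k ← ln 2 / (time
to reach A/2); for the bi-exponential, k₁ ← 5× and k₂ ← 1/5× the
single-fit rate with the amplitude split evenly. Bounds: A ∈ [0, 1.5],
k ∈ [10⁻⁴, 10³] s⁻¹. Components are reported fast-to-slow. A fitted
amplitude below 10⁻³ means the rate is unidentifiable (no recovery) and the
fit is flagged failed rather than raising. If the two bi-exponential rates
collapse (k₁/k₂ < 3) the components are unresolved: a warning is issued and
the single-exponential fit is returned. The fiber fit can optionally pin
the fast rate to an independently measured free-diffusion (nucleoplasmic)
rate; the free fit is the default.

Model choice uses the small-sample-corrected AIC,
AICc = n ln(SSE/n) + 2p + 2p(p+1)/(n−p−1), with p = 2 (single) or 4
(biexp). Because the collapse rule already rejects unresolved second
components, the false-selection rate of the bi-exponential model on noisy
single-component data stays well below the ~14% a bare ΔAIC > 0 rule would
give (measured ~3–4% at trace noise sd 0.02 over 1000 points).

### Diffusion coefficient

For diffusion into a uniformly bleached disk the closed-form recovery is
f(t) = e^(−2τ/t)[I₀(2τ/t)+I₁(2τ/t)], τ = r²/(4D), evaluated with the
exponentially scaled Bessel functions (`i0e`, `i1e`) so it is overflow-free;
f(0) is taken as the limit 0. Setting f = 1/2 gives the half-time relation
D = γ·r²/t½ with γ = 1/(2x½) = 0.22365, x½ the root of
e^(−x)[I₀(x)+I₁(x)] = 1/2 (γ is stored to full precision; 0.224 is its
conventional rounding). Applied to the full-FRAP geometry (t½ = 3.6 s,
r = 1.5 µm) this yields D = 0.140 µm²/s, about 4.9% below the 0.147 µm²/s
conventionally quoted for these parameters; the formula or radius
convention behind that figure is not stated in the source literature, so
the discrepancy is documented rather than resolved. It is inside the 5%
band the relation's own parameter uncertainties imply.

## Colocalization

Manders split coefficients and Spearman rank correlation (mid-rank ties,
via `scipy.stats.spearmanr`) are computed over masked pixels. Threshold
policies for Manders: `zero` (default; every positive pixel counts — note
that with a nonzero background this saturates M toward 1, so Otsu is the
practical choice for spot-on-background images), per-channel `otsu`, or a
Costes-style scan (joint threshold lowered along the ch2-on-ch1 regression
until the below-threshold pixels are uncorrelated). The policy in effect is
recorded in outputs. Coefficients undefined for a cell (zero-intensity or
constant channel) are NaN, excluded and counted.

The randomized control rotates one channel 90° counter-clockwise on a
centered square crop (rotation must map the frame onto itself); the
analysis mask becomes the intersection of the original mask with its own
rotation. Rotation preserves the channel's intensity histogram and spatial
autocorrelation while destroying cross-channel correspondence, so the
randomized coefficients estimate the chance-overlap null. Group comparison
is a two-sided Student's t test — classic equal-variance two-sample by
default, paired optional — flagged at p ≤ 0.05 and p ≤ 0.007. Because the
real and randomized values derive from the same cells, the unpaired test is
mildly conservative; measured type-I flag rates on independent-channel
simulations are ~1–3% at the nominal 5%.

The coloc generator places Gaussian-PSF spots (default σ = 45 nm at
28 nm/px) uniformly in an elliptical nuclear mask, with a configurable
fraction of spot centers shared between channels. It emulates spot density,
PSF width, background and detector noise; it does not model STED-specific
PSF shape, chromatic shift, or structured (non-spot) colocalization.

## Morphology

Condensates: global Otsu threshold inside the nuclear mask, 8-connected
components, objects below a minimum equivalent diameter (default 1 µm)
removed; per-object area, equivalent diameter, Crofton perimeter and
circularity 4πA/P², all in physical units. Digitized disks give
circularity ≈ 0.95–1.05 (digitization excess above 1 is possible and not
clipped).

Fibers: multi-scale Sato tubeness at scales spanning the expected width
range (default 150–250 nm), with three cleanup rules calibrated on the
generator: (a) response above 10% of the image's robust amplitude
(p99.9 − median inside the mask); (b) raw intensity above the median plus
half the robust amplitude — granular texture whose correlation length
matches the fiber scale produces tubeness response but lacks this absolute
contrast; (c) compact bright blobs (mean width along the skeleton
> 2.5× the upper width bound) and a one-width rim zone around them are
excluded, since condensate edges also respond to the tubeness filter.
Remaining components shorter than 25 skeleton pixels are dropped; the mask
is skeletonized to 1-px centerlines.

Thickness is the FWHM of intensity profiles sampled perpendicular to the
skeleton every 5th pixel (cubic interpolation at half-pixel resolution,
profile half-length 450 nm), above a local background taken as the smaller
of the two profile-tail means; crossings are located by linear
interpolation. Skeleton junctions (fiber crossings) and endpoints, where
the perpendicular profile is contaminated or ill-defined, are excluded; a
skeleton too short for tangent estimation falls back to the local image
Hessian's ridge direction, so even a single-point skeleton yields a
measurement. On generator ridges the estimator is unbiased for straight
fibers and retains a small positive bias (≲ 0.5 px median) on curved ones,
from residual curvature within the profile window.

Phenotype classification is rule-based on two evidence scores inside the
nuclear mask: ridge area fraction (from the fiber detector) and condensate
area fraction counting only round objects (circularity ≥ 0.4 — this
rejects thresholded texture networks and elongated fibers). The call is
fibrous if ridge fraction > 0.005, else condensed if condensate fraction
> 0.01, else diffuse. The thresholds are calibrated on the generator (the
original phenotypes were assigned by eye; no numeric thresholds exist to
inherit) and sit roughly mid-way between the class-conditional score
distributions (diffuse ridge fraction ≤ ~0.003; fibrous ≥ ~0.01).

The phenotype generator draws an elliptical nucleus with granular texture
(Gaussian random field, 1.5 px correlation, 5% amplitude) and adds, per
class, anti-aliased disks of 1–5 µm diameter or smooth random curvilinear
ridges (bounded-random-walk paths, Gaussian cross-section of 150–250 nm
FWHM) at 65 nm/px for classification images and 13 nm/px for STED-like
fiber crops. It emulates relative contrast and geometry, not optical
realism: no depth structure, no deconvolution artifacts, no intensity
heterogeneity along real chromatin. Passing tests therefore establish that
the estimators are correct for their geometric model, not that the fixed
classifier thresholds transfer to any particular instrument's images —
on real data the thresholds should be re-calibrated on a few labelled
examples.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit integer seed
(`numpy.random.default_rng`; no global state); identical seeds give
bit-identical artifacts, and the pipeline driver writes its exact
configuration plus SHA-256 hashes of all outputs. Validation uses 100
seeded movies per FRAP design (64² grid, 1000 post frames), 100-seed
model-selection and rotation-null calibrations, 100 replicate
colocalization experiments of 6 cells each (256² images), 100 generator
images per phenotype class (256² at 65 nm/px) and 5 fiber widths × 6 seeds
for thickness recovery — sizes chosen so the whole suite validates the
statistical claims in a few minutes on one CPU.

## Known limitations

* The movie generator is 2-D and single-plane; no photophysics (blinking,
  reversible dark states) or vectorial/STED PSF modelling.
* Exchange kinetics treats the surround as an infinite reservoir; the
  diffusion mode's finite field recovers only to 1 − (bleached/total) mass,
  so oracle comparisons use fields ≳ 7× the ROI diameter.
* The equal-variance t test and the unpaired default are conventions;
  Welch or paired alternatives are one flag away but change the null
  calibration slightly.
* Fiber thickness assumes an isolated ridge within the profile window;
  dense meshes bias the FWHM upward, and the 150–250 nm defaults assume
  STED-scale pixels (≤ ~65 nm).
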