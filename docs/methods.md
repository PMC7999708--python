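# Methods

## Scope

`fluorsense` implements a stress-detection analysis built on three
measurement streams — leaf reflectance/fluorescence spectra, plain 8-bit
fluorescence images, and PAM fluorometry — plus a mechanistic simulator
that generates all three with the statistical structure the analysis
assumes. This note documents the models, the tunable parameters and their
defaults, the numerical choices, and the limits of what the synthetic
experiments demonstrate.

## Energy partition

Absorbed photon energy has three fates: PSII photochemistry (yield
Φ_PSII), heat dissipation (Φ_heat) and chlorophyll-*a* fluorescence (Φ_F),
with Φ_PSII + Φ_heat + Φ_F = 1. Under steady actinic light the simulator
splits the non-photochemical share with a fixed branching fraction:

    Φ_F = k_f · (1 − Φ_PSII),    Φ_heat = (1 − k_f) · (1 − Φ_PSII)

`k_f` defaults to 0.10 (dimensionless); leaf-level fluorescence yields are
a few percent, so with Φ_PSII in [0.05, 0.75] this puts Φ_F in
[0.03, 0.10], the right order of magnitude. In darkness with an active NPQ
quencher the partition instead follows competing first-order rates: the
basal non-photochemical rate is normalised to 1 (fraction `k_f` radiative),
photochemistry runs at rate `k_p` (open centres; default 4.0, giving a
dark-adapted Φ_PSII of k_p/(1+k_p) = 0.8), and the quencher obeys
Stern–Volmer kinetics scaled so that Fm/Fm′ = 1 + NPQ holds exactly. This
makes derived NPQ = (Fm − Fm′)/Fm′ round-trip the simulated ground truth to
machine precision in the noise-free case, and makes Φ_PSII, Φ_F and pixel
intensity all rise monotonically as NPQ relaxes.

## Herbicide kinetics

The observed whole-leaf response to a soil-drench PSII inhibitor is a
stable phase followed by a gradual decline. The simulator uses the simplest
curve with that shape, a logistic in time:

    Φ(t) = Φ_min + (Φ_0 − Φ_min) / (1 + exp((t − lag)/τ))

Defaults: Φ_0 = 0.75, Φ_min = 0.05, lag = 150 min, τ = 60 min, over an
8-h course sampled every 15 min (33 scans, t = 0…480 inclusive). The
damaged-tissue fraction is the complementary sigmoid c(t), and local tissue
yield interpolates Φ_0 → Φ_min with c.

## Spectra

A scan is modelled as

    R(λ, t) = B(λ, t) · (1 + ε) + Φ_F(t) · E(λ)

- **Baseline** B: reflectance floor 0.04, green peak (amplitude 0.08,
  centre 550 nm, σ 35 nm), red-edge logistic rise to a NIR plateau of 0.45
  (centre 710 nm, width 15 nm). Two slow deterministic terms ride on it:
  a damage-coupled reflectance rise in absorbing regions (pigment loss;
  maximal relative rise `bleach_fraction` = 0.02, weighted by the
  absorptance proxy 1 − B/B_max) and, in the study preset, a small early
  transient depressing the red-edge component (amplitude 1.2 %, peaking at
  80 min) that reproduces the slight initial dip of the in-band average
  sometimes seen before fluorescence growth dominates. Its amplitude is a
  free parameter, not a physiological claim.
- **Emission** E: Gaussian bands at 680 nm (amplitude 1.0, σ 10 nm) and
  740 nm (amplitude 2.0, σ 18 nm) attenuated by an escape probability
  exp(−κ·absorptance) with κ = 2.0. Re-absorption is what makes real
  leaves' far-red emission dominate the observed signal and shifts the red
  emission maximum away from 680 nm; with these defaults the most
  treatment-responsive channel of the normalized series is the far-red one
  (≈741 nm) and the flattest is the green-peak channel, so the
  variability-driven selection rediscovers the far-red/green band pair
  deterministically on noise-free data.
- **Noise** ε: multiplicative Gaussian per channel and scan,
  CV 0.5 % by default.

## Image stacks

The leaf is an ellipse (semi-axes 0.36/0.42 of the frame) with a midvein
and six pairs of secondary veins as polylines. A soil-applied herbicide
arrives through the petiole and rides the transpiration stream, so the
damage front travels the vein network at `vein_speed` (2 px/min) and then
crosses lamina tissue `lamina_factor` (4×) slower; each pixel's arrival
time is min over vein samples of (along-vein distance + 4 × Euclidean
hop) / speed. Pixel grey level is an affine map of the local fluorescence
yield (gain 800, offset 15, background 3), modulated by a fixed
illumination vignette (10 %) and a fine leaf-surface/photo-response texture
(3 %) — both deterministic functions of pixel position, identical for every
seed, which also dither the 8-bit quantisation so ROI means move smoothly —
plus additive camera noise (SD 2 grey levels) and clipping to 0–255.
The simulator also returns ground truth (distance map, damage maps, leaf
mask) and a suggested probe-site ROI on the midvein near the entry point,
mirroring the practice of measuring "as close as possible" to the probes.

Relaxation-study radiometry (gain 4000, offset 2, NPQ₀ = 2.4, τ_NPQ =
50 min over a 15-min dark period at 1-min cadence) was chosen to land near
the printed pixel intensities of the original study (≈56 → 61 during
relaxation; ≈82 dark-adapted).

## Analysis chain

- **Normalization** divides every scan element-wise by the t = 0 scan; the
  baseline column is exactly 1 by construction.
- **nARFS** is the unweighted mean of normalized values over channels with
  669.8 ≤ λ ≤ 760.7 (both edges inclusive; membership by wavelength value,
  not index). nARFS(0) = 1 exactly.
- **Variability** is the sample (n − 1) standard deviation per wavelength
  across all scans.
- **Selection**: candidate signal channels are interior local maxima of the
  variability curve at or above its 90th percentile (configurable); the
  winner is the candidate whose normalized series has the largest |Pearson
  r| against Φ_PSII; the reference is the global variability minimum. Named
  wavelengths resolve to the nearest grid channel, lower channel on ties.
- **FBSI** is computed on the *raw* spectra — a deployable two-band sensor
  has no baseline scan — as (R_sig − R_ref)/(R_sig + R_ref), strictly
  inside (−1, 1), gain-invariant and antisymmetric under band exchange.
- **ROI statistics** are the float mean and sample SD of the ROI pixels
  (half-open extent, 0-based row-major origin); only stored frames are
  8-bit.
- **Yields**: Φ_PSII = (Fm′ − Fs)/Fm′, NPQ = (Fm − Fm′)/Fm′. Physically
  impossible orderings (Fs > Fm′, Fm < Fm′), which instrument noise can
  produce near saturation, yield flagged values rather than errors.
- **Alignment** matches the three streams to the spectral clock by nearest
  timestamp, strictly within a tolerance (default 5 min, one third of the
  sampling interval); unmatched timepoints are dropped with a logged count,
  a stream with zero matches is an error.
- **Correlation**: ordinary least squares plus Pearson r with a two-sided
  t-test on n − 2 degrees of freedom per variable pair, per replication.
  Replications are never pooled: absolute fluorescence levels differ plant
  to plant and the method is deliberately qualitative. No multiple-testing
  correction is applied; the report carries n so users can adjust.

## Reproducibility

All randomness flows from one seed through fixed per-generator substreams
(`SeedSequence([seed, stream_id])`), so adding a generator never perturbs
another's draws, identical seeds give byte-identical pipeline outputs, and
noise-free runs are identical across seeds. Replication *i* of a study run
uses seed `base_seed + i`.

## Problem sizes

The test suite and the acceptance script use the full study geometry where
the claim depends on it (3 replications × 33 scans × 256 channels,
480 × 640 frames) and a reduced 128 × 160 frame for structural image tests;
oracle-equivalence checks run on 20 random small instances against
brute-force loop implementations.

## What the synthetic experiments do and do not show

Passing tests demonstrate that the analysis chain is internally correct
(oracle-equivalent statistics, exact identities, determinism) and that
*under the stated generative assumptions* the study's qualitative
conclusions follow: pixel intensity is a usable inverse proxy for Φ_PSII,
nARFS tracks it, and the two-band FBSI retains that information. They do
not validate the generator against real leaves: the simulator has no
radiative-transfer optics, no Kautsky induction, no leaf movement or
specular artefacts, treats illumination as an arbitrary gain, and its
correlation magnitudes (|r| ≈ 0.97–0.998) are tighter than field data
because plant-to-plant biological variation beyond noise levels is not
modelled. Known limitations of the analysis itself, inherited by design:
simple OLS/Pearson inference ignores temporal autocorrelation of the time
courses, and ROI placement is an explicit input rather than an estimated
quantity.
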