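# Methods

This note documents the models implemented in `crabcamo`, the defaults and
why they were chosen, what the synthetic scenes do and do not emulate, and
the numerical decisions a user auditing results should know about.

## Spectral representation and rendering

All spectra live on a fixed 300–700 nm grid in 5 nm steps — wide enough to
cover the UV-A window a quartz-converted camera records. Reflectance is a
unitless fraction in [0, 1]; receptor and camera sensitivities are
non-negative and need not be normalised because responses are computed as
illuminant-normalised quantum catches,

    q_c = ∫ R(λ) I(λ) S_c(λ) dλ / ∫ I(λ) S_c(λ) dλ ,

evaluated with trapezoid quadrature. A spectrally flat reflector of
reflectance r therefore produces catch r in every channel, and catches are
linear in reflectance. The default illuminant is equal-energy, emulating
flat overcast lighting; any illuminant on the grid can be substituted.

The camera model is four Gaussian channels truncated to hard filter
cut-offs: UV 360–400 nm (peak 380), SW 400–550 (peak 460), MW 420–620
(peak 540), LW 560–700 (peak 625).

## Synthetic scenes

The generator's defaults *are* the study conditions the pipeline assumes:
47 background images per habitat class, a black/white reflectance standard
(8.2% and 94.8% across the spectrum) in the image corner with an exclusion
zone around it, all imagery standardised to a common spatial scale
(default 10 px/mm), and juvenile crabs under 15 mm carapace width.

* **Mudflat** scenes are one dark-brown mud spectrum modulated by smoothed
  low-frequency noise (patch scale 16–64 px), calibrated to a luminance RMS
  contrast (std/mean of the achromatic band) of 0.08.
* **Rockpool** scenes are a multi-scale tessellation of sand, dark/light
  rock and algae discs with radii log-uniform over 3–48 px, drawn large to
  small, calibrated to RMS contrast 0.35.

The contrast calibration scales palette spectra about their area-weighted
mean and iterates against clipping until the achieved contrast is within
2% of target (the generator's contract guarantees ±20%). The contrast
targets and substrate spectra are plausibility choices, not measurements;
they were fixed once so that the two classes are cleanly separated in both
contrast and granularity energy.

Crab targets are star-shaped smoothed ellipses (width:depth 1:0.8) with a
scalloped anterior margin. Uniform phenotypes carry one base spectrum.
Disruptive phenotypes add alternating dark/light blotches: margin blotches
are thin and elongated *across* the body margin, so their side edges cross
the outline — the geometry that creates false perpendicular edges — while
their inward extent stays within the outer quartile of the distance-to-edge
range; the `edge_bias` parameter is a verified area contract (≥ that
fraction of blotch area in the outer band, with bounded retries). Blotch
contrast c maps the base spectrum to base·(1−c) (dark) and
base + c·(0.9−base) (light).

The standard patches default to 5 mm rather than the physical 10 mm of
real standards so that the corner assembly fits comfortably into the
smallest supported scenes (256 px); the size is configurable.

What the synthetic scenes do **not** emulate: photon/sensor noise, optics
(vignetting, chromatic aberration, focus), specularities and wetness,
water-column attenuation, misregistration between UV and visible
exposures, and real crab morphology beyond a carapace-like outline.
Passing tests therefore demonstrate correctness and sensitivity of the
*metrics* under controlled conditions, not performance on raw field
photographs.

## Calibration

Channel values are mapped to percent reflectance by the affine transform
anchored at the measured black/white standard means (8.2 → 94.8). Values
outside that range extrapolate linearly and are deliberately not clipped;
downstream logarithms are protected instead (below). Synthetic renders are
already linear, so no separate RAW linearisation exists here; the
normalisation seam is where linearised camera data would enter. Rescaling
is downscale-only by default (refusing to invent sub-pixel detail), with
exact block averaging when the factor is integral and anti-aliased
bilinear resampling otherwise; masks are resampled nearest-neighbour.

## Visual systems and cone mapping

Two default viewers: a violet-type tetrachromatic bird with chromatic
peaks 405/445/508/565 nm and a 560 nm double-cone luminance channel
(relative densities UV:SW:MW:LW = 1.0:1.9:2.2:2.1), and a dichromatic fish
with SW/LW cones at 455/530 nm (densities 1:2) and an LW-based luminance
channel — fish lack double cones, so this is a flagged assumption. All
sensitivities are Gaussian stand-ins; real curves can be substituted per
channel. Receptor noise follows e_i = ω/√η_i with ω anchored so the most
abundant chromatic channel has e = 0.05, and e_L = 0.05; all of this is
configurable, and reported JND magnitudes scale inversely with these
Weber fractions.

The camera→cone mapping is ordinary least squares per receptor over the
fixed term list {1, x_i, x_i·x_j (i≤j)} of the camera channels (degree 2
default, degree 1 available). Rank deficiency is reported with the names
of the collinear terms. On the synthetic library of smooth random spectra
(sums of ≤4 broad Gaussian/sigmoid components — deliberately
low-dimensional, as natural substrate reflectances are), held-out R²
exceeds 0.99 for every receptor. Predicted catches are floored at 1e-6 so
log contrasts stay finite.

## Discrimination (JNDs)

Chromatic distance uses the general-n receptor-noise formula given in the
README, which reduces algebraically to the published closed forms for
2–4 receptors (verified to 1e-12 in tests); luminance distance is
|ln(q_A/q_B)|/e_L. Per-background stimuli are mean cone catches over the
whole usable image (standards and exclusion zone masked out), and each
crab's habitat score is the arithmetic mean of its per-image JNDs over
that habitat's backgrounds.

## Pattern granularity

Pattern is measured on the avian double-cone (luminance) image. Band-pass
filters are annuli in the Fourier domain keeping spatial periods in
[s/√2, s·√2) for octave scales s = 2, 4, …, capped at 256 px and at half
the image dimension; consecutive octave bands tile the spectrum without
overlap (band edges are snapped to rounding error, so summed squared
energies never exceed the ROI variance). Energy per band is the standard
deviation of the filtered pixels inside the ROI, with the outside mean-
filled to avoid spurious edge energy. PED is the summed absolute energy
difference; energies are not normalised, so amplitude and shape mismatch
both register. Crab spectra are computed on the carapace ROI embedded in a
scene-sized canvas so crab and background spectra share one scale series.

## Edge disruption (GabRat)

The outline is an ordered Moore-neighbour boundary trace; local tangents
come from an orthogonal least-squares fit over a 7-sample circular window
(robust for vertical edges, exactly equivariant under 90° rotation). At
each outline pixel, an even/odd Gabor quadrature pair (σ = 3 px,
λ = 2σ√2, isotropic envelope, kernel half-width 3σ) is oriented along the
tangent (coherent energy E_par) and across it (false-edge energy E_perp);
kernels are envelope-weighted zero-meaned and L2-normalised over their
valid support, which also handles truncation at image borders. GabRat is
the mean over outline samples of E_perp/(E_par+E_perp); samples with total
energy below 1e-9 are skipped, and an all-skipped outline returns 0 with a
warning. The per-sample-ratio-then-mean aggregation is one reading of
"ratio of false to coherent edges"; it is the default and the engine
exposes the raw energies for alternatives.

Random placement is rejection sampling of mask offsets, uniform over
positions keeping the footprint inside the image, pairwise disjoint and
disjoint from the exclusion mask, deterministic per seed. The per-crab
score on one background averages 50 placements (default); habitat scores
average over that habitat's backgrounds.

GabRat is scale-dependent by construction (σ fixed in px): the same
phenotype scores differently at different px/mm. The phenotype sweep used
to characterise the metric's range therefore fixes one resolution
(15 px/mm) and varies phenotype from large uniform crabs (salient coherent
outlines, ≈0.03–0.05) to dense thin margin-crossing blotches (≈0.4–0.5).

## Statistics

The design is a 2×2 split plot: origin (between subjects) × background
(within subjects), two rows per crab. For this design, type-III tests with
sum-to-zero coding reduce exactly to contrasts on per-subject means m_i
(origin) and differences d_i = y_RP − y_MF (background: unweighted grand
mean of group means; interaction: difference of group means), each against
its stratum's pooled error with 1 and N−2 degrees of freedom — matching
R's `car::Anova` (the engine behind `ezANOVA`) on unbalanced groups, which
the tests verify to 1e-6. The reported sums of squares are type III
(F·MS_error); on balanced designs the five SS partition the total exactly.
A zero error variance in a stratum is an error rather than an infinite F.
The avian colour JND is natural-log transformed before the ANOVA by
default (right-skewed); the base does not affect F. Levene's test uses
median centring (Brown–Forsythe) by default over the four origin ×
background cells. Crabs missing a metric drop out of that metric's ANOVA
only, so denominator df per metric is (usable crabs − 2); no exclusion
rule is hard-coded.

## Problem sizes

Tests and the acceptance script run the study scaled down — typically 3–6
backgrounds per habitat at 320–384 px, 3–6 crabs per origin, 5–10
placements — sizes chosen to keep the full suite interactive while leaving
every code path identical to the full-scale run (47+47 backgrounds at
1024 px, 50 placements), which completes in well under 15 minutes on one
CPU via the CLI.

## Known limitations

* Receptor sensitivities, Weber fractions and cone ratios are literature-
  conventional stand-ins, not species measurements; absolute JND values
  shift with these settings even though orderings are robust.
* GabRat is reported for a single σ; multi-σ sweeps are out of scope.
* The mapping is validated on smooth spectra; spiky reflectances (e.g.
  iridescence) would degrade the polynomial approximation.
* Chromatic pattern statistics, spatial acuity modelling and viewing-
  distance effects are not modelled.
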