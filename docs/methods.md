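# Methods

`nucleomech` quantifies the nuclear mechanophenotype of cultured cells —
how taut the nuclear envelope is, how large and flat the nucleus is, how
viscous and crowded the nucleoplasm is, how stiff the nuclear/chromatin
composite is, how strongly a chromatin protein condenses and where, and
how its genome-wide occupancy redistributes between culture conditions.
Every analysis stage is paired with a synthetic-data generator whose
ground truth is known exactly, so the whole package is validated by
parameter recovery rather than by comparison to any external dataset.

Units are μm, s, Pa and N throughout, except AFM deflections, which are
carried in nm as is conventional for the instrument output.

## Envelope fluctuations

The statistic is deliberately simple: the sample standard deviation
(ddof = 1) of the envelope position about its temporal mean, measured
along lines perpendicular to the envelope at several locations per
nucleus and averaged over locations. A taut envelope fluctuates little;
growth-factor withdrawal or cytoskeletal perturbation raises the
amplitude. The pipeline is

1. **Bleach correction** by the simple-ratio convention: every frame is
   scaled by mean(frame 0)/mean(frame t), making the frame-mean exactly
   constant. No exponential fit is attempted.
2. **Rotational drift correction.** Colonies rotate slowly and rigidly,
   so the drift model is linear in time. The envelope radius profile
   r(φ) is extracted per frame (subpixel ridge maximum along rays from
   the intensity centroid); a rigid rotation by ω per frame advances the
   phase of every circular harmonic k of r(φ) by 2πkω/N between frames.
   ω is estimated from lag-L cross-spectra pooled over all frame pairs
   (L up to 12 by default) and harmonics k ≤ 8, weighted by cross power
   times (kL)². A circularly symmetric envelope carries no angular
   signal; the estimate is then zero, which is also the correct
   correction (rotating a circle is a no-op). The frames are
   counter-rotated about the centroid by the fitted line. Frames whose
   post-correction correlation with frame 0 drops below 0.2 are flagged.
3. **Normal placement.** The paper-equivalent manual step is automated:
   a closed contour is detected on the temporal mean frame (star-convex
   ridge detection from the centroid, 720 rays), and `n_normals`
   anchors are placed at equal arc-length intervals with outward local
   normals. Contour tangents use a ±2.5° stencil because adjacent
   contour points are sub-pixel apart and a short-baseline tangent
   amplifies detection noise. Default 8 normals, line half-length 1 μm;
   the acquisition emulated is 150 ms/frame for 5 min.
4. **Edge tracking.** Intensity is sampled along each normal by linear
   interpolation at half-pixel steps; the envelope position per frame is
   the ridge maximum refined by a 3-point quadratic fit. Frames whose
   maximum sits at the window edge are marked invalid and dropped (not
   interpolated); a series needs ≥ 10 valid frames.

The synthetic movie renders the radius field piecewise-constant over
angular sectors, each sector an independent Ornstein–Uhlenbeck process
simulated with the exact discrete-time update
x(t+1) = ρx(t) + σ√(1−ρ²)ξ, ρ = exp(−Δt/τ), so the stationary sd is σ
at any frame interval. Sector-wise rendering (rather than interpolating
radii between control angles) keeps the stationary amplitude exactly σ
at *every* sampling direction — angular interpolation would shrink the
variance between control points by up to 2× and bias recovery low by
~10–15%. The membrane is a Gaussian ridge of width `psf_sigma`
(default 0.15 μm) and global intensity decays as exp(−bleach·t).
What this generator does not emulate: camera shot noise, neighbouring
nuclei, out-of-focus light, and envelope wrinkling/folding (the contour
is always star-convex). Passing tests therefore demonstrate correctness
of the estimator on clean single-nucleus movies, not robustness to
segmentation failures on crowded fields.

A note on identifiability: when the shape correlation time τ is short,
the envelope texture that carries the rotation signal decorrelates and
the drift-rate estimate gets noisy. The fluctuation statistic itself is
insensitive to this — a residual rotation only slides the sampling
point along the envelope, and every material point has the same
stationary amplitude — which is why amplitude recovery holds at τ = 1 s
while the drift-rate unit test uses a more persistent envelope (τ = 5 s).

## 3D morphometry

Volume is voxel count × voxel volume. Height is the full z-extent of
the labelled voxels ((z_max − z_min + 1)·Δz); a 5–95 percentile variant
is available because the paper-style full extent is sensitive to single
stray voxels. Surface area is measured on a marching-cubes isosurface
at level 0.5 with anisotropic voxel spacing; the binary mask is first
smoothed with a σ = 1 voxel Gaussian because the isosurface of a raw
binary field is staircased and overestimates smooth surfaces by ~8%
(voxel-face counting overestimates by up to ~50% and is used only as a
flagged fallback for masks without interior). Digitized spheres at
0.1 μm voxels come out within ~0.5% of 4πr². The ellipsoid generator
provides (4/3)πabc and the Thomsen surface approximation
(p = 1.6075, ≤ ~1% error) as oracles. Relative volume time courses are
volume(t)/volume(0) with missing labels reported as NaN gaps, never
interpolated.

## GEM microrheology

Trajectories of nucleoplasmic multimeric nanoparticles are summarized
by the time-averaged MSD per track, msd(kΔt) = mean_i |r(i+k) − r(i)|²,
pooled across tracks with n_pairs weights (identical to pooling all
displacement pairs). The transport fit is ordinary least squares of
log msd on log lag over the first ceil(0.25·n_lags) lags (the paper
does not state its fit range; short lags are the least biased by
confinement and statistical starvation at long lags). The 2D convention
msd = 4·D_eff·t^b reflects single-focal-plane imaging: **D_eff is a 2D
effective diffusivity in μm²/s^b**. D_eff is taken from the intercept,
exp(intercept)/4; a first-lag estimate msd(Δt)/(4Δt^b) is reported
alongside since the two conventions differ in the wild. Tracks shorter
than 10 frames are dropped. Localization noise adds ≈ 4·loc_noise² to
every lag; the fit does not subtract it (the tests quantify the offset
instead).

The generator produces Brownian increments for α = 1 and exact
fractional Brownian motion (Davies–Harte circulant embedding, Cholesky
fallback when the embedding is not non-negative definite) for α ≠ 1,
scaled so the ensemble MSD is 4Dt^α exactly; α = 2 degenerates to
straight-line motion. Exact synthesis matters: an approximate fBm
integrator would leak bias into the exponent-recovery tests.
Confinement is implemented as radial reflection at a circular boundary —
a phenomenological choice; it reproduces MSD saturation but is not a
model of the nucleoplasm.

## Condensate scoring

Cluster enrichment is mean marker intensity over condensate pixels
divided by the mean over the whole nucleus, computed on
background-subtracted images. The denominator *includes* cluster pixels
(the literal cluster:nucleus reading); the ratio against the
non-cluster area alone is reported next to it because the field uses
both. The identical ratio on the DNA counterstain gives the relative
amount of DNA at the condensates. Cluster detection is a median + k·MAD
threshold (k = 3) with a minimum component area — a deliberately simple,
documented stand-in for trained segmentation models; externally
generated cluster masks can be passed instead and are used by all tests
that need exactness.

The peripheral profile dilates the nucleus mask by 0.4 μm and erodes in
twenty 0.15 μm steps, ring i being the set difference of consecutive
erosions; ring mean / whole-nucleus mean is reported per channel. The
steps are sub-pixel at 0.1 μm sampling, so dilation/erosion are
implemented as thresholds of the signed Euclidean distance transform —
isotropic and exact at sub-pixel step sizes, where repeated
structuring-element erosion would quantize to whole pixels. Profiles
that exhaust the nucleus early are truncated and flagged.

The generator solves the cluster intensity v from the enrichment
identity v·N/(v·A + b·(N−A)) = e exactly on the truth masks, places
cluster centers with a radial density controlled by `peripheral_bias`
(0 = uniform over the nucleus area, 1 = rim of the allowed region), and
defaults to noiseless rendering — the exactness contract is the point;
Gaussian noise is available as a parameter.

## AFM Hertz analysis

Approach curves (piezo height z in μm, deflection d in nm, spring
constant k = 0.01 N/m emulating soft silicon-nitride levers) are
processed as: straight-line baseline fit over the first 30% of samples
subtracted everywhere; threshold contact point (first z from which d
exceeds 5× the baseline noise sd for all subsequent samples, refined by
a local linear fit intersected with zero); indentation δ = (z − z0) − d
with cantilever bending subtracted, F = k·d. The contact laws are
F = (4/3)·E/(1−ν²)·√R·δ^{3/2} (sphere) and
F = tanθ/√2 · E/(1−ν²) · δ² (four-sided pyramid, the default with
θ = 35°, matching pyramidal probe geometry; the model is always an
explicit configuration choice). ν defaults to 0.5 (incompressible) and
fits are restricted to δ ≤ 500 nm, the acquisition depth. Since both
laws are linear in the prefactor, the fit is a closed-form projection.

The threshold contact point is systematically *late* on soft samples —
for a quadratic contact law the deflection clears the noise only well
past contact — which inflates E severely. The full pipeline therefore
refines z0 jointly with E: a grid-then-Brent search over z0 between the
end of the assumed-pre-contact baseline region and the half-rise of the
deflection, minimizing the rmse of the piecewise model (zero force
before contact, contact law after) over a fixed evaluation span. The
fixed span is essential: scoring each candidate on its own
δ ≤ 500 nm window lets an early candidate choose a baseline-only window
where any modulus fits perfectly. The refined fit is accepted only when
it does not increase the final fit rmse. Per-map summaries are the
median E over valid curves, with skipped curves itemized. Noiseless
round trips recover E to < 0.1%; at 5% force noise the median of 50
curves stays within ~2–4% of truth.

The generator solves the implicit force balance k·d = F_tip((z−z0)−d)
with Brent's method per sample, so generated curves satisfy the contact
law to machine precision and the analysis round trip is an exact oracle.
Viscoelasticity, adhesion, and finite-thickness corrections are out of
scope, as are vendor binary formats.

## Occupancy filtering and clustering

All coordinates are 0-based half-open (BED dialect). The filter stack
mirrors standard chromatin-profiling post-processing:

- **Reproducibility**: keep peaks called in ≥ 2 samples of the same
  condition ("more than one sample" read as strictly ≥ 2). An
  any-condition scope is available.
- **Size and signal**: width strictly > 1000 bp AND mean signal over
  replicates strictly > 0.075 in at least one condition. Both
  boundaries are strict — a 1000 bp peak or an exactly-0.075 mean is
  dropped. The 0.075 threshold is pipeline-specific normalized track
  signal and is exposed as plain configuration.
- **Merging**: peaks with gaps strictly < 1 kb merge transitively per
  chromosome; a gap of exactly 1 kb stays unmerged. Merged signal is
  the length-weighted mean of constituents — a documented proxy, since
  recomputing from reads requires the alignments, which are upstream of
  this package.
- **Blacklist**: any ≥ 1 bp overlap with a blacklist interval removes
  the peak (pyranges overlap join).
- **Promoter/enhancer classification**: a peak overlapping
  [tss − 1 kb, tss + 1 kb) of any TSS (clipped at 0) is a promoter;
  others are putative enhancers annotated with the nearest gene by
  minimal interval-to-TSS distance, ties broken by lexicographically
  smallest gene id.

Condition means (arithmetic over replicates) are scaled to a reference
condition and log2-transformed, giving a matrix whose reference column
is identically zero; intervals with zero reference signal are dropped
and counted (a pseudocount variant exists). Ward-linkage hierarchical
clustering on Euclidean distances (scipy) with a flat cut at tree
height 7 (the scipy `fcluster` "distance" criterion: every
within-cluster cophenetic distance ≤ cutoff) yields the cluster
assignment; labels are contiguous from 1.

The generator plants non-overlapping peaks on a 10 Mb toy chromosome
with lognormal replicate noise of chosen CV around per-cluster
condition means, plus controlled fractions of short, weak and
non-reproducible violators, all flagged in the truth table. With
4-fold separated cluster means and CV = 0.1, Ward recovery is
essentially perfect (adjusted Rand index 1.0); this certifies the
pipeline plumbing, not clustering performance on real occupancy data,
whose effect sizes are far smaller.

## Problem sizes and reproducibility

Every stochastic stage draws from a per-modality child stream of a
single seed (`SimConfig.rng(name)`), so outputs are bit-identical for
identical seed and parameters and adding draws in one generator never
perturbs another. The test suite and the acceptance script size their
simulations to run comfortably on one CPU: envelope movies of 2000
frames (the 5 min / 150 ms acquisition) for amplitude recovery, 200–400
tracks for transport fits, 500-peak tables, 50-curve AFM ensembles.

## Known limitations

- The envelope pipeline assumes one star-convex nucleus per movie;
  wrinkled or touching nuclei need external segmentation first.
- Drift correction handles rotation only (translation correction sits
  behind a flag and is off by default); non-rigid envelope deformation
  is treated as signal, not drift.
- The condensate detector is an intensity threshold, not a learned
  segmenter; its absolute cluster counts on noisy data are
  configuration-dependent.
- The AFM model is purely elastic; moduli from cells are
  "apparent" values conditioned on tip geometry, depth cap, and ν.
- Merged-peak signal is a length-weighted proxy, and condition means
  assume replicates are exchangeable; no differential-occupancy
  statistics are computed.
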