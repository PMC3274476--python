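# Methods

`mitospim` reconstructs and quantifies live cell-division dynamics in
multicellular tumor spheroids imaged by selective-plane illumination
microscopy (SPIM). This note records the models behind each stage, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

Conventions: arrays are `(z, y, x)` with `x` the illumination axis of
the light sheet and `z` the detection axis; voxel sizes are carried as
`(x, y, z)` triples in micrometers, default `0.645 x 0.645 x 1 um`;
physical position of voxel index `i` is `i * spacing`.

## Synthetic SPIM forward model (`mitospim.synthetic`)

The generator produces spheroid stacks with exact ground truth so that
every downstream stage has a quantitative target.

**Scene.** Nucleus centers are placed by dart throwing (uniform in the
sphere, rejection below the minimum separation, bounded attempts).
Each nucleus is labeled with probability `labeled_fraction` — the
imaged line expresses the histone reporter in only a subpopulation of
cells — and nuclei within `rim_thickness_um` of the surface are mitotic
with probability `mitotic_fraction`; deeper cells are quiescent and
never mitotic, reproducing the proliferation gradient of large
spheroids.

**Photometry.** Interphase nuclei are isotropic Gaussian blobs
(`sigma = nucleus_radius / 2`, peak 0.4 on the [0, 1] scale); condensed
mitotic chromosomes are prolate Gaussians (axis ratio 2.5, narrower
`sigma = 0.35 r`) with peak multiplied by `mitotic_gain`; the metaphase
plate is an oblate disc (`sigma = 0.18 r` along the spindle, `0.6 r`
across); anaphase is two compact masses separating at constant speed
along the spindle, reaching one nucleus diameter apart at the last
anaphase frame. Intensities stay in [0, 1] before noise and are never
clipped afterwards, preserving linearity for quantitative checks.

**Optics.** Each voxel's signal is attenuated by `exp(-d_x / l)` where
`d_x` is the chord length from the light-sheet entry point of the ideal
truth sphere to the voxel (closed form, not ray-marched) — this is the
progressive signal loss along `x` caused by scattering and absorption.
Each z-slice is additionally blurred laterally with
`sigma0 + k * depth_z` (depth measured from the spheroid's near surface
along the detection axis). Shot noise is Poisson at `photon_scale`
photons per intensity unit; read noise is additive Gaussian.

**Stripes.** The stationary stripe artifact is sparse white noise
convolved with an elementary stripe-like pattern: coefficients
`lam ~ Bernoulli(noise_density) x N(0, noise_sd^2)` on the voxel grid,
pattern `psi` an anisotropic Gaussian elongated along `x` (unit L2
norm, odd support truncated at 4 sigma), `b = lam (*) psi` by linear
FFT convolution, independently per z-slice by default. Corrupted
volumes are exactly `clean + b`, so destriping can be scored against
the injected field.

**Time lapse.** Frame `t` is translated by `t * drift_per_frame_um`
(everything — nuclei, attenuation geometry — moves together). Each
division event runs interphase -> condensed -> metaphase -> anaphase ->
two daughter nuclei over `mitosis_duration_min` (frames split roughly
35/35/30 between the three mitotic phases); in paclitaxel mode
chromosomes condense and then jitter (an AR(1) walk, 0.8 um scale) with
no plate and no anaphase through the movie's end, reproducing the
drug's mitotic block with continuously moving condensed chromosomes.
The spindle axis is chosen among 24 seeded candidate directions to
maximize the daughters' clearance from neighboring nuclei (divisions
orient into free space; a uniformly random axis could land a daughter
on top of a neighbor and violate the scene's minimum-separation
geometry). A fresh stripe field is drawn per frame. Every operation is
a pure function of (spec, seed).

**Defaults and why.** Nucleus radius 4.5 um and minimum separation
9 um match colon-carcinoma nuclei at cell-scale packing; labeled
fraction 0.5 mimics the partially labeled clone; mitotic fraction 0.25
within a 15 um (2-3 cell layers) rim gives a handful of mitoses per
scene; attenuation length 150 um keeps nuclei identifiable through a
desk-scale spheroid while producing a clear near/far asymmetry;
mitotic gain 2 reflects condensed chromatin being visibly brighter
than interphase nuclei; stripe density 0.05 and amplitude 0.5 with a
30 x 1 um pattern produce streaks comparable in strength to the
underlying signal; movies default to 3-minute frames, the acquisition
cadence of live spheroid imaging.

**What the generator does not emulate:** real point-spread functions
(no pupil-function optics, no refraction), photobleaching, nucleus
deformation or migration, cell death, chromosome substructure, and
sample-dependent stripe statistics that vary within a slice. Passing
tests therefore demonstrate correct recovery under this idealized but
physically structured forward model — not performance on real data.

## Stripe removal by MAP estimation (`mitospim.destripe`)

Stripes are modeled as white noise convolved with an elementary
pattern. With a total-variation prior on the clean image and a prior
`Phi` on the coefficients, the MAP estimate solves the convex problem

    min_lam  TV(u0 - lam (*) psi) + alpha * Phi(lam)

and the decomposition is `clean = u0 - lam_hat (*) psi`,
`noise = lam_hat (*) psi` (their sum reconstructs `u0` to machine
precision). TV is isotropic with forward differences and reflective
boundaries; the convolution is linear (zero-padded FFT, cropped back),
avoiding periodic wrap-around streaks; `psi` has odd support so the
adjoint is an exact correlation.

**Solver.** Chambolle–Pock primal–dual iteration, zero-initialized,
with the operator norm `L` of `grad o conv` estimated by power
iteration. Steps are asymmetric: `tau = 0.95 a / L`,
`sigma = 0.95 / (a L)` with `a = 0.05` (`sigma tau L^2 < 1`
preserved). The forward operator is strongly smoothing, so the dual
(TV) side needs the large steps: the symmetric choice needed more than
500 iterations to reach the objective the asymmetric one reaches in
about 100. Iterates run in single precision with cached kernel FFTs;
`K x_bar` is assembled from cached `K x` terms, so one iteration costs
two FFT convolutions.

The raw primal objective of Chambolle–Pock oscillates, so the solver
keeps the best-objective iterate and reports that monotone trace;
stopping is by mean relative improvement over a 25-iteration window
(window mean, because the best-so-far trace plateaus for a few
iterations at a time), `tol = 1e-4`, `max_iter = 200`.

**Defaults.** `alpha = 0.2` with the l1 prior on [0, 1]-scaled images:
at the benchmark's stripe amplitude, `alpha = 1` removes almost
nothing (under 2 dB of PSNR gain) while 0.2 recovers the injected
field with correlation above 0.95; the l2 prior is available and, with
`psi = delta`, reduces the problem to classical ROF denoising — the
test suite exploits this reduction to cross-check the solver against
an independent Chambolle-projection implementation. Per-slice 2D
processing is the default (stripes lie in the light-sheet plane); a 3D
solve is available with a 3D `psi`. Scaling behavior: with the l1
prior the decomposition is equivariant under intensity scaling at
fixed `alpha` (both terms are 1-homogeneous); with the l2 prior
`alpha` must scale as `1/c` when the image scales by `c`. There is no
blind kernel estimation: `psi` is supplied (the default is the
anisotropic Gaussian of `default_psi`).

## Opposing-view fusion and drift correction (`mitospim.register`)

A 180-degree rotation about the vertical axis maps the sample to a
flip of `x` and `z`; the residual between the two acquisitions is
modeled as a pure translation. Translation is estimated by spectral
correlation: mild pre-smoothing (sigma 2 voxels), Hann windowing,
*partial* whitening of the cross-power spectrum (`R / |R|^0.5`), a
per-axis log-parabolic (Gaussian) peak fit, and up to three
re-centering passes in which the current estimate is undone and the
residual re-estimated. Full whitening turns shot-noise-dominated high
frequencies into pure phase noise and biases the subvoxel fit on
smooth content, and a fixed window biases large shifts toward zero;
partial whitening plus re-centering brought worst-case drift error
from 0.58 to 0.02 voxels on the benchmark. The reported score is the
Pearson correlation of the aligned pair (1 for an exact copy, about 0
for unrelated content), which supports a fixed reliability floor
(default 0.05) independent of volume size; an unreliable opposing-view
registration raises, an unreliable drift frame falls back to zero
incremental shift with a warning.

Fusion resamples all views into the reference frame (trilinear) and
averages with weights normalized to sum to one at every voxel. Ramp
weights (default) decrease linearly away from each view's light-entry
side — each view is trusted where its illumination path is short;
local-contrast weights (Gaussian-windowed gradient energy) are
available. The true fusion rule of the original multiview software is
not published; this weighted average is the package's own stand-in.
Drift correction references the first frame by default (no error
accumulation); chaining against the previous frame is available for
large drifts but accumulates per-step error.

## Nucleus detection and classification (`mitospim.detect`)

Detection is multiscale scale-normalized Laplacian-of-Gaussian in
physical units (anisotropic voxels honored), scales bracketing the
blob radius `sigma sqrt(3)`: defaults 2.5–5.5 um for 4.5 um nuclei.
Larger scales are deliberately excluded — they merge 9-um-separated
daughter pairs into one detection. Local maxima above a relative
response threshold (0.25 of the scene maximum; relative, so detection
counts are invariant under global intensity scaling) are kept with
greedy minimum-separation suppression. LoG was chosen over global
thresholding because the attenuation gradient makes any single
threshold wrong somewhere.

Segmentation is marker-based watershed on the smoothed volume, after
which each region is thresholded at 30% of *its own seed's* peak —
relative to the nucleus itself, not its neighborhood, so a bright
mitotic neighbor cannot truncate a dim nucleus and attenuation cancels
out. Features per nucleus: volume, mean intensity, local background
(median in a shell 2–4 equivalent radii out, excluding all segmented
nuclei — attenuation makes a global background meaningless),
background ratio, principal-axis elongation and a sphericity proxy
from the intensity-weighted second-moment tensor.

What an observer uses to call a cell mitotic — condensed chromatin
that is markedly brighter and more compact or elongated than the round
interphase nuclei around it — is operationalized as: mitotic iff
`background_ratio >= 1.6` AND
(`elongation >= 1.6` OR `volume < 0.6 x median volume`). The
elongation threshold sits between interphase measurements (1.2–1.4)
and condensed/metaphase figures (1.7 and up once depth-dependent blur
has inflated the plate's thin axis). All thresholds are configurable
and the rule text is attached to outputs.

Spheroid geometry: sphere center by algebraic least squares on the
convex-hull vertices of the centroids plus one geometric Gauss–Newton
pass. The least-squares radius runs through the middle of the
hull-vertex shell and systematically underestimates the surface, so
the reported radius is the farthest hull vertex from the refined
center plus half the median nucleus equivalent radius (outermost
nucleus centers sit about half a nucleus radius inside the surface
they define). Depth from surface is `R - ||c - center||`, reported per
detection together with its z position — the coordinate pair used to
locate mitoses relative to the spheroid surface. The sphere model is
deliberate; the rms residual is reported so non-spherical samples can
be flagged.

## Mitosis dynamics (`mitospim.dynamics`)

Linking is greedy nearest-neighbor under a 10 um gate with up to one
bridged gap, plus two division-aware rules: an unassigned *mitotic*
detection within the gate of a currently mitotic track is the second
anaphase chromosome mass of the same cell (suppressed, not a new
track); and when a mitotic track transitions to interphase in the same
frame that a fresh interphase track appears nearby, the continuation
is split off so both daughters register as births. A mitotic track
followed by two new interphase tracks within twice the gate becomes
their parent (exactly 0 or 2 children).

Events are maximal runs of mitotic classification (runs shorter than 2
frames are discarded as flicker). Exit is the daughters' first frame
(outcome `completed`); a run reaching the movie's end is `censored`,
or `arrested` once its observed duration passes the arrest threshold —
default 60 minutes, the horizon over which drug-blocked cells were
observed stuck in mitosis, configurable. A reversion to interphase
without detected daughters is scored `censored` (the fate is
ambiguous; there is no slippage category).

Metaphase-plate alignment: per frame, the chromosome mass around the
tracked centroid (voxels above half the local maximum, connected
component containing the cell — neighbors clipping into the window
would distort the moments) gives a planarity ratio
`lambda_min / lambda_mid` of the second-moment tensor; the event is
aligned when the ratio stays below 0.35 for at least two consecutive
frames. Arrested condensed balls measure 0.5–0.65; rendered plates
0.1–0.3.

`compare_conditions` reports per-arm counts, median completed
duration (censored medians reported separately as lower bounds),
arrested and aligned fractions, and a Mann–Whitney rank test on
observed durations (arrested durations enter as observed lower
bounds) — reporting plumbing, not a scientific claim.

## Pipeline (`mitospim.pipeline`, `mitospim.cli`)

One flat YAML config with per-stage blocks; unknown keys anywhere are
rejected before any work runs. Stage order is fixed: simulate (or load
TIFFs) -> destripe -> fuse -> drift-correct -> detect -> track; each
stage logs parameters, outputs and wall time into a JSON manifest.
Images travel as multi-page float32 TIFFs with resolution tags plus a
JSON sidecar (voxel size, axis order, producing command line); voxel
size resolution order is TIFF tags, then sidecar, then explicit
override. Integer TIFFs are scaled to [0, 1] by the dtype maximum.
Runs are pure functions of (config, seed): repeated runs produce
byte-identical CSV/JSON artifacts.

## Benchmark problem sizes

The package defaults describe a desk-scale spheroid (radius 50 um,
~180 nuclei, 192 x 192 x 128 voxels; the 400 um spheroids of real
experiments are a documented "large" configuration, not the default).
The automated experiments use deliberately reduced sizes chosen to
exercise every code path at full fidelity: stripe-recovery volumes at
192 x 192 x 64 (radius 25 um), detection scenes at 150 x 150 x 96
(radius 40 um, 120 nuclei), and division movies at 96 x 96 x 64
(radius 22 um, 24 frames at 3 min — long enough that an arrested cell
crosses the 60-minute horizon). Quality figures quoted anywhere in the
docs are produced by `scripts/acceptance.py` and the test suite at
exactly these sizes.

## Known limitations

- The MAP destriper assumes the stripe pattern `psi` is known; a badly
  wrong pattern degrades gracefully (small `lam_hat`) but is not
  detected.
- The opposing-view model is flip-plus-translation; rotational
  misalignment between views is out of scope, as is bead-based
  multi-angle registration.
- Greedy nearest-neighbor linking is adequate at benchmark densities
  but will swap identities in dense, fast-moving fields; the gate and
  gap are exposed.
- The mitotic classifier is a two-feature rule tuned to the forward
  model's photometry; real chromatin textures will need threshold
  adjustment (all thresholds are config-exposed).
- The sphere fit assumes a roughly spherical aggregate; strongly
  ellipsoidal samples show up as a large rms residual rather than a
  better fit.
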