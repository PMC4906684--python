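# Methods

This note documents the models, numerical choices and limitations behind
`spiraldense`. The package simulates accelerated 2D spiral cine DENSE
acquisition, reconstructs the undersampled data with BLOSM-SENSE, and
quantifies myocardial circumferential strain; everything is validated on a
computer-generated contracting-ring phantom with an analytic strain oracle.

## Phantom

The left ventricle in short axis is the annulus between two concentric
circles (epicardial and endocardial borders). Masks are rendered at 4×
supersampling and box-averaged so edges are not pure staircases. Cardiac
motion is a radial scaling `r = α(t)·R` about the centre plus an optional
solid-body twist. The temporal waveform descends as a half sine over the
first 40% of frames (systole) to the peak scale `α_peak` and relaxes back
exponentially with a time constant of one third of the remaining frames.
Frame 0 is the material (end-diastolic) reference, so displacement there is
identically zero.

This motion has two virtues: it is analytically invertible (the Eulerian
displacement at any pixel is exact, no interpolation), and the Lagrangian
circumferential strain is spatially uniform and known in closed form,
`Ecc(t) = (α(t)² − 1)/2` — the oracle used throughout the tests. Defaults:
`α_peak = 0.82` (peak `Ecc = −0.164`, a realistic healthy-heart value), no
twist, `ke = 0.1` cycles/mm (the encoding frequency is configurable; with the
default 2.5–10 mm pixels the encoded phase spans more than one cycle across
the wall, so unwrapping is genuinely exercised).

DENSE encoding writes displacement into phase: the x-/y-encoded series carry
`φ = 2π·ke·u` at each deformed pixel, the reference series carries zero
phase. No artifact-generating relaxation echo is simulated (the phase-cycling
algebra is tested separately on synthetic echoes). Complex Gaussian noise can
be added at a configured SNR, defined as `20·log10(mean |signal| over the
ring / σ)` with `σ` the standard deviation of each of the real and imaginary
noise components; the dB convention is a package choice since the source
convention is not fixed. Multi-coil data multiply in smooth synthetic
Gaussian-lobe sensitivities placed on a ring around the FOV (5 coils for the
noise study, single-coil otherwise).

## Spiral trajectories

Sampling density is expressed relative to Nyquist (spacing `1/matrix`
cycles/pixel between successive revolutions of the full interleaf set) and
interpolates linearly in k-radius between the endpoint densities of
each protocol (full: 8 interleaves, 3 → 0.8; rate 2: 4, 1.2 → 0.4; rate 4:
2, 1.2 → 0.12; rate 8: 1, 1.2 → 0.03). With a linear density the spiral
angle is a closed-form quadratic in radius, so the geometry is exact.
Samples are placed at uniform arc length (half a Nyquist pixel per step);
interleaves are uniform rotations; frames rotate by the golden angle
222.4922° (its complement 137.5078° is equivalent up to orientation;
configurable). Gradient-hardware feasibility (slew/amplitude) is out of
scope — the spiral is purely geometric.

Density-compensation weights are the exact area element of the (arc length ×
interleaf offset) parameter grid, `w = Δs · (2π/n_il) · r · dr/ds`, which
reduces to arc-step × revolution-spacing in the tightly-wound limit and to
the azimuthal gap near the centre where the curve runs almost radially; the
k = 0 sample of each interleaf receives an equal share of the half-spacing
disc. For (near-)fully-sampled designs (minimum density ≥ 0.5) the weights
are then polished by 10 deterministic fixed-point iterations that divide each
weight by the local sample density seen through a compact width-4 gridding
kernel; this removes a smooth ~2% low-frequency miscalibration of the purely
analytic weights. Undersampled designs keep the analytic weights: the
fixed point assumes gap-free coverage, and inflating weights across sampling
gaps was found to corrupt the zero-filled baseline several-fold.

Protocol timing uses one interleaf per encoded acquisition per heartbeat,
`heartbeats = interleaves × (encoding directions + 1) + 2`, where the
2-heartbeat overhead is a scheduling constant that reproduces all reference
protocol durations; temporal resolution is `views per cardiac phase × TR`
(default 2 × 9.8 ms = 19.6 ms).

## NUFFT

No NUFFT library is a dependency; the package implements Kaiser–Bessel
gridding (oversampling 2, kernel width 6, Beatty β) with analytic
deapodization. The frequency-domain interpolator is materialised as a sparse
matrix, so the adjoint is the exact conjugate transpose of the forward map —
the inner-product identity holds to machine precision — while the forward
map agrees with the direct DFT to ~1e−6 relative error. A spiral samples
only the inscribed disc of the square k-space band; image content in the
band corners (≈11% of a hard-edged annulus's energy, ≈5% of the smoothed
one's) is invisible to any spiral acquisition, so reconstruction fidelity is
assessed against the disc-band-limited image where exactness is claimed.

## Coil maps and SENSE combination

Sensitivities are estimated from the time-averaged phase-reference images:
8×8 blocks at stride 4, per-block coil covariance, dominant eigenvector,
per-pixel averaging of phase-aligned overlapping estimates, then a pointwise
refinement that projects the calibration images onto the eigen-combined
image (Gaussian-smoothed, σ = 1 px) to remove the window-smoothing bias of
the block estimates. Maps are phase-referenced to coil 0, normalised to unit
sum-of-squares, and zeroed outside a support mask (10% of the
99th-percentile magnitude). SENSE combination is `Σ conj(S_c)·m_c`.

## BLOSM-SENSE reconstruction

The iteration is proximal gradient (ISTA) on ½‖A x − d‖²_W + λ‖·‖* applied
cluster-wise:

- **Fidelity**: `x ← x − step · Aᴴ W (A x − d)` per frame and encoding, where
  `A` applies coil maps and the NUFFT and `W` holds the density weights
  (density-compensated preconditioning; the residual is monotone in the
  weighted norm). `step = 0.9/L` with `L` from 20 power iterations per frame.
- **Regularisation**: the first combined frame is tiled into 8×8 blocks at
  stride 4; anchors are clustered by k-means (K = 8, deterministic seeding)
  on their block-magnitude vectors; blocks keep their spatial location across
  frames (no motion tracking) and all frames and both/all encodings of an
  anchor share its cluster. Each cluster's Casorati matrix (b² rows; one
  column per block, column order member → frame → encoding) undergoes
  singular-value soft thresholding with the proximally-scaled threshold
  `step·λ₀·0.95^i`, `λ₀ = 0.02 ×` the largest first-pass singular value.
  Overlapping blocks are merged by uniform averaging; the λ = 0 chain is the
  identity to 1e−10.
- The partition and clustering are computed once from the initial
  density-compensated SENSE-combined images and frozen; 200 iterations is
  the full operating point, the reduced test profile uses 50.

Two design constants differ from their first drafts for documented numerical
reasons: the threshold is scaled by the step size (the correct proximal
form — an unscaled threshold overwhelms the small gradient steps and the
iterate drifts from the data), and the anneal factor is 0.95 per iteration
so the threshold bias decays within a 50-iteration budget; with a slower
anneal the bias floor exceeded the rate-dependent aliasing differences that
the acceleration study measures.

The comparators are density-compensated zero padding (adjoint only — the
undersampling-artifact baseline) and frame-by-frame CG-SENSE on the weighted
normal equations with no temporal or low-rank coupling.

## Strain analysis

Displacement phases `arg(enc · conj(ref))` are unwrapped per frame inside a
magnitude mask (skimage's quality-ordering unwrapper on a masked array),
then anchored temporally: each frame is shifted by the 2π multiple that
keeps its masked median nearest the previous frame's (frame 0 carries ~zero
phase). Phase converts to displacement in mm; the measured field is
Eulerian (each pixel reports where its tissue came from), so it is inverted
onto the material grid by scattering samples at their material origins
`X = x − u` and linearly interpolating onto the reference-frame myocardium.

The deformation gradient at each material pixel comes from a 5×5-window
weighted least-squares fit of neighbouring displacements (Gaussian weights,
σ = 1.5 px; pixels with fewer than 6 valid neighbours are dropped), then
`E = (FᵀF − I)/2` and `Ecc = ê_cᵀ E ê_c` with `ê_c` the circumferential
direction about the epicardial-contour centroid. The Lagrangian convention
makes contraction negative and rigid rotations exactly strain-free (verified
to 1e−6). Segments follow the AHA 6-sector model: 60° sectors about the
centroid, numbered counterclockwise (anatomically) from the anterior RV
insertion; segment means are unweighted pixel means. Phantom contours are
analytic circles; external data supply JSON polylines.

## Quality metrics

rRMSE is the per-pixel normalised form, `(1/N)·sqrt(Σ |m_ref − m_recon|² /
|m_ref|²)`, averaged over cardiac phases; pixels with exactly zero reference
magnitude are excluded (with N reduced) because the phantom background is
exactly zero, and experiment-level scores are evaluated on the reference's
signal support (|m_ref| above 5% of its frame maximum) — with a noiseless
phantom the per-pixel ratio is unbounded on empty background. For *phase*
images the per-pixel ratio diverges wherever the reference phase crosses
zero inside the ROI, so aggregated phase scores use the energy-normalised
variant (`per_pixel=False`); both forms are available and the per-pixel form
remains the default for complex images. SNR is `20·log10(mean |signal| /
σ)` with σ pooled over the real and imaginary parts of a noise region.
Agreement uses ordinary least squares + Pearson r, and Bland–Altman bias
with 1.96·SD limits.

## Experiments and problem sizes

`run_phantom_experiment` simulates the noiseless single-coil phantom,
samples it fully and at rates 2/4/8, reconstructs with BLOSM and zero
padding, and scores complex rRMSE, myocardial phase rRMSE, and segmental-Ecc
agreement against the fully-sampled reconstruction. `run_snr_experiment`
runs the 5-coil phantom at SNR −10 … −2 dB, rate-4 undersampled,
reconstructed with BLOSM-SENSE and CG-SENSE (maps estimated from each noisy
dataset's own time-averaged reference data; the scoring reference is the
noiseless fully-sampled reconstruction). The default profiles are reduced so
the sweeps run in minutes on one CPU — 64×64, 16 frames, 50 iterations
(noise sweep: 12 frames, 40 iterations); the full 128×128 / 32-phase /
200-iteration profile is `ExperimentConfig.full_profile()` or `--full` on
the CLI. All randomness (noise, k-means seeding, power-iteration
initialisation) derives from the experiment seed; runs are bit-reproducible.

## What the phantom does and does not show

The phantom exercises the full chain — encoding, undersampling, iterative
recovery, unwrapping, strain — against exact ground truth, but it is
deliberately idealised: piecewise-uniform magnitude, spatially uniform
strain, no through-plane motion, no T1-relaxation echo, no off-resonance or
trajectory infidelity, and Gaussian noise only. Block-low-rank priors are
especially effective on such content (at rate 8 the reconstruction error is
nearly as low as at rate 4), so phantom rRMSE margins should be read as
algorithmic orderings, not as predictions of in vivo image quality. Absolute
rRMSE values also depend on the evaluation mask and on the reference
reconstruction's own ~1.5% gridding/density error.

## Known limitations

- The ISMRMRD raw-data reader is a documented stub; external data enter via
  the HDF5 container.
- The balanced-encoding scheme is modelled as a complex linear mixture with
  a symmetric 120° matrix and inverted by pseudo-inverse; vendor-specific
  encoding conventions are not reproduced.
- Contour propagation and masking are automatic and tuned to the phantom's
  geometry (magnitude thresholds); clinical images would need manual
  contours.
- Motion-tracked block propagation, 3D/volumetric imaging, radial or
  longitudinal strain, and gradient-waveform design are out of scope.
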