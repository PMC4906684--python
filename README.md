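# spiraldense

Accelerated 2D spiral cine DENSE cardiovascular MR, end to end in simulation:
variable-density golden-angle spiral sampling, BLOSM-SENSE compressed-sensing
+ parallel-imaging reconstruction, and myocardial displacement /
circumferential-strain quantification, validated on a computer-generated
contracting left-ventricle phantom.

## The problem

Cine DENSE (Displacement ENcoding with Stimulated Echoes) encodes tissue
displacement into image phase, `u = φ / (2π·ke)`, giving accurate myocardial
strain maps — but it is a phase-contrast method needing `n + 1` encoded
acquisitions for `n` displacement directions, so a conventional 2D protocol
costs 20–26 heartbeats of breathholding. Undersampling the spiral k-space
trajectory shortens the breathhold to 14 (rate 2) or 8 (rate 4) heartbeats;
the price is aliasing, which the reconstruction must remove without corrupting
the phase that carries the physiology.

The reconstruction is **BLOSM-SENSE**: the image series (all cardiac phases ×
all displacement encodings) is divided into square blocks, blocks are grouped
into clusters of structurally-similar content, each cluster is rearranged into
a Casorati matrix (one vectorised block per column), and its singular values
are soft-thresholded — block-wise low rank across time and encoding
directions. This proximal step alternates with a density-compensated
data-fidelity gradient step through the multi-coil non-uniform Fourier (NUFFT)
model for a fixed number of iterations:

    x ← prox_{step·λᵢ‖·‖*} ( x − step · Aᴴ W (A x − d) ),   λᵢ = λ₀·γⁱ

Strain analysis follows the standard DENSE chain: phase unwrapping inside the
myocardium, phase → displacement, inversion onto the material grid, a windowed
least-squares deformation gradient `F`, Lagrangian strain `E = (FᵀF − I)/2`,
and the circumferential component `Ecc = ê_cᵀ E ê_c` reported per AHA
6-segment sector. On the phantom the motion is a pure radial scaling
`r = α(t)·R`, for which `Ecc = (α² − 1)/2` exactly — an analytic oracle for
the whole pipeline.

## Worked example

```python
import numpy as np
from spiraldense import *

# rate-4 protocol timing: 2 interleaves x 3 encoded acquisitions + 2 overhead
protocol = ProtocolSpec(n_interleaves=2, encoding_dims=2)
scan_duration(protocol)        # -> 8 heartbeats
temporal_resolution(protocol)  # -> 19.6 ms

# contracting-ring phantom and trajectories
cfg = PhantomConfig(matrix_size=64, epi_radius=14, endo_radius=8,
                    n_frames=16, contraction_amplitude=0.82, seed=0)
motion = generate_motion(cfg)
images = simulate_dense_images(cfg, motion)
traj_full = design_vd_spiral(preset_config("full", matrix_size=64, n_frames=16))
traj4 = design_vd_spiral(preset_config("rate4", matrix_size=64, n_frames=16))
measure_sampling_density(traj4, 0.5)   # -> 0.121 (design target 0.12)

# reconstruct rate-4 data two ways and score against the fully-sampled recon
reference = zero_pad_reconstruct(sample_kspace(images, traj_full))
k4 = sample_kspace(images, traj4)
blosm = blosm_sense_reconstruct(k4, traj4, config=ReconConfig(iterations=50, seed=0))
zeropad = zero_pad_reconstruct(k4)

# strain from the accelerated reconstruction
contours = Contours(endo=circle_contour((32, 32), 8),
                    epi=circle_contour((32, 32), 14))
strain = strain_from_images(blosm, contours)
strain.peak_global_ecc                                   # -> -0.1639
analytic_ecc(motion, int(np.argmin(motion.alpha)))       # -> -0.1638
```

Scored on the signal support, the rate-4 reconstructions give
`rRMSE = 0.0279` for BLOSM versus `0.0472` for density-compensated zero
padding — the iterative reconstruction removes most of the undersampling
artifact, and the peak global circumferential strain from the 8-heartbeat
acquisition matches the analytic value to 4 decimal places.

A command-line interface wraps the same pipeline:

```sh
dense-cs simulate --preset rate4 --seed 1 --out data.h5
dense-cs reconstruct --method blosm-sense --in data.h5 --out recon.h5
dense-cs analyze --in recon.h5 --out strain/
dense-cs experiment phantom --out report/
```

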