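"""DENSE echo algebra and the multi-coil non-Cartesian imaging model.

The stimulated echo carrying displacement information is isolated from the
artifact-generating T1-relaxation echo by phase-cycling subtraction, and the
acquired encodings are mapped to (reference, x-encoded, y-encoded) components
by the (pseudo-inverse of the) encoding-scheme matrix.  The forward model per
coil is sensitivity-weighting followed by the type-2 NUFFT onto the spiral
trajectory; its adjoint is exact.  Reference reconstructions (sum-of-squares
for fully-sampled multi-coil data, density-compensated zero-padding for
undersampled data) live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nufft import Nufft2
from .phantom import DenseImageSeries, KSpaceData
from .trajectory import SpiralTrajectory

__all__ = [
    "EncodingScheme",
    "phase_cycle_subtract",
    "combine_encodings",
    "nufft_forward",
    "nufft_adjoint",
    "sos_reconstruct",
    "zero_pad_reconstruct",
    "frame_operators",
]


@dataclass(frozen=True)
class EncodingScheme:
    """Mapping from acquired encoded echoes to (ref, x-enc, y-enc) components.

    ``matrix`` has one row per acquisition and one column per component; the
    acquisitions are modelled as ``matrix @ components`` and inverted by
    least squares.  The ``simple`` scheme is the identity; the ``balanced``
    scheme mixes a symmetric set of encoding directions.
    """

    name: str
    matrix: np.ndarray
    ke: float = 0.1  # cycles/mm per encoded direction

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise ValueError("encoding matrix must have full column rank")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def simple(cls, ke: float = 0.1) -> "EncodingScheme":
        return cls("simple", np.eye(3), ke)

    @classmethod
    def balanced(cls, ke: float = 0.1) -> "EncodingScheme":
        """Three acquisitions whose displacement-encoding axes sit 120 degrees
        apart; each mixes the phase reference with the x/y components."""
        angles = np.deg2rad([0.0, 120.0, 240.0])
        mat = np.stack(
            [np.ones(3), np.cos(angles), np.sin(angles)], axis=1
        )
        return cls("balanced", mat, ke)


def phase_cycle_subtract(raw: KSpaceData) -> KSpaceData:
    """Isolate the stimulated echo: (cycle0 - cycle1)/2 along the phase-cycle
    axis.  The stimulated echo inverts sign between the two cycles while the
    T1-relaxation echo does not, so the subtraction cancels the artifact and
    the factor 1/2 preserves the echo amplitude."""
    if raw.data.shape[2] != 2:
        raise ValueError("phase-cycling subtraction needs exactly 2 cycles")
    ste = 0.5 * (raw.data[:, :, :1] - raw.data[:, :, 1:2])
    return KSpaceData(data=ste, trajectory=raw.trajectory,
                      encoding_labels=raw.encoding_labels,
                      ke=raw.ke, pixel_spacing=raw.pixel_spacing)


def combine_encodings(ste, scheme: EncodingScheme):
    """Apply the scheme's pseudo-inverse along the encoding axis, relabelling
    the result (reference, x-enc, y-enc).  Works on :class:`KSpaceData` and
    :class:`DenseImageSeries` alike (the combination is linear in the complex
    data, so it commutes with the Fourier transform)."""
    pinv = np.linalg.pinv(scheme.matrix)
    labels = ("ref", "x-enc", "y-enc")[: pinv.shape[0]]
    if isinstance(ste, KSpaceData):
        if ste.data.shape[1] != scheme.matrix.shape[0]:
            raise ValueError("acquisition count does not match the scheme")
        combined = np.einsum("ce,fe...->fc...", pinv, ste.data)
        return KSpaceData(data=combined, trajectory=ste.trajectory,
                          encoding_labels=labels, ke=scheme.ke,
                          pixel_spacing=ste.pixel_spacing)
    if isinstance(ste, DenseImageSeries):
        if ste.data.shape[1] != scheme.matrix.shape[0]:
            raise ValueError("acquisition count does not match the scheme")
        combined = np.einsum("ce,fe...->fc...", pinv, ste.data)
        return DenseImageSeries(data=combined, encoding_labels=labels,
                                ke=scheme.ke, pixel_spacing=ste.pixel_spacing,
                                config=ste.config)
    raise TypeError("expected KSpaceData or DenseImageSeries")


# ---------------------------------------------------------------------------
# linear operators


def nufft_forward(image: np.ndarray, nufft: Nufft2,
                  maps: np.ndarray | None = None) -> np.ndarray:
    """Forward model for one frame: optional per-coil sensitivity weighting
    followed by the NUFFT.  Returns (coil, nsamp) or (nsamp,) without maps."""
    if maps is None:
        return nufft.forward(image)
    return np.stack([nufft.forward(maps[c] * image) for c in range(maps.shape[0])])


def nufft_adjoint(samples: np.ndarray, nufft: Nufft2,
                  maps: np.ndarray | None = None,
                  dcf: np.ndarray | None = None) -> np.ndarray:
    """Adjoint model for one frame: optional density weighting, gridding
    adjoint per coil, conjugate-sensitivity combination."""
    s = np.asarray(samples, dtype=complex)
    if dcf is not None:
        s = s * dcf
    if maps is None:
        return nufft.adjoint(s)
    imgs = np.stack([nufft.adjoint(s[c]) for c in range(maps.shape[0])])
    return np.sum(np.conj(maps) * imgs, axis=0)


def frame_operators(traj: SpiralTrajectory, shape) -> list[Nufft2]:
    """Precompute one NUFFT per frame of a trajectory."""
    return [Nufft2(shape, traj.frame_coords(t)) for t in range(traj.n_frames)]


# ---------------------------------------------------------------------------
# reference reconstructions


def zero_pad_reconstruct(kspace: KSpaceData, traj: SpiralTrajectory | None = None,
                         maps: np.ndarray | None = None) -> DenseImageSeries:
    """Density-compensated adjoint NUFFT with no iterations: the
    undersampling-artifact baseline.  Multi-coil data are combined with the
    conjugate sensitivities when maps are given, otherwise per-coil images are
    summed coherently only for a single coil."""
    traj = traj if traj is not None else kspace.trajectory
    n = traj.config.matrix_size
    t_frames, n_enc, n_pc, n_coils = kspace.data.shape[:4]
    if n_pc != 1:
        raise ValueError("subtract phase cycles before reconstruction")
    dcf = traj.frame_dcf()
    out = np.empty((t_frames, n_enc, 1, n, n), dtype=complex)
    for t in range(t_frames):
        nufft = Nufft2((n, n), traj.frame_coords(t))
        for e in range(n_enc):
            coil_samps = kspace.data[t, e, 0].reshape(n_coils, -1)
            if maps is not None:
                out[t, e, 0] = nufft_adjoint(coil_samps, nufft, maps=maps, dcf=dcf)
            elif n_coils == 1:
                out[t, e, 0] = nufft_adjoint(coil_samps[0], nufft, dcf=dcf)
            else:
                raise ValueError("multi-coil zero-pad needs sensitivity maps")
    return DenseImageSeries(data=out, encoding_labels=kspace.encoding_labels,
                            ke=kspace.ke, pixel_spacing=kspace.pixel_spacing)


def sos_reconstruct(kspace: KSpaceData, traj: SpiralTrajectory | None = None):
    """Sum-of-squares reconstruction of fully-sampled multi-coil data.

    Magnitude is the root-sum-of-squares of the per-coil dcf-adjoint images.
    For the phase, each coil's background phase (estimated from its
    time-averaged phase-reference image) is removed and the coils are summed
    as complex numbers; the phase of that coherent sum is returned.  Summing
    wrapped per-coil phase angles directly is not meaningful, so the aligned
    complex sum stands in for the per-channel phase average.

    Returns ``(magnitude, phase, series)`` where ``series`` combines the two
    as magnitude * exp(i*phase).
    """
    traj = traj if traj is not None else kspace.trajectory
    n = traj.config.matrix_size
    t_frames, n_enc, n_pc, n_coils = kspace.data.shape[:4]
    if n_pc != 1:
        raise ValueError("subtract phase cycles before reconstruction")
    dcf = traj.frame_dcf()
    coil_imgs = np.empty((t_frames, n_enc, n_coils, n, n), dtype=complex)
    for t in range(t_frames):
        nufft = Nufft2((n, n), traj.frame_coords(t))
        for e in range(n_enc):
            for c in range(n_coils):
                coil_imgs[t, e, c] = nufft_adjoint(
                    kspace.data[t, e, 0, c].reshape(-1), nufft, dcf=dcf
                )
    magnitude = np.sqrt(np.sum(np.abs(coil_imgs) ** 2, axis=2))
    # background phase per coil from the time-averaged reference encoding
    ref_avg = coil_imgs[:, 0].mean(axis=0)            # (coil, y, x)
    phasor = np.exp(-1j * np.angle(ref_avg))
    aligned = np.sum(coil_imgs * phasor[None, None], axis=2)
    phase = np.angle(aligned)
    series = DenseImageSeries(
        data=(magnitude * np.exp(1j * phase))[:, :, None],
        encoding_labels=kspace.encoding_labels,
        ke=kspace.ke, pixel_spacing=kspace.pixel_spacing,
    )
    return magnitude, phase, series
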