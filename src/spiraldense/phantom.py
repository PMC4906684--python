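"""Computer-generated contracting left-ventricle phantom for cine DENSE.

A short-axis myocardial ring is modelled as the annulus between two concentric
circles (epicardial and endocardial borders).  Contraction/relaxation is a
radial scaling r -> alpha(t) * R with a half-sine systolic descent over the
first 40% of the cine and an exponential return toward end-diastole, plus an
optional solid-body twist.  The pure radial scaling admits an exact strain
oracle: Lagrangian circumferential strain is 0.5*(alpha^2 - 1) everywhere on
the ring.

Displacement is encoded into image phase the way DENSE does: the phase of the
x-/y-encoded series equals 2*pi*ke*u along that direction, with a zero-phase
reference series.  Complex Gaussian noise may be added at a configurable SNR,
and k-space is sampled on spiral trajectories through the NUFFT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nufft import Nufft2
from .trajectory import SpiralTrajectory

__all__ = [
    "PhantomConfig",
    "MotionField",
    "DenseImageSeries",
    "KSpaceData",
    "generate_motion",
    "simulate_dense_images",
    "sample_kspace",
    "synthetic_coil_maps",
    "analytic_ecc",
]

ENCODING_LABELS = ("ref", "x-enc", "y-enc")


@dataclass(frozen=True)
class PhantomConfig:
    matrix_size: int = 128
    fov: float = 320.0              # mm
    epi_radius: float = 28.0        # pixels, end-diastole
    endo_radius: float = 16.0       # pixels, end-diastole
    n_frames: int = 32
    contraction_amplitude: float = 0.82   # peak radial scale alpha (<1 contracts)
    twist_amplitude: float = 0.0          # degrees peak solid-body rotation
    ke: float = 0.1                 # displacement-encoding frequency, cycles/mm
    snr_db: float | None = None
    n_coils: int = 1                # single-coil acquisition by default
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.endo_radius < self.epi_radius < self.matrix_size / 2):
            raise ValueError("need 0 < endo_radius < epi_radius < matrix/2")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 < self.contraction_amplitude <= 1):
            raise ValueError("contraction amplitude must be in (0, 1]")
        if self.contraction_amplitude < 0.5:
            raise ValueError(
                "contraction amplitude < 0.5 gives a near-degenerate deformation"
            )
        if self.ke <= 0:
            raise ValueError("ke must be positive")

    @property
    def pixel_spacing(self) -> float:
        """mm per pixel."""
        return self.fov / self.matrix_size


@dataclass
class MotionField:
    """Analytic deformation of the phantom.

    ``alpha[t]`` is the radial scale and ``twist_rad[t]`` the solid-body
    rotation of frame ``t`` relative to the end-diastolic (material)
    configuration; frame 0 is the identity.
    """

    alpha: np.ndarray
    twist_rad: np.ndarray
    config: PhantomConfig

    def material_to_deformed(self, xy: np.ndarray, frame: int) -> np.ndarray:
        """Map material coordinates (pixels, origin at image centre) to their
        deformed position at ``frame``."""
        a, tw = self.alpha[frame], self.twist_rad[frame]
        c, s = np.cos(tw), np.sin(tw)
        rot = np.array([[c, -s], [s, c]])
        return a * (xy @ rot.T)

    def deformed_to_material(self, xy: np.ndarray, frame: int) -> np.ndarray:
        """Inverse deformation map (exact for scaling + rotation)."""
        a, tw = self.alpha[frame], self.twist_rad[frame]
        c, s = np.cos(-tw), np.sin(-tw)
        rot = np.array([[c, -s], [s, c]])
        return (xy / a) @ rot.T

    def displacement(self, xy_material: np.ndarray, frame: int) -> np.ndarray:
        """Displacement u = deformed - material position, in pixels."""
        return self.material_to_deformed(xy_material, frame) - xy_material

    def eulerian_displacement(self, frame: int) -> np.ndarray:
        """Displacement evaluated on the pixel grid of the *deformed* frame:
        for each pixel position x, u(x) = x - X(x) with X the material origin.
        Shape (2, N, N), components (ux, uy)."""
        n = self.config.matrix_size
        xy = _pixel_grid(n)
        mat = self.deformed_to_material(xy.reshape(-1, 2), frame)
        u = xy.reshape(-1, 2) - mat
        return u.T.reshape(2, n, n)


@dataclass
class DenseImageSeries:
    """Complex image stack (frame, encoding, coil, y, x) with DENSE metadata."""

    data: np.ndarray
    encoding_labels: tuple
    ke: float                   # cycles/mm
    pixel_spacing: float        # mm
    config: PhantomConfig | None = None

    def __post_init__(self):
        if self.data.ndim != 5:
            raise ValueError("image data must be (frame, encoding, coil, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite image values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self):
        return self.data.shape


@dataclass
class KSpaceData:
    """Non-Cartesian samples aligned 1:1 with a :class:`SpiralTrajectory`,
    indexed (frame, encoding, phase_cycle, coil, interleaf, sample)."""

    data: np.ndarray
    trajectory: SpiralTrajectory
    encoding_labels: tuple
    ke: float
    pixel_spacing: float

    def __post_init__(self):
        if self.data.ndim != 6:
            raise ValueError(
                "k-space data must be (frame, encoding, phase_cycle, coil, interleaf, sample)"
            )
        t = self.trajectory
        if self.data.shape[0] != t.n_frames or self.data.shape[-2:] != (
            t.n_interleaves, t.n_samples
        ):
            raise ValueError("k-space data shape does not match trajectory")

    def frame_samples(self, frame, encoding, coil, phase_cycle=0) -> np.ndarray:
        return self.data[frame, encoding, phase_cycle, coil].reshape(-1)


def _pixel_grid(n: int) -> np.ndarray:
    """(N, N, 2) array of pixel coordinates relative to the image centre,
    (x, y) ordering, y increasing downward."""
    idx = np.arange(n) - n // 2
    xx, yy = np.meshgrid(idx, idx)
    return np.stack([xx, yy], axis=-1).astype(float)


def _temporal_waveform(n_frames: int, peak: float) -> np.ndarray:
    """Contraction waveform in [0, 1]: half-sine rise over the first 40% of
    frames, exponential decay back toward baseline afterwards."""
    t = np.arange(n_frames, dtype=float)
    t_sys = max(1, int(round(0.4 * (n_frames - 1))))
    w = np.empty(n_frames)
    rise = t[: t_sys + 1] / t_sys
    w[: t_sys + 1] = np.sin(0.5 * np.pi * rise)
    tau = max((n_frames - 1 - t_sys) / 3.0, 1.0)
    w[t_sys + 1:] = np.exp(-(t[t_sys + 1:] - t_sys) / tau)
    return peak * w


def generate_motion(config: PhantomConfig) -> MotionField:
    """Analytic contraction/relaxation motion for the phantom."""
    depth = 1.0 - config.contraction_amplitude
    alpha = 1.0 - _temporal_waveform(config.n_frames, depth)
    twist = np.deg2rad(
        _temporal_waveform(config.n_frames, config.twist_amplitude)
    )
    if np.any(alpha <= 0):
        raise ValueError("deformation is not invertible (alpha <= 0)")
    return MotionField(alpha=alpha, twist_rad=twist, config=config)


def _annulus_mask(n: int, r_in: float, r_out: float, supersample: int = 4) -> np.ndarray:
    """Anti-aliased ring: rendered at ``supersample`` x resolution and
    box-averaged, so edges are not pure staircases."""
    m = supersample * n
    sub = (np.arange(m) + 0.5) / supersample - 0.5 - n // 2
    xx, yy = np.meshgrid(sub, sub)
    rr = np.hypot(xx, yy)
    hi = ((rr >= r_in) & (rr <= r_out)).astype(float)
    return hi.reshape(n, supersample, n, supersample).mean(axis=(1, 3))


def synthetic_coil_maps(n: int, n_coils: int, fov_fraction: float = 0.55,
                        normalize: bool = True) -> np.ndarray:
    """Smooth synthetic receive sensitivities: Gaussian magnitude lobes centred
    on a ring around the FOV with gentle linear phase ramps, loosely emulating
    a surface-coil array.  Shape (coil, N, N)."""
    if n_coils == 1:
        return np.ones((1, n, n), dtype=complex)
    xy = _pixel_grid(n)
    sigma = fov_fraction * n
    maps = np.empty((n_coils, n, n), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        centre = 0.55 * n * np.array([np.cos(ang), np.sin(ang)])
        d2 = np.sum((xy - centre) ** 2, axis=-1)
        mag = np.exp(-d2 / (2 * sigma ** 2))
        phase = 2 * np.pi * (xy @ centre) / (8.0 * n * n)
        maps[c] = mag * np.exp(1j * phase)
    if normalize:
        maps /= np.sqrt(np.sum(np.abs(maps) ** 2, axis=0, keepdims=True))
    return maps


def simulate_dense_images(config: PhantomConfig,
                          motion: MotionField) -> DenseImageSeries:
    """Render the displacement-encoded complex cine.

    Magnitude is the deformed anti-aliased annulus; the phase of the x-/y-
    encoded series is 2*pi*ke*u along that axis evaluated at each deformed
    pixel; the reference series has zero phase.  Multi-coil data multiply in
    smooth synthetic sensitivities; optional complex Gaussian noise is added
    at the configured SNR (see :func:`_noise_sigma`).
    """
    geom = ("matrix_size", "epi_radius", "endo_radius", "n_frames",
            "contraction_amplitude", "twist_amplitude")
    if any(getattr(motion.config, f) != getattr(config, f) for f in geom):
        raise ValueError("motion field does not match this configuration")
    n, t_frames = config.matrix_size, config.n_frames
    maps = synthetic_coil_maps(n, config.n_coils, normalize=False)
    data = np.empty((t_frames, 3, config.n_coils, n, n), dtype=complex)
    for t in range(t_frames):
        a = motion.alpha[t]
        mag = _annulus_mask(n, a * config.endo_radius, a * config.epi_radius)
        u_px = motion.eulerian_displacement(t)          # (2, N, N), pixels
        u_mm = u_px * config.pixel_spacing
        phases = [np.zeros((n, n)),
                  2 * np.pi * config.ke * u_mm[0],
                  2 * np.pi * config.ke * u_mm[1]]
        for e, ph in enumerate(phases):
            data[t, e] = maps * (mag * np.exp(1j * ph))[None]
    if config.snr_db is not None:
        sigma = _noise_sigma(data, config)
        rng = np.random.default_rng(config.seed)
        data = data + sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return DenseImageSeries(data=data, encoding_labels=ENCODING_LABELS,
                            ke=config.ke, pixel_spacing=config.pixel_spacing,
                            config=config)


def _noise_sigma(data: np.ndarray, config: PhantomConfig) -> float:
    """Noise scale for the configured SNR.

    SNR(dB) = 20*log10(mean |signal| over the end-diastolic ring / sigma),
    where sigma is the standard deviation of each of the real and imaginary
    noise components.
    """
    n = config.matrix_size
    ring = _annulus_mask(n, config.endo_radius, config.epi_radius) > 0.5
    mean_sig = np.mean(np.abs(data[0, 0][:, ring]))
    return mean_sig / 10 ** (config.snr_db / 20.0)


def sample_kspace(images: DenseImageSeries, traj: SpiralTrajectory) -> KSpaceData:
    """Evaluate spiral k-space samples of every frame/encoding/coil image via
    the type-2 NUFFT.  Deterministic; phase-cycle axis has length 1 (no
    artifact-generating echo is simulated)."""
    if traj.n_frames != images.n_frames:
        raise ValueError("trajectory frame count must match the image series")
    t_frames, n_enc, n_coils = images.shape[:3]
    out = np.empty(
        (t_frames, n_enc, 1, n_coils, traj.n_interleaves, traj.n_samples),
        dtype=complex,
    )
    shape = images.shape[-2:]
    for t in range(t_frames):
        nufft = Nufft2(shape, traj.frame_coords(t))
        for e in range(n_enc):
            for c in range(n_coils):
                out[t, e, 0, c] = nufft.forward(images.data[t, e, c]).reshape(
                    traj.n_interleaves, traj.n_samples
                )
    return KSpaceData(data=out, trajectory=traj,
                      encoding_labels=images.encoding_labels,
                      ke=images.ke, pixel_spacing=images.pixel_spacing)


def analytic_ecc(motion: MotionField, frame: int) -> float:
    """Exact Lagrangian circumferential strain of the radial-scaling motion:
    Ecc = (alpha^2 - 1) / 2, identical at every material point of the ring."""
    a = motion.alpha[frame]
    return 0.5 * (a * a - 1.0)
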