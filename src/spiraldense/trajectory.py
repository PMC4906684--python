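"""Variable-density spiral k-space trajectories with golden-angle rotation.

A single Archimedean-type base spiral is designed so that the radial spacing
between successive revolutions of the full interleaf set corresponds to a
prescribed fraction of the Nyquist spacing (1/matrix cycles/pixel), varying
linearly with k-space radius from ``density_initial`` at the centre to
``density_final`` at the edge.  Interleaves are uniform rotated copies of the
base spiral; frames are rotated by the golden angle for temporal incoherence.
Analytic radial-Jacobian density-compensation weights are attached.

The standard protocol presets (fully sampled and rates 2/4/8) are available
by name via :func:`preset_config`.  Protocol timing (breathhold length in
heartbeats, temporal resolution) is modelled by :func:`scan_duration` and
:func:`temporal_resolution`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "TABLE_PRESETS",
    "TrajectoryConfig",
    "SpiralTrajectory",
    "ProtocolSpec",
    "preset_config",
    "design_vd_spiral",
    "rotate_golden_angle",
    "measure_sampling_density",
    "scan_duration",
    "temporal_resolution",
]

#: Golden-angle increment in degrees (360 * (1 - 1/phi); its complement
#: 137.5078 deg is equivalent up to orientation).
GOLDEN_ANGLE_DEG = 222.4922

#: (n_interleaves, density_initial, density_final) for the reference
#: fully-sampled and accelerated protocols; density 1 = Nyquist.
TABLE_PRESETS = {
    "full": (8, 3.0, 0.8),
    "rate2": (4, 1.2, 0.4),
    "rate4": (2, 1.2, 0.12),
    "rate8": (1, 1.2, 0.03),
}


@dataclass(frozen=True)
class TrajectoryConfig:
    n_interleaves: int
    density_initial: float
    density_final: float
    matrix_size: int = 128
    fov: float = 320.0           # mm
    samples_per_interleaf: int | None = None
    n_frames: int = 1

    def __post_init__(self):
        if self.n_interleaves < 1:
            raise ValueError("n_interleaves must be >= 1")
        if self.density_initial <= 0 or self.density_final <= 0:
            raise ValueError("sampling densities must be positive")
        if self.matrix_size < 8:
            raise ValueError("matrix_size too small")


@dataclass
class SpiralTrajectory:
    """k-space coordinates (frame, interleaf, sample, 2) in cycles/pixel plus
    per-sample density-compensation weights (interleaf, sample)."""

    coords: np.ndarray
    dcf: np.ndarray
    config: TrajectoryConfig

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_interleaves(self) -> int:
        return self.coords.shape[1]

    @property
    def n_samples(self) -> int:
        return self.coords.shape[2]

    def frame_coords(self, frame: int) -> np.ndarray:
        """All samples of one frame, flattened to (interleaf*sample, 2)."""
        return self.coords[frame].reshape(-1, 2)

    def frame_dcf(self) -> np.ndarray:
        """Density weights flattened to match :meth:`frame_coords`."""
        return self.dcf.reshape(-1)


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition schedule for one cine DENSE scan.

    ``encoding_dims`` in-plane displacement-encoding directions require
    ``encoding_dims + 1`` encoded acquisitions (phase-contrast principle).
    Phase cycling is interleaved within the per-heartbeat schedule; the two
    views acquired per cardiac phase set the temporal resolution.
    """

    n_interleaves: int
    encoding_dims: int = 2
    tr_ms: float = 9.8
    views_per_frame: int = 2
    overhead_heartbeats: int = 2

    def __post_init__(self):
        if self.n_interleaves < 1 or self.encoding_dims not in (1, 2):
            raise ValueError("invalid protocol")
        if self.tr_ms <= 0 or self.views_per_frame < 1:
            raise ValueError("invalid protocol timing")


def preset_config(name: str, matrix_size: int = 128, fov: float = 320.0,
                  n_frames: int = 1,
                  samples_per_interleaf: int | None = None) -> TrajectoryConfig:
    """Named protocol preset ('full', 'rate2', 'rate4', 'rate8')."""
    try:
        n_il, d0, d1 = TABLE_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(TABLE_PRESETS)}")
    return TrajectoryConfig(n_il, d0, d1, matrix_size=matrix_size, fov=fov,
                            samples_per_interleaf=samples_per_interleaf,
                            n_frames=n_frames)


# ---------------------------------------------------------------------------
# spiral geometry

K_MAX = 0.5  # cycles/pixel


def _theta_of_r(r, cfg: TrajectoryConfig):
    """Closed-form spiral angle as a function of k-radius.

    With linear density d(r) = d0 + (d1-d0) r/kmax and combined-interleaf
    revolution spacing 1/(N d(r)), one interleaf advances n_il revolutions'
    worth per turn: dtheta/dr = 2 pi N d(r) / n_il, which integrates to a
    quadratic in r.
    """
    d0, d1 = cfg.density_initial, cfg.density_final
    n, n_il = cfg.matrix_size, cfg.n_interleaves
    return (2 * np.pi * n / n_il) * (d0 * r + (d1 - d0) * r ** 2 / (2 * K_MAX))


def _r_of_theta(theta, cfg: TrajectoryConfig):
    """Inverse of :func:`_theta_of_r` (quadratic formula; exact)."""
    d0, d1 = cfg.density_initial, cfg.density_final
    n, n_il = cfg.matrix_size, cfg.n_interleaves
    tp = np.asarray(theta) * n_il / (2 * np.pi * n)
    a = (d1 - d0) / (2 * K_MAX)
    if abs(a) < 1e-12:
        return tp / d0
    disc = d0 ** 2 + 4 * a * tp
    return (-d0 + np.sqrt(disc)) / (2 * a)


def _density_at(r, cfg: TrajectoryConfig):
    return cfg.density_initial + (cfg.density_final - cfg.density_initial) * (
        np.asarray(r) / K_MAX
    )


def design_vd_spiral(config: TrajectoryConfig, dcf_refine: int = 10) -> SpiralTrajectory:
    """Design the variable-density spiral for one protocol.

    Samples are placed at uniform arc length along the base spiral (spacing
    half the Nyquist pixel spacing unless ``samples_per_interleaf`` pins the
    count); interleaves are uniform rotations of the base; every frame after
    the first is rotated by the golden angle times its index.

    ``dcf_refine`` fixed-point iterations (density estimated by spreading the
    current weights onto the gridding kernel and re-sampling) polish the
    analytic radial-Jacobian weights; 0 keeps the purely analytic weights.
    """
    cfg = config
    theta_max = _theta_of_r(K_MAX, cfg)
    # dense parameterisation for arc length
    n_dense = max(2000, int(theta_max / (2 * np.pi) * 400))
    theta = np.linspace(0.0, theta_max, n_dense)
    r = _r_of_theta(theta, cfg)
    dr = np.gradient(r, theta)
    ds = np.sqrt(r ** 2 + dr ** 2)
    s = np.concatenate(([0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(theta))))
    length = s[-1]
    if cfg.samples_per_interleaf is None:
        n_samp = int(np.ceil(length / (0.5 / cfg.matrix_size))) + 1
    else:
        n_samp = int(cfg.samples_per_interleaf)
    s_samp = np.linspace(0.0, length, n_samp)
    theta_samp = np.interp(s_samp, s, theta)
    r_samp = _r_of_theta(theta_samp, cfg)

    rot = 2 * np.pi * np.arange(cfg.n_interleaves) / cfg.n_interleaves
    ang = theta_samp[None, :] + rot[:, None]
    base = np.stack(
        [r_samp[None, :] * np.cos(ang), r_samp[None, :] * np.sin(ang)], axis=-1
    )  # (interleaf, sample, 2)

    dcf = _radial_jacobian_dcf(r_samp, s_samp, cfg)
    dcf = np.tile(dcf[None, :], (cfg.n_interleaves, 1))
    # The fixed-point density refinement assumes gap-free coverage, so it is
    # only applied to (near-)fully-sampled designs; undersampled spirals keep
    # the analytic weights -- their dcf-adjoint is a zero-filling baseline and
    # inflating weights across sampling gaps would corrupt it.
    if dcf_refine > 0 and min(cfg.density_initial, cfg.density_final) >= 0.5:
        dcf = _refine_dcf(base.reshape(-1, 2), dcf.reshape(-1), cfg,
                          dcf_refine).reshape(dcf.shape)

    ga = np.deg2rad(GOLDEN_ANGLE_DEG)
    frames = []
    for f in range(cfg.n_frames):
        c, sn = np.cos(f * ga), np.sin(f * ga)
        rotm = np.array([[c, -sn], [sn, c]])
        frames.append(base @ rotm.T)
    coords = np.stack(frames, axis=0)
    # numerical safety: keep strictly inside the sampled band
    np.clip(coords, -0.5, 0.5 - 1e-9, out=coords)
    return SpiralTrajectory(coords=coords, dcf=dcf, config=cfg)


def _radial_jacobian_dcf(r_samp, s_samp, cfg: TrajectoryConfig):
    """Analytic radial-Jacobian area weights w ~ |k| d|k|.

    The interleaf set is the image of the (arc length, interleaf offset)
    parameter grid, whose exact area element is
    ``ds * (2 pi / n_il) * r * dr/ds``; dr/ds follows from the design pitch
    dr/dtheta = n_il / (2 pi N d(r)).  In the tightly-wound limit this reduces
    to arc step times the combined revolution spacing; near the centre, where
    the curve runs almost radially, it reduces to the azimuthal gap between
    interleaves.  Each interleaf's k=0 sample gets an equal share of the
    half-spacing disc around DC.
    """
    n, n_il = cfg.matrix_size, cfg.n_interleaves
    ds = np.gradient(s_samp)
    g = n_il / (2 * np.pi * n * _density_at(r_samp, cfg))  # dr/dtheta
    drds = g / np.sqrt(r_samp ** 2 + g ** 2)
    w = ds * (2 * np.pi / n_il) * r_samp * drds
    w[0] = np.pi * (ds[1] / 2.0) ** 2 / n_il
    return w


def _refine_dcf(coords, w, cfg: TrajectoryConfig, n_iter: int) -> np.ndarray:
    """Fixed-point density refinement: divide weights by the local sample
    density seen through a compact (width-4) gridding kernel, then
    renormalise to the sampled disc area.  Deterministic."""
    from ._nufft import Nufft2

    interp = Nufft2((cfg.matrix_size, cfg.matrix_size), coords, width=4)._interp
    w = w.astype(float).copy()
    area = np.pi * K_MAX ** 2
    for _ in range(n_iter):
        dens = interp @ (interp.T @ w)
        w = w / np.maximum(dens, 1e-12)
        w *= area / w.sum()
    return w


def rotate_golden_angle(traj: SpiralTrajectory, frame_index: int) -> SpiralTrajectory:
    """Rotate every interleaf of ``traj`` by ``frame_index`` golden angles."""
    if frame_index < 0:
        raise ValueError("frame_index must be >= 0")
    ang = frame_index * np.deg2rad(GOLDEN_ANGLE_DEG)
    c, s = np.cos(ang), np.sin(ang)
    rotm = np.array([[c, -s], [s, c]])
    return SpiralTrajectory(coords=traj.coords @ rotm.T, dcf=traj.dcf.copy(),
                            config=traj.config)


def measure_sampling_density(traj: SpiralTrajectory, k_radius: float,
                             frame: int = 0) -> float:
    """Empirical Nyquist-relative sampling density at one k-space radius.

    The radius-vs-angle profile of one interleaf is differentiated at the
    requested radius to obtain the revolution spacing of the combined
    interleaf set (2*pi*dr/dtheta divided by the interleaf count); the result
    is the Nyquist spacing 1/matrix divided by that spacing.
    """
    cfg = traj.config
    pts = traj.coords[frame, 0]
    r = np.hypot(pts[:, 0], pts[:, 1])
    theta = np.unwrap(np.arctan2(pts[:, 1], pts[:, 0]))
    if not (0 < k_radius <= r.max() + 1e-12):
        raise ValueError("k_radius outside the sampled support")
    k_radius = min(k_radius, r.max())
    drdtheta = np.gradient(r, theta)
    # r is monotone along the spiral: invert by interpolation
    spacing = 2 * np.pi * np.interp(k_radius, r, drdtheta) / cfg.n_interleaves
    if spacing <= 0:
        raise ValueError("degenerate spiral geometry at this radius")
    return (1.0 / cfg.matrix_size) / spacing


# ---------------------------------------------------------------------------
# protocol timing


def scan_duration(protocol: ProtocolSpec) -> int:
    """Breathhold length in heartbeats.

    One heartbeat acquires one spiral interleaf for one encoded acquisition;
    ``encoding_dims + 1`` encoded acquisitions are needed, plus a fixed
    scheduling overhead (default 2 heartbeats).  This model reproduces all
    reference protocol durations.
    """
    return protocol.n_interleaves * (protocol.encoding_dims + 1) \
        + protocol.overhead_heartbeats


def temporal_resolution(protocol: ProtocolSpec) -> float:
    """Cine temporal resolution in ms (views per cardiac phase times TR)."""
    return protocol.views_per_frame * protocol.tr_ms
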