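"""Displacement and circumferential-strain analysis of cine DENSE images.

From phase to strain the pipeline is: wrap-robust spatial phase unwrapping
within the myocardial mask (with a temporal-consistency pass anchored at the
reference frame), conversion of phase to displacement u = phi / (2 pi ke),
inversion of the measured Eulerian displacement onto the reference-frame
(material) grid, a windowed weighted-least-squares fit of the local
deformation gradient F, the Lagrangian strain tensor E = (F^T F - I)/2, and
projection onto the circumferential direction about the LV centroid.
Segmental reporting follows the standard AHA 6-sector division of the
short-axis ring anchored at the anterior RV insertion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from skimage.draw import polygon2mask
from skimage.restoration import unwrap_phase as _unwrap2d

__all__ = [
    "Contours",
    "DisplacementField",
    "StrainResult",
    "circle_contour",
    "contours_mask",
    "propagate_contours",
    "unwrap_phase",
    "phase_to_displacement",
    "lagrangian_from_eulerian",
    "compute_ecc",
    "segment_aha6",
    "segmental_ecc_curves",
    "strain_from_images",
]


@dataclass
class Contours:
    """Closed endo-/epicardial polylines (vertex arrays of (x, y) pixel
    coordinates, image-indexed) at the reference frame, plus the anterior RV
    insertion angle in degrees (image convention, y down)."""

    endo: np.ndarray
    epi: np.ndarray
    rv_insertion_deg: float = 0.0

    def __post_init__(self):
        self.endo = np.asarray(self.endo, float)
        self.epi = np.asarray(self.epi, float)
        for c in (self.endo, self.epi):
            if c.ndim != 2 or c.shape[1] != 2 or len(c) < 3:
                raise ValueError("contours must be (n, 2) vertex arrays")

    def centroid(self) -> np.ndarray:
        return self.epi.mean(axis=0)


@dataclass
class DisplacementField:
    """Per-frame Lagrangian displacement (mm) sampled on reference-frame
    myocardial pixels: ``u[frame, :, y, x]`` with components (ux, uy) valid
    where ``mask`` is true.  Frame 0 is identically zero."""

    u: np.ndarray
    mask: np.ndarray
    pixel_spacing: float

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]


@dataclass
class StrainResult:
    """Circumferential strain maps and AHA-6 segmental curves."""

    ecc: np.ndarray              # (frame, y, x), NaN outside the valid mask
    mask: np.ndarray             # reference myocardium
    segments: np.ndarray         # (y, x) labels 1..6, 0 outside
    segmental: pd.DataFrame      # frames x 6 mean Ecc
    global_curve: np.ndarray     # (frame,) mean Ecc over the valid myocardium

    @property
    def peak_global_ecc(self) -> float:
        return float(np.min(self.global_curve))


def circle_contour(centre, radius: float, n_vertices: int = 96) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.stack([centre[0] + radius * np.cos(ang),
                     centre[1] + radius * np.sin(ang)], axis=1)


def contours_mask(contours: Contours, shape) -> np.ndarray:
    """Myocardium mask: inside the epicardial polygon, outside the
    endocardial one.  polygon2mask expects (row, col) = (y, x)."""
    epi = polygon2mask(shape, contours.epi[:, ::-1])
    endo = polygon2mask(shape, contours.endo[:, ::-1])
    return epi & ~endo


def propagate_contours(contours: Contours,
                       displacement: DisplacementField) -> list[Contours]:
    """Advect contour vertices by the local Lagrangian displacement each
    frame.  Vertices whose displacement is not defined (outside the mask) use
    the nearest valid value; vertices leaving the image are clipped with a
    warning."""
    ny, nx = displacement.mask.shape
    yy, xx = np.nonzero(displacement.mask)
    pts = np.stack([xx, yy], axis=1).astype(float)
    out = []
    for t in range(displacement.n_frames):
        u_px = displacement.u[t, :, yy, xx] / displacement.pixel_spacing  # (npts, 2)
        new = {}
        for name in ("endo", "epi"):
            verts = getattr(contours, name)
            shift = np.stack([
                griddata(pts, u_px[:, c], verts, method="nearest")
                for c in range(2)
            ], axis=1)
            moved = verts + shift
            oob = ((moved[:, 0] < 0) | (moved[:, 0] > nx - 1)
                   | (moved[:, 1] < 0) | (moved[:, 1] > ny - 1))
            if oob.any():
                warnings.warn("contour vertex left the image; clipping",
                              RuntimeWarning, stacklevel=2)
                moved[:, 0] = np.clip(moved[:, 0], 0, nx - 1)
                moved[:, 1] = np.clip(moved[:, 1], 0, ny - 1)
            new[name] = moved
        out.append(Contours(endo=new["endo"], epi=new["epi"],
                            rv_insertion_deg=contours.rv_insertion_deg))
    return out


# ---------------------------------------------------------------------------
# phase processing


def unwrap_phase(phase_series: np.ndarray, mask: np.ndarray,
                 reference_frame: int = 0) -> np.ndarray:
    """Spatially unwrap each frame within its mask, then anchor frames
    temporally so the masked median matches the reference frame (which is
    assumed to carry ~zero phase) up to much less than 2 pi.

    ``mask`` may be a single 2-D mask or one mask per frame.  Disconnected
    mask regions unwrap independently (a warning is emitted by the caller's
    logger if needed).  The output is congruent to the input modulo 2 pi.
    """
    phase_series = np.asarray(phase_series, float)
    single = phase_series.ndim == 2
    phases = phase_series[None] if single else phase_series
    masks = np.asarray(mask, bool)
    if masks.ndim == 2:
        masks = np.broadcast_to(masks, phases.shape)
    out = np.zeros_like(phases)
    for t in range(phases.shape[0]):
        m = masks[t]
        ma = np.ma.array(phases[t], mask=~m)
        uw = np.ma.filled(_unwrap2d(ma), 0.0)
        # temporal anchoring: shift by the 2-pi multiple closest to zero
        # median (the reference encoding is subtracted, so the true phase at
        # the reference frame is ~0 and stays within one cycle elsewhere
        # relative to the previous frame's median)
        anchor = 0.0 if t == 0 else float(np.median(out[t - 1][masks[t - 1]]))
        med = np.median(uw[m])
        shift = 2 * np.pi * np.round((med - anchor) / (2 * np.pi))
        out[t] = np.where(m, uw - shift, 0.0)
    return out[0] if single else out


def phase_to_displacement(phase: np.ndarray, ke: float,
                          pixel_spacing: float | None = None) -> np.ndarray:
    """Displacement (mm) from unwrapped displacement-encoded phase:
    u = phi / (2 pi ke) with ke in cycles/mm."""
    if ke == 0:
        raise ValueError("ke must be non-zero")
    return np.asarray(phase, float) / (2 * np.pi * ke)


def lagrangian_from_eulerian(u_e: np.ndarray, frame_masks: np.ndarray,
                             ref_mask: np.ndarray,
                             pixel_spacing: float) -> DisplacementField:
    """Resample Eulerian DENSE displacements onto the material grid.

    DENSE phase at a deformed pixel x gives u(x) = x - X, i.e. the material
    origin X = x - u.  Scattering the samples at their material origins and
    linearly interpolating onto the reference-frame myocardium yields the
    Lagrangian field u_L(X) (zero at the reference frame by construction).

    Parameters
    ----------
    u_e : (frame, 2, N, N) Eulerian displacement in mm, components (ux, uy)
    frame_masks : (frame, N, N) validity of ``u_e`` per frame
    ref_mask : (N, N) reference-frame myocardium
    """
    n_frames = u_e.shape[0]
    ny, nx = ref_mask.shape
    yy, xx = np.nonzero(ref_mask)
    targets = np.stack([xx, yy], axis=1).astype(float)
    u = np.zeros((n_frames, 2, ny, nx))
    for t in range(n_frames):
        m = frame_masks[t]
        py, px = np.nonzero(m)
        pos = np.stack([px, py], axis=1).astype(float)
        disp_px = np.stack([u_e[t, 0][m], u_e[t, 1][m]], axis=1) / pixel_spacing
        material = pos - disp_px
        for c in range(2):
            vals = griddata(material, disp_px[:, c], targets, method="linear")
            hole = np.isnan(vals)
            if hole.any():
                vals[hole] = griddata(material, disp_px[:, c], targets[hole],
                                      method="nearest")
            u[t, c, yy, xx] = vals * pixel_spacing
    return DisplacementField(u=u, mask=ref_mask, pixel_spacing=pixel_spacing)


# ---------------------------------------------------------------------------
# strain


def _fit_deformation_gradient(u_px: np.ndarray, mask: np.ndarray,
                              window: int = 5, sigma: float = 1.5):
    """Per-pixel 2x2 deformation gradient from a windowed weighted-least-
    squares fit of neighbouring displacements (Gaussian weights); pixels with
    fewer than 6 valid neighbours are masked out."""
    ny, nx = mask.shape
    half = window // 2
    offs = np.arange(-half, half + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    w_kernel = np.exp(-(oy ** 2 + ox ** 2) / (2 * sigma ** 2)).ravel()
    yy, xx = np.nonzero(mask)
    F = np.full((ny, nx, 2, 2), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    for y, x in zip(yy, xx):
        ys = y + oy.ravel()
        xs = x + ox.ravel()
        ok = (ys >= 0) & (ys < ny) & (xs >= 0) & (xs < nx)
        ok[ok] &= mask[ys[ok], xs[ok]]
        if ok.sum() < 6:
            continue
        a = np.stack([np.ones(ok.sum()), xs[ok] - x, ys[ok] - y], axis=1)
        w = w_kernel[ok]
        aw = a * w[:, None]
        try:
            coef, *_ = np.linalg.lstsq(aw, u_px[:, ys[ok], xs[ok]].T * w[:, None],
                                       rcond=None)
        except np.linalg.LinAlgError:
            continue
        # coef rows: [offset, d/dx, d/dy]; columns: (ux, uy)
        grad = coef[1:].T          # (2 comps, 2 derivs) = du_i/dx_j
        F[y, x] = np.eye(2) + grad
        valid[y, x] = True
    return F, valid


def compute_ecc(displacement: DisplacementField,
                contours: Contours) -> StrainResult:
    """Lagrangian circumferential strain from the material displacement
    field: E = (F^T F - I)/2 projected on the circumferential unit vector
    about the LV centroid.  Rotation-invariant; contraction gives Ecc < 0."""
    centre = contours.centroid()
    mask = displacement.mask
    ny, nx = mask.shape
    n_frames = displacement.n_frames
    ecc = np.full((n_frames, ny, nx), np.nan)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny))
    theta = np.arctan2(yy - centre[1], xx - centre[0])
    e_c = np.stack([-np.sin(theta), np.cos(theta)], axis=-1)  # (y, x, 2)
    for t in range(n_frames):
        u_px = displacement.u[t] / displacement.pixel_spacing
        F, valid = _fit_deformation_gradient(u_px, mask)
        e = 0.5 * (np.einsum("yxji,yxjk->yxik", F, F)
                   - np.eye(2)[None, None])
        proj = np.einsum("yxi,yxij,yxj->yx", e_c, e, e_c)
        ecc[t] = np.where(valid, proj, np.nan)
    segments = segment_aha6(mask, contours)
    segmental = segmental_ecc_curves(ecc, segments)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        global_curve = np.nanmean(ecc.reshape(n_frames, -1), axis=1)
    return StrainResult(ecc=ecc, mask=mask, segments=segments,
                        segmental=segmental, global_curve=global_curve)


def segment_aha6(mask: np.ndarray, contours: Contours) -> np.ndarray:
    """AHA 6-segment labels: equal 60-degree sectors about the LV centroid,
    numbered 1..6 counterclockwise from the anterior RV insertion."""
    centre = contours.centroid()
    ny, nx = mask.shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny))
    # anatomical counterclockwise is clockwise in image coordinates (y down)
    theta = -np.rad2deg(np.arctan2(yy - centre[1], xx - centre[0]))
    rel = np.mod(theta - contours.rv_insertion_deg, 360.0)
    labels = (rel // 60).astype(int) + 1
    return np.where(mask, labels, 0)


def segmental_ecc_curves(ecc: np.ndarray, segments: np.ndarray) -> pd.DataFrame:
    """Mean Ecc per AHA segment per frame (unweighted pixel mean)."""
    n_frames = ecc.shape[0]
    cols = {}
    for s in range(1, 7):
        sel = segments == s
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cols[f"segment_{s}"] = [
                float(np.nanmean(ecc[t][sel])) if sel.any() else np.nan
                for t in range(n_frames)
            ]
    return pd.DataFrame(cols, index=pd.RangeIndex(n_frames, name="frame"))


# ---------------------------------------------------------------------------
# end-to-end


def strain_from_images(images, contours: Contours,
                       magnitude_threshold: float = 0.4,
                       erode_mask: int = 1) -> StrainResult:
    """Full DENSE analysis of a combined image series (ref, x-enc, y-enc).

    Phase differences arg(enc * conj(ref)) are unwrapped within per-frame
    magnitude masks, converted to displacement, resampled onto the material
    grid bounded by the contours, and differentiated into circumferential
    strain.  ``magnitude_threshold`` is relative to the 99th-percentile
    frame magnitude; the reference myocardium is optionally eroded to keep
    partial-volume edge pixels out of the strain aggregation.
    """
    from scipy.ndimage import binary_erosion

    data = images.data[:, :, 0]  # combined: coil axis length 1
    n_frames = data.shape[0]
    mag = np.abs(data[:, 0])
    thresh = magnitude_threshold * np.percentile(mag, 99, axis=(1, 2))
    frame_masks = mag > thresh[:, None, None]
    phases = np.stack([
        np.angle(data[:, e] * np.conj(data[:, 0])) for e in (1, 2)
    ], axis=1)  # (frame, 2, N, N)
    u_e = np.empty_like(phases)
    for c in range(2):
        uw = unwrap_phase(phases[:, c], frame_masks)
        u_e[:, c] = phase_to_displacement(uw, images.ke)
    ref_mask = contours_mask(contours, frame_masks.shape[-2:])
    if erode_mask:
        ref_mask_eroded = binary_erosion(ref_mask, iterations=erode_mask)
        if ref_mask_eroded.sum() >= 16:
            ref_mask = ref_mask_eroded
    disp = lagrangian_from_eulerian(u_e, frame_masks, ref_mask,
                                    images.pixel_spacing)
    return compute_ecc(disp, contours)
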