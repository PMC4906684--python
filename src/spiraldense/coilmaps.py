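"""Coil sensitivity estimation by blockwise eigen-analysis.

The time-averaged (undersampled) phase-reference images are the calibration
data: within each 8x8 block (stride 4) the coil-by-coil sample covariance is
formed and its dominant eigenvector taken as the local sensitivity vector.
Overlapping block estimates are phase-aligned and averaged per pixel, the
maps are normalised so that the sensitivities have unit sum-of-squares on the
support, and pixels below a magnitude threshold are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoilSensitivities", "estimate_sensitivities", "sense_combine"]


@dataclass
class CoilSensitivities:
    """Complex sensitivity per coil (coil, y, x); sum_c |S|^2 = 1 on the
    support mask and S = 0 outside it."""

    maps: np.ndarray
    support: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


def estimate_sensitivities(reference_time_avg: np.ndarray,
                           block: int = 8, stride: int = 4,
                           support_frac: float = 0.10,
                           refine_sigma: float | None = 1.0) -> CoilSensitivities:
    """Estimate sensitivity maps from per-coil time-averaged reference images.

    The blockwise eigen-analysis smooths the sensitivities over the analysis
    window; a final pointwise refinement projects the calibration images onto
    the eigen-combined image (with light Gaussian smoothing of the projection
    products) to remove that window bias while keeping noise averaging.

    Parameters
    ----------
    reference_time_avg : (coil, N, N) complex array
    block, stride : blockwise eigen-analysis window geometry (pixels)
    support_frac : support threshold as a fraction of the 99th-percentile
        coil-combined magnitude
    refine_sigma : smoothing of the refinement pass; None skips refinement
    """
    imgs = np.asarray(reference_time_avg, dtype=complex)
    if imgs.ndim != 3:
        raise ValueError("expected (coil, y, x) calibration images")
    n_coils, ny, nx = imgs.shape
    if not np.any(imgs):
        raise ValueError("all-zero calibration data")

    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    support = rss > support_frac * np.percentile(rss, 99)

    if n_coils == 1:
        maps = np.zeros_like(imgs)
        maps[0][support] = 1.0
        return CoilSensitivities(maps=maps, support=support)

    acc = np.zeros((n_coils, ny, nx), dtype=complex)
    cnt = np.zeros((ny, nx))
    ys = _anchors(ny, block, stride)
    xs = _anchors(nx, block, stride)
    for y0 in ys:
        for x0 in xs:
            patch = imgs[:, y0:y0 + block, x0:x0 + block].reshape(n_coils, -1)
            cov = patch @ patch.conj().T
            w, v = np.linalg.eigh(cov)
            e = v[:, -1]
            # fix the per-block phase ambiguity before averaging
            ref = e[np.argmax(np.abs(e))]
            e = e * np.conj(ref) / max(np.abs(ref), 1e-30)
            acc[:, y0:y0 + block, x0:x0 + block] += e[:, None, None]
            cnt[y0:y0 + block, x0:x0 + block] += 1.0
    maps = acc / np.maximum(cnt, 1.0)

    # phase-reference every pixel to coil 0 and normalise on the support
    norm = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        maps = np.where(norm > 0, maps / norm, 0.0)
    ph0 = np.exp(-1j * np.angle(np.where(maps[0] == 0, 1.0, maps[0])))
    maps = maps * ph0[None]
    maps[:, ~support] = 0.0
    if refine_sigma is not None:
        maps = _pointwise_refine(imgs, maps, support, refine_sigma)
    return CoilSensitivities(maps=maps, support=support)


def _pointwise_refine(imgs: np.ndarray, maps: np.ndarray, support: np.ndarray,
                      sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    combined = np.sum(np.conj(maps) * imgs, axis=0)
    prod = imgs * np.conj(combined)[None]
    num = np.stack([
        gaussian_filter(p.real, sigma) + 1j * gaussian_filter(p.imag, sigma)
        for p in prod
    ])
    norm = np.sqrt(np.sum(np.abs(num) ** 2, axis=0))
    out = np.where(norm > 0, num / np.maximum(norm, 1e-30), 0.0)
    ph0 = np.exp(-1j * np.angle(np.where(out[0] == 0, 1.0, out[0])))
    out = out * ph0[None]
    out[:, ~support] = 0.0
    return out


def _anchors(n: int, block: int, stride: int) -> np.ndarray:
    a = list(range(0, n - block + 1, stride))
    if a[-1] != n - block:
        a.append(n - block)
    return np.asarray(a)


def sense_combine(multicoil_images: np.ndarray,
                  maps: CoilSensitivities | np.ndarray) -> np.ndarray:
    """SENSE combination sum_c conj(S_c) * m_c along the leading coil axis
    (the maps are normalised, so no denominator is needed on the support)."""
    s = maps.maps if isinstance(maps, CoilSensitivities) else np.asarray(maps)
    m = np.asarray(multicoil_images)
    if s.shape != m.shape:
        raise ValueError("image and map shapes must match")
    return np.sum(np.conj(s) * m, axis=0)
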