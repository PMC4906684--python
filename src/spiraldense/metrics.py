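"""Image-quality and agreement statistics.

The relative root-mean-square error follows the per-pixel-normalised form

    rRMSE = (1/N) * sqrt( sum |m_ref - m_recon|^2 / |m_ref|^2 )

with the 1/N factor outside the square root and the sum running over the
evaluated pixels; a series is scored frame by frame and averaged over the
cardiac phases.  Pixels where the reference magnitude is exactly zero are
excluded from the sum (with N reduced accordingly) rather than regularised,
because the phantom background is exactly zero.  A conventional global-norm
variant is available behind a flag for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementStats",
    "rrmse",
    "roi_phase_rrmse",
    "snr_estimate",
    "linear_correlation",
    "bland_altman",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementStats:
    slope: float | None = None
    intercept: float | None = None
    r: float | None = None
    bias: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _rrmse_single(ref: np.ndarray, recon: np.ndarray,
                  mask: np.ndarray | None, per_pixel: bool) -> float:
    ref = np.asarray(ref)
    recon = np.asarray(recon)
    if ref.shape != recon.shape:
        raise ValueError("reference and reconstruction shapes differ")
    sel = np.ones(ref.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    zero = np.abs(ref) == 0
    if np.any(zero & sel):
        log.debug("rRMSE: excluding %d zero-reference pixels", int((zero & sel).sum()))
    sel = sel & ~zero
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no valid pixels to evaluate")
    diff2 = np.abs(ref[sel] - recon[sel]) ** 2
    if per_pixel:
        return float(np.sqrt(np.sum(diff2 / np.abs(ref[sel]) ** 2)) / n)
    return float(np.sqrt(np.sum(diff2) / np.sum(np.abs(ref[sel]) ** 2)))


def rrmse(m_ref: np.ndarray, m_recon: np.ndarray,
          mask: np.ndarray | None = None, per_pixel: bool = True) -> float:
    """Relative RMS error of complex images.

    2-D inputs are scored directly; higher-dimensional inputs are treated as
    stacks of 2-D frames (leading axes flattened) whose scores are averaged
    over the cardiac phases.  ``mask`` restricts the evaluated pixels and may
    be 2-D (shared) or match the stacked shape.  ``per_pixel=False`` selects
    the conventional global-norm ratio instead of the per-pixel form.
    """
    m_ref = np.asarray(m_ref)
    m_recon = np.asarray(m_recon)
    if m_ref.ndim <= 2:
        return _rrmse_single(m_ref, m_recon, mask, per_pixel)
    lead = m_ref.shape[:-2]
    ref2 = m_ref.reshape((-1,) + m_ref.shape[-2:])
    rec2 = m_recon.reshape((-1,) + m_ref.shape[-2:])
    if mask is None:
        masks = [None] * len(ref2)
    elif np.asarray(mask).ndim == 2:
        masks = [mask] * len(ref2)
    else:
        masks = np.asarray(mask, bool).reshape((-1,) + m_ref.shape[-2:])
    return float(np.mean([
        _rrmse_single(a, b, m, per_pixel) for a, b, m in zip(ref2, rec2, masks)
    ]))


def roi_phase_rrmse(phase_ref: np.ndarray, phase_recon: np.ndarray,
                    mask: np.ndarray, per_pixel: bool = True) -> float:
    """rRMSE of phase images over a region of interest (the myocardium).

    Phase differences are taken wrap-consistently (pi and -pi are the same
    angle) before entering the ratio.  The per-pixel form is numerically
    meaningless wherever the reference phase crosses zero inside the ROI
    (the ratio diverges), so aggregated reports use ``per_pixel=False``,
    which normalises by the ROI's phase energy instead.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    ref = np.asarray(phase_ref, float)
    rec = np.asarray(phase_recon, float)
    delta = np.angle(np.exp(1j * (ref - rec)))
    # score |delta| against |phase_ref| with the same Eq-form as rrmse
    return rrmse(ref, ref - delta, mask=mask, per_pixel=per_pixel)


def snr_estimate(image: np.ndarray, signal_mask: np.ndarray,
                 noise_mask: np.ndarray) -> float:
    """SNR in dB: 20*log10(mean |signal| / std of the real and imaginary
    noise components pooled over the noise region)."""
    signal_mask = np.asarray(signal_mask, bool)
    noise_mask = np.asarray(noise_mask, bool)
    if np.any(signal_mask & noise_mask):
        raise ValueError("signal and noise masks must be disjoint")
    img = np.asarray(image, complex)
    noise = img[noise_mask]
    sigma = np.std(np.concatenate([noise.real, noise.imag]))
    if sigma == 0:
        raise ValueError("noise region has zero variance")
    return float(20.0 * np.log10(np.mean(np.abs(img[signal_mask])) / sigma))


def linear_correlation(a, b) -> AgreementStats:
    """Ordinary least-squares fit of b on a plus the Pearson correlation."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need two paired series of length >= 2")
    res = stats.linregress(a, b)
    return AgreementStats(slope=float(res.slope), intercept=float(res.intercept),
                          r=float(res.rvalue))


def bland_altman(a, b) -> AgreementStats:
    """Bland-Altman agreement: bias = mean(a - b) with 95% limits of
    agreement at bias +/- 1.96 * sd(a - b)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need two paired series of length >= 2")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(bias=bias, loa_low=bias - 1.96 * sd,
                          loa_high=bias + 1.96 * sd)
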