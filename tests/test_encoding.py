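"""DENSE echo algebra, operator properties, and reference reconstructions."""

import numpy as np
import pytest

from spiraldense import (EncodingScheme, KSpaceData, Nufft2, combine_encodings,
                         design_vd_spiral, nufft_adjoint, nufft_forward,
                         phase_cycle_subtract, preset_config, sample_kspace,
                         simulate_dense_images, sos_reconstruct,
                         zero_pad_reconstruct)


def _kspace_like(traj, data):
    return KSpaceData(data=data, trajectory=traj, encoding_labels=("a", "b", "c"),
                      ke=0.1, pixel_spacing=2.5)


@pytest.fixture(scope="module")
def traj8():
    return design_vd_spiral(preset_config("rate4", matrix_size=32, n_frames=1))


def test_phase_cycle_subtraction_cancels_t1_echo(traj8):
    """cycle0 = S + T, cycle1 = -S + T  ->  exactly S."""
    rng = np.random.default_rng(0)
    shape = (1, 3, 1, 1, traj8.n_interleaves, traj8.n_samples)
    s = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    t1 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    raw = _kspace_like(traj8, np.concatenate([s + t1, -s + t1], axis=2))
    out = phase_cycle_subtract(raw)
    assert np.max(np.abs(out.data - s)) < 1e-12
    # T = 0 path
    raw2 = _kspace_like(traj8, np.concatenate([s, -s], axis=2))
    assert np.max(np.abs(phase_cycle_subtract(raw2).data - s)) < 1e-12


def test_phase_cycle_needs_two_cycles(traj8):
    raw = _kspace_like(traj8, np.zeros((1, 3, 1, 1, traj8.n_interleaves,
                                        traj8.n_samples), complex))
    with pytest.raises(ValueError):
        phase_cycle_subtract(raw)


def test_simple_scheme_is_identity(traj8):
    rng = np.random.default_rng(1)
    shape = (1, 3, 1, 1, traj8.n_interleaves, traj8.n_samples)
    data = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    k = _kspace_like(traj8, data)
    out = combine_encodings(k, EncodingScheme.simple())
    assert np.allclose(out.data, data, atol=1e-12)
    assert out.encoding_labels == ("ref", "x-enc", "y-enc")


def test_balanced_forward_then_invert(traj8):
    """Synthetic acquisitions built by mixing known (ref, x, y) components
    through the balanced matrix are inverted to < 1e-10."""
    scheme = EncodingScheme.balanced()
    rng = np.random.default_rng(2)
    comp = rng.standard_normal((1, 3, 1, 1, traj8.n_interleaves, traj8.n_samples)) \
        + 1j * rng.standard_normal((1, 3, 1, 1, traj8.n_interleaves, traj8.n_samples))
    acquired = np.einsum("ae,fe...->fa...", scheme.matrix, comp)
    out = combine_encodings(_kspace_like(traj8, acquired), scheme)
    assert np.max(np.abs(out.data - comp)) < 1e-10
    zero = combine_encodings(_kspace_like(traj8, np.zeros_like(acquired)), scheme)
    assert np.allclose(zero.data, 0.0)


def test_rank_deficient_scheme_rejected():
    with pytest.raises(ValueError):
        EncodingScheme("bad", np.array([[1.0, 0, 0], [1.0, 0, 0], [0, 0, 1.0]]))


def test_operator_linearity_with_maps():
    rng = np.random.default_rng(3)
    coords = rng.uniform(-0.45, 0.45, size=(80, 2))
    nufft = Nufft2((16, 16), coords)
    maps = rng.standard_normal((3, 16, 16)) + 1j * rng.standard_normal((3, 16, 16))
    x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    y = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    a, b = 1.5 - 0.5j, 0.25j
    lhs = nufft_forward(a * x + b * y, nufft, maps)
    rhs = a * nufft_forward(x, nufft, maps) + b * nufft_forward(y, nufft, maps)
    assert np.allclose(lhs, rhs, atol=1e-10 * np.abs(lhs).max())
    # adjoint consistency <Ax, s> = <x, A^H s>
    s = rng.standard_normal((3, 80)) + 1j * rng.standard_normal((3, 80))
    lhs2 = np.vdot(s, nufft_forward(x, nufft, maps))
    rhs2 = np.vdot(nufft_adjoint(s, nufft, maps=maps), x)
    assert abs(lhs2 - rhs2) / abs(lhs2) < 1e-6


def test_sos_single_and_duplicated_coils(small_phantom, small_full_kspace):
    cfg, motion, images = small_phantom
    traj, k_full = small_full_kspace
    mag1, phase1, _ = sos_reconstruct(k_full)
    # duplicating the single coil doubles energy: magnitude scales by sqrt(2)
    dup = KSpaceData(data=np.concatenate([k_full.data] * 2, axis=3),
                     trajectory=traj, encoding_labels=k_full.encoding_labels,
                     ke=k_full.ke, pixel_spacing=k_full.pixel_spacing)
    mag2, phase2, _ = sos_reconstruct(dup)
    assert np.allclose(mag2, np.sqrt(2) * mag1, rtol=1e-9)
    support = mag1 > 0.2 * mag1.max()
    dphi = np.angle(np.exp(1j * (phase2 - phase1)))
    assert np.max(np.abs(dphi[support])) < 1e-9


def test_sos_zero_data(small_full_kspace):
    traj, k_full = small_full_kspace
    zero = KSpaceData(data=np.zeros_like(k_full.data), trajectory=traj,
                      encoding_labels=k_full.encoding_labels, ke=k_full.ke,
                      pixel_spacing=k_full.pixel_spacing)
    mag, phase, _ = sos_reconstruct(zero)
    assert np.allclose(mag, 0.0)


def test_zero_pad_matches_sos_on_full_sampling(small_full_kspace):
    """For fully-sampled single-coil data the zero-padding reconstruction is
    the same dcf-adjoint operator as the SOS path."""
    traj, k_full = small_full_kspace
    mag, phase, _ = sos_reconstruct(k_full)
    zp = zero_pad_reconstruct(k_full)
    assert np.allclose(np.abs(zp.data[:, :, 0]), mag, rtol=1e-9, atol=1e-12)


def test_phase_difference_recovers_displacement(small_phantom, small_full_kspace):
    """arg(enc * conj(ref)) / (2 pi ke) returns the simulated displacement:
    exactly (< 1e-3 px) on the noiseless images, and to within a small
    gridding/band-limiting tolerance after the fully-sampled reconstruction."""
    cfg, motion, images = small_phantom
    traj, k_full = small_full_kspace
    t = int(np.argmin(motion.alpha))
    u_true_px = motion.eulerian_displacement(t)
    from scipy.ndimage import binary_erosion
    interior = binary_erosion(np.abs(images.data[t, 0, 0]) > 0.99, iterations=2)
    scale = 2 * np.pi * cfg.ke * cfg.pixel_spacing

    phase_sim = np.angle(images.data[t, 1, 0] * np.conj(images.data[t, 0, 0]))
    # compare wrap-consistently: the phase may exceed +/- pi inside the ring
    err_sim = np.angle(np.exp(1j * (phase_sim - scale * u_true_px[0]))) / scale
    assert np.max(np.abs(err_sim[interior])) < 1e-3

    rec = zero_pad_reconstruct(k_full)
    phase_rec = np.angle(rec.data[t, 1, 0] * np.conj(rec.data[t, 0, 0]))
    err_rec = np.angle(np.exp(1j * (phase_rec - scale * u_true_px[0]))) / scale
    assert np.max(np.abs(err_rec[interior])) < 0.05
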