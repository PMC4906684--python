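"""Phantom motion, DENSE encoding and k-space sampling."""

import numpy as np
import pytest

from spiraldense import (Nufft2, PhantomConfig, TrajectoryConfig, analytic_ecc,
                         design_vd_spiral, generate_motion, preset_config,
                         sample_kspace, simulate_dense_images)


def test_identity_motion_when_no_contraction():
    cfg = PhantomConfig(matrix_size=64, epi_radius=14, endo_radius=8,
                        n_frames=8, contraction_amplitude=1.0)
    motion = generate_motion(cfg)
    pts = np.array([[10.0, 0.0], [-3.0, 7.0]])
    for t in range(cfg.n_frames):
        assert np.allclose(motion.displacement(pts, t), 0.0)


def test_peak_systolic_radial_displacement():
    """A material point at R = 25 px displaces radially by (alpha-1)*R at the
    frame of peak contraction."""
    cfg = PhantomConfig(matrix_size=128, epi_radius=28, endo_radius=16,
                        n_frames=16, contraction_amplitude=0.9)
    motion = generate_motion(cfg)
    peak = int(np.argmin(motion.alpha))
    assert motion.alpha[peak] == pytest.approx(0.9)
    u = motion.displacement(np.array([[25.0, 0.0]]), peak)
    assert u[0, 0] == pytest.approx(-2.5, abs=1e-9)
    assert u[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_frame_zero_is_reference():
    cfg = PhantomConfig(matrix_size=64, epi_radius=14, endo_radius=8, n_frames=8)
    motion = generate_motion(cfg)
    assert motion.alpha[0] == 1.0
    assert np.allclose(motion.eulerian_displacement(0), 0.0)


def test_static_phantom_has_zero_phase_and_identical_frames():
    cfg = PhantomConfig(matrix_size=32, epi_radius=10, endo_radius=5,
                        n_frames=4, contraction_amplitude=1.0)
    images = simulate_dense_images(cfg, generate_motion(cfg))
    assert np.allclose(np.angle(images.data[np.abs(images.data) > 1e-9]), 0.0)
    for t in range(1, 4):
        assert np.allclose(images.data[t], images.data[0])


def test_encoded_phase_follows_displacement(tiny_phantom):
    """Phase of the x-encoded series equals 2*pi*ke*ux at deformed pixels;
    a 5 px displacement at ke*pixel = 0.1 cycles/px gives phase pi."""
    cfg, motion, images = tiny_phantom
    assert cfg.ke * cfg.pixel_spacing == pytest.approx(1.0)  # 0.1 c/mm * 10 mm/px
    t = int(np.argmin(motion.alpha))
    u_mm = motion.eulerian_displacement(t) * cfg.pixel_spacing
    mag = np.abs(images.data[t, 0, 0])
    interior = mag > 0.99
    expected = np.angle(np.exp(2j * np.pi * cfg.ke * u_mm[0]))
    got = np.angle(images.data[t, 1, 0] * np.conj(images.data[t, 0, 0]))
    assert np.allclose(got[interior], expected[interior], atol=1e-9)
    # hand value: phase pi exactly when ux = 5 px and ke*pixel = 0.1 c/px
    assert 2 * np.pi * 0.1 * 5 == pytest.approx(np.pi)


def test_single_coil_default_axis():
    cfg = PhantomConfig(matrix_size=32, epi_radius=10, endo_radius=5, n_frames=3)
    images = simulate_dense_images(cfg, generate_motion(cfg))
    assert images.n_coils == 1


def test_noise_reproducible_under_seed():
    cfg = PhantomConfig(matrix_size=32, epi_radius=10, endo_radius=5,
                        n_frames=3, snr_db=5.0, seed=42)
    a = simulate_dense_images(cfg, generate_motion(cfg))
    b = simulate_dense_images(cfg, generate_motion(cfg))
    assert np.array_equal(a.data, b.data)
    c = simulate_dense_images(
        PhantomConfig(matrix_size=32, epi_radius=10, endo_radius=5,
                      n_frames=3, snr_db=5.0, seed=43),
        generate_motion(cfg))
    assert not np.array_equal(a.data, c.data)


def test_analytic_strain_oracle():
    cfg = PhantomConfig(matrix_size=64, epi_radius=14, endo_radius=8,
                        n_frames=10, contraction_amplitude=0.8)
    motion = generate_motion(cfg)
    peak = int(np.argmin(motion.alpha))
    assert analytic_ecc(motion, 0) == 0.0
    assert analytic_ecc(motion, peak) == pytest.approx(0.5 * (0.8 ** 2 - 1))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        PhantomConfig(epi_radius=10, endo_radius=12)
    with pytest.raises(ValueError):
        PhantomConfig(n_frames=1)
    with pytest.raises(ValueError):
        PhantomConfig(contraction_amplitude=0.3)


# ---------------------------------------------------------------------------
# k-space sampling


def test_zero_image_gives_zero_kspace(tiny_phantom):
    cfg, motion, images = tiny_phantom
    traj = design_vd_spiral(preset_config("rate4", matrix_size=32,
                                          n_frames=cfg.n_frames))
    zero = simulate_dense_images(cfg, motion)
    zero.data = np.zeros_like(zero.data)
    k = sample_kspace(zero, traj)
    assert np.allclose(k.data, 0.0)


def test_unit_image_dc_sample(tiny_phantom):
    cfg, motion, images = tiny_phantom
    traj = design_vd_spiral(preset_config("full", matrix_size=32,
                                          n_frames=cfg.n_frames))
    ones = simulate_dense_images(cfg, motion)
    ones.data = np.ones_like(ones.data)
    k = sample_kspace(ones, traj)
    # first sample of every interleaf sits at k = 0
    dc = k.data[0, 0, 0, 0, :, 0]
    assert np.allclose(np.abs(dc), 32 * 32, rtol=1e-3)


def test_fully_sampled_roundtrip_recovers_annulus():
    """dcf-weighted adjoint of fully-sampled spiral data recovers the
    disc-band-limited annulus to < 2% (the spiral measures only the inscribed
    k-space disc, so content in the square-band corners is not recoverable)."""
    n = 64
    cfg = PhantomConfig(matrix_size=n, epi_radius=14, endo_radius=8, n_frames=2,
                        contraction_amplitude=1.0)
    images = simulate_dense_images(cfg, generate_motion(cfg))
    img = images.data[0, 0, 0]
    traj = design_vd_spiral(preset_config("full", matrix_size=n, n_frames=2))
    nufft = Nufft2((n, n), traj.frame_coords(0))
    rec = nufft.adjoint(nufft.forward(img) * traj.frame_dcf())
    f = (np.arange(n) - n // 2) / n
    disc = np.hypot(f[None, :], f[:, None]) <= 0.5
    spectrum = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
    ref = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spectrum * disc)))
    assert np.linalg.norm(rec - ref) / np.linalg.norm(ref) < 0.02


def test_trajectory_frame_mismatch_rejected(tiny_phantom):
    cfg, motion, images = tiny_phantom
    traj = design_vd_spiral(preset_config("rate4", matrix_size=32, n_frames=3))
    with pytest.raises(ValueError):
        sample_kspace(images, traj)
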