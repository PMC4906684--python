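"""Shared fixtures: small phantom datasets generated at test time."""

import numpy as np
import pytest

from spiraldense import (PhantomConfig, design_vd_spiral, generate_motion,
                         preset_config, sample_kspace, simulate_dense_images)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 64x64, 16-frame single-coil phantom with its motion field."""
    cfg = PhantomConfig(matrix_size=64, epi_radius=14.0, endo_radius=8.0,
                        n_frames=16, contraction_amplitude=0.82, seed=7)
    motion = generate_motion(cfg)
    images = simulate_dense_images(cfg, motion)
    return cfg, motion, images


@pytest.fixture(scope="session")
def small_full_kspace(small_phantom):
    """Fully-sampled spiral k-space of the small phantom."""
    cfg, motion, images = small_phantom
    traj = design_vd_spiral(preset_config("full", matrix_size=cfg.matrix_size,
                                          fov=cfg.fov, n_frames=cfg.n_frames))
    return traj, sample_kspace(images, traj)


@pytest.fixture(scope="session")
def tiny_phantom():
    """6-frame 32x32 phantom for the fastest end-to-end checks."""
    cfg = PhantomConfig(matrix_size=32, epi_radius=10.0, endo_radius=5.0,
                        n_frames=6, contraction_amplitude=0.85, seed=3)
    motion = generate_motion(cfg)
    images = simulate_dense_images(cfg, motion)
    return cfg, motion, images
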