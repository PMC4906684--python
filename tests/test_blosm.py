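"""Block partition, clustering, Casorati/SVT algebra, and the iterative
reconstructions."""

import numpy as np
import pytest

from spiraldense import (KSpaceData, ReconConfig, blosm_sense_reconstruct,
                         build_casorati, casorati_to_blocks, design_vd_spiral,
                         merge_blocks, partition_blocks, preset_config,
                         propagate_and_cluster, sense_reconstruct, svt,
                         zero_pad_reconstruct)
from spiraldense.blosm import _regularize


def test_partition_counts_and_coverage():
    cfg = ReconConfig(block_size=8, stride=8)
    part = partition_blocks((128, 128), cfg)
    assert part.n_blocks == 256

    cfg2 = ReconConfig(block_size=8, stride=4)
    part2 = partition_blocks((128, 128), cfg2)
    cover = np.zeros((128, 128), dtype=int)
    for y, x in part2.anchors:
        cover[y:y + 8, x:x + 8] += 1
    assert cover.min() >= 1
    assert np.all(cover[8:-8, 8:-8] == 4)  # interior overlap factor

    one = partition_blocks((16, 16), ReconConfig(block_size=16, stride=16))
    assert one.n_blocks == 1


def test_single_anchor_cluster_contains_all_frames_and_encodings():
    cfg = ReconConfig(block_size=16, stride=16, n_clusters=1)
    part = partition_blocks((16, 16), cfg)
    imgs = np.random.default_rng(0).standard_normal((5, 3, 16, 16))
    clusters = propagate_and_cluster(imgs, part, cfg)
    assert clusters.n_clusters == 1
    blocks = np.stack([imgs[:, :, y:y + 16, x:x + 16]
                       for y, x in part.anchors[clusters.members(0)]])
    assert build_casorati(blocks).shape == (256, 5 * 3)


def test_two_region_clustering_matches_nearest_centroid():
    """K = 2 on a flat-background/bright-ring image separates the regions the
    same way exhaustive nearest-centroid assignment does."""
    n = 16
    yy, xx = np.mgrid[0:n, 0:n]
    ring = ((np.hypot(xx - 8, yy - 8) > 3) & (np.hypot(xx - 8, yy - 8) < 7))
    img = np.where(ring, 5.0, 0.1)[None, None]
    cfg = ReconConfig(block_size=4, stride=4, n_clusters=2, seed=1)
    part = partition_blocks((n, n), cfg)
    clusters = propagate_and_cluster(img, part, cfg)
    feats = np.stack([np.abs(img[0, 0, y:y + 4, x:x + 4]).ravel()
                      for y, x in part.anchors])
    # brute-force Lloyd assignment from the returned clustering's centroids
    cents = np.stack([feats[clusters.labels == k].mean(axis=0) for k in (0, 1)])
    brute = np.argmin(((feats[:, None] - cents[None]) ** 2).sum(-1), axis=1)
    assert np.array_equal(brute, clusters.labels)
    # the two clusters separate ring-dominated from background blocks
    mean_bright = [feats[clusters.labels == k].mean() for k in (0, 1)]
    assert abs(mean_bright[0] - mean_bright[1]) > 1.0


def test_cluster_count_validation():
    cfg = ReconConfig(block_size=8, stride=8, n_clusters=99)
    part = partition_blocks((16, 16), cfg)
    with pytest.raises(ValueError):
        propagate_and_cluster(np.ones((2, 3, 16, 16)), part, cfg)


def test_casorati_shape_and_roundtrip():
    rng = np.random.default_rng(2)
    blocks = rng.standard_normal((1, 12, 3, 8, 8)) \
        + 1j * rng.standard_normal((1, 12, 3, 8, 8))
    mat = build_casorati(blocks)
    assert mat.shape == (64, 36)
    back = casorati_to_blocks(mat, 1, 12, 3)
    assert np.array_equal(back, blocks)
    static = np.broadcast_to(blocks[:, :1, :1], blocks.shape)
    assert np.linalg.matrix_rank(build_casorati(np.array(static))) == 1


def test_svt_identity_zero_and_full_threshold():
    rng = np.random.default_rng(3)
    m = rng.standard_normal((10, 6)) + 1j * rng.standard_normal((10, 6))
    assert np.max(np.abs(svt(m, 0.0) - m)) < 1e-10
    smax = np.linalg.svd(m, compute_uv=False)[0]
    assert np.allclose(svt(m, smax + 1e-9), 0.0, atol=1e-9)


def test_svt_rank_one_shrinks_singular_value():
    u = np.array([1.0, 1.0, 1.0, 1.0])[:, None] / 2
    v = np.array([1.0, -1.0, 1.0, -1.0])[None, :] / 2
    m = 5.0 * u @ v
    out = svt(m, 2.0)
    assert np.allclose(out, 3.0 * u @ v, atol=1e-10)


def test_svt_matches_explicit_svd_prox_oracle():
    """SVT equals the nuclear-norm proximal operator computed by a separate
    explicit SVD on random complex matrices."""
    rng = np.random.default_rng(4)
    for _ in range(10):
        m = rng.standard_normal((10, 10)) + 1j * rng.standard_normal((10, 10))
        lam = float(rng.uniform(0.1, 3.0))
        u, s, vh = np.linalg.svd(m)
        oracle = u[:, :10] @ np.diag(np.clip(s - lam, 0, None)) @ vh
        assert np.max(np.abs(svt(m, lam) - oracle)) < 1e-10


def test_lambda_zero_regularizer_chain_is_identity():
    """partition -> cluster -> Casorati -> SVT(0) -> merge returns the input
    bit-near exactly."""
    rng = np.random.default_rng(5)
    x = rng.standard_normal((4, 3, 32, 32)) + 1j * rng.standard_normal((4, 3, 32, 32))
    cfg = ReconConfig(block_size=8, stride=4, n_clusters=4, seed=0)
    part = partition_blocks((32, 32), cfg)
    clusters = propagate_and_cluster(np.abs(x), part, cfg)
    out = _regularize(x, clusters, 0.0)
    assert np.max(np.abs(out - x)) < 1e-10


def test_constant_image_preserved_by_regularizer():
    """A constant stack is rank 1: SVT keeps it spatially constant and only
    shrinks its amplitude by exactly lambda/sigma_1."""
    x = np.full((3, 3, 32, 32), 2.0 + 1.0j)
    cfg = ReconConfig(block_size=8, stride=8, n_clusters=2, seed=0)
    part = partition_blocks((32, 32), cfg)
    clusters = propagate_and_cluster(np.abs(x), part, cfg)
    lam = 0.5
    out = _regularize(x, clusters, lam)
    assert np.ptp(out.real) < 1e-10 and np.ptp(out.imag) < 1e-10
    sigma1 = np.abs(2 + 1j) * np.sqrt(64 * 16 * 9)  # rank-1 Casorati norm
    expected = (1 - lam / sigma1) * (2 + 1j)
    assert np.allclose(out, expected, atol=1e-10)


def test_merge_uncovered_pixel_rejected():
    cfg = ReconConfig(block_size=8, stride=8, n_clusters=1)
    part = partition_blocks((32, 32), cfg)
    part.anchors = part.anchors[:-1]  # drop one tile
    clusters = propagate_and_cluster(np.ones((1, 1, 32, 32)), part,
                                     ReconConfig(block_size=8, stride=8,
                                                 n_clusters=1))
    clusters.labels = clusters.labels[:-1]
    blocks = [np.ones((len(clusters.members(0)), 1, 1, 8, 8), complex)]
    with pytest.raises(ValueError):
        merge_blocks(blocks, clusters, 1, 1)


# ---------------------------------------------------------------------------
# iterative reconstructions (shared small dataset)


@pytest.fixture(scope="module")
def tiny32():
    from spiraldense import (PhantomConfig, generate_motion, sample_kspace,
                             simulate_dense_images)
    cfg = PhantomConfig(matrix_size=32, epi_radius=10, endo_radius=5,
                        n_frames=6, contraction_amplitude=0.85, seed=3)
    images = simulate_dense_images(cfg, generate_motion(cfg))
    traj_full = design_vd_spiral(preset_config("full", matrix_size=32, n_frames=6))
    traj4 = design_vd_spiral(preset_config("rate4", matrix_size=32, n_frames=6))
    return {
        "images": images,
        "traj_full": traj_full,
        "k_full": sample_kspace(images, traj_full),
        "traj4": traj4,
        "k4": sample_kspace(images, traj4),
    }


@pytest.fixture(scope="module")
def smooth32(tiny32):
    """Band-limited variant: the ring is Gaussian-smoothed so its spectrum is
    negligible at the k-space edge, isolating operator agreement from
    edge-of-band truncation."""
    from scipy.ndimage import gaussian_filter

    from spiraldense import sample_kspace
    from spiraldense.phantom import DenseImageSeries

    src = tiny32["images"]
    data = np.empty_like(src.data)
    for t in range(data.shape[0]):
        for e in range(3):
            d = src.data[t, e, 0]
            data[t, e, 0] = gaussian_filter(d.real, 1.5) \
                + 1j * gaussian_filter(d.imag, 1.5)
    images = DenseImageSeries(data=data, encoding_labels=src.encoding_labels,
                              ke=src.ke, pixel_spacing=src.pixel_spacing)
    return sample_kspace(images, tiny32["traj_full"])


def test_blosm_full_sampling_lambda_zero_matches_adjoint(tiny32, smooth32):
    """No undersampling and no regularisation: the iteration stays at the
    dcf-adjoint solution (band-limited content)."""
    ref = zero_pad_reconstruct(smooth32)
    cfg = ReconConfig(iterations=5, lambda_scale=0.0, n_clusters=4, seed=0)
    rec = blosm_sense_reconstruct(smooth32, tiny32["traj_full"], config=cfg)
    err = np.linalg.norm(rec.data - ref.data) / np.linalg.norm(ref.data)
    assert err < 0.01


def test_blosm_beats_zero_padding_at_rate4(tiny32):
    ref = zero_pad_reconstruct(tiny32["k_full"])
    zp = zero_pad_reconstruct(tiny32["k4"])
    cfg = ReconConfig(iterations=30, n_clusters=4, seed=0)
    bl = blosm_sense_reconstruct(tiny32["k4"], tiny32["traj4"], config=cfg)
    num_bl = np.linalg.norm(bl.data - ref.data)
    num_zp = np.linalg.norm(zp.data - ref.data)
    assert num_bl < num_zp


def test_blosm_deterministic(tiny32):
    cfg = ReconConfig(iterations=4, n_clusters=4, seed=11)
    a = blosm_sense_reconstruct(tiny32["k4"], tiny32["traj4"], config=cfg)
    b = blosm_sense_reconstruct(tiny32["k4"], tiny32["traj4"], config=cfg)
    assert np.array_equal(a.data, b.data)


def test_fidelity_fixed_point_and_residual_decrease(tiny32):
    """A consistent image is a fixed point of the data-fidelity step, and the
    weighted residual decreases over gradient iterations."""
    from spiraldense.blosm import _SystemModel, data_fidelity_step

    model = _SystemModel(tiny32["k_full"], tiny32["traj_full"], None)
    x = model.initial_image()
    step = 0.9 / model.lipschitz(10, 0)
    _, r_prev = model.gradient(x)
    for _ in range(4):
        x = data_fidelity_step(x, tiny32["k_full"], None, tiny32["traj_full"],
                               step, model=model)
        _, r = model.gradient(x)
        assert r <= r_prev * (1 + 1e-9)
        r_prev = r

    # zero data, zero image stays zero
    zero_k = KSpaceData(data=np.zeros_like(tiny32["k_full"].data),
                        trajectory=tiny32["traj_full"],
                        encoding_labels=tiny32["k_full"].encoding_labels,
                        ke=0.1, pixel_spacing=10.0)
    model0 = _SystemModel(zero_k, tiny32["traj_full"], None)
    x0 = np.zeros_like(x)
    out = data_fidelity_step(x0, zero_k, None, tiny32["traj_full"], step,
                             model=model0)
    assert np.allclose(out, 0.0)


def test_sense_full_sampling_matches_adjoint(tiny32, smooth32):
    ref = zero_pad_reconstruct(smooth32)
    rec = sense_reconstruct(smooth32, tiny32["traj_full"], iterations=30)
    err = np.linalg.norm(rec.data - ref.data) / np.linalg.norm(ref.data)
    assert err < 0.01


def test_sense_is_linear_in_data(tiny32):
    a = sense_reconstruct(tiny32["k4"], tiny32["traj4"], iterations=6)
    doubled = KSpaceData(data=2 * tiny32["k4"].data, trajectory=tiny32["traj4"],
                         encoding_labels=tiny32["k4"].encoding_labels,
                         ke=0.1, pixel_spacing=10.0)
    b = sense_reconstruct(doubled, tiny32["traj4"], iterations=6)
    assert np.allclose(b.data, 2 * a.data, rtol=1e-8, atol=1e-10)
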