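"""Unit tests of the processing pipeline and Richardson-Lucy deconvolution."""

import numpy as np
import pandas as pd
import pytest

import lfcyto as lf
from lfcyto.reconstruct import _frame_stats


def _mini_seq(frames, channels=None, timestamps=None, two_color=False):
    n = len(frames)
    return lf.FrameSequence(
        frames=np.asarray(frames, dtype=np.uint16),
        channels=np.asarray(channels if channels is not None else [0] * n),
        timestamps=np.asarray(timestamps if timestamps is not None
                              else np.arange(n, dtype=float)),
        truth=pd.DataFrame(columns=["frame", "object_id", "kind", "channel",
                                    "x", "y", "z", "photons"]),
        voxel=(0.1, 0.2, 0.2),
        saturated=np.zeros(n, dtype=bool),
        meta={"two_color": two_color},
    )


# ---------------------------------------------------------------- screening

def test_screen_blank_sequence_keeps_nothing(rng):
    frames = rng.normal(100, 3, size=(5, 64, 64)).clip(0, None)
    keep = lf.screen_frames(_mini_seq(frames))
    assert len(keep) == 0


def test_screen_keeps_exactly_occupied_frames(rng):
    frames = rng.normal(100, 3, size=(6, 64, 64))
    for i in (1, 3, 4):
        frames[i, 28:34, 28:34] += 120.0      # a compact bright object
    keep = lf.screen_frames(_mini_seq(frames.clip(0, None)))
    assert list(keep) == [1, 3, 4]


def test_screen_zero_threshold_keeps_all(rng):
    frames = rng.normal(100, 3, size=(4, 32, 32)).clip(0, None)
    cfg = lf.PipelineConfig(screen_threshold=0.0)
    assert list(lf.screen_frames(_mini_seq(frames), cfg)) == [0, 1, 2, 3]


def test_screen_rejects_debris(rng):
    frames = rng.normal(100, 3, size=(2, 64, 64))
    frames[0, 25:30, 25:30] += 120.0          # object-sized
    frames[1, 5:60, 5:60] += 120.0            # debris-sized blob
    cfg = lf.PipelineConfig(max_object_extent=40)
    keep = lf.screen_frames(_mini_seq(frames.clip(0, None)), cfg)
    assert list(keep) == [0]


# ---------------------------------------------------------------- pairing

def test_pairing_six_alternating_frames():
    seq = _mini_seq(np.zeros((6, 8, 8)), channels=[0, 1, 0, 1, 0, 1],
                    two_color=True)
    assert lf.pair_color_frames(seq) == [(0, 1), (2, 3), (4, 5)]


def test_pairing_drops_trailing_frame():
    seq = _mini_seq(np.zeros((7, 8, 8)), channels=[0, 1, 0, 1, 0, 1, 0],
                    two_color=True)
    assert lf.pair_color_frames(seq) == [(0, 1), (2, 3), (4, 5)]


def test_pairing_requires_alternation():
    seq = _mini_seq(np.zeros((4, 8, 8)), channels=[0, 0, 1, 1])
    with pytest.raises(lf.SequenceError):
        lf.pair_color_frames(seq)


def test_pairing_respects_screened_subset():
    seq = _mini_seq(np.zeros((6, 8, 8)), channels=[0, 1, 0, 1, 0, 1],
                    two_color=True)
    # frame 2 screened out: its partner 3 cannot pair either
    assert lf.pair_color_frames(seq, indices=[0, 1, 3, 4, 5]) == [(0, 1), (4, 5)]


# ---------------------------------------------------------------- background

def test_rolling_ball_constant_image_to_zero():
    out = lf.rolling_ball_background(np.full((32, 32), 57.0), radius=5)
    assert np.allclose(out, 0.0)


def test_rolling_ball_preserves_impulse_on_offset():
    img = np.full((33, 33), 40.0)
    img[16, 16] += 90.0
    out = lf.rolling_ball_background(img, radius=5)
    assert out[16, 16] == pytest.approx(90.0, abs=1.0)
    out[16, 16] = 0.0
    assert np.allclose(out, 0.0, atol=1.0)


def test_rolling_ball_output_nonnegative(rng):
    img = rng.normal(50, 10, size=(40, 40))
    assert lf.rolling_ball_background(img, radius=4).min() >= 0.0


def test_rolling_ball_bad_radius():
    with pytest.raises(lf.ParameterError):
        lf.rolling_ball_background(np.zeros((8, 8)), radius=0)


# ---------------------------------------------------------------- denoising

def _gauss_spot(n=96, sigma=2.5, amp=60.0, cy=None, cx=None):
    cy = n / 2 if cy is None else cy
    cx = n / 2 if cx is None else cx
    yy, xx = np.mgrid[0:n, 0:n]
    return amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2)))


def test_denoise_noiseless_is_nearly_identity():
    img = _gauss_spot() + 10.0
    out = lf.denoise(img)
    assert np.abs(out - img).max() <= 0.01 * img.max()


def test_denoise_improves_psnr_by_3db(rng):
    clean = _gauss_spot(amp=25.0)           # peak SNR ~ 5 under shot noise
    nm = lf.NoiseModel(gain=1.0, read_sigma=2.0, offset=0.0)
    noisy = nm.apply(clean, rng)
    den = lf.denoise(noisy, noise=nm)

    def psnr(x):
        return 10 * np.log10(clean.max() ** 2 / np.mean((x - clean) ** 2))

    assert psnr(den) - psnr(noisy) >= 3.0


def test_denoise_does_not_shift_centroids(rng):
    clean = _gauss_spot(amp=30.0, cy=42.3, cx=55.8)
    nm = lf.NoiseModel(gain=1.0, read_sigma=2.0, offset=0.0)
    den = lf.denoise(nm.apply(clean, rng), noise=nm)

    def centroid(img):
        img = np.maximum(img - 0.1 * img.max(), 0)
        yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        return np.array([(img * yy).sum(), (img * xx).sum()]) / img.sum()

    assert np.linalg.norm(centroid(den) - centroid(clean)) <= 0.5


def test_denoise_plugin_interface():
    img = _gauss_spot()
    out = lf.denoise(img, method=lambda x: x * 2.0)
    assert np.allclose(out, img * 2.0)
    assert np.allclose(lf.denoise(img, method="none"), img)


# ---------------------------------------------------------------- padding

def test_pad_to_square_camera_dialect():
    # the 1024x900 camera crop pads to the 1024 PSF grid (scaled here)
    img = np.arange(64 * 56, dtype=float).reshape(64, 56)
    out, crop = lf.pad_to_square(img, 64, return_slices=True)
    assert out.shape == (64, 64)
    assert out.sum() == pytest.approx(img.sum())
    assert np.array_equal(out[crop], img)


def test_pad_to_square_noop_and_errors():
    img = np.ones((16, 16))
    assert lf.pad_to_square(img, 16) is not img
    assert np.array_equal(lf.pad_to_square(img, 16), img)
    with pytest.raises(lf.ParameterError):
        lf.pad_to_square(img, 8)


# ---------------------------------------------------------------- RL

def _dense_operator_matrix(op):
    nvox = int(np.prod(op.volume_shape))
    npix = int(np.prod(op.shape))
    A = np.zeros((npix, nvox))
    basis = np.zeros(op.volume_shape)
    for i in range(nvox):
        basis.flat[i] = 1.0
        A[:, i] = op.forward(basis).ravel()
        basis.flat[i] = 0.0
    return A


def _dense_rl(y, A, shape, iterations, eps):
    x = np.full(int(np.prod(shape)), y.sum() / np.prod(shape))
    sens = A.T @ np.ones(A.shape[0])
    sens = np.maximum(sens, 1e-6 * sens.max())
    for _ in range(iterations):
        est = A @ x
        ratio = y.ravel() / np.maximum(est, eps)
        x = x * (A.T @ ratio) / sens
    return x.reshape(shape)


@pytest.mark.parametrize("iterations", [1, 5])
def test_rl_matches_dense_matrix_oracle(tiny_psf, iterations):
    # brute-force matrix implementation of the same multiplicative update
    op = lf.LightFieldOperator(tiny_psf, shape=(8, 8), dtype=np.float64)
    rng = np.random.default_rng(0)
    truth = rng.uniform(size=op.volume_shape) ** 3
    y = op.forward(truth)
    y = np.clip(y, 0, None)
    A = _dense_operator_matrix(op)
    eps = 1e-12 * y.max()
    expected = _dense_rl(y, A, op.volume_shape, iterations, eps)
    vol = lf.richardson_lucy_3d(y, tiny_psf, iterations, operator=op)
    assert np.allclose(vol.data, expected, rtol=1e-6, atol=1e-6 * expected.max())


def test_rl_delta_self_consistency(tiny_psf):
    op = lf.LightFieldOperator(tiny_psf, shape=(8, 8), dtype=np.float64)
    truth = np.zeros(op.volume_shape)
    truth[1, 4, 4] = 10.0
    y = np.clip(op.forward(truth), 0, None)
    vol = lf.richardson_lucy_3d(y, tiny_psf, 50, operator=op)
    assert np.unravel_index(np.argmax(vol.data), vol.data.shape) == (1, 4, 4)


def test_rl_flux_conservation(tiny_psf):
    op = lf.LightFieldOperator(tiny_psf, shape=(8, 8), dtype=np.float64)
    rng = np.random.default_rng(3)
    y = np.clip(op.forward(rng.uniform(size=op.volume_shape)), 0, None)
    for iters in (1, 5, 20):
        vol = lf.richardson_lucy_3d(y, tiny_psf, iters, operator=op)
        reprojected = op.forward(vol.data.astype(np.float64)).sum()
        assert reprojected == pytest.approx(y.sum(), rel=0.10)


def test_rl_poisson_likelihood_monotone_on_noiseless_input(tiny_psf):
    op = lf.LightFieldOperator(tiny_psf, shape=(8, 8), dtype=np.float64)
    rng = np.random.default_rng(1)
    y = np.clip(op.forward(rng.uniform(size=op.volume_shape)), 0, None)

    def loglik(vol):
        est = np.maximum(op.forward(vol), 1e-30)
        return float((y * np.log(est) - est).sum())

    lls = [loglik(lf.richardson_lucy_3d(y, tiny_psf, k, operator=op)
                  .data.astype(np.float64)) for k in range(1, 12)]
    assert np.all(np.diff(lls) >= -1e-9 * np.abs(lls[0]))


def test_rl_degenerate_inputs(tiny_psf):
    with pytest.warns(UserWarning):
        vol = lf.richardson_lucy_3d(np.zeros((8, 8)), tiny_psf, 5)
    assert vol.data.max() == 0.0
    with pytest.raises(lf.DataError):
        lf.richardson_lucy_3d(np.full((8, 8), np.nan), tiny_psf, 5)
    with pytest.raises(lf.DataError):
        lf.richardson_lucy_3d(np.full((8, 8), -1.0), tiny_psf, 5)
    with pytest.raises(lf.DomainError):
        lf.richardson_lucy_3d(np.ones((8, 8)), tiny_psf, 0)


def test_recon_volume_rejects_negative():
    with pytest.raises(lf.DataError):
        lf.ReconVolume(data=np.array([[[-1.0]]]), voxel=(0.1, 0.1, 0.1))


# ---------------------------------------------------------------- resolution

def test_two_point_sources_at_600nm_are_resolved(psf_far, op_far):
    # nearby emitters separated by 600 nm laterally reconstruct as two
    # distinct maxima
    nz = psf_far.n_planes
    sep_px = 0.6 / psf_far.voxel_xy
    dens = np.zeros((nz, 512, 512))
    lo, hi = int(round(256 - sep_px / 2)), int(round(256 + sep_px / 2))
    dens[nz // 2, lo, 256] = 1.0
    dens[nz // 2, hi, 256] = 1.0
    frame = np.clip(op_far.forward(dens), 0, None)
    vol = lf.richardson_lucy_3d(frame, psf_far, 30, operator=op_far)
    labels, recs = lf.segment_objects(
        vol, method="peak_fraction",
        params={"min_distance": 1, "fraction": 0.5, "min_size": 1})
    bright = [r for r in recs if r.intensity > 0.1 * max(x.intensity for x in recs)]
    assert len(bright) == 2


# ---------------------------------------------------------------- pipeline

def test_pipeline_empty_keepset_is_not_an_error(psf_far):
    seq = lf.simulate_sequence([], psf_far, noise=lf.NoiseModel(),
                               n_frames=3, seed=0)
    volumes, prov = lf.run_pipeline(seq, psf_far)
    assert volumes == []
    assert prov["screen"]["kept"] == []


def test_pipeline_stage_isolation(psf_far, op_far):
    obj = lf.PhantomObject("bead", (0.0, 0.0, 0.0),
                           [lf.Component("b", lf.Sphere(1.0), 0, 2e5)],
                           truth={})
    seq = lf.simulate_sequence([obj], psf_far,
                               flow=lf.FlowConfig(flow_speed=0.0),
                               noise=lf.NoiseModel(), n_frames=1, seed=4)
    base = lf.PipelineConfig(rl_iterations=2)
    off = lf.PipelineConfig(rl_iterations=2, denoiser="none")
    vols_a, prov_a = lf.run_pipeline(seq, psf_far, base)
    vols_b, prov_b = lf.run_pipeline(seq, psf_far, off)
    assert len(vols_a) == len(vols_b) == 1
    sa = prov_a["frames"][0]["stages"]
    sb = prov_b["frames"][0]["stages"]
    assert [s for s in sa if s != "stand_in"] == [s for s in sb if s != "none"]
    assert prov_a["screen"] == prov_b["screen"]


def test_pipeline_two_color_produces_both_channels(psf_far):
    obj = lf.make_cell_phantom("membrane_nucleus", seed=0)
    seq = lf.simulate_sequence([obj], psf_far,
                               flow=lf.FlowConfig(flow_speed=0.0),
                               noise=lf.NoiseModel(), n_frames=2,
                               two_color=True, seed=2)
    cfg = lf.PipelineConfig(rl_iterations=2)
    volumes, prov = lf.run_pipeline(seq, psf_far, cfg)
    assert len(volumes) == 2
    assert sorted(v.channel for v in volumes) == [0, 1]
    assert prov["pairs"] == [(0, 1)]
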