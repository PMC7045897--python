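"""Preprocessing: registration recovery, resampling oracles, pad/crop arithmetic."""

import numpy as np
import pytest

from deuseg import (
    PhantomConfig,
    RegistrationOptions,
    downsample_t2,
    generate_study,
    minmax_normalize,
    pad_crop,
    preprocess_study,
    register_t1_to_t2,
)
from deuseg.preprocess import RegistrationError
from deuseg.volume import Volume


def test_self_registration_recovers_identity():
    cfg = PhantomConfig(grid_shape=(16, 64, 64), spacing_ch1=(4, 1, 1),
                        spacing_ch2=(4, 1, 1), misregistration_offset=(0, 0, 0),
                        noise_sd=0.0, seed=5)
    st = generate_study(cfg)
    _, params = register_t1_to_t2(st.t2w, st.t2w)
    t = np.array(params["translation_mm_xyz"])
    assert np.all(np.abs(t[:2]) < 0.5)   # < 0.5 in-plane voxel (1 mm spacing)
    assert abs(t[2]) < 2.0               # < 0.5 slice (4 mm)


def test_registration_recovers_known_misalignment():
    """Phantom channel 1 shifted by (3, 2, 0) mm in (x, y, z); the rigid
    transform should recover about (-3, -2, 0) within one voxel."""
    cfg = PhantomConfig(grid_shape=(16, 64, 64), spacing_ch1=(4, 0.93, 0.93),
                        spacing_ch2=(4, 0.48, 0.48), n_lesions=2,
                        lesion_radius_range=(5, 9), confuser_count=3,
                        misregistration_offset=(0.0, 2.0, 3.0), noise_sd=0.0,
                        seed=11)
    st = generate_study(cfg)
    reg, params = register_t1_to_t2(st.t1w, st.t2w)
    t = np.array(params["translation_mm_xyz"])
    assert abs(t[0] - (-3.0)) < 0.93
    assert abs(t[1] - (-2.0)) < 0.93
    assert abs(t[2] - 0.0) < 4.0
    assert params["metric_final"] <= params["metric_initial"]
    assert reg.shape == st.t2w.shape  # resampled onto the fixed grid


def test_non_overlapping_extents_rejected():
    a = Volume(np.ones((4, 8, 8)), (4, 1, 1), origin=(0, 0, 0))
    b = Volume(np.ones((4, 8, 8)), (4, 1, 1), origin=(1000.0, 0, 0))
    with pytest.raises(RegistrationError):
        register_t1_to_t2(a, b)


def test_downsample_constant_stays_constant():
    v = Volume(np.full((3, 4, 4), 2.5), (4, 1, 1))
    out = downsample_t2(v)
    assert out.shape == (3, 2, 2)
    assert np.allclose(out.values, 2.5)
    assert out.spacing == (4, 2, 2)


def test_downsample_mask_stays_binary():
    rng = np.random.default_rng(0)
    v = Volume((rng.random((4, 9, 9)) > 0.5).astype(np.uint8), (4, 1, 1))
    out = downsample_t2(v, is_mask=True)
    assert out.shape == (4, 4, 4)  # floor division on odd dims
    assert set(np.unique(out.values)) <= {0, 1}


def test_downsample_linear_ramp_matches_direct_evaluation():
    """f(col) = col sampled at output coordinate 2j + 0.5 must equal 2j + 0.5."""
    S, R, C = 2, 8, 16
    vals = np.broadcast_to(np.arange(C, dtype=float), (S, R, C)).copy()
    out = downsample_t2(Volume(vals, (4, 1, 1)))
    expected = 2.0 * np.arange(C // 2) + 0.5
    assert np.allclose(out.values[0, 0], expected)


def test_minmax_examples():
    v = Volume(np.array([[[2.0, 4.0, 6.0]]]), (1, 1, 1))
    assert np.allclose(minmax_normalize(v).values, [[[0.0, 0.5, 1.0]]])
    const = Volume(np.full((2, 3, 3), 7.0), (1, 1, 1))
    assert np.all(minmax_normalize(const).values == 0.0)
    rng = np.random.default_rng(1)
    r = minmax_normalize(Volume(rng.random((3, 5, 5)), (1, 1, 1)))
    assert r.values.min() == 0.0 and r.values.max() == 1.0


def test_pad_crop_symmetric_padding_arithmetic():
    img = np.ones((200, 240))
    out, off = pad_crop(img, (256, 256), return_offset=True)
    assert out.shape == (256, 256)
    assert off == (28, 8)
    assert np.all(out[:28] == 0) and np.all(out[-28:] == 0)
    assert np.all(out[:, :8] == 0) and np.all(out[:, -8:] == 0)
    assert out[28:-28, 8:-8].sum() == img.sum()


def test_pad_crop_identity_and_centered_crop():
    img = np.arange(256 * 256, dtype=float).reshape(256, 256)
    assert np.array_equal(pad_crop(img, (256, 256)), img)
    tall = np.arange(300 * 256, dtype=float).reshape(300, 256)
    out, off = pad_crop(tall, (256, 256), return_offset=True)
    assert off == (-22, 0)
    assert np.array_equal(out, tall[22:278])


def test_pad_crop_idempotent():
    rng = np.random.default_rng(2)
    img = rng.random((37, 61))
    once = pad_crop(img, (48, 48))
    assert np.array_equal(pad_crop(once, (48, 48)), once)


def test_pad_crop_rejects_nonpositive_target():
    with pytest.raises(ValueError):
        pad_crop(np.ones((4, 4)), (0, 4))


def test_preprocess_study_aligns_grids_and_preserves_binarity(tiny_study):
    pp = preprocess_study(tiny_study, (32, 32))
    assert pp.t1w.shape == pp.t2w.shape == pp.gold.shape == (12, 32, 32)
    assert pp.gold.is_binary()
    assert pp.t1w.values.min() >= 0.0 and pp.t1w.values.max() <= 1.0
    assert pp.t2w.values.min() >= 0.0 and pp.t2w.values.max() <= 1.0
    assert pp.gold.values.sum() > 0  # lesion survives the geometric chain


def test_strict_mask_interp_also_binary(tiny_study):
    pp = preprocess_study(tiny_study, (32, 32), strict_mask_interp=True)
    assert pp.gold.is_binary()


def test_registration_options_validation():
    with pytest.raises(ValueError):
        RegistrationOptions(initial_radius=0.0)
    with pytest.raises(ValueError):
        RegistrationOptions(max_iterations=0)
    with pytest.raises(ValueError):
        RegistrationOptions(transform_model="deformable")
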