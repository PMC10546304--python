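"""Resampling, windowing, cropping, slice pairing and paired augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cystfuse as cf
from cystfuse.constants import MODALITIES, PAD_VALUE
from cystfuse.preprocess import AugmentSpec, _round_half_away


@pytest.mark.parametrize(
    "dims,spacing,expected",
    [
        ((256, 256, 40), (0.78, 0.78, 2.59), (200, 200, 104)),
        ((320, 320, 30), (0.625, 0.625, 4.80), (200, 200, 144)),
    ],
)
def test_resample_output_dims(dims, spacing, expected):
    vol = cf.ModalityVolume(np.zeros(dims, dtype=np.float32), spacing, "T1pre")
    out = cf.resample_isotropic(vol)
    assert out.dims == expected
    assert out.spacing_mm == (1.0, 1.0, 1.0)


def test_resample_identity_at_unit_spacing():
    rng = np.random.default_rng(0)
    vox = rng.normal(size=(12, 13, 7)).astype(np.float32)
    vol = cf.ModalityVolume(vox, (1.0, 1.0, 1.0), "T2")
    out = cf.resample_isotropic(vol)
    np.testing.assert_array_equal(out.voxels, vox)


def test_resample_rounds_half_away_from_zero():
    assert _round_half_away(np.array([2.5, 3.5, 2.49, 103.6])).tolist() == [3, 4, 2, 104]


def test_resample_is_trilinear():
    """On a linear intensity ramp, linear interpolation is exact."""
    x = np.arange(10, dtype=np.float32)
    vox = np.broadcast_to(x[:, None, None], (10, 8, 6)).copy()
    vol = cf.ModalityVolume(vox, (2.0, 1.0, 1.0), "T1a2")
    out = cf.resample_isotropic(vol)
    assert out.dims == (20, 8, 6)
    expected = np.clip(np.arange(20) / 2.0, 0, 9)
    np.testing.assert_allclose(out.voxels[:, 0, 0], expected, atol=1e-6)


def test_window_normalize_endpoints_and_midpoint():
    spec = cf.WindowSpec(windows={m: (0.0, 200.0) for m in MODALITIES})
    vox = np.array([[[0.0, 100.0, 200.0, 50.0, 300.0, -10.0]]])
    vol = cf.ModalityVolume(vox, (1, 1, 1), "T1pre")
    out = cf.window_normalize(vol, spec).voxels[0, 0]
    np.testing.assert_allclose(out, [-1.0, 0.0, 1.0, -0.5, 1.0, -1.0], atol=1e-6)


def test_window_normalize_monotone():
    spec = cf.WindowSpec(windows={m: (-3.0, 7.0) for m in MODALITIES})
    v = np.sort(np.random.default_rng(1).normal(scale=5, size=100))
    vol = cf.ModalityVolume(v.reshape(100, 1, 1), (1, 1, 1), "T2")
    out = cf.window_normalize(vol, spec).voxels.ravel()
    assert np.all(np.diff(out) >= 0)
    assert out.min() >= -1 and out.max() <= 1


def test_window_requires_lo_below_hi():
    with pytest.raises(cf.ConfigurationError):
        cf.WindowSpec(windows={"T2": (5.0, 5.0)})


def _normalized_series(fast_config, seed=0):
    import dataclasses

    series, _ = cf.generate_phantom("SCN", dataclasses.replace(fast_config, seed=seed))
    spec = cf.WindowSpec.from_series(series)
    vols = {
        m: cf.window_normalize(cf.resample_isotropic(series.volumes[m]), spec)
        for m in MODALITIES
    }
    center = tuple(
        int(round(c * s))
        for c, s in zip(series.lesion_center_vox, series.volumes["T1post"].spacing_mm)
    )
    return cf.PatientSeries(series.patient_id, vols, center, series.label)


def test_crop_dims_and_center(fast_config):
    series = _normalized_series(fast_config)
    cropped = cf.crop_lesion(series)
    for m in MODALITIES:
        assert cropped.volumes[m].dims == (80, 80, 80)
    assert cropped.lesion_center_vox == (40, 40, 40)


def test_crop_interior_no_padding():
    vox = np.random.default_rng(2).uniform(-1, 1, (100, 100, 100)).astype(np.float32)
    vols = {m: cf.ModalityVolume(vox, (1, 1, 1), m) for m in MODALITIES}
    series = cf.PatientSeries("p", vols, (50, 50, 50), "SCN")
    cropped = cf.crop_lesion(series)
    np.testing.assert_array_equal(
        cropped.volumes["T2"].voxels, vox[10:90, 10:90, 10:90]
    )


def test_crop_pads_out_of_bounds_with_minus_one():
    vox = np.zeros((100, 100, 100), dtype=np.float32)
    vols = {m: cf.ModalityVolume(vox, (1, 1, 1), m) for m in MODALITIES}
    series = cf.PatientSeries("p", vols, (10, 50, 50), "MCN")
    out = cf.crop_lesion(series).volumes["T1pre"].voxels
    # center x=10: the crop starts at x=-30, so 30 leading yz-planes are padding
    assert np.all(out[:30] == PAD_VALUE)
    assert np.all(out[30:] == 0)


def test_crop_center_outside_volume_rejected():
    vox = np.zeros((50, 50, 50), dtype=np.float32)
    vols = {m: cf.ModalityVolume(vox, (1, 1, 1), m) for m in MODALITIES}
    with pytest.raises(cf.ValidationError):
        cf.PatientSeries("p", vols, (60, 10, 10), "SCN")


def test_slice_pack_extraction(fast_config):
    cropped = cf.crop_lesion(_normalized_series(fast_config))
    packs = cf.extract_slice_packs(cropped, 1)
    assert len(packs) == 1 and packs[0].z_index == 40
    packs = cf.extract_slice_packs(cropped, 5)
    assert [p.z_index for p in packs] == [38, 39, 40, 41, 42]
    for p in packs:
        assert p.slices.shape == (7, 80, 80)
        assert p.slices.min() >= -1 and p.slices.max() <= 1
    for bad in (0, 2, 4, 81):
        with pytest.raises(cf.ValidationError):
            cf.extract_slice_packs(cropped, bad)


def test_pipeline_on_phantom_yields_valid_packs(fast_config):
    series, _ = cf.generate_phantom("MCN", fast_config)
    packs = cf.preprocess_series(series, k_slices=3)
    assert len(packs) == 3
    for p in packs:
        assert p.label == "MCN"
        assert p.slices.shape == (7, 80, 80)
        assert p.slices.min() >= -1 and p.slices.max() <= 1
    # packs carry signal: the lesion makes the central slice non-constant
    assert packs[1].slices.std() > 0


def _make_pack(seed=0):
    rng = np.random.default_rng(seed)
    return cf.SlicePack(
        "p", 40, np.clip(rng.normal(0, 0.3, (7, 80, 80)), -1, 1).astype(np.float32), "SCN"
    )


def test_augment_identity_config_is_identity():
    pack = _make_pack()
    out = cf.augment(pack, seed=3, spec=AugmentSpec.identity())
    np.testing.assert_array_equal(out.slices, pack.slices)


def test_augment_deterministic():
    pack = _make_pack()
    a = cf.augment(pack, seed=7)
    b = cf.augment(pack, seed=7)
    np.testing.assert_array_equal(a.slices, b.slices)


def test_augment_horizontal_flip_index_mapping():
    pack = _make_pack()
    spec = AugmentSpec(p_hflip=1.0, p_vflip=0.0, rot_deg=0.0,
                       scale_range=(1.0, 1.0), shift_range=(0.0, 0.0))
    out = cf.augment(pack, seed=1, spec=spec)
    # pixel (i, j) moves to (i, 79 - j) in every modality simultaneously
    np.testing.assert_array_equal(out.slices, pack.slices[:, :, ::-1])


def test_augment_geometric_part_shared_across_modalities():
    """Augmenting then selecting modality m equals selecting then applying the
    same geometric transform: all modalities move together."""
    pack = _make_pack()
    spec = AugmentSpec(p_hflip=1.0, p_vflip=1.0, rot_deg=0.0,
                       scale_range=(1.0, 1.0), shift_range=(0.0, 0.0))
    out = cf.augment(pack, seed=5, spec=spec)
    for m in range(7):
        np.testing.assert_array_equal(out.slices[m], pack.slices[m, ::-1, ::-1])


def test_augment_stays_in_range_and_valid():
    pack = _make_pack()
    for seed in range(5):
        out = cf.augment(pack, seed=seed)
        assert out.slices.shape == (7, 80, 80)
        assert out.slices.min() >= -1 and out.slices.max() <= 1


def test_expand_training_packs_multiplicity():
    packs = [_make_pack(s) for s in range(3)]
    out = cf.expand_training_packs(packs, n_aug=3, seed=0)
    assert len(out) == 12
    assert out[:3] == packs  # originals retained


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    lo=st.floats(-100, 99),
    width=st.floats(0.5, 200),
    v=st.floats(-500, 500),
)
def test_window_normalize_formula_property(lo, width, v):
    hi = lo + width
    spec = cf.WindowSpec(windows={"T2": (lo, hi)})
    vol = cf.ModalityVolume(np.full((1, 1, 1), v), (1, 1, 1), "T2")
    out = float(cf.window_normalize(vol, spec).voxels[0, 0, 0])
    expected = 2 * (np.clip(v, lo, hi) - lo) / (hi - lo) - 1
    assert out == pytest.approx(expected, abs=1e-5)
    assert -1 <= out <= 1
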