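import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from alpaca_cwas.atlas import build_phantom_atlas
from alpaca_cwas.preprocess import (
    LabeledVolume,
    MotionTrace,
    PreprocessError,
    PreprocessReport,
    highpass_filter,
    kernel_volume_mm3,
    load_labeled_volume,
    load_motion,
    median_filter_3x3x3,
    regress_confounds,
    roi_overlap_filter,
    save_labeled_volume,
    save_motion,
    scrub,
    trim_volumes,
)


def make_volume(t=160, shape=(6, 6, 4), tr=2.0, rng=None, data=None):
    if data is None:
        rng = rng or np.random.default_rng(0)
        data = rng.standard_normal((*shape, t))
    else:
        shape = data.shape[:3]
    return LabeledVolume(
        data=data,
        labels=np.zeros(shape, dtype=int),
        brain_mask=np.ones(shape, dtype=bool),
        tr=tr,
        voxel_dims=(3.4, 3.4, 4.0),
    )


def make_motion(t, rel=None, rng=None):
    rng = rng or np.random.default_rng(1)
    params = rng.normal(0, 0.05, size=(t, 6))
    if rel is None:
        rel = np.abs(rng.normal(0, 0.1, size=t))
        rel[0] = 0
    return MotionTrace(params, np.asarray(rel, float))


# -- trimming ---------------------------------------------------------------


@pytest.mark.parametrize("t_in,expected", [(250, 156), (160, 156), (140, 136)])
def test_trim_truncates_to_160_then_drops_first_four(t_in, expected):
    v, m = trim_volumes(make_volume(t=t_in), make_motion(t_in))
    assert v.n_volumes == expected
    assert m.n_volumes == expected
    assert m.rel_displacement[0] == 0.0


def test_trim_with_nothing_left_raises():
    with pytest.raises(PreprocessError, match="remains"):
        trim_volumes(make_volume(t=4), make_motion(4))


def test_trim_keeps_lockstep_slice_of_data():
    t = 200
    data = np.zeros((2, 2, 2, t))
    data[0, 0, 0, :] = np.arange(t)
    v, _ = trim_volumes(make_volume(t=t, shape=(2, 2, 2), data=data), make_motion(t))
    assert np.array_equal(v.data[0, 0, 0], np.arange(4, 160))


# -- high-pass --------------------------------------------------------------


def _band_power(x, freq, tr):
    f = np.fft.rfftfreq(len(x), d=tr)
    p = np.abs(np.fft.rfft(x)) ** 2
    return p[np.argmin(np.abs(f - freq))]


def test_highpass_zeroes_constant_series():
    v = make_volume(t=160, data=np.full((2, 2, 2, 160), 7.0))
    out = highpass_filter(v)
    assert np.allclose(out.data, 0.0, atol=1e-10)


def test_highpass_passes_band_above_cutoff():
    t, tr = 160, 2.0
    time = np.arange(t) * tr
    sig = np.sin(2 * np.pi * 0.1 * time)
    data = np.tile(sig, (2, 2, 2, 1))
    out = highpass_filter(make_volume(t=t, data=data))
    ratio = _band_power(out.data[0, 0, 0], 0.1, tr) / _band_power(sig, 0.1, tr)
    assert abs(ratio - 1) < 0.05


def test_highpass_attenuates_slow_drift():
    t, tr = 160, 2.0
    time = np.arange(t) * tr
    sig = np.sin(2 * np.pi * 0.002 * time)
    data = np.tile(sig, (2, 2, 2, 1))
    out = highpass_filter(make_volume(t=t, data=data))
    ratio = _band_power(out.data[0, 0, 0], 0.002, tr) / _band_power(sig, 0.002, tr)
    assert ratio < 0.10


def test_highpass_cutoff_above_nyquist_rejected():
    with pytest.raises(PreprocessError, match="Nyquist"):
        highpass_filter(make_volume(t=160, tr=2.0), cutoff_hz=0.3)


# -- confound regression ----------------------------------------------------


def test_confound_regression_annihilates_wm_copy(rng):
    t = 160
    wm = rng.standard_normal(t)
    csf = rng.standard_normal(t)
    data = np.tile(wm, (2, 2, 2, 1))
    v = make_volume(t=t, data=data)
    out = regress_confounds(v, make_motion(t, rng=rng), wm, csf)
    assert np.allclose(out.data, 0.0, atol=1e-8)


def test_confound_residuals_orthogonal_to_all_regressors(rng):
    t = 160
    v = make_volume(t=t, rng=rng)
    m = make_motion(t, rng=rng)
    wm = rng.standard_normal(t)
    csf = rng.standard_normal(t)
    out = regress_confounds(v, m, wm, csf)
    resid = out.data.reshape(-1, t)
    regressors = [np.ones(t), *m.params.T, wm, csf]
    for reg in regressors:
        assert np.max(np.abs(resid @ reg)) < 1e-8


def test_orthogonal_series_only_loses_its_mean(rng):
    t = 160
    m = MotionTrace(np.zeros((t, 6)), np.zeros(t))  # constant params: collinear
    series = rng.standard_normal(t)
    data = np.tile(series, (1, 1, 1, 1))
    v = make_volume(t=t, shape=(1, 1, 1), data=data)
    with pytest.warns(RuntimeWarning, match="collinear"):
        out = regress_confounds(v, m, None, None)
    assert np.allclose(out.data[0, 0, 0], series - series.mean(), atol=1e-10)


# -- scrubbing --------------------------------------------------------------


def test_scrub_removes_exactly_supra_threshold_volumes():
    rel = [0.0, 0.6, 0.2, 0.51]
    v = make_volume(t=4)
    marked = v.data.copy()
    out, m2, report = scrub(v, make_motion(4, rel=rel), min_volumes=2)
    assert report.scrubbed_indices == [1, 3]
    assert out.n_volumes == 2
    assert np.array_equal(out.data, marked[..., [0, 2]])
    assert not report.excluded_subject  # 2 kept >= the floor of 2


def test_scrub_keeps_everything_below_threshold():
    rel = np.full(160, 0.4)
    rel[0] = 0
    _, _, report = scrub(make_volume(t=160), make_motion(160, rel=rel))
    assert report.scrubbed_indices == []
    assert report.volumes_kept == 160


def test_scrub_flags_subject_below_volume_floor():
    rel = np.zeros(160)
    rel[5:50] = 0.9  # 45 spikes -> 115 kept < 125
    out, _, report = scrub(make_volume(t=160), make_motion(160, rel=rel))
    assert out.n_volumes == 115
    assert report.excluded_subject


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hst.lists(hst.floats(0, 1.2), min_size=5, max_size=60))
def test_scrub_accounting_and_order_preserved(rels):
    rels = [0.0] + rels
    t = len(rels)
    v = make_volume(t=t, shape=(2, 2, 2))
    v.data[0, 0, 0, :] = np.arange(t)  # volume identity channel
    out, _, report = scrub(v, make_motion(t, rel=rels))
    assert report.volumes_in - len(report.scrubbed_indices) == out.n_volumes
    kept = out.data[0, 0, 0, :]
    assert np.all(np.diff(kept) > 0)  # original order, strictly increasing


# -- median filter ----------------------------------------------------------


def test_median_filter_fixes_isolated_spike():
    data = np.zeros((5, 5, 5, 1))
    data[2, 2, 2, 0] = 100.0
    out = median_filter_3x3x3(make_volume(t=1, shape=(5, 5, 5), data=data))
    assert out.data[2, 2, 2, 0] == 0.0


def test_median_filter_identity_on_constant_and_idempotent_on_blocks():
    const = make_volume(t=2, shape=(4, 4, 4), data=np.full((4, 4, 4, 2), 3.0))
    assert np.array_equal(median_filter_3x3x3(const).data, const.data)
    # piecewise-constant block pattern: two applications agree
    data = np.zeros((6, 6, 6, 1))
    data[:3] = 1.0
    v = make_volume(t=1, shape=(6, 6, 6), data=data)
    once = median_filter_3x3x3(v)
    twice = median_filter_3x3x3(once)
    assert np.array_equal(once.data, twice.data)


def test_median_filter_respects_mask():
    data = np.zeros((5, 5, 5, 1))
    data[2, 2, 2, 0] = 100.0
    v = make_volume(t=1, shape=(5, 5, 5), data=data)
    v.brain_mask[2, 2, 2] = False  # spike voxel outside mask: untouched
    out = median_filter_3x3x3(v)
    assert out.data[2, 2, 2, 0] == 100.0
    # and its value does not leak into in-mask neighbors
    assert out.data[2, 2, 1, 0] == 0.0


def test_kernel_physical_volume_is_about_1248_mm3():
    assert kernel_volume_mm3((3.4, 3.4, 4.0)) == pytest.approx(1248.48)


# -- ROI overlap ------------------------------------------------------------


def test_full_masks_include_everything(small_atlas):
    full = np.ones(small_atlas.label_volume.shape, dtype=bool)
    included, overlaps = roi_overlap_filter(small_atlas, [full, full])
    assert included == small_atlas.keys
    assert all(v == 1.0 for v in overlaps.values())


def test_half_covered_region_excluded(small_atlas):
    mask = np.ones(small_atlas.label_volume.shape, dtype=bool)
    key = small_atlas.keys[0]
    coords = small_atlas.voxel_indices(key)
    half = coords[: len(coords) // 2]
    mask[half[:, 0], half[:, 1], half[:, 2]] = False  # ~0.5 overlap < 0.90
    included, overlaps = roi_overlap_filter(small_atlas, [mask, mask])
    assert key not in included
    assert overlaps[key] == pytest.approx(1 - len(half) / len(coords))


def test_manual_exclusions_removed_regardless_of_overlap():
    atlas = build_phantom_atlas((64, 50, 20), "full", include_excluded=True)
    full = np.ones(atlas.label_volume.shape, dtype=bool)
    included, _ = roi_overlap_filter(atlas, [full])
    included_names = {atlas.region(k).name for k in included}
    from alpaca_cwas.atlas import SUSCEPTIBILITY_EXCLUDED_NAMES

    assert not included_names & set(SUSCEPTIBILITY_EXCLUDED_NAMES)
    assert len(included) == 70


# -- report arithmetic and I/O ----------------------------------------------


def test_report_volume_arithmetic():
    r = PreprocessReport(volumes_in=160, volumes_trimmed=4, scrubbed_indices=[1, 2])
    assert r.volumes_kept == 154


def test_nifti_and_motion_roundtrip(tmp_path, rng):
    v = make_volume(t=12, shape=(4, 4, 3), rng=rng)
    v.wm_series = rng.standard_normal(12)
    v.csf_series = rng.standard_normal(12)
    paths = save_labeled_volume(v, tmp_path / "sub")
    again = load_labeled_volume(
        paths["data"], paths["labels"], paths["mask"], tr=2.0,
        confounds_path=paths["confounds"],
    )
    assert np.allclose(again.data, v.data, atol=1e-5)
    assert again.voxel_dims == pytest.approx((3.4, 3.4, 4.0))
    assert np.allclose(again.wm_series, v.wm_series)

    m = make_motion(12, rng=rng)
    save_motion(m, tmp_path / "m.tsv")
    again_m = load_motion(tmp_path / "m.tsv")
    assert np.allclose(again_m.params, m.params)
    assert np.allclose(again_m.rel_displacement, m.rel_displacement)
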