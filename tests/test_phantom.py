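"""Synthetic phantom generator: closed loops, determinism, noise behavior."""

import numpy as np
import pytest

from emct2 import (
    PhantomSpec,
    SequenceParams,
    fit_map,
    make_phantom,
    make_study,
    render_mese,
)
from emct2.phantom import FLUID_LABEL
from emct2.regions import DEFAULT_SCHEME, SampleKey, region_stats


def test_zero_noise_on_grid_closed_loop_is_exact(full_dict, seq):
    """Generator -> matcher recovers the truth T2 exactly inside cartilage
    and fluid, and region means equal the (rounded) spec values."""
    spec = PhantomSpec(noise_model="none", on_grid=True)
    ph = make_phantom(spec)
    img = render_mese(ph.truth_t2, ph.truth_b1, seq)
    maps = fit_map(img, ph.labels > 0, full_dict)
    tissue = ph.labels > 0
    assert np.array_equal(maps.t2_map[tissue], ph.truth_t2[tissue])
    assert np.all(maps.score_map[tissue] > 1 - 1e-6)
    key = SampleKey("P01", "left", False, 1, "rest", "male")
    df = region_stats(maps, ph.labels, key, strict_labels=False).set_index("region")
    for section, baseline in spec.baseline_t2.items():
        assert df.loc[section, "mean_t2_ms"] == round(baseline)


def test_fluid_filter_removes_exactly_fluid_pixels(full_dict, seq):
    """Noise-free fluid pixels (T2 120-250 ms) are exactly the ones removed
    by the 100 ms cutoff."""
    from emct2 import fluid_filter

    spec = PhantomSpec(noise_model="none", on_grid=True)
    ph = make_phantom(spec)
    img = render_mese(ph.truth_t2, ph.truth_b1, seq)
    maps = fit_map(img, ph.labels > 0, full_dict)
    keep = fluid_filter(maps, ph.labels > 0)
    assert np.array_equal(keep, (ph.labels > 0) & (ph.labels != FLUID_LABEL))


def test_phantom_is_deterministic_for_fixed_seed():
    a = make_phantom(PhantomSpec(seed=42))
    b = make_phantom(PhantomSpec(seed=42))
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.truth_t2, b.truth_t2)
    c = make_phantom(PhantomSpec(seed=43))
    assert not np.array_equal(a.truth_t2, c.truth_t2)  # fluid draws differ


def test_timepoint_effects_scale_cartilage_only():
    spec = PhantomSpec(effects={"global": (-2.0, 0.5)})
    rest = make_phantom(spec, "rest")
    run = make_phantom(spec, "21k")
    ctrl = make_phantom(spec, "control")
    cart = (rest.labels > 0) & (rest.labels != FLUID_LABEL)
    np.testing.assert_allclose(run.truth_t2[cart], rest.truth_t2[cart] * 0.98)
    np.testing.assert_allclose(ctrl.truth_t2[cart], rest.truth_t2[cart] * 1.005)


def test_overlapping_labels_raise():
    spec = PhantomSpec(shape=(12, 12, 1))  # too small: patches collide
    with pytest.raises(ValueError, match="overlap"):
        make_phantom(spec)


def test_smooth_b1_field_within_range():
    spec = PhantomSpec(b1_model="smooth", b1_range=(0.85, 1.15))
    ph = make_phantom(spec)
    assert ph.truth_b1.min() >= 0.85 - 1e-12
    assert ph.truth_b1.max() <= 1.15 + 1e-12
    assert np.ptp(ph.truth_b1) > 0.1  # genuinely non-constant


def test_manifest_counts_with_and_without_dropout(seq):
    spec = PhantomSpec()
    study = make_study(spec, n_participants=11, dropout_knees=3, seq=seq,
                       render=False)
    assert len(study.manifest) == 57
    full = make_study(spec, n_participants=11, dropout_knees=0, seq=seq,
                      render=False)
    assert len(full.manifest) == 66
    assert set(full.manifest.sex.unique()) == {"male", "female"}
    assert (full.manifest.sex == "female").sum() == 4 * 6  # 4 of 11, 6 rows each
    assert set(study.sample_keys()[0].__dict__) == {
        "participant", "knee", "dominant", "slice_index", "timepoint", "sex"}


def test_study_noise_streams_survive_dropout(seq):
    """Dropout must not shift the noise of the remaining knees."""
    spec = PhantomSpec(seed=3, shape=(48, 48, 3))
    a = make_study(spec, n_participants=3, dropout_knees=0, seq=seq)
    b = make_study(spec, n_participants=3, dropout_knees=1, seq=seq)
    shared = set(b.images) & set(a.images)
    assert shared
    k = sorted(shared)[0]
    np.testing.assert_array_equal(a.images[k].voxels, b.images[k].voxels)


def test_noise_monotonicity_doubling_sigma_raises_rmse(full_dict, seq):
    """Halving the SNR (doubling sigma) increases the T2-map RMSE,
    checked across 8 seeds."""
    spec = PhantomSpec(on_grid=True)
    ph = make_phantom(spec)
    cart = (ph.labels > 0) & (ph.labels != FLUID_LABEL)
    worse = 0
    for s in range(8):
        rmse = []
        for snr in (50.0, 25.0):
            img = render_mese(ph.truth_t2, ph.truth_b1, seq,
                              noise_model="rician", snr=snr,
                              rng=np.random.default_rng(s),
                              fluid_mask=ph.labels == FLUID_LABEL)
            maps = fit_map(img, cart, full_dict)
            rmse.append(np.sqrt(np.mean(
                (maps.t2_map[cart] - ph.truth_t2[cart]) ** 2)))
        worse += rmse[1] > rmse[0]
    assert worse == 8


def test_rician_noise_model_differs_from_gaussian(seq):
    spec = PhantomSpec()
    ph = make_phantom(spec)
    args = dict(snr=50.0, fluid_mask=ph.labels == FLUID_LABEL)
    g = render_mese(ph.truth_t2, ph.truth_b1, seq, noise_model="gaussian",
                    rng=np.random.default_rng(0), **args)
    r = render_mese(ph.truth_t2, ph.truth_b1, seq, noise_model="rician",
                    rng=np.random.default_rng(0), **args)
    assert not np.array_equal(g.voxels, r.voxels)
    assert g.voxels.min() >= 0 and r.voxels.min() >= 0
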