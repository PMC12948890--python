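"""Dictionary matching: exact recovery, noise robustness, and the
mono-exponential baseline's stimulated-echo bias."""

import numpy as np
import pytest

from emct2 import (
    ImageSeries,
    SequenceParams,
    echo_train,
    fit_map,
    fit_monoexponential,
    match_pixel,
    simulate_emc_batch,
)
from emct2.matching import match_pixels


def _atom_for(d, t2, b1):
    idx = np.flatnonzero((d.t2_index == t2) & (np.isclose(d.b1_index, b1)))[0]
    return d.atoms[idx]


def test_self_match_returns_own_grid_pair(full_dict):
    atom = _atom_for(full_dict, 43.0, 1.0)
    t2, b1, score = match_pixel(atom, full_dict)
    assert (t2, b1) == (43.0, 1.0)
    assert score == pytest.approx(1.0, abs=1e-6)


def test_matching_is_scale_invariant(full_dict):
    atom = _atom_for(full_dict, 43.0, 1.0)
    assert match_pixel(3.7 * atom, full_dict) == match_pixel(atom, full_dict)


def test_zero_norm_pixel_marked_invalid_not_raised(full_dict):
    t2, b1, score = match_pixel(np.zeros(10), full_dict)
    assert np.isnan(t2) and np.isnan(b1) and np.isnan(score)


def test_noise_free_on_grid_recovery_is_exact(full_dict, seq):
    """Every on-grid (T2, B1) pair in a 10x5 subgrid is recovered exactly
    from its own noise-free simulated train."""
    t2s = np.arange(25.0, 75.0, 5.0)
    b1s = np.array([0.80, 0.90, 1.00, 1.10, 1.20])
    T2, B1 = np.meshgrid(t2s, b1s, indexing="ij")
    curves = simulate_emc_batch(T2.ravel(), 1000.0, B1.ravel(), seq)
    t2, b1, score = match_pixels(curves, full_dict)
    assert np.array_equal(t2, T2.ravel())
    np.testing.assert_allclose(b1, B1.ravel())
    assert np.all(score > 1 - 1e-6)


def test_matching_equals_naive_double_loop(full_dict, seq, rng):
    """Cross-check against an independent brute-force implementation on a
    20-pixel noisy fixture."""
    truth_t2 = rng.integers(30, 60, 20).astype(float)
    curves = simulate_emc_batch(truth_t2, 1000.0, 1.0, seq)
    noisy = curves + rng.normal(0, curves[:, :1] / 60.0, curves.shape)
    noisy = np.abs(noisy)
    t2, b1, _ = match_pixels(noisy, full_dict)
    # naive reference: python loop over pixels, full float64 score vector
    for i in range(20):
        p = noisy[i] / np.linalg.norm(noisy[i])
        scores = full_dict.atoms @ p
        j = int(np.argmax(scores))
        assert t2[i] == full_dict.t2_index[j]
        assert b1[i] == full_dict.b1_index[j]


def test_snr50_monte_carlo_recovery_within_2ms(full_dict, seq):
    """At first-echo SNR 50 and truth 43 ms, matching with B1 known stays
    within +/-2 ms in at least 95% of 200 noise draws; joint (T2, B1)
    estimation pays a calibrated ambiguity penalty but still holds 85%."""
    from emct2 import build_dictionary, build_grid

    curve = simulate_emc_batch(43.0, 1000.0, 1.0, seq)[0]
    rng = np.random.default_rng(43)
    sigma = curve[0] / 50.0
    draws = np.abs(curve + rng.normal(0.0, sigma, (200, curve.size)))
    b1_known = build_dictionary(build_grid(b1_min=1.0, b1_max=1.0), seq)
    t2_fixed, _, _ = match_pixels(draws, b1_known)
    assert np.mean(np.abs(t2_fixed - 43.0) <= 2.0) >= 0.95
    t2_joint, _, _ = match_pixels(draws, full_dict)
    assert np.mean(np.abs(t2_joint - 43.0) <= 2.0) >= 0.85


def test_fit_map_empty_mask_and_determinism(full_dict, seq, rng):
    vol = np.abs(rng.normal(1.0, 0.1, (4, 4, 2, 10)))
    series = ImageSeries(voxels=vol, echo_times=echo_train(seq))
    empty = fit_map(series, np.zeros((4, 4, 2), bool), full_dict)
    assert not empty.validity_mask.any()
    assert np.all(np.isnan(empty.t2_map))
    mask = np.ones((4, 4, 2), bool)
    a = fit_map(series, mask, full_dict)
    b = fit_map(series, mask, full_dict)
    assert np.array_equal(a.t2_map, b.t2_map)
    assert np.array_equal(a.score_map, b.score_map)
    assert np.all(np.abs(a.score_map[a.validity_mask]) <= 1.0)


def test_fit_map_shape_and_echo_mismatch_rejected(full_dict, seq):
    vol = np.ones((4, 4, 2, 10))
    series = ImageSeries(voxels=vol, echo_times=echo_train(seq))
    with pytest.raises(ValueError, match="mask shape"):
        fit_map(series, np.ones((5, 4, 2), bool), full_dict)
    bad = ImageSeries(voxels=np.ones((4, 4, 2, 6)),
                      echo_times=np.arange(1.0, 7.0))
    with pytest.raises(ValueError, match="echo"):
        fit_map(bad, np.ones((4, 4, 2), bool), full_dict)


def test_monoexponential_exact_on_true_exponential(seq):
    te = echo_train(seq)
    assert fit_monoexponential(np.exp(-te / 50.0), te) == pytest.approx(50.0, abs=1e-9)


def test_monoexponential_two_points_line_through_both():
    assert fit_monoexponential(np.array([1.0, np.exp(-1.0)]),
                               np.array([0.0, 30.0])) == pytest.approx(30.0)


def test_monoexponential_degenerate_inputs():
    te = np.arange(1.0, 11.0)
    assert np.isnan(fit_monoexponential(np.zeros(10), te))
    assert np.isnan(fit_monoexponential(np.exp(+te / 50.0), te))  # growing


def test_monoexp_biased_versus_emc_on_stimulated_echo_trains(full_dict, seq):
    """On 125-degree refocused trains, the mono-exponential fit has a
    strictly larger absolute T2 error than dictionary matching across the
    cartilage band 30-60 ms."""
    te = echo_train(seq)
    for t2 in np.arange(30.0, 61.0, 2.5):
        curve = simulate_emc_batch(t2, 1000.0, 1.0, seq)[0]
        emc_t2, _, _ = match_pixel(curve, full_dict)
        mono_t2 = fit_monoexponential(curve, te)
        assert abs(mono_t2 - t2) > abs(emc_t2 - t2)
        assert abs(emc_t2 - t2) <= 0.5  # grid quantization only
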