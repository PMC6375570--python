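import numpy as np
import pytest

from teloherit.trf import (
    LaneProfile,
    SizeLadder,
    WindowLimits,
    calibrate_ladder,
    mean_tl,
    set_window,
    synth_lane,
)


# -- ladder calibration -----------------------------------------------------

def test_calibration_exact_at_every_band(ladder, calib):
    assert np.allclose(calib(ladder.band_distance), ladder.band_size, rtol=1e-10)


def test_two_point_log_linear_interpolation():
    # 10000 bp at d=10 and 1000 bp at d=20 -> midpoint is 10^3.5 bp
    lad = SizeLadder([10000.0, 3162.2776601683795, 1000.0], [10.0, 15.0, 20.0])
    calib = calibrate_ladder(lad)
    assert calib(15.0) == pytest.approx(10 ** 3.5, rel=1e-9)
    assert calib(12.5) == pytest.approx(10 ** 3.75, rel=1e-3)


def test_calibration_strictly_monotone(calib):
    d = np.linspace(8.0, 52.0, 500)  # includes extrapolated tails
    sizes = calib(d)
    assert np.all(np.diff(sizes) < 0)


def test_extrapolation_is_flagged(calib, ladder):
    calib(np.array([ladder.band_distance[0] - 1.0, 30.0]))
    assert calib.last_extrapolated.tolist() == [True, False]


def test_non_monotone_ladder_rejected():
    with pytest.raises(ValueError, match="strictly decreasing"):
        SizeLadder([10000.0, 12000.0, 1000.0], [10.0, 15.0, 20.0])


def test_inverse_round_trips(calib):
    sizes = np.array([2000.0, 7000.0, 20000.0])
    assert np.allclose(calib(calib.inverse(sizes)), sizes, rtol=1e-8)


# -- window rule ------------------------------------------------------------

def _gauss_profile(background=10.0, peak=110.0, n=200):
    d = np.linspace(10.0, 50.0, n)
    inten = background + (peak - background) * np.exp(-0.5 * ((d - 30) / 4) ** 2)
    return LaneProfile(d, inten)


def test_threshold_is_background_plus_tenth_of_range():
    limits = set_window(_gauss_profile(background=10.0, peak=110.0))
    assert limits.threshold_y == pytest.approx(
        limits.background + 0.1 * (limits.peak - limits.background))
    assert limits.threshold_y == pytest.approx(20.0, abs=0.5)


def test_window_threshold_identity_holds_on_random_lanes(calib):
    rng = np.random.default_rng(3)
    for seed in range(10):
        tl = rng.normal(7000, 600, size=400)
        prof = synth_lane(tl, calib, blur_sd=1.0, noise_sd=1.0, seed=seed)
        lim = set_window(prof)
        assert lim.threshold_y == pytest.approx(
            lim.background + 0.1 * (lim.peak - lim.background), rel=1e-12)
        assert lim.long_side_index < lim.short_side_index


def test_long_side_limit_at_first_crossing_of_y():
    prof = _gauss_profile()
    lim = set_window(prof)
    inten = prof.intensity
    assert inten[lim.long_side_index] >= lim.threshold_y
    assert inten[lim.long_side_index - 1] < lim.threshold_y


def test_flat_profile_rejected():
    with pytest.raises(ValueError, match="constant"):
        set_window(LaneProfile(np.arange(10.0), np.full(10, 5.0)))


def test_peak_at_short_edge_has_no_background_point():
    d = np.arange(10.0)
    inten = np.linspace(1.0, 10.0, 10)  # rises to the short-fragment edge
    with pytest.raises(ValueError, match="no background point"):
        set_window(LaneProfile(d, inten))


# -- mean TL ----------------------------------------------------------------

def test_point_mass_recovers_its_size(calib):
    d0 = calib.inverse(7000.0)
    d = np.linspace(d0 - 2, d0 + 2, 41)
    inten = np.zeros(41)
    inten[20] = 50.0
    limits = WindowLimits(0, 40, background=0.0, peak=50.0, threshold_y=5.0)
    tl = mean_tl(LaneProfile(d, inten), calib, limits)
    assert tl == pytest.approx(7000.0, rel=5e-4)


def test_two_equal_peaks_average(calib):
    d1, d2 = calib.inverse(6000.0), calib.inverse(8000.0)
    d = np.sort(np.concatenate([np.linspace(15, 45, 100), [d1, d2]]))
    inten = np.where(np.isin(d, [d1, d2]), 40.0, 0.0)
    limits = WindowLimits(0, len(d) - 1, 0.0, 40.0, 4.0)
    tl = mean_tl(LaneProfile(d, inten), calib, limits)
    assert tl == pytest.approx(7000.0, rel=1e-9)


def test_mean_tl_invariant_to_intensity_scaling(calib):
    tlvals = np.random.default_rng(0).normal(7200, 500, size=500)
    prof = synth_lane(tlvals, calib, blur_sd=0.8, noise_sd=0.0, seed=1)
    lim = set_window(prof)
    base = mean_tl(prof, calib, lim)
    scaled = LaneProfile(prof.distance, prof.intensity * 7.3)
    lim2 = set_window(scaled)
    assert mean_tl(scaled, calib, lim2) == pytest.approx(base, rel=1e-9)


def test_synthetic_smear_mean_recovered_within_2pct(calib):
    rng = np.random.default_rng(5)
    tlvals = rng.normal(7200, 500, size=2000)
    prof = synth_lane(tlvals, calib, blur_sd=0.6, noise_sd=1.5, seed=2)
    lim = set_window(prof)
    est = mean_tl(prof, calib, lim)
    assert est == pytest.approx(7200.0, rel=0.02)


def test_shift_of_distribution_shifts_mean(calib):
    rng = np.random.default_rng(8)
    base_tl = rng.normal(6500, 400, size=2000)
    for delta in (500.0, 1000.0):
        p0 = synth_lane(base_tl, calib, blur_sd=0.6, seed=3)
        p1 = synth_lane(base_tl + delta, calib, blur_sd=0.6, seed=3)
        m0 = mean_tl(p0, calib, set_window(p0))
        m1 = mean_tl(p1, calib, set_window(p1))
        assert m1 - m0 == pytest.approx(delta, rel=0.02, abs=0.02 * (6500 + delta))


def test_blur_leaves_mean_stable(calib):
    tlvals = np.random.default_rng(4).normal(7200, 500, size=3000)
    means = []
    for blur in (0.0, 0.4, 1.0):
        prof = synth_lane(tlvals, calib, blur_sd=blur, noise_sd=0.0, seed=0)
        means.append(mean_tl(prof, calib, set_window(prof)))
    assert max(means) - min(means) < 0.02 * 7200


def test_synth_lane_reproducible_and_range_checked(calib):
    tlvals = np.full(50, 7000.0)
    a = synth_lane(tlvals, calib, blur_sd=0.5, noise_sd=2.0, seed=9)
    b = synth_lane(tlvals, calib, blur_sd=0.5, noise_sd=2.0, seed=9)
    assert np.array_equal(a.intensity, b.intensity)
    with pytest.raises(ValueError, match="outside the ladder"):
        synth_lane(np.array([100.0]), calib)


def test_zero_total_window_intensity_errors(calib):
    d = np.linspace(20, 40, 30)
    prof = LaneProfile(d, np.full(30, 3.0) + np.linspace(1, 0, 30))
    limits = WindowLimits(0, 29, background=10.0, peak=12.0, threshold_y=10.2)
    with pytest.raises(ValueError, match="zero corrected intensity"):
        mean_tl(prof, calib, limits)
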