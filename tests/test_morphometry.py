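"""AY-angle measurement, profile summaries and group contrasts."""

import numpy as np
import pytest

import trochwarp as tw
from trochwarp.frames import CANONICAL_FRAME
from trochwarp.morphometry import (AYProfile, compare_groups, fit_plate_line,
                                   summarize_profile)
from trochwarp.phantom import CohortSpec, sample_cohort
from trochwarp.profiles import WarpProfile, solve_warp_profile


# ---------------------------------------------------------------------- lines

def test_collinear_points_fit_exactly():
    t = np.linspace(-3, 3, 11)
    pts = t[:, None] * np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    d = fit_plate_line(pts)
    np.testing.assert_allclose(np.abs(d), [1 / np.sqrt(2), 1 / np.sqrt(2), 0],
                               atol=1e-12)


def test_noisy_line_direction_recovered_within_half_degree(rng):
    true = np.array([np.cos(0.6), 0.0, np.sin(0.6)])
    t = np.linspace(-15, 15, 40)
    worst = 0.0
    for _ in range(100):
        pts = t[:, None] * true + rng.normal(0, 0.1, (40, 3))
        d = fit_plate_line(pts)
        ang = np.degrees(np.arccos(np.clip(abs(d @ true), -1, 1)))
        worst = max(worst, ang)
    assert worst < 0.5


def test_symmetric_v_trace_fits_the_bisecting_axis():
    # arms at +-45 deg about the x axis: the principal axis is horizontal
    t = np.linspace(0, 1, 20)
    left = np.column_stack([-t, np.zeros(20), t])
    right = np.column_stack([t, np.zeros(20), t])
    d = fit_plate_line(np.vstack([left, right]))
    assert abs(d[2]) < 1e-9 and abs(abs(d[0]) - 1) < 1e-9


def test_coincident_points_rejected():
    with pytest.raises(ValueError):
        fit_plate_line(np.ones((5, 3)))


# --------------------------------------------------------------------- angles

@pytest.mark.parametrize("direction,expected", [
    ((1, 0, 0), 0.0),
    ((0, 0, 1), 90.0),
    ((np.cos(np.radians(43.7)), 0, np.sin(np.radians(43.7))), 43.7),
])
def test_ay_angle_reference_directions(direction, expected):
    assert tw.ay_angle(direction, CANONICAL_FRAME) == pytest.approx(expected)


def test_ay_angle_scale_invariance(rng):
    for _ in range(20):
        d = rng.normal(size=3)
        if np.hypot(d[0], d[2]) < 1e-6:
            continue
        a = tw.ay_angle(d, CANONICAL_FRAME)
        assert tw.ay_angle(1000 * d, CANONICAL_FRAME) == pytest.approx(a)
        assert tw.ay_angle(-d, CANONICAL_FRAME) == pytest.approx(a)


def test_ay_angle_rejects_out_of_plane_direction():
    with pytest.raises(ValueError):
        tw.ay_angle((0, 1, 0), CANONICAL_FRAME)


# ------------------------------------------------------------------- profiles

def test_noise_free_round_trip_for_random_warps(rng):
    """measure(generate(spec)) returns the planted warp, 100 random specs."""
    for _ in range(100):
        angles = np.sort(rng.uniform(5, 85, 12))[::-1]
        angles[0], angles[1] = angles[1], angles[0]  # keep the ventral rise shape
        warp = WarpProfile(tuple(angles))
        ph = tw.generate_phantom(tw.default_phantom_spec("pooled", warp=warp),
                                 seed=int(rng.integers(1 << 30)))
        measured = tw.measure_profile(ph)
        for k in range(1, 13):
            assert measured.angles_deg[k] == pytest.approx(warp[k], abs=1e-6)


def test_uniform_phantom_measures_uniform_profile():
    ph = tw.generate_phantom(
        tw.default_phantom_spec("pooled", warp=WarpProfile((30.0,) * 12)), seed=2)
    prof = tw.measure_profile(ph)
    assert all(a == pytest.approx(30.0, abs=1e-9)
               for a in prof.angles_deg.values())


def test_summary_of_default_pooled_profile(pooled_profile):
    s = summarize_profile(pooled_profile)
    assert s.ventral_third_mean == pytest.approx(51.64, abs=1e-6)
    assert s.dorsal_third_mean == pytest.approx(18.6, abs=1e-6)
    assert s.calibration_angle == pytest.approx(43.7, abs=1e-6)
    assert s.total_decrease == pytest.approx(33.44, abs=1e-6)
    assert s.transition_pair == (8, 9)


def test_thirds_means_average_to_overall_mean(pooled_profile):
    s = summarize_profile(pooled_profile)
    overall = np.mean(list(pooled_profile.angles_deg.values()))
    thirds = np.mean([s.ventral_third_mean, s.middle_third_mean,
                      s.dorsal_third_mean])
    assert thirds == pytest.approx(overall, abs=1e-9)


def test_partial_profile_gives_partial_summary():
    prof = AYProfile("p1", {k: 40.0 for k in range(1, 9)})  # dorsal third missing
    s = summarize_profile(prof)
    assert s.ventral_third_mean is not None
    assert s.dorsal_third_mean is None
    assert s.total_decrease is None


def test_noisy_cohort_layer_means_within_three_standard_errors():
    cohort = sample_cohort(CohortSpec(n_adult=20, noise_sd_mm=0.5,
                                      warp_sd_deg=1.0, seed=77))
    planted = tw.build_default_warp_profile("adult").as_array()
    measured = np.vstack([tw.measure_profile(p).layer_array() for p in cohort])
    mean, se = measured.mean(0), measured.std(0, ddof=1) / np.sqrt(len(cohort))
    inside = np.abs(mean - planted) <= 3 * se
    assert inside.sum() >= 11  # allow a single 3-sigma excursion


# ----------------------------------------------------------------- comparison

def _planted_cohort(juv_decrease, adult_decrease, n=5, noise=0.0, seed=0):
    juv = solve_warp_profile(dorsal_third_mean=18.6 + (33.44 - juv_decrease),
                             total_decrease=juv_decrease)
    adu = solve_warp_profile(dorsal_third_mean=18.6 + (33.44 - adult_decrease),
                             total_decrease=adult_decrease)
    return sample_cohort(CohortSpec(n_juvenile=n, n_adult=n, noise_sd_mm=noise,
                                    seed=seed, warp_juvenile=juv, warp_adult=adu))


def test_noise_free_group_difference_is_exact():
    cohort = _planted_cohort(25.0, 33.0)
    comp = compare_groups([tw.measure_profile(p) for p in cohort], seed=1)
    assert comp.decrease_difference == pytest.approx(8.0, abs=1e-6)


def test_identical_groups_interval_covers_zero():
    cohort = sample_cohort(CohortSpec(
        n_juvenile=5, n_adult=5, noise_sd_mm=0.3, seed=3,
        warp_juvenile=tw.build_default_warp_profile("pooled"),
        warp_adult=tw.build_default_warp_profile("pooled")))
    comp = compare_groups([tw.measure_profile(p) for p in cohort], seed=3)
    assert comp.ci_low <= 0.0 <= comp.ci_high


def test_single_group_input_has_no_contrast():
    cohort = sample_cohort(CohortSpec(n_adult=3, seed=4))
    comp = compare_groups([tw.measure_profile(p) for p in cohort])
    assert comp.decrease_difference is None
    assert "adult" in comp.layer_means


def test_group_difference_sign_recovered_under_noise():
    """Planted 10-deg decrease difference, subject noise SD 1 deg, 200 reruns."""
    hits = 0
    for rerun in range(200):
        cohort = _planted_cohort(23.44, 33.44, n=5, seed=1000 + rerun)
        # add subject-level variation via warp_sd through a fresh spec
        cohort = sample_cohort(CohortSpec(
            n_juvenile=5, n_adult=5, noise_sd_mm=0.0, warp_sd_deg=1.0,
            seed=1000 + rerun,
            warp_juvenile=solve_warp_profile(dorsal_third_mean=28.6,
                                             total_decrease=23.44),
            warp_adult=tw.build_default_warp_profile("adult")))
        profiles = [tw.measure_profile(p) for p in cohort]
        comp = compare_groups(profiles, n_bootstrap=1, seed=0)
        hits += comp.decrease_difference > 0
    assert hits >= 190  # >= 95% of reruns recover the sign
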