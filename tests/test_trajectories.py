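"""Straight-line trajectory directions, planar angles and the centroid oracle."""

import numpy as np
import pytest

import trochwarp as tw
from trochwarp.frames import CANONICAL_FRAME
from trochwarp.trajectories import (MuscleAttachment, centroid_direction,
                                    default_attachment_map,
                                    direction_from_angles, frontal_angle,
                                    regional_table, straight_line_direction,
                                    transverse_angle)


def test_straight_line_direction_simple_and_scale_invariant():
    att = MuscleAttachment("m", "middle", (0, 0, 0), (10, 0, 10))
    d = straight_line_direction(att)
    np.testing.assert_allclose(d, [0.7071, 0, 0.7071], atol=5e-5)
    att3 = MuscleAttachment("m", "middle", (0, 0, 0), (30, 0, 30))
    np.testing.assert_allclose(straight_line_direction(att3), d, atol=1e-12)


@pytest.mark.parametrize("muscle,region,group,plane,expected", [
    ("gluteus medius", "ventral", "pooled", "frontal", 22.55),
    ("gluteus medius", "ventral", "adult", "frontal", 26.44),
    ("gluteus medius", "middle", "adult", "frontal", 37.01),
    ("gluteus medius", "dorsal", "adult", "frontal", 39.21),
    ("vastus lateralis", "middle", "pooled", "frontal", -6.35),
    ("piriformis", "middle", "pooled", "frontal", 48.64),
    ("piriformis", "cranial", "pooled", "transverse", 22.38),
    ("gluteus maximus", "middle", "pooled", "transverse", -8.34),
    ("quadratus femoris", "middle", "juvenile", "transverse", -10.56),
])
def test_default_attachments_reproduce_published_mean_angles(
        muscle, region, group, plane, expected):
    att = default_attachment_map(group)[
        (muscle, {"cranial": "ventral", "caudal": "dorsal"}.get(region, region))]
    d = straight_line_direction(att)
    measured = frontal_angle(d) if plane == "frontal" else transverse_angle(d)
    assert measured == pytest.approx(expected, abs=1e-6)


def test_angle_pair_round_trips_through_the_direction(rng):
    for _ in range(200):
        fa = rng.uniform(-85, 85)
        ta = rng.uniform(-85, 85)
        d = direction_from_angles(fa, ta)
        assert frontal_angle(d) == pytest.approx(fa, abs=1e-9)
        assert transverse_angle(d) == pytest.approx(ta, abs=1e-9)


def test_planar_angles_reject_degenerate_projections():
    with pytest.raises(ValueError):
        frontal_angle((0, 1, 0))
    with pytest.raises(ValueError):
        transverse_angle((0, 0, 1))


def test_frontal_sign_convention():
    # caudomedially descending course has a negative frontal angle
    assert frontal_angle((-1, 0, -0.3)) < 0
    # dorsomedial course has a negative transverse angle
    assert transverse_angle((-1, -0.3, 0)) < 0


# ------------------------------------------------------------------ centroids

def _prismatic_sections(direction, n=6):
    ring = np.array([[0, 1.0, 0], [0, -1.0, 0], [0, 0, 1.0], [0, 0, -1.0]])
    return [k * 10.0 * direction + ring for k in range(n)]


def test_centroid_method_equals_straight_line_for_prismatic_muscle():
    d_true = np.array([3.0, 1.0, 4.0]) / np.linalg.norm([3.0, 1.0, 4.0])
    d = centroid_direction(_prismatic_sections(d_true))
    np.testing.assert_allclose(d, d_true, atol=1e-9)


def test_centroid_method_two_sections_equals_straight_line():
    f, p = np.zeros(3), np.array([5.0, 2.0, 8.0])
    att = MuscleAttachment("m", "middle", f, p)
    sections = [f + np.array([[0, 0.5, 0], [0, -0.5, 0]]),
                p + np.array([[0, 0.5, 0], [0, -0.5, 0]])]
    np.testing.assert_allclose(centroid_direction(sections),
                               straight_line_direction(att), atol=1e-12)


def test_curved_belly_returns_the_centroid_chord():
    # centroids on a quarter circle of radius r in the x-z plane:
    # the chord direction is analytically (cos 45, 0, sin 45) rotated ends
    r = 20.0
    thetas = np.linspace(0, np.pi / 2, 7)
    sections = [np.array([r * np.cos(t), 0, r * np.sin(t)]) +
                np.array([[0, 1.0, 0], [0, -1.0, 0]]) for t in thetas]
    d = centroid_direction(sections)
    chord = np.array([r * np.cos(np.pi / 2) - r, 0, r * np.sin(np.pi / 2) - 0])
    np.testing.assert_allclose(d, chord / np.linalg.norm(chord), atol=1e-12)
    # and it differs from the local fiber tangent at either end
    assert abs(d @ np.array([0.0, 0.0, 1.0])) < 0.99


def test_centroid_method_needs_two_sections():
    with pytest.raises(ValueError):
        centroid_direction(_prismatic_sections(np.array([1.0, 0, 0]), n=1))


# ------------------------------------------------------------- regional table

def test_regional_table_single_phantom_matches_tables(pooled_phantom):
    records = {(r.muscle, r.region): r for r in regional_table(pooled_phantom)}
    rec = records[("gluteus medius", "ventral")]
    assert rec.frontal_angle_deg == pytest.approx(22.55, abs=1e-6)
    rec = records[("piriformis", "ventral")]  # cranial slot
    assert rec.transverse_angle_deg == pytest.approx(22.38, abs=1e-6)


def test_cohort_of_identical_phantoms_has_zero_variance(pooled_phantom):
    single = {(r.muscle, r.region): r for r in regional_table(pooled_phantom)}
    trio = {(r.muscle, r.region): r
            for r in regional_table([pooled_phantom] * 3)}
    for key, rec in single.items():
        assert trio[key].frontal_angle_deg == pytest.approx(
            rec.frontal_angle_deg, abs=1e-12)


def test_missing_muscle_warns_and_omits_record(pooled_phantom):
    reduced = dict(pooled_phantom.attachments)
    reduced.pop(("piriformis", "ventral"))
    import dataclasses
    partial = dataclasses.replace(pooled_phantom, attachments=reduced)
    with pytest.warns(UserWarning, match="piriformis"):
        records = regional_table([pooled_phantom, partial])
    # record for the present phantoms still emitted
    assert any(r.muscle == "piriformis" and r.region == "ventral"
               for r in records)
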