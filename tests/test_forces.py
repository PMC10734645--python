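"""PCSA arithmetic, the periosteal counterforce and regional predictions."""

import numpy as np
import pytest

import trochwarp.forces as forces
from trochwarp.forces import (ForceModelConfig, PCSATable,
                              calibrate_counterforce_beta, muscle_force_vector,
                              pcsa_group_ratio, pcsa_group_sum, pcsa_table,
                              periosteal_counterforce,
                              posterior_system_resolution,
                              predicted_ay_from_resultant,
                              warp_prediction_profile)


# ------------------------------------------------------------ PCSA arithmetic

def test_lube_group_sums_reproduce_published_values_exactly():
    t = pcsa_table("lube")
    assert pcsa_group_sum(t, "A_proximal") == pytest.approx(99.7, abs=1e-9)
    assert pcsa_group_sum(t, "B_rotators") == pytest.approx(45.7, abs=1e-9)


def test_pierrynowski_ratio_reproduces_to_one_decimal():
    a, b = forces.GROUPED_PCSA_PRINTED["pierrynowski"][:2]
    assert round(pcsa_group_ratio(a, b), 1) == 41.2


def test_lube_recomputed_ratio_differs_from_printed():
    # printed 45.70; direct arithmetic on the printed sums gives 45.8
    assert round(pcsa_group_ratio(99.7, 45.7), 1) == 45.8


def test_group_sum_scales_linearly():
    t = pcsa_table("lube")
    doubled = PCSATable("lube2", {m: 2 * a for m, a in t.areas_cm2.items()})
    assert pcsa_group_sum(doubled, "A_proximal") == pytest.approx(
        2 * pcsa_group_sum(t, "A_proximal"))


def test_missing_member_error_names_the_muscle():
    with pytest.raises(KeyError, match="quadratus femoris"):
        pcsa_group_sum(pcsa_table("brand"), "B_rotators")


def test_ratio_rejects_zero_denominator():
    with pytest.raises(ValueError):
        pcsa_group_ratio(0.0, 10.0)


def test_brand_typo_correction_is_flagged_and_optional():
    corrected = pcsa_table("brand")
    raw = pcsa_table("brand", corrected=False)
    assert raw.get("obturator externus") == 3795.0
    assert corrected.get("obturator externus") == pytest.approx(3.795)
    assert corrected.corrections_applied == (("obturator externus", 3.795),)


# --------------------------------------------------------- elementary vectors

def test_muscle_force_vector_scales_direction_by_area():
    np.testing.assert_allclose(
        muscle_force_vector((1, 0, 0), pcsa_cm2=2.0, sigma=1.0), [2, 0, 0])
    with pytest.raises(ValueError):
        muscle_force_vector((1, 0, 0), pcsa_cm2=-1.0)


def test_counterforce_phi_zero_beta_one_is_pure_caudal():
    v = periosteal_counterforce((-1.0, 0, 0), phi_deg=0.0, beta=1.0)
    np.testing.assert_allclose(v, [0, 0, -1], atol=1e-12)


def test_counterforce_beta_zero_vanishes():
    v = periosteal_counterforce((-3.0, 1.0, 4.0), phi_deg=15.0, beta=0.0)
    np.testing.assert_allclose(v, 0.0, atol=1e-15)


def test_counterforce_rejects_zero_input():
    with pytest.raises(ValueError):
        periosteal_counterforce((0.0, 0.0, 0.0))


def test_calibrated_beta_makes_posterior_resultant_frontally_vertical():
    r = np.array([-14.0, 6.0, 27.0])
    beta = calibrate_counterforce_beta(r, phi_deg=60.0)
    total = r + periosteal_counterforce(r, phi_deg=60.0, beta=beta)
    assert abs(total[0]) < 1e-9  # no lateral component left
    assert forces.frontal_elevation(total) == pytest.approx(90.0)


@pytest.mark.parametrize("source", forces.PCSA_SOURCES)
def test_posterior_parallelogram_is_almost_vertical(source):
    with pytest.warns(UserWarning) if source == "brand" else _nullcontext():
        res = posterior_system_resolution(
            config=ForceModelConfig(pcsa_source=source))
    assert forces.frontal_elevation(res.resultant) >= 75.0


def _nullcontext():
    import contextlib
    return contextlib.nullcontext()


# -------------------------------------------------------- predicted AY angles

@pytest.mark.parametrize("resultant,expected", [
    ((0, 0, 10), 0.0),     # vertical force -> horizontal plate
    ((1, 0, 1), 45.0),
    ((10, 0, 0), 90.0),    # horizontal force -> vertical plate
])
def test_predicted_ay_from_resultant(resultant, expected):
    assert predicted_ay_from_resultant(resultant) == pytest.approx(expected)


@pytest.mark.parametrize("source", forces.PCSA_SOURCES)
def test_predicted_warp_ordering_ventral_middle_dorsal(source):
    with pytest.warns(UserWarning) if source == "brand" else _nullcontext():
        res = warp_prediction_profile(config=ForceModelConfig(pcsa_source=source))
    v, m, d = (res[r].predicted_ay_deg for r in ("ventral", "middle", "dorsal"))
    assert v > m > d


def test_ventral_system_steeper_than_posterior_prediction():
    res = warp_prediction_profile()
    post = posterior_system_resolution()
    assert res["ventral"].predicted_ay_deg > post.predicted_ay_deg


def test_posterior_ablation_reduces_dorsal_to_middle():
    res = warp_prediction_profile(config=ForceModelConfig(posterior_weight=0.0))
    assert res["dorsal"].predicted_ay_deg == pytest.approx(
        res["middle"].predicted_ay_deg, abs=1e-12)


def test_predicted_dorsal_ay_decreases_monotonically_with_posterior_weight():
    weights = [0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 8.0]
    preds = [warp_prediction_profile(
        config=ForceModelConfig(posterior_weight=w))["dorsal"].predicted_ay_deg
        for w in weights]
    assert all(a > b for a, b in zip(preds, preds[1:]))


def test_directions_invariant_to_sigma_and_uniform_pcsa_rescaling():
    base = warp_prediction_profile()
    scaled = warp_prediction_profile(config=ForceModelConfig(sigma=7.5))
    for region in base:
        assert scaled[region].predicted_ay_deg == pytest.approx(
            base[region].predicted_ay_deg, abs=1e-9)
        # resultants are parallel
        a, b = base[region].resultant, scaled[region].resultant
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos == pytest.approx(1.0, abs=1e-12)


def test_resultant_is_linear_in_the_member_vectors():
    res = warp_prediction_profile()
    for region in ("ventral", "middle"):
        total = np.sum(list(res[region].member_vectors.values()), axis=0)
        np.testing.assert_allclose(res[region].resultant, total, atol=1e-9)
    dorsal = res["dorsal"]
    total = np.sum(list(dorsal.member_vectors.values()), axis=0) + dorsal.counterforce
    np.testing.assert_allclose(dorsal.resultant, total, atol=1e-9)


def test_incomplete_attachment_coverage_names_missing_muscles():
    from trochwarp.trajectories import default_attachment_map
    att = default_attachment_map("pooled")
    att.pop(("piriformis", "dorsal"))
    with pytest.raises(KeyError, match="piriformis"):
        warp_prediction_profile(attachments=att)
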