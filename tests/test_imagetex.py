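"""Topography analysis tests: leveling, segmentation, roughness, texture."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import small_scene
from ommech import imagetex, synthgen
from ommech.datatypes import HeightMap
from ommech.synthgen.presets import SceneSpec, StripeSpec, VesicleSpec


def _hm(heights, px=4.0):
    return HeightMap(heights=np.asarray(heights, float), pixel_size=px)


# --------------------------------------------------------------------------
# flatten_map
# --------------------------------------------------------------------------


def test_flatten_removes_pure_row_tilts():
    rng = np.random.default_rng(0)
    n = 128
    offsets = rng.normal(0, 0.3, n)
    tilts = rng.normal(0, 0.5, n)
    x = np.linspace(-0.5, 0.5, n)
    hm = _hm(offsets[:, None] + tilts[:, None] * x[None, :])
    flat = imagetex.flatten_map(hm, order=1)
    row_slopes = [np.polyfit(x, row, 1)[0] for row in flat.heights]
    assert np.max(np.abs(row_slopes)) < 1e-9
    assert np.sqrt(np.mean(flat.heights ** 2)) < 1e-6


def test_flatten_recovers_artifact_free_truth(flat_two_phase_scene):
    hm, truth = flat_two_phase_scene
    flat = imagetex.flatten_map(hm, order=1)
    clean = truth.clean_heights
    clean = clean - np.median(clean[truth.labels == 0])
    rms = np.sqrt(np.mean((flat.heights - clean) ** 2))
    assert rms < 0.05


def test_flatten_is_idempotent(flat_two_phase_scene):
    hm, _ = flat_two_phase_scene
    once = imagetex.flatten_map(hm, order=1)
    twice = imagetex.flatten_map(once, order=1)
    rms = np.sqrt(np.mean((twice.heights - once.heights) ** 2))
    assert rms < 1e-6


def test_order_zero_on_offset_free_map_only_shifts_mean():
    hm = _hm(np.full((96, 96), 5.0))
    flat = imagetex.flatten_map(hm, order=0)
    np.testing.assert_allclose(flat.heights, 0.0, atol=1e-9)


def test_flatten_rejects_bad_order(flat_two_phase_scene):
    with pytest.raises(ValueError):
        imagetex.flatten_map(flat_two_phase_scene[0], order=3)


# --------------------------------------------------------------------------
# segmentation and coverage
# --------------------------------------------------------------------------


def test_two_plateau_map_yields_substrate_fluid_solid(flat_two_phase_scene):
    hm, _ = flat_two_phase_scene
    seg = imagetex.segment_heights(imagetex.flatten_map(hm, order=1))
    assert {"substrate", "fluid", "solid"} <= set(seg.class_names)
    assert seg.class_heights["substrate"] == pytest.approx(0.0, abs=0.1)
    assert seg.class_heights["fluid"] == pytest.approx(4.0, abs=0.1)
    assert seg.class_heights["solid"] == pytest.approx(5.0, abs=0.1)


def test_constant_map_is_a_single_class():
    seg = imagetex.segment_heights(_hm(np.full((96, 96), 4.0)))
    assert len(set(seg.labels.ravel())) == 1


def test_rough_domains_overlap_truth_with_high_jaccard():
    scene = small_scene("LPS-DMPC", px=512)
    hm, truth = synthgen.gen_height_map(scene, seed=5)
    seg = imagetex.segment_heights(imagetex.flatten_map(hm, order=1))
    det = seg.mask("rough")
    true_r = truth.labels == truth.class_names.index("rough")
    jaccard = (det & true_r).sum() / (det | true_r).sum()
    assert jaccard >= 0.8


def test_coverage_fractions_sum_to_one(flat_two_phase_scene):
    hm, _ = flat_two_phase_scene
    seg = imagetex.segment_heights(imagetex.flatten_map(hm, order=1))
    for denom in ("lipid", "total"):
        cov = imagetex.coverage_fractions(seg, denom)
        assert sum(cov.values()) == pytest.approx(1.0, abs=1e-9)


def test_all_fluid_scene_reports_full_fluid_coverage():
    scene = SceneSpec(name="fluid", pixels_per_side=128,
                      phase_heights={"fluid": 4.0},
                      target_coverages={"fluid": 1.0},
                      texture_sd={"fluid": 0.08}, scanline=None,
                      plane_tilt_nm=0.0)
    hm, _ = synthgen.gen_height_map(scene, seed=6)
    seg = imagetex.segment_heights(hm)
    cov = imagetex.coverage_fractions(seg, "lipid")
    assert cov == {"fluid": 1.0}


def test_substrate_only_map_has_undefined_lipid_coverage():
    seg = imagetex.segment_heights(_hm(np.random.default_rng(2).normal(0, 0.05, (96, 96))))
    with pytest.raises(ValueError):
        imagetex.coverage_fractions(seg, "lipid")


def test_rough_fraction_increases_with_lps_content():
    """Scenes spanning the low-to-high LPS range give monotone rough coverage."""
    base = small_scene("LPS-DMPC", px=256)
    fractions = []
    for rough_target in (0.08, 0.2, 0.4):
        solid = 0.72 - 0.28 - rough_target
        scene = dataclasses.replace(
            base, target_coverages={"fluid": 0.28, "solid": solid,
                                    "rough": rough_target})
        hm, _ = synthgen.gen_height_map(scene, seed=8)
        seg = imagetex.segment_heights(imagetex.flatten_map(hm, order=1))
        cov = imagetex.coverage_fractions(seg, "lipid")
        fractions.append(cov.get("rough", 0.0))
    assert fractions == sorted(fractions)


# --------------------------------------------------------------------------
# roughness
# --------------------------------------------------------------------------


def test_rq_of_plane_is_zero():
    assert imagetex.roughness_rq(_hm(np.full((64, 64), 3.0))) == 0.0


def test_rq_of_sinusoid_is_amplitude_over_sqrt2():
    x = np.arange(128) * 2.0
    hm = _hm(np.tile(0.5 * np.sin(2 * np.pi * x / 32.0), (128, 1)), px=2.0)
    assert imagetex.roughness_rq(hm) == pytest.approx(0.5 / np.sqrt(2), rel=0.01)


def test_rq_estimator_recovers_gaussian_texture_sd():
    rng = np.random.default_rng(3)
    hm = _hm(rng.normal(0, 0.77, (256, 256)))
    assert imagetex.roughness_rq(hm) == pytest.approx(0.77, abs=0.05)


def test_rq_rejects_tiny_masks():
    hm = _hm(np.zeros((64, 64)))
    mask = np.zeros((64, 64), bool)
    mask[:5, :5] = True
    with pytest.raises(ValueError):
        imagetex.roughness_rq(hm, mask)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(shift=st.floats(-10, 10), scale=st.floats(0.1, 5.0))
def test_rq_translation_invariance_and_linear_scaling(shift, scale):
    rng = np.random.default_rng(4)
    base = rng.normal(0, 0.5, (96, 96))
    rq = imagetex.roughness_rq(_hm(base))
    assert imagetex.roughness_rq(_hm(base + shift)) == pytest.approx(rq, rel=1e-9)
    assert imagetex.roughness_rq(_hm(base * scale)) == pytest.approx(scale * rq, rel=1e-9)


# --------------------------------------------------------------------------
# profiles
# --------------------------------------------------------------------------


def test_profile_on_constant_map_is_constant():
    hm = _hm(np.full((96, 96), 2.5), px=3.0)
    dist, heights = imagetex.extract_profile(hm, (0, 30), (280, 30))
    np.testing.assert_allclose(heights, 2.5)
    assert dist[-1] == pytest.approx(280.0)


def test_profile_across_patch_edge_shows_height_step():
    h = np.zeros((128, 128))
    h[:, 64:] = 5.0
    hm = _hm(h, px=2.0)
    dist, prof = imagetex.extract_profile(hm, (40, 128), (210, 128))
    assert prof[0] == pytest.approx(0.0, abs=1e-9)
    assert prof[-1] == pytest.approx(5.0, abs=1e-9)
    assert np.max(np.diff(prof)) > 2.0  # sharp step


def test_profile_across_stripes_is_sinusoidal():
    scene = SceneSpec(name="s", image_size_um=1.0, pixels_per_side=256,
                      phase_heights={"solid": 5.0}, target_coverages={"solid": 1.0},
                      texture_sd={}, stripe=StripeSpec(15.0, 0.4, 0.0),
                      scanline=None, plane_tilt_nm=0.0)
    hm, truth = synthgen.gen_height_map(scene, seed=3)
    dist, prof = imagetex.extract_profile(hm, (0, 500), (900, 500))
    # FFT of the profile peaks at the stripe frequency
    p = np.abs(np.fft.rfft(prof - prof.mean())) ** 2
    freqs = np.fft.rfftfreq(len(prof), d=dist[1] - dist[0])
    assert 1.0 / freqs[np.argmax(p)] == pytest.approx(15.0, abs=1.0)


def test_profile_rejects_degenerate_or_outside_endpoints():
    hm = _hm(np.zeros((96, 96)), px=2.0)
    with pytest.raises(ValueError):
        imagetex.extract_profile(hm, (10, 10), (10, 10))
    with pytest.raises(ValueError):
        imagetex.extract_profile(hm, (0, 0), (500, 0))


# --------------------------------------------------------------------------
# stripe periodicity
# --------------------------------------------------------------------------


def _stripe_scene(noise=0.1, orientation=0.6, px=512):
    return SceneSpec(name="om", image_size_um=2.0, pixels_per_side=px,
                     phase_heights={"solid": 6.0}, target_coverages={"solid": 1.0},
                     texture_sd={"solid": noise},
                     stripe=StripeSpec(15.0, 0.4, orientation),
                     scanline=None, plane_tilt_nm=0.0)


def test_stripe_wavelength_recovered_within_one_bin():
    hm, _ = synthgen.gen_height_map(_stripe_scene(), seed=9)
    spec = imagetex.stripe_period(hm)
    assert spec.periodic
    assert spec.dominant_wavelength == pytest.approx(
        15.0, abs=spec.extras["frequency_bin_nm"])


def test_white_noise_map_reports_no_periodicity():
    rng = np.random.default_rng(5)
    hm = _hm(rng.normal(0, 0.2, (256, 256)), px=4.0)
    spec = imagetex.stripe_period(hm)
    assert not spec.periodic
    assert spec.dominant_wavelength is None


def test_stripe_amplitude_recovered_by_parseval_bookkeeping():
    hm, _ = synthgen.gen_height_map(_stripe_scene(noise=0.1), seed=10)
    spec = imagetex.stripe_period(hm)
    assert spec.dominant_amplitude == pytest.approx(0.4, abs=0.08)


def test_stripe_wavelength_invariant_under_right_angle_rotation():
    hm, _ = synthgen.gen_height_map(_stripe_scene(px=256), seed=11)
    spec = imagetex.stripe_period(hm)
    rotated = HeightMap(np.rot90(hm.heights).copy(), hm.pixel_size)
    spec_rot = imagetex.stripe_period(rotated)
    assert spec_rot.dominant_wavelength == pytest.approx(
        spec.dominant_wavelength, abs=spec.extras["frequency_bin_nm"])


# --------------------------------------------------------------------------
# vesicles
# --------------------------------------------------------------------------


def test_empty_scene_has_no_detections():
    hm = _hm(np.random.default_rng(6).normal(0, 0.05, (128, 128)), px=3.9)
    assert imagetex.detect_vesicles(hm) == []


def test_single_cap_diameter_matches_construction():
    scene = SceneSpec(name="one", pixels_per_side=128,
                      texture_sd={}, scanline=None, plane_tilt_nm=0.0,
                      vesicles=VesicleSpec(count=1, diameter_mean=40.0,
                                           diameter_sd=0.0, min_diameter=8.0))
    hm, truth = synthgen.gen_height_map(scene, seed=12)
    det = imagetex.detect_vesicles(hm)
    assert len(det) == 1
    assert det[0]["diameter"] == pytest.approx(truth.vesicles[0]["diameter"],
                                               abs=2 * hm.pixel_size)


def test_vesicle_batch_mean_tracks_truth():
    scene = small_scene("LPS-VESICLES", px=512)
    hm, truth = synthgen.gen_height_map(scene, seed=13)
    flat = imagetex.flatten_map(hm, order=1)
    det = imagetex.detect_vesicles(flat)
    truth_mean = np.mean([v["diameter"] for v in truth.vesicles])
    got = imagetex.vesicle_summary(det)
    assert got["count"] >= 0.9 * len(truth.vesicles)
    assert got["mean_diameter"] == pytest.approx(truth_mean, rel=0.12)
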