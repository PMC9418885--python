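"""Detector tests: preprocessing, contact, step detection, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_ramp_curve
from ommech import forcespec, synthgen
from ommech.datatypes import CurveResult, ForceCurve, NoContactError, RuptureEvent


# --------------------------------------------------------------------------
# preprocess_curve
# --------------------------------------------------------------------------


def test_window_one_is_identity_on_forces():
    curve = make_ramp_curve(noise_sd=0.02)
    out = forcespec.preprocess_curve(curve, window=1)
    np.testing.assert_allclose(out.force, curve.force - np.mean(
        curve.force[:len(out.force) // 5]), atol=1e-9)


def test_median_filter_removes_single_sample_spike():
    curve = make_ramp_curve(noise_sd=0.0)
    spiked = curve.force.copy()
    spiked[100] += 1.0
    curve2 = ForceCurve(curve.separation, spiked, "approach", {})
    out = forcespec.preprocess_curve(curve2, window=5)
    clean = forcespec.preprocess_curve(curve, window=5)
    assert np.max(np.abs(out.force - clean.force)) < 1e-9


def test_baseline_offset_is_removed():
    curve = make_ramp_curve()
    shifted = ForceCurve(curve.separation, curve.force + 0.2, "approach", {})
    out = forcespec.preprocess_curve(shifted)
    far = out.separation > 25.0
    assert abs(np.mean(out.force[far])) < 1e-9


def test_preprocess_rejects_bad_window():
    curve = make_ramp_curve()
    for w in (0, 2, len(curve) + 1):
        with pytest.raises(ValueError):
            forcespec.preprocess_curve(curve, window=w)


# --------------------------------------------------------------------------
# find_contact_point
# --------------------------------------------------------------------------


def test_contact_point_of_noiseless_ramp():
    curve = forcespec.preprocess_curve(make_ramp_curve(contact=20.0, ds=0.05))
    assert forcespec.find_contact_point(curve) == pytest.approx(20.0, abs=0.11)


def test_all_noise_curve_signals_no_contact():
    rng = np.random.default_rng(1)
    s = np.arange(40.0, 0.0, -0.05)
    curve = ForceCurve(s, rng.normal(0, 0.05, len(s)), "approach", {})
    with pytest.raises(NoContactError):
        forcespec.find_contact_point(forcespec.preprocess_curve(curve))


def test_contact_point_matches_generator_truth(dmpc20_preset):
    curve, truth = synthgen.gen_force_curve(dmpc20_preset, seed=9, noise_sd=0.0)
    prepped = forcespec.preprocess_curve(curve)
    found = forcespec.find_contact_point(prepped)
    ds = curve.separation[0] - curve.separation[1]
    assert abs(found - truth.contact_separation) <= 2 * ds


# --------------------------------------------------------------------------
# detect_steps
# --------------------------------------------------------------------------


@pytest.mark.parametrize("name", ["DMPC-20C", "DMPC-30C", "LPS-DMPC",
                                  "OM-DMPC", "LPS-VESICLE"])
def test_noiseless_detection_equals_truth_exactly(name):
    """Oracle equivalence: every event's force/thickness matches the
    grid-realised ground truth with no tolerance."""
    preset = synthgen.get_force_preset(name)
    for counter in range(10):
        curve, truth = synthgen.gen_force_curve(preset, seed=21,
                                                counter=counter, noise_sd=0.0)
        events = forcespec.detect_steps(forcespec.preprocess_curve(curve))
        expected = [ev for ev in truth.events
                    if ev.grid_rupture_force > 0.1 and ev.grid_thickness > 0.1]
        assert len(events) == len(expected)
        for got, want in zip(events, expected):
            assert got.rupture_force == want.grid_rupture_force
            assert got.thickness == want.grid_thickness
            assert got.yield_separation == want.grid_yield_separation


def test_flat_curve_yields_no_events():
    s = np.arange(30.0, 0.0, -0.05)
    curve = ForceCurve(s, np.zeros(len(s)), "approach", {})
    assert forcespec.detect_steps(forcespec.preprocess_curve(curve)) == []


def test_sub_threshold_drop_is_gated_out():
    """A 0.05 nN drop dies at the 0.1 nN / 0.1 nm gates; a 0.5 nN one lives."""
    ds = 0.02
    s = np.arange(30.0, 3.0, -ds)
    f = np.zeros(len(s))
    # small event: load to 0.05 at s=10.5, drop, 1 nm gap
    load1 = (s <= 10.55) & (s > 10.5)
    f[load1] = 10.55 - s[load1]
    # large event: load to 0.5 at s=9.0, drop, 1 nm gap
    load2 = (s <= 9.5) & (s > 9.0)
    f[load2] = 9.5 - s[load2]
    tail = s <= 8.0
    f[tail] = 8.0 - s[tail]
    curve = ForceCurve(s, f, "approach", {})
    events = forcespec.detect_steps(forcespec.preprocess_curve(curve))
    assert len(events) == 1
    assert events[0].rupture_force == pytest.approx(0.5, abs=0.05)


def test_detect_rejects_retract_curves(dmpc20_preset):
    curve, _ = synthgen.gen_retract_curve(dmpc20_preset, seed=1)
    with pytest.raises(ValueError):
        forcespec.detect_steps(curve)


def test_raising_min_force_never_adds_events(lps_dmpc_preset):
    """Monotone gating over a noisy batch."""
    curves, _ = synthgen.gen_force_batch(lps_dmpc_preset, 30, seed=3,
                                         noise_sd=0.05)
    prepped = [forcespec.preprocess_curve(c) for c in curves]
    thresholds = [0.05, 0.1, 0.2, 0.4, 0.8, 1.6]
    counts = []
    for thr in thresholds:
        counts.append(sum(len(forcespec.detect_steps(c, min_force=thr))
                          for c in prepped))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_thickness_positive_and_events_ordered(lps_dmpc_preset):
    curves, _ = synthgen.gen_force_batch(lps_dmpc_preset, 20, seed=5,
                                         noise_sd=0.05)
    for c in curves:
        events = forcespec.detect_steps(forcespec.preprocess_curve(c))
        seps = [e.yield_separation for e in events]
        assert all(e.thickness > 0 for e in events)
        assert seps == sorted(seps, reverse=True)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


def _result(forces, thickness=5.0):
    events = [RuptureEvent(yield_separation=10.0 - i, rupture_force=f,
                           thickness=thickness, force_drop=f, index_in_curve=i)
              for i, f in enumerate(forces)]
    return CurveResult(events=events)


def test_two_step_curve_labelled_alpha_beta():
    results = [_result([0.5, 1.4])]
    forcespec.classify_events(results, forcespec.PopulationModel())
    assert [e.label for e in results[0].events] == ["alpha", "beta"]


def test_single_high_force_step_in_om_batch_is_gamma():
    curves, _ = synthgen.gen_force_batch(synthgen.get_force_preset("OM-DMPC"),
                                         60, seed=8, noise_sd=0.02)
    results = forcespec.analyze_batch(curves)
    model = forcespec.classify_events(results)
    singles = [r.events[0] for r in results if r.step_count == 1]
    near_two = [e for e in singles if abs(e.rupture_force - 2.0) < 0.3]
    assert near_two and all(e.label == "gamma" for e in near_two)
    assert model.gamma_gate <= 2.0


def test_classification_consistency_alpha_precedes_beta(lps_dmpc_preset):
    curves, _ = synthgen.gen_force_batch(lps_dmpc_preset, 80, seed=13,
                                         noise_sd=0.05)
    results = forcespec.analyze_batch(curves)
    forcespec.classify_events(results)
    for r in results:
        labels = [e.label for e in r.events]
        assert labels.count("beta") <= 1
        if "beta" in labels:
            assert labels[-1] == "beta"
        for i, lab in enumerate(labels):
            if lab == "alpha":
                assert "beta" in labels[i + 1:]


def test_no_events_warns_and_labels_nothing():
    with pytest.warns(UserWarning):
        forcespec.classify_events([CurveResult(events=[])])


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------


def test_single_event_summary_is_exact():
    results = [_result([2.0])]
    forcespec.classify_events(results, forcespec.PopulationModel())
    s = forcespec.summarize_curves(results)
    assert s["mean_final_rupture_force"] == 2.0
    assert s["sd_final_rupture_force"] == 0.0
    assert s["mean_step_count"] == 1.0


def test_beta_without_alpha_fraction_tracks_presence(lps_dmpc_preset):
    curves, _ = synthgen.gen_force_batch(lps_dmpc_preset, 400, seed=17,
                                         noise_sd=0.02)
    results = forcespec.analyze_batch(curves)
    forcespec.classify_events(results)
    s = forcespec.summarize_curves(results)
    # alpha present in 95% of curves; a few more fall below the gates
    assert 0.02 <= s["frac_beta_without_alpha"] <= 0.12
    assert s["mean_step_count"] == pytest.approx(1.95, abs=0.1)


def test_scatter_map_lists_every_event(lps_dmpc_preset):
    curves, _ = synthgen.gen_force_batch(lps_dmpc_preset, 10, seed=2,
                                         noise_sd=0.03)
    results = forcespec.analyze_batch(curves)
    df = forcespec.scatter_map(results)
    assert len(df) == sum(r.step_count for r in results)
    assert set(df.columns) >= {"force_nN", "thickness_nm", "label"}


# --------------------------------------------------------------------------
# unfolding
# --------------------------------------------------------------------------


def test_unfolding_releases_found_at_truth_positions(dmpc20_preset):
    curve, truth = synthgen.gen_retract_curve(dmpc20_preset, seed=19,
                                              unfolding=True, n_teeth=2,
                                              noise_sd=0.01)
    releases = forcespec.detect_unfolding(curve)
    assert len(releases) == 2
    ds = curve.separation[1] - curve.separation[0]
    for got, want in zip(sorted(r["separation"] for r in releases),
                         sorted(truth.release_positions)):
        assert abs(got - want) <= 2 * ds


def test_adhesion_only_and_noise_only_retracts_are_empty(dmpc20_preset):
    curve, _ = synthgen.gen_retract_curve(dmpc20_preset, seed=3,
                                          unfolding=False, noise_sd=0.01)
    assert forcespec.detect_unfolding(curve) == []
    rng = np.random.default_rng(4)
    s = np.arange(0.0, 40.0, 0.05)
    noise = ForceCurve(s, rng.normal(0, 0.02, len(s)), "retract", {})
    assert forcespec.detect_unfolding(noise) == []


def test_unfolding_rejects_approach(dmpc20_preset):
    curve, _ = synthgen.gen_force_curve(dmpc20_preset, seed=1)
    with pytest.raises(ValueError):
        forcespec.detect_unfolding(curve)


# --------------------------------------------------------------------------
# property: recovery at moderate noise
# --------------------------------------------------------------------------


@settings(max_examples=8, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_single_curve_detection_is_close_to_truth_under_noise(seed):
    preset = synthgen.get_force_preset("DMPC-20C")
    curve, truth = synthgen.gen_force_curve(preset, seed=seed, noise_sd=0.04)
    events = forcespec.detect_steps(forcespec.preprocess_curve(curve))
    assert len(events) == 1
    assert events[0].rupture_force == pytest.approx(
        truth.events[0].rupture_force, abs=0.2)
    assert events[0].thickness == pytest.approx(
        truth.events[0].thickness, abs=0.4)
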