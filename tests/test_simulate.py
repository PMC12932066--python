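"""Insertion simulation: chord oracles, calibration hits, Monte-Carlo
robustness and its analytic sphere oracle."""

import dataclasses

import numpy as np
import pytest

import prostmould as pm
from prostmould.guides import NeedleGuide
from prostmould.mould import MouldModel
from prostmould.simulate import sphere_notch_hit_probability

from conftest import make_cube, make_sphere


def _toy_mould(needle, insertion_depth=50.0) -> MouldModel:
    """Minimal mould carrying only what the simulator reads (spec, guides)."""
    spec = pm.MouldSpec(needle=needle, insertion_depth_mm=insertion_depth)
    box = make_cube(extent=2.0, center=(0, 0, 0))
    return MouldModel(case_id="toy", variant_offset_mm=0.0, solid=box,
                      cavity_surface=box,
                      block_bounds=np.array([[-1.0, -1, -1], [1.0, 1, 1]]),
                      guides=[], spec=spec)


def _guide_at(target, direction, reach, diameter=2.61) -> NeedleGuide:
    target = np.asarray(target, float)
    direction = np.asarray(direction, float)
    return NeedleGuide(guide_id="toy:g", roi_label="roi", approach="superior",
                       entry_point_mm=target - direction * reach,
                       direction=direction, tower_height_mm=0.0,
                       target_point_mm=target, channel_diameter_mm=diameter)


@pytest.mark.parametrize("lateral_offset,expected", [
    (0.0, 10.0),              # axis through the centre: chord = diameter
    (3.0, 2 * np.sqrt(16.0)), # chord formula 2*sqrt(r^2 - h^2)
    (6.0, 0.0),               # axis misses the r=5 sphere entirely
])
def test_notch_intersection_matches_sphere_chords(lateral_offset, expected):
    needle = pm.NeedleModel("test", 2.11, 0.0, 18.0, 0.0)
    mould = _toy_mould(needle)
    roi = make_sphere(5.0, center=(lateral_offset, 0.0, 0.0), subdivisions=3)
    guide = _guide_at((0, 0, 0), (0, 0, -1), reach=50.0)
    rep = pm.simulate_insertion(mould, guide, roi, needle)
    assert rep.notch_roi_intersection_mm == pytest.approx(expected, rel=0.01,
                                                          abs=1e-9)
    assert rep.hit == (expected > 0)
    assert rep.axis_to_centroid_mm == pytest.approx(lateral_offset, abs=1e-6)
    assert rep.notch_roi_intersection_mm <= needle.notch_length_mm


def test_oversized_needle_rejected():
    needle = pm.NeedleModel("fat", 3.0, 0.0, 18.0, 0.0)
    mould = _toy_mould(needle)
    guide = _guide_at((0, 0, 0), (0, 0, -1), reach=50.0, diameter=2.61)
    roi = make_sphere(5.0, subdivisions=2)
    with pytest.raises(ValueError):
        pm.simulate_insertion(mould, guide, roi, needle)


def test_zero_error_hit_rate_is_one(mould_variants, phantom_small):
    model = mould_variants[0]
    reports = pm.perturbed_hit_rate(model, phantom_small,
                                    pm.ErrorModel(seed=4), n_trials=8)
    for rep in reports:
        assert rep.hit_rate == 1.0
        assert rep.hit
        assert rep.axis_to_centroid_mm < 1e-6


def test_perturbed_trials_deterministic(mould_variants, phantom_small):
    err = pm.ErrorModel(translation_sigma_mm=3.0, rotation_sigma_deg=5.0,
                        seed=9)
    a = pm.perturbed_hit_rate(mould_variants[0], phantom_small, err, 300)
    b = pm.perturbed_hit_rate(mould_variants[0], phantom_small, err, 300)
    assert [dataclasses.asdict(x) for x in a] == \
        [dataclasses.asdict(x) for x in b]


def test_hit_rate_decreases_with_translation_error(mould_variants,
                                                   phantom_small):
    rates = []
    for sigma in (0.5, 2.0, 6.0):
        err = pm.ErrorModel(translation_sigma_mm=sigma, seed=2)
        reps = pm.perturbed_hit_rate(mould_variants[0], phantom_small, err,
                                     600)
        rates.append(np.mean([r.hit_rate for r in reps]))
    assert rates[0] > rates[1] > rates[2]


def test_monte_carlo_matches_analytic_oracle(mould_variants, phantom_small):
    """Pure translation error on a spherical ROI: the MC hit rate must match
    the closed-form Gaussian-displacement probability."""
    model = mould_variants[0]
    roi_radius = 5.0  # phantom_small ROI
    sigma = 2 * roi_radius
    err = pm.ErrorModel(translation_sigma_mm=sigma, seed=13)
    reps = pm.perturbed_hit_rate(model, phantom_small, err, 2000)
    expected = sphere_notch_hit_probability(
        roi_radius, sigma, model.spec.needle.notch_length_mm)
    for rep in reps:
        assert rep.hit_rate == pytest.approx(expected, abs=0.03)


def test_oracle_limits():
    # no error: certain hit when the sphere overlaps the notch
    assert sphere_notch_hit_probability(5.0, 0.0, 18.0) == 1.0
    assert sphere_notch_hit_probability(5.0, 0.0, 18.0,
                                        center_offset_mm=20.0) == 0.0
    # huge error: probability collapses toward zero
    assert sphere_notch_hit_probability(5.0, 50.0, 18.0) < 0.05
    # monotone in sigma
    ps = [sphere_notch_hit_probability(5.0, s, 18.0)
          for s in (1.0, 3.0, 6.0, 12.0)]
    assert ps == sorted(ps, reverse=True)
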