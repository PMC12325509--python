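"""Phantom and cohort generators against their analytic ground truth."""

import numpy as np
import pytest
from scipy.stats import norm

from lungdens import (CohortSpec, ParameterError, PhantomSpec,
                      analytic_mixture_laa, analytic_mixture_percentile,
                      compute_laa, compute_percentile_point, convolve_noise,
                      generate_cohort_measurements, generate_thorax_phantom,
                      lognormal_from_quantiles, mixture_mean,
                      normal_from_median_iqr)
from lungdens.synthetic import PhantomSpecError, _allocate_subtypes


# ---------------------------------------------------------------------------
# analytic mixture oracles
# ---------------------------------------------------------------------------

def test_analytic_laa_symmetry_and_degenerate_components():
    assert analytic_mixture_laa([(1.0, -950.0, 10.0)], -950) == pytest.approx(50.0)
    assert analytic_mixture_laa([(1.0, -980.0, 0.0)], -950) == 100.0
    assert analytic_mixture_laa([(1.0, -980.0, 0.0)], -990) == 0.0


def test_analytic_laa_default_mixture_matches_normal_cdf():
    mixture = [(0.2, -980.0, 15.0), (0.8, -850.0, 60.0)]
    expected = 100 * (0.2 * norm.cdf((-950 + 980) / 15)
                      + 0.8 * norm.cdf((-950 + 850) / 60))
    assert analytic_mixture_laa(mixture, -950) == pytest.approx(expected)
    assert analytic_mixture_laa(mixture, -950) == pytest.approx(23.3682, abs=1e-3)


def test_analytic_percentile_of_single_normal():
    assert analytic_mixture_percentile([(1.0, -850.0, 40.0)], 0.5) == \
        pytest.approx(-850.0, abs=1e-5)
    assert analytic_mixture_percentile([(1.0, 0.0, 1.0)], 0.15) == \
        pytest.approx(-1.0364, abs=1e-3)


def test_analytic_percentile_monotone_in_fraction():
    mixture = [(0.2, -980.0, 15.0), (0.8, -850.0, 60.0)]
    qs = [analytic_mixture_percentile(mixture, f) for f in (0.05, 0.15, 0.5, 0.9)]
    assert qs == sorted(qs)


def test_mixture_validation():
    with pytest.raises(ParameterError):
        analytic_mixture_laa([(0.5, -900, 10)], -950)          # weights != 1
    with pytest.raises(ParameterError):
        analytic_mixture_percentile([(1.0, -900, 0.0)], 0.15)  # all degenerate
    with pytest.raises(ParameterError):
        analytic_mixture_percentile([(1.0, -900, 10.0)], 1.5)


def test_empirical_mixture_draws_match_oracles():
    rng = np.random.default_rng(12)
    mixture = [(0.2, -980.0, 15.0), (0.8, -850.0, 60.0)]
    n = 10 ** 6
    comp = rng.choice(2, size=n, p=[0.2, 0.8])
    mus = np.array([-980.0, -850.0])[comp]
    sds = np.array([15.0, 60.0])[comp]
    draws = mus + sds * rng.standard_normal(n)
    assert compute_laa(draws, -950) == pytest.approx(
        analytic_mixture_laa(mixture, -950), abs=0.5)
    assert compute_percentile_point(draws, 0.15) == pytest.approx(
        analytic_mixture_percentile(mixture, 0.15), abs=2.0)


# ---------------------------------------------------------------------------
# voxel phantom
# ---------------------------------------------------------------------------

def test_zero_noise_single_component_is_constant():
    spec = PhantomSpec(dims=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                       lung_mixture=[(1.0, -850.0, 0.0)], noise_sd=0.0,
                       airway=None, seed=0)
    vol, lung, airway = generate_thorax_phantom(spec)
    assert np.all(vol.voxels[lung.flags] == -850.0)
    assert not airway.flags.any()


def test_phantom_is_deterministic(default_phantom):
    spec, vol, lung, airway = default_phantom
    vol2, lung2, airway2 = generate_thorax_phantom(spec)
    np.testing.assert_array_equal(vol.voxels, vol2.voxels)
    np.testing.assert_array_equal(lung.flags, lung2.flags)
    np.testing.assert_array_equal(airway.flags, airway2.flags)


def test_phantom_lung_mean_matches_mixture_mean(default_phantom):
    spec, vol, lung, airway = default_phantom
    assert lung.flags.sum() >= 10 ** 5
    emp = vol.voxels[lung.flags].mean()
    assert emp == pytest.approx(mixture_mean(spec.lung_mixture), abs=3.0)


def test_lungs_outside_body_rejected():
    from lungdens import Ellipsoid
    spec = PhantomSpec(dims=(48, 48, 48), spacing=(2.0, 2.0, 2.0))
    bad = PhantomSpec(
        dims=spec.dims, spacing=spec.spacing, body=spec.body,
        lungs=(Ellipsoid((10.0, 48.0, 48.0), (20.0, 20.0, 20.0)),
               spec.lungs[1]),
        airway=None)
    with pytest.raises(PhantomSpecError):
        generate_thorax_phantom(bad)


def test_gradient_shifts_dependent_region():
    kw = dict(dims=(64, 64, 64), spacing=(2.0, 2.0, 2.0), noise_sd=0.0,
              lung_mixture=[(1.0, -850.0, 0.0)], airway=None, seed=3)
    vol_g, lung, _ = generate_thorax_phantom(PhantomSpec(gradient_slope=2.0, **kw))
    ys = np.nonzero(lung.flags)[1]
    hu = vol_g.voxels[lung.flags]
    front = hu[ys < np.median(ys)].mean()
    back = hu[ys >= np.median(ys)].mean()
    assert back > front   # denser toward the dependent (posterior) side


def test_noise_convolution_widens_components():
    mix = convolve_noise([(1.0, -850.0, 30.0)], 40.0)
    assert mix[0][2] == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def test_quantile_calibration_helpers():
    mu, sigma = lognormal_from_quantiles(3.1, 4.98)
    assert np.exp(mu) == pytest.approx(3.1)
    assert np.exp(mu + sigma * norm.ppf(0.75)) == pytest.approx(4.98)
    mean, sd = normal_from_median_iqr(-816, -886, -745)
    assert mean == -816
    assert mean + sd * norm.ppf(0.75) == pytest.approx(-745, abs=0.5)


def test_cohort_generator_is_deterministic():
    a = generate_cohort_measurements(CohortSpec(seed=5))
    b = generate_cohort_measurements(CohortSpec(seed=5))
    assert len(a) == len(b) == 41
    for ra, rb in zip(a, b):
        assert ra == rb


def test_cohort_structure_and_invariants():
    recs = generate_cohort_measurements(CohortSpec(seed=9))
    groups = [r.group for r in recs]
    assert groups.count("control") == 21
    assert (groups.count("HA"), groups.count("CH"), groups.count("LS"),
            groups.count("MS"), groups.count("SM")) == (9, 3, 1, 4, 3)
    for r in recs:
        d = r.densitometry
        assert d.laa910 >= d.laa950 >= 0
        assert d.pd15 == pytest.approx(d.perc15 + 1000)
        assert 16 <= r.age <= 80 and 0 < r.pmi_days <= 5
        assert r.putrefaction != "severe"
    ctrl = [r for r in recs if r.is_control]
    assert all(r.control_cause is not None for r in ctrl)


def test_subtype_allocation_proportions():
    assert _allocate_subtypes(20).count("HA") == 9
    assert len(_allocate_subtypes(7)) == 7
    assert _allocate_subtypes(1) == ["HA"]


def test_zero_effect_spec_shares_control_distribution():
    rng_medians = []
    for seed in range(40):
        recs = generate_cohort_measurements(CohortSpec(seed=seed, zero_effect=True))
        a = np.median([r.densitometry.laa950 for r in recs if not r.is_control])
        c = np.median([r.densitometry.laa950 for r in recs if r.is_control])
        rng_medians.append(a > c)
    # under zero effect the direction is a coin flip, not systematically up
    assert 5 <= sum(rng_medians) <= 35
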