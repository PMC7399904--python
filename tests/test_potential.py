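"""Gravity/potential models: power decay, cancellation, and limits."""
import logging

import numpy as np
import pytest
from shapely.geometry import Point

from access2sfca.fca import two_step_fca, weighted_two_step
from access2sfca.kernels import indicator_kernel, power_kernel
from access2sfca.potential import gravity_two_step, potential_plain
from access2sfca.region import DemandUnit, Facility, Region
from access2sfca.synthetic import SynthConfig, generate_region

from conftest import naive_gravity, naive_potential


def _pair_region(distance: float, beds: int = 100) -> Region:
    return Region(
        demand_units=[DemandUnit(id="c", geometry=Point(0, 0), population=100)],
        facilities=[Facility(id="f", location=Point(distance, 0), beds=beds)],
    )


@pytest.mark.parametrize("beta, expected", [(1.0, 10.0), (2.0, 1.0)])
def test_plain_potential_single_facility(beta, expected):
    res = potential_plain(_pair_region(10.0), beta=beta)
    assert res.scores == pytest.approx([expected])


def test_plain_potential_two_facilities(line_region):
    # from the first community: 10 beds at 250 m + 35 beds at 1000 m, beta=1
    res = potential_plain(line_region, beta=1.0)
    assert res.scores[0] == pytest.approx(10 / 250 + 35 / 1000)


@pytest.mark.parametrize("distance", [1.0, 80.0, 2500.0])
@pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
def test_gravity_single_pair_decay_cancels(distance, beta):
    """With one facility and one demand unit, R = S/(D w) and A = R w = S/D."""
    res = gravity_two_step(_pair_region(distance, beds=10), beta=beta)
    assert res.scores == pytest.approx([0.1])


def test_gravity_beta_zero_equals_unbounded_catchment():
    region = generate_region(SynthConfig(seed=5))
    grav = gravity_two_step(region, beta=0.0)
    huge_radius = two_step_fca(region, d0=1e12)
    assert grav.scores == pytest.approx(huge_radius.scores, rel=1e-12)
    assert grav.ratios == pytest.approx(huge_radius.ratios, rel=1e-12)


def test_indicator_kernel_reproduces_catchment_worked_example(line_region):
    weights = indicator_kernel(line_region.distances, 600.0)
    res = weighted_two_step(line_region, weights, model="2sfca", params={"d0": 600.0})
    assert res.scores == pytest.approx([0.05, 0.225, 0.175])


@pytest.mark.parametrize("seed", range(5))
def test_gravity_conservation_on_random_regions(seed):
    region = generate_region(SynthConfig(seed=seed))
    res = gravity_two_step(region, beta=1.0)
    # power weights are positive, so every facility's demand is positive:
    # the weighted score total recovers the full bed supply
    assert region.populations @ res.scores == pytest.approx(region.beds.sum(), rel=1e-10)


def test_plain_potential_beta_to_zero_limit():
    region = generate_region(SynthConfig(n_demand=10, n_facilities=6, seed=2))
    total_beds = region.beds.sum()
    res = potential_plain(region, beta=1e-12)
    assert res.scores == pytest.approx(np.full(10, total_beds), rel=1e-6)
    exact = potential_plain(region, beta=0.0)
    assert exact.scores == pytest.approx(np.full(10, total_beds))


@pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
def test_scores_strictly_positive_everywhere(beta):
    """Power kernels never produce exact zeros while any facility has beds:
    published zero counts under this model can only be display rounding."""
    region = generate_region(SynthConfig(seed=9, zero_bed_fraction=0.2))
    assert region.beds.sum() > 0
    assert (potential_plain(region, beta=beta).scores > 0).all()
    assert (gravity_two_step(region, beta=beta).scores > 0).all()


def test_moving_facility_farther_never_raises_plain_potential():
    region = generate_region(SynthConfig(n_demand=15, n_facilities=5, seed=4))
    base = potential_plain(region, beta=1.0).scores
    # push facility 0 outward along the direction away from the extent center
    fac = region.facilities[0]
    shift = Point(fac.location.x + 50000, fac.location.y + 50000)
    moved = Region(
        demand_units=region.demand_units,
        facilities=[Facility(id=fac.id, location=shift, beds=fac.beds)] + list(region.facilities[1:]),
    )
    assert (potential_plain(moved, beta=1.0).scores <= base + 1e-15).all()


def test_matches_naive_loops():
    region = generate_region(SynthConfig(n_demand=18, n_facilities=12, seed=6))
    res = gravity_two_step(region, beta=1.3)
    ratios, scores = naive_gravity(region, beta=1.3)
    assert res.ratios == pytest.approx(ratios, abs=1e-12)
    assert res.scores == pytest.approx(scores, abs=1e-12)
    plain = potential_plain(region, beta=1.3)
    assert plain.scores == pytest.approx(naive_potential(region, beta=1.3), abs=1e-12)


def test_min_distance_floors_coincident_points():
    res = potential_plain(_pair_region(0.0, beds=50), beta=2.0, min_distance=1.0)
    assert np.isfinite(res.scores).all()
    assert res.scores == pytest.approx([50.0])  # 50 / max(0,1)^2


def test_all_zero_demand_warns_and_zeroes_ratios(caplog):
    region = Region(
        demand_units=[DemandUnit(id="c", geometry=Point(0, 0), population=0)],
        facilities=[Facility(id="f", location=Point(10, 0), beds=10)],
    )
    with caplog.at_level(logging.WARNING, logger="access2sfca"):
        res = gravity_two_step(region, beta=1.0)
    assert res.ratios == pytest.approx([0.0])
    assert any("zero" in rec.message for rec in caplog.records)


def test_kernel_validation():
    with pytest.raises(ValueError, match="beta"):
        power_kernel(np.ones((1, 1)), beta=-1)
    with pytest.raises(ValueError, match="min_distance"):
        power_kernel(np.ones((1, 1)), beta=1, min_distance=0)
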