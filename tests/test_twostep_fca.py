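"""Catchment-model supply-demand ratios and accessibility scores."""
import logging

import numpy as np
import pytest
from shapely.geometry import Point

from access2sfca.fca import accessibility_scores, supply_demand_ratios, two_step_fca
from access2sfca.region import DemandUnit, Facility, Region
from access2sfca.synthetic import SynthConfig, generate_region

from conftest import naive_two_step, served_supply


def test_line_region_worked_example(line_region):
    ratios = supply_demand_ratios(line_region, d0=600)
    assert ratios == pytest.approx([0.05, 0.175])
    scores = accessibility_scores(line_region, ratios, d0=600)
    assert scores == pytest.approx([0.05, 0.225, 0.175])
    # population-weighted score total equals the 45 beds supplied
    assert line_region.populations @ scores == pytest.approx(45.0)


def test_single_pair_direct_ratio():
    region = Region(
        demand_units=[DemandUnit(id="c", geometry=Point(0, 0), population=100)],
        facilities=[Facility(id="f", location=Point(100, 0), beds=10)],
    )
    res = two_step_fca(region, d0=600)
    assert res.ratios == pytest.approx([0.1])
    assert res.scores == pytest.approx([0.1])


def test_unreached_facility_gets_zero_ratio_with_warning(caplog):
    region = Region(
        demand_units=[DemandUnit(id="c", geometry=Point(0, 0), population=100)],
        facilities=[
            Facility(id="near", location=Point(100, 0), beds=10),
            Facility(id="far", location=Point(5000, 0), beds=20),
        ],
    )
    with caplog.at_level(logging.WARNING, logger="access2sfca.fca"):
        ratios = supply_demand_ratios(region, d0=600)
    assert ratios == pytest.approx([0.1, 0.0])
    assert any("far" in rec.message for rec in caplog.records)


def test_zero_population_unit_receives_scores_but_adds_no_demand():
    region = Region(
        demand_units=[
            DemandUnit(id="campus", geometry=Point(0, 0), population=0),
            DemandUnit(id="town", geometry=Point(100, 0), population=200),
        ],
        facilities=[Facility(id="f", location=Point(50, 0), beds=10)],
    )
    res = two_step_fca(region, d0=600)
    assert res.ratios == pytest.approx([10 / 200])  # campus contributes nothing
    assert res.scores[0] == pytest.approx(0.05)  # but is still scored


def test_demand_unit_out_of_reach_scores_zero(line_region):
    # at 200 m only c3 (coincident with f2) reaches a facility
    res = two_step_fca(line_region, d0=200)
    assert res.scores == pytest.approx([0.0, 0.0, 0.35])


def test_dimension_mismatch_raises(line_region):
    with pytest.raises(ValueError, match="ratio vector"):
        accessibility_scores(line_region, np.ones(5), d0=600)


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("d0", [500.0, 600.0])
def test_conservation_on_random_regions(seed, d0):
    """Population-weighted scores account exactly for all reachable beds."""
    region = generate_region(SynthConfig(seed=seed, zero_bed_fraction=0.1))
    res = two_step_fca(region, d0)
    assert region.populations @ res.scores == pytest.approx(served_supply(region, d0), rel=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_matches_naive_triple_loop(seed):
    region = generate_region(SynthConfig(n_demand=20, n_facilities=15, seed=seed))
    res = two_step_fca(region, 600.0)
    ratios, scores = naive_two_step(region, 600.0)
    assert res.ratios == pytest.approx(ratios, abs=1e-12)
    assert res.scores == pytest.approx(scores, abs=1e-12)


def test_homogeneity_in_beds_and_population():
    base = generate_region(SynthConfig(n_demand=15, n_facilities=10, seed=3))
    scaled_beds = Region(
        demand_units=base.demand_units,
        facilities=[Facility(id=f.id, location=f.location, beds=f.beds * 3) for f in base.facilities],
    )
    scaled_pop = Region(
        demand_units=[DemandUnit(id=u.id, geometry=u.geometry, population=u.population * 4)
                      for u in base.demand_units],
        facilities=base.facilities,
    )
    a = two_step_fca(base, 600.0).scores
    assert two_step_fca(scaled_beds, 600.0).scores == pytest.approx(3 * a)
    assert two_step_fca(scaled_pop, 600.0).scores == pytest.approx(a / 4)


def test_zero_score_iff_no_facility_in_reach():
    region = generate_region(SynthConfig(seed=11))
    res = two_step_fca(region, 500.0)
    reachable = (region.distances <= 500.0).any(axis=1)
    positive_pop = region.populations > 0
    # for units with positive population the equivalence is exact
    np.testing.assert_array_equal((res.scores == 0)[positive_pop], (~reachable)[positive_pop])


def test_result_label_and_validation(line_region):
    res = two_step_fca(line_region, 600.0)
    assert res.model == "2sfca"
    assert res.params == {"d0": 600.0}
    assert "2sfca" in res.label and "d0=600" in res.label
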