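"""Shared fixtures and deliberately naive reference implementations.

The naive functions below re-derive every quantity with explicit Python
loops straight from the defining formulas. They stay independent of the
vectorized code paths they are used to check.
"""
from __future__ import annotations

import numpy as np
import pytest

from access2sfca.region import Region
from access2sfca.synthetic import SynthConfig, generate_region, line_fixture


@pytest.fixture
def line_region() -> Region:
    return line_fixture()


@pytest.fixture
def small_region() -> Region:
    return generate_region(SynthConfig(n_demand=12, n_facilities=8, seed=7))


def naive_two_step(region: Region, d0: float) -> tuple[list[float], list[float]]:
    """Triple-loop catchment model: ratios then scores, straight from the formulas."""
    d = region.distances
    pops = [u.population for u in region.demand_units]
    ratios = []
    for j, fac in enumerate(region.facilities):
        demand = 0.0
        for k in range(len(region.demand_units)):
            if d[k][j] <= d0:
                demand += pops[k]
        ratios.append(fac.beds / demand if demand > 0 else 0.0)
    scores = []
    for i in range(len(region.demand_units)):
        total = 0.0
        for j in range(len(region.facilities)):
            if d[i][j] <= d0:
                total += ratios[j]
        scores.append(total)
    return ratios, scores


def naive_gravity(region: Region, beta: float, min_distance: float = 1.0) -> tuple[list[float], list[float]]:
    """Triple-loop two-search gravity model with power decay."""
    d = region.distances
    pops = [u.population for u in region.demand_units]

    def w(x: float) -> float:
        return max(x, min_distance) ** (-beta)

    ratios = []
    for j, fac in enumerate(region.facilities):
        demand = sum(pops[k] * w(d[k][j]) for k in range(len(pops)))
        ratios.append(fac.beds / demand if demand > 0 else 0.0)
    scores = [
        sum(ratios[j] * w(d[i][j]) for j in range(len(ratios)))
        for i in range(len(pops))
    ]
    return ratios, scores


def naive_potential(region: Region, beta: float, min_distance: float = 1.0) -> list[float]:
    """Double-loop plain potential of facility bed masses."""
    d = region.distances
    return [
        sum(fac.beds * max(d[i][j], min_distance) ** (-beta)
            for j, fac in enumerate(region.facilities))
        for i in range(len(region.demand_units))
    ]


def served_supply(region: Region, d0: float) -> float:
    """Total beds of facilities whose catchment holds positive population."""
    total = 0.0
    for j, fac in enumerate(region.facilities):
        if any(region.distances[k][j] <= d0 and u.population > 0
               for k, u in enumerate(region.demand_units)):
            total += fac.beds
    return total
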