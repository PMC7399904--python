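"""Two-step floating catchment area (2SFCA) accessibility.

Step 1 computes, for each facility j, the supply-demand ratio

    R_j = S_j / sum_{k : d_kj <= d0} D_k      (beds per person),

the facility's beds divided by the total elderly population within its
catchment radius d0. Step 2 sums, for each demand unit i, the ratios of all
facilities within d0 of it:

    A_i = sum_{j : d_ij <= d0} R_j.

A_i is a beds-per-person measure of the service available to unit i. Both
steps use the same inclusive straight-line radius, so supply and demand
interact across administrative boundaries.

A facility whose catchment contains no positive demand gets R_j = 0 (its
beds are unreachable, hence unusable) with a logged warning; this choice
preserves the conservation identity sum_i D_i * A_i = sum_j S_j over served
facilities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .kernels import indicator_kernel
from .region import Region

__all__ = ["AccessibilityResult", "supply_demand_ratios", "accessibility_scores", "two_step_fca", "weighted_two_step"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AccessibilityResult:
    """Per-facility ratios and per-demand-unit scores of one model run.

    ``model`` is one of ``"2sfca"``, ``"potential"``, ``"gravity2s"``;
    ``params`` records d0 and/or beta. ``ratios`` is empty for the plain
    potential model, which has no supply-demand step.
    """

    model: str
    params: dict[str, Any]
    scores: np.ndarray
    ratios: np.ndarray = field(default_factory=lambda: np.empty(0))
    demand_ids: tuple[str, ...] = ()
    facility_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))
        if (self.scores < 0).any() or (self.ratios < 0).any():
            raise ValueError("accessibility scores and ratios must be non-negative")

    @property
    def label(self) -> str:
        parts = [self.model] + [f"{k}={v:g}" if isinstance(v, (int, float)) else f"{k}={v}"
                                for k, v in sorted(self.params.items())]
        return " ".join(parts)


def weighted_two_step(region: Region, weights: np.ndarray, *, model: str, params: dict[str, Any]) -> AccessibilityResult:
    """Generic two-step computation for an arbitrary weight matrix.

    With weight w_ij between demand unit i and facility j:
    R_j = S_j / sum_k D_k w_kj  and  A_i = sum_j R_j w_ij. The indicator
    kernel recovers 2SFCA; a power kernel gives the two-search gravity model.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (region.n_demand, region.n_facilities):
        raise ValueError(
            f"weight matrix shape {weights.shape} does not match region "
            f"({region.n_demand}, {region.n_facilities})"
        )
    weighted_demand = region.populations @ weights  # per-facility person-weights
    ratios = np.zeros(region.n_facilities)
    served = weighted_demand > 0
    ratios[served] = region.beds[served] / weighted_demand[served]
    for j in np.flatnonzero(~served):
        logger.warning(
            "facility %s has no positive demand in reach; supply-demand ratio set to 0",
            region.facility_ids[j],
        )
    scores = weights @ ratios
    return AccessibilityResult(
        model=model,
        params=params,
        scores=scores,
        ratios=ratios,
        demand_ids=tuple(region.demand_ids),
        facility_ids=tuple(region.facility_ids),
    )


def supply_demand_ratios(region: Region, d0: float) -> np.ndarray:
    """Step 1: per-facility supply-demand ratio R_j under catchment radius d0."""
    weights = indicator_kernel(region.distances, d0)
    weighted_demand = region.populations @ weights
    ratios = np.zeros(region.n_facilities)
    served = weighted_demand > 0
    ratios[served] = region.beds[served] / weighted_demand[served]
    for j in np.flatnonzero(~served):
        logger.warning(
            "facility %s has no positive demand within %g m; supply-demand ratio set to 0",
            region.facility_ids[j], d0,
        )
    return ratios


def accessibility_scores(region: Region, ratios: np.ndarray, d0: float) -> np.ndarray:
    """Step 2: per-demand-unit accessibility A_i = sum of reachable ratios."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (region.n_facilities,):
        raise ValueError(f"ratio vector length {ratios.shape} does not match {region.n_facilities} facilities")
    weights = indicator_kernel(region.distances, d0)
    return weights @ ratios


def two_step_fca(region: Region, d0: float) -> AccessibilityResult:
    """Full 2SFCA run at catchment radius d0 (meters)."""
    return weighted_two_step(
        region, indicator_kernel(region.distances, d0), model="2sfca", params={"d0": d0}
    )
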