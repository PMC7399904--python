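"""Potential (gravity) accessibility models with friction coefficient beta.

Two variants are provided:

``potential_plain``
    The classical potential of supply masses, A_i = sum_j M_j / D_ij^beta,
    with M_j the facility's bed count. No search radius: every facility
    contributes to every demand point, attenuated by distance.

``gravity_two_step``
    The two-search variant: the supply-demand ratio of each facility is
    computed against distance-attenuated demand, then summed per demand
    unit with the same attenuation —
    R_j = S_j / sum_k D_k w(d_kj),  A_i = sum_j R_j w(d_ij),
    with w(d) = max(d, min_distance)^(-beta). At beta = 0 this reduces
    exactly to 2SFCA with an infinite radius; it is the default reading of
    "the potential model" in reporting because the study procedure performs
    two searches and attenuates the supply-demand ratio.

Both kernels are strictly positive, so an exact zero score is impossible
whenever any facility has beds — published zero counts under this model can
only arise from display rounding, which is why reporting offers an optional
threshold instead of guessing a cutoff.
"""
from __future__ import annotations

import logging

import numpy as np

from .fca import AccessibilityResult, weighted_two_step
from .kernels import power_kernel
from .region import Region

__all__ = ["potential_plain", "gravity_two_step"]

logger = logging.getLogger(__name__)


def potential_plain(region: Region, beta: float = 1.0, min_distance: float = 1.0) -> AccessibilityResult:
    """Plain potential scores A_i = sum_j S_j * max(D_ij, min_distance)^(-beta)."""
    weights = power_kernel(region.distances, beta, min_distance)
    scores = weights @ region.beds
    return AccessibilityResult(
        model="potential",
        params={"beta": beta, "min_distance": min_distance},
        scores=scores,
        demand_ids=tuple(region.demand_ids),
        facility_ids=tuple(region.facility_ids),
    )


def gravity_two_step(region: Region, beta: float = 1.0, min_distance: float = 1.0) -> AccessibilityResult:
    """Two-search gravity run: distance-attenuated supply-demand ratios, then
    attenuated summation per demand unit."""
    if not region.populations.any():
        logger.warning("all demand populations are zero; all supply-demand ratios set to 0")
    weights = power_kernel(region.distances, beta, min_distance)
    return weighted_two_step(
        region, weights, model="gravity2s", params={"beta": beta, "min_distance": min_distance}
    )
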