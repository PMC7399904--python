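"""Distance-weight kernels shared by the catchment and gravity models.

Every model in the package is the same two-step computation with a different
weight function w(d): the hard-radius catchment model uses the indicator
kernel 1{d <= d0}; the gravity models use the power kernel d^(-beta). Writing
both through one abstraction makes the three study runs one code path and
gives an exact cross-model equivalence (indicator-kernel gravity == 2SFCA).
"""
from __future__ import annotations

import numpy as np

__all__ = ["indicator_kernel", "power_kernel"]


def indicator_kernel(distances: np.ndarray, d0: float) -> np.ndarray:
    """Hard catchment weight: 1 inside the radius (boundary inclusive), 0 outside."""
    if not d0 > 0:
        raise ValueError(f"search radius d0 must be > 0, got {d0}")
    return (np.asarray(distances, dtype=float) <= d0).astype(float)


def power_kernel(distances: np.ndarray, beta: float, min_distance: float = 1.0) -> np.ndarray:
    """Power-law decay weight w(d) = max(d, min_distance)^(-beta).

    ``min_distance`` (meters) floors the distance before exponentiation so a
    facility coincident with a demand point does not produce a division by
    zero; 1 m is far below any real community-to-facility distance.
    """
    if beta < 0:
        raise ValueError(f"friction coefficient beta must be >= 0, got {beta}")
    if not min_distance > 0:
        raise ValueError(f"min_distance must be > 0, got {min_distance}")
    d = np.maximum(np.asarray(distances, dtype=float), min_distance)
    return d ** (-beta)
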