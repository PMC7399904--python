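"""Score classification: equal-interval map levels and percentile bands.

Equal-interval levels reproduce choropleth legends ("divided into k levels
from the minimum to the maximum value"). Percentile bands reproduce the
cross-model ranking scheme: top 10% of units, 10-27%, 27-45%, and the
remaining 55%, with rank cutoffs taken as ceilings of the cumulative
fractions.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["equal_interval_levels", "percentile_bands", "DEFAULT_BREAKS"]

#: cumulative rank fractions separating bands 1|2, 2|3 and 3|4
DEFAULT_BREAKS: tuple[float, ...] = (0.10, 0.27, 0.45)


def equal_interval_levels(scores: Sequence[float], ids: Sequence[str], k: int = 6) -> pd.DataFrame:
    """Bin scores into k equal-width intervals between min and max.

    A unit with score s gets level floor((s - min) / width) + 1, capped at k
    so the maximum falls in the top level. If all scores are equal the range
    is degenerate and every unit gets level 1.

    Returns a DataFrame with columns ``id``, ``score``, ``level``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot classify an empty score vector")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if k < 1:
        raise ValueError(f"number of levels k must be >= 1, got {k}")
    if len(ids) != scores.size:
        raise ValueError("ids and scores must have equal length")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        levels = np.ones(scores.size, dtype=int)
    else:
        width = (hi - lo) / k
        levels = np.minimum(np.floor((scores - lo) / width).astype(int) + 1, k)
    return pd.DataFrame({"id": list(ids), "score": scores, "level": levels})


def percentile_bands(
    scores: Sequence[float],
    ids: Sequence[str],
    breaks: Sequence[float] = DEFAULT_BREAKS,
    model: str | None = None,
) -> pd.DataFrame:
    """Assign rank-percentile bands 1..len(breaks)+1 (1 = best accessibility).

    Units are ranked by descending score (ties broken by ascending id); the
    top ceil(breaks[0] * n) ranks get band 1, ranks up to ceil(breaks[1] * n)
    band 2, and so on, with the remainder in the bottom band. A score of
    exactly 0 always lands in the bottom band regardless of rank: "top x%"
    is meaningless for units with no accessibility at all, and zero scores
    drive the priority logic downstream.

    Returns a DataFrame with columns ``id``, ``score``, ``band`` (and
    ``model`` when given), in the input unit order.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("cannot band an empty score vector")
    if len(ids) != n:
        raise ValueError("ids and scores must have equal length")
    breaks = tuple(float(b) for b in breaks)
    if not breaks or any(not 0 < b < 1 for b in breaks) or any(
        b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])
    ):
        raise ValueError(f"breaks must be strictly increasing within (0, 1), got {breaks}")

    order = sorted(range(n), key=lambda i: (-scores[i], str(ids[i])))
    cutoffs = [math.ceil(b * n) for b in breaks]
    n_bands = len(breaks) + 1
    bands = np.empty(n, dtype=int)
    for rank, i in enumerate(order, start=1):
        band = n_bands
        for b, cut in enumerate(cutoffs, start=1):
            if rank <= cut:
                band = b
                break
        bands[i] = band
    bands[scores == 0.0] = n_bands

    out = pd.DataFrame({"id": list(ids), "score": scores, "band": bands})
    if model is not None:
        out.insert(1, "model", model)
    return out
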