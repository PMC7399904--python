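"""Run-level summary statistics: means, zero counts, demand-meeting counts.

The demand threshold defaults to 0.035 beds per person — the policy
benchmark of 35 beds per 1000 elderly residents — and flags communities
whose accessibility score would meet planned provision. Percentages are
reported both raw and rounded to the nearest integer percent (half away
from zero), matching how such figures are printed in planning reports.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np

__all__ = ["RunSummary", "summarize_run", "round_percent", "DEMAND_THRESHOLD"]

#: beds per person equivalent of 35 beds per 1000 elderly
DEMAND_THRESHOLD = 0.035


def round_percent(fraction: float) -> int:
    """Round a fraction to the nearest integer percent, half away from zero."""
    return int(math.floor(abs(fraction) * 100 + 0.5)) * (1 if fraction >= 0 else -1)


@dataclass(frozen=True)
class RunSummary:
    """Summary of one accessibility run over n demand units.

    ``worst_to_best_pct`` is 100 * (minimum positive score) / (maximum
    score); it is None when no unit has a positive score. ``mean_weighted``
    is the population-weighted mean, provided alongside the plain unweighted
    mean for completeness.
    """

    model: str
    params: dict[str, Any]
    n: int
    mean_score: float
    mean_weighted: float | None
    threshold: float
    n_zero: int
    pct_zero: float
    pct_zero_rounded: int
    n_meeting: int
    pct_meeting: float
    pct_meeting_rounded: int
    best_unit: str
    best_score: float
    worst_nonzero_unit: str | None
    worst_nonzero_score: float | None
    worst_to_best_pct: float | None
    worst_to_best_pct_rounded: int | None = field(default=None)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def text(self) -> str:
        lines = [
            f"model: {self.model}  params: {self.params}",
            f"units: {self.n}",
            f"mean accessibility: {self.mean_score:.4g} beds/person"
            + (f" (population-weighted {self.mean_weighted:.4g})" if self.mean_weighted is not None else ""),
            f"zero accessibility: {self.n_zero} units ({self.pct_zero_rounded}%)",
            f"meeting threshold {self.threshold:g}: {self.n_meeting} units ({self.pct_meeting_rounded}%)",
            f"best: {self.best_unit} = {self.best_score:.5g}",
        ]
        if self.worst_nonzero_unit is not None:
            lines.append(
                f"worst non-zero: {self.worst_nonzero_unit} = {self.worst_nonzero_score:.5g}"
                f" ({self.worst_to_best_pct_rounded}% of best)"
            )
        else:
            lines.append("worst non-zero: (no unit with positive accessibility)")
        return "\n".join(lines)


def summarize_run(
    scores: Sequence[float],
    ids: Sequence[str],
    populations: Sequence[float] | None = None,
    threshold: float = DEMAND_THRESHOLD,
    model: str = "",
    params: dict[str, Any] | None = None,
) -> RunSummary:
    """Summarize one run's per-unit scores.

    The mean is unweighted over demand units, zeros included. ``n_meeting``
    counts scores >= threshold (boundary inclusive: provision exactly at the
    benchmark meets it). Best/worst tie-breaks go to the lexicographically
    first id for determinism.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("cannot summarize an empty score vector")
    if not np.isfinite(scores).all() or (scores < 0).any():
        raise ValueError("scores must be finite and non-negative")
    if len(ids) != n:
        raise ValueError("ids and scores must have equal length")

    order = sorted(range(n), key=lambda i: (-scores[i], str(ids[i])))
    best_i = order[0]
    positive = scores > 0
    n_zero = int(n - positive.sum())
    n_meeting = int((scores >= threshold).sum())

    mean_weighted = None
    if populations is not None:
        pops = np.asarray(populations, dtype=float)
        if pops.shape != scores.shape:
            raise ValueError("populations must align with scores")
        if pops.sum() > 0:
            mean_weighted = float((scores * pops).sum() / pops.sum())

    worst_unit = worst_score = wtb = wtb_r = None
    if positive.any() and scores[best_i] > 0:
        pos_order = sorted(np.flatnonzero(positive), key=lambda i: (scores[i], str(ids[i])))
        worst_i = pos_order[0]
        worst_unit, worst_score = str(ids[worst_i]), float(scores[worst_i])
        wtb = 100.0 * worst_score / float(scores[best_i])
        wtb_r = round_percent(wtb / 100.0)

    return RunSummary(
        model=model,
        params=dict(params or {}),
        n=n,
        mean_score=float(scores.mean()),
        mean_weighted=mean_weighted,
        threshold=threshold,
        n_zero=n_zero,
        pct_zero=100.0 * n_zero / n,
        pct_zero_rounded=round_percent(n_zero / n),
        n_meeting=n_meeting,
        pct_meeting=100.0 * n_meeting / n,
        pct_meeting_rounded=round_percent(n_meeting / n),
        best_unit=str(ids[best_i]),
        best_score=float(scores[best_i]),
        worst_nonzero_unit=worst_unit,
        worst_nonzero_score=worst_score,
        worst_to_best_pct=wtb,
        worst_to_best_pct_rounded=wtb_r,
    )
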