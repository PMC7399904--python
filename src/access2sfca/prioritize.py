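"""Facility-planning prioritization from multiple accessibility runs.

The study design combines three model runs (catchment model at 500 m and
600 m, plus the gravity model) into one planning recommendation per
community:

* a community whose accessibility reached the top decile band in *any* run
  needs no new facilities (``not_considered``);
* a community with exactly zero accessibility in *all* runs is the top
  priority (``highest``) — unless the analyst excludes it (e.g. campus or
  park communities with few elderly residents);
* otherwise the combined (best-achieved) band maps to a priority class,
  worse accessibility meaning higher priority.

The band-to-class mapping is overridable; the default follows the narrative
rule above. The exclusion list is always an explicit analyst input, never
inferred from the data.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["combine_runs", "priority_classes", "DEFAULT_CLASS_MAP", "PRIORITY_CLASSES"]

PRIORITY_CLASSES = ("highest", "high", "low", "very_low", "not_considered")

#: combined band -> priority class (band 1 = top decile in some run)
DEFAULT_CLASS_MAP: dict[int, str] = {1: "not_considered", 2: "very_low", 3: "low", 4: "high"}


def combine_runs(run_bands: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Most favorable (minimum) band per unit across >= 1 model runs.

    Each input frame needs columns ``id`` and ``band`` (as produced by
    :func:`access2sfca.classify.percentile_bands`). All runs must cover the
    same set of unit ids. Returns ``id``, ``combined_band`` in the order of
    the first run.
    """
    if not run_bands:
        raise ValueError("need at least one model run")
    base_ids = list(run_bands[0]["id"])
    base_set = set(base_ids)
    combined = pd.Series(run_bands[0]["band"].to_numpy(), index=base_ids, dtype=int)
    for run in run_bands[1:]:
        ids = set(run["id"])
        if ids != base_set:
            missing = sorted(base_set ^ ids)
            raise ValueError(f"model runs cover different unit ids; mismatched: {missing}")
        other = pd.Series(run["band"].to_numpy(), index=list(run["id"]), dtype=int)
        combined = np.minimum(combined, other.reindex(base_ids))
    return pd.DataFrame({"id": base_ids, "combined_band": combined.to_numpy(dtype=int)})


def priority_classes(
    run_bands: Sequence[pd.DataFrame],
    run_scores: Sequence[pd.DataFrame],
    exclusions: Sequence[str] = (),
    class_map: Mapping[int, str] = DEFAULT_CLASS_MAP,
) -> pd.DataFrame:
    """Per-unit priority summary across model runs.

    Parameters
    ----------
    run_bands : band frames (``id``, ``band``), one per run
    run_scores : score frames (``id``, ``score``), one per run, same ids
    exclusions : unit ids excluded by analyst judgment
    class_map : combined band -> class for the non-zero, non-excluded units

    Returns a DataFrame with one row per unit: per-run bands, combined band,
    ``zero_in_all``, ``excluded`` and ``priority_class``.
    """
    if len(run_bands) != len(run_scores):
        raise ValueError("run_bands and run_scores must pair up one-to-one")
    combined = combine_runs(run_bands)
    ids = list(combined["id"])

    zero_in_all = pd.Series(True, index=ids)
    for run in run_scores:
        if set(run["id"]) != set(ids):
            raise ValueError("score runs cover different unit ids than band runs")
        s = pd.Series(run["score"].to_numpy(dtype=float), index=list(run["id"]))
        zero_in_all &= s.reindex(ids) == 0.0

    unknown = sorted(set(exclusions) - set(ids))
    if unknown:
        raise ValueError(f"exclusion list names unknown unit id(s): {unknown}")
    excluded = pd.Series([i in set(exclusions) for i in ids], index=ids)

    classes = []
    for uid, band in zip(ids, combined["combined_band"]):
        if excluded[uid]:
            classes.append("not_considered")
        elif zero_in_all[uid]:
            classes.append("highest")
        else:
            classes.append(class_map[int(band)])

    out = combined.copy()
    for r, run in enumerate(run_bands, start=1):
        b = pd.Series(run["band"].to_numpy(dtype=int), index=list(run["id"]))
        label = str(run["model"].iloc[0]) if "model" in run.columns else f"run{r}"
        col = f"band_{label}"
        while col in out.columns:  # two runs of the same model, e.g. different radii
            col += f"_{r}"
        out[col] = b.reindex(ids).to_numpy(dtype=int)
    out["zero_in_all"] = zero_in_all.to_numpy()
    out["excluded"] = excluded.to_numpy()
    out["priority_class"] = classes
    return out
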