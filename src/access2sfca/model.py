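"""Model/Results facade over the accessibility computations.

``AccessibilityModel`` is constructed from a :class:`~access2sfca.region.Region`
plus model choice and parameters; ``fit()`` runs the computation and returns
an ``AccessibilityResults`` object carrying the per-facility ratios, the
per-unit scores, classification helpers and a summary table::

    region = synthetic.generate_region(seed=42)
    res = AccessibilityModel(region, model="2sfca", d0=600).fit()
    print(res.summary())
    res.to_frame()          # id, population, score, ...
    res.levels(k=6)         # equal-interval map levels
    res.bands()             # percentile bands for prioritization
"""
from __future__ import annotations

from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import classify, fca, potential, report
from .region import Region

__all__ = ["AccessibilityModel", "AccessibilityResults"]

_MODELS = ("2sfca", "potential", "gravity2s")


class AccessibilityModel:
    """Spatial-accessibility model bound to a region.

    Parameters
    ----------
    region : Region
        Demand and supply layers with the cached distance matrix.
    model : {"2sfca", "potential", "gravity2s"}
        ``"2sfca"`` is the hard-radius catchment model (needs ``d0``);
        ``"potential"`` the gravity family (needs ``beta``), with
        ``variant="two_step"`` (attenuated supply-demand ratios, the
        default) or ``variant="plain"`` (raw potential of bed masses);
        ``"gravity2s"`` is shorthand for the two-step variant.
    d0 : float
        Catchment radius in meters (2SFCA only). Defaults to 600, the
        walking range observed for elderly pedestrians; 500 is the other
        conventional radius.
    beta : float
        Friction coefficient of the power decay kernel (gravity family).
    min_distance : float
        Floor in meters applied to distances before exponentiation.
    """

    def __init__(
        self,
        region: Region,
        model: str = "2sfca",
        d0: float = 600.0,
        beta: float = 1.0,
        min_distance: float = 1.0,
        variant: str = "two_step",
    ) -> None:
        if model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
        if variant not in ("plain", "two_step"):
            raise ValueError(f"variant must be 'plain' or 'two_step', got {variant!r}")
        if model == "2sfca" and not d0 > 0:
            raise ValueError(f"2sfca requires a positive search radius d0, got {d0}")
        if model != "2sfca" and beta < 0:
            raise ValueError(f"gravity models require beta >= 0, got {beta}")
        self.region = region
        self.model = model
        self.d0 = float(d0)
        self.beta = float(beta)
        self.min_distance = float(min_distance)
        self.variant = "two_step" if model == "gravity2s" else variant

    @classmethod
    def from_dataframes(
        cls,
        demand: pd.DataFrame,
        supply: pd.DataFrame,
        crs: str | None = None,
        **kwargs: Any,
    ) -> "AccessibilityModel":
        """Build from attribute tables ``id,x,y,population`` and ``id,x,y,beds``."""
        from shapely.geometry import Point

        from .region import DemandUnit, Facility

        units = [
            DemandUnit(id=str(r.id), geometry=Point(float(r.x), float(r.y)), population=int(r.population))
            for r in demand.itertuples(index=False)
        ]
        facilities = [
            Facility(id=str(r.id), location=Point(float(r.x), float(r.y)), beds=int(r.beds))
            for r in supply.itertuples(index=False)
        ]
        return cls(Region(demand_units=units, facilities=facilities, crs=crs), **kwargs)

    def fit(self) -> "AccessibilityResults":
        """Run the model and return the results object."""
        if self.model == "2sfca":
            raw = fca.two_step_fca(self.region, self.d0)
        elif self.model == "gravity2s" or self.variant == "two_step":
            raw = potential.gravity_two_step(self.region, self.beta, self.min_distance)
        else:
            raw = potential.potential_plain(self.region, self.beta, self.min_distance)
        return AccessibilityResults(self, raw)


class AccessibilityResults:
    """Fitted accessibility scores with classification and summary helpers."""

    def __init__(self, model: AccessibilityModel, raw: fca.AccessibilityResult) -> None:
        self.model = model
        self.raw = raw
        self.scores: np.ndarray = raw.scores
        self.ratios: np.ndarray = raw.ratios
        self.params: dict[str, Any] = dict(raw.params)

    @property
    def region(self) -> Region:
        return self.model.region

    @property
    def model_label(self) -> str:
        return self.raw.model

    def to_frame(self) -> pd.DataFrame:
        """Per-unit table: ``id, population, score, model`` plus parameters."""
        df = pd.DataFrame({
            "id": self.region.demand_ids,
            "population": self.region.populations.astype(int),
            "score": self.scores,
            "model": self.raw.model,
        })
        for key, val in self.params.items():
            df[key] = val
        return df

    def ratios_frame(self) -> pd.DataFrame:
        """Per-facility supply-demand ratios (empty for the plain potential)."""
        if self.ratios.size == 0:
            return pd.DataFrame(columns=["id", "beds", "ratio"])
        return pd.DataFrame({
            "id": self.region.facility_ids,
            "beds": self.region.beds.astype(int),
            "ratio": self.ratios,
        })

    def levels(self, k: int = 6) -> pd.DataFrame:
        """Equal-interval choropleth levels 1..k over the score range."""
        return classify.equal_interval_levels(self.scores, self.region.demand_ids, k)

    def bands(self, breaks: Sequence[float] = classify.DEFAULT_BREAKS) -> pd.DataFrame:
        """Percentile bands (1 = top decile) for cross-run prioritization."""
        return classify.percentile_bands(self.scores, self.region.demand_ids, breaks, model=self.raw.model)

    def summarize(self, threshold: float = report.DEMAND_THRESHOLD) -> report.RunSummary:
        """Structured run summary (means, zero counts, best/worst units)."""
        return report.summarize_run(
            self.scores,
            self.region.demand_ids,
            populations=self.region.populations,
            threshold=threshold,
            model=self.raw.model,
            params=self.params,
        )

    def summary(self, threshold: float = report.DEMAND_THRESHOLD) -> str:
        """Human-readable summary table."""
        return self.summarize(threshold).text()

    def plot(self, k: int = 6, ax=None):
        """Scatter the demand points colored by equal-interval level; facilities as triangles."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        lv = self.levels(k)
        pts = self.region.demand_points
        sc = ax.scatter(pts[:, 0], pts[:, 1], c=lv["level"], cmap="viridis", vmin=1, vmax=k, s=40)
        fp = self.region.facility_points
        ax.scatter(fp[:, 0], fp[:, 1], marker="^", c="red", s=30, label="facilities")
        ax.set_aspect("equal")
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        ax.set_title(self.raw.label)
        ax.legend(loc="upper right")
        plt.colorbar(sc, ax=ax, label=f"accessibility level (1..{k})")
        return ax
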