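"""Economic benefit estimation for cessation interventions.

Two outputs per development and intervention:

* **Return on investment** — averted annual smoking-related medical costs
  (societal perspective) relative to the annual cost of delivering the
  intervention:

      ROI = (cost without intervention − cost with intervention)
            / cost of intervention

  where the post-intervention smoker count is the expected value
  ``before × (1 − participation × effectiveness)``. ROI > 1 means the
  averted medical costs exceed what the intervention costs.

* **Cross-sector savings** — annual housing-system costs avoided in
  addition to the medical ROI: fewer smoking-related evictions and fires
  (proportional to the drop in smokers) and cheaper unit turnover as the
  share of smoking units shifts down.

All default parameter values are illustrative placeholders, not published
estimates; every figure is a config input. The horizon is a single
point-in-time year with no discounting, relapse, or phase-in dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError


@dataclass
class InterventionSpec:
    """One cessation intervention offered to a development's smokers."""

    name: str
    cost_per_participant: float  # USD per participant per year
    effectiveness: float  # fraction of participating smokers who quit
    participation: float = 1.0  # fraction of smokers reached

    def validate(self) -> None:
        if self.cost_per_participant < 0:
            raise ValidationError(f"{self.name}: cost_per_participant must be >= 0")
        for fname in ("effectiveness", "participation"):
            v = getattr(self, fname)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{self.name}: {fname} must lie in [0, 1]")


@dataclass
class CostModel:
    """Annual cost parameters (USD) for the ROI and cross-sector estimates."""

    medical_cost_per_smoker: float = 2000.0  # societal perspective, USD/year
    eviction_cost: float = 1000.0  # USD per eviction event
    eviction_rate_per_smoker: float = 0.01  # events per smoker per year
    turnover_cost_smoking_unit: float = 3000.0  # USD per turnover
    turnover_cost_nonsmoking_unit: float = 1000.0  # USD per turnover
    turnover_rate: float = 0.10  # turnovers per unit per year
    fire_cost: float = 10000.0  # USD per smoking-related fire
    fire_rate_per_smoker: float = 0.001  # events per smoker per year

    def validate(self) -> None:
        for fname, v in self.__dict__.items():
            if v < 0:
                raise ValidationError(f"cost model field {fname} must be >= 0")


@dataclass
class ROIResult:
    """One ROI computation; the identity
    roi = (cost_no_intervention − cost_with_intervention) / intervention_cost
    holds exactly by construction and is recomputable from the fields."""

    smokers_before: float
    smokers_after: float
    cost_no_intervention: float
    cost_with_intervention: float
    intervention_cost: float
    roi: float

    @property
    def exceeds_breakeven(self) -> bool:
        """True when averted costs are greater than the intervention's cost."""
        return self.roi > 1.0


def smokers_after_intervention(before: float, spec: InterventionSpec) -> float:
    """Expected smokers remaining: before × (1 − participation × effectiveness)."""
    if before < 0:
        raise ValidationError("smoker count before intervention must be >= 0")
    spec.validate()
    return before * (1.0 - spec.participation * spec.effectiveness)


def compute_roi(
    before: float, spec: InterventionSpec, costs: CostModel
) -> ROIResult:
    """ROI of a cessation intervention from averted medical costs."""
    costs.validate()
    after = smokers_after_intervention(before, spec)
    cost_no = before * costs.medical_cost_per_smoker
    cost_with = after * costs.medical_cost_per_smoker
    intervention_cost = before * spec.participation * spec.cost_per_participant
    if intervention_cost == 0.0:
        if before * spec.participation > 0:
            raise ValidationError(
                "intervention cost is zero with nonzero uptake; ROI undefined"
            )
        roi = 0.0
    else:
        roi = (cost_no - cost_with) / intervention_cost
    return ROIResult(
        smokers_before=before,
        smokers_after=after,
        cost_no_intervention=cost_no,
        cost_with_intervention=cost_with,
        intervention_cost=intervention_cost,
        roi=roi,
    )


def cross_sector_savings(
    before: float,
    after: float,
    n_units: int,
    costs: CostModel,
    n_residents: int | None = None,
) -> float:
    """Annual housing-sector savings from the drop in smokers.

    savings = (before − after) × (eviction_rate × eviction_cost
                                  + fire_rate × fire_cost)
              + turnover_rate × n_units × share_shift
                × (turnover_cost_smoking − turnover_cost_nonsmoking)

    where share_shift = (before − after) / n_residents is the drop in the
    smoking share applied proportionally to units (n_residents defaults to
    n_units, i.e. one tracked resident per unit).
    """
    if after > before:
        raise ValidationError("after-intervention smokers exceed before count")
    costs.validate()
    if n_residents is None:
        n_residents = n_units
    drop = before - after
    event_savings = drop * (
        costs.eviction_rate_per_smoker * costs.eviction_cost
        + costs.fire_rate_per_smoker * costs.fire_cost
    )
    if n_residents > 0 and n_units > 0:
        share_shift = drop / n_residents
        turnover_savings = (
            costs.turnover_rate
            * n_units
            * share_shift
            * (costs.turnover_cost_smoking_unit - costs.turnover_cost_nonsmoking_unit)
        )
    else:
        turnover_savings = 0.0
    return event_savings + turnover_savings


def roi_table(
    estimates,
    interventions: list[InterventionSpec],
    costs: CostModel,
    *,
    units_per_phd: dict[str, int] | None = None,
) -> pd.DataFrame:
    """ROI and cross-sector savings per (phd_id, intervention).

    ``estimates`` is a list of SmokerEstimate; the before-count is each
    development's bootstrap-mean smoker estimate. Units per PHD default to
    the resident count (one tracked resident per unit).
    """
    rows = []
    for est in estimates:
        n_units = (
            units_per_phd.get(est.phd_id, est.n_residents)
            if units_per_phd
            else est.n_residents
        )
        for spec in interventions:
            r = compute_roi(est.estimated_smokers_mean, spec, costs)
            savings = cross_sector_savings(
                r.smokers_before, r.smokers_after, n_units, costs, est.n_residents
            )
            rows.append(
                {
                    "phd_id": est.phd_id,
                    "intervention": spec.name,
                    "smokers_before": r.smokers_before,
                    "smokers_after": r.smokers_after,
                    "cost_no_intervention": r.cost_no_intervention,
                    "cost_with_intervention": r.cost_with_intervention,
                    "intervention_cost": r.intervention_cost,
                    "roi": r.roi,
                    "exceeds_breakeven": r.exceeds_breakeven,
                    "cross_sector_savings": savings,
                }
            )
    cols = [
        "phd_id",
        "intervention",
        "smokers_before",
        "smokers_after",
        "cost_no_intervention",
        "cost_with_intervention",
        "intervention_cost",
        "roi",
        "exceeds_breakeven",
        "cross_sector_savings",
    ]
    return pd.DataFrame(rows, columns=cols)


def default_economic_config() -> tuple[CostModel, list[InterventionSpec]]:
    """Illustrative (non-authoritative) cost model and intervention menu."""
    interventions = [
        InterventionSpec("brief counseling", 50.0, 0.05, 0.50),
        InterventionSpec("counseling plus NRT", 300.0, 0.20, 0.50),
    ]
    return CostModel(), interventions


def write_economic_config(
    path, costs: CostModel, interventions: list[InterventionSpec]
) -> None:
    doc = {
        "cost_model": {k: float(v) for k, v in costs.__dict__.items()},
        "interventions": [
            {
                "name": i.name,
                "cost_per_participant": float(i.cost_per_participant),
                "effectiveness": float(i.effectiveness),
                "participation": float(i.participation),
            }
            for i in interventions
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_economic_config(path) -> tuple[CostModel, list[InterventionSpec]]:
    doc = yaml.safe_load(Path(path).read_text())
    costs = CostModel(**doc["cost_model"])
    costs.validate()
    interventions = [InterventionSpec(**i) for i in doc["interventions"]]
    for i in interventions:
        i.validate()
    return costs, interventions
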