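"""Ground-survey vs UAV-survey cost calculator.

Per-hectare survey and data-elaboration times are converted to hours,
rounded half-up to 0.1 h, and multiplied by mode-specific man-hour
rates; the UAV mode additionally carries the annualized equipment cost
(platform + camera purchase spread over a straight-line depreciation
cycle, one survey per year).

Default rates and timings:

    ground:  25 min/ha survey at $16/h;   2 min/ha digitization at $16/h
    uav:     1 min fixed + 2 min/ha flight at $24/h;
             10 min/ha image selection + recognition at $20/h;
             $620 equipment over 3 years.

Times are rounded *before* costing, which is what the published
per-category figures follow for every UAV entry and for ground survey
costs; ground elaboration at these tiny times (0.2-1.7 h) is the one
place where rounding first visibly inflates the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "CostScenario",
    "CostBreakdown",
    "ground_scenario",
    "uav_scenario",
    "survey_time_h",
    "elaboration_time_h",
    "cost_breakdown",
    "compare_modes",
    "cost_table",
]


def round_half_up(value: float, step: float = 0.1) -> float:
    """Round to the nearest multiple of ``step``, halves away from zero."""
    q = Decimal(str(step))
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CostScenario:
    area_ha: float
    mode: str  # "ground" | "uav"
    survey_rate: float  # $/h
    elaboration_rate: float  # $/h
    ground_survey_min_per_ha: float = 25.0
    uav_fixed_min: float = 1.0
    uav_min_per_ha: float = 2.0
    ground_elab_min_per_ha: float = 2.0
    uav_elab_min_per_ha: float = 10.0
    equipment_cost: float = 620.0
    depreciation_years: float = 3.0

    def __post_init__(self):
        if self.area_ha <= 0:
            raise ValueError("area must be positive")
        if self.mode not in ("ground", "uav"):
            raise ValueError(f"mode must be 'ground' or 'uav', got {self.mode!r}")


def ground_scenario(area_ha: float, **overrides) -> CostScenario:
    return CostScenario(
        area_ha=area_ha, mode="ground", survey_rate=16.0, elaboration_rate=16.0,
        **overrides,
    )


def uav_scenario(area_ha: float, **overrides) -> CostScenario:
    return CostScenario(
        area_ha=area_ha, mode="uav", survey_rate=24.0, elaboration_rate=20.0,
        **overrides,
    )


@dataclass(frozen=True)
class CostBreakdown:
    survey_time_h: float
    survey_cost: float
    elaboration_time_h: float
    elaboration_cost: float
    total_time_h: float
    equipment_cost_annual: float
    total_cost: float
    total_cost_excl_equipment: float


def survey_time_h(s: CostScenario) -> float:
    """Field time in hours, rounded half-up to 0.1 h."""
    if s.mode == "ground":
        minutes = s.ground_survey_min_per_ha * s.area_ha
    else:
        minutes = s.uav_fixed_min + s.uav_min_per_ha * s.area_ha
    return round_half_up(minutes / 60.0)


def elaboration_time_h(s: CostScenario) -> float:
    """Data-processing time in hours, rounded half-up to 0.1 h."""
    per_ha = s.ground_elab_min_per_ha if s.mode == "ground" else s.uav_elab_min_per_ha
    return round_half_up(per_ha * s.area_ha / 60.0)


def cost_breakdown(s: CostScenario) -> CostBreakdown:
    st = survey_time_h(s)
    et = elaboration_time_h(s)
    survey_cost = round_half_up(st * s.survey_rate)
    elab_cost = round_half_up(et * s.elaboration_rate)
    if s.mode == "uav":
        equipment = round_half_up(s.equipment_cost / s.depreciation_years)
    else:
        equipment = 0.0
    total = round_half_up(survey_cost + elab_cost + equipment)
    return CostBreakdown(
        survey_time_h=st,
        survey_cost=survey_cost,
        elaboration_time_h=et,
        elaboration_cost=elab_cost,
        total_time_h=round_half_up(st + et),
        equipment_cost_annual=equipment,
        total_cost=total,
        total_cost_excl_equipment=round_half_up(total - equipment),
    )


def compare_modes(area_ha: float, **overrides) -> dict:
    """Side-by-side ground vs UAV breakdown with absolute and relative
    savings, with and without the equipment purchase."""
    g = cost_breakdown(ground_scenario(area_ha, **overrides))
    u = cost_breakdown(uav_scenario(area_ha, **overrides))
    savings_excl = g.total_cost - u.total_cost_excl_equipment
    savings_incl = g.total_cost - u.total_cost
    return {
        "area_ha": area_ha,
        "ground": g,
        "uav": u,
        "savings_excl_equipment": savings_excl,
        "savings_excl_equipment_pct": savings_excl / g.total_cost * 100.0,
        "savings_incl_equipment": savings_incl,
        "savings_incl_equipment_pct": savings_incl / g.total_cost * 100.0,
        "time_saved_h": round_half_up(g.total_time_h - u.total_time_h),
    }


def cost_table(areas=(5.0, 10.0, 50.0)) -> pd.DataFrame:
    """Cost breakdown table over the standard vineyard sizes."""
    rows = []
    for mode, factory in (("ground", ground_scenario), ("uav", uav_scenario)):
        for area in areas:
            b = cost_breakdown(factory(area))
            rows.append(
                {
                    "mode": mode,
                    "area_ha": area,
                    "survey_time_h": b.survey_time_h,
                    "survey_cost": b.survey_cost,
                    "elaboration_time_h": b.elaboration_time_h,
                    "elaboration_cost": b.elaboration_cost,
                    "total_time_h": b.total_time_h,
                    "equipment_cost_annual": b.equipment_cost_annual,
                    "total_cost": b.total_cost,
                    "total_cost_excl_equipment": b.total_cost_excl_equipment,
                }
            )
    return pd.DataFrame(rows)
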