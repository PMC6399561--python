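"""Discounting, costs, and quality-adjusted life-year accounting.

Costs have two sources: colonoscopies (procedure plus expected
adverse-event cost, weighted by the probability that a colonoscopy happens)
and CRC treatment, which follows a phase structure by time since diagnosis:
an initial cost in the first year, surveillance costs in years 2-5, and a
terminal cost in the year of a CRC death (added to that year's phase cost).

QALYs are the utility-weighted occupancy of the health states: alive
without a cancer diagnosis scores the healthy utility (undetected neoplasia
is asymptomatic), a diagnosed cancer scores the utility of its stage at
diagnosis, death scores zero.

Both streams are accounted annually — monthly state masses are averaged
within each year of age — and discounted continuously at rate ``r``
anchored at the screening age: the net multiplier at ``t`` is
``exp(-r (t - tau))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CostValues, DiscountSpec, UtilityTable

__all__ = [
    "discount_multiplier",
    "colonoscopy_cost",
    "crc_phase_costs",
    "qaly_step",
    "YearRecord",
    "lifetime_totals",
]

_STAGES = ("local", "regional", "distant")


def discount_multiplier(t: float, spec: DiscountSpec) -> float:
    """Net discount multiplier ``exp(-r (t - anchor))`` at age ``t``.

    Equals 1 at the anchor age and for all ages when the rate is zero.
    Ages before the anchor are a domain error: pre-screening flows are
    identical between compared scenarios and are never discounted.
    """
    if t < spec.anchor_age:
        raise ValueError(f"age {t} precedes the discounting anchor {spec.anchor_age}")
    return float(np.exp(-spec.rate * (t - spec.anchor_age)))


def colonoscopy_cost(p_colonoscopy: float, costs: CostValues) -> float:
    """Expected colonoscopy cost: probability times (procedure + adverse events)."""
    if not 0.0 <= p_colonoscopy <= 1.0 + 1e-12:
        raise ValueError(f"colonoscopy probability {p_colonoscopy} outside [0, 1]")
    return p_colonoscopy * costs.per_colonoscopy


def crc_phase_costs(
    diagnosed_year_mass: np.ndarray,
    crc_deaths_by_stage: np.ndarray,
    costs: CostValues,
) -> float:
    """CRC treatment cost for one year of age.

    ``diagnosed_year_mass`` is the (3 stages, years-since-diagnosis) average
    occupancy during the year; year 0 accrues the stage's initial cost,
    years 1-4 (i.e. years 2-5 after diagnosis) the surveillance cost, and
    nothing thereafter.  ``crc_deaths_by_stage`` is the CRC death mass
    during the year, which accrues the terminal cost on top of the phase
    cost.
    """
    total = 0.0
    for row, stage in enumerate(_STAGES):
        total += costs.initial[stage] * diagnosed_year_mass[row, 0]
        total += costs.surveillance[stage] * diagnosed_year_mass[row, 1:5].sum()
    total += costs.terminal * float(np.asarray(crc_deaths_by_stage).sum())
    return total


def qaly_step(
    healthy_mass: float,
    diagnosed_mass_by_stage: np.ndarray,
    utilities: UtilityTable,
) -> float:
    """Utility-weighted QALY accrual for one year of average occupancy."""
    u = np.array([utilities.local, utilities.regional, utilities.distant])
    return utilities.healthy * healthy_mass + float(u @ np.asarray(diagnosed_mass_by_stage))


@dataclass(frozen=True)
class YearRecord:
    """Undiscounted annual accrual for one year of age."""

    age: float  # age at the start of the year
    p_colonoscopy: float  # expected number of colonoscopies during the year
    cost_colonoscopy: float
    cost_crc: float
    qalys: float


def lifetime_totals(
    trajectory: list[YearRecord],
    spec: DiscountSpec,
    horizon_age: float = 100.0,
) -> tuple[float, float, pd.DataFrame]:
    """Discount and accumulate an annual trajectory from the anchor age.

    Returns (total discounted cost, total discounted QALYs, per-year
    ledger).  Each year is discounted by the multiplier at its starting
    age.  The trajectory must reach the horizon.
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    last = trajectory[-1]
    if last.age + 1.0 < horizon_age - 1e-9:
        raise ValueError(
            f"trajectory ends at age {last.age + 1.0}, short of the horizon {horizon_age}"
        )
    rows = []
    total_cost = 0.0
    total_qalys = 0.0
    for rec in trajectory:
        f = discount_multiplier(rec.age, spec)
        d_cost = f * (rec.cost_colonoscopy + rec.cost_crc)
        d_qaly = f * rec.qalys
        total_cost += d_cost
        total_qalys += d_qaly
        rows.append(
            {
                "age": rec.age,
                "p_colonoscopy": rec.p_colonoscopy,
                "cost_colonoscopy": rec.cost_colonoscopy,
                "cost_crc": rec.cost_crc,
                "qalys": rec.qalys,
                "discount": f,
                "discounted_cost": d_cost,
                "discounted_qalys": d_qaly,
            }
        )
    return total_cost, total_qalys, pd.DataFrame(rows)
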