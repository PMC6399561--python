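"""Scenario orchestration and cost-effectiveness analysis.

A scenario is a screening colonoscopy at age tau, an optional set of
follow-up (surveillance) colonoscopies, and an optional conditioning on the
screening finding category.  The cohort is propagated from birth, survivors
are conditioned to be screen-eligible at tau, the screening colonoscopy is
applied, and costs and QALYs are accumulated to age 100 with continuous
discounting anchored at tau.  The control arm receives the screening
colonoscopy only; symptom-triggered diagnosis operates in both arms.

The incremental cost-effectiveness ratio (ICER) of a follow-up schedule is
Delta cost / Delta QALY against the screening-only control.  For a given
willingness-to-pay threshold, the cost-effective window is the maximal
contiguous run of grid intervals with ICER at or below the threshold, with
endpoints refined by linear interpolation of the ICER curve; the
recommended interval is the vertex of the parabola through the maximum
in-window Delta-QALY grid point and its two neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import economics, observation
from .economics import YearRecord
from .mortality import LifeTableModel, default_life_table_model
from .natural_history import (
    CohortDistribution,
    KernelOperator,
    MortalityInputs,
    adenoma_appearance_probability,
    arrival_shift,
    enumerate_states,
    lesion_kernel,
    propagate,
    yearly_to_monthly,
)
from .observation import FindingCategory
from .params import CostValues, DiscountSpec, ModelConfig

__all__ = [
    "Scenario",
    "ScenarioResult",
    "Pipeline",
    "run_scenario",
    "ICERResult",
    "icer",
    "interval_grid",
    "Window",
    "cost_effective_window",
    "OptimalInterval",
    "optimal_interval",
    "CEAOutcome",
    "recommend",
    "optimize_schedule",
    "sensitivity_analysis",
]

GRID_INTERVALS = tuple(range(2, 21, 2))
SCREEN_AGES = (50, 55, 60, 65, 70, 75)
THRESHOLDS = (50_000.0, 75_000.0, 100_000.0)


@dataclass(frozen=True)
class Scenario:
    """One screening + follow-up protocol to evaluate."""

    screen_age: float = 50.0
    follow_up_ages: tuple[float, ...] = ()
    finding: FindingCategory | None = None  # None = all findings combined
    discount_rate: float | None = None  # None = config default
    colonoscopy_cost: str = "base"  # base | low | high
    cancer_cost: str = "base"

    def __post_init__(self) -> None:
        for a in self.follow_up_ages:
            if a <= self.screen_age:
                raise ValueError("follow-up ages must exceed the screening age")


@dataclass
class ScenarioResult:
    """Discounted totals and per-year ledger of one scenario."""

    scenario: Scenario
    total_cost: float
    total_qalys: float
    ledger: pd.DataFrame
    finding_probs: dict[FindingCategory, float]
    stratum_mass: float = 1.0


@dataclass(frozen=True)
class ICERResult:
    value: float
    delta_cost: float
    delta_qaly: float
    flag: str  # ok | dominant | dominated

    @property
    def cost_effective_at(self):
        def check(threshold: float) -> bool:
            if self.flag == "dominant":
                return True
            if self.flag == "dominated":
                return False
            return self.value <= threshold

        return check


def icer(intervention: ScenarioResult, control: ScenarioResult) -> ICERResult:
    """Incremental cost-effectiveness ratio of intervention vs control."""
    d_cost = intervention.total_cost - control.total_cost
    d_qaly = intervention.total_qalys - control.total_qalys
    if abs(d_qaly) < 1e-12:
        raise ZeroDivisionError("Delta QALY is zero; ICER undefined")
    flag = "ok"
    if d_qaly > 0 and d_cost <= 0:
        flag = "dominant"
    elif d_qaly < 0:
        flag = "dominated"
    return ICERResult(value=d_cost / d_qaly, delta_cost=d_cost, delta_qaly=d_qaly, flag=flag)


class Pipeline:
    """Cohort model with precomputed operators and cached propagations."""

    def __init__(self, config: ModelConfig, life_model: LifeTableModel | None = None):
        self.config = config
        self.space = enumerate_states(config.adenoma_cap)
        self._lesion = lesion_kernel(config.rates, config.adenoma_cap)
        self._shift = arrival_shift(config.adenoma_cap)
        if life_model is None:
            if config.life_table is not None:
                life_model = LifeTableModel(config.life_table)
            else:
                life_model = default_life_table_model()
        self.life_model = life_model
        self.hazards = MortalityInputs(life_model.all_cause_rate, dict(config.hazards))
        self._pre: dict[int, CohortDistribution] = {}

    def kernel_at(self, age: float) -> KernelOperator:
        p = yearly_to_monthly(adenoma_appearance_probability(age, self.config.rates))
        return KernelOperator(self._lesion, self._shift, p)

    # -- natural history -----------------------------------------------------

    def natural_history_to(self, age: int) -> CohortDistribution:
        """Cohort distribution at an integer age, from birth, no screening.

        Symptomatic cancer is diagnosed as it arises (symptom-triggered
        colonoscopy); results are cached per age.
        """
        age = int(age)
        if age in self._pre:
            return self._pre[age].copy()
        start = max((a for a in self._pre if a < age), default=None)
        if start is None:
            dist = CohortDistribution.newborn(self.space)
        else:
            dist = self._pre[start].copy()
        for m in range(int(round(dist.age * 12)), age * 12):
            dist, _ = propagate(dist, self.kernel_at(m / 12.0), self.hazards)
            _, dist = observation.symptom_presentation(dist)
        dist.age = float(age)
        self._pre[age] = dist.copy()
        return dist

    def screen_eligible(self, screen_age: int) -> CohortDistribution:
        """Alive, asymptomatic, undiagnosed cohort at the screening age."""
        return observation.condition_healthy_at_screening(self.natural_history_to(screen_age))

    # -- full scenario -------------------------------------------------------

    def run(self, scenario: Scenario) -> ScenarioResult:
        config = self.config
        costs = config.costs.at(scenario.colonoscopy_cost, scenario.cancer_cost)
        rate = config.discount_rate if scenario.discount_rate is None else scenario.discount_rate
        spec = DiscountSpec(rate=rate, anchor_age=scenario.screen_age)

        eligible = self.screen_eligible(int(scenario.screen_age))
        op = observation.get_operator(self.space, config.sensitivity)

        if scenario.finding is None:
            dist, findings = op.apply(eligible)
            stratum_mass = 1.0
        else:
            strata = observation.stratify_by_finding(eligible, config.sensitivity)
            if scenario.finding not in strata:
                raise ValueError(f"finding stratum {scenario.finding} has zero probability")
            _, full_findings = op.apply(eligible)
            findings = full_findings
            stratum_mass, dist = strata[scenario.finding]

        trajectory = self._accumulate(dist, scenario, costs)
        total_cost, total_qalys, ledger = economics.lifetime_totals(
            trajectory, spec, config.horizon_age
        )
        return ScenarioResult(
            scenario=scenario,
            total_cost=total_cost,
            total_qalys=total_qalys,
            ledger=ledger,
            finding_probs=findings,
            stratum_mass=stratum_mass,
        )

    def _accumulate(
        self, dist: CohortDistribution, scenario: Scenario, costs: CostValues
    ) -> list[YearRecord]:
        """Propagate from the screening age to the horizon, accruing annually.

        Monthly occupancies are averaged within each year of age.  The
        screening colonoscopy (already applied to ``dist``) is costed at
        month 0 with probability 1; scheduled follow-ups are applied at the
        start of their month to the alive undiagnosed mass, which is also
        the probability of that colonoscopy.  Symptom-triggered diagnostic
        colonoscopies accrue in the month the symptoms appear.
        """
        config = self.config
        tau = scenario.screen_age
        n_months = int(round((config.horizon_age - tau) * 12))
        follow_up_months = {int(round((a - tau) * 12)) for a in scenario.follow_up_ages}
        op = observation.get_operator(self.space, config.sensitivity)

        records: list[YearRecord] = []

        def fresh_acc(p_colo: float = 0.0) -> dict:
            return {
                "p_colo": p_colo,
                "healthy": 0.0,
                "diag_phase": np.zeros((3, 5)),  # avg mass by years-since-dx 0..4
                "diag_stage": np.zeros(3),
                "crc_deaths": np.zeros(3),
            }

        acc = fresh_acc(p_colo=1.0)  # the screening colonoscopy itself

        for m in range(n_months):
            if m > 0 and m in follow_up_months:
                p_scheduled = dist.undiagnosed_mass()
                dist, _ = op.apply(dist)
                acc["p_colo"] += p_scheduled

            # record occupancy at the start of the month
            acc["healthy"] += dist.state_probs.sum() / 12.0
            diag = dist.diagnosed
            acc["diag_phase"][:, 0] += diag[:, :12].sum(axis=1) / 12.0
            for y in range(1, 5):
                acc["diag_phase"][:, y] += diag[:, 12 * y : 12 * (y + 1)].sum(axis=1) / 12.0
            acc["diag_stage"] += diag.sum(axis=1) / 12.0

            dist, info = propagate(dist, self.kernel_at(tau + m / 12.0), self.hazards)
            acc["crc_deaths"] += info.deaths_crc_by_stage
            sym_diag, dist = observation.symptom_presentation(dist)
            acc["p_colo"] += float(sym_diag.sum())

            if m % 12 == 11:
                year = m // 12
                records.append(
                    YearRecord(
                        age=tau + year,
                        p_colonoscopy=acc["p_colo"],
                        cost_colonoscopy=acc["p_colo"] * costs.per_colonoscopy,
                        cost_crc=economics.crc_phase_costs(
                            acc["diag_phase"], acc["crc_deaths"], costs
                        ),
                        qalys=economics.qaly_step(
                            acc["healthy"], acc["diag_stage"], config.utilities
                        ),
                    )
                )
                acc = fresh_acc()
        return records


def run_scenario(config: ModelConfig, scenario: Scenario, pipeline: Pipeline | None = None) -> ScenarioResult:
    """Evaluate one scenario; builds (or reuses) a :class:`Pipeline`."""
    pipe = pipeline or Pipeline(config)
    return pipe.run(scenario)


# ---------------------------------------------------------------------------
# interval grid, windows, optimization


def interval_grid(
    pipeline: Pipeline,
    screen_age: float = 50.0,
    finding: FindingCategory | None = None,
    intervals: tuple[int, ...] = GRID_INTERVALS,
    discount_rate: float | None = None,
    colonoscopy_cost: str = "base",
    cancer_cost: str = "base",
    control: ScenarioResult | None = None,
) -> pd.DataFrame:
    """ICER table over the follow-up interval grid for one stratum."""
    base = Scenario(
        screen_age=screen_age,
        finding=finding,
        discount_rate=discount_rate,
        colonoscopy_cost=colonoscopy_cost,
        cancer_cost=cancer_cost,
    )
    if control is None:
        control = pipeline.run(base)
    rows = []
    for dt in intervals:
        res = pipeline.run(replace(base, follow_up_ages=(screen_age + dt,)))
        r = icer(res, control)
        rows.append(
            {
                "interval": float(dt),
                "total_cost": res.total_cost,
                "total_qalys": res.total_qalys,
                "delta_cost": r.delta_cost,
                "delta_qaly": r.delta_qaly,
                "icer": r.value,
                "flag": r.flag,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Window:
    """Cost-effective follow-up interval window at one threshold."""

    lo: float | None
    hi: float | None
    members: tuple[float, ...]  # grid intervals inside the window

    @property
    def empty(self) -> bool:
        return self.lo is None


def cost_effective_window(table: pd.DataFrame, threshold: float) -> Window:
    """Maximal contiguous run of grid intervals with ICER <= threshold.

    Eligibility requires a positive QALY gain; dominant (cost-saving)
    intervals are always eligible.  Boundary endpoints between an eligible
    grid point and its ineligible neighbour are refined by linear
    interpolation of the ICER curve at the threshold crossing; runs
    touching the grid edge keep the grid endpoint.
    """
    intervals = table["interval"].to_numpy()
    icers = table["icer"].to_numpy()
    eligible = (table["delta_qaly"].to_numpy() > 0) & (
        (icers <= threshold) | (table["flag"] == "dominant").to_numpy()
    )
    runs = []
    start = None
    for i, ok in enumerate(eligible):
        if ok and start is None:
            start = i
        if not ok and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(eligible) - 1))
    if not runs:
        return Window(lo=None, hi=None, members=())
    first, last = max(runs, key=lambda r: r[1] - r[0])

    lo = float(intervals[first])
    if first > 0 and np.isfinite(icers[first - 1]) and icers[first - 1] > threshold:
        x0, x1 = intervals[first - 1], intervals[first]
        y0, y1 = icers[first - 1], icers[first]
        if y0 != y1:
            lo = float(x0 + (x1 - x0) * (y0 - threshold) / (y0 - y1))
    hi = float(intervals[last])
    if last < len(intervals) - 1 and np.isfinite(icers[last + 1]) and icers[last + 1] > threshold:
        x0, x1 = intervals[last], intervals[last + 1]
        y0, y1 = icers[last], icers[last + 1]
        if y0 != y1:
            hi = float(x0 + (x1 - x0) * (threshold - y0) / (y1 - y0))
    return Window(lo=lo, hi=hi, members=tuple(float(x) for x in intervals[first : last + 1]))


@dataclass(frozen=True)
class OptimalInterval:
    interval: float
    delta_qaly: float  # per person, from the interpolating parabola
    flag: str  # interpolated | boundary | degenerate | clamped

    @property
    def delta_qaly_per_10k(self) -> float:
        return self.delta_qaly * 10_000.0


def quadratic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Vertex of the parabola through three equally spaced points.

    Returns None when the points are collinear (zero curvature).
    """
    x1, x2, x3 = x
    y1, y2, y3 = y
    h = x2 - x1
    denom = y1 - 2.0 * y2 + y3
    if abs(denom) < 1e-300 or denom == 0.0:
        return None
    xv = x2 + h * (y1 - y3) / (2.0 * denom)
    # evaluate the Lagrange parabola at the vertex
    yv = (
        y1 * (xv - x2) * (xv - x3) / ((x1 - x2) * (x1 - x3))
        + y2 * (xv - x1) * (xv - x3) / ((x2 - x1) * (x2 - x3))
        + y3 * (xv - x1) * (xv - x2) / ((x3 - x1) * (x3 - x2))
    )
    return float(xv), float(yv)


def optimal_interval(table: pd.DataFrame, window: Window) -> OptimalInterval:
    """QALY-maximizing follow-up interval via quadratic interpolation.

    Takes the in-window grid interval with the largest QALY gain (ties go
    to the longer interval) and fits a parabola through it and its two grid
    neighbours; the vertex is the recommended interval.  When the maximum
    sits at the edge of the grid, or the three points are collinear, the
    grid point itself is returned with a flag; a vertex falling outside the
    window is clamped to the window endpoint.
    """
    if window.empty:
        raise ValueError("empty cost-effective window; no recommendation")
    intervals = table["interval"].to_numpy()
    dq = table["delta_qaly"].to_numpy()
    member_idx = [int(np.where(intervals == m)[0][0]) for m in window.members]
    best = max(member_idx, key=lambda i: (dq[i], intervals[i]))
    if best == 0 or best == len(intervals) - 1:
        return OptimalInterval(float(intervals[best]), float(dq[best]), "boundary")
    vertex = quadratic_vertex(intervals[best - 1 : best + 2], dq[best - 1 : best + 2])
    if vertex is None:
        return OptimalInterval(float(intervals[best]), float(dq[best]), "degenerate")
    xv, yv = vertex
    flag = "interpolated"
    if xv < window.lo:
        xv, yv, flag = window.lo, _parabola_at(intervals, dq, best, window.lo), "clamped"
    elif xv > window.hi:
        xv, yv, flag = window.hi, _parabola_at(intervals, dq, best, window.hi), "clamped"
    return OptimalInterval(float(xv), float(yv), flag)


def _parabola_at(x: np.ndarray, y: np.ndarray, center: int, xq: float) -> float:
    x1, x2, x3 = x[center - 1 : center + 2]
    y1, y2, y3 = y[center - 1 : center + 2]
    return float(
        y1 * (xq - x2) * (xq - x3) / ((x1 - x2) * (x1 - x3))
        + y2 * (xq - x1) * (xq - x3) / ((x2 - x1) * (x2 - x3))
        + y3 * (xq - x1) * (xq - x2) / ((x3 - x1) * (x3 - x2))
    )


@dataclass
class CEAOutcome:
    """Headline cost-effectiveness outcome for one stratum and threshold."""

    screen_age: float
    finding: FindingCategory | None
    threshold: float
    window: Window
    recommended: OptimalInterval | None
    table: pd.DataFrame

    @property
    def cost_effective(self) -> bool:
        return not self.window.empty


def recommend(
    pipeline: Pipeline,
    screen_age: float = 50.0,
    finding: FindingCategory | None = None,
    threshold: float = 100_000.0,
    table: pd.DataFrame | None = None,
    **grid_kwargs,
) -> CEAOutcome:
    """End-to-end recommendation for one screening age / stratum / threshold."""
    if table is None:
        table = interval_grid(pipeline, screen_age=screen_age, finding=finding, **grid_kwargs)
    window = cost_effective_window(table, threshold)
    rec = None if window.empty else optimal_interval(table, window)
    return CEAOutcome(
        screen_age=screen_age,
        finding=finding,
        threshold=threshold,
        window=window,
        recommended=rec,
        table=table,
    )


# ---------------------------------------------------------------------------
# multi-colonoscopy schedules and sensitivity analysis


def optimize_schedule(
    pipeline: Pipeline,
    screen_age: float = 50.0,
    threshold: float = 100_000.0,
    discount_rate: float | None = None,
    colonoscopy_cost: str = "base",
    cancer_cost: str = "base",
    max_followups: int = 6,
) -> tuple[list[float], float]:
    """Greedy sequential schedule construction.

    Starting from screening only, repeatedly consider adding one more
    follow-up colonoscopy 2-20 years (grid step 2) after the previous one
    and accept the quadratic-interpolated optimum while its marginal ICER
    against the current schedule stays at or below the threshold.  Returns
    the accepted follow-up intervals (years after the previous colonoscopy)
    and the total QALY gain per person versus screening only.
    """
    base = Scenario(
        screen_age=screen_age,
        discount_rate=discount_rate,
        colonoscopy_cost=colonoscopy_cost,
        cancer_cost=cancer_cost,
    )
    screening_only = pipeline.run(base)
    current = screening_only
    schedule: list[float] = []
    last_age = screen_age
    horizon = pipeline.config.horizon_age
    for _ in range(max_followups):
        rows = []
        for dt in GRID_INTERVALS:
            age = last_age + dt
            if age >= horizon - 1:
                break
            res = pipeline.run(
                replace(base, follow_up_ages=tuple(screen_age + sum(schedule[: i + 1]) for i in range(len(schedule))) + (age,))
            )
            r = icer(res, current)
            rows.append(
                {
                    "interval": float(dt),
                    "total_cost": res.total_cost,
                    "total_qalys": res.total_qalys,
                    "delta_cost": r.delta_cost,
                    "delta_qaly": r.delta_qaly,
                    "icer": r.value,
                    "flag": r.flag,
                }
            )
        if not rows:
            break
        table = pd.DataFrame(rows)
        window = cost_effective_window(table, threshold)
        if window.empty:
            break
        rec = optimal_interval(table, window)
        schedule.append(rec.interval)
        followup_ages = []
        s = screen_age
        for dt in schedule:
            s += dt
            followup_ages.append(s)
        current = pipeline.run(replace(base, follow_up_ages=tuple(followup_ages)))
        last_age = followup_ages[-1]
    return schedule, current.total_qalys - screening_only.total_qalys


SENSITIVITY_AXES = (
    "base",
    "colonoscopy_cost_low",
    "colonoscopy_cost_high",
    "cancer_cost_low",
    "cancer_cost_high",
    "discount_0",
)


def sensitivity_analysis(
    pipeline: Pipeline,
    screen_ages: tuple[int, ...] = SCREEN_AGES,
    thresholds: tuple[float, ...] = THRESHOLDS,
    axes: tuple[str, ...] = SENSITIVITY_AXES,
) -> pd.DataFrame:
    """One-way sensitivity analysis over cost bounds and a 0% discount rate.

    Each axis changes exactly one input (colonoscopy cost to its low/high
    bound, all CRC treatment costs to their low/high bounds, or the
    discount rate to zero) and re-runs the full single-follow-up pipeline
    for every screening age; the 0% discount axis additionally searches
    greedy multi-colonoscopy schedules.  Returns one row per
    (axis, screening age, threshold).
    """
    rows = []
    for axis in axes:
        kwargs = dict(colonoscopy_cost="base", cancer_cost="base", discount_rate=None)
        if axis == "colonoscopy_cost_low":
            kwargs["colonoscopy_cost"] = "low"
        elif axis == "colonoscopy_cost_high":
            kwargs["colonoscopy_cost"] = "high"
        elif axis == "cancer_cost_low":
            kwargs["cancer_cost"] = "low"
        elif axis == "cancer_cost_high":
            kwargs["cancer_cost"] = "high"
        elif axis == "discount_0":
            kwargs["discount_rate"] = 0.0
        elif axis != "base":
            raise ValueError(f"unknown axis {axis!r}")
        for age in screen_ages:
            table = interval_grid(pipeline, screen_age=age, **kwargs)
            for threshold in thresholds:
                window = cost_effective_window(table, threshold)
                if window.empty:
                    rows.append(
                        {
                            "axis": axis,
                            "screen_age": age,
                            "threshold": threshold,
                            "cost_effective": False,
                            "recommended_interval": np.nan,
                            "window_lo": np.nan,
                            "window_hi": np.nan,
                            "qalys_gained_per_10k": np.nan,
                        }
                    )
                    continue
                rec = optimal_interval(table, window)
                rows.append(
                    {
                        "axis": axis,
                        "screen_age": age,
                        "threshold": threshold,
                        "cost_effective": True,
                        "recommended_interval": rec.interval,
                        "window_lo": window.lo,
                        "window_hi": window.hi,
                        "qalys_gained_per_10k": rec.delta_qaly_per_10k,
                    }
                )
    return pd.DataFrame(rows)
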