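"""Synthetic data generation and Monte-Carlo validation.

Three generators live here:

* :func:`generate_life_table` — a Gompertz-Makeham period life table in the
  banded (age_lo, age_hi, annual_death_rate) schema consumed by the
  mortality module, calibrated so life expectancy is about 79 years.
* :func:`generate_survival_curves` — per-stage five-year survival points
  and an 11-point overall survival curve drawn from the breakpoint model,
  for fitting-recovery studies.
* :func:`simulate_patients` — an individual-level microsimulation of the
  identical natural history, observation and economic rules as the cohort
  model, sharing the same parameter objects and the same monthly update
  order, so cohort-model expectations can be validated against Monte-Carlo
  means within sampling error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mortality import LifeTableModel, crc_survival, overall_crc_survival
from .natural_history import (
    ColonState,
    _monthly_lesion_probs,
    adenoma_appearance_probability,
    yearly_to_monthly,
)
from .observation import FindingCategory
from .params import BreakpointHazard, CRCStage, ModelConfig, StageMix, SURVIVAL_STAGES

__all__ = [
    "GompertzMakeham",
    "generate_life_table",
    "generate_survival_curves",
    "Microsim",
    "PatientArrays",
    "simulate_patients",
    "MicrosimResult",
]

MONTH = 1.0 / 12.0

#: finding codes aligned with ``list(FindingCategory)``
_FINDING_LIST = list(FindingCategory)
_FINDING_CODE = {f: i for i, f in enumerate(_FINDING_LIST)}


# ---------------------------------------------------------------------------
# synthetic life table


@dataclass(frozen=True)
class GompertzMakeham:
    """All-cause hazard ``makeham + a * exp(b * age)`` per year.

    Defaults are calibrated so the implied life expectancy is ~79 years.
    """

    makeham: float = 4.5e-4
    a: float = 2.65e-5
    b: float = 0.0945

    def rate(self, age) -> np.ndarray:
        return self.makeham + self.a * np.exp(self.b * np.asarray(age, dtype=float))

    def life_expectancy(self) -> float:
        """Period life expectancy at birth by trapezoidal survivorship integral."""
        x = np.linspace(0.0, 120.0, 12001)
        h = self.rate(x)
        cum = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2.0 * np.diff(x))])
        return float(np.trapezoid(np.exp(-cum), x))


_DEFAULT_BANDS = [(0, 1), (1, 5)] + [(lo, lo + 5) for lo in range(5, 90, 5)]


def generate_life_table(
    params: GompertzMakeham | None = None,
    bands: list[tuple[float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit an age-banded life table with the hazard at each band midpoint.

    With ``noise_sd > 0`` multiplicative noise is applied; the default
    table is deterministic.  Raises if the parameters imply decreasing
    adult mortality.
    """
    params = params or GompertzMakeham()
    if params.a <= 0 or params.b <= 0:
        raise ValueError("Gompertz parameters must imply increasing adult mortality")
    bands = bands or _DEFAULT_BANDS
    mids = np.array([(lo + hi) / 2.0 for lo, hi in bands])
    rates = params.rate(mids)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        rates = rates * np.exp(rng.normal(0.0, noise_sd, size=rates.shape))
    return pd.DataFrame(
        {
            "age_lo": [float(lo) for lo, _ in bands],
            "age_hi": [float(hi) for _, hi in bands],
            "annual_death_rate": rates,
        }
    )


def default_life_model() -> LifeTableModel:
    return LifeTableModel(generate_life_table())


# ---------------------------------------------------------------------------
# synthetic survival curves


def generate_survival_curves(
    hazards: dict[str, BreakpointHazard],
    mix: StageMix,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[dict[str, float], tuple[np.ndarray, np.ndarray]]:
    """Stage five-year survival points and an 11-point overall curve.

    Points are generated from the breakpoint survival model and its
    prevalence-weighted mixture; additive Gaussian noise (sd ``noise_sd``)
    is truncated to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    stage_points = {s: float(crc_survival(hazards[s], 5.0)) for s in SURVIVAL_STAGES}
    t = np.arange(0.0, 11.0)
    s = np.asarray(overall_crc_survival(hazards, mix, t), dtype=float)
    if noise_sd > 0.0:
        stage_points = {
            k: float(np.clip(v + rng.normal(0.0, noise_sd), 0.0, 1.0))
            for k, v in stage_points.items()
        }
        s = np.clip(s + rng.normal(0.0, noise_sd, size=s.shape), 0.0, 1.0)
    return stage_points, (t, s)


# ---------------------------------------------------------------------------
# microsimulation


class PatientArrays:
    """Vectorized patient-state arrays."""

    def __init__(self, n: int, state: ColonState = ColonState(0, 0, 0)):
        self.n = n
        self.nd = np.full(n, state.n_diminutive, dtype=np.int16)
        self.nm = np.full(n, state.n_medium, dtype=np.int16)
        self.nl = np.full(n, state.n_large, dtype=np.int16)
        self.stage = np.full(n, int(state.crc_stage), dtype=np.int8)
        self.sympt = np.full(n, state.symptomatic, dtype=bool)
        self.diag = np.zeros(n, dtype=bool)
        self.dxstage = np.zeros(n, dtype=np.int8)  # 0 local, 1 regional, 2 distant
        self.dxm = np.zeros(n, dtype=np.int32)  # months since diagnosis
        self.alive = np.ones(n, dtype=bool)


@dataclass(frozen=True)
class StepEvents:
    died_crc: np.ndarray  # bool per patient
    sym_diag: np.ndarray  # bool per patient


class Microsim:
    """Monte-Carlo twin of the deterministic cohort model.

    Uses the same parameter objects, the same monthly probabilities, and
    the same within-month order of operations (all-cause death; CRC death
    and diagnosis-clock advance; lesion and cancer transitions drawn
    independently from the pre-step state; one possible new-adenoma
    arrival; symptom-triggered diagnosis) so its expectations coincide with
    the cohort model's per step, not just asymptotically.
    """

    def __init__(
        self,
        config: ModelConfig,
        life_model: LifeTableModel | None = None,
        seed: int | None = None,
    ):
        self.config = config
        self.life = life_model or default_life_model()
        self.rng = np.random.default_rng(seed)
        self.p = _monthly_lesion_probs(config.rates)
        h = config.hazards
        self.k_stage = [
            (h[s].k1, h[s].breakpoint, h[s].k2) for s in ("local", "regional", "distant")
        ]

    def monthly_death_prob(self, age: float) -> float:
        return 1.0 - math.exp(-self.life.all_cause_rate(age) * MONTH)

    def step(self, c: PatientArrays, age: float) -> StepEvents:
        """Advance every patient one month (age = age at the month start)."""
        rng, p, cap = self.rng, self.p, self.config.adenoma_cap
        died_crc = np.zeros(c.n, dtype=bool)
        sym_diag = np.zeros(c.n, dtype=bool)

        # (1) all-cause death
        alive_idx = np.flatnonzero(c.alive)
        if alive_idx.size:
            u = rng.random(alive_idx.size)
            c.alive[alive_idx[u < self.monthly_death_prob(age)]] = False

        # (2) CRC death on diagnosed survivors, then clock advance
        dx_idx = np.flatnonzero(c.alive & c.diag)
        if dx_idx.size:
            t = c.dxm[dx_idx] / 12.0
            pk = np.empty(dx_idx.size)
            for s, (k1, b, k2) in enumerate(self.k_stage):
                sel = c.dxstage[dx_idx] == s
                pk[sel] = 1.0 - np.exp(-np.where(t[sel] < b, k1, k2) * MONTH)
            u = rng.random(dx_idx.size)
            dead = dx_idx[u < pk]
            c.alive[dead] = False
            died_crc[dead] = True
            c.dxm[c.alive & c.diag] += 1

        # (3) neoplasia dynamics on undiagnosed survivors; cancer-state and
        # lesion transitions are drawn independently from the pre-step state
        idx = np.flatnonzero(c.alive & ~c.diag)
        if idx.size:
            pre_stage = c.stage[idx].copy()
            new_stage, new_sympt = self._cancer_transitions(idx, pre_stage, c.sympt[idx])
            onset = self._lesion_transitions(c, idx)
            fresh = onset & (pre_stage == 0)
            new_stage[fresh] = int(CRCStage.LOCAL)
            c.stage[idx] = new_stage
            c.sympt[idx] = new_sympt

            p_arr = yearly_to_monthly(adenoma_appearance_probability(age, self.config.rates))
            if p_arr > 0.0:
                u = rng.random(idx.size)
                arr = idx[u < p_arr]
                c.nd[arr] = np.minimum(cap, c.nd[arr] + 1)

        # (4) symptomatic cancer is diagnosed immediately
        sym_idx = np.flatnonzero(c.alive & ~c.diag & c.sympt)
        if sym_idx.size:
            c.diag[sym_idx] = True
            c.dxstage[sym_idx] = c.stage[sym_idx] - 1
            c.dxm[sym_idx] = 0
            sym_diag[sym_idx] = True
        return StepEvents(died_crc=died_crc, sym_diag=sym_diag)

    def _cancer_transitions(
        self, idx: np.ndarray, stage: np.ndarray, sympt: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        rng, p = self.rng, self.p
        new_stage = stage.copy()
        new_sympt = sympt.copy()
        specs = [
            (int(CRCStage.LOCAL), p["loc_reg"], p["sym_loc"], int(CRCStage.REGIONAL)),
            (int(CRCStage.REGIONAL), p["reg_dis"], p["sym_reg"], int(CRCStage.DISTANT)),
            (int(CRCStage.DISTANT), 0.0, p["sym_dis"], int(CRCStage.DISTANT)),
        ]
        for s, p_prog, p_sym, s_next in specs:
            sel = np.flatnonzero((stage == s) & ~sympt)
            if not sel.size:
                continue
            u = rng.random(sel.size)
            new_stage[sel[u < p_prog]] = s_next
            new_sympt[sel[(u >= p_prog) & (u < p_prog + p_sym)]] = True
        return new_stage, new_sympt

    def _lesion_transitions(self, c: PatientArrays, idx: np.ndarray) -> np.ndarray:
        """Per-lesion monthly multinomials; returns onset flags (new CRC)."""
        rng, p, cap = self.rng, self.p, self.config.adenoma_cap
        n = idx.size
        z = lambda: np.zeros(n, dtype=np.int16)  # noqa: E731
        d2none, d2med = z(), z()
        m2dim, m2lar, m2crc = z(), z(), z()
        l2med, l2crc = z(), z()
        for slot in range(cap):
            has = np.flatnonzero(c.nd[idx] > slot)
            if has.size:
                u = rng.random(has.size)
                d2none[has[u < p["d_none"]]] += 1
                d2med[has[(u >= p["d_none"]) & (u < p["d_none"] + p["d_med"])]] += 1
            has = np.flatnonzero(c.nm[idx] > slot)
            if has.size:
                u = rng.random(has.size)
                c1 = p["m_dim"]
                c2 = c1 + p["m_lar"]
                c3 = c2 + p["m_crc"]
                m2dim[has[u < c1]] += 1
                m2lar[has[(u >= c1) & (u < c2)]] += 1
                m2crc[has[(u >= c2) & (u < c3)]] += 1
            has = np.flatnonzero(c.nl[idx] > slot)
            if has.size:
                u = rng.random(has.size)
                c1 = p["l_med"]
                c2 = c1 + p["l_crc"]
                l2med[has[u < c1]] += 1
                l2crc[has[(u >= c1) & (u < c2)]] += 1
        c.nd[idx] = np.minimum(cap, c.nd[idx] - d2none - d2med + m2dim)
        c.nm[idx] = np.minimum(cap, c.nm[idx] - m2dim - m2lar - m2crc + d2med + l2med)
        c.nl[idx] = np.minimum(cap, c.nl[idx] - l2med - l2crc + m2lar)
        return (m2crc + l2crc) > 0

    def colonoscopy(self, c: PatientArrays, idx: np.ndarray) -> np.ndarray:
        """Colonoscopy with polypectomy on patients ``idx``; returns finding codes.

        Each lesion is detected independently with its size-class
        sensitivity; detected adenomas are removed, a detected cancer is
        diagnosed at its true stage.
        """
        rng, sens = self.rng, self.config.sensitivity
        kd = rng.binomial(c.nd[idx], sens.diminutive)
        km = rng.binomial(c.nm[idx], sens.medium)
        kl = rng.binomial(c.nl[idx], sens.large)
        crc_det = (c.stage[idx] > 0) & (rng.random(idx.size) < sens.crc)
        c.nd[idx] -= kd.astype(np.int16)
        c.nm[idx] -= km.astype(np.int16)
        c.nl[idx] -= kl.astype(np.int16)

        ndet = kd + km + kl
        codes = np.zeros(idx.size, dtype=np.int8)  # NO_ADENOMAS
        codes[(ndet >= 1) & (ndet <= 2) & (kl == 0)] = 1
        codes[(ndet >= 3) & (kl == 0)] = 2
        codes[(ndet >= 1) & (ndet <= 2) & (kl > 0)] = 3
        codes[(ndet >= 3) & (kl > 0)] = 4
        codes[crc_det] = 4 + c.stage[idx][crc_det]  # 5/6/7 by stage

        det_idx = idx[crc_det]
        c.diag[det_idx] = True
        c.dxstage[det_idx] = c.stage[det_idx] - 1
        c.dxm[det_idx] = 0
        return codes


@dataclass
class MicrosimResult:
    """Per-patient outcomes and summaries from one scenario microsimulation."""

    n_simulated: int
    n_eligible: int
    findings: np.ndarray  # finding codes for eligible patients
    pre_screen: dict  # arrays of the true state at screening (eligible)
    total_cost: np.ndarray  # per accounted patient, discounted
    total_qalys: np.ndarray
    summary: dict = field(default_factory=dict)

    @staticmethod
    def mean_se(values: np.ndarray) -> tuple[float, float]:
        values = np.asarray(values, dtype=float)
        return float(values.mean()), float(values.std(ddof=1) / math.sqrt(values.size))

    def finding_shares(self) -> dict[FindingCategory, tuple[float, float]]:
        """Share of each finding category with its binomial standard error."""
        out = {}
        n = self.findings.size
        for f, code in _FINDING_CODE.items():
            p = float((self.findings == code).mean())
            out[f] = (p, math.sqrt(max(p * (1 - p), 1e-12) / n))
        return out


def simulate_patients(
    n: int,
    scenario,
    config: ModelConfig | None = None,
    seed: int | None = None,
    life_model: LifeTableModel | None = None,
) -> MicrosimResult:
    """Run the full scenario pipeline on ``n`` simulated patients.

    Mirrors the cohort pipeline: natural history from birth, conditioning
    on being alive/asymptomatic/undiagnosed at the screening age, screening
    colonoscopy, optional finding stratification, scheduled follow-ups,
    symptom-triggered diagnosis, and annually accounted discounted costs
    and QALYs anchored at the screening age.
    """
    from .cea import Scenario  # deferred to avoid a hard dependency at import

    assert isinstance(scenario, Scenario)
    config = config or ModelConfig()
    sim = Microsim(config, life_model=life_model, seed=seed)
    rng = sim.rng
    c = PatientArrays(n)
    tau = int(scenario.screen_age)

    # before the appearance ramp starts the only process is all-cause
    # death; monthly survival factors are exp(-h/12), so the period
    # collapses to a single survival draw with the identical probability
    a0 = int(min(config.rates.appearance_ramp_start_age, tau))
    if a0 > 0:
        log_s = -sum(sim.life.all_cause_rate(m / 12.0) * MONTH for m in range(a0 * 12))
        c.alive = rng.random(n) < math.exp(log_s)
    for m in range(a0 * 12, tau * 12):
        sim.step(c, m / 12.0)

    eligible = np.flatnonzero(c.alive & ~c.diag)
    pre_screen = {
        "n_diminutive": c.nd[eligible].copy(),
        "n_medium": c.nm[eligible].copy(),
        "n_large": c.nl[eligible].copy(),
        "stage": c.stage[eligible].copy(),
    }

    findings = sim.colonoscopy(c, eligible)

    if scenario.finding is not None:
        accounted = eligible[findings == _FINDING_CODE[scenario.finding]]
    else:
        accounted = eligible
    pop = np.zeros(n, dtype=bool)
    pop[accounted] = True

    costs = config.costs.at(scenario.colonoscopy_cost, scenario.cancer_cost)
    utilities = config.utilities
    r = config.discount_rate if scenario.discount_rate is None else scenario.discount_rate
    u_stage = np.array([utilities.local, utilities.regional, utilities.distant])
    init_cost = np.array([costs.initial[s] for s in ("local", "regional", "distant")])
    surv_cost = np.array([costs.surveillance[s] for s in ("local", "regional", "distant")])

    total_cost = np.zeros(n)
    total_qalys = np.zeros(n)
    total_cost[pop] += costs.per_colonoscopy  # the screening colonoscopy, year 0

    n_months = int(round((config.horizon_age - tau) * 12))
    follow_up_months = {int(round((a - tau) * 12)) for a in scenario.follow_up_ages}

    for m in range(n_months):
        year = m // 12
        f = math.exp(-r * year)
        if m > 0 and m in follow_up_months:
            screened = np.flatnonzero(pop & c.alive & ~c.diag)
            total_cost[screened] += f * costs.per_colonoscopy
            sim.colonoscopy(c, screened)

        # occupancy at the month start
        healthy = pop & c.alive & ~c.diag
        total_qalys[healthy] += f * utilities.healthy / 12.0
        dsel = np.flatnonzero(pop & c.alive & c.diag)
        if dsel.size:
            total_qalys[dsel] += f * u_stage[c.dxstage[dsel]] / 12.0
            phase_initial = c.dxm[dsel] < 12
            phase_surv = (c.dxm[dsel] >= 12) & (c.dxm[dsel] < 60)
            total_cost[dsel[phase_initial]] += f * init_cost[c.dxstage[dsel[phase_initial]]] / 12.0
            total_cost[dsel[phase_surv]] += f * surv_cost[c.dxstage[dsel[phase_surv]]] / 12.0

        events = sim.step(c, tau + m / 12.0)
        total_cost[pop & events.died_crc] += f * costs.terminal
        total_cost[pop & events.sym_diag] += f * costs.per_colonoscopy

    res = MicrosimResult(
        n_simulated=n,
        n_eligible=eligible.size,
        findings=findings,
        pre_screen=pre_screen,
        total_cost=total_cost[accounted],
        total_qalys=total_qalys[accounted],
    )
    cm, cse = res.mean_se(res.total_cost)
    qm, qse = res.mean_se(res.total_qalys)
    res.summary = {
        "cost_mean": cm,
        "cost_se": cse,
        "qalys_mean": qm,
        "qalys_se": qse,
        "eligible_fraction": eligible.size / n,
    }
    return res
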