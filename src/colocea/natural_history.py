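"""Colonic neoplasia natural-history model.

The colon is described by a joint state: the number of diminutive, medium
and large adenomas (each capped at a configurable count), the stage of an
invasive cancer if one exists (local, regional, distant), and whether that
cancer has become symptomatic.  Lesions evolve independently: each adenoma
can regress, stay, grow one size class, or (for medium/large adenomas)
transform to a local cancer; new diminutive adenomas appear with an
age-dependent probability; an existing cancer progresses through stages and
develops symptoms with stage-specific probabilities.

All published transition probabilities are annual; the model integrates the
dynamics in monthly steps, converting via the constant-rate identity
``1 - (1 - p_month)**12 = p_year``.  The yearly kernel is defined as the
12-fold composition of the monthly kernel (with the appearance probability
frozen at the given age).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import product
from typing import Callable, NamedTuple

import numpy as np

from .params import CRCStage, LesionTransitionRates

__all__ = [
    "yearly_to_monthly",
    "monthly_to_yearly",
    "adenoma_appearance_probability",
    "ColonState",
    "StateSpace",
    "enumerate_states",
    "CohortDistribution",
    "KernelOperator",
    "build_kernel",
    "MortalityInputs",
    "StepInfo",
    "propagate",
]

#: number of months of post-diagnosis follow-up tracked per stage
DX_MONTHS = 1212

MONTH = 1.0 / 12.0

#: undiagnosed cancer stages that can appear in the state space
_CANCER_STAGES = (CRCStage.LOCAL, CRCStage.REGIONAL, CRCStage.DISTANT)
_STAGE_NAMES = {CRCStage.LOCAL: "local", CRCStage.REGIONAL: "regional", CRCStage.DISTANT: "distant"}


def yearly_to_monthly(p_yearly: float) -> float:
    """Convert a yearly transition probability to its monthly equivalent.

    Uses the constant-rate interpretation: the monthly probability ``p`` is
    the unique solution of ``1 - (1 - p)**12 = p_yearly``.
    """
    if not 0.0 <= p_yearly < 1.0:
        raise ValueError(f"yearly probability {p_yearly} outside [0, 1)")
    return 1.0 - (1.0 - p_yearly) ** (1.0 / 12.0)


def monthly_to_yearly(p_monthly: float) -> float:
    """Inverse of :func:`yearly_to_monthly` (compound 12 months)."""
    if not 0.0 <= p_monthly < 1.0:
        raise ValueError(f"monthly probability {p_monthly} outside [0, 1)")
    return 1.0 - (1.0 - p_monthly) ** 12


def adenoma_appearance_probability(age: float, rates: LesionTransitionRates) -> float:
    """Yearly probability that a new diminutive adenoma appears, by age.

    The default profile is a linear ramp: zero up to the ramp start age,
    rising to the published maximum at the plateau age and constant beyond.
    """
    if age < 0:
        raise ValueError(f"age {age} is negative")
    a0, a1 = rates.appearance_ramp_start_age, rates.appearance_plateau_age
    if age <= a0:
        return 0.0
    if age >= a1:
        return rates.appearance_max
    return rates.appearance_max * (age - a0) / (a1 - a0)


class ColonState(NamedTuple):
    """Joint colonic configuration: adenoma counts, cancer stage, symptoms."""

    n_diminutive: int
    n_medium: int
    n_large: int
    crc_stage: CRCStage = CRCStage.NONE
    symptomatic: bool = False

    def validate(self, cap: int) -> None:
        for n in (self.n_diminutive, self.n_medium, self.n_large):
            if not 0 <= n <= cap:
                raise ValueError(f"lesion count {n} outside [0, {cap}]")
        if self.symptomatic and self.crc_stage == CRCStage.NONE:
            raise ValueError("symptomatic state requires a cancer stage")

    @property
    def n_adenomas(self) -> int:
        return self.n_diminutive + self.n_medium + self.n_large


@dataclass(frozen=True)
class StateSpace:
    """Enumerated, index-addressable colonic state space."""

    cap: int
    states: tuple[ColonState, ...]
    _index: dict[ColonState, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.states)})

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state: ColonState) -> int:
        return self._index[state]

    def state(self, i: int) -> ColonState:
        return self.states[i]

    @property
    def no_neoplasia_index(self) -> int:
        return self.index(ColonState(0, 0, 0))

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-state lesion counts as integer arrays (diminutive, medium, large)."""
        nd = np.array([s.n_diminutive for s in self.states])
        nm = np.array([s.n_medium for s in self.states])
        nl = np.array([s.n_large for s in self.states])
        return nd, nm, nl

    def stage_array(self) -> np.ndarray:
        return np.array([int(s.crc_stage) for s in self.states])

    def symptomatic_array(self) -> np.ndarray:
        return np.array([s.symptomatic for s in self.states])

    def symptomatic_indices(self, stage: CRCStage) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.states) if s.symptomatic and s.crc_stage == stage],
            dtype=int,
        )


@lru_cache(maxsize=8)
def enumerate_states(cap: int) -> StateSpace:
    """Enumerate every valid colonic state for a per-class count cap.

    States are ordered by (cancer stage, symptomatic flag, lesion counts);
    index 0 is always the all-clear state.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    states: list[ColonState] = []
    for stage in (CRCStage.NONE, *_CANCER_STAGES):
        for symptomatic in ((False,) if stage == CRCStage.NONE else (False, True)):
            for nd, nm, nl in product(range(cap + 1), repeat=3):
                states.append(ColonState(nd, nm, nl, stage, symptomatic))
    return StateSpace(cap=cap, states=tuple(states))


# ---------------------------------------------------------------------------
# kernel construction


def _multinomial_outcomes(n: int, probs: tuple[float, ...]):
    """All count-vectors over outcome classes with their multinomial pmf.

    Yields ``(counts, probability)`` for ``n`` independent lesions each
    drawing one of ``len(probs)`` outcomes.
    """
    k = len(probs)
    if n == 0:
        yield (0,) * k, 1.0
        return

    def rec(remaining: int, idx: int, counts: list[int]):
        if idx == k - 1:
            yield tuple(counts + [remaining])
            return
        for c in range(remaining + 1):
            yield from rec(remaining - c, idx + 1, counts + [c])

    for counts in rec(n, 0, []):
        coef = math.factorial(n)
        p = 1.0
        for c, pr in zip(counts, probs):
            coef //= math.factorial(c)
            p *= pr**c
        yield counts, coef * p


def _monthly_lesion_probs(rates: LesionTransitionRates) -> dict[str, float]:
    m = yearly_to_monthly
    return {
        "d_none": m(rates.diminutive_to_none),
        "d_med": m(rates.diminutive_to_medium),
        "m_dim": m(rates.medium_to_diminutive),
        "m_lar": m(rates.medium_to_large),
        "m_crc": m(rates.medium_to_crc),
        "l_med": m(rates.large_to_medium),
        "l_crc": m(rates.large_to_crc),
        "loc_reg": m(rates.local_to_regional),
        "reg_dis": m(rates.regional_to_distant),
        "sym_loc": m(rates.symptoms_local),
        "sym_reg": m(rates.symptoms_regional),
        "sym_dis": m(rates.symptoms_distant),
    }


def _crc_outcomes(state: ColonState, p: dict[str, float]):
    """Monthly outcomes of the cancer sub-state: (stage, symptomatic, prob)."""
    stage, sym = state.crc_stage, state.symptomatic
    if stage == CRCStage.NONE:
        return [(CRCStage.NONE, False, 1.0)]
    if sym:
        # symptomatic cancer is diagnosed by the observation layer within
        # the same step; the kernel holds it in place
        return [(stage, True, 1.0)]
    if stage == CRCStage.LOCAL:
        pr, ps = p["loc_reg"], p["sym_loc"]
        return [
            (CRCStage.LOCAL, False, 1.0 - pr - ps),
            (CRCStage.REGIONAL, False, pr),
            (CRCStage.LOCAL, True, ps),
        ]
    if stage == CRCStage.REGIONAL:
        pr, ps = p["reg_dis"], p["sym_reg"]
        return [
            (CRCStage.REGIONAL, False, 1.0 - pr - ps),
            (CRCStage.DISTANT, False, pr),
            (CRCStage.REGIONAL, True, ps),
        ]
    ps = p["sym_dis"]
    return [(CRCStage.DISTANT, False, 1.0 - ps), (CRCStage.DISTANT, True, ps)]


@lru_cache(maxsize=8)
def lesion_kernel(rates: LesionTransitionRates, cap: int) -> np.ndarray:
    """Monthly transition matrix over the state space, without new arrivals.

    Combines the per-lesion monthly multinomials across the lesions of each
    size class (lesions evolve independently), the cancer stage/symptom
    transitions, and the cap-overflow rule (counts exceeding the cap are
    redirected to the cap).  Rows index source states, columns targets;
    returns a column-stochastic operator transposed so that ``K @ v``
    propagates a probability vector ``v`` (i.e. ``K[j, i]`` is the i -> j
    probability).
    """
    space = enumerate_states(cap)
    p = _monthly_lesion_probs(rates)
    n = len(space)
    K = np.zeros((n, n))

    dim_probs = (1.0 - p["d_none"] - p["d_med"], p["d_none"], p["d_med"])
    med_probs = (1.0 - p["m_dim"] - p["m_lar"] - p["m_crc"], p["m_dim"], p["m_lar"], p["m_crc"])
    lar_probs = (1.0 - p["l_med"] - p["l_crc"], p["l_med"], p["l_crc"])

    for i, s in enumerate(space.states):
        crc_out = _crc_outcomes(s, p)
        for d_counts, pd in _multinomial_outcomes(s.n_diminutive, dim_probs):
            _, d2none, d2med = d_counts
            for m_counts, pm in _multinomial_outcomes(s.n_medium, med_probs):
                _, m2dim, m2lar, m2crc = m_counts
                for l_counts, pl in _multinomial_outcomes(s.n_large, lar_probs):
                    _, l2med, l2crc = l_counts
                    p_lesions = pd * pm * pl
                    if p_lesions == 0.0:
                        continue
                    nd = min(cap, s.n_diminutive - d2none - d2med + m2dim)
                    nm = min(cap, s.n_medium - m2dim - m2lar - m2crc + d2med + l2med)
                    nl = min(cap, s.n_large - l2med - l2crc + m2lar)
                    onset = (m2crc + l2crc) > 0
                    for stage, sym, pc in crc_out:
                        if pc == 0.0:
                            continue
                        # a transforming lesion starts a local cancer only if
                        # none exists; with an existing cancer it simply
                        # leaves the adenoma pool (single cancer per patient)
                        new_stage = CRCStage.LOCAL if (onset and stage == CRCStage.NONE) else stage
                        j = space.index(ColonState(nd, nm, nl, new_stage, sym))
                        K[j, i] += p_lesions * pc
    return K


@lru_cache(maxsize=8)
def arrival_shift(cap: int) -> np.ndarray:
    """Operator adding one diminutive adenoma (redirected to the cap)."""
    space = enumerate_states(cap)
    n = len(space)
    S = np.zeros((n, n))
    for i, s in enumerate(space.states):
        j = space.index(replace_count(s, min(cap, s.n_diminutive + 1)))
        S[j, i] = 1.0
    return S


def replace_count(s: ColonState, nd: int) -> ColonState:
    return ColonState(nd, s.n_medium, s.n_large, s.crc_stage, s.symptomatic)


@dataclass(frozen=True)
class KernelOperator:
    """One-month transition operator ``A(p_arrival) @ K_lesion``.

    Kept in factored form so the age-dependent arrival probability can vary
    without re-assembling a matrix: applying to a vector costs one dense
    matvec plus a rank-structured correction.
    """

    lesion: np.ndarray
    shift: np.ndarray
    p_arrival_month: float

    def apply(self, v: np.ndarray) -> np.ndarray:
        w = self.lesion @ v
        if self.p_arrival_month == 0.0:
            return w
        return w + self.p_arrival_month * (self.shift @ w - w)

    def materialize(self) -> np.ndarray:
        n = self.lesion.shape[0]
        A = (1.0 - self.p_arrival_month) * np.eye(n) + self.p_arrival_month * self.shift
        return A @ self.lesion


def build_kernel(
    age: float,
    rates: LesionTransitionRates,
    space: StateSpace,
    step: str = "month",
) -> np.ndarray:
    """Materialize the transition matrix at ``age`` for one step.

    ``step='month'`` gives the monthly kernel; ``step='year'`` the 12-fold
    composition of the monthly kernel with the appearance probability frozen
    at ``age``.  The returned matrix ``K`` satisfies ``v' = K @ v`` and has
    columns summing to 1 (each source state's outgoing probabilities).
    """
    if step not in ("month", "year"):
        raise ValueError(f"unknown step {step!r}")
    p_arr = yearly_to_monthly(adenoma_appearance_probability(age, rates))
    op = KernelOperator(lesion_kernel(rates, space.cap), arrival_shift(space.cap), p_arr)
    K = op.materialize()
    if step == "year":
        K = np.linalg.matrix_power(K, 12)
    return K


# ---------------------------------------------------------------------------
# cohort distribution and propagation


@dataclass
class CohortDistribution:
    """Probability distribution of a cohort over the model's support.

    ``state_probs`` covers the undiagnosed colonic states; ``diagnosed``
    holds mass by (stage, months since diagnosis); the two death
    compartments are absorbing.
    """

    age: float
    space: StateSpace
    state_probs: np.ndarray
    diagnosed: np.ndarray  # (3 stages, DX_MONTHS)
    death_other: float = 0.0
    death_crc: float = 0.0

    @classmethod
    def newborn(cls, space: StateSpace) -> "CohortDistribution":
        v = np.zeros(len(space))
        v[space.no_neoplasia_index] = 1.0
        return cls(age=0.0, space=space, state_probs=v, diagnosed=np.zeros((3, DX_MONTHS)))

    def total(self) -> float:
        return float(
            self.state_probs.sum() + self.diagnosed.sum() + self.death_other + self.death_crc
        )

    def alive_mass(self) -> float:
        return float(self.state_probs.sum() + self.diagnosed.sum())

    def undiagnosed_mass(self) -> float:
        return float(self.state_probs.sum())

    def diagnosed_by_year(self) -> np.ndarray:
        """Diagnosed mass aggregated to (stage, whole years since diagnosis)."""
        n_years = DX_MONTHS // 12
        return self.diagnosed[:, : n_years * 12].reshape(3, n_years, 12).sum(axis=2)

    def copy(self) -> "CohortDistribution":
        return CohortDistribution(
            age=self.age,
            space=self.space,
            state_probs=self.state_probs.copy(),
            diagnosed=self.diagnosed.copy(),
            death_other=self.death_other,
            death_crc=self.death_crc,
        )

    def validate(self, atol: float = 1e-9) -> None:
        if (self.state_probs < -atol).any() or (self.diagnosed < -atol).any():
            raise ValueError("negative probability mass")
        if abs(self.total() - 1.0) > atol:
            raise ValueError(f"total mass {self.total()} != 1")


@dataclass(frozen=True)
class MortalityInputs:
    """Hazard inputs for propagation.

    ``all_cause`` maps age (years) to an annual death rate; ``crc`` maps
    stage name to its post-diagnosis breakpoint hazard.
    """

    all_cause: Callable[[float], float]
    crc: dict

    def crc_monthly_death_probs(self) -> np.ndarray:
        """(3, DX_MONTHS) monthly death probabilities by months since dx."""
        t = np.arange(DX_MONTHS) / 12.0
        out = np.empty((3, DX_MONTHS))
        for row, stage in enumerate(("local", "regional", "distant")):
            h = self.crc[stage]
            k = np.where(t < h.breakpoint, h.k1, h.k2)
            out[row] = 1.0 - np.exp(-k * MONTH)
        return out


@dataclass(frozen=True)
class StepInfo:
    """Mass-flow bookkeeping of one propagation step."""

    deaths_other: float
    deaths_crc: float
    deaths_crc_by_stage: np.ndarray  # (3,)


_crc_prob_cache: dict[tuple, np.ndarray] = {}


def _cached_crc_probs(hazards: MortalityInputs) -> np.ndarray:
    key = tuple(
        (h.k1, h.breakpoint, h.k2) for h in (hazards.crc[s] for s in ("local", "regional", "distant"))
    )
    probs = _crc_prob_cache.get(key)
    if probs is None:
        probs = hazards.crc_monthly_death_probs()
        _crc_prob_cache[key] = probs
    return probs


def propagate(
    dist: CohortDistribution,
    kernel: np.ndarray | KernelOperator,
    hazards: MortalityInputs,
) -> tuple[CohortDistribution, StepInfo]:
    """Advance the cohort by one month.

    Order of operations within the step: (1) all-cause death is applied to
    everyone alive; (2) diagnosed compartments bleed into the CRC death
    compartment per the stage's breakpoint hazard and advance their
    months-since-diagnosis clock; (3) the neoplasia kernel acts on the
    undiagnosed states.  Mass is conserved exactly up to floating-point
    rounding.  Symptom-triggered diagnosis is a separate operation
    (:func:`colocea.observation.symptom_presentation`).
    """
    if isinstance(kernel, np.ndarray) and kernel.shape[0] != len(dist.state_probs):
        raise ValueError("kernel and distribution supports differ")

    out = dist.copy()

    # (1) all-cause mortality competes first within the step
    p_die = 1.0 - math.exp(-hazards.all_cause(dist.age) * MONTH)
    dead_now = p_die * out.state_probs.sum() + p_die * out.diagnosed.sum()
    out.state_probs *= 1.0 - p_die
    out.diagnosed *= 1.0 - p_die
    out.death_other += dead_now

    # (2) CRC mortality on diagnosed survivors, then clock advance
    p_crc = _cached_crc_probs(hazards)
    crc_deaths = out.diagnosed * p_crc
    deaths_by_stage = crc_deaths.sum(axis=1)
    out.diagnosed -= crc_deaths
    out.death_crc += float(deaths_by_stage.sum())
    # advance months-since-diagnosis; the last column absorbs
    out.diagnosed[:, -1] += out.diagnosed[:, -2]
    out.diagnosed[:, 1:-1] = out.diagnosed[:, :-2]
    out.diagnosed[:, 0] = 0.0

    # (3) neoplasia dynamics on the undiagnosed states
    if isinstance(kernel, KernelOperator):
        out.state_probs = kernel.apply(out.state_probs)
    else:
        out.state_probs = kernel @ out.state_probs

    out.age = dist.age + MONTH
    return out, StepInfo(
        deaths_other=float(dead_now),
        deaths_crc=float(deaths_by_stage.sum()),
        deaths_crc_by_stage=deaths_by_stage,
    )
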