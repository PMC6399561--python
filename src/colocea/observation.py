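"""Partial observation of the colon: colonoscopy findings and intervention.

Colonoscopy sees each lesion independently with a size-dependent
sensitivity, so the clinical finding is a noisy function of the true state.
Findings are grouped into the eight categories used clinically: no
adenomas; 1-2 nonadvanced; 3+ nonadvanced; 1-2 with some advanced; 3+ with
some advanced; and local/regional/distant cancer.  "Advanced" is
operationalized as any detected large (>= 10 mm) adenoma.

The intervention is polypectomy plus diagnosis: detected adenomas are
removed, a detected cancer moves to the diagnosed compartment of its true
stage, and anything missed persists unchanged.  Symptomatic cancer is
diagnosed with certainty (symptom-triggered colonoscopy).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from itertools import product

import numpy as np

from .natural_history import ColonState, CohortDistribution, StateSpace, enumerate_states
from .params import CRCStage, SensitivityTable

__all__ = [
    "FindingCategory",
    "ADENOMA_FINDINGS",
    "observe",
    "finding_probabilities",
    "ColonoscopyOperator",
    "apply_colonoscopy",
    "stratify_by_finding",
    "symptom_presentation",
    "condition_healthy_at_screening",
]


class FindingCategory(Enum):
    """The eight clinical colonoscopy finding categories."""

    NO_ADENOMAS = "no adenomas"
    NONADVANCED_1_2 = "1-2 nonadvanced only"
    NONADVANCED_3_PLUS = "3+ nonadvanced only"
    ADVANCED_1_2 = "1-2 with some advanced"
    ADVANCED_3_PLUS = "3+ with some advanced"
    LOCAL_CRC = "local CRC"
    REGIONAL_CRC = "regional CRC"
    DISTANT_CRC = "distant CRC"


#: the five non-cancer strata eligible for scheduled follow-up
ADENOMA_FINDINGS = (
    FindingCategory.NO_ADENOMAS,
    FindingCategory.NONADVANCED_1_2,
    FindingCategory.NONADVANCED_3_PLUS,
    FindingCategory.ADVANCED_1_2,
    FindingCategory.ADVANCED_3_PLUS,
)

_CRC_FINDING = {
    CRCStage.LOCAL: FindingCategory.LOCAL_CRC,
    CRCStage.REGIONAL: FindingCategory.REGIONAL_CRC,
    CRCStage.DISTANT: FindingCategory.DISTANT_CRC,
}


def _category(n_detected: int, any_large: bool, crc_stage: CRCStage | None) -> FindingCategory:
    if crc_stage is not None:
        return _CRC_FINDING[crc_stage]
    if n_detected == 0:
        return FindingCategory.NO_ADENOMAS
    if any_large:
        return FindingCategory.ADVANCED_1_2 if n_detected <= 2 else FindingCategory.ADVANCED_3_PLUS
    return FindingCategory.NONADVANCED_1_2 if n_detected <= 2 else FindingCategory.NONADVANCED_3_PLUS


@dataclass(frozen=True)
class DetectionOutcome:
    """One detection configuration with its probability."""

    detected: tuple[int, int, int]  # (diminutive, medium, large) detected
    crc_detected: bool
    category: FindingCategory
    post_state: ColonState
    probability: float


def _binom_pmf(n: int, k: int, p: float) -> float:
    from math import comb

    return comb(n, k) * p**k * (1.0 - p) ** (n - k)


def observe(state: ColonState, sens: SensitivityTable) -> list[DetectionOutcome]:
    """Enumerate the detection outcomes of a colonoscopy on a true state.

    Each lesion is detected independently with its class sensitivity; an
    asymptomatic cancer is detected with the cancer sensitivity.  The
    finding category is computed from detected lesions only; the post state
    removes detected adenomas (a detected cancer exits to the diagnosed
    compartment, so the post state is only meaningful when the cancer was
    missed or absent).
    """
    outcomes = []
    crc_present = state.crc_stage != CRCStage.NONE
    p_crc = sens.crc if crc_present else 0.0
    for kd, km, kl in product(
        range(state.n_diminutive + 1), range(state.n_medium + 1), range(state.n_large + 1)
    ):
        p_lesions = (
            _binom_pmf(state.n_diminutive, kd, sens.diminutive)
            * _binom_pmf(state.n_medium, km, sens.medium)
            * _binom_pmf(state.n_large, kl, sens.large)
        )
        if p_lesions == 0.0:
            continue
        post = ColonState(
            state.n_diminutive - kd,
            state.n_medium - km,
            state.n_large - kl,
            state.crc_stage,
            state.symptomatic,
        )
        for crc_detected, p_crc_out in ((True, p_crc), (False, 1.0 - p_crc)):
            p = p_lesions * p_crc_out
            if p == 0.0:
                continue
            category = _category(kd + km + kl, kl > 0, state.crc_stage if crc_detected else None)
            outcomes.append(DetectionOutcome((kd, km, kl), crc_detected, category, post, p))
    return outcomes


def finding_probabilities(state: ColonState, sens: SensitivityTable) -> dict[FindingCategory, float]:
    """Marginal probability of each finding category for one true state."""
    probs = {f: 0.0 for f in FindingCategory}
    for o in observe(state, sens):
        probs[o.category] += o.probability
    return probs


class ColonoscopyOperator:
    """Precomputed colonoscopy intervention over a state space.

    For each finding category ``f`` this stores a matrix ``M_f`` mapping the
    pre-colonoscopy state distribution to the joint (finding = f, post
    state) mass, plus the per-category mass of detected (hence diagnosed)
    cancer by stage.  Summing over categories recovers the unconditional
    intervention; individual categories support stratified analyses.
    """

    def __init__(self, space: StateSpace, sens: SensitivityTable):
        self.space = space
        self.sens = sens
        n = len(space)
        cats = list(FindingCategory)
        self._cat_index = {f: k for k, f in enumerate(cats)}
        M = np.zeros((len(cats), n, n))  # post-state mass staying undiagnosed
        D = np.zeros((len(cats), 3, n))  # detected-cancer mass by stage
        for i, s in enumerate(space.states):
            for o in observe(s, sens):
                k = self._cat_index[o.category]
                if o.crc_detected:
                    D[k, int(s.crc_stage) - 1, i] += o.probability
                else:
                    M[k, space.index(o.post_state), i] += o.probability
        self.M = M
        self.D = D

    def apply(
        self, dist: CohortDistribution, categories=None
    ) -> tuple[CohortDistribution, dict[FindingCategory, float]]:
        """Apply colonoscopy to the undiagnosed mass of ``dist``.

        Returns the post-intervention distribution (detected cancers moved
        to months-since-diagnosis zero) and the finding-category
        probabilities.  ``categories`` restricts the result to a subset of
        findings (mass in other findings is dropped, for stratification).
        """
        if categories is None:
            categories = list(FindingCategory)
        out = dist.copy()
        v = dist.state_probs
        post = np.zeros_like(v)
        findings = {}
        for f in categories:
            k = self._cat_index[f]
            undetected_post = self.M[k] @ v
            detected = self.D[k] @ v
            post += undetected_post
            out.diagnosed[:, 0] += detected
            findings[f] = float(undetected_post.sum() + detected.sum())
        out.state_probs = post
        return out, findings


@lru_cache(maxsize=4)
def _cached_operator(cap: int, sens: SensitivityTable) -> ColonoscopyOperator:
    return ColonoscopyOperator(enumerate_states(cap), sens)


def get_operator(space: StateSpace, sens: SensitivityTable) -> ColonoscopyOperator:
    return _cached_operator(space.cap, sens)


def apply_colonoscopy(
    dist: CohortDistribution, sens: SensitivityTable
) -> tuple[CohortDistribution, dict[FindingCategory, float]]:
    """Colonoscopy with polypectomy/diagnosis on a cohort distribution."""
    return get_operator(dist.space, sens).apply(dist)


def stratify_by_finding(
    dist: CohortDistribution, sens: SensitivityTable
) -> dict[FindingCategory, tuple[float, CohortDistribution]]:
    """Per-finding (probability, conditional post distribution) decomposition.

    The conditional distributions are renormalized to unit mass within the
    stratum; categories with zero probability are omitted.
    """
    op = get_operator(dist.space, sens)
    result = {}
    for f in FindingCategory:
        post, findings = op.apply(dist, categories=[f])
        mass = findings[f]
        if mass <= 0.0:
            continue
        strat = post.copy()
        undiag_and_new = strat.state_probs.sum() + strat.diagnosed[:, 0].sum() - dist.diagnosed[:, 0].sum()
        # keep only the mass that went through this finding; other
        # compartments (previously diagnosed, deaths) are not part of the
        # screened population and are zeroed before renormalizing
        strat.diagnosed = strat.diagnosed - dist.diagnosed
        strat.death_other = 0.0
        strat.death_crc = 0.0
        strat.state_probs /= mass
        strat.diagnosed /= mass
        result[f] = (mass, strat)
    return result


def symptom_presentation(dist: CohortDistribution) -> tuple[np.ndarray, CohortDistribution]:
    """Diagnose all currently symptomatic cancer mass.

    Symptom-triggered colonoscopy is assumed perfectly sensitive: the full
    symptomatic mass moves to the diagnosed compartment of its stage with a
    months-since-diagnosis clock of zero.  Returns the per-stage diagnosed
    mass (which is also the probability of a diagnostic colonoscopy this
    step) and the updated distribution.
    """
    out = dist.copy()
    diagnosed = np.zeros(3)
    for row, stage in enumerate((CRCStage.LOCAL, CRCStage.REGIONAL, CRCStage.DISTANT)):
        idx = dist.space.symptomatic_indices(stage)
        mass = out.state_probs[idx].sum()
        if mass > 0.0:
            diagnosed[row] = mass
            out.diagnosed[row, 0] += mass
            out.state_probs[idx] = 0.0
    return diagnosed, out


def condition_healthy_at_screening(dist: CohortDistribution) -> CohortDistribution:
    """Condition the cohort on being screen-eligible.

    Patients who died, became symptomatic, or were already diagnosed are
    removed and the remaining (alive, asymptomatic, undiagnosed) mass is
    renormalized to 1 — each hypothetical patient is considered healthy
    until the screening colonoscopy.
    """
    out = dist.copy()
    sym = dist.space.symptomatic_array()
    out.state_probs[sym] = 0.0
    out.diagnosed[:] = 0.0
    out.death_other = 0.0
    out.death_crc = 0.0
    remaining = out.state_probs.sum()
    if remaining <= 0.0:
        raise ValueError("no surviving asymptomatic mass to condition on")
    out.state_probs /= remaining
    return out
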