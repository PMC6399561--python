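import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from colocea.natural_history import ColonState, CohortDistribution, enumerate_states
from colocea.observation import (
    FindingCategory,
    apply_colonoscopy,
    condition_healthy_at_screening,
    finding_probabilities,
    get_operator,
    observe,
    stratify_by_finding,
    symptom_presentation,
)
from colocea.params import CRCStage, LesionTransitionRates, SensitivityTable


@pytest.fixture(scope="module")
def space():
    return enumerate_states(3)


@pytest.fixture(scope="module")
def sens():
    return SensitivityTable()


def point_mass(space, state):
    dist = CohortDistribution.newborn(space)
    dist.state_probs[:] = 0.0
    dist.state_probs[space.index(state)] = 1.0
    dist.age = 50.0
    return dist


class TestObserve:
    def test_clean_colon_always_reads_clean(self, sens):
        probs = finding_probabilities(ColonState(0, 0, 0), sens)
        assert probs[FindingCategory.NO_ADENOMAS] == 1.0

    def test_single_diminutive_split(self, sens):
        probs = finding_probabilities(ColonState(1, 0, 0), sens)
        assert probs[FindingCategory.NO_ADENOMAS] == pytest.approx(0.61)
        assert probs[FindingCategory.NONADVANCED_1_2] == pytest.approx(0.39)

    def test_two_large_detection_split(self, sens):
        # binomial over two independent detections at 0.958
        outcomes = observe(ColonState(0, 0, 2), sens)
        by_detected = {}
        for o in outcomes:
            by_detected[o.detected[2]] = by_detected.get(o.detected[2], 0.0) + o.probability
        assert by_detected[2] == pytest.approx(0.917764)
        assert by_detected[1] == pytest.approx(0.080472)
        assert by_detected[0] == pytest.approx(0.001764)
        probs = finding_probabilities(ColonState(0, 0, 2), sens)
        assert probs[FindingCategory.ADVANCED_1_2] == pytest.approx(0.917764 + 0.080472)

    def test_marginal_detection_equals_sensitivity(self, sens):
        # for a single lesion of each class the detection probability is the
        # table value exactly
        for state, p in [
            (ColonState(1, 0, 0), sens.diminutive),
            (ColonState(0, 1, 0), sens.medium),
            (ColonState(0, 0, 1), sens.large),
        ]:
            detected = sum(
                o.probability for o in observe(state, sens) if sum(o.detected) == 1
            )
            assert detected == pytest.approx(p, rel=1e-12)

    @given(
        st.integers(0, 3), st.integers(0, 3), st.integers(0, 3),
        st.sampled_from(list(CRCStage)),
    )
    def test_outcomes_sum_to_one(self, nd, nm, nl, stage):
        sens = SensitivityTable()
        state = ColonState(nd, nm, nl, stage, False)
        total = sum(o.probability for o in observe(state, sens))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_crc_category_requires_detected_cancer(self, sens):
        probs = finding_probabilities(ColonState(0, 0, 0, CRCStage.REGIONAL, False), sens)
        assert probs[FindingCategory.REGIONAL_CRC] == pytest.approx(sens.crc)
        assert probs[FindingCategory.NO_ADENOMAS] == pytest.approx(1 - sens.crc)


class TestApplyColonoscopy:
    def test_perfect_sensitivity_clears_colon(self, space):
        perfect = SensitivityTable(1.0, 1.0, 1.0, 1.0)
        dist = point_mass(space, ColonState(2, 1, 3, CRCStage.LOCAL, False))
        post, findings = apply_colonoscopy(dist, perfect)
        assert post.state_probs.sum() == pytest.approx(0.0, abs=1e-15)
        assert post.diagnosed[0, 0] == pytest.approx(1.0)
        assert findings[FindingCategory.LOCAL_CRC] == pytest.approx(1.0)

    def test_zero_sensitivity_changes_nothing(self, space):
        blind = SensitivityTable(0.0, 0.0, 0.0, 0.0)
        dist = point_mass(space, ColonState(2, 1, 0, CRCStage.LOCAL, False))
        post, findings = apply_colonoscopy(dist, blind)
        assert np.allclose(post.state_probs, dist.state_probs)
        assert findings[FindingCategory.NO_ADENOMAS] == pytest.approx(1.0)

    def test_mixed_state_brute_force(self, space, sens):
        # (1 diminutive, 1 large): four detection configurations
        dist = point_mass(space, ColonState(1, 0, 1))
        post, findings = apply_colonoscopy(dist, sens)
        p_both = 0.39 * 0.958
        assert post.state_probs[space.no_neoplasia_index] == pytest.approx(p_both)
        assert post.state_probs[space.index(ColonState(1, 0, 0))] == pytest.approx(0.61 * 0.958)
        assert post.state_probs[space.index(ColonState(0, 0, 1))] == pytest.approx(0.39 * 0.042)
        assert post.state_probs[space.index(ColonState(1, 0, 1))] == pytest.approx(0.61 * 0.042)
        assert findings[FindingCategory.ADVANCED_1_2] == pytest.approx(
            0.958
        )  # any outcome detecting the large lesion

    def test_mass_conserved_and_counts_never_increase(self, space, sens, pipeline):
        dist = pipeline.screen_eligible(50)
        post, findings = apply_colonoscopy(dist, sens)
        assert post.total() == pytest.approx(1.0, abs=1e-12)
        assert sum(findings.values()) == pytest.approx(1.0, abs=1e-12)
        # operator structure: no flow from a state to one with more lesions
        op = get_operator(space, sens)
        nd, nm, nl = space.counts()
        total = nd + nm + nl
        for k in range(op.M.shape[0]):
            rows, cols = np.nonzero(op.M[k])
            assert (total[rows] <= total[cols]).all()


class TestSymptomPresentation:
    def test_no_crc_mass_no_diagnoses(self, space):
        dist = point_mass(space, ColonState(1, 1, 0))
        diagnosed, out = symptom_presentation(dist)
        assert diagnosed.sum() == 0.0
        assert np.array_equal(out.state_probs, dist.state_probs)

    def test_local_symptom_onset_compounds_to_yearly_017(self, space, config):
        # isolate the symptom transition: only the local symptom rate is
        # non-zero, so after 12 monthly kernel steps the diagnosed fraction
        # is the yearly probability
        from colocea.natural_history import MortalityInputs, build_kernel, propagate

        rates = LesionTransitionRates(
            appearance_max=0.0,
            diminutive_to_none=0.0, diminutive_to_medium=0.0,
            medium_to_diminutive=0.0, medium_to_large=0.0, medium_to_crc=0.0,
            large_to_medium=0.0, large_to_crc=0.0,
            local_to_regional=0.0, regional_to_distant=0.0,
            symptoms_local=0.17, symptoms_regional=0.0, symptoms_distant=0.0,
        )
        from colocea.params import BreakpointHazard

        K = build_kernel(50.0, rates, space, "month")
        dist = point_mass(space, ColonState(0, 0, 0, CRCStage.LOCAL, False))
        no_crc_death = {
            s: BreakpointHazard(s, 0.0, 5.0, 0.0)
            for s in ("local", "regional", "distant", "unknown")
        }
        hz = MortalityInputs(all_cause=lambda a: 0.0, crc=no_crc_death)
        for _ in range(12):
            dist, _ = propagate(dist, K, hz)
            _, dist = symptom_presentation(dist)
        assert dist.diagnosed.sum() == pytest.approx(0.17, rel=1e-8)

    def test_symptomatic_mass_fully_diagnosed(self, space):
        dist = point_mass(space, ColonState(0, 0, 0, CRCStage.DISTANT, True))
        diagnosed, out = symptom_presentation(dist)
        assert diagnosed[2] == pytest.approx(1.0)
        assert out.diagnosed[2, 0] == pytest.approx(1.0)
        assert out.state_probs.sum() == 0.0


class TestConditioning:
    def test_identity_when_nothing_to_remove(self, space):
        dist = point_mass(space, ColonState(1, 0, 0))
        out = condition_healthy_at_screening(dist)
        assert np.allclose(out.state_probs, dist.state_probs)

    def test_renormalization_arithmetic(self, space):
        dist = point_mass(space, ColonState(1, 0, 0))
        dist.state_probs *= 0.8
        dist.death_other = 0.2
        out = condition_healthy_at_screening(dist)
        assert out.state_probs[space.index(ColonState(1, 0, 0))] == pytest.approx(1.0)
        assert out.total() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_cohort_rejected(self, space):
        dist = point_mass(space, ColonState(0, 0, 0))
        dist.state_probs[:] = 0.0
        dist.death_other = 1.0
        with pytest.raises(ValueError):
            condition_healthy_at_screening(dist)

    def test_finding_distribution_sums_to_one(self, pipeline):
        eligible = pipeline.screen_eligible(50)
        strata = stratify_by_finding(eligible, pipeline.config.sensitivity)
        assert sum(m for m, _ in strata.values()) == pytest.approx(1.0, abs=1e-9)
        for mass, dist in strata.values():
            assert dist.total() == pytest.approx(1.0, abs=1e-9)


class TestOracleAgreement:
    def test_finding_shares_match_microsim(self, pipeline, micro_full):
        # screening-finding distribution at age 50 vs the Monte-Carlo twin
        scenario, micro = micro_full
        cohort = pipeline.run(scenario)
        shares = micro.finding_shares()
        for f, p in cohort.finding_probs.items():
            mean, se = shares[f]
            n = micro.findings.size
            se_model = max(np.sqrt(p * (1 - p) / n), 1e-12)
            assert abs(p - mean) < 3 * max(se, se_model) + 1e-12
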