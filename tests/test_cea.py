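import numpy as np
import pandas as pd
import pytest

from colocea.cea import (
    Pipeline,
    Scenario,
    ScenarioResult,
    cost_effective_window,
    icer,
    optimal_interval,
    quadratic_vertex,
    recommend,
)
from colocea.observation import FindingCategory
from colocea.params import LesionTransitionRates, SensitivityTable


def _result(cost, qalys):
    return ScenarioResult(
        scenario=Scenario(), total_cost=cost, total_qalys=qalys,
        ledger=pd.DataFrame(), finding_probs={},
    )


def _table(intervals, icers, dqalys=None):
    icers = np.asarray(icers, dtype=float)
    dq = np.ones_like(icers) * 1e-3 if dqalys is None else np.asarray(dqalys, dtype=float)
    return pd.DataFrame(
        {
            "interval": np.asarray(intervals, dtype=float),
            "delta_cost": icers * dq,
            "delta_qaly": dq,
            "icer": icers,
            "flag": ["ok"] * len(icers),
        }
    )


class TestICER:
    def test_arithmetic(self):
        r = icer(_result(1100.0, 10.001), _result(1000.0, 10.0))
        assert r.value == pytest.approx(100_000.0)
        assert r.flag == "ok"

    def test_identical_scenarios_undefined(self):
        with pytest.raises(ZeroDivisionError):
            icer(_result(1000.0, 10.0), _result(1000.0, 10.0))

    def test_dominant_and_dominated_flags(self):
        assert icer(_result(900.0, 10.1), _result(1000.0, 10.0)).flag == "dominant"
        assert icer(_result(1100.0, 9.9), _result(1000.0, 10.0)).flag == "dominated"


class TestQuadraticVertex:
    def test_worked_triple(self):
        xv, yv = quadratic_vertex(np.array([6.0, 8.0, 10.0]), np.array([10.0, 12.0, 11.0]))
        assert xv == pytest.approx(8.0 + 2.0 * (10.0 - 11.0) / (2.0 * (10.0 - 24.0 + 11.0)))
        assert xv == pytest.approx(8.333333, abs=1e-6)

    def test_symmetric_points(self):
        xv, _ = quadratic_vertex(np.array([6.0, 8.0, 10.0]), np.array([1.0, 2.0, 1.0]))
        assert xv == pytest.approx(8.0)

    def test_collinear_degenerates(self):
        assert quadratic_vertex(np.array([6.0, 8.0, 10.0]), np.array([1.0, 2.0, 3.0])) is None


class TestWindow:
    def test_all_above_threshold_is_empty(self):
        w = cost_effective_window(_table([2, 4, 6], [150e3, 140e3, 130e3]), 100e3)
        assert w.empty

    def test_infinite_threshold_spans_grid(self):
        w = cost_effective_window(_table(range(2, 21, 2), [9e4] * 10), np.inf)
        assert (w.lo, w.hi) == (2.0, 20.0)

    def test_interpolated_lower_endpoint(self):
        # ICER falls from 120k at 6y to 80k at 8y; crosses 100k at 7y
        table = _table([2, 4, 6, 8, 10], [200e3, 150e3, 120e3, 80e3, 70e3])
        w = cost_effective_window(table, 100e3)
        assert w.lo == pytest.approx(6 + 2 * (120e3 - 100e3) / (120e3 - 80e3))
        assert w.lo == pytest.approx(7.0)
        assert w.hi == 10.0
        assert w.members == (8.0, 10.0)

    def test_interpolated_upper_endpoint(self):
        table = _table([2, 4, 6], [90e3, 95e3, 105e3])
        w = cost_effective_window(table, 100e3)
        assert w.lo == 2.0
        assert w.hi == pytest.approx(4 + 2 * (100e3 - 95e3) / (105e3 - 95e3))

    def test_negative_qaly_gain_never_eligible(self):
        table = _table([2, 4], [50e3, 60e3], dqalys=[-1e-3, 1e-3])
        w = cost_effective_window(table, 100e3)
        assert w.members == (4.0,)


class TestOptimalInterval:
    def test_interior_maximum_interpolates(self):
        table = _table(
            [2, 4, 6, 8, 10], [90e3] * 5, dqalys=[0.5e-3, 0.8e-3, 1.0e-3, 1.2e-3, 1.1e-3]
        )
        w = cost_effective_window(table, 100e3)
        rec = optimal_interval(table, w)
        xv, yv = quadratic_vertex(
            np.array([6.0, 8.0, 10.0]), np.array([1.0e-3, 1.2e-3, 1.1e-3])
        )
        assert rec.interval == pytest.approx(xv)
        assert rec.delta_qaly == pytest.approx(yv)
        assert rec.delta_qaly_per_10k == pytest.approx(yv * 1e4)
        assert rec.flag == "interpolated"

    def test_boundary_maximum_flagged(self):
        table = _table([2, 4, 6], [90e3] * 3, dqalys=[3e-3, 2e-3, 1e-3])
        w = cost_effective_window(table, 100e3)
        rec = optimal_interval(table, w)
        assert rec.interval == 2.0 and rec.flag == "boundary"

    def test_collinear_returns_grid_max(self):
        table = _table([2, 4, 6], [90e3] * 3, dqalys=[1e-3, 2e-3, 3e-3])
        rec = optimal_interval(table, cost_effective_window(table, 100e3))
        assert rec.interval == 6.0 and rec.flag == "boundary"

    def test_empty_window_rejected(self):
        table = _table([2, 4], [150e3, 160e3])
        with pytest.raises(ValueError):
            optimal_interval(table, cost_effective_window(table, 100e3))

    def test_vertex_outside_window_clamps(self):
        # maximum at the first in-window point with a vertex to its left
        table = _table(
            [2, 4, 6, 8], [120e3, 99e3, 95e3, 94e3], dqalys=[1.3e-3, 1.2e-3, 1.0e-3, 0.8e-3]
        )
        w = cost_effective_window(table, 100e3)
        rec = optimal_interval(table, w)
        assert rec.flag == "clamped"
        assert rec.interval == pytest.approx(w.lo)


class TestScenarioPipeline:
    def test_inert_interventions_leave_qalys_unchanged(self, config):
        # zero sensitivity and zero symptom rates: colonoscopies see and
        # remove nothing and no symptomatic diagnosis occurs, so follow-up
        # cannot change QALYs
        rates = LesionTransitionRates(
            symptoms_local=0.0, symptoms_regional=0.0, symptoms_distant=0.0
        )
        cfg = config.with_(
            rates=rates, sensitivity=SensitivityTable(0.0, 0.0, 0.0, 0.0)
        )
        pipe = Pipeline(cfg)
        control = pipe.run(Scenario(screen_age=50.0))
        followed = pipe.run(Scenario(screen_age=50.0, follow_up_ages=(58.0,)))
        assert followed.total_qalys == pytest.approx(control.total_qalys, abs=1e-9)
        assert followed.total_cost > control.total_cost  # the extra procedure

    def test_follow_up_costs_more_when_crc_costs_are_zero(self, config):
        from colocea.params import Bounded, CostTables

        zero_crc = CostTables(
            initial={s: Bounded(0.0) for s in ("local", "regional", "distant")},
            surveillance={s: Bounded(0.0) for s in ("local", "regional", "distant")},
            terminal=Bounded(0.0),
        )
        pipe = Pipeline(config.with_(costs=zero_crc))
        control = pipe.run(Scenario(screen_age=50.0))
        followed = pipe.run(Scenario(screen_age=50.0, follow_up_ages=(58.0,)))
        assert followed.total_cost > control.total_cost

    def test_zero_probability_stratum_dropped(self, pipeline):
        # a lesion-free cohort cannot yield a cancer finding: the stratum is
        # absent from the decomposition rather than present with zero mass
        from colocea.natural_history import CohortDistribution
        from colocea.observation import stratify_by_finding

        dist = CohortDistribution.newborn(pipeline.space)
        dist.age = 50.0
        strata = stratify_by_finding(dist, pipeline.config.sensitivity)
        assert FindingCategory.DISTANT_CRC not in strata
        assert list(strata) == [FindingCategory.NO_ADENOMAS]

    def test_windows_nested_across_thresholds(self, age50_table):
        windows = {
            thr: cost_effective_window(age50_table, thr) for thr in (50e3, 75e3, 100e3)
        }
        for lo_thr, hi_thr in [(50e3, 75e3), (75e3, 100e3)]:
            wl, wh = windows[lo_thr], windows[hi_thr]
            if wl.empty:
                continue
            assert not wh.empty
            assert wh.lo <= wl.lo and wh.hi >= wl.hi

    def test_icer_strictly_increasing_in_colonoscopy_cost(self, pipeline):
        base_control = pipeline.run(Scenario(screen_age=50.0))
        high_control = pipeline.run(Scenario(screen_age=50.0, colonoscopy_cost="high"))
        base = pipeline.run(Scenario(screen_age=50.0, follow_up_ages=(58.0,)))
        high = pipeline.run(
            Scenario(screen_age=50.0, follow_up_ages=(58.0,), colonoscopy_cost="high")
        )
        r_base = icer(base, base_control)
        r_high = icer(high, high_control)
        assert r_high.delta_qaly == pytest.approx(r_base.delta_qaly, rel=1e-12)
        assert r_high.value > r_base.value

    def test_recommendation_scale_invariance(self, config):
        # doubling every cost and the threshold leaves the recommended
        # interval unchanged
        from colocea.params import Bounded, CostTables

        def scale(b, f):
            return Bounded(b.base * f, None if b.low is None else b.low * f,
                           None if b.high is None else b.high * f)

        doubled = CostTables(
            colonoscopy=scale(config.costs.colonoscopy, 2.0),
            adverse_events=scale(config.costs.adverse_events, 2.0),
            initial={s: scale(b, 2.0) for s, b in config.costs.initial.items()},
            surveillance={s: scale(b, 2.0) for s, b in config.costs.surveillance.items()},
            terminal=scale(config.costs.terminal, 2.0),
        )
        intervals = (6, 8, 10, 12)
        base_pipe = Pipeline(config)
        out1 = recommend(base_pipe, 50.0, threshold=100e3, intervals=intervals)
        out2 = recommend(Pipeline(config.with_(costs=doubled)), 50.0,
                         threshold=200e3, intervals=intervals)
        assert out2.recommended.interval == pytest.approx(out1.recommended.interval, abs=1e-9)

    def test_stratified_recommendations_stay_inside_windows(self, strata_outcomes):
        for f, outcome in strata_outcomes.items():
            assert not outcome.window.empty
            rec = outcome.recommended
            assert 2.0 <= rec.interval <= 20.0
            assert outcome.window.lo - 1e-9 <= rec.interval <= outcome.window.hi + 1e-9

    def test_advanced_findings_have_later_windows(self, strata_outcomes):
        # strata with advanced findings become cost-effective later than the
        # no-neoplasia stratum, mirroring their lower marginal benefit after
        # polypectomy
        lo_none = strata_outcomes[FindingCategory.NO_ADENOMAS].window.lo
        for f in (FindingCategory.ADVANCED_1_2, FindingCategory.ADVANCED_3_PLUS):
            assert strata_outcomes[f].window.lo >= lo_none


class TestCohortOracleEquivalence:
    def test_totals_match_microsimulation(self, pipeline, micro_full):
        scenario, micro = micro_full
        cohort = pipeline.run(scenario)
        s = micro.summary
        assert abs(cohort.total_qalys - s["qalys_mean"]) < 3 * s["qalys_se"]
        assert abs(cohort.total_cost - s["cost_mean"]) < 3 * s["cost_se"]
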