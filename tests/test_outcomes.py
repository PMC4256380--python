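"""Outcome metrics: cumulative incidence, LE, HALE, and replicate
aggregation."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcasim
from pcasim.engine import CohortResult, run_replicate
from pcasim.outcomes import aggregate, default_strata, replicate_summary, summarize_run
from pcasim.parameters import UtilityWeights
from pcasim.states import DeathCause, HealthState, RiskGroup, Strategy

from .conftest import make_simple_params

H = HealthState


def fake_result(params, death_years, causes, rec_years=None, yis=None, last_state=None):
    """Hand-built cohort result for arithmetic checks."""
    n = len(death_years)
    res = CohortResult(params, np.zeros(n, np.int8), np.full(n, int(Strategy.RP), np.int8),
                       params.n_cycles())
    res.death_year = np.asarray(death_years, np.int32)
    res.death_cause = np.asarray(causes, np.int8)
    if rec_years is not None:
        res.recurrence_year = np.asarray(rec_years, np.int32)
    if yis is not None:
        res.years_in_state = np.asarray(yis, np.int32)
    if last_state is not None:
        res.last_state = np.asarray(last_state, np.int8)
    return res


OTHER, PCA = int(DeathCause.OTHER), int(DeathCause.PCA)


class TestCumulativeIncidence:
    def test_share_with_event_by_horizon(self, simple_params):
        rec = [3, 5, 0, 0, 6, 0, 0, 0, 0, 0]
        res = fake_result(simple_params, [10] * 10, [OTHER] * 10, rec_years=rec)
        assert pcasim.cumulative_incidence(res, "recurrence", 5) == 20.0
        assert pcasim.cumulative_incidence(res, "recurrence", 6) == 30.0

    def test_death_partition_at_lifetime(self, simple_params):
        res = fake_result(simple_params, [5, 8, 20], [PCA, OTHER, OTHER])
        pca = pcasim.cumulative_incidence(res, "pca_death", "lifetime")
        other = pcasim.cumulative_incidence(res, "overall_death", "lifetime")
        assert pca + other == pytest.approx(100.0)

    def test_monotone_in_horizon(self, base):
        small = copy.deepcopy(base)
        small.cohort_size = 2000
        res = run_replicate(small, 13)
        for event in pcasim.outcomes.EVENTS:
            values = [pcasim.cumulative_incidence(res, event, h) for h in range(1, 41)]
            assert all(a <= b for a, b in zip(values, values[1:]))

    def test_empty_stratum_is_undefined(self, simple_params):
        res = fake_result(simple_params, [5], [OTHER])
        with pytest.warns(UserWarning, match="empty stratum"):
            out = pcasim.cumulative_incidence(res, "recurrence", 5, RiskGroup.HIGH)
        assert np.isnan(out)


class TestLifeExpectancy:
    def test_everyone_dies_in_first_cycle(self, simple_params):
        res = fake_result(simple_params, [1, 1, 1], [OTHER] * 3)
        assert pcasim.life_expectancy(res) == 1.0

    def test_unabsorbed_records_rejected(self, simple_params):
        res = fake_result(simple_params, [5, 0], [OTHER, 0])
        with pytest.raises(ValueError, match="lifetime"):
            pcasim.life_expectancy(res)

    def test_overall_is_risk_weighted_mean(self, base):
        small = copy.deepcopy(base)
        small.cohort_size = 3000
        res = run_replicate(small, 21)
        per_group = [
            (np.count_nonzero(res.risk == int(g)), pcasim.life_expectancy(res, g))
            for g in RiskGroup
        ]
        weighted = sum(n * le for n, le in per_group) / sum(n for n, _ in per_group)
        assert pcasim.life_expectancy(res) == pytest.approx(weighted)


class TestHale:
    def test_single_state_scaling(self, simple_params):
        # 10 years in recurrence-free at utility 0.90, other-cause death
        yis = np.zeros((3, len(H)), int)
        yis[:, int(H.RECURRENCE_FREE)] = 10
        res = fake_result(simple_params, [10] * 3, [OTHER] * 3, yis=yis,
                          last_state=[int(H.RECURRENCE_FREE)] * 3)
        assert pcasim.hale(res) == pytest.approx(0.90 * 10)

    def test_unit_utilities_reduce_to_life_expectancy(self, simple_params):
        yis = np.zeros((2, len(H)), int)
        yis[:, int(H.RECURRENCE_FREE)] = 7
        res = fake_result(simple_params, [7, 7], [OTHER] * 2, yis=yis,
                          last_state=[int(H.RECURRENCE_FREE)] * 2)
        ones = UtilityWeights(1.0, 1.0, 1.0, 1.0)
        assert pcasim.hale(res, utilities=ones) == pcasim.life_expectancy(res)

    def test_hand_built_three_year_record(self, simple_params):
        """Treatment year + recurrence-free year + metastatic death year:
        0.88 + 0.90 + 0.50 (the end-of-life weight replaces the mCRPC
        weight in the death year)."""
        yis = np.zeros((1, len(H)), int)
        yis[0, int(H.ACTIVE_TREATMENT)] = 1
        yis[0, int(H.RECURRENCE_FREE)] = 1
        yis[0, int(H.MCRPC)] = 1
        res = fake_result(simple_params, [3], [PCA], yis=yis, last_state=[int(H.MCRPC)])
        assert pcasim.hale(res) == pytest.approx(0.88 + 0.90 + 0.50)

    @settings(max_examples=25, deadline=None)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
    )
    def test_never_exceeds_life_expectancy(self, base, u1, u2, u3, u4):
        small = copy.deepcopy(base)
        small.cohort_size = 400
        res = run_replicate(small, 3)
        utilities = UtilityWeights(u1, u2, u3, u4)
        assert pcasim.hale(res, utilities=utilities) <= pcasim.life_expectancy(res) + 1e-12


class TestAggregate:
    def test_constant_replicates(self):
        est = aggregate([4.2] * 10)
        assert (est.mean, est.lower95, est.upper95) == pytest.approx((4.2, 4.2, 4.2))

    def test_percentile_bounds(self):
        # frozen from the linear-interpolation percentile definition:
        # 2.5th/97.5th percentiles of 1..100 are 3.475 and 97.525
        est = aggregate(np.arange(1, 101, dtype=float))
        assert est.mean == pytest.approx(50.5)
        assert est.lower95 == pytest.approx(3.475)
        assert est.upper95 == pytest.approx(97.525)

    def test_normal_intervals_bracket_mean(self):
        est = aggregate([1.0, 2.0, 3.0, 4.0], method="normal")
        assert est.lower95 < est.mean < est.upper95

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="at least 2"):
            aggregate([1.0])

    def test_interval_width_scales_with_cohort_size(self):
        """Replicate spread of a percentage shrinks like 1/sqrt(n)
        (binomial sampling)."""
        def spread(n_cohort):
            params = make_simple_params(p_rec=0.1, cohort_size=n_cohort, horizon=10,
                                        max_cycles=10)
            vals = [
                pcasim.cumulative_incidence(r, "recurrence", 10)
                for r in pcasim.run_model(params, 60, seed=7)
            ]
            return np.std(vals, ddof=1)

        ratio = spread(400) / spread(3600)
        assert 2.0 < ratio < 4.5  # ideal ratio 3


class TestSummaries:
    def test_replicate_summary_covers_every_cell_class(self, base):
        """The writer can emit every (stratum x horizon x event) cell plus
        LE and HALE."""
        small = copy.deepcopy(base)
        small.cohort_size = 600
        res = run_replicate(small, 2)
        df = replicate_summary(res)
        strata = {"overall", "low", "intermediate", "high"} | {
            "low/AS", "low/RP", "low/IMRT", "low/BT",
            "intermediate/RP", "intermediate/IMRT", "intermediate/IMRT_ADT",
            "intermediate/IMRT_BT", "high/IMRT_ADT", "high/IMRT_ADT_BT",
        }
        assert set(df["stratum"]) == strata
        for stratum in strata:
            sub = df[df["stratum"] == stratum]
            assert set(sub["horizon"]) == {"5", "10", "15", "lifetime"}
            assert {"pct_recurrence", "pct_mcrpc", "pct_pca_death", "pct_overall_death",
                    "life_expectancy", "hale"} <= set(sub["metric"])

    def test_summarize_run_aggregates(self, base):
        small = copy.deepcopy(base)
        small.cohort_size = 400
        out = summarize_run(small, 5, seed=3, horizons=(5,), strata=[None])
        assert set(out.columns) >= {"stratum", "horizon", "metric", "mean",
                                    "lower95", "upper95", "n_replicates", "seed"}
        assert (out["n_replicates"] == 5).all()
        assert (out["lower95"] <= out["mean"] + 1e-12).all()
        assert (out["mean"] <= out["upper95"] + 1e-12).all()
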