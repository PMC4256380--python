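"""Microsimulation engine: strategy assignment, exit partitions,
stepping, and whole-replicate invariants."""

import copy

import numpy as np
import pytest

from pcasim.engine import (
    assign_strategy,
    cohort_composition,
    exit_probabilities,
    run_replicate,
    simulate_patient,
    step,
    PatientProfile,
)
from pcasim.parameters import base_case
from pcasim.states import DeathCause, HealthState, RiskGroup, Strategy

from .conftest import make_simple_params

G, S, H = RiskGroup, Strategy, HealthState


class FakeRng:
    """Deterministic stand-in yielding a scripted sequence of uniforms."""

    def __init__(self, *values):
        self.values = list(values)

    def random(self, size=None):
        if size is None:
            return self.values.pop(0)
        out = np.array(self.values[:size])
        del self.values[:size]
        return out


class TestCohortComposition:
    def test_printed_cohort_split(self, base):
        counts = cohort_composition(base.cohort_size, base.risk_fractions)
        assert counts == {G.LOW: 7080, G.INTERMEDIATE: 4248, G.HIGH: 2832}

    def test_exact_proportions(self, base):
        counts = cohort_composition(10, base.risk_fractions)
        assert counts == {G.LOW: 5, G.INTERMEDIATE: 3, G.HIGH: 2}

    def test_largest_remainder_conserves_total(self, base):
        for n in (1, 7, 99, 1001):
            counts = cohort_composition(n, base.risk_fractions)
            assert sum(counts.values()) == n


class TestAssignStrategy:
    def test_low_draw_below_allocation_gets_surveillance(self, base):
        # AS is first in enum order with allocation 0.10
        assert assign_strategy(G.LOW, base, FakeRng(0.05)) == S.AS
        assert assign_strategy(G.LOW, base, FakeRng(0.15)) == S.RP

    def test_high_risk_only_gets_permitted_strategies(self, base, rng):
        drawn = {assign_strategy(G.HIGH, base, rng) for _ in range(500)}
        assert drawn <= {S.IMRT_ADT, S.IMRT_ADT_BT}

    def test_empirical_frequencies_match_allocations(self, base, rng):
        n = 100_000
        for g in G:
            counts = {}
            for _ in range(n):
                s = assign_strategy(g, base, rng)
                counts[s] = counts.get(s, 0) + 1
            for s, frac in base.allocations[g].items():
                sd = np.sqrt(frac * (1 - frac) / n)
                assert counts.get(s, 0) / n == pytest.approx(frac, abs=3 * sd + 1e-12)


class TestExitProbabilities:
    def test_recurrence_state_partition(self, base):
        out = exit_probabilities(H.RECURRENCE, G.LOW, S.RP, False, 3, base)
        assert out[H.MCRPC] == 0.07
        assert out[H.OVERALL_DEATH] == 0.02
        assert out[H.RECURRENCE] == pytest.approx(0.91)

    def test_mcrpc_excludes_other_cause_death(self, base):
        out = exit_probabilities(H.MCRPC, G.HIGH, S.IMRT_ADT, False, 3, base)
        assert out == {H.PCA_DEATH: 0.27, H.MCRPC: pytest.approx(0.73)}
        assert H.OVERALL_DEATH not in out

    def test_treatment_tunnel_exits_to_recurrence_free(self, base):
        out = exit_probabilities(H.ACTIVE_TREATMENT, G.HIGH, S.IMRT_ADT, False, 1, base)
        assert out[H.OVERALL_DEATH] == 0.02
        assert out[H.RECURRENCE_FREE] == pytest.approx(0.98)

    def test_partition_sums_to_one_everywhere(self, base):
        for state in (H.ACTIVE_SURVEILLANCE, H.ACTIVE_TREATMENT, H.RECURRENCE_FREE,
                      H.RECURRENCE, H.MCRPC):
            for cycle in (1, 3, 8, 13, 18, 25, 60):
                for post_as in (False, True):
                    out = exit_probabilities(state, G.LOW, S.RP, post_as, cycle, base)
                    assert sum(out.values()) == pytest.approx(1.0)
                    assert all(p >= 0 for p in out.values())

    def test_absorbing_state_rejected(self, base):
        with pytest.raises(ValueError, match="absorbing"):
            exit_probabilities(H.PCA_DEATH, G.LOW, S.RP, False, 1, base)


class TestStep:
    def test_residual_draw_stays(self, base):
        nxt = step(H.RECURRENCE, G.LOW, S.RP, False, 3, base, FakeRng(0.999))
        assert nxt == H.RECURRENCE

    def test_draw_order_is_event_death_stay(self, base):
        # recurrence partition at cycle 3: [mCRPC 0.07 | death 0.02 | stay]
        assert step(H.RECURRENCE, G.LOW, S.RP, False, 3, base, FakeRng(0.05)) == H.MCRPC
        assert step(H.RECURRENCE, G.LOW, S.RP, False, 3, base, FakeRng(0.08)) == H.OVERALL_DEATH
        assert step(H.RECURRENCE, G.LOW, S.RP, False, 3, base, FakeRng(0.10)) == H.RECURRENCE

    def test_empirical_step_distribution(self, base, rng):
        n = 100_000
        draws = [step(H.RECURRENCE, G.LOW, S.RP, False, 3, base, rng) for _ in range(n)]
        expected = {H.MCRPC: 0.07, H.OVERALL_DEATH: 0.02, H.RECURRENCE: 0.91}
        for state, p in expected.items():
            sd = np.sqrt(p * (1 - p) / n)
            assert draws.count(state) / n == pytest.approx(p, abs=3 * sd)


class TestSimulatePatient:
    def test_forced_death_in_first_cycle(self):
        params = make_simple_params(p_od=0.5)
        profile = PatientProfile(0, G.LOW, S.RP)
        rec = simulate_patient(profile, params, FakeRng(0.0))
        assert len(rec.states) == 1
        assert rec.states == [H.ACTIVE_TREATMENT]
        assert rec.trackers.death_year == 1
        assert rec.trackers.death_cause == DeathCause.OTHER

    def test_metastasis_requires_prior_recurrence(self, rng):
        params = make_simple_params(p_rec=0.2, p_mcrpc=0.3)
        profile = PatientProfile(0, G.LOW, S.RP)
        seen = 0
        for _ in range(300):
            rec = simulate_patient(profile, params, rng)
            trk = rec.trackers
            if trk.mcrpc_year:
                seen += 1
                assert 0 < trk.recurrence_year <= trk.mcrpc_year
                if trk.death_cause == DeathCause.PCA:
                    assert trk.mcrpc_year <= trk.death_year
        assert seen > 10  # the pathway was actually exercised

    def test_fixed_seed_reproduces_record(self, base):
        profile = PatientProfile(7, G.LOW, S.AS)
        a = simulate_patient(profile, base, np.random.default_rng(5))
        b = simulate_patient(profile, base, np.random.default_rng(5))
        assert a.states == b.states
        assert a.trackers == b.trackers


class TestRunReplicate:
    def test_cohort_counts_and_legal_strategies(self, base):
        result = run_replicate(base, 1)
        assert result.n == 14_160
        for g in G:
            assert int((result.risk == int(g)).sum()) == {
                G.LOW: 7080, G.INTERMEDIATE: 4248, G.HIGH: 2832,
            }[g]
        from pcasim.parameters import PERMITTED_STRATEGIES
        for g in G:
            used = set(result.strategy[result.risk == int(g)].tolist())
            assert used <= {int(s) for s in PERMITTED_STRATEGIES[g]}

    def test_seed_determinism(self, base):
        small = copy.deepcopy(base)
        small.cohort_size = 500
        a = run_replicate(small, 11)
        b = run_replicate(small, 11)
        for attr in ("risk", "strategy", "recurrence_year", "mcrpc_year",
                     "death_year", "death_cause", "years_in_state"):
            np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))

    def test_occupancy_conservation_and_absorption(self, base):
        small = copy.deepcopy(base)
        small.cohort_size = 2000
        result = run_replicate(small, 3, record_history=True)
        hist = result.state_history
        # exactly one state per patient per cycle, counts sum to cohort size
        counts = np.array(
            [[np.count_nonzero(hist[:, k] == int(s)) for s in H] for k in range(hist.shape[1])]
        )
        assert (counts.sum(axis=1) == small.cohort_size).all()
        # absorbing states are constant once entered
        for dead in (H.PCA_DEATH, H.OVERALL_DEATH):
            entered = hist == int(dead)
            first = entered.argmax(axis=1)
            for i in np.nonzero(entered.any(axis=1))[0]:
                assert (hist[i, first[i]:] == int(dead)).all()
        # the metastatic state is never followed by other-cause death
        prev, nxt = hist[:, :-1], hist[:, 1:]
        assert not ((prev == int(H.MCRPC)) & (nxt == int(H.OVERALL_DEATH))).any()

    def test_lifetime_run_absorbs_everyone(self, base):
        result = run_replicate(base, 2)
        assert result.all_absorbed
        assert (result.death_cause != int(DeathCause.NONE)).all()

    def test_finite_horizon_leaves_survivors_unabsorbed(self, base):
        short = copy.deepcopy(base)
        short.horizon = 5
        short.cohort_size = 1000
        result = run_replicate(short, 4)
        assert not result.all_absorbed
        assert (result.death_year == 0).any()

    def test_per_cycle_transition_frequencies_recover_partition(self):
        """Empirical exits out of the recurrence state match the
        configured partition within binomial sampling error."""
        params = make_simple_params(p_rec=0.3, p_mcrpc=0.1, p_od=0.05, cohort_size=8000)
        result = run_replicate(params, 9, record_history=True)
        hist = result.state_history
        at_risk = hist[:, :-1] == int(H.RECURRENCE)
        n_at_risk = int(at_risk.sum())
        nxt = hist[:, 1:][at_risk]
        for to_state, p in ((H.MCRPC, 0.1), (H.OVERALL_DEATH, 0.05), (H.RECURRENCE, 0.85)):
            frac = np.count_nonzero(nxt == int(to_state)) / n_at_risk
            sd = np.sqrt(p * (1 - p) / n_at_risk)
            assert frac == pytest.approx(p, abs=3 * sd)
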