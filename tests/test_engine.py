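"""Stochastic engine: bookkeeping, exact SSA oracles, tau-leap consistency."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from cmlsim import EvolutionParams, ExchangeParams, make_toy_hierarchy
from cmlsim.engine import (
    RateTables,
    RunControl,
    SystemState,
    _apply_exact_event,
    build_rate_tables,
    event_propensities,
    initialize_state,
    run_phase_batch,
    run_simulation,
    step_exact,
    step_tau_leap,
    step_tau_leap_batch,
)


def single_class_tables(
    r_self=0.0, r_diff=0.0, death=1.0, mature_out=0.0, n_ref=1e9,
) -> RateTables:
    """Minimal two-level system (one mitotic level + mature) built by hand."""
    return RateTables(
        r_self=np.full((2, 1, 1), r_self),
        r_diff=np.full((2, 1, 1), r_diff),
        mob_weight=np.zeros(1),
        mature_out=mature_out,
        death=np.array([death, death]),
        mu_level=np.zeros(1),
        n_ref=n_ref,
        pool2_start=1,
        exch=ExchangeParams(),
    )


def empty_state(M=1, L=2) -> SystemState:
    return SystemState(counts=np.zeros((2, 2, M, L)), t=0.0)


class TestInitialization:
    def test_founder_replaces_one_hsc(self, default_rates, default_exchange):
        st_ = initialize_state(default_rates, default_exchange, m_cap=20)
        assert st_.counts[0, 1, 0, 0] == 1
        assert st_.counts[0, 1].sum() == 1
        assert st_.counts[0, 0, 0, 0] == 1e4 - 1

    def test_blood_starts_with_target_mature_only(self, default_rates,
                                                  default_exchange):
        st_ = initialize_state(default_rates, default_exchange, m_cap=20)
        assert st_.counts[1, 0, 0, 20] == 5e10
        assert st_.counts[1].sum() == 5e10

    def test_cellularity_is_one(self, default_rates, default_exchange):
        st_ = initialize_state(default_rates, default_exchange, m_cap=20)
        n_ref = float(np.round(default_rates.N).sum())
        assert st_.cellularity(n_ref) == 1.0


class TestPropensities:
    def test_empty_state_all_zero(self, toy_rates, toy_exchange):
        tables = build_rate_tables(
            toy_rates, EvolutionParams(mu=0, s_bcrabl=0.5), toy_exchange,
            delta=0.25)
        props = event_propensities(empty_state(M=21, L=4), tables)
        assert all(p.sum() == 0 for p in props)

    def test_single_class_self_renewal(self):
        tables = single_class_tables(r_self=1.0)
        st_ = empty_state()
        st_.counts[0, 0, 0, 0] = 100
        p_self, p_diff, p_trans, p_death = event_propensities(st_, tables)
        assert p_self.sum() == 100.0
        assert p_diff.sum() == p_trans.sum() == p_death.sum() == 0.0

    def test_hsc_division_plus_mobilization(self, default_rates,
                                            default_exchange):
        """A marrow class contributes division and (gated) mobilization."""
        evol = EvolutionParams(mu=0, s_bcrabl=1.0, m_crit=1, m_cap=1)
        tables = build_rate_tables(default_rates, evol, default_exchange)
        st_ = initialize_state(default_rates, default_exchange, m_cap=1)
        p_self, p_diff, p_trans, p_death = event_propensities(st_, tables)
        founder = p_self[1, 0, 0] + p_diff[1, 0, 0] + p_trans[1, 0, 0]
        f = 0.03 * np.exp(st_.cellularity(tables.n_ref) / 10)
        expected = default_rates.R[0] * (1 + f)  # division + Eq.-(3) transfer
        assert founder == pytest.approx(expected, rel=1e-9)


class TestApplyEvent:
    def _tables(self, toy_rates, toy_exchange, mu=0.0):
        evol = EvolutionParams(mu=mu, s_bcrabl=0.5, m_crit=3, m_cap=3)
        return build_rate_tables(toy_rates, evol, toy_exchange, delta=0.25)

    def test_symmetric_differentiation_conserves_plus_one(
            self, toy_rates, toy_exchange):
        tables = self._tables(toy_rates, toy_exchange)
        st_ = empty_state(M=4, L=4)
        st_.counts[0, 0, 0, 1] = 1.0
        M, Lm = 4, 3
        idx_diff = (2 * M * Lm) + np.ravel_multi_index((0, 0, 1), (2, M, Lm))
        # second block of the flat channel layout is symmetric differentiation
        n_div = 2 * M * Lm
        _apply_exact_event(st_, tables, n_div + np.ravel_multi_index(
            (0, 0, 1), (2, M, Lm)), n_div, 2 * M * 4,
            np.random.default_rng(0))
        assert st_.counts[0, 0, 0, 1] == 0.0
        assert st_.counts[0, 0, 0, 2] == 2.0
        assert st_.counts.sum() == 2.0

    def test_mobilization_moves_between_compartments(
            self, toy_rates, toy_exchange):
        tables = self._tables(toy_rates, toy_exchange)
        st_ = empty_state(M=4, L=4)
        st_.counts[0, 1, 2, 2] = 5.0
        n_div = 2 * 4 * 3
        idx = 2 * n_div + np.ravel_multi_index((1, 2, 2), (2, 4, 4))
        _apply_exact_event(st_, tables, idx, n_div, 2 * 4 * 4,
                           np.random.default_rng(0))
        assert st_.counts[0, 1, 2, 2] == 4.0
        assert st_.counts[1, 1, 2, 2] == 1.0
        assert st_.counts.sum() == 5.0

    def test_self_renewal_with_mutation_adds_one_mutant(
            self, toy_rates, toy_exchange):
        tables = self._tables(toy_rates, toy_exchange, mu=1.0)  # always mutate
        st_ = empty_state(M=4, L=4)
        st_.counts[0, 1, 0, 0] = 3.0
        n_div = 2 * 4 * 3
        idx = np.ravel_multi_index((1, 0, 0), (2, 4, 3))
        _apply_exact_event(st_, tables, idx, n_div, 2 * 4 * 4,
                           np.random.default_rng(0))
        assert st_.counts[0, 1, 0, 0] == 3.0  # parent class unchanged
        assert st_.counts[0, 1, 1, 0] == 1.0  # one daughter carries +1 driver


class TestStepExact:
    def test_zero_propensity_signals_extinction(self):
        tables = single_class_tables()
        assert step_exact(empty_state(), tables,
                          np.random.default_rng(0)) is None

    def test_pure_death_mean_extinction_time(self):
        """Linear death from n=10 at rate 1/day: E[T] is the harmonic sum."""
        tables = single_class_tables(death=1.0)
        rng = np.random.default_rng(42)
        times = []
        for _ in range(400):
            st_ = empty_state()
            st_.counts[1, 0, 0, 0] = 10
            while True:
                dt = step_exact(st_, tables, rng)
                if dt is None:
                    break
            times.append(st_.t)
        expected = sum(1 / k for k in range(1, 11))  # 2.9290
        se = np.sqrt(sum(1 / k ** 2 for k in range(1, 11)) / len(times))
        assert np.mean(times) == pytest.approx(expected, abs=3 * se)

    def test_waiting_times_exponential(self):
        """Single channel at rate r: waiting times follow Exp(r) (KS)."""
        r = 0.7
        tables = single_class_tables(death=r)
        rng = np.random.default_rng(7)
        waits = []
        for _ in range(500):
            st_ = empty_state()
            st_.counts[1, 0, 0, 0] = 1
            waits.append(step_exact(st_, tables, rng))
        res = stats.kstest(waits, "expon", args=(0, 1 / r))
        assert res.pvalue > 0.01


class TestStepTauLeap:
    def test_all_zero_propensities_only_advances_time(self):
        tables = single_class_tables()
        st_ = empty_state()
        step_tau_leap(st_, tables, 0.5, np.random.default_rng(0))
        assert st_.t == 0.5
        assert st_.counts.sum() == 0.0

    def test_linear_birth_matches_closed_form_mean(self):
        """Self-renewal-only class grows like exp(b t) in the mean."""
        b, T, n0, reps = 0.08, 20.0, 50, 200
        tables = single_class_tables(r_self=b, death=0.0)
        rng = np.random.default_rng(3)
        finals = []
        for _ in range(reps):
            st_ = empty_state()
            st_.counts[0, 0, 0, 0] = n0
            for _ in range(int(T / 0.1)):
                step_tau_leap(st_, tables, 0.1, rng)
            finals.append(st_.counts[0, 0, 0, 0])
        mean_expected = n0 * np.exp(b * T)
        # Var of a Yule process from n0: n0 e^{2bt}(1 - e^{-bt})
        sd = np.sqrt(n0 * np.exp(2 * b * T) * (1 - np.exp(-b * T)) / reps)
        assert np.mean(finals) == pytest.approx(mean_expected, abs=3 * sd)

    def test_linear_death_matches_closed_form_mean(self):
        d, T, n0, reps = 0.3, 5.0, 200, 200
        tables = single_class_tables(death=d)
        rng = np.random.default_rng(4)
        finals = []
        for _ in range(reps):
            st_ = empty_state()
            st_.counts[1, 0, 0, 0] = n0
            for _ in range(int(T / 0.05)):
                step_tau_leap(st_, tables, 0.05, rng)
            finals.append(st_.counts[1, 0, 0, 0])
        mean_expected = n0 * np.exp(-d * T)
        sd = np.sqrt(n0 * np.exp(-d * T) * (1 - np.exp(-d * T)) / reps)
        assert np.mean(finals) == pytest.approx(mean_expected, abs=3 * sd)

    def test_counts_never_negative_under_overdraw(self):
        tables = single_class_tables(r_diff=50.0, death=80.0)  # stiff on purpose
        rng = np.random.default_rng(9)
        st_ = empty_state()
        st_.counts[0, 0, 0, 0] = 5
        st_.counts[1, 0, 0, 0] = 5
        for _ in range(50):
            step_tau_leap(st_, tables, 0.5, rng)
            assert (st_.counts >= 0).all()

    def test_single_rep_batch_matches_unbatched_stream(
            self, toy_rates, toy_exchange):
        evol = EvolutionParams(mu=0.05, s_bcrabl=0.5, m_cap=5)
        tables = build_rate_tables(toy_rates, evol, toy_exchange, delta=0.25)
        st_ = initialize_state(toy_rates, toy_exchange, m_cap=5)
        batch = st_.counts[None, ...].copy()
        single = dataclasses.replace(st_, counts=st_.counts.copy())
        for seed_step in range(30):
            step_tau_leap(single, tables, 0.2,
                          np.random.default_rng(seed_step))
        for seed_step in range(30):
            step_tau_leap_batch(batch, tables, 0.2,
                                np.random.default_rng(seed_step))
        assert np.array_equal(single.counts, batch[0])


class TestRunSimulation:
    def test_zero_horizon_single_sample(self, toy_rates, toy_exchange):
        evol = EvolutionParams(mu=0, s_bcrabl=0.5)
        ctl = RunControl(seed=1, horizon_days=0.0, engine_mode="exact")
        traj = run_simulation(toy_rates, evol, toy_exchange, ctl, delta=0.25)
        assert len(traj.t) == 1
        assert traj.t[0] == 0.0

    def test_deterministic_under_fixed_seed(self, toy_rates, toy_exchange):
        evol = EvolutionParams(mu=0.02, s_bcrabl=0.5)
        for mode in ("exact", "tau", "hybrid"):
            ctl = RunControl(seed=33, horizon_days=15.0, engine_mode=mode,
                             sample_interval_days=1.0, tau_days=0.1)
            t1 = run_simulation(toy_rates, evol, toy_exchange, ctl, delta=0.25)
            t2 = run_simulation(toy_rates, evol, toy_exchange, ctl, delta=0.25)
            assert np.array_equal(t1.blast_pct_blood, t2.blast_pct_blood)
            assert np.array_equal(t1.total_blood, t2.total_blood)
            assert t1.stop_time == t2.stop_time

    def test_hybrid_equals_exact_on_small_system(self, toy_rates,
                                                 toy_exchange):
        evol = EvolutionParams(mu=0.02, s_bcrabl=0.5)
        kw = dict(horizon_days=10.0, sample_interval_days=1.0, seed=5)
        th = run_simulation(toy_rates, evol, toy_exchange,
                            RunControl(engine_mode="hybrid", **kw), delta=0.25)
        te = run_simulation(toy_rates, evol, toy_exchange,
                            RunControl(engine_mode="exact", **kw), delta=0.25)
        assert np.array_equal(th.total_blood, te.total_blood)

    def test_founder_survival_increases_with_strength(self, toy_rates,
                                                      toy_exchange):
        """Founder-clone establishment probability grows with s_bcrabl.

        A lone founder HSC (no healthy background, so only clone events fire)
        either dies out or establishes; a stronger driver tilts the critical
        HSC level further supercritical.
        """
        surv = {}
        for s in (0.2, 0.9):
            evol = EvolutionParams(mu=0, s_bcrabl=s)
            tables = build_rate_tables(toy_rates, evol, toy_exchange,
                                       delta=0.5)
            rng = np.random.default_rng(int(s * 100))
            alive = 0
            for _ in range(150):
                st_ = empty_state(M=21, L=4)
                st_.counts[0, 1, 0, 0] = 1.0
                while 0 < st_.counts[:, 1].sum() < 50 and st_.t < 400:
                    if step_exact(st_, tables, rng) is None:
                        break
                alive += st_.counts[:, 1].sum() >= 50
            surv[s] = alive
        assert surv[0.9] > surv[0.2] > 0


class TestPhaseBatch:
    def test_deterministic_in_master_seed(self, toy_rates, toy_exchange):
        evol = EvolutionParams(mu=0.05, s_bcrabl=0.9, m_cap=5)
        ctl = RunControl(seed=11, horizon_days=30.0, engine_mode="tau",
                         tau_days=0.2, stop_blast_pct=30.0)
        a = run_phase_batch(toy_rates, evol, toy_exchange, ctl, n_reps=8,
                            delta=0.25)
        b = run_phase_batch(toy_rates, evol, toy_exchange, ctl, n_reps=8,
                            delta=0.25)
        for key in ("crossings_days", "stop_crossing_days"):
            assert np.array_equal(a[key], b[key], equal_nan=True)

    def test_crossing_times_ordered(self, toy_rates, toy_exchange):
        evol = EvolutionParams(mu=0.05, s_bcrabl=0.9, m_cap=5)
        ctl = RunControl(seed=2, horizon_days=60.0, engine_mode="tau",
                         tau_days=0.2)
        res = run_phase_batch(toy_rates, evol, toy_exchange, ctl, n_reps=8,
                              delta=0.25)
        c = res["crossings_days"]
        with np.errstate(invalid="ignore"):
            assert np.all((np.diff(c, axis=1) >= 0) | np.isnan(np.diff(c, axis=1)))
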