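"""Dynamics and replica exchange: integrator statistics, the Metropolis
swap criterion, scheduling, determinism and detailed balance."""

import numpy as np
import pytest

from mses.analysis import acceptance_stats, variance_standard_error
from mses.constants import DEFAULT_LADDER, KB_KCAL
from mses.finemodels import harmonic_1d
from mses.sampler import (
    CampaignConfig,
    DivergenceError,
    ExchangeEvent,
    Ladder,
    ReplicaState,
    StateCorruptionError,
    ThermostatSpec,
    attempt_exchanges,
    campaign_accounting,
    exchange_delta,
    exchange_probability,
    langevin_step,
    maxwell_velocities,
    propagate,
    run_campaign,
    run_plain,
)
from mses.synthetic import make_coupled_harmonic


class TestLangevin:
    def test_free_particle_moves_in_a_straight_line(self):
        x = np.array([0.0])
        v = np.array([2.0])
        masses = np.ones(1)
        f = np.zeros(1)
        zero_force = lambda xx: (0.0, np.zeros_like(xx))
        for _ in range(10):
            x, v, f, _ = langevin_step(x, v, f, masses, 1.0, 0.0, 0.1, zero_force, None)
        assert np.isclose(x[0], 2.0 * 10 * 0.1, atol=1e-12)
        assert np.isclose(v[0], 2.0)

    def test_harmonic_variance_matches_equipartition(self):
        """Long Langevin run in a 1D well: Var(x) -> k_B T / a."""
        model = harmonic_1d(2.0)
        th = ThermostatSpec(temperature_fine=1.5, temperature_cg=1.5,
                            friction=1.0, timestep=0.05, units="natural")
        samples = run_plain(model, th, 200_000, seed=7, x0=np.array([0.0]), record_every=10)
        x = samples.ravel()
        target = 1.5 / 2.0
        se = variance_standard_error(x)
        assert abs(np.var(x) - target) < 3 * se

    def test_zero_friction_conserves_energy(self):
        """With friction 0 the BAOAB step is velocity Verlet: energy drift
        in a harmonic well stays at round-off scale."""
        model = harmonic_1d(1.0)
        x = np.array([1.0])
        v = np.array([0.0])
        masses = np.ones(1)

        def ef(xx):
            return model.energy_forces(xx)

        _, f = ef(x)
        e0 = model.potential(x[0]) + 0.5 * v[0] ** 2
        emax = 0.0
        for _ in range(10_000):
            x, v, f, _ = langevin_step(x, v, f, masses, 1.0, 0.0, 0.01, ef, None)
            e = model.potential(x[0]) + 0.5 * v[0] ** 2
            emax = max(emax, abs(e - e0))
        assert emax < 1e-4

    def test_divergence_is_reported(self):
        model = harmonic_1d(1.0)
        with pytest.raises(DivergenceError):
            propagate(
                np.array([1.0]), np.array([0.0]), 2000, np.ones(1), 1.0, 0.0,
                10.0, model.energy_forces, None,
            )

    def test_maxwell_velocities_scale(self, rng):
        masses = np.array([1.0, 4.0])
        draws = np.array([maxwell_velocities(masses, 2.0, rng) for _ in range(4000)])
        np.testing.assert_allclose(draws.var(axis=0), [2.0, 0.5], rtol=0.1)


class TestExchangeCriterion:
    def test_zero_cases(self):
        assert exchange_delta(0.5, 0.5, 1.0, 9.0, beta=2.0) == 0.0
        assert exchange_delta(0.1, 0.5, 4.0, 4.0, beta=2.0) == 0.0

    def test_printed_arithmetic(self):
        """beta at 300 K, dk = 2e-4, dB = 100 A^2 gives Delta = 0.033547."""
        beta = 1.0 / (KB_KCAL * 300.0)
        delta = exchange_delta(0.0002, 0.0, 100.0, 0.0, beta)
        assert np.isclose(delta, 0.0335473, atol=1e-6)

    def test_antisymmetric(self):
        d1 = exchange_delta(0.3, 0.1, 7.0, 2.0, beta=1.7)
        d2 = exchange_delta(0.1, 0.3, 2.0, 7.0, beta=1.7)
        assert np.isclose(d1, d2)
        d3 = exchange_delta(0.1, 0.3, 7.0, 2.0, beta=1.7)
        assert np.isclose(d1, -d3)

    def test_probability_limits(self):
        assert exchange_probability(0.0) == 1.0
        assert np.isclose(exchange_probability(-np.log(2.0)), 0.5)
        assert exchange_probability(700.0) == 1.0  # no overflow
        assert exchange_probability(-1e6) == 0.0


class TestLadder:
    def test_default_preset_is_valid_16_rung(self):
        ladder = Ladder(DEFAULT_LADDER)
        assert len(ladder) == 16
        assert ladder[0] == 0.0
        assert ladder[15] == 0.098

    @pytest.mark.parametrize(
        "values", [(), (0.1, 0.2), (0.0, 0.2, 0.1), (0.0, 0.1, 0.1)]
    )
    def test_invalid_ladders_rejected(self, values):
        with pytest.raises(ValueError):
            Ladder(values)


def _replicas(b_values):
    return [
        ReplicaState(coords=np.zeros(1), velocities=np.zeros(1), rung=i, mismatch=b)
        for i, b in enumerate(b_values)
    ]


class TestAttemptExchanges:
    def test_equal_mismatch_always_swaps(self):
        ladder = Ladder((0.0, 0.5))
        rng = np.random.default_rng(0)
        reps = _replicas([3.0, 3.0])
        events = attempt_exchanges(reps, ladder, parity=0, beta=1.0, rng=rng)
        assert len(events) == 1 and events[0].accepted
        assert {r.rung for r in reps} == {0, 1}

    def test_parity_scheduling(self):
        ladder = Ladder((0.0, 0.1, 0.2, 0.3))
        rng = np.random.default_rng(0)
        even = attempt_exchanges(_replicas([1, 1, 1, 1]), ladder, 0, 1.0, rng)
        assert [e.rung_pair for e in even] == [(0, 1), (2, 3)]
        odd = attempt_exchanges(_replicas([1, 1, 1, 1]), ladder, 1, 1.0, rng)
        assert [e.rung_pair for e in odd] == [(1, 2)]

    def test_duplicate_rung_detected(self):
        reps = _replicas([1.0, 1.0])
        reps[1].rung = 0
        with pytest.raises(StateCorruptionError):
            attempt_exchanges(reps, Ladder((0.0, 0.5)), 0, 1.0, np.random.default_rng(0))

    def test_empirical_acceptance_matches_analytic(self):
        """10^4 swap attempts at fixed (k, B): the empirical rate must sit
        within 3 binomial standard errors of min(1, exp(Delta))."""
        ladder = Ladder((0.0, 0.4))
        beta, b0, b1 = 1.0, 4.0, 1.0  # high mismatch at the low rung: Delta < 0
        delta = exchange_delta(0.0, 0.4, b0, b1, beta)
        p = exchange_probability(delta)
        assert 0.0 < p < 1.0
        rng = np.random.default_rng(123)
        n, accepted = 10_000, 0
        for _ in range(n):
            reps = _replicas([b0, b1])  # fresh assignment each attempt
            ev = attempt_exchanges(reps, ladder, 0, beta, rng)[0]
            accepted += ev.accepted
        se = np.sqrt(p * (1 - p) / n)
        assert abs(accepted / n - p) < 3 * se

    def test_swap_chain_satisfies_detailed_balance(self):
        """Two-rung toy with two enumerable configurations: alternating
        exact Gibbs resampling and swap moves, the empirical swap-move flux
        must balance, pi_i P_ij = pi_j P_ji, within Monte-Carlo error."""
        ladder = Ladder((0.0, 0.6))
        beta = 1.0
        b_lo, b_hi = 0.5, 3.0
        rng = np.random.default_rng(99)

        # configuration c in {0, 1} has mismatch B_c; at rung with k the
        # conditional weight is exp(-beta k B_c)
        def gibbs(k):
            w = np.exp(-beta * k * np.array([b_lo, b_hi]))
            return int(rng.random() < w[1] / w.sum())

        state = [0, 1]  # configuration held at rung 0 and rung 1
        counts = np.zeros((2, 2))  # joint-state transition counts of swaps
        occupancy = np.zeros(2)

        def joint(s):
            return 0 if s == [0, 1] else 1

        for _ in range(40_000):
            state = [gibbs(ladder[0]), gibbs(ladder[1])]
            if state[0] == state[1]:
                continue  # swap is a no-op between identical configurations
            before = joint(state)
            occupancy[before] += 1
            b = [b_lo if c == 0 else b_hi for c in state]
            reps = _replicas(b)
            ev = attempt_exchanges(reps, ladder, 0, beta, rng)[0]
            if ev.accepted:
                state = [state[1], state[0]]
            counts[before, joint(state)] += 1

        pi = occupancy / occupancy.sum()
        p01 = counts[0, 1] / counts[0].sum()
        p10 = counts[1, 0] / counts[1].sum()
        flux_01, flux_10 = pi[0] * p01, pi[1] * p10
        assert abs(flux_01 - flux_10) < 4 * np.sqrt(flux_01 / 40_000 + flux_10 / 40_000)


class TestAccounting:
    def test_interval_and_duration_arithmetic(self):
        """10,000 iterations at a 20 ps exchange interval = 200 ns per
        simulation; 16 replicas x 2 simulations = 6.4 us aggregate."""
        config = CampaignConfig(ladder=Ladder(DEFAULT_LADDER))
        acct = campaign_accounting(config, n_simulations=2)
        assert acct["exchange_interval_ps"] == 20.0
        assert acct["per_simulation_ns"] == 200.0
        assert acct["aggregate_us"] == 6.4
        assert acct["n_replicas"] == 16.0


class TestCampaign:
    def _tiny_config(self, system, seed=5, n_iterations=60, n_rungs=4, **kw):
        return CampaignConfig(
            ladder=system.default_ladder(1.0, n_rungs),
            thermostat=system.default_thermostat(),
            exchange_interval=10,
            n_iterations=n_iterations,
            seed=seed,
            **kw,
        )

    def test_same_seed_is_bit_identical(self):
        system = make_coupled_harmonic()
        cfg = self._tiny_config(system)
        r1 = run_campaign(cfg, system.fine_model, system.cg_model, system.coupling)
        r2 = run_campaign(cfg, system.fine_model, system.cg_model, system.coupling)
        np.testing.assert_array_equal(r1.rung0_samples, r2.rung0_samples)
        np.testing.assert_array_equal(r1.energy_log, r2.energy_log)
        assert r1.exchange_events == r2.exchange_events

    def test_near_degenerate_ladder_always_swaps(self):
        """With a vanishing k spacing the criterion is Delta ~ 0 and every
        attempted swap is accepted (the [0, 0] ladder limit)."""
        system = make_coupled_harmonic()
        cfg = CampaignConfig(
            ladder=Ladder((0.0, 1e-12)),
            thermostat=system.default_thermostat(),
            exchange_interval=10,
            n_iterations=50,
            seed=2,
        )
        res = run_campaign(cfg, system.fine_model, system.cg_model, system.coupling)
        overall, _ = acceptance_stats(res.exchange_events)
        assert overall == 1.0

    def test_every_replica_visits_every_rung(self):
        system = make_coupled_harmonic()
        cfg = self._tiny_config(system, n_iterations=300)
        res = run_campaign(cfg, system.fine_model, system.cg_model, system.coupling)
        for i in range(len(cfg.ladder)):
            assert len(np.unique(res.rung_history[:, i])) == len(cfg.ladder)

    def test_energy_log_decomposition_consistent(self):
        system = make_coupled_harmonic()
        cfg = self._tiny_config(system, n_iterations=20)
        res = run_campaign(cfg, system.fine_model, system.cg_model, system.coupling)
        log = res.energy_log
        np.testing.assert_allclose(log[:, 3] + log[:, 4] + log[:, 5], log[:, 6], rtol=1e-12)
        assert np.all(log[:, 5] >= 0)  # coupling term never negative

    def test_symmetric_mode_matches_coupled_closed_form(self):
        """In symmetric mode a replica pinned at coupling k samples the
        joint Gaussian: Var(x) = (c+2k) / (beta (ac + 2k(a+c)))."""
        system = make_coupled_harmonic()
        k = 0.8
        cfg = CampaignConfig(
            ladder=Ladder((0.0, k)),
            thermostat=system.default_thermostat(),
            exchange_interval=10,
            n_iterations=3000,
            seed=31,
            mode="symmetric",
            record_all_rungs=True,
            log_energies=False,
        )
        res = run_campaign(cfg, system.fine_model, system.cg_model, system.coupling)
        x_k = res.samples_by_rung[:, 1].ravel()
        target = system.var_x_coupled(k)
        se = variance_standard_error(x_k)
        assert abs(np.var(x_k) - target) < 3 * se

    def test_save_outputs(self, tmp_path):
        system = make_coupled_harmonic()
        cfg = self._tiny_config(system, n_iterations=10)
        res = run_campaign(cfg, system.fine_model, system.cg_model, system.coupling)
        res.save(tmp_path / "out")
        for name in ("energy_log.tsv", "exchange_log.tsv", "rung_history.tsv", "rung0_samples.tsv"):
            assert (tmp_path / "out" / name).exists()
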