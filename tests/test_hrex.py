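"""Hamiltonian replica exchange: exchange law, reservoir coupling, chain BAR."""

import numpy as np
import pytest

from neqfe.dynamics import Conformation, SwitchingProtocol, run_md_ensemble
from neqfe.errors import ConfigurationError, EstimationError, InputError
from neqfe.estimators import ti
from neqfe.hrex import (
    LambdaSchedule,
    ReplicaState,
    chain_free_energy,
    exchange_attempt,
    reservoir_from_hrex,
    reservoir_swap,
    run_hrex,
)
from neqfe.pipeline import BindingToy, torsion_chain_system
from neqfe.reservoir import ReservoirConfig, generate_reservoir
from neqfe.systems import (
    Domain,
    Harmonic,
    HybridSpec,
    SofteningSpec,
    SystemSpec,
    energy,
    hybridize,
    quadrature_free_energy,
    soften,
)


def harmonic(k, x0=0.0):
    return SystemSpec(
        1,
        (Harmonic(coord=0, k=k, x0=x0, name="w"),),
        coordinates=(Domain(kind="real", lo=-8, hi=8),),
    )


def state(spec, x, idx=0):
    return ReplicaState(
        lambda_index=idx, spec=spec, conformation=Conformation(x=np.atleast_1d(x))
    )


class TestLambdaSchedule:
    def test_uniform_includes_terminals(self):
        s = LambdaSchedule.uniform(11)
        assert s.lambdas[0] == 0.0 and s.lambdas[-1] == 1.0 and len(s) == 11

    def test_softening_ladder_tent_shape(self):
        s = LambdaSchedule.with_softening(21, 1.0, targets=("t",))
        lad = np.asarray(s.softness_ladder)
        assert lad[0] == 0.0 and lad[-1] == 0.0
        assert lad[10] == pytest.approx(1.0)
        assert np.allclose(lad, lad[::-1])

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ConfigurationError):
            LambdaSchedule(lambdas=(0.0, 0.5))  # missing terminal 1
        with pytest.raises(ConfigurationError):
            LambdaSchedule(lambdas=(0.0, 0.5, 0.5, 1.0))
        with pytest.raises(ConfigurationError):
            LambdaSchedule(
                lambdas=(0.0, 0.5, 1.0), softness_ladder=(0.1, 1.0, 0.0)
            )


class TestExchangeAttempt:
    def test_identical_hamiltonians_always_accept(self):
        spec = harmonic(1.0)
        for trial in range(20):
            ri, rj = state(spec, 0.3, 0), state(spec, -0.8, 1)
            assert exchange_attempt(ri, rj, np.random.default_rng(trial))

    def test_acceptance_follows_boltzmann_factor(self):
        # fixture with Delta = 2 kT exactly: empirical rate ~ e^-2
        sa, sb = harmonic(1.0), harmonic(3.0)
        # Delta = [U_a(xb)+U_b(xa)] - [U_a(xa)+U_b(xb)] = (k_b-k_a)(xa^2-xb^2)/2
        xa, xb = np.sqrt(2.0), 0.0  # -> Delta = 2
        n = 20_000
        rng = np.random.default_rng(28)
        hits = 0
        for _ in range(n):
            ri, rj = state(sa, xa, 0), state(sb, xb, 1)
            hits += exchange_attempt(ri, rj, rng)
        p = np.exp(-2.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_swap_exchanges_conformations(self):
        spec = harmonic(1.0)
        ri, rj = state(spec, 1.0, 0), state(spec, -1.0, 1)
        assert exchange_attempt(ri, rj, np.random.default_rng(0))
        assert ri.conformation.x[0] == -1.0 and rj.conformation.x[0] == 1.0

    def test_non_neighbors_rejected(self):
        spec = harmonic(1.0)
        with pytest.raises(InputError):
            exchange_attempt(state(spec, 0.0, 0), state(spec, 0.0, 2),
                             np.random.default_rng(0))

    def test_seeded_determinism(self):
        sa, sb = harmonic(1.0), harmonic(4.0)
        outcomes = []
        for _ in range(2):
            rng = np.random.default_rng(33)
            outcomes.append(
                [exchange_attempt(state(sa, 1.2, 0), state(sb, 0.1, 1), rng)
                 for _ in range(50)]
            )
        assert outcomes[0] == outcomes[1]


@pytest.fixture(scope="module")
def matched_reservoir(double_well_6):
    ns, soft_spec = double_well_6
    cfg = ReservoirConfig(
        n_snapshots=200, seed=3, n_walkers=20, sample_every=40, burn_in=1500,
        protocol=SwitchingProtocol(duration=2.0),
    )
    return ns, generate_reservoir(ns, soft_spec, cfg)


class TestReservoirSwap:
    def test_matched_ensemble_accepts_always(self, matched_reservoir):
        ns, res = matched_reservoir
        rng = np.random.default_rng(5)
        for _ in range(20):
            r0 = state(ns, 1.0, 0)
            _, ok = reservoir_swap(r0, res, rng)
            assert ok
            assert r0.conformation.meta["source"] == "reservoir_insert"

    def test_mismatched_hotter_ensemble_accepts_below_one(self, matched_reservoir):
        ns, res = matched_reservoir
        import dataclasses

        colder = dataclasses.replace(ns, temperature=0.4)
        rng = np.random.default_rng(6)
        oks = []
        for _ in range(300):
            r0 = state(colder, 1.0, 0)
            _, ok = reservoir_swap(r0, res, rng)
            oks.append(ok)
        assert 0.0 < np.mean(oks) < 1.0

    def test_only_end_replica_may_swap(self, matched_reservoir):
        ns, res = matched_reservoir
        with pytest.raises(InputError):
            reservoir_swap(state(ns, 1.0, idx=3), res, np.random.default_rng(0))

    def test_empty_reservoir_rejected(self, matched_reservoir):
        ns, res = matched_reservoir
        import dataclasses

        empty = dataclasses.replace(res, conformations=[])
        with pytest.raises(InputError):
            reservoir_swap(state(ns, 1.0, 0), empty, np.random.default_rng(0))


class TestRunHrex:
    def test_identity_chain_preserves_ensemble(self):
        spec = harmonic(1.0)
        sched = LambdaSchedule.uniform(5)
        out = run_hrex(spec, spec, sched, n_cycles=400, steps_per_cycle=20,
                       seed=5, burn_in_cycles=40)
        assert np.all(out.acceptance_rates == 1.0)
        est = chain_free_energy(out)
        assert est.value == pytest.approx(0.0, abs=1e-12)
        # replica histograms match direct MD (thinned against autocorrelation)
        from scipy.stats import ks_2samp

        direct = run_md_ensemble(spec, 360, n_walkers=40, sample_every=50, seed=6)
        for i in range(5):
            xs = out.replica_samples(i, thin=10)[:, 0]
            assert ks_2samp(xs, direct[:, 0]).pvalue > 0.01

    def test_chain_dg_matches_quadrature_and_ti(self, harmonic_1_4):
        a, b = harmonic_1_4
        sched = LambdaSchedule.uniform(11)
        out = run_hrex(a, b, sched, n_cycles=500, steps_per_cycle=20, seed=7,
                       burn_in_cycles=50)
        est = chain_free_energy(out)
        exact = quadrature_free_energy(a, b).value
        assert abs(est.value - exact) < 3 * est.stderr
        # TI on windows sampled by MD agrees within combined errors
        windows = []
        for lam in sched.lambdas:
            spec = hybridize(HybridSpec(a, b, lam))
            X = run_md_ensemble(spec, 1000, n_walkers=50, sample_every=20,
                                seed=int(100 * lam) + 8)
            du = energy(b, X) - energy(a, X)  # dU/dlambda for linear k-mixing
            windows.append((lam, du.mean(), du.std(ddof=1) / np.sqrt(du.size / 3)))
        ti_est = ti(windows)
        assert abs(ti_est.value - est.value) < 3 * np.hypot(ti_est.stderr, est.stderr)

    def test_chain_additivity(self, harmonic_1_4):
        a, b = harmonic_1_4
        mid = hybridize(HybridSpec(a, b, 0.5))
        sched = LambdaSchedule.uniform(6)
        full = chain_free_energy(
            run_hrex(a, b, sched, 400, 20, seed=9, burn_in_cycles=40)
        )
        lo = chain_free_energy(
            run_hrex(a, mid, sched, 400, 20, seed=10, burn_in_cycles=40)
        )
        hi = chain_free_energy(
            run_hrex(mid, b, sched, 400, 20, seed=11, burn_in_cycles=40)
        )
        se = np.sqrt(full.stderr**2 + lo.stderr**2 + hi.stderr**2)
        assert abs((lo.value + hi.value) - full.value) < 3 * se

    def test_replica_walk_reaches_both_terminals(self, harmonic_1_4):
        a, b = harmonic_1_4
        out = run_hrex(a, b, LambdaSchedule.uniform(11), n_cycles=800,
                       steps_per_cycle=10, seed=12)
        at_zero = set(out.replica_trace[:, 0])
        at_one = set(out.replica_trace[:, -1])
        for rid in range(11):
            assert rid in at_zero and rid in at_one

    def test_softening_ladder_keeps_exchange_rates_up(self, binding_toy):
        H_R = binding_toy.bound_spec("R")
        H_T = binding_toy.bound_spec("T")
        sched = LambdaSchedule.with_softening(21, 1.0, targets=("backbone",))
        out = run_hrex(H_R, H_T, sched, n_cycles=200, steps_per_cycle=10, seed=13,
                       x0=[[1.2, 0.0]])
        assert out.acceptance_rates.min() > 0.1

    def test_reservoir_unlocks_unvisited_states(self):
        # high-barrier two-torsion chain started in one well: only the
        # reservoir-coupled run reaches the opposite torsional state
        chain = torsion_chain_system(8.0)
        soft = SofteningSpec(s=1.0, targets=("tor0", "tor1"), floor_fraction=0.9)
        cfg = ReservoirConfig(
            n_snapshots=400, seed=14, n_walkers=40, sample_every=40, burn_in=2000,
            protocol=SwitchingProtocol(duration=2.0),
        )
        res = generate_reservoir(chain, soft, cfg, x0=[[-np.pi / 2, -np.pi / 2]])
        sched = LambdaSchedule.uniform(5)
        kw = dict(n_cycles=200, steps_per_cycle=20, seed=15,
                  x0=[[-np.pi / 2, -np.pi / 2]])
        bare = run_hrex(chain, chain, sched, **kw)
        coupled = run_hrex(chain, chain, sched, reservoir=res, **kw)
        frac_bare = np.mean(bare.replica_samples(4)[:, 0] > 0)
        frac_coupled = np.mean(coupled.replica_samples(4)[:, 0] > 0)
        assert frac_bare == 0.0
        assert frac_coupled > 0.2

    def test_missing_pair_data_raises(self, harmonic_1_4):
        a, b = harmonic_1_4
        out = run_hrex(a, b, LambdaSchedule.uniform(3), n_cycles=3,
                       steps_per_cycle=5, seed=16, burn_in_cycles=2)
        with pytest.raises(EstimationError, match="pair"):
            chain_free_energy(out)

    def test_result_directory_export(self, tmp_path, harmonic_1_4):
        a, b = harmonic_1_4
        out = run_hrex(a, b, LambdaSchedule.uniform(3), n_cycles=10,
                       steps_per_cycle=5, seed=17)
        out.to_dir(tmp_path / "hrex")
        assert (tmp_path / "hrex" / "pair_00.csv").exists()
        assert (tmp_path / "hrex" / "exchange_trace.csv").exists()
        assert (tmp_path / "hrex" / "metadata.json").exists()


class TestHrexReservoir:
    def test_hrex_built_reservoir_matches_quadrature(self, double_well_6):
        ns, soft_spec = double_well_6
        res = reservoir_from_hrex(ns, soft_spec, n_states=9, n_cycles=300,
                                  steps_per_cycle=20, seed=18, burn_in_cycles=30)
        exact = quadrature_free_energy(soften(ns, soft_spec), ns).value
        assert abs(res.dG_s_to_ns.value - exact) < 3 * res.dG_s_to_ns.stderr + 0.1
        assert len(res) == 270  # post-burn-in terminal samples
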