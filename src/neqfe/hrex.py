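"""Hamiltonian replica exchange over an alchemical lambda chain.

Replicas at different lambda values (optionally with a softness ladder that
peaks at lambda = 0.5 and vanishes at the terminals) alternate Langevin MD
bursts with deterministic odd/even neighbor-exchange sweeps.  Per-neighbor
energy differences are collected every cycle so the chain free energy can be
assembled from pairwise BAR estimates.  A pre-built Boltzmann conformation
reservoir can be coupled to the lambda = 0 replica: one random reservoir
conformation is proposed per cycle, accepted unconditionally when the
reservoir was built for exactly that replica's Hamiltonian and by a
Metropolis test on the ensemble mismatch otherwise.

Exchanges are scheduled by cycle count (deterministic and reproducible), not
by wall clock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Conformation, _baoab, maxwell_boltzmann_velocities
from .errors import ConfigurationError, EstimationError, InputError
from .estimators import FreeEnergyEstimate, WorkSet, bar_ml
from .reservoir import Reservoir
from .systems import HybridSpec, SofteningSpec, SystemSpec, energy, hybridize, soften

__all__ = [
    "LambdaSchedule",
    "ReplicaState",
    "HREXResult",
    "exchange_attempt",
    "reservoir_swap",
    "run_hrex",
    "chain_free_energy",
    "reservoir_from_hrex",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Sorted lambda values in [0, 1] with optional per-state softness ladder.

    The ladder must vanish at the terminal states and be symmetric about
    lambda = 0.5 (softening is strongest for the middle replica).
    """

    lambdas: tuple
    softness_ladder: tuple | None = None
    soften_targets: tuple = ()
    floor_fraction: float = 0.8

    def __post_init__(self):
        lam = tuple(float(v) for v in self.lambdas)
        object.__setattr__(self, "lambdas", lam)
        if len(lam) < 2 or lam[0] != 0.0 or lam[-1] != 1.0:
            raise ConfigurationError("schedule must include terminals 0 and 1")
        if any(b <= a for a, b in zip(lam, lam[1:])):
            raise ConfigurationError("lambdas must be strictly increasing")
        if self.softness_ladder is not None:
            lad = tuple(float(v) for v in self.softness_ladder)
            object.__setattr__(self, "softness_ladder", lad)
            if len(lad) != len(lam):
                raise ConfigurationError("softness ladder must match schedule length")
            if lad[0] != 0.0 or lad[-1] != 0.0:
                raise ConfigurationError("softness must vanish at the terminal replicas")
            if not np.allclose(lad, lad[::-1]):
                raise ConfigurationError("softness ladder must be symmetric about 0.5")
            object.__setattr__(self, "soften_targets", tuple(self.soften_targets))

    def __len__(self) -> int:
        return len(self.lambdas)

    @classmethod
    def uniform(cls, n: int = 11) -> "LambdaSchedule":
        return cls(lambdas=tuple(np.linspace(0.0, 1.0, n)))

    @classmethod
    def with_softening(
        cls, n: int, s_max: float, targets, floor_fraction: float = 0.8
    ) -> "LambdaSchedule":
        """Tent-shaped softness: 0 at the terminals, ``s_max`` at lambda 0.5."""
        lam = np.linspace(0.0, 1.0, n)
        ladder = s_max * (1.0 - np.abs(2.0 * lam - 1.0))
        return cls(
            lambdas=tuple(lam),
            softness_ladder=tuple(ladder),
            soften_targets=tuple(targets),
            floor_fraction=floor_fraction,
        )


@dataclass
class ReplicaState:
    """One replica: its lambda slot, Hamiltonian, and current conformation."""

    lambda_index: int
    spec: SystemSpec
    conformation: Conformation
    energy: float = np.nan

    def refresh_energy(self) -> float:
        self.energy = float(energy(self.spec, self.conformation.x))
        return self.energy


@dataclass
class HREXResult:
    """Per-pair energy-difference samples, exchange statistics, walk trace."""

    lambdas: tuple
    pair_forward: list  # [n_pairs] arrays: U_{i+1}(x_i) - U_i(x_i)
    pair_reverse: list  # [n_pairs] arrays: U_i(x_{i+1}) - U_{i+1}(x_{i+1})
    exchange_attempts: np.ndarray
    exchange_accepts: np.ndarray
    replica_trace: np.ndarray  # (n_cycles, n_replicas) replica id per lambda slot
    samples: np.ndarray  # (n_cycles, n_replicas, dim)
    temperature: float = 1.0
    burn_in: int = 0
    reservoir_attempts: int = 0
    reservoir_accepts: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.lambdas) - 1

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.exchange_attempts > 0,
                self.exchange_accepts / np.maximum(self.exchange_attempts, 1),
                np.nan,
            )

    def replica_samples(self, index: int, thin: int = 1) -> np.ndarray:
        """Post-burn-in coordinate samples of the replica at one lambda slot."""
        return self.samples[self.burn_in :: thin, index, :]

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for p in range(self.n_pairs):
            pd.DataFrame(
                {"forward": self.pair_forward[p], "reverse": self.pair_reverse[p]}
            ).to_csv(path / f"pair_{p:02d}.csv", index=False)
        trace = pd.DataFrame(
            self.replica_trace,
            columns=[f"slot_{i}" for i in range(len(self.lambdas))],
        )
        trace.insert(0, "cycle", np.arange(len(trace)))
        trace.to_csv(path / "exchange_trace.csv", index=False)
        meta = {
            "lambdas": list(self.lambdas),
            "temperature": self.temperature,
            "burn_in": self.burn_in,
            "exchange_attempts": self.exchange_attempts.tolist(),
            "exchange_accepts": self.exchange_accepts.tolist(),
            "reservoir_attempts": self.reservoir_attempts,
            "reservoir_accepts": self.reservoir_accepts,
        }
        with open(path / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def exchange_attempt(
    ri: ReplicaState, rj: ReplicaState, rng: np.random.Generator
) -> bool:
    """Metropolis swap of two neighboring replicas' conformations.

    Accepts with probability ``min(1, exp(-Delta/kT))`` where
    ``Delta = [U_i(x_j) + U_j(x_i)] - [U_i(x_i) + U_j(x_j)]``; on acceptance
    the conformations (not the lambda slots) are swapped.
    """
    if abs(ri.lambda_index - rj.lambda_index) != 1:
        raise InputError("exchange attempted between non-neighboring replicas")
    kT = ri.spec.temperature
    xi, xj = ri.conformation.x, rj.conformation.x
    delta = (
        energy(ri.spec, xj) + energy(rj.spec, xi)
        - energy(ri.spec, xi) - energy(rj.spec, xj)
    )
    accept = rng.random() < np.exp(min(-delta / kT, 0.0))
    if accept:
        ri.conformation, rj.conformation = rj.conformation, ri.conformation
        ri.refresh_energy()
        rj.refresh_energy()
    return bool(accept)


def reservoir_swap(
    r0: ReplicaState, res: Reservoir, rng: np.random.Generator
) -> tuple[ReplicaState, bool]:
    """Propose a uniformly drawn reservoir conformation for the end replica.

    When the reservoir was built for exactly this replica's Hamiltonian the
    proposal is accepted unconditionally (matched Boltzmann ensembles);
    otherwise a Metropolis test on the ensemble mismatch
    ``Delta = [U_rep(x_new) - U_rep(x_old)]/kT_rep
            - [U_res(x_new) - U_res(x_old)]/kT_res``
    is applied (each difference weighted by its own ensemble's temperature).
    """
    if r0.lambda_index != 0:
        raise InputError("reservoir couples to the lambda = 0 replica only")
    if len(res) == 0:
        raise InputError("reservoir is empty")
    k = int(rng.integers(0, len(res)))
    cand = res.conformations[k]
    matched = res.hamiltonian is not None and res.hamiltonian == r0.spec
    if matched:
        accept = True
        rng.random()  # keep the draw budget identical in both branches
    else:
        d_rep = energy(r0.spec, cand.x) - energy(r0.spec, r0.conformation.x)
        delta = d_rep / r0.spec.temperature
        if res.hamiltonian is not None:
            d_res = energy(res.hamiltonian, cand.x) - energy(
                res.hamiltonian, r0.conformation.x
            )
            delta -= d_res / res.hamiltonian.temperature
        accept = rng.random() < np.exp(min(-delta, 0.0))
    if accept:
        r0.conformation = Conformation(
            x=np.array(cand.x, copy=True),
            v=None,
            meta={**cand.meta, "source": "reservoir_insert"},
        )
        r0.refresh_energy()
    return r0, bool(accept)


def _replica_specs(
    H_R: SystemSpec,
    H_T: SystemSpec,
    schedule: LambdaSchedule,
    coupling_rule: str,
) -> list[SystemSpec]:
    specs = []
    for i, lam in enumerate(schedule.lambdas):
        s = hybridize(HybridSpec(H_R, H_T, lam, coupling_rule))
        if schedule.softness_ladder is not None and schedule.softness_ladder[i] > 0:
            s = soften(
                s,
                SofteningSpec(
                    s=schedule.softness_ladder[i],
                    targets=schedule.soften_targets,
                    floor_fraction=schedule.floor_fraction,
                ),
            )
        specs.append(s)
    return specs


def run_hrex(
    H_R: SystemSpec,
    H_T: SystemSpec,
    schedule: LambdaSchedule,
    n_cycles: int = 800,
    steps_per_cycle: int = 20,
    reservoir: Reservoir | None = None,
    seed: int = 0,
    dt: float = 0.01,
    friction: float = 1.0,
    coupling_rule: str = "linear",
    x0=None,
    burn_in_cycles: int = 0,
) -> HREXResult:
    """Alternate MD bursts, neighbor exchanges, and reservoir insertions.

    Each cycle: every replica runs ``steps_per_cycle`` Langevin steps; the
    per-neighbor forward/backward energy differences are recorded; an
    odd/even alternating sweep of neighbor exchanges is applied; and, when a
    reservoir is attached, one insertion is attempted at lambda = 0.
    """
    if n_cycles < 1:
        raise InputError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    specs = _replica_specs(H_R, H_T, schedule, coupling_rule)
    n_rep = len(specs)
    dim = H_R.dimension
    kT = H_R.temperature

    if x0 is None:
        X = np.zeros((n_rep, dim))
    else:
        x0 = np.atleast_2d(np.asarray(x0, float))
        X = np.repeat(x0, int(np.ceil(n_rep / len(x0))), axis=0)[:n_rep]
    replicas = []
    for i in range(n_rep):
        conf = Conformation(
            x=specs[i].wrap(X[i]),
            v=maxwell_boltzmann_velocities((dim,), kT, rng),
            meta={"source": "hrex_init", "cycle": 0},
        )
        replicas.append(ReplicaState(lambda_index=i, spec=specs[i], conformation=conf))

    n_pairs = n_rep - 1
    fwd = np.empty((n_cycles, n_pairs))
    rev = np.empty((n_cycles, n_pairs))
    attempts = np.zeros(n_pairs, dtype=int)
    accepts = np.zeros(n_pairs, dtype=int)
    trace = np.empty((n_cycles, n_rep), dtype=int)
    samples = np.empty((n_cycles, n_rep, dim))
    ids = np.arange(n_rep)  # replica identity occupying each lambda slot
    res_att = res_acc = 0

    for cyc in range(n_cycles):
        for i, r in enumerate(replicas):
            x = np.atleast_2d(r.conformation.x)
            v = np.atleast_2d(r.conformation.v)
            x, v = _baoab(x, v, r.spec, dt, friction, rng, n_steps=steps_per_cycle)
            r.conformation = Conformation(x=x[0], v=v[0], meta=r.conformation.meta)
        for p in range(n_pairs):
            x_lo = replicas[p].conformation.x
            x_hi = replicas[p + 1].conformation.x
            fwd[cyc, p] = energy(specs[p + 1], x_lo) - energy(specs[p], x_lo)
            rev[cyc, p] = energy(specs[p], x_hi) - energy(specs[p + 1], x_hi)
        start = cyc % 2
        for p in range(start, n_pairs, 2):
            attempts[p] += 1
            swapped = exchange_attempt(replicas[p], replicas[p + 1], rng)
            if swapped:
                accepts[p] += 1
                ids[p], ids[p + 1] = ids[p + 1], ids[p]
        if reservoir is not None:
            res_att += 1
            _, ok = reservoir_swap(replicas[0], reservoir, rng)
            if ok:
                res_acc += 1
                replicas[0].conformation.v = maxwell_boltzmann_velocities(
                    (dim,), kT, rng
                )
        trace[cyc] = ids
        for i, r in enumerate(replicas):
            samples[cyc, i] = r.conformation.x

    return HREXResult(
        lambdas=schedule.lambdas,
        pair_forward=[fwd[:, p] for p in range(n_pairs)],
        pair_reverse=[rev[:, p] for p in range(n_pairs)],
        exchange_attempts=attempts,
        exchange_accepts=accepts,
        replica_trace=trace,
        samples=samples,
        temperature=kT,
        burn_in=burn_in_cycles,
        reservoir_attempts=res_att,
        reservoir_accepts=res_acc,
    )


def chain_free_energy(
    res: HREXResult,
    temperature: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
    block: int = 10,
) -> FreeEnergyEstimate:
    """Chain dG as the sum of per-neighbor-pair BAR estimates.

    The stderr is the quadrature sum of the pair stderrs (pairs use disjoint
    replica samples, so correlations between pair estimates are weak).  The
    pair bootstrap uses moving blocks (default length 10 cycles) because
    consecutive cycles of one replica are autocorrelated.
    """
    kT = float(temperature if temperature is not None else res.temperature)
    total = 0.0
    var = 0.0
    n_min = None
    for p in range(res.n_pairs):
        wf = res.pair_forward[p][res.burn_in :]
        wr = res.pair_reverse[p][res.burn_in :]
        if wf.size < 2 or wr.size < 2:
            raise EstimationError(f"neighbor pair {p} has too few samples")
        est = bar_ml(
            WorkSet(W_F=wf, W_R=wr, temperature=kT),
            n_boot=n_boot,
            block=block,
            seed=seed + p,
        )
        total += est.value
        var += est.stderr**2
        n_min = wf.size if n_min is None else min(n_min, wf.size)
    return FreeEnergyEstimate(total, float(np.sqrt(var)), "hrex_bar", (n_min, n_min))


def reservoir_from_hrex(
    H_nonsoft: SystemSpec,
    soft: SofteningSpec,
    n_states: int = 11,
    n_cycles: int = 400,
    steps_per_cycle: int = 20,
    seed: int = 0,
    dt: float = 0.01,
    friction: float = 1.0,
    burn_in_cycles: int = 40,
    x0=None,
) -> Reservoir:
    """Convert a softened ensemble to a nonsoftened reservoir via HREX.

    Runs replica exchange over a ladder interpolating the softened (state 0)
    and nonsoftened (state 1) Hamiltonians and collects the post-burn-in
    samples of the nonsoftened terminal replica as the reservoir.
    """
    H_soft = soften(H_nonsoft, soft)
    schedule = LambdaSchedule.uniform(n_states)
    out = run_hrex(
        H_soft,
        H_nonsoft,
        schedule,
        n_cycles=n_cycles,
        steps_per_cycle=steps_per_cycle,
        seed=seed,
        dt=dt,
        friction=friction,
        x0=x0,
        burn_in_cycles=burn_in_cycles,
    )
    est = chain_free_energy(out, n_boot=200, seed=seed)
    xs = out.replica_samples(len(schedule) - 1)
    confs = [
        Conformation(x=np.array(x, copy=True), meta={"source": "hrex_reservoir", "cycle": i})
        for i, x in enumerate(xs)
    ]
    rates = out.acceptance_rates
    return Reservoir(
        conformations=confs,
        dG_s_to_ns=est,
        acceptance_ratio=float(np.nanmean(rates)),
        iteration_trace=[est.value],
        hamiltonian=H_nonsoft,
        end_points=xs,
    )
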