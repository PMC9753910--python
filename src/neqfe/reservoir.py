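"""Boltzmann conformation reservoirs from nonequilibrium switching.

The workflow turns equilibrium samples of a *softened* Hamiltonian (lowered
inter-minima barriers, fast conformational transitions) into a Boltzmann-
distributed pool of conformations of the *nonsoftened* Hamiltonian:

0. sample the softened Hamiltonian by Langevin MD;
1. take equally spaced snapshots;
2. run forward switching (softened -> nonsoftened) from every snapshot;
3. first-pass dG(s->ns) from the Jarzynski equality over the forward works;
4. Metropolis-filter the end points: accept i iff
   ``xi_i < min(1, exp(-(W_i - dG)/kT))``;
5. run reverse switching (nonsoftened -> softened) from accepted end points
   only (reverse runs are added lazily as new points get accepted);
6. refine dG with the bidirectional BAR estimator;
7-8. iterate filter/refine (default 500 cycles, with early exit once the
   trace has stabilized);
9. average the post-burn-in dG trace;
10. final filter with the averaged dG gives the reservoir.

The accepted end points approximate the Boltzmann ensemble of the
nonsoftened Hamiltonian; the approximation is exact up to the clipping of
the Metropolis weight at 1 (negligible when most works exceed dG, which the
second law makes typical).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import (
    Conformation,
    SwitchingProtocol,
    read_conformations,
    run_md_ensemble,
    switching_batch,
    write_conformations,
)
from .errors import EstimationError, InputError, ReservoirError
from .estimators import FreeEnergyEstimate, WorkSet, bar_ml, jarzynski
from .systems import SofteningSpec, SystemSpec, soften

__all__ = [
    "Reservoir",
    "ReservoirConfig",
    "metropolis_filter",
    "refine_dg",
    "generate_reservoir",
]


@dataclass(frozen=True)
class ReservoirConfig:
    """Knobs of the reservoir workflow (defaults follow the method's recipe)."""

    n_snapshots: int = 500
    protocol: SwitchingProtocol = field(default_factory=SwitchingProtocol)
    n_refinement_cycles: int = 500
    convergence_tol: float = 0.1  # energy units; early-exit window span
    seed: int = 0
    sample_every: int = 50
    n_walkers: int = 32
    burn_in: int = 2000
    friction: float = 1.0
    dt: float = 0.01

    def __post_init__(self):
        if self.n_refinement_cycles < 1:
            raise InputError("n_refinement_cycles must be >= 1")
        if self.convergence_tol <= 0:
            raise InputError("convergence_tol must be > 0")
        if self.n_snapshots < 1:
            raise InputError("n_snapshots must be >= 1")

    def as_dict(self) -> dict:
        return {
            "n_snapshots": self.n_snapshots,
            "protocol": {
                "duration": self.protocol.duration,
                "timestep": self.protocol.timestep,
            },
            "n_refinement_cycles": self.n_refinement_cycles,
            "convergence_tol": self.convergence_tol,
            "seed": self.seed,
            "sample_every": self.sample_every,
            "n_walkers": self.n_walkers,
            "burn_in": self.burn_in,
            "friction": self.friction,
            "dt": self.dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReservoirConfig":
        d = dict(d)
        proto = d.pop("protocol", {})
        return cls(
            protocol=SwitchingProtocol(
                duration=float(proto.get("duration", 10.0)),
                timestep=float(proto.get("timestep", 0.01)),
            ),
            **{k: v for k, v in d.items()},
        )


@dataclass
class Reservoir:
    """Accepted end-point conformations plus the dG used for filtering."""

    conformations: list
    dG_s_to_ns: FreeEnergyEstimate
    acceptance_ratio: float
    iteration_trace: list
    hamiltonian: SystemSpec | None = None
    works_forward: np.ndarray | None = None
    end_points: np.ndarray | None = None  # all (unfiltered) end points

    def __len__(self) -> int:
        return len(self.conformations)

    def coordinates(self) -> np.ndarray:
        return np.array([c.x for c in self.conformations])

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_conformations(path / "conformations.xyz", self.conformations)
        meta = {
            "acceptance_ratio": float(self.acceptance_ratio),
            "dG_s_to_ns": self.dG_s_to_ns.as_dict(),
            "n_conformations": len(self.conformations),
        }
        if self.hamiltonian is not None:
            meta["hamiltonian"] = self.hamiltonian.as_dict()
        with open(path / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.DataFrame(
            {"cycle": np.arange(len(self.iteration_trace)), "dG": self.iteration_trace}
        ).to_csv(path / "iteration_trace.csv", index=False)

    @classmethod
    def from_dir(cls, path) -> "Reservoir":
        path = Path(path)
        confs = read_conformations(path / "conformations.xyz")
        with open(path / "metadata.json") as fh:
            meta = json.load(fh)
        trace = pd.read_csv(path / "iteration_trace.csv")["dG"].tolist()
        est = FreeEnergyEstimate(
            value=meta["dG_s_to_ns"]["value"],
            stderr=meta["dG_s_to_ns"]["stderr"],
            method=meta["dG_s_to_ns"]["method"],
            n_used=tuple(meta["dG_s_to_ns"].get("n_used", (0, 0))),
        )
        ham = None
        if "hamiltonian" in meta:
            ham = SystemSpec.from_dict(meta["hamiltonian"])
        return cls(
            conformations=confs,
            dG_s_to_ns=est,
            acceptance_ratio=float(meta["acceptance_ratio"]),
            iteration_trace=trace,
            hamiltonian=ham,
        )


def metropolis_filter(
    works,
    dG: float,
    temperature: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Indices accepted by ``xi < min(1, exp(-(W - dG)/kT))``.

    Deterministic under a seeded generator: one uniform draw per work sample,
    in order.
    """
    W = np.asarray(works, dtype=float).ravel()
    if not np.all(np.isfinite(W)):
        raise InputError("non-finite work values")
    if not np.isfinite(dG):
        raise InputError("non-finite dG")
    rng = rng if rng is not None else np.random.default_rng(0)
    xi = rng.random(W.size)
    p = np.exp(np.minimum(-(W - dG) / temperature, 0.0))
    return np.flatnonzero(xi < p)


def refine_dg(
    ws: WorkSet,
    current_dG: float,
    temperature: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FreeEnergyEstimate, np.ndarray]:
    """One filter/refine cycle of the iterative dG(s->ns) procedure.

    ``ws.W_R`` must be aligned with ``ws.W_F`` (reverse run started from the
    end point of forward run i); the cycle re-filters the forward runs with
    ``current_dG`` and re-solves BAR using the reverse works of the accepted
    set.  An empty accepted set returns the previous estimate with a warning.
    """
    if ws.n_F == 0:
        raise EstimationError("refine_dg needs forward works")
    if ws.n_R != ws.n_F:
        raise InputError("refine_dg expects reverse works aligned with forward works")
    kT = float(temperature if temperature is not None else ws.temperature)
    accepted = metropolis_filter(ws.W_F, current_dG, kT, rng)
    if accepted.size == 0:
        warnings.warn("refinement cycle accepted nothing; keeping previous dG", stacklevel=2)
        prev = FreeEnergyEstimate(float(current_dG), 0.0, "bar_ml", (ws.n_F, 0))
        return prev, accepted
    sub = WorkSet(W_F=ws.W_F, W_R=ws.W_R[accepted], temperature=kT)
    est = bar_ml(sub, n_boot=0)
    return est, accepted


def _trace_converged(trace, tol: float, window: int = 10) -> bool:
    if len(trace) < window:
        return False
    tail = np.asarray(trace[-window:])
    return float(tail.max() - tail.min()) < tol


def generate_reservoir(
    H_nonsoft: SystemSpec,
    soft: SofteningSpec,
    cfg: ReservoirConfig,
    x0=None,
) -> Reservoir:
    """Run the full softened-MD -> NEQ -> filter -> refine workflow.

    With ``soft.s == 0`` the softened and nonsoftened Hamiltonians coincide:
    every work is zero, dG = 0, and every snapshot is accepted.
    """
    kT = H_nonsoft.temperature
    H_soft = soften(H_nonsoft, soft)
    rng = np.random.default_rng(cfg.seed)
    md_seed = int(rng.integers(0, 2**31 - 1))

    # steps 0-1: softened sampling, equally spaced snapshots
    snaps = run_md_ensemble(
        H_soft,
        n_samples=cfg.n_snapshots,
        n_walkers=cfg.n_walkers,
        sample_every=cfg.sample_every,
        seed=md_seed,
        x0=x0,
        dt=cfg.dt,
        friction=cfg.friction,
        burn_in=cfg.burn_in,
    )

    # step 2: forward switching runs (softened -> nonsoftened)
    W_F, X_end, _ = switching_batch(
        snaps, H_soft, H_nonsoft, cfg.protocol, rng, friction=cfg.friction
    )
    ok = np.isfinite(W_F)
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} non-finite forward works", stacklevel=2)
        W_F, X_end, snaps = W_F[ok], X_end[ok], snaps[ok]
    n_att = W_F.size

    # step 3: first-pass Jarzynski estimate
    dG = jarzynski(W_F, kT, n_boot=0).value
    trace = [dG]

    # step 4: initial Metropolis filter
    accepted = metropolis_filter(W_F, dG, kT, rng)
    if accepted.size == 0:
        raise ReservoirError(
            "no switching run passed the first Metropolis filter; "
            "use weaker softening or a slower switching protocol"
        )

    # steps 5-8: lazy reverse runs + iterative bidirectional refinement
    rev_proto = cfg.protocol.reversed()
    have_rev = np.zeros(n_att, dtype=bool)
    W_R = np.full(n_att, np.nan)

    def ensure_reverse(idx: np.ndarray) -> None:
        new = idx[~have_rev[idx]]
        if new.size == 0:
            return
        w, _, _ = switching_batch(
            X_end[new], H_nonsoft, H_soft, rev_proto, rng, friction=cfg.friction
        )
        W_R[new] = w
        have_rev[new] = True

    ensure_reverse(accepted)
    for _ in range(cfg.n_refinement_cycles):
        rev = W_R[have_rev]
        rev = rev[np.isfinite(rev)]
        if rev.size:
            dG = bar_ml(WorkSet(W_F=W_F, W_R=rev, temperature=kT), n_boot=0).value
        trace.append(dG)
        if _trace_converged(trace[1:], cfg.convergence_tol):
            break
        accepted = metropolis_filter(W_F, dG, kT, rng)
        ensure_reverse(accepted)

    # step 9: average the bidirectional part of the trace, first 10% burn-in
    bar_trace = np.asarray(trace[1:])
    cut = int(0.1 * bar_trace.size)
    dG_final = float(bar_trace[cut:].mean())

    # step 10: final filter with the averaged dG
    final_idx = metropolis_filter(W_F, dG_final, kT, rng)
    if final_idx.size == 0:
        raise ReservoirError("final filter accepted nothing; reservoir would be empty")
    rev = W_R[have_rev]
    rev = rev[np.isfinite(rev)]
    final_est = bar_ml(WorkSet(W_F=W_F, W_R=rev, temperature=kT), n_boot=200, seed=cfg.seed)
    final_est = FreeEnergyEstimate(
        dG_final, final_est.stderr, "bar_ml", (W_F.size, rev.size)
    )

    confs = [
        Conformation(
            x=X_end[i].copy(),
            meta={"source": "neq_reservoir", "cycle": 0, "id": int(i)},
        )
        for i in final_idx
    ]
    return Reservoir(
        conformations=confs,
        dG_s_to_ns=final_est,
        acceptance_ratio=final_idx.size / n_att,
        iteration_trace=[float(v) for v in trace],
        hamiltonian=H_nonsoft,
        works_forward=W_F,
        end_points=X_end,
    )
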