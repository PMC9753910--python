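"""Canonical sampling and nonequilibrium switching on toy Hamiltonians.

Sampling uses a BAOAB-split Langevin integrator (unit masses) targeting the
canonical distribution at the spec's temperature.  Nonequilibrium switching
drives a linear lambda path between two Hamiltonians; the work is accumulated
as a discrete potential-difference sum with a symmetric (midpoint) splitting:

    half jump  W += U(l_{i+1/2}, x) - U(l_i, x)
    propagate  one Langevin step under the midpoint Hamiltonian
    half jump  W += U(l_{i+1}, x') - U(l_{i+1/2}, x')

Alternating measure-preserving dynamics with instantaneous potential jumps is
exactly the discrete protocol for which the Jarzynski identity holds, and the
symmetric splitting makes a forward run followed by its exact time-reversed
path accumulate zero total work in the deterministic (zero-friction,
zero-noise) limit.

All randomness flows from one seeded ``numpy.random.Generator`` per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, IntegrationError
from .systems import HybridSpec, SystemSpec, energy, gradient, hybridize

__all__ = [
    "Conformation",
    "SwitchingProtocol",
    "WorkRecord",
    "langevin_step",
    "run_md",
    "run_md_ensemble",
    "switching_run",
    "switching_batch",
    "maxwell_boltzmann_velocities",
    "write_conformations",
    "read_conformations",
    "conformations_to_frame",
    "work_records_to_frame",
]


@dataclass
class Conformation:
    """Coordinates (and optionally velocities) with provenance metadata."""

    x: np.ndarray
    v: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.v is not None:
            self.v = np.asarray(self.v, dtype=float)
            if self.v.shape != self.x.shape:
                raise InputError("velocity shape must match coordinate shape")
        if int(self.meta.get("cycle", 0)) < 0:
            raise InputError("meta.cycle must be >= 0")


@dataclass(frozen=True)
class SwitchingProtocol:
    """Linear lambda path of duration T with timestep dt.

    ``direction="forward"`` switches softened -> nonsoftened (the first spec
    argument to :func:`switching_run` toward the second); ``"reverse"`` is
    the opposite labelling for bookkeeping in work tables.  ``T = 0`` is the
    instantaneous limit where the work is a single potential difference.
    """

    duration: float = 10.0
    timestep: float = 0.01
    lambda_path: str = "linear"
    direction: str = "forward"

    def __post_init__(self):
        if self.duration < 0:
            raise ConfigurationError("duration must be >= 0")
        if self.timestep <= 0:
            raise ConfigurationError("timestep must be > 0")
        if self.lambda_path != "linear":
            raise ConfigurationError(f"unknown lambda path {self.lambda_path!r}")
        if self.direction not in ("forward", "reverse"):
            raise ConfigurationError("direction must be 'forward' or 'reverse'")
        steps = self.duration / self.timestep
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigurationError("duration must be an integer number of timesteps")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.timestep))

    def reversed(self) -> "SwitchingProtocol":
        other = "reverse" if self.direction == "forward" else "forward"
        return SwitchingProtocol(self.duration, self.timestep, self.lambda_path, other)


@dataclass
class WorkRecord:
    direction: str
    work: float
    start_id: int
    end_conformation: Conformation
    seed: int = 0
    flagged: bool = False  # non-finite work; excluded downstream


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def maxwell_boltzmann_velocities(shape, kT: float, rng: np.random.Generator) -> np.ndarray:
    """Velocities drawn from the Maxwell-Boltzmann distribution (unit mass)."""
    return rng.normal(0.0, np.sqrt(kT), size=shape)


def _force(spec: SystemSpec, X: np.ndarray) -> np.ndarray:
    F = -gradient(spec, X)
    if not np.all(np.isfinite(F)):
        raise IntegrationError(
            f"non-finite force encountered at x={X[~np.isfinite(F).all(axis=-1)][:3]!r}"
        )
    return F


def _baoab(
    X: np.ndarray,
    V: np.ndarray,
    spec: SystemSpec,
    dt: float,
    friction: float,
    rng: np.random.Generator,
    n_steps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized BAOAB steps on an ensemble (X, V of shape (n, dim))."""
    kT = spec.temperature
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    F = _force(spec, X)
    for _ in range(n_steps):
        V = V + 0.5 * dt * F
        X = X + 0.5 * dt * V
        if c2 > 0.0:
            V = c1 * V + c2 * rng.standard_normal(V.shape)
        else:
            V = c1 * V
        X = X + 0.5 * dt * V
        X = spec.wrap(X)
        F = _force(spec, X)
        V = V + 0.5 * dt * F
    return X, V


def langevin_step(
    c: Conformation,
    spec: SystemSpec,
    dt: float = 0.01,
    friction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Conformation:
    """One BAOAB update of a single conformation (deterministic given rng state)."""
    if friction < 0:
        raise InputError("friction must be >= 0")
    if not np.all(np.isfinite(c.x)):
        raise InputError("non-finite coordinates")
    rng = rng if rng is not None else np.random.default_rng(0)
    X = np.atleast_2d(spec.wrap(c.x))
    if c.v is None:
        V = maxwell_boltzmann_velocities(X.shape, spec.temperature, rng)
    else:
        V = np.atleast_2d(c.v).copy()
    X, V = _baoab(X, V, spec, dt, friction, rng)
    meta = dict(c.meta)
    return Conformation(x=X[0], v=V[0], meta=meta)


# ---------------------------------------------------------------------------
# equilibrium sampling
# ---------------------------------------------------------------------------

def run_md(
    spec: SystemSpec,
    n_steps: int,
    sample_every: int,
    seed: int = 0,
    x0=None,
    dt: float = 0.01,
    friction: float = 1.0,
    burn_in: int = 0,
) -> list[Conformation]:
    """A single Langevin trajectory; equally spaced snapshots.

    Returns ``floor(n_steps / sample_every)`` conformations taken every
    ``sample_every`` steps after ``burn_in`` equilibration steps.
    """
    if n_steps < sample_every:
        raise InputError("n_steps must be >= sample_every")
    rng = np.random.default_rng(seed)
    X = np.zeros((1, spec.dimension)) if x0 is None else np.atleast_2d(np.asarray(x0, float))
    X = spec.wrap(X)
    V = maxwell_boltzmann_velocities(X.shape, spec.temperature, rng)
    if burn_in:
        X, V = _baoab(X, V, spec, dt, friction, rng, n_steps=burn_in)
    out = []
    n_snap = n_steps // sample_every
    for i in range(n_snap):
        X, V = _baoab(X, V, spec, dt, friction, rng, n_steps=sample_every)
        out.append(
            Conformation(x=X[0].copy(), v=V[0].copy(), meta={"source": "md", "cycle": i})
        )
    return out


def run_md_ensemble(
    spec: SystemSpec,
    n_samples: int,
    n_walkers: int = 32,
    sample_every: int = 50,
    seed: int = 0,
    x0=None,
    dt: float = 0.01,
    friction: float = 1.0,
    burn_in: int = 1000,
) -> np.ndarray:
    """Near-independent equilibrium samples from parallel Langevin walkers.

    Walkers are propagated together (vectorized); samples are collected
    round-robin across walkers every ``sample_every`` steps after a common
    burn-in.  Returns an array of shape (n_samples, dim).
    """
    rng = np.random.default_rng(seed)
    if x0 is None:
        X = np.zeros((n_walkers, spec.dimension))
    else:
        x0 = np.atleast_2d(np.asarray(x0, float))
        X = np.repeat(x0, int(np.ceil(n_walkers / len(x0))), axis=0)[:n_walkers]
    X = spec.wrap(X)
    V = maxwell_boltzmann_velocities(X.shape, spec.temperature, rng)
    X, V = _baoab(X, V, spec, dt, friction, rng, n_steps=burn_in)
    rounds = int(np.ceil(n_samples / n_walkers))
    samples = np.empty((rounds * n_walkers, spec.dimension))
    for r in range(rounds):
        X, V = _baoab(X, V, spec, dt, friction, rng, n_steps=sample_every)
        samples[r * n_walkers : (r + 1) * n_walkers] = X
    return samples[:n_samples]


# ---------------------------------------------------------------------------
# nonequilibrium switching
# ---------------------------------------------------------------------------

def switching_batch(
    X0: np.ndarray,
    H_start: SystemSpec,
    H_end: SystemSpec,
    protocol: SwitchingProtocol,
    rng: np.random.Generator,
    V0: np.ndarray | None = None,
    friction: float = 1.0,
    coupling_rule: str = "linear",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized nonequilibrium switching runs from a batch of start points.

    Drives lambda linearly 0 -> 1 between ``H_start`` and ``H_end`` over the
    protocol duration, accumulating the midpoint-split potential-difference
    work per walker.  Returns ``(W, X_end, V_end)``.  Velocities are redrawn
    from Maxwell-Boltzmann unless ``V0`` is given (the redraw-vs-reuse switch
    for the start of a switching run).
    """
    X = H_start.wrap(np.atleast_2d(np.asarray(X0, float)))
    kT = H_start.temperature
    if V0 is None:
        V = maxwell_boltzmann_velocities(X.shape, kT, rng)
    else:
        V = np.array(V0, dtype=float, copy=True)
    n = protocol.n_steps
    dt = protocol.timestep
    if n == 0:  # instantaneous switch: a single potential jump
        W = energy(H_end, X) - energy(H_start, X)
        return W, X, V

    def spec_at(lam: float) -> SystemSpec:
        return hybridize(HybridSpec(H_start, H_end, lam, coupling_rule))

    W = np.zeros(X.shape[0])
    u_prev = energy(H_start, X)
    for i in range(n):
        lam_mid = (i + 0.5) / n
        lam_next = (i + 1.0) / n
        spec_mid = spec_at(lam_mid)
        W += energy(spec_mid, X) - u_prev
        X, V = _baoab(X, V, spec_mid, dt, friction, rng)
        u_mid = energy(spec_mid, X)
        spec_next = spec_at(lam_next)
        u_prev = energy(spec_next, X)
        W += u_prev - u_mid
    return W, X, V


def switching_run(
    start: Conformation,
    H_soft: SystemSpec,
    H_nonsoft: SystemSpec,
    protocol: SwitchingProtocol,
    rng: np.random.Generator | None = None,
    friction: float = 1.0,
    reuse_velocities: bool = False,
    seed: int = 0,
) -> WorkRecord:
    """One switching run; direction labels the soft->nonsoft orientation.

    With ``direction="forward"`` the Hamiltonian is driven from ``H_soft`` to
    ``H_nonsoft``; ``"reverse"`` drives the opposite way.  A non-finite work
    yields a flagged record that downstream consumers exclude.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if protocol.direction == "forward":
        H_a, H_b = H_soft, H_nonsoft
    else:
        H_a, H_b = H_nonsoft, H_soft
    V0 = None
    if reuse_velocities and start.v is not None:
        V0 = np.atleast_2d(start.v)
    W, X, V = switching_batch(
        np.atleast_2d(start.x), H_a, H_b, protocol, rng, V0=V0, friction=friction
    )
    w = float(W[0])
    end = Conformation(
        x=X[0],
        v=V[0],
        meta={
            "source": f"neq_{protocol.direction}",
            "cycle": int(start.meta.get("cycle", 0)),
            "parent": int(start.meta.get("id", start.meta.get("cycle", 0))),
        },
    )
    return WorkRecord(
        direction=protocol.direction,
        work=w,
        start_id=int(start.meta.get("id", start.meta.get("cycle", 0))),
        end_conformation=end,
        seed=seed,
        flagged=not np.isfinite(w),
    )


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def _meta_str(meta: dict) -> str:
    return " ".join(f"{k}={meta[k]}" for k in sorted(meta))


def write_conformations(path, confs) -> None:
    """XYZ-like text format: count line, '#' meta line, one row of floats."""
    with open(path, "w") as fh:
        for c in confs:
            fh.write(f"{c.x.size}\n")
            fh.write(f"# {_meta_str(c.meta)}\n")
            fh.write(" ".join(repr(float(v)) for v in np.ravel(c.x)) + "\n")


def read_conformations(path) -> list[Conformation]:
    confs = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        meta: dict = {}
        for tok in lines[i + 1].lstrip("# ").split():
            k, _, v = tok.partition("=")
            try:
                meta[k] = int(v)
            except ValueError:
                meta[k] = v
        x = np.array([float(t) for t in lines[i + 2].split()])
        if x.size != n:
            raise InputError(f"conformation block at line {i + 1} has wrong length")
        confs.append(Conformation(x=x, meta=meta))
        i += 3
    return confs


def conformations_to_frame(confs) -> pd.DataFrame:
    """Columnar table: one row per conformation, x0..x{d-1} plus metadata."""
    dim = confs[0].x.size
    data = {f"x{j}": [float(c.x[j]) for c in confs] for j in range(dim)}
    data["source"] = [c.meta.get("source", "") for c in confs]
    data["cycle"] = [int(c.meta.get("cycle", 0)) for c in confs]
    return pd.DataFrame(data)


def work_records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "direction": r.direction,
            "work": r.work,
            "start_id": r.start_id,
            "seed": r.seed,
            "flagged": r.flagged,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["direction", "work", "start_id", "seed", "flagged"])
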