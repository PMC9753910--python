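"""Toy Hamiltonians with softening and lambda coupling, plus exact oracles.

A :class:`SystemSpec` is a sum of low-dimensional potential terms standing in
for a molecular Hamiltonian:

* ``harmonic`` -- ``U = k/2 (x - x0)^2`` (restraints; never softened),
* ``periodic_torsion`` -- ``U = V/2 (1 + cos(n*phi - phase))`` so the barrier
  height between adjacent minima is literally ``V``,
* ``double_well`` -- ``U = b ((x/a)^2 - 1)^2`` with minima at ``+-a`` and a
  barrier ``b`` at the origin,
* ``external_binding`` -- a Gaussian well ``U = -depth exp(-(x-c)^2 / 2 w^2)``
  modelling an environment (binding-site) interaction,
* ``pair_soft_repulsion`` -- ``U = eps exp(-(xi - xj)^2 / sigma^2)`` coupling
  two coordinates.

"Softening" multiplies barrier-like amplitudes (``V``, ``b``, ``eps`` and the
environment well ``depth``) by ``(1 - s*c)`` to lower inter-minima barriers
without touching harmonic restraints.  Hybrid Hamiltonians interpolate two
specs with matching term structure linearly in the parameters (an optional
soft-core rule handles appearing/disappearing pair repulsions).  Because the
systems are 1-3 dimensional, free-energy differences have an exact oracle by
numerical quadrature of the partition functions.

Temperatures are stored as kT in reduced energy units (kT = 1 by default); a
kcal/mol convention at 298 K is available through :func:`kt_kcal_mol`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import ClassVar

import numpy as np
import yaml

from .errors import ConfigurationError, InputError, UnsupportedError
from .estimators import FreeEnergyEstimate

__all__ = [
    "Domain",
    "Harmonic",
    "PeriodicTorsion",
    "DoubleWell",
    "ExternalBinding",
    "PairSoftRepulsion",
    "SystemSpec",
    "SofteningSpec",
    "HybridSpec",
    "energy",
    "gradient",
    "soften",
    "hybridize",
    "hybrid_energy",
    "quadrature_free_energy",
    "boltzmann_marginal",
    "marginal_cdf",
    "spec_to_yaml",
    "spec_from_yaml",
    "softening_to_yaml",
    "softening_from_yaml",
    "kt_kcal_mol",
    "wrap_periodic",
]

#: Boltzmann constant in kcal mol^-1 K^-1 (CODATA), for the kcal/mol mode.
K_B_KCAL = 0.0019872041


def kt_kcal_mol(T: float = 298.0) -> float:
    """kT in kcal/mol at temperature ``T`` (kelvin); the 298 K convention."""
    return K_B_KCAL * T


def wrap_periodic(x):
    """Wrap angles into the canonical interval [-pi, pi)."""
    return np.mod(np.asarray(x) + np.pi, 2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class Domain:
    """Integration/sampling domain of one coordinate.

    ``kind`` is ``"periodic"`` (fixed [-pi, pi)) or ``"real"`` with finite
    bounds used by the quadrature oracle; real-line dynamics is confined by
    the potential itself, not by the bounds.
    """

    kind: str = "real"
    lo: float = -8.0
    hi: float = 8.0

    def __post_init__(self):
        if self.kind not in ("real", "periodic"):
            raise ConfigurationError(f"unknown domain kind {self.kind!r}")
        if self.kind == "periodic":
            object.__setattr__(self, "lo", -math.pi)
            object.__setattr__(self, "hi", math.pi)
        elif not (self.lo < self.hi):
            raise ConfigurationError("domain requires lo < hi")

    @property
    def periodic(self) -> bool:
        return self.kind == "periodic"

    def as_dict(self) -> dict:
        if self.periodic:
            return {"kind": "periodic"}
        return {"kind": "real", "lo": float(self.lo), "hi": float(self.hi)}

    @classmethod
    def from_dict(cls, d: dict) -> "Domain":
        if d.get("kind") == "periodic":
            return cls(kind="periodic")
        return cls(kind="real", lo=float(d["lo"]), hi=float(d["hi"]))


# ---------------------------------------------------------------------------
# potential terms
# ---------------------------------------------------------------------------

class _Term:
    """Shared term behaviour: (de)serialization, softening bookkeeping."""

    kind: ClassVar[str]
    amplitude_params: ClassVar[tuple] = ()

    def coords_used(self) -> tuple:
        raise NotImplementedError

    def energy(self, X: np.ndarray, domains) -> np.ndarray:
        raise NotImplementedError

    def add_grad(self, X: np.ndarray, domains, out: np.ndarray) -> None:
        raise NotImplementedError

    def as_dict(self) -> dict:
        d = {"type": self.kind}
        d.update(dataclasses.asdict(self))
        return d

    def scaled(self, factor: float) -> "_Term":
        """Return a copy with amplitude parameters scaled by ``factor``."""
        if not self.amplitude_params:
            raise ConfigurationError(
                f"term {self.name!r} ({self.kind}) has no softenable amplitude"
            )
        return dataclasses.replace(
            self, **{p: getattr(self, p) * factor for p in self.amplitude_params}
        )


@dataclass(frozen=True)
class Harmonic(_Term):
    coord: int
    k: float
    x0: float = 0.0
    name: str = ""
    kind: ClassVar[str] = "harmonic"
    amplitude_params: ClassVar[tuple] = ()  # restraints are never softened

    def __post_init__(self):
        if self.k < 0:
            raise ConfigurationError("harmonic k must be >= 0")

    def coords_used(self):
        return (self.coord,)

    def energy(self, X, domains):
        d = X[:, self.coord] - self.x0
        return 0.5 * self.k * d * d

    def add_grad(self, X, domains, out):
        out[:, self.coord] += self.k * (X[:, self.coord] - self.x0)


@dataclass(frozen=True)
class PeriodicTorsion(_Term):
    coord: int
    barrier: float
    multiplicity: int = 1
    phase: float = 0.0
    name: str = ""
    kind: ClassVar[str] = "periodic_torsion"
    amplitude_params: ClassVar[tuple] = ("barrier",)

    def __post_init__(self):
        if self.barrier < 0:
            raise ConfigurationError("torsion barrier must be >= 0")
        if self.multiplicity < 1:
            raise ConfigurationError("torsion multiplicity must be >= 1")

    def coords_used(self):
        return (self.coord,)

    def energy(self, X, domains):
        phi = X[:, self.coord]
        return 0.5 * self.barrier * (1.0 + np.cos(self.multiplicity * phi - self.phase))

    def add_grad(self, X, domains, out):
        phi = X[:, self.coord]
        out[:, self.coord] += (
            -0.5 * self.barrier * self.multiplicity
            * np.sin(self.multiplicity * phi - self.phase)
        )


@dataclass(frozen=True)
class DoubleWell(_Term):
    coord: int
    barrier: float
    separation: float = 1.0
    name: str = ""
    kind: ClassVar[str] = "double_well"
    amplitude_params: ClassVar[tuple] = ("barrier",)

    def __post_init__(self):
        if self.barrier < 0:
            raise ConfigurationError("double-well barrier must be >= 0")
        if self.separation <= 0:
            raise ConfigurationError("double-well separation must be > 0")

    def coords_used(self):
        return (self.coord,)

    def energy(self, X, domains):
        u = (X[:, self.coord] / self.separation) ** 2 - 1.0
        return self.barrier * u * u

    def add_grad(self, X, domains, out):
        x = X[:, self.coord]
        u = (x / self.separation) ** 2 - 1.0
        out[:, self.coord] += 4.0 * self.barrier * x * u / self.separation**2


@dataclass(frozen=True)
class ExternalBinding(_Term):
    coord: int
    depth: float
    width: float = 0.5
    center: float = 0.0
    name: str = ""
    kind: ClassVar[str] = "external_binding"
    amplitude_params: ClassVar[tuple] = ("depth",)

    def __post_init__(self):
        if self.depth < 0:
            raise ConfigurationError("binding well depth must be >= 0")
        if self.width <= 0:
            raise ConfigurationError("binding well width must be > 0")

    def coords_used(self):
        return (self.coord,)

    def _dx(self, X, domains):
        d = X[:, self.coord] - self.center
        if domains[self.coord].periodic:
            d = wrap_periodic(d)
        return d

    def energy(self, X, domains):
        d = self._dx(X, domains)
        return -self.depth * np.exp(-(d * d) / (2.0 * self.width**2))

    def add_grad(self, X, domains, out):
        d = self._dx(X, domains)
        g = self.depth * d / self.width**2 * np.exp(-(d * d) / (2.0 * self.width**2))
        out[:, self.coord] += g


@dataclass(frozen=True)
class PairSoftRepulsion(_Term):
    coord_i: int
    coord_j: int
    epsilon: float
    sigma: float = 1.0
    name: str = ""
    kind: ClassVar[str] = "pair_soft_repulsion"
    amplitude_params: ClassVar[tuple] = ("epsilon",)

    def __post_init__(self):
        if self.epsilon < 0:
            raise ConfigurationError("pair repulsion epsilon must be >= 0")
        if self.sigma <= 0:
            raise ConfigurationError("pair repulsion sigma must be > 0")
        if self.coord_i == self.coord_j:
            raise ConfigurationError("pair repulsion needs two distinct coordinates")

    def coords_used(self):
        return (self.coord_i, self.coord_j)

    def _dr(self, X, domains):
        d = X[:, self.coord_i] - X[:, self.coord_j]
        if domains[self.coord_i].periodic and domains[self.coord_j].periodic:
            d = wrap_periodic(d)
        return d

    def energy(self, X, domains):
        r = self._dr(X, domains)
        return self.epsilon * np.exp(-(r * r) / self.sigma**2)

    def add_grad(self, X, domains, out):
        r = self._dr(X, domains)
        g = -2.0 * self.epsilon * r / self.sigma**2 * np.exp(-(r * r) / self.sigma**2)
        out[:, self.coord_i] += g
        out[:, self.coord_j] -= g


@dataclass(frozen=True)
class _SoftcorePair(_Term):
    """Lambda-coupled appearing/disappearing pair repulsion.

    ``U = w * eps * exp(-(r^2 + alpha*(1-lam)*sigma^2) / sigma^2)`` with the
    overall weight ``w`` interpolating the endpoint amplitudes; the shifted
    "distance" keeps the energy finite and smooth at all lambda.  Internal:
    produced by :func:`hybridize`, not part of the config-file vocabulary.
    """

    coord_i: int
    coord_j: int
    epsilon: float
    sigma: float
    lam: float
    alpha: float = 1.0
    name: str = ""
    kind: ClassVar[str] = "_softcore_pair"
    amplitude_params: ClassVar[tuple] = ("epsilon",)

    def coords_used(self):
        return (self.coord_i, self.coord_j)

    def _dr(self, X, domains):
        d = X[:, self.coord_i] - X[:, self.coord_j]
        if domains[self.coord_i].periodic and domains[self.coord_j].periodic:
            d = wrap_periodic(d)
        return d

    def energy(self, X, domains):
        r = self._dr(X, domains)
        shift = self.alpha * (1.0 - self.lam)
        return self.epsilon * np.exp(-(r * r / self.sigma**2 + shift))

    def add_grad(self, X, domains, out):
        r = self._dr(X, domains)
        shift = self.alpha * (1.0 - self.lam)
        g = -2.0 * self.epsilon * r / self.sigma**2 * np.exp(-(r * r / self.sigma**2 + shift))
        out[:, self.coord_i] += g
        out[:, self.coord_j] -= g


_TERM_TYPES = {
    t.kind: t
    for t in (Harmonic, PeriodicTorsion, DoubleWell, ExternalBinding, PairSoftRepulsion)
}


def _term_from_dict(d: dict) -> _Term:
    d = dict(d)
    kind = d.pop("type")
    if kind not in _TERM_TYPES:
        raise ConfigurationError(f"unknown term type {kind!r}")
    return _TERM_TYPES[kind](**d)


# ---------------------------------------------------------------------------
# system / softening / hybrid specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemSpec:
    """A toy Hamiltonian: potential terms on a low-dimensional domain."""

    dimension: int
    terms: tuple
    temperature: float = 1.0  # kT in energy units
    coordinates: tuple = ()

    def __post_init__(self):
        if self.dimension < 1:
            raise ConfigurationError("dimension must be a positive integer")
        if self.temperature < 0:
            raise ConfigurationError("temperature (kT) must be >= 0")
        object.__setattr__(self, "terms", tuple(self.terms))
        coords = tuple(self.coordinates) or tuple(Domain() for _ in range(self.dimension))
        if len(coords) != self.dimension:
            raise ConfigurationError("one coordinate domain per dimension required")
        object.__setattr__(self, "coordinates", coords)
        for t in self.terms:
            for c in t.coords_used():
                if not (0 <= c < self.dimension):
                    raise ConfigurationError(
                        f"term {t.name!r} references coordinate {c} "
                        f"outside dimension {self.dimension}"
                    )

    def term_named(self, name: str) -> _Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise ConfigurationError(f"no term named {name!r}")

    @property
    def periodic_mask(self) -> np.ndarray:
        return np.array([d.periodic for d in self.coordinates])

    def wrap(self, X: np.ndarray) -> np.ndarray:
        """Wrap periodic coordinates of ``X`` (last axis = dimension)."""
        X = np.array(X, dtype=float, copy=True)
        mask = self.periodic_mask
        if mask.any():
            X[..., mask] = wrap_periodic(X[..., mask])
        return X

    def as_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "temperature": float(self.temperature),
            "coordinates": [d.as_dict() for d in self.coordinates],
            "terms": [t.as_dict() for t in self.terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SystemSpec":
        return cls(
            dimension=int(d["dimension"]),
            temperature=float(d.get("temperature", 1.0)),
            coordinates=tuple(Domain.from_dict(c) for c in d.get("coordinates", [])),
            terms=tuple(_term_from_dict(t) for t in d["terms"]),
        )


@dataclass(frozen=True)
class SofteningSpec:
    """Barrier softening: scale targeted amplitudes by ``(1 - s * c)``.

    ``s`` is the dimensionless softness in [0, 1]; ``floor_fraction`` c is the
    fraction of the barrier removed at full softness, so the scale factor
    stays in [0, 1] and ``s = 0`` is the identity.
    """

    s: float
    targets: tuple
    floor_fraction: float = 0.8

    def __post_init__(self):
        if not (0.0 <= self.s <= 1.0):
            raise ConfigurationError("softness s must be in [0, 1]")
        if not (0.0 <= self.floor_fraction <= 1.0):
            raise ConfigurationError("floor_fraction must be in [0, 1]")
        object.__setattr__(self, "targets", tuple(self.targets))

    @property
    def scale(self) -> float:
        return 1.0 - self.s * self.floor_fraction

    def with_softness(self, s: float) -> "SofteningSpec":
        return dataclasses.replace(self, s=s)

    def as_dict(self) -> dict:
        return {
            "s": float(self.s),
            "targets": list(self.targets),
            "floor_fraction": float(self.floor_fraction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SofteningSpec":
        return cls(
            s=float(d["s"]),
            targets=tuple(d["targets"]),
            floor_fraction=float(d.get("floor_fraction", 0.8)),
        )


@dataclass(frozen=True)
class HybridSpec:
    """Two endpoint Hamiltonians coupled by a scalar lambda in [0, 1]."""

    H_R: SystemSpec
    H_T: SystemSpec
    lam: float
    coupling_rule: str = "linear"

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise ConfigurationError("lambda must be in [0, 1]")
        if self.coupling_rule not in ("linear", "linear_with_softcore"):
            raise ConfigurationError(f"unknown coupling rule {self.coupling_rule!r}")
        a, b = self.H_R, self.H_T
        if a.dimension != b.dimension or a.coordinates != b.coordinates:
            raise ConfigurationError("hybrid endpoints must share dimension and domains")
        if not np.isclose(a.temperature, b.temperature):
            raise ConfigurationError("hybrid endpoints must share temperature")
        if len(a.terms) != len(b.terms):
            raise ConfigurationError("hybrid endpoints must have matching term lists")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def energy(spec: SystemSpec, x) -> float | np.ndarray:
    """Total potential energy at ``x`` (shape (dim,) or (n, dim))."""
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != spec.dimension:
        raise InputError(
            f"coordinate vector has length {X.shape[1]}, expected {spec.dimension}"
        )
    e = np.zeros(X.shape[0])
    for t in spec.terms:
        e += t.energy(X, spec.coordinates)
    return float(e[0]) if single else e


def gradient(spec: SystemSpec, x) -> np.ndarray:
    """Gradient dU/dx at ``x`` (same leading shape as the input)."""
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != spec.dimension:
        raise InputError(
            f"coordinate vector has length {X.shape[1]}, expected {spec.dimension}"
        )
    g = np.zeros_like(X)
    for t in spec.terms:
        t.add_grad(X, spec.coordinates, g)
    return g[0] if single else g


def soften(spec: SystemSpec, soft: SofteningSpec) -> SystemSpec:
    """Scale the targeted barrier amplitudes by ``(1 - s*c)``.

    ``s = 0`` returns a spec equal to the input; targeting a term without a
    softenable amplitude (e.g. a harmonic restraint) is a configuration error.
    """
    names = [t.name for t in spec.terms]
    for tgt in soft.targets:
        if tgt not in names:
            raise ConfigurationError(f"softening target {tgt!r} not in spec")
    if soft.s == 0.0:
        return spec
    factor = soft.scale
    new_terms = tuple(
        t.scaled(factor) if t.name in soft.targets else t for t in spec.terms
    )
    return dataclasses.replace(spec, terms=new_terms)


def _mix_terms(ta: _Term, tb: _Term, lam: float, rule: str) -> _Term:
    if type(ta) is not type(tb) or ta.coords_used() != tb.coords_used():
        raise ConfigurationError(
            f"cannot couple term {ta.name!r} ({ta.kind}) with {tb.name!r} ({tb.kind})"
        )
    if isinstance(ta, PeriodicTorsion) and ta.multiplicity != tb.multiplicity:
        raise ConfigurationError("cannot interpolate torsion multiplicity")
    if (
        rule == "linear_with_softcore"
        and isinstance(ta, PairSoftRepulsion)
        and (ta.epsilon == 0.0) != (tb.epsilon == 0.0)
    ):
        # appearing/disappearing repulsion: lambda-shifted soft-core form
        ref = tb if ta.epsilon == 0.0 else ta
        weight = lam if ta.epsilon == 0.0 else (1.0 - lam)
        grow = lam if ta.epsilon == 0.0 else (1.0 - lam)
        return _SoftcorePair(
            coord_i=ref.coord_i,
            coord_j=ref.coord_j,
            epsilon=weight * ref.epsilon,
            sigma=ref.sigma,
            lam=grow,
            name=ref.name,
        )
    fields = {}
    for f in dataclasses.fields(ta):
        va, vb = getattr(ta, f.name), getattr(tb, f.name)
        if isinstance(va, float) and not isinstance(va, bool):
            fields[f.name] = (1.0 - lam) * va + lam * vb
        else:
            if va != vb:
                raise ConfigurationError(
                    f"non-interpolable field {f.name!r} differs between endpoints"
                )
            fields[f.name] = va
    return type(ta)(**fields)


def hybridize(h: HybridSpec) -> SystemSpec:
    """Materialize the hybrid Hamiltonian at its lambda as a concrete spec.

    The endpoints are returned as-is (bit-exact) at lambda 0 and 1.
    """
    if h.lam == 0.0:
        return h.H_R
    if h.lam == 1.0:
        return h.H_T
    terms = tuple(
        _mix_terms(ta, tb, h.lam, h.coupling_rule)
        for ta, tb in zip(h.H_R.terms, h.H_T.terms)
    )
    return dataclasses.replace(h.H_R, terms=terms)


def hybrid_energy(h: HybridSpec, x) -> float | np.ndarray:
    """Energy of the lambda-coupled Hamiltonian at ``x``."""
    return energy(hybridize(h), x)


# ---------------------------------------------------------------------------
# quadrature oracles
# ---------------------------------------------------------------------------

def _axis_points(dom: Domain, n: int) -> np.ndarray:
    if dom.periodic:
        # uniform grid without the duplicated endpoint: trapezoid == rectangle
        return np.linspace(dom.lo, dom.hi, n, endpoint=False)
    return np.linspace(dom.lo, dom.hi, n)


def _log_partition(spec: SystemSpec, n: int) -> float:
    """log Z by tensor-grid trapezoid quadrature (dimension <= 3)."""
    axes = [_axis_points(d, n) for d in spec.coordinates]
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([m.ravel() for m in mesh], axis=-1)
    U = energy(spec, X).reshape(mesh[0].shape)
    logw = -U / spec.temperature
    m = logw.max()
    w = np.exp(logw - m)
    for axis in reversed(range(spec.dimension)):
        dom = spec.coordinates[axis]
        if dom.periodic:
            h = (dom.hi - dom.lo) / len(axes[axis])
            w = w.sum(axis=axis) * h
        else:
            w = np.trapezoid(w, axes[axis], axis=axis)
    return float(m + np.log(w))


def quadrature_free_energy(
    spec_a: SystemSpec, spec_b: SystemSpec, grid: int | None = None
) -> FreeEnergyEstimate:
    """Exact ``dG = -kT ln(Z_b / Z_a)`` by deterministic quadrature.

    The quoted uncertainty is the change under halving the grid, i.e. a
    grid-refinement delta rather than a statistical error.
    """
    if spec_a.dimension != spec_b.dimension or spec_a.coordinates != spec_b.coordinates:
        raise ConfigurationError("quadrature endpoints must share dimension and domains")
    if not np.isclose(spec_a.temperature, spec_b.temperature):
        raise ConfigurationError("quadrature endpoints must share temperature")
    if spec_a.temperature <= 0:
        raise ConfigurationError("quadrature needs a positive temperature")
    dim = spec_a.dimension
    if dim > 3:
        raise UnsupportedError("quadrature oracle supports dimension <= 3")
    if grid is None:
        grid = {1: 4096, 2: 512, 3: 96}[dim]
    kT = spec_a.temperature
    if spec_a == spec_b:
        return FreeEnergyEstimate(0.0, 0.0, "quadrature", (grid**dim, grid**dim))

    def dg(n):
        return -kT * (_log_partition(spec_b, n) - _log_partition(spec_a, n))

    full = dg(grid)
    half = dg(grid // 2)
    return FreeEnergyEstimate(full, abs(full - half), "quadrature", (grid**dim, grid**dim))


def boltzmann_marginal(
    spec: SystemSpec, coord: int = 0, grid: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Exact marginal Boltzmann density of one coordinate on a grid.

    Returns ``(points, pdf)`` with the density normalized by trapezoid
    quadrature on the returned points.
    """
    if not (0 <= coord < spec.dimension):
        raise InputError(f"coordinate {coord} outside dimension {spec.dimension}")
    if spec.temperature <= 0:
        raise ConfigurationError("marginal density needs a positive temperature")
    if spec.dimension > 3:
        raise UnsupportedError("marginal oracle supports dimension <= 3")
    n_other = max(grid // 8, 128)
    axes = [
        _axis_points(d, grid if i == coord else n_other)
        for i, d in enumerate(spec.coordinates)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([m.ravel() for m in mesh], axis=-1)
    U = energy(spec, X).reshape(mesh[0].shape)
    logw = -U / spec.temperature
    w = np.exp(logw - logw.max())
    for axis in reversed(range(spec.dimension)):
        if axis == coord:
            continue
        dom = spec.coordinates[axis]
        if dom.periodic:
            w = w.sum(axis=axis) * (dom.hi - dom.lo) / len(axes[axis])
        else:
            w = np.trapezoid(w, axes[axis], axis=axis)
    pts = axes[coord]
    dom = spec.coordinates[coord]
    if dom.periodic:
        norm = w.sum() * (dom.hi - dom.lo) / len(pts)
    else:
        norm = np.trapezoid(w, pts)
    return pts, w / norm


def marginal_cdf(spec: SystemSpec, coord: int = 0, grid: int = 2048):
    """Callable CDF of one coordinate's Boltzmann marginal (for KS tests)."""
    pts, pdf = boltzmann_marginal(spec, coord, grid)
    dom = spec.coordinates[coord]
    if dom.periodic:
        h = (dom.hi - dom.lo) / len(pts)
        cum = np.concatenate([[0.0], np.cumsum(pdf) * h])
        xs = np.concatenate([pts, [dom.hi]])
    else:
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(pts))]
        )
        xs = pts
    cum = cum / cum[-1]

    def cdf(x):
        return np.interp(np.asarray(x, dtype=float), xs, cum, left=0.0, right=1.0)

    return cdf


# ---------------------------------------------------------------------------
# config-file round trip
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: SystemSpec) -> str:
    return yaml.safe_dump(spec.as_dict(), sort_keys=True)


def spec_from_yaml(text: str) -> SystemSpec:
    return SystemSpec.from_dict(yaml.safe_load(text))


def softening_to_yaml(soft: SofteningSpec) -> str:
    return yaml.safe_dump(soft.as_dict(), sort_keys=True)


def softening_from_yaml(text: str) -> SofteningSpec:
    return SofteningSpec.from_dict(yaml.safe_load(text))
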