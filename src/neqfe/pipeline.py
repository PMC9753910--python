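"""End-to-end relative binding free energies on a toy bound/free pair.

The :class:`BindingToy` emulates an alchemical ligand mutation (reference R
to target T) in two environments: "bound" (an asymmetric external binding
well acting on the ligand's torsion, placed at site A or its mirror image,
site B) and "free" (no environment term).  The relative binding free energy
is the leg difference

    ddG = dG_bound(R->T) - dG_free(R->T),

each leg computed by reservoir-coupled Hamiltonian replica exchange and
pairwise BAR, with an exact 2D-quadrature oracle available for validation.
When a ligand can occupy either site, the two ddG values are combined by the
Boltzmann average of the two site ensembles:

    ddG_combined = -kT ln[ (exp(-ddG_A/kT) + exp(-ddG_B/kT)) / 2 ].

The module also houses the diagnostic analyses: torsion-angle histograms
(fixed 72-bin convention on [-pi, pi)) and forward/reverse work-histogram
reports with Gaussian fits and estimator markers.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, InputError
from .estimators import (
    FreeEnergyEstimate,
    WorkSet,
    bar_ml,
    crooks_crossing,
    jarzynski,
)
from .hrex import HREXResult, LambdaSchedule, chain_free_energy, run_hrex
from .reservoir import Reservoir
from .systems import (
    Domain,
    DoubleWell,
    ExternalBinding,
    Harmonic,
    PairSoftRepulsion,
    PeriodicTorsion,
    SofteningSpec,
    SystemSpec,
    quadrature_free_energy,
    soften,
)

__all__ = [
    "BindingToy",
    "DdgResult",
    "relative_binding_dg",
    "combine_sites",
    "quadrature_ddg",
    "run_binding_leg",
    "leg_free_energy",
    "ddg_estimate",
    "torsion_distribution",
    "TorsionDistribution",
    "work_histogram_report",
    "make_fixtures",
    "harmonic_pair",
    "double_well_system",
    "double_well_softening",
    "torsion_chain_system",
]

TORSION_BINS = 72  # fixed binning convention for angle histograms


# ---------------------------------------------------------------------------
# canonical toy systems
# ---------------------------------------------------------------------------

def harmonic_pair(k_a: float = 1.0, k_b: float = 4.0) -> tuple[SystemSpec, SystemSpec]:
    """1D harmonic pair; exact dG = (1/2) ln(k_b/k_a) kT (= ln 2 for 1 -> 4)."""
    dom = (Domain(kind="real", lo=-8.0, hi=8.0),)
    a = SystemSpec(1, (Harmonic(coord=0, k=k_a, name="well"),), coordinates=dom)
    b = SystemSpec(1, (Harmonic(coord=0, k=k_b, name="well"),), coordinates=dom)
    return a, b


def double_well_system(barrier: float = 6.0) -> SystemSpec:
    """Asymmetric 1D double well: quartic barrier plus a binding well at +1.

    The Gaussian well makes the right basin deeper and narrower; softening
    the quartic amplitude broadens the wells and floods the barrier region,
    so the raw end points of switching runs carry excess barrier mass and
    distorted well shapes that the work-based Metropolis filter must remove.
    """
    return SystemSpec(
        1,
        (
            DoubleWell(coord=0, barrier=barrier, separation=1.0, name="dw"),
            ExternalBinding(coord=0, depth=2.0, width=0.5, center=1.0, name="site"),
        ),
        coordinates=(Domain(kind="real", lo=-4.0, hi=4.0),),
    )


def double_well_softening(s: float = 1.0) -> SofteningSpec:
    """Softening of the double-well fixture's barrier: 6 -> 1.2 kT at s=1.

    Only the quartic barrier amplitude is softened; the binding well is an
    environment term kept intact so the softened-to-nonsoftened switch does
    not *lower* the energy anywhere it is sampled (works stay mostly above
    dG, where the Metropolis filter reproduces the exact Boltzmann
    reweighting).
    """
    return SofteningSpec(s=s, targets=("dw",), floor_fraction=0.8)


def torsion_chain_system(barrier: float = 8.0) -> SystemSpec:
    """Two coupled torsions with high barriers (rare-transition regime)."""
    return SystemSpec(
        2,
        (
            PeriodicTorsion(coord=0, barrier=barrier, multiplicity=2, name="tor0"),
            PeriodicTorsion(coord=1, barrier=barrier, multiplicity=2, name="tor1"),
            PairSoftRepulsion(coord_i=0, coord_j=1, epsilon=2.0, sigma=0.8, name="coupling"),
        ),
        coordinates=(Domain(kind="periodic"), Domain(kind="periodic")),
    )


# ---------------------------------------------------------------------------
# binding toy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingToy:
    """Toy R -> T ligand mutation in a bound and a free environment.

    The ligand lives on (torsion phi, breathing mode y).  R and T share all
    terms except the depth of a "substituent" well on phi (the grown group's
    intramolecular preference).  The bound environment adds an asymmetric
    "pocket" well on phi at ``site_center`` (site A) or ``-site_center``
    (site B, the mirror image); the free environment adds nothing, so bound
    and free legs share the ligand terms exactly.
    """

    torsion_barrier: float = 3.0
    substituent_depth: float = 1.2
    substituent_center: float = math.pi / 2
    substituent_width: float = 0.5
    pocket_depth: float = 2.0
    pocket_width: float = 0.6
    site_center: float = 1.2
    breathing_k: float = 1.0
    temperature: float = 1.0
    site_variant: str = "A"

    def __post_init__(self):
        if self.site_variant not in ("A", "B"):
            raise ConfigurationError("site_variant must be 'A' or 'B'")

    def _domains(self):
        return (Domain(kind="periodic"), Domain(kind="real", lo=-6.0, hi=6.0))

    def _ligand_terms(self, substituent_depth: float):
        return (
            PeriodicTorsion(
                coord=0, barrier=self.torsion_barrier, multiplicity=2, name="backbone"
            ),
            ExternalBinding(
                coord=0,
                depth=substituent_depth,
                width=self.substituent_width,
                center=self.substituent_center,
                name="substituent",
            ),
            Harmonic(coord=1, k=self.breathing_k, name="breathing"),
        )

    def _pocket_term(self):
        center = self.site_center if self.site_variant == "A" else -self.site_center
        return ExternalBinding(
            coord=0,
            depth=self.pocket_depth,
            width=self.pocket_width,
            center=center,
            name="pocket",
        )

    def ligand_spec(self, ligand: str) -> SystemSpec:
        """Free-leg Hamiltonian of ligand 'R' or 'T'."""
        depth = {"R": 0.0, "T": self.substituent_depth}[ligand]
        return SystemSpec(
            2,
            self._ligand_terms(depth),
            temperature=self.temperature,
            coordinates=self._domains(),
        )

    def bound_spec(self, ligand: str) -> SystemSpec:
        """Bound-leg Hamiltonian: ligand terms plus the pocket well."""
        lig = self.ligand_spec(ligand)
        return dataclasses.replace(lig, terms=lig.terms + (self._pocket_term(),))

    def mirrored(self) -> "BindingToy":
        other = "B" if self.site_variant == "A" else "A"
        return dataclasses.replace(self, site_variant=other)

    def softening(self, s: float = 1.0) -> SofteningSpec:
        """Soften the ligand backbone torsion (the inter-minima barrier).

        The pocket well is left intact: lowering a *well* on softening would
        put switching works below dG where the Metropolis filter's min(1, .)
        clip degrades the reweighting; lowering the torsion *barrier* keeps
        the softened-to-nonsoftened energy change non-negative.
        """
        return SofteningSpec(s=s, targets=("backbone",), floor_fraction=0.8)

    def free_softening(self, s: float = 1.0) -> SofteningSpec:
        return SofteningSpec(s=s, targets=("backbone",), floor_fraction=0.8)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "BindingToy":
        return cls(**d)


@dataclass
class DdgResult:
    """Relative binding free energy: the bound-minus-free leg difference."""

    dG_bound: FreeEnergyEstimate
    dG_free: FreeEnergyEstimate
    site: str = "A"

    @property
    def ddG(self) -> float:
        return self.dG_bound.value - self.dG_free.value

    @property
    def stderr(self) -> float:
        return float(np.hypot(self.dG_bound.stderr, self.dG_free.stderr))

    def as_dict(self) -> dict:
        return {
            "site": self.site,
            "dG_bound": self.dG_bound.as_dict(),
            "dG_free": self.dG_free.as_dict(),
            "ddG": self.ddG,
            "stderr": self.stderr,
        }


def relative_binding_dg(
    bound: HREXResult,
    free: HREXResult,
    temperature: float | None = None,
    site: str = "A",
) -> DdgResult:
    """Assemble ddG from the bound- and free-leg HREX results."""
    if bound.lambdas != free.lambdas:
        raise ConfigurationError("bound and free legs must use the same R->T schedule")
    kT = temperature if temperature is not None else bound.temperature
    dG_b = chain_free_energy(bound, kT)
    dG_f = chain_free_energy(free, kT)
    return DdgResult(dG_bound=dG_b, dG_free=dG_f, site=site)


def combine_sites(ddG_A: float, ddG_B: float, temperature: float = 1.0) -> float:
    """Boltzmann-average the two site placements of an asymmetric ligand.

    ``-kT ln[(exp(-A/kT) + exp(-B/kT)) / 2]``, computed with a stable
    log-sum.  The 1/2 normalization makes the combination symmetric with
    ``combine(x, x) = x``; the value always lies in
    ``[min(A, B), min(A, B) + kT ln 2]``, reaching the upper edge when one
    site dominates.
    """
    if not (np.isfinite(ddG_A) and np.isfinite(ddG_B)):
        raise InputError("site ddG values must be finite")
    kT = float(temperature)
    return float(-kT * (logsumexp([-ddG_A / kT, -ddG_B / kT]) - np.log(2.0)))


def quadrature_ddg(toy: BindingToy, grid: int = 384) -> float:
    """Exact ddG of the toy by 2D quadrature of all four end states."""
    dg_bound = quadrature_free_energy(toy.bound_spec("R"), toy.bound_spec("T"), grid)
    dg_free = quadrature_free_energy(toy.ligand_spec("R"), toy.ligand_spec("T"), grid)
    return dg_bound.value - dg_free.value


def run_binding_leg(
    toy: BindingToy,
    leg: str,
    schedule: LambdaSchedule | None = None,
    n_cycles: int = 1600,
    steps_per_cycle: int = 10,
    seed: int = 0,
    reservoir: Reservoir | None = None,
    burn_in_cycles: int | None = None,
) -> HREXResult:
    """Run one alchemical leg (R -> T) of the toy by HREX."""
    if leg not in ("bound", "free"):
        raise ConfigurationError("leg must be 'bound' or 'free'")
    make = toy.bound_spec if leg == "bound" else toy.ligand_spec
    H_R, H_T = make("R"), make("T")
    schedule = schedule if schedule is not None else LambdaSchedule.uniform(11)
    if burn_in_cycles is None:
        burn_in_cycles = max(n_cycles // 10, 1)
    start = toy.site_center if (leg == "bound" and toy.site_variant == "A") else (
        -toy.site_center if leg == "bound" else math.pi / 2
    )
    return run_hrex(
        H_R,
        H_T,
        schedule,
        n_cycles=n_cycles,
        steps_per_cycle=steps_per_cycle,
        reservoir=reservoir,
        seed=seed,
        x0=np.array([[start, 0.0]]),
        burn_in_cycles=burn_in_cycles,
    )


def leg_free_energy(
    toy: BindingToy,
    leg: str,
    schedule: LambdaSchedule | None = None,
    n_cycles: int = 1600,
    steps_per_cycle: int = 10,
    seed: int = 0,
    reservoir: Reservoir | None = None,
    n_repeats: int = 3,
) -> FreeEnergyEstimate:
    """Leg dG as the mean over independent HREX repeats.

    The stderr is the between-repeat scatter (sd / sqrt(n_repeats)), which,
    unlike a within-run bootstrap, is honest about slow conformational
    autocorrelation in the replica chain.
    """
    vals = []
    for k in range(n_repeats):
        run = run_binding_leg(
            toy, leg, schedule, n_cycles, steps_per_cycle,
            seed=seed + 1000 * k, reservoir=reservoir,
        )
        vals.append(chain_free_energy(run, n_boot=0).value)
    vals = np.asarray(vals)
    stderr = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return FreeEnergyEstimate(float(vals.mean()), stderr, "hrex_bar",
                              (n_repeats, n_repeats))


def ddg_estimate(
    toy: BindingToy,
    schedule: LambdaSchedule | None = None,
    n_cycles: int = 1600,
    steps_per_cycle: int = 10,
    seed: int = 0,
    reservoir_bound: Reservoir | None = None,
    reservoir_free: Reservoir | None = None,
    n_repeats: int = 3,
    dG_free: FreeEnergyEstimate | None = None,
) -> DdgResult:
    """Replicated-leg ddG for one site variant.

    ``dG_free`` may be supplied to reuse a free-leg estimate across sites
    (the free environment is site-independent).
    """
    dG_bound = leg_free_energy(
        toy, "bound", schedule, n_cycles, steps_per_cycle, seed=seed,
        reservoir=reservoir_bound, n_repeats=n_repeats,
    )
    if dG_free is None:
        dG_free = leg_free_energy(
            toy, "free", schedule, n_cycles, steps_per_cycle, seed=seed + 7,
            reservoir=reservoir_free, n_repeats=n_repeats,
        )
    return DdgResult(dG_bound=dG_bound, dG_free=dG_free, site=toy.site_variant)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class TorsionDistribution:
    """Normalized torsion histograms: 1D per angle, 2D per angle pair."""

    ids: tuple
    edges: np.ndarray
    hist1d: dict
    hist2d: dict

    def occupied_bins(self, torsion_id: int, threshold: float = 0.0) -> int:
        return int(np.count_nonzero(self.hist1d[torsion_id] > threshold))


def torsion_distribution(confs, torsion_ids) -> TorsionDistribution:
    """Histogram torsion angles on [-pi, pi) with the 72-bin convention.

    Accepts a list of conformations or an (n, dim) coordinate array; bin
    masses sum to 1 in each histogram.
    """
    if isinstance(confs, np.ndarray):
        X = np.atleast_2d(confs)
    else:
        X = np.array([c.x for c in confs])
    if X.size == 0:
        raise InputError("no conformations to histogram")
    ids = tuple(int(i) for i in torsion_ids)
    for i in ids:
        if not (0 <= i < X.shape[1]):
            raise InputError(f"torsion id {i} outside dimension {X.shape[1]}")
    edges = np.linspace(-np.pi, np.pi, TORSION_BINS + 1)
    hist1d = {}
    for i in ids:
        h, _ = np.histogram(X[:, i], bins=edges)
        hist1d[i] = h / h.sum()
    hist2d = {}
    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1 :]:
            h, _, _ = np.histogram2d(X[:, a], X[:, b], bins=[edges, edges])
            hist2d[(a, b)] = h / h.sum()
    return TorsionDistribution(ids=ids, edges=edges, hist1d=hist1d, hist2d=hist2d)


def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def work_histogram_report(
    ws: WorkSet,
    out_path=None,
    reservoir: Reservoir | None = None,
    seed: int = 0,
) -> dict:
    """Forward / negated-reverse work histograms with estimator markers.

    Returns a dict with the three estimates, the Gaussian fit parameters,
    and (when a reservoir is supplied) its acceptance ratio; when
    ``out_path`` is given, also renders the overlaid-histogram figure.
    """
    if ws.n_F == 0:
        raise InputError("empty work set")
    report: dict = {
        "n_F": ws.n_F,
        "n_R": ws.n_R,
        "gaussian_forward": {
            "mean": float(np.mean(ws.W_F)),
            "std": float(np.std(ws.W_F, ddof=1)) if ws.n_F > 1 else 0.0,
        },
    }
    jz = jarzynski(ws.W_F, ws.temperature, n_boot=200, seed=seed)
    report["jarzynski"] = jz.as_dict()
    if ws.n_R >= 3:
        negR = -ws.W_R
        report["gaussian_reverse_negated"] = {
            "mean": float(np.mean(negR)),
            "std": float(np.std(negR, ddof=1)),
        }
        report["bar_ml"] = bar_ml(ws, n_boot=200, seed=seed).as_dict()
        report["crooks_cross"] = crooks_crossing(ws, n_boot=200, seed=seed).as_dict()
    if reservoir is not None:
        report["acceptance_ratio"] = float(reservoir.acceptance_ratio)

    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(ws.W_F, bins=40, density=True, alpha=0.5, label="forward work")
        lo, hi = float(np.min(ws.W_F)), float(np.max(ws.W_F))
        if ws.n_R >= 3:
            negR = -ws.W_R
            ax.hist(negR, bins=40, density=True, alpha=0.5, label="-reverse work")
            lo, hi = min(lo, float(negR.min())), max(hi, float(negR.max()))
        xs = np.linspace(lo, hi, 400)
        gf = report["gaussian_forward"]
        if gf["std"] > 0:
            ax.plot(xs, _gauss(xs, gf["mean"], gf["std"]), "C0-")
        if "gaussian_reverse_negated" in report:
            gr = report["gaussian_reverse_negated"]
            ax.plot(xs, _gauss(xs, gr["mean"], gr["std"]), "C1-")
        markers = [("jarzynski", "green"), ("bar_ml", "black"), ("crooks_cross", "purple")]
        for key, color in markers:
            if key in report:
                ax.axvline(report[key]["value"], color=color, ls="--", label=key)
        ax.set_xlabel("work (kT)")
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return report


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "harmonic_1_to_4",
    "double_well_6kT",
    "double_well_8kT",
    "torsion_chain",
    "binding_toy_site_A",
    "binding_toy_site_B",
)


def make_fixtures(out_dir, seed: int = 0) -> Path:
    """Write the canonical toy set with embedded quadrature reference values.

    Deterministic: the same seed produces byte-identical files.  Returns the
    manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": int(seed), "fixtures": {}}

    def emit(name: str, payload: dict, reference: dict) -> None:
        payload = dict(payload)
        payload["reference"] = reference
        with open(out / f"{name}.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["fixtures"][name] = reference

    h_a, h_b = harmonic_pair()
    dg = quadrature_free_energy(h_a, h_b)
    emit(
        "harmonic_1_to_4",
        {"system_a": h_a.as_dict(), "system_b": h_b.as_dict()},
        {"dG": dg.value, "dG_refinement_delta": dg.stderr},
    )

    for barrier, name in ((6.0, "double_well_6kT"), (8.0, "double_well_8kT")):
        ns = double_well_system(barrier)
        soft_spec = double_well_softening()
        softened = soften(ns, soft_spec)
        dg = quadrature_free_energy(softened, ns)
        emit(
            name,
            {"system": ns.as_dict(), "softening": soft_spec.as_dict()},
            {"dG_s_to_ns": dg.value, "dG_refinement_delta": dg.stderr},
        )

    chain = torsion_chain_system()
    emit("torsion_chain", {"system": chain.as_dict()}, {"dG": 0.0})

    toy = BindingToy()
    for variant in ("A", "B"):
        t = toy if variant == "A" else toy.mirrored()
        emit(
            f"binding_toy_site_{variant}",
            {"binding_toy": t.as_dict()},
            {"ddG": quadrature_ddg(t)},
        )

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
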