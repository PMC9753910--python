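"""Free-energy estimators over nonequilibrium work samples.

The estimators operate on forward works (switching a system from state A to
state B) and reverse works (B to A).  Sign convention: a reverse work sample
``W_R`` is the work of the reverse process itself, so the Crooks fluctuation
theorem reads ``P_F(W) / P_R(-W) = exp((W - dG)/kT)`` and the forward and
negated-reverse work densities cross at ``W = dG``.

Implemented estimators:

* :func:`jarzynski` -- unidirectional exponential average,
  ``dG = -kT ln < exp(-W/kT) >``.
* :func:`bar_ml` -- bidirectional Bennett acceptance ratio / maximum
  likelihood, solving the self-consistency equation with the Fermi function
  and ``M = kT ln(n_F / n_R)``.
* :func:`crooks_crossing` -- crossing point of Gaussians fitted to the
  forward and negated-reverse work densities.
* :func:`ti` -- thermodynamic integration by the trapezoid rule over
  ``<dU/dlambda>`` window averages.

Uncertainties are (block-)bootstrap standard errors with a seeded generator,
so repeated calls with the same seed are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .errors import EstimationError, InputError

__all__ = [
    "WorkSet",
    "FreeEnergyEstimate",
    "jarzynski",
    "bar_ml",
    "crooks_crossing",
    "ti",
    "estimates_to_frame",
    "read_work_csv",
]

_METHODS = ("jarzynski", "bar_ml", "crooks_cross", "ti", "quadrature", "hrex_bar")


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy difference with its statistical uncertainty.

    ``value`` and ``stderr`` are in the energy units of the temperature used
    to produce them (kT = 1 by default throughout the package).
    """

    value: float
    stderr: float
    method: str
    n_used: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise InputError(f"unknown method tag {self.method!r}")
        if not np.isfinite(self.value):
            raise EstimationError(f"non-finite free-energy value ({self.method})")
        if self.stderr < 0:
            raise InputError("stderr must be >= 0")

    def as_dict(self) -> dict:
        return {
            "value": float(self.value),
            "stderr": float(self.stderr),
            "method": self.method,
            "n_used": list(self.n_used),
        }


@dataclass
class WorkSet:
    """Forward and reverse nonequilibrium work samples at one temperature."""

    W_F: np.ndarray
    W_R: np.ndarray = field(default_factory=lambda: np.empty(0))
    temperature: float = 1.0

    def __post_init__(self) -> None:
        self.W_F = np.asarray(self.W_F, dtype=float).ravel()
        self.W_R = np.asarray(self.W_R, dtype=float).ravel()
        if self.temperature <= 0:
            raise InputError("temperature (kT) must be positive")
        if self.W_F.size and not np.all(np.isfinite(self.W_F)):
            raise InputError("non-finite forward work values")
        if self.W_R.size and not np.all(np.isfinite(self.W_R)):
            raise InputError("non-finite reverse work values")

    @property
    def n_F(self) -> int:
        return int(self.W_F.size)

    @property
    def n_R(self) -> int:
        return int(self.W_R.size)


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------

def _block_indices(n: int, n_boot: int, block: int, rng: np.random.Generator) -> np.ndarray:
    """Moving-block bootstrap index matrix of shape (n_boot, n).

    ``block=1`` reduces to the ordinary iid bootstrap, which is the default
    because work samples are independent switching runs by construction.
    """
    if block <= 1:
        return rng.integers(0, n, size=(n_boot, n))
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, max(n - block + 1, 1), size=(n_boot, n_blocks))
    offs = np.arange(block)
    idx = (starts[:, :, None] + offs[None, None, :]).reshape(n_boot, -1)
    return idx[:, :n]


def _bootstrap_stderr(estimate_fn, arrays, n_boot, block, seed) -> float:
    """Generic seeded bootstrap over one or two sample arrays."""
    if n_boot <= 0:
        return 0.0
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    index_sets = [_block_indices(a.size, n_boot, block, rng) for a in arrays]
    for b in range(n_boot):
        resampled = [a[idx[b]] for a, idx in zip(arrays, index_sets)]
        vals[b] = estimate_fn(*resampled)
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _jarzynski_value(W: np.ndarray, kT: float) -> float:
    # stable: -kT * (logsumexp(-W/kT) - ln n)
    return float(-kT * (logsumexp(-W / kT) - np.log(W.size)))


def jarzynski(
    W_F,
    temperature: float = 1.0,
    n_boot: int = 1000,
    block: int = 1,
    seed: int = 0,
) -> FreeEnergyEstimate:
    """Unidirectional free energy from the Jarzynski equality.

    ``dG = -kT ln <exp(-W/kT)>`` computed with a log-sum-exp; the bootstrap
    stderr quantifies only the sampling noise, not the (one-sided) finite-n
    bias that the exponential average is known to carry.
    """
    W = np.asarray(W_F, dtype=float).ravel()
    if W.size == 0:
        raise EstimationError("jarzynski needs at least one work sample")
    if not np.all(np.isfinite(W)):
        raise InputError("non-finite work values")
    kT = float(temperature)
    value = _jarzynski_value(W, kT)
    stderr = _bootstrap_stderr(lambda w: _jarzynski_value(w, kT), [W], n_boot, block, seed)
    return FreeEnergyEstimate(value, stderr, "jarzynski", (W.size, 0))


def _bar_residual(dG: float, W_F: np.ndarray, W_R: np.ndarray, kT: float, M: float) -> float:
    # Self-consistency: sum_F f(M + W_F - dG) = sum_R f(-M + W_R + dG),
    # f the Fermi function (arguments in units of kT).  Strictly increasing
    # in dG, so a bracketing root search is safe.
    lhs = expit(-(M + W_F - dG) / kT).sum()
    rhs = expit(-(-M + W_R + dG) / kT).sum()
    return float(lhs - rhs)


def _bar_solve(W_F: np.ndarray, W_R: np.ndarray, kT: float, tol: float) -> float:
    M = kT * np.log(W_F.size / W_R.size)
    all_w = np.concatenate([W_F, -W_R])
    lo = float(all_w.min() - 50.0 * kT)
    hi = float(all_w.max() + 50.0 * kT)
    flo = _bar_residual(lo, W_F, W_R, kT, M)
    fhi = _bar_residual(hi, W_F, W_R, kT, M)
    if flo > 0 or fhi < 0:  # pragma: no cover - bracket is generous
        raise EstimationError("BAR residual does not change sign across bracket")
    root = brentq(_bar_residual, lo, hi, args=(W_F, W_R, kT, M), xtol=tol)
    return float(root)


def bar_ml(
    ws: WorkSet,
    tol: float = 1e-6,
    n_boot: int = 1000,
    block: int = 1,
    seed: int = 0,
) -> FreeEnergyEstimate:
    """Bidirectional BAR / maximum-likelihood free energy.

    Solves the self-consistency equation over forward and reverse works with
    ``M = kT ln(n_F/n_R)``.  The residual is strictly monotone in ``dG`` so
    the bracketed root is unique.  Non-overlapping work distributions produce
    a warning and an inflated stderr, but a root is still returned.
    """
    if ws.n_F < 1 or ws.n_R < 1:
        raise EstimationError("bar_ml needs work samples in both directions")
    kT = float(ws.temperature)
    W_F, W_R = ws.W_F, ws.W_R
    value = _bar_solve(W_F, W_R, kT, tol)
    stderr = _bootstrap_stderr(
        lambda f, r: _bar_solve(f, r, kT, tol), [W_F, W_R], n_boot, block, seed
    )
    overlap = (W_F.min() <= (-W_R).max()) and ((-W_R).min() <= W_F.max())
    if not overlap:
        spread = float(np.abs(W_F.mean() + W_R.mean()))
        warnings.warn(
            "forward and negated-reverse work distributions do not overlap; "
            "BAR estimate is unreliable",
            stacklevel=2,
        )
        stderr = max(stderr, spread)
    return FreeEnergyEstimate(value, stderr, "bar_ml", (ws.n_F, ws.n_R))


def _crossing_value(W_F: np.ndarray, negW_R: np.ndarray) -> float:
    """Crossing abscissa of Gaussians fitted to forward / negated-reverse works."""
    mF, sF = float(np.mean(W_F)), float(np.std(W_F, ddof=1))
    mR, sR = float(np.mean(negW_R)), float(np.std(negW_R, ddof=1))
    lo_m, hi_m = min(mF, mR), max(mF, mR)
    if np.isclose(sF, sR, rtol=1e-6, atol=1e-12):
        return 0.5 * (mF + mR)
    # equate Gaussian log densities: quadratic a x^2 + b x + c = 0, solved in
    # the cancellation-safe form (a -> 0 when the variances are close)
    a = 1.0 / sR**2 - 1.0 / sF**2
    b = 2.0 * (mF / sF**2 - mR / sR**2)
    c = mR**2 / sR**2 - mF**2 / sF**2 + 2.0 * np.log(sR / sF)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise EstimationError("fitted Gaussians have no real crossing")
    q = -0.5 * (b + np.copysign(np.sqrt(disc), b))
    roots = np.array([q / a, c / q]) if q != 0.0 else np.array([0.0, 0.0])
    tol = 1e-9 * (abs(lo_m) + abs(hi_m) + sF + sR)
    inside = roots[(roots >= lo_m - tol) & (roots <= hi_m + tol)]
    if inside.size == 0:
        raise EstimationError("no Gaussian crossing between the two means")
    return float(inside[0])


def crooks_crossing(
    ws: WorkSet,
    n_boot: int = 1000,
    block: int = 1,
    seed: int = 0,
) -> FreeEnergyEstimate:
    """Free energy as the crossing of fitted forward / reverse work Gaussians.

    By the Crooks fluctuation theorem the forward and negated-reverse work
    densities cross at ``W = dG``; for Gaussian fits with unequal variances
    the root lying between the two means is taken.
    """
    if ws.n_F < 3 or ws.n_R < 3:
        raise EstimationError("crooks_crossing needs >= 3 samples per direction")
    negW_R = -ws.W_R
    value = _crossing_value(ws.W_F, negW_R)
    stderr = _bootstrap_stderr(
        lambda f, r: _crossing_value(f, r), [ws.W_F, negW_R], n_boot, block, seed
    )
    return FreeEnergyEstimate(value, stderr, "crooks_cross", (ws.n_F, ws.n_R))


def ti(mean_dudl) -> FreeEnergyEstimate:
    """Thermodynamic integration over ``(lambda, <dU/dlambda>, stderr)`` triples.

    Trapezoid rule; the stderr of the integral propagates the per-window
    standard errors through the trapezoid weights.
    """
    pts = [(float(l), float(m), float(s)) for (l, m, s) in mean_dudl]
    if len(pts) < 2:
        raise EstimationError("ti needs at least two lambda windows")
    lam = np.array([p[0] for p in pts])
    if np.any(np.diff(lam) <= 0):
        raise InputError("lambda values must be strictly increasing")
    if lam[0] < 0 or lam[-1] > 1:
        raise InputError("lambda values must lie in [0, 1]")
    mean = np.array([p[1] for p in pts])
    se = np.array([p[2] for p in pts])
    value = float(np.trapezoid(mean, lam))
    w = np.zeros_like(lam)
    dl = np.diff(lam)
    w[:-1] += dl / 2.0
    w[1:] += dl / 2.0
    stderr = float(np.sqrt(np.sum((w * se) ** 2)))
    return FreeEnergyEstimate(value, stderr, "ti", (len(pts), 0))


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def estimates_to_frame(estimates) -> pd.DataFrame:
    """Tidy table (method, value, stderr, n_F, n_R) from estimates."""
    rows = [
        {
            "method": e.method,
            "value": e.value,
            "stderr": e.stderr,
            "n_F": e.n_used[0],
            "n_R": e.n_used[1],
        }
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=["method", "value", "stderr", "n_F", "n_R"])


def read_work_csv(path, temperature: float = 1.0) -> WorkSet:
    """Build a :class:`WorkSet` from a work-record CSV (direction, work, ...)."""
    df = pd.read_csv(path)
    if "direction" not in df.columns or "work" not in df.columns:
        raise InputError("work CSV needs 'direction' and 'work' columns")
    W_F = df.loc[df["direction"] == "forward", "work"].to_numpy(float)
    W_R = df.loc[df["direction"] == "reverse", "work"].to_numpy(float)
    return WorkSet(W_F=W_F, W_R=W_R, temperature=temperature)
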