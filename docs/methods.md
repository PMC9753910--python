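# Methods

`neqfe` re-implements, on exactly solvable toy Hamiltonians, an
enhanced-sampling and free-energy workflow built from four ingredients:
nonequilibrium (NEQ) switching with work accumulation, fluctuation-theorem
free-energy estimators, Metropolis-filtered conformation reservoirs, and
Hamiltonian replica exchange (HREX) over an alchemical lambda chain.  This
note records the models, the numerical choices, and what the toy setting
does and does not demonstrate.

## Model systems and units

A system is a sum of potential terms on a 1-3 dimensional domain:
harmonic restraints `k/2 (x-x0)^2`; periodic torsions
`V/2 (1 + cos(n phi - phase))`, chosen so the inter-minima barrier is
literally `V`; quartic double wells `b ((x/a)^2 - 1)^2` with minima at
`+-a` and barrier `b`; Gaussian binding wells
`-depth exp(-(x-c)^2 / 2 w^2)` standing in for environment (binding-site)
interactions; and Gaussian pair repulsions `eps exp(-(xi-xj)^2/sigma^2)`
coupling two coordinates.  Energies are in units of kT (kT = 1 by default);
`kt_kcal_mol()` gives the kcal/mol value at 298 K for users who prefer that
convention.  Masses are 1 and time is in reduced units throughout.

Because every system is low-dimensional, partition functions are computed
by tensor-grid trapezoid quadrature (spectrally accurate on periodic
coordinates), giving *exact* reference free energies and marginal Boltzmann
densities.  Every statistical claim in the test suite is checked against
these oracles, with the quoted quadrature uncertainty taken as the change
under grid halving (typically < 1e-9 kT on the shipped fixtures).

## Softening

The softened Hamiltonian multiplies targeted barrier amplitudes (torsion
`V`, double-well `b`, pair `eps`, environment-well `depth`) by
`(1 - s*c)`, with softness `s` in [0, 1] and floor fraction `c` (default
0.8) the fraction removed at full softness.  Harmonic restraints are never
softened; targeting one is a configuration error.  `s = 0` returns the
input unchanged.

A practical rule encoded in the shipped fixtures: soften *barriers*, not
*wells*.  If softening deepens a well on the way back to the physical
Hamiltonian, switching works in that basin fall below dG(s->ns), where the
Metropolis filter's `min(1, .)` clip can no longer reproduce the exact
`exp(-(W - dG)/kT)` reweighting and the reservoir inherits a basin-weight
bias.  Softening only the barrier keeps the s->ns energy change
non-negative wherever the softened ensemble has mass, which keeps the
filter nearly exact.

## Dynamics and work accumulation

Sampling uses the BAOAB splitting of Langevin dynamics (friction 1.0,
timestep 0.01 by default), which targets the canonical distribution with
O(dt^2) configurational bias - negligible against the statistical
tolerances used here (the stiffest shipped mode has omega*dt ~ 0.04).
Velocities at the start of a switching run are redrawn from
Maxwell-Boltzmann by default (a reuse switch exists); the work involves
only potential differences, so the kinetic part cancels identically.

Switching drives lambda linearly between two Hamiltonians over a duration
T (default 10 time units, i.e. 1000 steps - the analog of a short,
affordable switching protocol).  The work is a discrete
potential-difference sum with a symmetric midpoint splitting per step:

    W += U(l_{i+1/2}, x) - U(l_i, x)          (half jump)
    propagate one BAOAB step under l_{i+1/2}
    W += U(l_{i+1}, x') - U(l_{i+1/2}, x')    (half jump)

Alternating measure-preserving dynamics with instantaneous potential jumps
satisfies the Jarzynski identity exactly for any T; the symmetric
splitting additionally makes a forward run followed by its exact
time-reversed path accumulate zero total work in the deterministic limit
(friction 0, no noise), which the suite asserts to 1e-12.  T = 0 is the
instantaneous limit, a single potential difference.

## Estimators

* **Jarzynski**: `dG = -kT ln <exp(-W/kT)>` via log-sum-exp.  One-sided and
  tail-sensitive: on the stiff-to-soft harmonic leg (k=4 -> k=1) the
  exponential average has heavy tails and the finite-n estimate is biased -
  the pathology the bidirectional route exists to fix.
* **BAR / maximum likelihood**: solves the self-consistency equation with
  Fermi functions and `M = kT ln(nF/nR)` by bracketed Brent root-finding
  (bracket `[min W - 50 kT, max W + 50 kT]`, tolerance 1e-6 kT); the
  residual is strictly monotone so the root is unique.  Non-overlapping
  work distributions warn and inflate the stderr.  The implementation is
  validated against Crooks-consistent Gaussian ensembles with known dG,
  including unequal counts.
* **Crooks Gaussian crossing**: fits Gaussians to forward and negated
  reverse works and returns their crossing between the two means, solving
  the log-density quadratic in a cancellation-safe form (the leading
  coefficient vanishes as the variances approach each other).  The
  estimator is only meaningful when the works are near-Gaussian and the
  mean separation is at least comparable to the width; the shipped
  near-Gaussian fixture is a dragged harmonic well (x0: 0 -> 2), whose
  works are exactly Gaussian in both directions.
* **TI**: trapezoid over `(lambda, <dU/dlambda>, stderr)` windows with
  propagated errors.

Uncertainties are seeded (block-)bootstrap standard errors, 1000 resamples
by default, block length 1 for independent switching runs and 10 cycles
for autocorrelated HREX series.  For full HREX legs even block bootstraps
are dishonest (torsional well weights relax over hundreds of cycles), so
production ddG estimates use between-repeat scatter across independent
replica-exchange runs instead (`leg_free_energy`, 3 repeats by default).

## Conformation reservoir (NEQ route)

The workflow: sample the softened Hamiltonian (parallel walkers, common
burn-in, equally spaced snapshots); run one forward switching run per
snapshot; take a first dG(s->ns) from Jarzynski; Metropolis-filter the end
points with `xi < min(1, exp(-(W - dG)/kT))`; run reverse switching only
from newly accepted end points (cumulative across cycles); re-solve BAR on
all forward works plus the available reverse works; iterate filter/refine
up to 500 cycles with early exit once the last 10 trace values span less
than the convergence tolerance (default 0.1 kT, the analog of converging
to a tenth-of-a-kcal); average the post-burn-in (first 10% discarded)
bidirectional trace; filter once more with the averaged dG to obtain the
reservoir.

The accepted end points are exactly Boltzmann-distributed for the
nonsoftened Hamiltonian up to the clipping of the acceptance weight at 1;
the residual bias is small when works exceed dG (second law) and is
measured directly in the suite: on the double-well fixture (barrier 6 kT
softened to 1.2 kT) the filtered set passes a KS test against the exact
marginal density while the unfiltered end points fail it decisively.

An HREX route to the same reservoir (`reservoir_from_hrex`) transforms the
softened ensemble through a lambda ladder and keeps the nonsoftened
terminal replica's samples; the suite checks that both routes give
consistent ddG values downstream.

## HREX

Replicas at lambda values including both terminals (11 states by default;
21 with the direct-softening ladder, whose tent-shaped softness peaks at
lambda = 0.5 and vanishes at the ends) alternate Langevin bursts with
deterministic odd/even neighbor-exchange sweeps under the standard
Metropolis criterion on `[U_i(x_j) + U_j(x_i)] - [U_i(x_i) + U_j(x_j)]`.
Exchanges are scheduled by cycle count for reproducibility.  Per-pair
forward/backward energy differences feed pairwise BAR; the chain free
energy is their sum with quadrature-summed errors.

A reservoir couples to the lambda = 0 replica: one uniform draw per cycle,
accepted unconditionally when the reservoir was built for exactly that
Hamiltonian, and otherwise by a Metropolis test on the ensemble mismatch
with each energy difference weighted by its own ensemble's temperature.
Production legs run 1600 cycles of 10 steps rather than 800 of 20: the
same MD cost but twice the exchange frequency, which halves the
conformation-transport time along the chain - the transport of reservoir
conformations from lambda = 0 to lambda = 1 is the slowest mode of the
whole pipeline.

## The binding toy and ddG

The binding toy emulates a relative binding free-energy calculation.  The
ligand lives on a torsion phi (barrier 3 kT, two minima at +-pi/2) plus a
harmonic breathing mode; the target ligand T differs from the reference R
by a "substituent" Gaussian well at +pi/2 (depth 1.2 kT), introduced by
linear parameter mixing along lambda.  The bound environment adds an
asymmetric "pocket" well on phi at +1.2 rad (site A) or -1.2 rad (its
mirror, site B); the free environment adds nothing, so both legs share the
ligand terms exactly.  ddG = dG_bound - dG_free, with a 2D-quadrature
oracle for every end state.  Reservoirs are attached to the lambda = 0
replica of both legs (the toy free ligand has the same torsional barrier
as the bound one).  Two asymmetric placements combine as
`-kT ln[(e^{-ddG_A/kT} + e^{-ddG_B/kT})/2]`; the 1/2 normalization makes
`combine(x, x) = x`, and the combined value always lies within
`[min(A,B), min(A,B) + kT ln 2]`.

## What the toys show, and what they do not

The fixtures reproduce the workflow's load-bearing phenomena: rare
torsional transitions under the physical Hamiltonian, fast interconversion
under softening, work-based filtering restoring the correct Boltzmann
weights, reservoir insertions unlocking conformational states never
visited in plain runs, and bidirectional estimators out-performing the
unidirectional exponential average on dissipative protocols.  They do not
probe high-dimensional force fields, solvent, electrostatics, finite
acceptance of reservoir insertions into an imperfectly matched replica at
scale, or the wall-clock scheduling of exchanges on heterogeneous
hardware; passing here validates the machinery and its statistics, not any
claim about real protein-ligand systems.

## Problem sizes

Defaults were chosen so each study resolves its reference value with
errors well inside the asserted tolerances: 2000 switching runs for
estimator recovery; 2000 snapshots for the reservoir study; 2000 repeated
experiments (100 works per direction each) for the bias comparison; 11
lambda states with 1600 x 10-step cycles and 3 independent repeats per ddG
leg.  The complete test suite and the acceptance script each run in a few
minutes on a single CPU.
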