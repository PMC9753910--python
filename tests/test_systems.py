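"""Model systems: term energies, softening, hybrids, quadrature oracles."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neqfe.errors import ConfigurationError, InputError, UnsupportedError
from neqfe.systems import (
    Domain,
    DoubleWell,
    ExternalBinding,
    Harmonic,
    HybridSpec,
    PairSoftRepulsion,
    PeriodicTorsion,
    SofteningSpec,
    SystemSpec,
    boltzmann_marginal,
    energy,
    gradient,
    hybrid_energy,
    hybridize,
    kt_kcal_mol,
    quadrature_free_energy,
    soften,
    softening_from_yaml,
    softening_to_yaml,
    spec_from_yaml,
    spec_to_yaml,
)


def make_spec(*terms, dim=1, periodic=False, kT=1.0):
    coords = tuple(
        Domain(kind="periodic") if periodic else Domain(kind="real", lo=-8, hi=8)
        for _ in range(dim)
    )
    return SystemSpec(dim, terms, temperature=kT, coordinates=coords)


class TestEnergy:
    def test_harmonic_half_k_x_squared(self):
        spec = make_spec(Harmonic(coord=0, k=2.0, name="h"))
        assert energy(spec, [1.0]) == pytest.approx(1.0)

    def test_torsion_barrier_height_is_literal(self):
        # U = V/2 (1 + cos(n phi - phase)): max-min difference equals V
        spec = make_spec(
            PeriodicTorsion(coord=0, barrier=5.0, multiplicity=2, name="t"),
            periodic=True,
        )
        assert energy(spec, [0.0]) - energy(spec, [math.pi / 2]) == pytest.approx(5.0)

    def test_gradient_vanishes_at_minimum(self):
        spec = make_spec(
            DoubleWell(coord=0, barrier=4.0, separation=1.5, name="dw"),
            ExternalBinding(coord=0, depth=0.0, name="s"),
        )
        g = gradient(spec, [1.5])
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_gradient_matches_finite_difference(self):
        spec = SystemSpec(
            2,
            (
                PeriodicTorsion(coord=0, barrier=3.0, multiplicity=2, phase=0.3, name="t"),
                ExternalBinding(coord=0, depth=1.5, width=0.4, center=0.7, name="b"),
                Harmonic(coord=1, k=2.0, x0=0.5, name="h"),
                PairSoftRepulsion(coord_i=0, coord_j=1, epsilon=1.2, sigma=0.8, name="p"),
            ),
            coordinates=(Domain(kind="periodic"), Domain(kind="real", lo=-8, hi=8)),
        )
        x = np.array([0.4, -0.3])
        g = gradient(spec, x)
        h = 1e-6
        for j in range(2):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (energy(spec, xp) - energy(spec, xm)) / (2 * h)
            assert g[j] == pytest.approx(fd, abs=1e-5)

    def test_dimension_mismatch_raises(self):
        spec = make_spec(Harmonic(coord=0, k=1.0, name="h"))
        with pytest.raises(InputError):
            energy(spec, [0.0, 1.0])

    def test_vectorized_energy_matches_scalar(self):
        spec = make_spec(DoubleWell(coord=0, barrier=2.0, name="dw"))
        X = np.linspace(-2, 2, 7)[:, None]
        ev = energy(spec, X)
        assert np.allclose(ev, [energy(spec, x) for x in X])


class TestSpecValidation:
    def test_term_outside_dimension(self):
        with pytest.raises(ConfigurationError):
            make_spec(Harmonic(coord=1, k=1.0, name="h"), dim=1)

    def test_negative_barrier(self):
        with pytest.raises(ConfigurationError):
            PeriodicTorsion(coord=0, barrier=-1.0, name="t")

    def test_kcal_mode_temperature(self):
        # kT at 298 K in kcal/mol, usable as a SystemSpec temperature
        kT = kt_kcal_mol()
        assert kT == pytest.approx(0.5922, abs=1e-4)
        spec = make_spec(Harmonic(coord=0, k=1.0, name="h"), kT=kT)
        assert spec.temperature == kT


class TestSoften:
    def test_identity_at_zero_softness(self):
        spec = make_spec(PeriodicTorsion(coord=0, barrier=5.0, name="t"), periodic=True)
        out = soften(spec, SofteningSpec(s=0.0, targets=("t",)))
        assert out == spec

    def test_full_softening_scale(self):
        spec = make_spec(PeriodicTorsion(coord=0, barrier=5.0, name="t"), periodic=True)
        out = soften(spec, SofteningSpec(s=1.0, targets=("t",), floor_fraction=0.8))
        assert out.term_named("t").barrier == pytest.approx(1.0)

    def test_untargeted_terms_unchanged(self):
        spec = make_spec(
            PeriodicTorsion(coord=0, barrier=5.0, name="t"),
            ExternalBinding(coord=0, depth=2.0, name="b"),
            periodic=True,
        )
        out = soften(spec, SofteningSpec(s=1.0, targets=("t",)))
        assert out.term_named("b") == spec.term_named("b")

    def test_unknown_target_raises(self):
        spec = make_spec(PeriodicTorsion(coord=0, barrier=5.0, name="t"), periodic=True)
        with pytest.raises(ConfigurationError):
            soften(spec, SofteningSpec(s=0.5, targets=("nope",)))

    def test_harmonic_restraint_cannot_be_softened(self):
        spec = make_spec(Harmonic(coord=0, k=1.0, name="h"))
        with pytest.raises(ConfigurationError):
            soften(spec, SofteningSpec(s=0.5, targets=("h",)))

    @given(
        s1=st.floats(0.0, 1.0),
        s2=st.floats(0.0, 1.0),
        c=st.floats(0.0, 1.0),
        barrier=st.floats(0.1, 20.0),
    )
    def test_softening_monotone_in_softness(self, s1, s2, c, barrier):
        s_lo, s_hi = sorted((s1, s2))
        spec = make_spec(
            PeriodicTorsion(coord=0, barrier=barrier, name="t"), periodic=True
        )
        b_lo = soften(spec, SofteningSpec(s=s_lo, targets=("t",), floor_fraction=c))
        b_hi = soften(spec, SofteningSpec(s=s_hi, targets=("t",), floor_fraction=c))
        assert b_lo.term_named("t").barrier >= b_hi.term_named("t").barrier
        assert 0.0 <= b_hi.term_named("t").barrier <= barrier


class TestHybrid:
    def test_endpoints_bit_exact(self, harmonic_1_4):
        a, b = harmonic_1_4
        assert hybridize(HybridSpec(a, b, 0.0)) is a
        assert hybridize(HybridSpec(a, b, 1.0)) is b
        x = [0.73]
        assert hybrid_energy(HybridSpec(a, b, 0.0), x) == energy(a, x)
        assert hybrid_energy(HybridSpec(a, b, 1.0), x) == energy(b, x)

    def test_identical_endpoints_any_lambda(self, harmonic_1_4):
        a, _ = harmonic_1_4
        x = [0.4]
        assert hybrid_energy(HybridSpec(a, a, 0.5), x) == pytest.approx(energy(a, x))

    def test_linear_mixing_of_k(self, harmonic_1_4):
        a, b = harmonic_1_4
        # k_R=1, k_T=3 at lambda=0.5 -> effective k=2
        b3 = dataclasses.replace(a, terms=(dataclasses.replace(a.terms[0], k=3.0),))
        assert hybrid_energy(HybridSpec(a, b3, 0.5), [1.0]) == pytest.approx(1.0)

    def test_continuity_in_lambda(self, harmonic_1_4):
        a, b = harmonic_1_4
        x = [1.1]
        lams = np.linspace(0, 1, 21)
        es = [hybrid_energy(HybridSpec(a, b, l), x) for l in lams]
        assert np.all(np.abs(np.diff(es)) < 0.2)

    def test_softcore_appearing_pair(self):
        dom = (Domain(kind="real", lo=-8, hi=8), Domain(kind="real", lo=-8, hi=8))
        base = (
            Harmonic(coord=0, k=1.0, name="h0"),
            Harmonic(coord=1, k=1.0, name="h1"),
        )
        pr_off = PairSoftRepulsion(coord_i=0, coord_j=1, epsilon=0.0, sigma=0.7, name="p")
        pr_on = PairSoftRepulsion(coord_i=0, coord_j=1, epsilon=2.0, sigma=0.7, name="p")
        A = SystemSpec(2, base + (pr_off,), coordinates=dom)
        B = SystemSpec(2, base + (pr_on,), coordinates=dom)
        x = [0.1, 0.2]
        e0 = hybrid_energy(HybridSpec(A, B, 0.0, "linear_with_softcore"), x)
        e1 = hybrid_energy(HybridSpec(A, B, 1.0, "linear_with_softcore"), x)
        em = hybrid_energy(HybridSpec(A, B, 0.5, "linear_with_softcore"), x)
        assert e0 == energy(A, x)
        assert e1 == energy(B, x)
        assert e0 <= em <= e1

    def test_mismatched_specs_raise(self, harmonic_1_4):
        a, _ = harmonic_1_4
        other = make_spec(Harmonic(coord=0, k=1.0, name="h"), dim=1, periodic=True)
        with pytest.raises(ConfigurationError):
            HybridSpec(a, other, 0.5)


class TestQuadrature:
    def test_harmonic_ratio_gives_half_log_k(self, harmonic_1_4):
        a, b = harmonic_1_4
        est = quadrature_free_energy(a, b)
        assert est.value == pytest.approx(np.log(2), abs=1e-9)
        assert est.method == "quadrature"

    def test_identical_specs_give_zero(self, harmonic_1_4):
        a, _ = harmonic_1_4
        assert quadrature_free_energy(a, a).value == 0.0

    def test_antisymmetry(self, double_well_6):
        ns, soft_spec = double_well_6
        softened = soften(ns, soft_spec)
        ab = quadrature_free_energy(softened, ns)
        ba = quadrature_free_energy(ns, softened)
        assert ab.value == pytest.approx(-ba.value, abs=1e-9)

    def test_grid_refinement_stable(self, double_well_6):
        ns, soft_spec = double_well_6
        softened = soften(ns, soft_spec)
        d1 = quadrature_free_energy(softened, ns, grid=4096).value
        d2 = quadrature_free_energy(softened, ns, grid=8192).value
        assert abs(d1 - d2) < 1e-6

    def test_dimension_above_three_unsupported(self):
        terms = tuple(Harmonic(coord=i, k=1.0, name=f"h{i}") for i in range(4))
        spec = SystemSpec(
            4, terms, coordinates=tuple(Domain(kind="real", lo=-8, hi=8) for _ in range(4))
        )
        with pytest.raises(UnsupportedError):
            quadrature_free_energy(spec, spec)

    def test_marginal_density_normalized(self, double_well_6):
        ns, _ = double_well_6
        pts, pdf = boltzmann_marginal(ns, 0)
        assert np.trapezoid(pdf, pts) == pytest.approx(1.0, abs=1e-6)
        # deeper right well: more mass at x > 0
        assert np.trapezoid(pdf[pts > 0], pts[pts > 0]) > 0.6


class TestSerialization:
    @pytest.mark.parametrize("periodic", [False, True])
    def test_spec_round_trip_lossless(self, periodic):
        spec = make_spec(
            PeriodicTorsion(coord=0, barrier=3.3, multiplicity=3, phase=0.1, name="t"),
            ExternalBinding(coord=0, depth=1.7, width=0.45, center=-0.2, name="b"),
            periodic=periodic,
            kT=0.5922,
        )
        assert spec_from_yaml(spec_to_yaml(spec)) == spec

    def test_softening_round_trip_lossless(self):
        soft = SofteningSpec(s=0.37, targets=("a", "b"), floor_fraction=0.65)
        assert softening_from_yaml(softening_to_yaml(soft)) == soft

    def test_pair_term_round_trip(self):
        spec = SystemSpec(
            2,
            (PairSoftRepulsion(coord_i=0, coord_j=1, epsilon=2.0, sigma=0.8, name="p"),),
            coordinates=(Domain(kind="periodic"), Domain(kind="periodic")),
        )
        assert spec_from_yaml(spec_to_yaml(spec)) == spec
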