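"""Yield computations: algebraic vs time-domain agreement, closed forms,
orientation averaging, sweeps, rate maps and the inverse field problem."""

import numpy as np
import pytest

from conftest import random_small_model
from triadspin.constants import GMF_UT, HMF_UT
from triadspin.model import RateSet, ReducedPairModel, reduced_hamiltonian
from triadspin.presets import preset_radical
from triadspin.spin import HyperfineTensor, Nucleus, Radical
from triadspin.yields import (
    DivergenceError,
    EigYieldSolver,
    FieldCondition,
    fibonacci_sphere,
    field_for_effect,
    field_sweep,
    mfe_ratio,
    orientation_average,
    rate_map,
    scavenging_yield,
    superoxide_yield,
    _phi_x_ode,
)


class TestClosedForms:
    @pytest.mark.parametrize("k_x,k_s", [(1.0, 1.0), (0.5, 2.0), (10.0, 1e-3)])
    def test_zero_hyperfine_closed_form(self, k_x, k_s):
        """No mixing: Phi_X = (1/4) k_X / (k_X + k_Sigma) at any field."""
        model = ReducedPairModel(Radical("e1"), Radical("e2"), RateSet(k_X=k_x, k_sigma=k_s))
        for b in (0.0, 55.26):
            res = scavenging_yield(model, b)
            assert np.isclose(res.phi_X, 0.25 * k_x / (k_x + k_s), atol=1e-10)

    def test_kx_zero_gives_zero_yield(self):
        model = ReducedPairModel(Radical("e1"), Radical("e2"), RateSet(k_X=0.0, k_sigma=1.0))
        assert scavenging_yield(model, 50.0).phi_X == 0.0

    def test_both_rates_zero_diverges(self):
        model = ReducedPairModel(Radical("e1"), Radical("e2"), RateSet(k_X=0.0, k_sigma=0.0))
        with pytest.raises(DivergenceError):
            scavenging_yield(model, 0.0)

    def test_exponential_singlet_decay_without_mixing(self):
        """Zero hyperfine: Tr(P_S sigma(t)) = (1/4) e^{-(k_X+k_Sigma) t}."""
        from scipy.linalg import expm

        k_x, k_s = 1.3, 0.4
        model = ReducedPairModel(Radical("e1"), Radical("e2"), RateSet(k_X=k_x, k_sigma=k_s))
        h = reduced_hamiltonian(model, [0, 0, 50.0])
        p = model.singlet_projector()
        a = h - 0.5j * k_x * p
        for t in (0.1, 0.7, 2.0):
            u = expm(-1j * a * t) * np.exp(-0.5 * k_s * t)
            sigma = u @ (np.eye(4) / 4) @ u.conj().T
            assert np.isclose(
                np.trace(p @ sigma).real, 0.25 * np.exp(-(k_x + k_s) * t), atol=1e-10
            )

    def test_nearly_free_limit_approaches_closed_form(self):
        """Vanishing hyperfine coupling reproduces the unmixed closed form."""
        tiny = Radical("r", (Nucleus("H", 2, HyperfineTensor.isotropic(1e-6)),))
        model = ReducedPairModel(tiny, Radical("e"), RateSet(k_X=1.0, k_sigma=0.5))
        res = scavenging_yield(model, 50.0)
        assert np.isclose(res.phi_X, 0.25 / 1.5, atol=1e-8)


class TestOracleEquivalence:
    def test_algebraic_matches_ode_on_random_models(self):
        """Resolvent and brute-force time integration agree to 1e-6."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 20:
            model = random_small_model(rng)
            b = float(rng.uniform(0.0, 80.0))
            h = reduced_hamiltonian(model, [0, 0, b])
            solver = EigYieldSolver(h, model.singlet_projector(), model.rates.k_X)
            phi_alg = solver.phi_x(model.rates.k_sigma)
            phi_ode = _phi_x_ode(model, h)[0]
            assert abs(phi_alg - phi_ode) < 1e-6
            assert 0.0 <= phi_alg <= 1.0
            checked += 1

    def test_conservation_of_exit_probability(self):
        """Phi_X + k_Sigma * integral Tr(sigma) dt = 1 on random models."""
        rng = np.random.default_rng(77)
        for _ in range(10):
            model = random_small_model(rng)
            h = reduced_hamiltonian(model, [0, 0, float(rng.uniform(0, 60))])
            solver = EigYieldSolver(h, model.singlet_projector(), model.rates.k_X)
            ks = model.rates.k_sigma
            total = solver.phi_x(ks) + ks * solver.integrated_trace(ks)
            assert abs(total - 1.0) < 1e-6

    def test_ode_method_exposed_through_public_api(self, free_flavin_model):
        small = ReducedPairModel(
            Radical("r", (Nucleus("H", 2, HyperfineTensor.isotropic(5.0)),)),
            Radical("e"),
            RateSet(k_X=1.0, k_sigma=0.3),
        )
        alg = scavenging_yield(small, 30.0, method="algebraic").phi_X
        ode = scavenging_yield(small, 30.0, method="ode").phi_X
        assert abs(alg - ode) < 1e-6


class TestSuperoxideYield:
    @pytest.mark.parametrize(
        "phi_x,phi,expected", [(0.5, 0.0, 0.5), (0.5, 1.0, 1.0), (0.5, 0.2, 0.6)]
    )
    def test_branching(self, phi_x, phi, expected):
        assert np.isclose(superoxide_yield(phi_x, phi), expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            superoxide_yield(1.5, 0.0)
        with pytest.raises(ValueError):
            superoxide_yield(0.5, -0.1)


class TestMfeRatio:
    def test_chi_is_one_at_reference(self, free_flavin_model):
        res = mfe_ratio(free_flavin_model, GMF_UT, GMF_UT)
        assert np.isclose(res.chi, 1.0, atol=1e-12)

    def test_phi_one_makes_chi_one(self):
        model = ReducedPairModel(
            preset_radical("flavin_3N"),
            preset_radical("ascorbyl_H4"),
            RateSet(k_X=1.0, k_sigma=0.1, phi=1.0),
        )
        res = mfe_ratio(model, HMF_UT, GMF_UT)
        assert np.isclose(res.chi, 1.0, atol=1e-12)

    def test_hypomagnetic_effect_is_negative(self, free_flavin_model):
        res = mfe_ratio(free_flavin_model, HMF_UT, GMF_UT)
        assert res.chi < 1.0
        assert res.effect_pct < 0.0


class TestOrientationAverage:
    def test_isotropic_model_returns_single_orientation(self, free_flavin_model):
        avg = orientation_average(free_flavin_model, GMF_UT, n_orientations=8)
        single = scavenging_yield(free_flavin_model, GMF_UT).phi_X
        assert np.isclose(avg, single, atol=1e-10)

    def test_average_lies_within_orientation_spread(self, bound_flavin_model):
        mean, lo, hi = orientation_average(
            bound_flavin_model, GMF_UT, n_orientations=16, return_spread=True
        )
        assert lo - 1e-12 <= mean <= hi + 1e-12
        assert hi > lo  # anisotropy produces a genuine spread

    def test_quadrature_self_convergence(self, bound_flavin_model):
        """Doubling the spherical quadrature changes the mean by < 1e-3."""
        a36 = orientation_average(bound_flavin_model, GMF_UT, n_orientations=36)
        a72 = orientation_average(bound_flavin_model, GMF_UT, n_orientations=72)
        assert abs(a72 - a36) < 1e-3

    def test_fibonacci_sphere_is_unit_and_balanced(self):
        pts = fibonacci_sphere(72)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.all(np.abs(pts.mean(axis=0)) < 0.02)


class TestSweepAndMap:
    def test_single_value_sweep_matches_scavenging_yield(self, free_flavin_model):
        res = field_sweep(free_flavin_model, [GMF_UT])[0]
        direct = scavenging_yield(free_flavin_model, GMF_UT)
        assert res.phi_X == direct.phi_X

    def test_one_by_one_map_matches_mfe_ratio(self, free_flavin_model):
        rm = rate_map(free_flavin_model, [1.0], [0.1], HMF_UT, GMF_UT)
        direct = mfe_ratio(
            ReducedPairModel(
                free_flavin_model.radical1,
                free_flavin_model.radical3,
                RateSet(k_X=1.0, k_sigma=0.1),
            ),
            HMF_UT,
            GMF_UT,
        )
        assert np.isclose(rm.chi[0, 0], direct.chi, atol=1e-12)

    def test_strong_scavenging_long_lifetime_yield_near_one(self):
        """k_Sigma -> 0 funnels almost everything through the singlet channel."""
        model = ReducedPairModel(
            preset_radical("flavin_3N"),
            preset_radical("ascorbyl_H4"),
            RateSet(k_X=1.0, k_sigma=1e-4),
        )
        assert scavenging_yield(model, GMF_UT).phi_X > 0.95

    def test_zero_field_limit_is_continuous(self, free_flavin_model):
        phis = [scavenging_yield(free_flavin_model, b).phi_X for b in (0.0, 1e-4, 1e-2)]
        assert abs(phis[1] - phis[0]) < 1e-6
        assert abs(phis[2] - phis[0]) < 1e-4

    def test_initial_correlation_independence(self, free_flavin_model):
        """Yields are bit-identical for singlet-, triplet- and F-pair-born
        primary pairs: the traced-out initial state is the same identity/d."""
        from triadspin.model import initial_state
        from triadspin.spin import Radical as R
        from triadspin.triad import InitialCondition, TriadSystem, initial_triad_state

        system = TriadSystem(R("FH"), R("O2"), R("A"), k_F=1.0, k_X=1.0)
        d2 = 2  # superoxide electron dimension
        reduced_states = []
        for cond in InitialCondition:
            rho = initial_triad_state(system, cond)
            # trace out electron 2 (site ordering: e1, e2, e3)
            r = rho.reshape(2, 2, 2, 2, 2, 2)  # (e1,e2,e3) x (e1,e2,e3)
            red = np.einsum("asbcsd->abcd", r).reshape(4, 4)
            reduced_states.append(red)
        target = initial_state(system.reduced_model().space)
        for red in reduced_states:
            assert np.allclose(red, target, atol=1e-14)
        # and the yields computed from that common initial state are one number
        vals = {scavenging_yield(free_flavin_model, GMF_UT).phi_X for _ in range(3)}
        assert len(vals) == 1


class TestFieldForEffect:
    def test_zero_target_returns_reference(self, free_flavin_model):
        assert field_for_effect(free_flavin_model, 0.0, 10.0, (0.1, 100.0)) == 10.0

    def test_no_sign_change_raises(self, free_flavin_model):
        with pytest.raises(ValueError):
            field_for_effect(free_flavin_model, 50.0, 0.0, (0.5, 5.0))

    def test_bracket_refinement_invariance(self):
        model = ReducedPairModel(
            preset_radical("flavin_3N"),
            preset_radical("ascorbyl_H4"),
            RateSet(k_X=10.0, k_sigma=1.0),
        )
        b1 = field_for_effect(model, 1.0, 0.0, (0.5, 40.0))
        b2 = field_for_effect(model, 1.0, 0.0, (0.5 + b1 / 2, 40.0 - (40.0 - b1) / 2))
        assert abs(b1 - b2) / b1 < 0.02
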