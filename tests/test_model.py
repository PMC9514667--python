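"""Reduced equation of motion: Hamiltonians, reaction and relaxation terms."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from triadspin.constants import GMF_UT
from triadspin.model import (
    InvalidRateError,
    RateSet,
    ReducedPairModel,
    haberkorn_reduced,
    hyperfine_hamiltonian,
    initial_state,
    random_field_relaxation,
    reduced_hamiltonian,
    zeeman_hamiltonian,
)
from triadspin.presets import preset_radical
from triadspin.spin import HyperfineTensor, Nucleus, Radical, SpinSpace


class TestRateSet:
    def test_component_aggregation(self):
        rs = RateSet(k_X=1.0, k_E=1.0, k_Ep=2.0, k_F=4.0, k_Xp=8.0)
        assert np.isclose(rs.k_sigma, 1.0 + 2.0 + 1.0 + 2.0)  # = 6

    def test_consistent_both_forms_accepted(self):
        rs = RateSet(k_X=1.0, k_sigma=6.0, k_E=1.0, k_Ep=2.0, k_F=4.0, k_Xp=8.0)
        assert rs.k_sigma == 6.0

    def test_inconsistent_forms_rejected(self):
        with pytest.raises(InvalidRateError):
            RateSet(k_X=1.0, k_sigma=5.0, k_E=1.0, k_Ep=2.0, k_F=4.0, k_Xp=8.0)

    @pytest.mark.parametrize("kwargs", [{"k_X": -1.0}, {"k_X": 1.0, "phi": 1.5}])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(InvalidRateError):
            RateSet(**kwargs)


class TestHamiltonians:
    def test_zeeman_zero_field_and_linearity(self):
        space = SpinSpace((2, 2))
        r = Radical("e")
        assert np.allclose(zeeman_hamiltonian(r, [0, 0, 0], space, 0), 0.0)
        h1 = zeeman_hamiltonian(r, [0, 0, 50.0], space, 0)
        h2 = zeeman_hamiltonian(r, [0, 0, 100.0], space, 0)
        assert np.allclose(2 * h1, h2, atol=1e-12)

    def test_larmor_splitting_at_50_ut(self):
        """Level splitting at 50 uT corresponds to a 1.4 MHz precession."""
        space = SpinSpace((2, 2))
        h = zeeman_hamiltonian(Radical("e"), [0, 0, 50.0], space, 0)
        ev = np.linalg.eigvalsh(h)
        splitting_mhz = (ev.max() - ev.min()) / (2 * np.pi)  # rad/us -> MHz
        assert np.isclose(splitting_mhz, 1.4, atol=0.005)

    def test_hyperfine_no_nuclei_is_zero(self):
        space = SpinSpace((2, 2))
        h = hyperfine_hamiltonian(Radical("O2"), space, 0, [])
        assert np.allclose(h, 0.0)

    def test_hyperfine_doublet_eigenvalues(self):
        """Isotropic a S.I for two spin-1/2: eigenvalues a/4 (x3), -3a/4."""
        a = 10.0  # MHz
        r = Radical("r", (Nucleus("H", 2, HyperfineTensor.isotropic(a)),))
        space = SpinSpace((2, 2), n_electrons=1)  # one electron + its proton
        h = hyperfine_hamiltonian(r, space, 0, [1]) / (2 * np.pi)  # back to MHz
        ev = np.sort(np.linalg.eigvalsh(h))
        assert np.allclose(ev, [-3 * a / 4, a / 4, a / 4, a / 4], atol=1e-10)

    def test_free_equals_bound_for_isotropic_tensors(self):
        nuc = (Nucleus("H", 2, HyperfineTensor.isotropic(7.0)),)
        space = SpinSpace((2, 2, 2))
        h_free = hyperfine_hamiltonian(Radical("r", nuc, mobility="free"), space, 0, [2])
        h_bound = hyperfine_hamiltonian(Radical("r", nuc, mobility="bound"), space, 0, [2])
        assert np.allclose(h_free, h_bound, atol=1e-12)

    def test_reduced_hamiltonian_dimension_and_hermiticity(self):
        model = ReducedPairModel(
            preset_radical("flavin_3N"), preset_radical("ascorbyl_H4"), RateSet(k_X=1.0)
        )
        h = reduced_hamiltonian(model, [0, 0, GMF_UT])
        assert h.shape == (144, 144)
        assert np.allclose(h, h.conj().T, atol=1e-10)

    def test_no_hyperfine_means_no_singlet_triplet_mixing(self):
        model = ReducedPairModel(Radical("e1"), Radical("e2"), RateSet(k_X=1.0))
        h = reduced_hamiltonian(model, [0, 0, 50.0])
        p = model.singlet_projector()
        assert np.allclose(h @ p - p @ h, 0.0, atol=1e-12)


class TestHaberkorn:
    def test_initial_trace_decay_rate(self):
        """From the mixed state: dTr/dt = -k_X/4 - k_Sigma = -0.75 /us here."""
        model = ReducedPairModel(
            Radical("e1"), Radical("e2"), RateSet(k_X=1.0, k_sigma=0.5)
        )
        k = haberkorn_reduced(model)
        sigma0 = initial_state(model.space)
        assert np.isclose(np.trace(k(sigma0)).real, -(1.0 * 0.25 + 0.5))

    def test_pure_uniform_decay_when_kx_zero(self):
        model = ReducedPairModel(Radical("e1"), Radical("e2"), RateSet(k_X=0.0, k_sigma=2.0))
        k = haberkorn_reduced(model)
        sigma = initial_state(model.space)
        assert np.allclose(k(sigma), -2.0 * sigma, atol=1e-12)

    def test_preserves_hermiticity(self):
        rng = np.random.default_rng(3)
        model = ReducedPairModel(Radical("e1"), Radical("e2"), RateSet(k_X=1.3, k_sigma=0.2))
        a = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        sigma = a + a.conj().T
        out = haberkorn_reduced(model)(sigma)
        assert np.allclose(out, out.conj().T, atol=1e-12)


class TestRandomFieldRelaxation:
    def test_zero_rates_give_zero_map(self):
        space = SpinSpace((2, 2))
        r = random_field_relaxation(0.0, 0.0, space)
        assert np.allclose(r(initial_state(space)), 0.0)

    def test_trace_preserving(self):
        rng = np.random.default_rng(7)
        space = SpinSpace((2, 2, 2))
        r = random_field_relaxation(1.5, 0.7, space)
        a = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        sigma = a + a.conj().T
        assert abs(np.trace(r(sigma))) < 1e-12

    @pytest.mark.parametrize("component", [0, 2])  # Sx and Sz
    def test_spin_components_decay_at_rate_gamma(self, component):
        """Isolated spin-1/2 under random-field relaxation: T1 = T2 = 1/gamma."""
        from triadspin.spin import spin_operators

        gamma = 0.8
        ops = spin_operators(2)
        s = ops[component]
        # start polarized along the chosen axis
        sigma0 = 0.5 * np.eye(2) + 0.6 * s
        terms = [(gamma, np.asarray(o)) for o in ops]

        def rhs(_t, y):
            m = y.reshape(2, 2)
            out = np.zeros_like(m)
            for g, a in terms:
                aa = a @ a
                out += g * (a @ m @ a - 0.5 * (aa @ m + m @ aa))
            return out.ravel()

        ts = np.linspace(0.0, 2.0, 9)
        sol = solve_ivp(
            rhs, (0, 2.0), sigma0.astype(complex).ravel(), t_eval=ts, rtol=1e-10, atol=1e-12
        )
        pol = [np.real(np.trace(s @ sol.y[:, i].reshape(2, 2))) for i in range(len(ts))]
        expected = pol[0] * np.exp(-gamma * ts)
        assert np.allclose(pol, expected, atol=1e-6)


def test_initial_state_is_maximally_mixed():
    space = SpinSpace((2, 2, 3, 3, 2, 2))
    sigma0 = initial_state(space)
    assert np.isclose(np.trace(sigma0).real, 1.0)
    assert np.allclose(sigma0, np.eye(144) / 144)
    from triadspin.spin import singlet_projector

    assert np.isclose(np.trace(singlet_projector(space) @ sigma0).real, 0.25)
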