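"""The reduced two-radical equation of motion.

With the fast-relaxing superoxide traced out, the spin dynamics of the
surviving pair (flavin semiquinone FH*, scavenger radical A*-) obey

    d sigma/dt = -i [H', sigma] + K'(sigma) + R'(sigma)

where H' = H_1 + H_3 contains Zeeman and hyperfine terms of the two
radicals only, the Haberkorn reaction superoperator is

    K'(sigma) = -(k_X/2) {P_S, sigma} - k_Sigma sigma

with P_S the FH*/A*- singlet projector, k_X the spin-selective scavenging
rate and k_Sigma = k_E + k_E' + k_F/4 + k_X'/4 the composite spin-
independent depopulation rate, and R' is an optional random-field
relaxation superoperator acting on the two electron spins.  The initial
state is maximally mixed (trace of any primary-pair correlation over the
superoxide yields the identity), so the result is independent of whether
the primary flavin/superoxide pair was born singlet, triplet or as F-pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import GAMMA_E_RAD_PER_US_UT, G_ELECTRON, MHZ_TO_RAD_PER_US
from .spin import (
    Mobility,
    Radical,
    SpinSpace,
    embed,
    singlet_projector,
    site_spin_operators,
    spin_operators,
)

__all__ = [
    "RateSet",
    "ReducedPairModel",
    "zeeman_hamiltonian",
    "hyperfine_hamiltonian",
    "reduced_hamiltonian",
    "haberkorn_reduced",
    "random_field_relaxation",
    "initial_state",
]


class InvalidRateError(ValueError):
    """Raised for negative or inconsistent reaction rates."""


@dataclass(frozen=True)
class RateSet:
    """Reaction rate constants of the triad, reduced form (all in 1/us).

    Either give ``k_sigma`` directly (aggregate form) or the components
    ``k_F`` (flavin/superoxide recombination), ``k_E``/``k_Ep`` (escape of
    A*- and O2*-), ``k_Xp`` (superoxide/ascorbyl recombination), from which
    k_Sigma = k_E + k_Ep + k_F/4 + k_Xp/4.  ``phi`` is the probability that
    the processes subsumed in k_Sigma release superoxide (phi = 0: efficient
    oxidation, superoxide only escapes via productive scavenging of FH*).
    """

    k_X: float
    k_sigma: float | None = None
    k_F: float = 0.0
    k_E: float = 0.0
    k_Ep: float = 0.0
    k_Xp: float = 0.0
    phi: float = 0.0

    def __post_init__(self):
        for name in ("k_X", "k_F", "k_E", "k_Ep", "k_Xp"):
            if getattr(self, name) < 0:
                raise InvalidRateError(f"{name} must be >= 0")
        if not (0.0 <= self.phi <= 1.0):
            raise InvalidRateError("phi must lie in [0, 1]")
        comp = self.k_E + self.k_Ep + self.k_F / 4.0 + self.k_Xp / 4.0
        if self.k_sigma is None:
            object.__setattr__(self, "k_sigma", comp)
        else:
            if self.k_sigma < 0:
                raise InvalidRateError("k_sigma must be >= 0")
            if (self.k_F or self.k_E or self.k_Ep or self.k_Xp) and abs(
                self.k_sigma - comp
            ) > 1e-9:
                raise InvalidRateError(
                    f"k_sigma={self.k_sigma} inconsistent with components "
                    f"(k_E + k_Ep + k_F/4 + k_Xp/4 = {comp})"
                )

    def with_rates(self, k_X: float | None = None, k_sigma: float | None = None) -> "RateSet":
        """Copy with k_X and/or the aggregate k_sigma replaced."""
        return RateSet(
            k_X=self.k_X if k_X is None else k_X,
            k_sigma=self.k_sigma if k_sigma is None else k_sigma,
            phi=self.phi,
        )


@dataclass(frozen=True)
class ReducedPairModel:
    """The reduced (FH*, scavenger) pair with its rates and relaxation.

    ``radical1`` is the flavin semiquinone, ``radical3`` the scavenger
    (ascorbyl by default); the fast-relaxing superoxide has been traced out
    and only enters through the composite rate k_Sigma.  ``relax_gamma1``
    and ``relax_gamma3`` are optional random-field relaxation rates (1/us)
    of the two electron spins.
    """

    radical1: Radical
    radical3: Radical
    rates: RateSet
    relax_gamma1: float = 0.0
    relax_gamma3: float = 0.0

    def __post_init__(self):
        if self.relax_gamma1 < 0 or self.relax_gamma3 < 0:
            raise InvalidRateError("relaxation rates must be >= 0")

    @property
    def space(self) -> SpinSpace:
        mults = (2, 2)
        mults += tuple(n.multiplicity for n in self.radical1.nuclei)
        mults += tuple(n.multiplicity for n in self.radical3.nuclei)
        return SpinSpace(mults, n_electrons=2)

    def electron_site(self, which: int) -> int:
        """Site index of the electron of radical 1 or 3."""
        if which == 1:
            return 0
        if which == 3:
            return 1
        raise ValueError("radical index must be 1 or 3")

    def nucleus_sites(self, which: int) -> range:
        n1 = len(self.radical1.nuclei)
        if which == 1:
            return range(2, 2 + n1)
        if which == 3:
            return range(2 + n1, 2 + n1 + len(self.radical3.nuclei))
        raise ValueError("radical index must be 1 or 3")

    def singlet_projector(self) -> np.ndarray:
        return singlet_projector(self.space, 0, 1)


def zeeman_hamiltonian(
    radical: Radical, field_ut: Sequence[float], space: SpinSpace, electron_site: int
) -> np.ndarray:
    """Electron Zeeman term omega . S in rad/us, omega = g mu_B B / hbar."""
    field = np.asarray(field_ut, dtype=float)
    omega = GAMMA_E_RAD_PER_US_UT * (radical.g_factor / G_ELECTRON) * field
    s_ops = site_spin_operators(electron_site, space)
    h = sum(w * s for w, s in zip(omega, s_ops))
    return np.asarray(h, dtype=complex)


def hyperfine_hamiltonian(
    radical: Radical,
    space: SpinSpace,
    electron_site: int,
    nucleus_sites: Sequence[int],
) -> np.ndarray:
    """Hyperfine term sum_j S . A_j . I_j in rad/us.

    For ``free`` radicals each tensor is replaced by its rotationally
    averaged isotropic part; tensors are supplied in MHz and converted to
    angular frequency here.
    """
    dim = space.dimension
    h = np.zeros((dim, dim), dtype=complex)
    if not radical.nuclei:
        return h
    s_ops = site_spin_operators(electron_site, space)
    for nuc, site in zip(radical.nuclei, nucleus_sites):
        a = radical.effective_tensor(nuc) * MHZ_TO_RAD_PER_US
        i_ops = site_spin_operators(site, space)
        for r in range(3):
            row = a[r]
            for c in range(3):
                if row[c] != 0.0:
                    h += row[c] * (s_ops[r] @ i_ops[c])
    return h


def reduced_hamiltonian(model: ReducedPairModel, field_ut: Sequence[float]) -> np.ndarray:
    """H' = H_1 + H_3: Zeeman plus hyperfine terms of the surviving pair."""
    space = model.space
    h = zeeman_hamiltonian(model.radical1, field_ut, space, model.electron_site(1))
    h += zeeman_hamiltonian(model.radical3, field_ut, space, model.electron_site(3))
    h += hyperfine_hamiltonian(
        model.radical1, space, model.electron_site(1), model.nucleus_sites(1)
    )
    h += hyperfine_hamiltonian(
        model.radical3, space, model.electron_site(3), model.nucleus_sites(3)
    )
    return h


def haberkorn_reduced(model: ReducedPairModel):
    """Reduced Haberkorn reaction superoperator as a callable on matrices.

    sigma -> -(k_X/2) {P_S, sigma} - k_Sigma sigma.  The anticommutator
    term removes singlet population of the scavenging pair at rate k_X; the
    uniform term removes population at the composite rate k_Sigma.
    """
    rates = model.rates
    p_s = model.singlet_projector()
    k_x = rates.k_X
    k_s = rates.k_sigma

    def apply(sigma: np.ndarray) -> np.ndarray:
        return -0.5 * k_x * (p_s @ sigma + sigma @ p_s) - k_s * sigma

    return apply


def _electron_dissipator_ops(space: SpinSpace, site: int) -> list[np.ndarray]:
    return site_spin_operators(site, space)


def random_field_relaxation(gamma1: float, gamma3: float, space: SpinSpace):
    """Random-field (isotropic depolarization) relaxation superoperator.

    Lindblad dissipators with the three Cartesian spin components of each
    electron as jump operators, each at rate gamma, so that longitudinal and
    transverse electron relaxation times are both 1/gamma (T1 = T2).
    Trace preserving; drives each electron spin toward the maximally mixed
    state.  gamma1 = gamma3 = 0 gives the zero map.
    """
    if gamma1 < 0 or gamma3 < 0:
        raise InvalidRateError("relaxation rates must be >= 0")
    terms: list[tuple[float, np.ndarray]] = []
    for gamma, site in ((gamma1, 0), (gamma3, 1)):
        if gamma > 0:
            for op in _electron_dissipator_ops(space, site):
                terms.append((gamma, op))

    def apply(sigma: np.ndarray) -> np.ndarray:
        out = np.zeros_like(sigma, dtype=complex)
        for gamma, a in terms:
            asa = a @ sigma @ a  # Cartesian spin ops are Hermitian
            aa = a @ a
            out += gamma * (asa - 0.5 * (aa @ sigma + sigma @ aa))
        return out

    return apply


def relaxation_dissipator_ops(model: ReducedPairModel) -> list[tuple[float, np.ndarray]]:
    """(rate, jump operator) pairs of the model's random-field relaxation."""
    terms: list[tuple[float, np.ndarray]] = []
    space = model.space
    for gamma, site in ((model.relax_gamma1, 0), (model.relax_gamma3, 1)):
        if gamma > 0:
            for op in site_spin_operators(site, space):
                terms.append((gamma, op))
    return terms


def initial_state(space: SpinSpace) -> np.ndarray:
    """Maximally mixed initial state, identity/dimension.

    This is the partial trace of any primary flavin/superoxide correlation
    (singlet-, triplet- or F-pair-born) over the fast-relaxing superoxide,
    so all initial spin correlations give identical reduced dynamics.
    """
    d = space.dimension
    return np.eye(d, dtype=complex) / d
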