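"""Spin-operator algebra and the domain types describing radicals.

Everything downstream (Hamiltonians, reaction superoperators, yields) is
built from the primitives here: Cartesian angular-momentum matrices for a
site of arbitrary multiplicity, Kronecker embedding of a site operator into
a composite space, and the two-electron singlet projector.

Site ordering convention (fixed throughout the package): electron of
radical 1 first, electron of radical 3 second, then the nuclei of radical 1
in declaration order, then the nuclei of radical 3.  All hyperfine tensors
are interpreted in one common molecular frame; orientation dependence is
implemented by rotating the magnetic field vector, not the tensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "HyperfineTensor",
    "Nucleus",
    "Mobility",
    "Radical",
    "SpinSpace",
    "spin_operators",
    "embed",
    "isotropic_part",
    "singlet_projector",
    "triplet_projector",
    "field_vector",
]


class InvalidSpinError(ValueError):
    """Raised for unphysical spin multiplicities."""


class InvalidSiteError(ValueError):
    """Raised when an operation addresses a site of the wrong kind."""


class InvalidFieldError(ValueError):
    """Raised for unphysical magnetic-field specifications."""


@dataclass(frozen=True, eq=False)
class HyperfineTensor:
    """A 3x3 hyperfine coupling tensor in MHz (linear frequency).

    The tensor is symmetrized on construction; antisymmetric hyperfine
    contributions are outside the model and trigger a warning if present in
    the input.
    """

    matrix: np.ndarray
    frame_label: str = "molecular"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"hyperfine tensor must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("hyperfine tensor entries must be finite")
        sym = 0.5 * (m + m.T)
        if not np.allclose(m, sym, atol=1e-9):
            warnings.warn(
                "non-symmetric hyperfine tensor symmetrized (antisymmetric "
                "part discarded)",
                stacklevel=2,
            )
        sym.setflags(write=False)
        object.__setattr__(self, "matrix", sym)

    def __eq__(self, other):
        if not isinstance(other, HyperfineTensor):
            return NotImplemented
        return self.frame_label == other.frame_label and np.array_equal(
            self.matrix, other.matrix
        )

    def __hash__(self):
        return hash((self.frame_label, self.matrix.tobytes()))

    @classmethod
    def isotropic(cls, a_iso: float, frame_label: str = "molecular") -> "HyperfineTensor":
        """Tensor ``a_iso * identity`` for a fully rotationally averaged coupling."""
        return cls(np.eye(3) * float(a_iso), frame_label)

    @property
    def a_iso(self) -> float:
        """Isotropic coupling constant, Tr(A)/3, in MHz."""
        return float(np.trace(self.matrix) / 3.0)

    def isotropic_reduction(self) -> "HyperfineTensor":
        """Rank-0 (rotationally averaged) part of the tensor."""
        return HyperfineTensor.isotropic(self.a_iso, self.frame_label)


def isotropic_part(tensor: HyperfineTensor) -> float:
    """Isotropic hyperfine coupling a_iso = Tr(A)/3 in MHz."""
    return tensor.a_iso


@dataclass(frozen=True)
class Nucleus:
    """A magnetic nucleus coupled to a radical electron.

    ``multiplicity`` is 2I+1 (2 for 1H, 3 for 14N).
    """

    label: str
    multiplicity: int
    tensor: HyperfineTensor

    def __post_init__(self):
        if int(self.multiplicity) < 2:
            raise InvalidSpinError(
                f"nuclear multiplicity must be >= 2, got {self.multiplicity}"
            )
        object.__setattr__(self, "multiplicity", int(self.multiplicity))


class Mobility(str, Enum):
    """Rotational mobility of a radical.

    ``free`` radicals tumble fast relative to the spin dynamics, so only the
    isotropic (rank-0) hyperfine components survive; ``bound`` radicals keep
    the full anisotropic tensors and make the yields orientation dependent.
    """

    FREE = "free"
    BOUND = "bound"


@dataclass(frozen=True)
class Radical:
    """A paramagnetic species: one unpaired electron plus magnetic nuclei."""

    label: str
    nuclei: tuple[Nucleus, ...] = ()
    g_factor: float = 2.0023
    mobility: Mobility = Mobility.FREE

    def __post_init__(self):
        if self.g_factor <= 0:
            raise ValueError("g-factor must be positive")
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        object.__setattr__(self, "mobility", Mobility(self.mobility))

    def effective_tensor(self, nucleus: Nucleus) -> np.ndarray:
        """Hyperfine tensor actually entering the Hamiltonian (MHz).

        Free radicals are rotationally averaged: only a_iso survives.
        """
        if self.mobility is Mobility.FREE:
            return np.eye(3) * nucleus.tensor.a_iso
        return nucleus.tensor.matrix


@dataclass(frozen=True)
class SpinSpace:
    """Tensor-product structure of a composite spin space.

    ``multiplicities[i]`` is the dimension of site i; the full Hilbert space
    dimension is their product.  Electron sites come first by convention.
    """

    multiplicities: tuple[int, ...]
    n_electrons: int = 2

    def __post_init__(self):
        mults = tuple(int(m) for m in self.multiplicities)
        if any(m < 2 for m in mults):
            raise InvalidSpinError("all site multiplicities must be >= 2")
        object.__setattr__(self, "multiplicities", mults)
        if self.dimension < 4:
            raise ValueError("composite spin space must have dimension >= 4")

    @property
    def dimension(self) -> int:
        return int(np.prod(self.multiplicities))

    @property
    def n_sites(self) -> int:
        return len(self.multiplicities)

    def is_electron_site(self, site: int) -> bool:
        return 0 <= site < self.n_electrons

    def identity(self) -> np.ndarray:
        return np.eye(self.dimension, dtype=complex)


def spin_operators(multiplicity: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cartesian angular-momentum matrices (Jx, Jy, Jz) for spin I=(m-1)/2.

    Built from the standard ladder-operator matrix elements
    <m'|J+-|m> = sqrt(I(I+1) - m(m+-1)); satisfies [Jx,Jy]=iJz and
    Jx^2+Jy^2+Jz^2 = I(I+1) * identity exactly (to rounding).
    """
    m = int(multiplicity)
    if m < 2:
        raise InvalidSpinError(f"multiplicity must be >= 2, got {multiplicity}")
    I = (m - 1) / 2.0
    mz = I - np.arange(m)  # descending magnetic quantum numbers
    jz = np.diag(mz).astype(complex)
    # J+ couples |m_z> -> |m_z + 1>
    cp = np.sqrt(I * (I + 1) - mz[1:] * (mz[1:] + 1))
    jp = np.zeros((m, m), dtype=complex)
    jp[np.arange(m - 1), np.arange(1, m)] = cp
    jm = jp.conj().T
    jx = 0.5 * (jp + jm)
    jy = -0.5j * (jp - jm)
    return jx, jy, jz


def embed(op: np.ndarray, site: int, space: SpinSpace) -> np.ndarray:
    """Embed a single-site operator into the full product space.

    Kronecker product with identities on every other site, respecting the
    space's site ordering.
    """
    op = np.asarray(op)
    if not (0 <= site < space.n_sites):
        raise InvalidSiteError(f"site {site} out of range for {space.n_sites} sites")
    m = space.multiplicities[site]
    if op.shape != (m, m):
        raise ValueError(
            f"operator shape {op.shape} does not match site multiplicity {m}"
        )
    left = int(np.prod(space.multiplicities[:site], initial=1))
    right = int(np.prod(space.multiplicities[site + 1:], initial=1))
    out = np.kron(np.kron(np.eye(left), op), np.eye(right))
    return np.ascontiguousarray(out, dtype=complex)


def site_spin_operators(site: int, space: SpinSpace) -> list[np.ndarray]:
    """The three Cartesian spin operators of ``site`` on the full space."""
    ops = spin_operators(space.multiplicities[site])
    return [embed(o, site, space) for o in ops]


def singlet_projector(space: SpinSpace, e1: int = 0, e2: int = 1) -> np.ndarray:
    """Singlet projector of the electron pair (e1, e2) on the full space.

    P_S = 1/4 - S_e1 . S_e2 for two spin-1/2 electrons; idempotent and
    Hermitian with trace dim/4.
    """
    if e1 == e2:
        raise InvalidSiteError("singlet projector needs two distinct electrons")
    for e in (e1, e2):
        if not space.is_electron_site(e) or space.multiplicities[e] != 2:
            raise InvalidSiteError(f"site {e} is not a spin-1/2 electron site")
    s1 = site_spin_operators(e1, space)
    s2 = site_spin_operators(e2, space)
    dot = sum(a @ b for a, b in zip(s1, s2))
    return 0.25 * np.eye(space.dimension, dtype=complex) - dot


def triplet_projector(space: SpinSpace, e1: int = 0, e2: int = 1) -> np.ndarray:
    """Triplet projector 1 - P_S of the electron pair (e1, e2)."""
    return np.eye(space.dimension, dtype=complex) - singlet_projector(space, e1, e2)


def field_vector(magnitude_ut: float, polar: float = 0.0, azimuth: float = 0.0) -> np.ndarray:
    """Cartesian magnetic field vector (uT) from spherical angles (rad).

    The polar angle is measured from the molecular z-axis (an arbitrary but
    fixed convention; only the orientation of the field relative to the
    hyperfine frames matters).
    """
    if magnitude_ut < 0:
        raise InvalidFieldError("field magnitude must be non-negative")
    st, ct = np.sin(polar), np.cos(polar)
    return magnitude_ut * np.array([st * np.cos(azimuth), st * np.sin(azimuth), ct])
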