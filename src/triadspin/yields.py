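"""Reaction quantum yields and magnetic field effects of the reduced pair.

The singlet scavenging yield is

    Phi_X = k_X * integral_0^inf Tr(P_S sigma(t)) dt,

the superoxide escape yield Y = (1 - phi) * Phi_X + phi, and the
magnetosensitivity metric is the yield ratio chi(B) = Y(B) / Y(B_ref)
between a field condition and a reference (conventionally the geomagnetic
field); effects are reported as signed percentages 100 * (chi - 1).

Two solution paths are provided.  The production path is algebraic: for
gamma = 0 the trajectory is sigma(t) = U sigma(0) U^dag with
U = exp(-i A t) exp(-k_Sigma t / 2), A = H' - i (k_X/2) P_S, so a single
eigendecomposition of the non-Hermitian A yields Phi_X in closed form for
every k_Sigma (the uniform decay enters only as a shift of the resolvent
denominators, which is exploited to reuse eigendecompositions across the
k_Sigma axis of rate maps).  With relaxation (gamma > 0) the yield is
obtained from a sparse linear solve in Liouville space.  The independent
oracle integrates the master equation in time with adaptive stepping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import ReducedPairModel, initial_state, reduced_hamiltonian, relaxation_dissipator_ops
from .spin import Mobility, field_vector

__all__ = [
    "FieldCondition",
    "YieldResult",
    "scavenging_yield",
    "superoxide_yield",
    "mfe_ratio",
    "orientation_average",
    "field_sweep",
    "rate_map",
    "field_for_effect",
    "fibonacci_sphere",
]


class DivergenceError(ValueError):
    """Raised when the yield integral does not converge (k_X = k_Sigma = 0)."""


class HorizonError(RuntimeError):
    """Raised when the time-domain oracle fails to reach a converged tail."""


@dataclass(frozen=True)
class FieldCondition:
    """A static magnetic field: magnitude (uT) plus direction or policy.

    ``direction`` is a unit 3-vector in the molecular frame, or None for the
    orientation-averaging policy (used for protein-bound, i.e. anisotropic,
    radicals).  ``n_orientations`` controls the spherical quadrature then.
    """

    magnitude_ut: float
    direction: tuple[float, float, float] | None = (0.0, 0.0, 1.0)
    n_orientations: int = 72

    def __post_init__(self):
        if self.magnitude_ut < 0:
            raise ValueError("field magnitude must be >= 0")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            if self.magnitude_ut > 0 and not math.isclose(n, 1.0, rel_tol=1e-6):
                d = d / n
            object.__setattr__(self, "direction", tuple(d))

    @property
    def averaged(self) -> bool:
        return self.direction is None

    def vector_ut(self) -> np.ndarray:
        if self.averaged:
            raise ValueError("orientation-averaged condition has no single vector")
        return self.magnitude_ut * np.asarray(self.direction)


@dataclass(frozen=True)
class YieldResult:
    """A computed yield with full parameter provenance."""

    phi_X: float
    Y: float
    magnitude_ut: float
    orientation_policy: str
    k_X: float
    k_sigma: float
    phi: float
    gamma1: float = 0.0
    gamma3: float = 0.0
    method: str = "algebraic"
    chi: float | None = None
    effect_pct: float | None = None


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors on the full sphere (n x 3)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


class EigYieldSolver:
    """Closed-form yield evaluator for one Hamiltonian and one k_X.

    Eigendecomposes A = H - i (k_X/2) P_S once; ``phi_x(k_sigma)`` then
    costs only an elementwise resolvent sum, so the k_Sigma axis of a rate
    map reuses the decomposition.
    """

    def __init__(self, hamiltonian: np.ndarray, p_singlet: np.ndarray, k_X: float):
        self.k_X = float(k_X)
        d = hamiltonian.shape[0]
        self.dim = d
        a = hamiltonian - 0.5j * self.k_X * p_singlet
        lam, v = scipy.linalg.eig(a)
        v_inv = scipy.linalg.inv(v)
        sigma0 = np.eye(d) / d
        m = v_inv @ v_inv.conj().T / d  # V^-1 sigma0 V^-dag
        q_p = v.conj().T @ p_singlet @ v
        q_i = v.conj().T @ v
        # W_jk = Q_kj * M_jk ; denominators D_jk = i (lam_j - conj(lam_k))
        self._w_p = q_p.T * m
        self._w_i = q_i.T * m
        self._d = 1j * (lam[:, None] - lam.conj()[None, :])
        #: rough conditioning diagnostic of the eigenbasis
        self.condition_estimate = float(
            np.linalg.norm(v, ord="fro") * np.linalg.norm(v_inv, ord="fro") / d
        )

    def _resolvent_sum(self, w: np.ndarray, k_sigma: float) -> float:
        denom = self._d + k_sigma
        small = np.abs(denom) < 1e-12
        if np.any(small):
            # zero-frequency, zero-decay components: only admissible when
            # their weight vanishes (otherwise the integral diverges)
            if np.any(np.abs(w[small]) > 1e-10):
                raise DivergenceError(
                    "yield integral diverges: undamped stationary component "
                    "(is k_X + k_Sigma > 0 and the singlet channel reachable?)"
                )
            denom = np.where(small, 1.0, denom)
            w = np.where(small, 0.0, w)
        return float(np.real(np.sum(w / denom)))

    def phi_x(self, k_sigma: float) -> float:
        """Singlet scavenging yield Phi_X at composite rate ``k_sigma``."""
        if self.k_X + k_sigma <= 0.0:
            raise DivergenceError("k_X + k_Sigma must be positive")
        if self.k_X == 0.0:
            return 0.0
        return self.k_X * self._resolvent_sum(self._w_p, k_sigma)

    def phi_x_grid(self, k_sigma_values: np.ndarray) -> np.ndarray:
        return np.array([self.phi_x(ks) for ks in np.asarray(k_sigma_values, float)])

    def integrated_trace(self, k_sigma: float) -> float:
        """integral Tr(sigma(t)) dt; Phi_X + k_Sigma * this equals 1."""
        return self._resolvent_sum(self._w_i, k_sigma)


def _liouvillian_sparse(model: ReducedPairModel, h: np.ndarray) -> sp.csc_matrix:
    """Vectorized generator (column-stacking convention) including relaxation."""
    d = h.shape[0]
    eye = sp.identity(d, format="csr")
    hs = sp.csr_matrix(h)
    p = sp.csr_matrix(model.singlet_projector())
    k_x, k_s = model.rates.k_X, model.rates.k_sigma
    lv = -1j * (sp.kron(eye, hs) - sp.kron(hs.T, eye))
    lv = lv - 0.5 * k_x * (sp.kron(eye, p) + sp.kron(p.T, eye))
    lv = lv - k_s * sp.identity(d * d, format="csr")
    for gamma, a in relaxation_dissipator_ops(model):
        a = sp.csr_matrix(a)
        aa = (a @ a).tocsr()
        lv = lv + gamma * (
            sp.kron(a.T, a) - 0.5 * (sp.kron(eye, aa) + sp.kron(aa.T, eye))
        )
    return lv.tocsc()


def _phi_x_liouville(model: ReducedPairModel, h: np.ndarray) -> float:
    d = h.shape[0]
    lv = _liouvillian_sparse(model, h)
    sigma0 = np.eye(d, dtype=complex) / d
    x = spla.spsolve(lv, -sigma0.flatten(order="F"))
    p_vec = model.singlet_projector().flatten(order="F")
    return float(np.real(model.rates.k_X * np.vdot(p_vec, x)))


def _phi_x_ode(
    model: ReducedPairModel,
    h: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[float, dict]:
    """Time-domain oracle: integrate the master equation and the yield.

    Returns (Phi_X, diagnostics).  The horizon is 20 / (k_X/4 + k_Sigma)
    (twenty times the slowest exit timescale from the maximally mixed
    state); the remaining tail mass is reported and must be small.
    """
    rates = model.rates
    k_x, k_s = rates.k_X, rates.k_sigma
    if k_x + k_s <= 0:
        raise DivergenceError("k_X + k_Sigma must be positive")
    d = h.shape[0]
    p_s = model.singlet_projector()
    diss = relaxation_dissipator_ops(model)

    def rhs(_t, y):
        sigma = y[: d * d].reshape(d, d)
        ds = -1j * (h @ sigma - sigma @ h)
        ds -= 0.5 * k_x * (p_s @ sigma + sigma @ p_s)
        ds -= k_s * sigma
        for gamma, a in diss:
            aa = a @ a
            ds += gamma * (a @ sigma @ a - 0.5 * (aa @ sigma + sigma @ aa))
        tr_p = np.real(np.trace(p_s @ sigma))
        tr = np.real(np.trace(sigma))
        return np.concatenate([ds.ravel(), [k_x * tr_p, k_s * tr]])

    y0 = np.concatenate([(np.eye(d, dtype=complex) / d).ravel(), [0.0, 0.0]])
    t_max = 20.0 / (k_x / 4.0 + k_s)
    # under fast scavenging (Zeno regime) the true exit rate can be much
    # slower than k_x/4; extend the horizon until the tail mass is small
    t0, tail = 0.0, 1.0
    for _ in range(8):
        sol = solve_ivp(rhs, (t0, t_max), y0, method="DOP853", rtol=rtol, atol=atol)
        if not sol.success:
            raise HorizonError(f"master-equation integration failed: {sol.message}")
        y0 = sol.y[:, -1]
        tail = float(np.real(np.trace(y0[: d * d].reshape(d, d))))
        if tail <= 1e-7:
            break
        t0, t_max = t_max, t_max * 2.0
    yf = y0
    phi_x = float(np.real(yf[d * d]))
    exit_total = phi_x + float(np.real(yf[d * d + 1]))
    if tail > 1e-4:
        raise HorizonError(
            f"trajectory not converged at horizon t={t_max:.3g} us "
            f"(tail mass {tail:.3g})"
        )
    # the surviving tail exits through the same channels in proportion
    phi_x += tail * (k_x / 4.0) / (k_x / 4.0 + k_s) if tail > 0 else 0.0
    return phi_x, {"tail_mass": tail, "exit_probability": exit_total, "t_max": t_max}


def _model_has_anisotropy(model: ReducedPairModel) -> bool:
    for rad in (model.radical1, model.radical3):
        if rad.mobility is Mobility.BOUND:
            for nuc in rad.nuclei:
                a = nuc.tensor.matrix
                if not np.allclose(a, np.eye(3) * nuc.tensor.a_iso, atol=1e-12):
                    return True
    return False


def _phi_x_single(model: ReducedPairModel, field_ut: np.ndarray, method: str) -> float:
    h = reduced_hamiltonian(model, field_ut)
    if method == "ode":
        return _phi_x_ode(model, h)[0]
    if method != "algebraic":
        raise ValueError(f"unknown method {method!r}")
    if model.relax_gamma1 > 0 or model.relax_gamma3 > 0:
        return _phi_x_liouville(model, h)
    solver = EigYieldSolver(h, model.singlet_projector(), model.rates.k_X)
    return solver.phi_x(model.rates.k_sigma)


def scavenging_yield(
    model: ReducedPairModel,
    field: FieldCondition | float,
    method: str = "algebraic",
) -> YieldResult:
    """Singlet scavenging yield Phi_X and superoxide yield Y at one field.

    ``field`` may be a FieldCondition or a bare magnitude in uT (taken along
    z, or orientation-averaged automatically if the model carries hyperfine
    anisotropy).  ``method`` is 'algebraic' (resolvent/linear solve) or
    'ode' (time integration oracle).
    """
    if not isinstance(field, FieldCondition):
        direction = None if _model_has_anisotropy(model) else (0.0, 0.0, 1.0)
        field = FieldCondition(float(field), direction)
    if field.averaged and _model_has_anisotropy(model):
        phi_x = orientation_average(
            model, field.magnitude_ut, n_orientations=field.n_orientations, method=method
        )
        policy = f"average[{field.n_orientations}]"
    else:
        vec = (
            field.magnitude_ut * np.array([0.0, 0.0, 1.0])
            if field.averaged
            else field.vector_ut()
        )
        phi_x = _phi_x_single(model, vec, method)
        policy = "fixed"
    rates = model.rates
    return YieldResult(
        phi_X=phi_x,
        Y=superoxide_yield(phi_x, rates.phi),
        magnitude_ut=field.magnitude_ut,
        orientation_policy=policy,
        k_X=rates.k_X,
        k_sigma=rates.k_sigma,
        phi=rates.phi,
        gamma1=model.relax_gamma1,
        gamma3=model.relax_gamma3,
        method=method,
    )


def superoxide_yield(phi_x: float, phi: float) -> float:
    """Superoxide escape yield Y = (1 - phi) * Phi_X + phi."""
    if not (0.0 <= phi <= 1.0):
        raise ValueError("phi must lie in [0, 1]")
    if not (-1e-9 <= phi_x <= 1.0 + 1e-9):
        raise ValueError("Phi_X must lie in [0, 1]")
    return (1.0 - phi) * phi_x + phi


def mfe_ratio(
    model: ReducedPairModel,
    field: FieldCondition | float,
    field_ref: FieldCondition | float,
    method: str = "algebraic",
) -> YieldResult:
    """Yield ratio chi = Y(B) / Y(B_ref) and the percentage effect.

    chi < 1 means the field condition suppresses superoxide release
    relative to the reference (the hypomagnetic-exposure situation).
    """
    res = scavenging_yield(model, field, method)
    ref = scavenging_yield(model, field_ref, method)
    if ref.Y <= 0:
        raise ZeroDivisionError("reference superoxide yield is zero")
    chi = res.Y / ref.Y
    return YieldResult(
        **{
            **res.__dict__,
            "chi": chi,
            "effect_pct": 100.0 * (chi - 1.0),
        }
    )


def orientation_average(
    model: ReducedPairModel,
    magnitude_ut: float,
    n_orientations: int = 72,
    method: str = "algebraic",
    return_spread: bool = False,
):
    """Phi_X averaged over magnetic-field orientations on the unit sphere.

    Uses a deterministic Fibonacci point set (near-uniform quadrature over
    the full sphere).  If the model has no hyperfine anisotropy the single
    z-orientation value is returned unchanged.
    """
    import warnings

    if not _model_has_anisotropy(model):
        val = _phi_x_single(model, magnitude_ut * np.array([0.0, 0.0, 1.0]), method)
        return (val, val, val) if return_spread else val
    if n_orientations < 6:
        warnings.warn("fewer than 6 orientations is a very coarse sphere quadrature")
    dirs = fibonacci_sphere(n_orientations)
    vals = np.array(
        [_phi_x_single(model, magnitude_ut * d, method) for d in dirs]
    )
    mean = float(vals.mean())
    if return_spread:
        return mean, float(vals.min()), float(vals.max())
    return mean


def field_sweep(
    model: ReducedPairModel,
    b_values_ut: Sequence[float],
    reference_ut: float | None = None,
    n_orientations: int = 72,
    method: str = "algebraic",
) -> list[YieldResult]:
    """MARY curve: yields over a list of field magnitudes.

    If ``reference_ut`` is given, chi and the percentage effect relative to
    that field are attached to every point.
    """
    averaged = _model_has_anisotropy(model)
    cond = lambda b: FieldCondition(
        b, None if averaged else (0.0, 0.0, 1.0), n_orientations
    )
    results = [scavenging_yield(model, cond(float(b)), method) for b in b_values_ut]
    if reference_ut is not None:
        ref = scavenging_yield(model, cond(float(reference_ut)), method)
        if ref.Y <= 0:
            raise ZeroDivisionError("reference superoxide yield is zero")
        results = [
            YieldResult(
                **{
                    **r.__dict__,
                    "chi": r.Y / ref.Y,
                    "effect_pct": 100.0 * (r.Y / ref.Y - 1.0),
                }
            )
            for r in results
        ]
    return results


@dataclass(frozen=True)
class RateMap:
    """chi and Phi_X over a (k_X, k_Sigma) grid at a field pair."""

    k_x_values: np.ndarray
    k_sigma_values: np.ndarray
    phi_x: np.ndarray          # shape (n_kx, n_ks), at the probe field
    phi_x_ref: np.ndarray      # at the reference field
    chi: np.ndarray
    field_ut: float
    field_ref_ut: float
    orientation_policy: str

    @property
    def effect_pct(self) -> np.ndarray:
        return 100.0 * (self.chi - 1.0)

    def max_effect(self) -> tuple[float, float, float]:
        """Most negative percentage effect and its (k_X, k_Sigma) location.

        Ties broken toward the lexicographically smallest grid index.
        """
        eff = self.effect_pct
        idx = np.unravel_index(int(np.argmin(eff)), eff.shape)
        return (
            float(eff[idx]),
            float(self.k_x_values[idx[0]]),
            float(self.k_sigma_values[idx[1]]),
        )


def default_rate_grids(points_per_decade: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced k_X in [1e-2, 1e3] and k_Sigma in [1e-2, 1e2] (1/us)."""
    kx = np.logspace(-2, 3, 5 * points_per_decade + 1)
    ks = np.logspace(-2, 2, 4 * points_per_decade + 1)
    return kx, ks


def _phi_x_grid_for_field(
    model: ReducedPairModel,
    kx_values: np.ndarray,
    ks_values: np.ndarray,
    magnitude_ut: float,
    n_orientations: int,
) -> np.ndarray:
    """Phi_X over the rate grid, reusing eigendecompositions across k_Sigma."""
    averaged = _model_has_anisotropy(model)
    dirs = fibonacci_sphere(n_orientations) if averaged else np.array([[0.0, 0.0, 1.0]])
    p_s = model.singlet_projector()
    out = np.zeros((len(kx_values), len(ks_values)))
    for d in dirs:
        h = reduced_hamiltonian(model, magnitude_ut * d)
        for i, kx in enumerate(kx_values):
            solver = EigYieldSolver(h, p_s, kx)
            out[i] += solver.phi_x_grid(ks_values)
    return out / len(dirs)


def rate_map(
    model: ReducedPairModel,
    kx_values: Sequence[float] | None = None,
    ks_values: Sequence[float] | None = None,
    field_ut: float | None = None,
    field_ref_ut: float | None = None,
    n_orientations: int = 72,
) -> RateMap:
    """chi(B vs B_ref) and Phi_X over a (k_X, k_Sigma) grid.

    Defaults: the package's log grids and the hypomagnetic-vs-geomagnetic
    field pair.  For models with hyperfine anisotropy every grid entry is
    orientation averaged.  Requires gamma = 0 (the eigendecomposition fast
    path); with relaxation, evaluate points individually via mfe_ratio.
    """
    from .constants import GMF_UT, HMF_UT

    if model.relax_gamma1 > 0 or model.relax_gamma3 > 0:
        raise NotImplementedError(
            "rate_map uses the gamma=0 fast path; with relaxation evaluate "
            "points via mfe_ratio"
        )
    kx = np.asarray(kx_values if kx_values is not None else default_rate_grids()[0], float)
    ks = np.asarray(ks_values if ks_values is not None else default_rate_grids()[1], float)
    if np.any(kx <= 0) or np.any(ks <= 0):
        raise ValueError("rate grids must be strictly positive")
    b = HMF_UT if field_ut is None else float(field_ut)
    b_ref = GMF_UT if field_ref_ut is None else float(field_ref_ut)
    averaged = _model_has_anisotropy(model)
    phi_b = _phi_x_grid_for_field(model, kx, ks, b, n_orientations)
    phi_ref = _phi_x_grid_for_field(model, kx, ks, b_ref, n_orientations)
    phi = model.rates.phi
    y_b = (1.0 - phi) * phi_b + phi
    y_ref = (1.0 - phi) * phi_ref + phi
    return RateMap(
        k_x_values=kx,
        k_sigma_values=ks,
        phi_x=phi_b,
        phi_x_ref=phi_ref,
        chi=y_b / y_ref,
        field_ut=b,
        field_ref_ut=b_ref,
        orientation_policy=f"average[{n_orientations}]" if averaged else "fixed",
    )


def field_for_effect(
    model: ReducedPairModel,
    target_effect_pct: float,
    field_ref_ut: float,
    bracket_ut: tuple[float, float],
    n_orientations: int = 72,
    rel_tol: float = 0.01,
    n_monotonicity_samples: int = 7,
) -> float:
    """Field magnitude producing a given |percentage change| of Phi_X.

    Solves |100 * (Phi_X(B) / Phi_X(B_ref) - 1)| = target by bracketed root
    finding; the magnitude of the effect must be monotone across the
    bracket (validated by sampling).
    """
    if target_effect_pct < 0:
        raise ValueError("target effect must be >= 0 (magnitude of the change)")
    ref = orientation_average(model, field_ref_ut, n_orientations)
    if ref <= 0:
        raise ZeroDivisionError("reference yield is zero")
    if target_effect_pct == 0.0:
        return float(field_ref_ut)

    def excess(b: float) -> float:
        val = orientation_average(model, b, n_orientations)
        return abs(100.0 * (val / ref - 1.0)) - target_effect_pct

    lo, hi = map(float, bracket_ut)
    samples = [excess(b) for b in np.linspace(lo, hi, n_monotonicity_samples)]
    if any(b < a - 1e-9 for a, b in zip(samples, samples[1:])) and any(
        b > a + 1e-9 for a, b in zip(samples, samples[1:])
    ):
        raise ValueError("effect magnitude is not monotone across the bracket")
    f_lo, f_hi = samples[0], samples[-1]
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change in bracket [{lo}, {hi}] uT "
            f"(effect excess {f_lo:.3g} .. {f_hi:.3g})"
        )
    return float(brentq(excess, lo, hi, rtol=rel_tol))
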