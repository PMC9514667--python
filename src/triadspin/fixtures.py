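"""Deterministic toy fixtures with independently computed reference yields.

Each fixture is a small spin system whose scavenging yield is recomputed by
the time-domain oracle (brute-force master-equation integration), together
with the closed-form zero-hyperfine case, so the algebraic production path
can be tested without any external data.  Generation is seed-free and
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import RateSet, ReducedPairModel, reduced_hamiltonian
from .spin import HyperfineTensor, Nucleus, Radical
from .yields import _phi_x_ode

__all__ = ["FixtureSet", "builtin_fixtures", "generate_fixtures"]

_ODE_TOL = 1e-6


@dataclass(frozen=True)
class Fixture:
    name: str
    model: ReducedPairModel
    field_ut: float
    reference_phi_x: float
    method: str
    tolerance: float


@dataclass(frozen=True)
class FixtureSet:
    fixtures: tuple[Fixture, ...]

    def __iter__(self):
        return iter(self.fixtures)

    def __getitem__(self, name: str) -> Fixture:
        for f in self.fixtures:
            if f.name == name:
                return f
        raise KeyError(name)


def _toy_models() -> list[tuple[str, ReducedPairModel, float]]:
    bare = Radical("e")
    one_proton = Radical(
        "r1H", (Nucleus("H", 2, HyperfineTensor.isotropic(10.0)),)
    )
    return [
        ("no_nucleus_pair", ReducedPairModel(bare, bare, RateSet(k_X=1.0, k_sigma=1.0)), 0.0),
        (
            "one_proton_pair",
            ReducedPairModel(one_proton, bare, RateSet(k_X=1.0, k_sigma=0.1)),
            0.0,
        ),
        (
            "one_proton_pair_gmf",
            ReducedPairModel(one_proton, bare, RateSet(k_X=1.0, k_sigma=0.1)),
            55.26,
        ),
    ]


def builtin_fixtures() -> FixtureSet:
    """Recompute all toy fixtures with the ODE oracle (plus closed forms)."""
    out = []
    for name, model, b in _toy_models():
        h = reduced_hamiltonian(model, [0.0, 0.0, b])
        if name == "no_nucleus_pair":
            # no hyperfine coupling: no singlet-triplet mixing, exact value
            k_x, k_s = model.rates.k_X, model.rates.k_sigma
            ref = 0.25 * k_x / (k_x + k_s)
            method, tol = "closed_form", 1e-12
        else:
            ref = _phi_x_ode(model, h)[0]
            method, tol = "ode_oracle", _ODE_TOL
        out.append(Fixture(name, model, b, float(ref), method, tol))
    return FixtureSet(tuple(out))


def generate_fixtures(outdir: str | Path) -> FixtureSet:
    """Write the fixture set (metadata + reference yields) as JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixtures = builtin_fixtures()
    payload = []
    for f in fixtures:
        payload.append(
            {
                "name": f.name,
                "field_uT": f.field_ut,
                "k_X": f.model.rates.k_X,
                "k_Sigma": f.model.rates.k_sigma,
                "n_nuclei": [len(f.model.radical1.nuclei), len(f.model.radical3.nuclei)],
                "reference_phi_X": f.reference_phi_x,
                "method": f.method,
                "tolerance": f.tolerance,
            }
        )
    (outdir / "fixtures.json").write_text(json.dumps(payload, indent=2))
    return fixtures
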