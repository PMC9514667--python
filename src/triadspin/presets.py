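"""Built-in radical definitions.

The flavin semiquinone (FH*) presets carry the dominant hyperfine couplings
of the neutral flavin radical FADH*, at the coupling strengths reported for
the protonated (neutral) semiquinone (a_iso in MHz: N5 20.3, N10 7.5,
H5 -19.6; the extended set adds H6 -5.9 and the 8alpha methyl-type proton
Hbeta1 +8.0).  Full tensors are constructed in a common molecular frame
with the z-axis perpendicular to the isoalloxazine ring plane: the ring
nitrogens N5/N10 carry the usual nearly axial pi-radical anisotropy (small
in-plane components, large out-of-plane A_zz), the alpha-protons H5/H6 the
canonical rhombic alpha-proton pattern (ratios ~0.5 : 1.5 : 1 of a_iso
along bond / in-plane perpendicular / out-of-plane), and the beta-type
proton is nearly isotropic.

The ascorbyl radical couples significantly to a single proton (H4) with
a_iso = 4.94 MHz; superoxide (16O) has no magnetic nuclei.

For ``free`` radicals only the isotropic parts enter the spin Hamiltonian,
so the free-flavin predictions depend only on the literature a_iso values;
the anisotropy patterns matter only for protein-bound (immobilized) flavin.
"""

from __future__ import annotations

import numpy as np

from .spin import HyperfineTensor, Mobility, Nucleus, Radical

__all__ = ["preset_radical", "PRESET_NAMES"]


def _axial(a_iso: float, a_zz: float) -> np.ndarray:
    """Axial tensor with out-of-plane (z) principal value a_zz, trace 3*a_iso."""
    perp = (3.0 * a_iso - a_zz) / 2.0
    return np.diag([perp, perp, a_zz])


def _alpha_proton(a_iso: float) -> np.ndarray:
    """Rhombic alpha-proton tensor: (0.5, 1.5, 1.0) * a_iso along (x, y, z).

    x is taken along the X-H bond, y in-plane perpendicular to it, z out of
    the ring plane (the McConnell-type pattern for pi-radical alpha-protons).
    """
    return np.diag([0.5 * a_iso, 1.5 * a_iso, 1.0 * a_iso])


# Isotropic couplings (MHz) for the neutral flavin semiquinone
_A_ISO = {"N5": 20.3, "N10": 7.5, "H5": -19.6, "H6": -5.9, "Hb1": 8.0}

# Out-of-plane principal values (MHz) for the ring nitrogens (pi spin density)
_A_ZZ = {"N5": 47.9, "N10": 17.5}


def _flavin_nuclei(extended: bool) -> tuple[Nucleus, ...]:
    nuclei = [
        Nucleus("N5", 3, HyperfineTensor(_axial(_A_ISO["N5"], _A_ZZ["N5"]))),
        Nucleus("N10", 3, HyperfineTensor(_axial(_A_ISO["N10"], _A_ZZ["N10"]))),
        Nucleus("H5", 2, HyperfineTensor(_alpha_proton(_A_ISO["H5"]))),
    ]
    if extended:
        nuclei.append(Nucleus("H6", 2, HyperfineTensor(_alpha_proton(_A_ISO["H6"]))))
        nuclei.append(
            Nucleus(
                "Hb1", 2, HyperfineTensor(np.diag([0.95, 0.95, 1.10]) * _A_ISO["Hb1"])
            )
        )
    return tuple(nuclei)


def preset_radical(name: str, mobility: str | Mobility | None = None) -> Radical:
    """Return a built-in radical by name.

    Presets: ``flavin_3N`` (N5, N10, H5), ``flavin_5N`` (adds H6, Hbeta1),
    ``ascorbyl_H4`` (one isotropic proton, a_iso = 4.94 MHz), ``superoxide``
    (no magnetic nuclei).  ``mobility`` overrides the preset default
    (flavins default to free; the scavenger and superoxide are always
    rotationally averaged).
    """
    key = name.strip().lower()
    if key == "flavin_3n":
        rad = Radical("FH", _flavin_nuclei(extended=False))
    elif key == "flavin_5n":
        rad = Radical("FH", _flavin_nuclei(extended=True))
    elif key == "ascorbyl_h4":
        rad = Radical(
            "A",
            (Nucleus("H4", 2, HyperfineTensor.isotropic(4.94)),),
        )
    elif key == "superoxide":
        rad = Radical("O2", ())
    else:
        raise KeyError(
            f"unknown radical preset {name!r}; available: {sorted(PRESET_NAMES)}"
        )
    if mobility is not None:
        rad = Radical(rad.label, rad.nuclei, rad.g_factor, Mobility(mobility))
    return rad


PRESET_NAMES = frozenset({"flavin_3n", "flavin_5n", "ascorbyl_h4", "superoxide"})
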