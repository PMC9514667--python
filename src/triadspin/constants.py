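"""Physical constants and field conditions.

Internal unit system: time in microseconds, rates in inverse microseconds,
magnetic fields in microtesla, Hamiltonians in angular frequency units
(rad/us).  Hyperfine couplings are supplied in MHz (linear frequency) and
converted with a factor of 2*pi on entering a Hamiltonian.
"""

import math

#: Bohr magneton, J/T (CODATA 2018)
MU_B = 9.2740100783e-24
#: reduced Planck constant, J s
HBAR = 1.054571817e-34
#: free-electron g-factor used for both radicals
G_ELECTRON = 2.0023

#: electron gyromagnetic prefactor g*mu_B/hbar in rad us^-1 uT^-1
GAMMA_E_RAD_PER_US_UT = G_ELECTRON * MU_B / HBAR * 1e-12

#: MHz (linear frequency) -> rad/us (angular frequency)
MHZ_TO_RAD_PER_US = 2.0 * math.pi

#: geomagnetic reference field used in the hypomagnetic-exposure comparison, uT
GMF_UT = 55.26
#: hypomagnetic field condition, uT
HMF_UT = 0.29


def larmor_frequency_mhz(field_ut: float, g_factor: float = G_ELECTRON) -> float:
    """Electron Larmor precession frequency (linear, MHz) at ``field_ut`` uT.

    At geomagnetic intensities (~50 uT) this is ~1.4 MHz, setting the
    timescale a radical system must survive to sense such fields.
    """
    omega = g_factor * MU_B / HBAR * 1e-12 * field_ut  # rad/us
    return omega / (2.0 * math.pi)
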