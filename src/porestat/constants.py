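"""Physical constants and unit helpers.

Internal unit policy: energies in kT, everything else SI.  Geometry types
carry Å fields (the natural scale for a selectivity filter) with SI
accessors; all conversion to/from display units (mV, pA, mM) happens at the
I/O boundary.
"""

from scipy import constants as _const

E_CHARGE = _const.e  # elementary charge, C
K_BOLTZMANN = _const.k  # J/K

DEFAULT_TEMPERATURE = 298.15  # K
DEFAULT_SOLVENT_MOLARITY = 55.5  # mol/L, water
CONCENTRATION_CLAMP = 1e-4  # mol/L floor for chemical gradients

ANGSTROM = 1e-10  # m


def kT_joules(T: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in joules."""
    return K_BOLTZMANN * T


def kT_over_e_volts(T: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal voltage kT/e in volts (25.693 mV at 298.15 K)."""
    return K_BOLTZMANN * T / E_CHARGE
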