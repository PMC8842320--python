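"""Internal unit system and physical constants.

Energies in eV, lengths in nm, time in ps, charge in units of the elementary
charge e, temperature in K.  Masses are specified in a.m.u. at the interface
and converted to the consistent internal unit eV ps^2 nm^-2 (so that
F [eV/nm] = m [internal] * a [nm/ps^2] without further factors).
"""

import math

#: Boltzmann constant, eV/K
KB = 8.617333262e-5

#: Coulomb constant e^2/(4 pi eps0), eV nm / e^2
KC = 1.439964548

#: 1 a.m.u. expressed in eV ps^2 / nm^2
AMU = 1.036426965e-2

#: 1 eV/nm^3 expressed in MPa (pressure / stress conversion)
EV_NM3_TO_MPA = 160.2176634

#: 1 eV/nm^2 expressed in N/m (spring stiffness conversion)
EV_NM2_TO_N_M = 0.1602176634

#: 1 N/m expressed in eV/nm^2
N_M_TO_EV_NM2 = 1.0 / EV_NM2_TO_N_M

#: 1 m/s expressed in nm/ps
M_S_TO_NM_PS = 1.0e-3

DEG = math.pi / 180.0


def mass_internal(mass_amu):
    """Convert a mass in a.m.u. to internal units (eV ps^2/nm^2)."""
    return mass_amu * AMU


def stress_mpa(force_ev_nm, area_nm2):
    """Convert force/area (eV nm^-1 / nm^2) to MPa."""
    return force_ev_nm / area_nm2 * EV_NM3_TO_MPA


def thermal_energy_mev(temperature_k):
    """k_B T in meV (e.g. ~86 meV at 1000 K)."""
    return KB * temperature_k * 1.0e3
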