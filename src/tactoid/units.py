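"""Physical constants and the internal unit system.

Internal units used throughout the package:

==========  ==============================================
quantity    unit
==========  ==============================================
length      nm
energy      kBT at the configured temperature (298 K default)
time        ps
mass        kBT * ps^2 / nm^2 (derived)
charge      elementary charge e (signed valency)
==========  ==============================================

Energies are reported in kBT because the short-range repulsion strength is
normalised that way (beta * eps_TLJ = 1); the electrostatic coupling then
enters only through the Bjerrum length.
"""

from __future__ import annotations

from scipy import constants as _const

DEFAULT_TEMPERATURE = 298.0  # K
DEFAULT_DIELECTRIC = 78.3  # relative permittivity of water at ~298 K


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kB*T in joule."""
    return _const.k * temperature


def bjerrum_length(
    temperature: float = DEFAULT_TEMPERATURE,
    dielectric: float = DEFAULT_DIELECTRIC,
) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r kB T) in nm.

    At 298 K in water (eps_r = 78.3) this is ~0.716 nm: the distance at
    which two unit charges interact with exactly 1 kBT.
    """
    lb_m = _const.e**2 / (
        4.0 * _const.pi * _const.epsilon_0 * dielectric * thermal_energy(temperature)
    )
    return lb_m * 1e9


def mass_reduced(molar_mass_g_mol: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a molar mass to the internal mass unit kBT*ps^2/nm^2.

    With lengths in nm and times in ps, kinetic energy (1/2) m v^2 comes out
    directly in kBT when the mass carries this unit.
    """
    m_kg = molar_mass_g_mol * 1e-3 / _const.N_A
    return m_kg * (1e-9 / 1e-12) ** 2 / thermal_energy(temperature)


# Equal reduced mass for every species (equilibrium observables are
# mass-independent); corresponds to ~100 g/mol at 298 K.
DEFAULT_MASS = 40.0

FEMTOSECOND = 1e-3  # ps
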