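"""Physical constants and material properties.

All constants are SI. User-facing geometry is expressed in nm and converted
at module boundaries (see :mod:`poresim.geometry`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

#: Relative permittivities of the materials occurring in the pore models.
RELATIVE_PERMITTIVITY: Mapping[str, float] = MappingProxyType({
    "water": 80.2,
    "protein": 2.0,
    "dna": 12.0,
    "lipid": 2.0,
    "silicon_nitride": 7.0,
    "gold": 6.9,
    "sam": 2.7,
})

NM = 1e-9  # metres per nanometre


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of physical constants used across the solver stack.

    Attributes
    ----------
    k : Boltzmann constant (J/K).
    T : temperature (K).
    q : elementary charge (C).
    N_A : Avogadro constant (1/mol).
    eps0 : vacuum permittivity (C/(V m)).
    eta : dynamic viscosity of water (Pa s).
    eps_r : relative permittivity per material name.
    """

    k: float = 1.3806e-23
    T: float = 293.0
    q: float = 1.602e-19
    N_A: float = 6.022e23
    eps0: float = 8.854e-12
    eta: float = 1.0e-3
    eps_r: Mapping[str, float] = field(default_factory=lambda: RELATIVE_PERMITTIVITY)

    def __post_init__(self) -> None:
        for name in ("k", "T", "q", "N_A", "eps0", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name!r} must be strictly positive")

    @property
    def kT(self) -> float:
        """Thermal energy (J)."""
        return self.k * self.T

    @property
    def C_F(self) -> float:
        """Faraday constant (C/mol), equal to q * N_A by construction."""
        return self.q * self.N_A

    def permittivity(self, material: str) -> float:
        """Absolute permittivity eps0 * eps_r of a named material."""
        return self.eps0 * self.eps_r[material]


#: Default constant set (water at 293 K).
CONSTANTS = PhysicalConstants()

#: Hydrodynamic radius of K+ and Cl- used in all ion-hydrodynamics
#: calculations (nm); chosen so the Stokes-Einstein bulk diffusivity
#: matches measured values.
ION_RADIUS_NM = 0.11

#: Conversion of surface charge density: 1 q/nm^2 in C/m^2.
Q_PER_NM2 = CONSTANTS.q / NM**2
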