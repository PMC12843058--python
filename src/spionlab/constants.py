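"""Physical constants used throughout the package.

The default values of the Boltzmann constant and the vacuum permeability are
the rounded figures conventionally used in magnetic-fluid modelling
(kB = 1.38e-23 J/K, mu0 = 1.257e-6 H/m).  Full-precision CODATA values are
available through :meth:`PhysicalConstants.codata` for callers that prefer
them; every public function in the package accepts a ``constants`` argument
so the choice is never hard-wired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of physical constants, SI units.

    Attributes
    ----------
    boltzmann : float
        Boltzmann constant kB [J/K].
    vacuum_permeability : float
        Vacuum magnetic permeability mu0 [H/m].
    reduced_planck : float
        Reduced Planck constant hbar [J s].
    avogadro : float
        Avogadro number NA [1/mol].
    proton_gyromagnetic : float
        Proton gyromagnetic ratio gammaI [rad/(s T)].
    electron_gyromagnetic : float
        Electron gyromagnetic ratio gammaS [rad/(s T)].
    """

    boltzmann: float = 1.38e-23
    vacuum_permeability: float = 1.257e-6
    reduced_planck: float = 1.054571817e-34
    avogadro: float = 6.02214076e23
    proton_gyromagnetic: float = 2.6752218744e8
    electron_gyromagnetic: float = 1.76085963023e11

    @classmethod
    def codata(cls) -> "PhysicalConstants":
        """Return the bundle with full-precision CODATA kB and mu0."""
        return cls(
            boltzmann=1.380649e-23,
            vacuum_permeability=1.25663706212e-6,
        )

    def with_overrides(self, **kwargs: float) -> "PhysicalConstants":
        return replace(self, **kwargs)


#: Default constant set (rounded kB and mu0).
CONSTANTS = PhysicalConstants()
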