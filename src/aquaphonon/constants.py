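"""Physical constants.

Two presets are provided.  ``paper()`` uses the rounded light speed
c = 3.00e8 m/s, which is the value that reproduces the printed mode table
(e.g. 3509 cm^-1 -> 661.4 Trad/s) to the last decimal; ``codata()`` uses the
2018 CODATA exact value.  Planck and Boltzmann constants are the exact
SI-defining values in both presets.
"""

from __future__ import annotations

from dataclasses import dataclass

#: exact SI defining constants (2019 redefinition)
KB_SI = 1.380649e-23  # J/K
HBAR_SI = 1.054571817e-34  # J s
H_SI = 6.62607015e-34  # J s
C_CODATA = 2.99792458e8  # m/s
C_PAPER = 3.00e8  # m/s, rounded value consistent with the printed mode table
AMU = 1.66054e-27  # kg


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the constants the model depends on.

    Attributes
    ----------
    kB : Boltzmann constant (J/K).
    hbar : reduced Planck constant (J s).
    c : speed of light (m/s); selectable so the spectroscopic
        wavenumber -> angular frequency conversion can reproduce tabulated
        values that were computed with the rounded c = 3.00e8 m/s.
    u : atomic mass unit (kg).
    """

    kB: float = KB_SI
    hbar: float = HBAR_SI
    c: float = C_PAPER
    u: float = AMU

    def __post_init__(self) -> None:
        for name in ("kB", "hbar", "c", "u"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be positive")

    @property
    def h(self) -> float:
        """Planck constant (J s)."""
        return 2.0 * 3.141592653589793 * self.hbar

    @classmethod
    def paper(cls) -> "PhysicalConstants":
        """Constants with the rounded light speed c = 3.00e8 m/s."""
        return cls(c=C_PAPER)

    @classmethod
    def codata(cls) -> "PhysicalConstants":
        """Constants with the exact CODATA light speed."""
        return cls(c=C_CODATA)


#: mass of the lumped H2 element, atomic mass units
M1_H2_U = 2.016
#: mass of the O element, atomic mass units
M2_O_U = 15.999
#: nearest-neighbour O...O distance used as the unit-cell length (m)
CELL_LENGTH_M = 0.319e-9
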