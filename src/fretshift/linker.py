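"""Effective mechanical parameters of a fluorophore linker from C-C bond chemistry.

A dye is tethered to its host biomolecule by a short aliphatic chain.  Treating
the chain of N carbon-carbon bonds as N identical springs in series gives an
effective stiffness k/N, and the tetrahedral bond geometry sets the projected
length of each C-C-C link via the law of cosines.  These two numbers are the
chemistry-derived inputs to the translational dye models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LinkerSpec",
    "effective_spring_constant",
    "effective_link_length",
    "linker_contour_length",
]


@dataclass(frozen=True)
class LinkerSpec:
    """Chemical description of a dye linker.

    Parameters
    ----------
    n_links : int
        Number N >= 1 of C-C links in the chain.
    bond_length : float
        C-C bond length l in Angstrom (1.54 for an aliphatic bond).
    bond_angle : float
        C-C-C bond angle theta in degrees (109.5 for sp3 carbon).
    single_bond_spring : float
        Spring constant k of a single C-C bond.  Units are whatever the
        caller declares; everything downstream only uses ratios.
    """

    n_links: int = 15
    bond_length: float = 1.54
    bond_angle: float = 109.5
    single_bond_spring: float = 1010.0

    def __post_init__(self) -> None:
        if int(self.n_links) != self.n_links or self.n_links < 1:
            raise ValueError(f"n_links must be a positive integer, got {self.n_links}")
        if self.bond_length <= 0:
            raise ValueError(f"bond_length must be > 0, got {self.bond_length}")
        if not 0 < self.bond_angle <= 180:
            raise ValueError(
                f"bond_angle must be in (0, 180] degrees, got {self.bond_angle}"
            )
        if self.single_bond_spring <= 0:
            raise ValueError(
                f"single_bond_spring must be > 0, got {self.single_bond_spring}"
            )


def effective_spring_constant(spec: LinkerSpec) -> float:
    """Series-spring stiffness of the whole linker: k_eff = k / N."""
    return spec.single_bond_spring / spec.n_links


def effective_link_length(spec: LinkerSpec) -> float:
    """Projected length L of one C-C link.

    For a C-C-C unit with bond length l and bond angle theta the end-to-end
    span of the unit is 2L = sqrt(2 l^2 - 2 l^2 cos(theta)), i.e.
    L = (l/2) sqrt(2 - 2 cos(theta)).  L = l at theta = 180 deg (straight
    chain) and decreases with the bond angle.
    """
    theta = math.radians(spec.bond_angle)
    return 0.5 * spec.bond_length * math.sqrt(2.0 - 2.0 * math.cos(theta))


def linker_contour_length(spec: LinkerSpec) -> float:
    """Total projected reach of the chain, N * L.

    Used to set the equilibrium arm length / accessible-volume scale of the
    translational dye models.
    """
    return spec.n_links * effective_link_length(spec)
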