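"""Molecular formulas and exact/nominal mass arithmetic for 3-hydroxy fatty
acid (HFA) chains and their HAA ester condensates.

An HAA -- 3-(3-hydroxyalkanoyloxy)alkanoic acid -- is two 3-hydroxy fatty
acids joined by an ester bond.  A saturated 3-hydroxy acid with ``n``
carbons has composition :math:`C_nH_{2n}O_3`; each double bond removes two
hydrogens; ester condensation of two chains loses one water.  Everything
observable in the negative-mode spectra (the [M-H]- precursor and the two
ester-cleavage chain fragments) follows from these three rules plus the
pinned atomic-mass table in :mod:`haams.masses`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .masses import (
    MONOISOTOPIC,
    NOMINAL,
    PROTON_MASS,
    SUPPORTED_ELEMENTS,
    round_half_up,
    round_mz,
)

__all__ = [
    "MolecularFormula",
    "ChainSpec",
    "WATER",
    "hfa_formula",
    "haa_formula",
    "fatty_acid_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "mz_deprotonated",
    "ppm_deviation",
    "signed_ppm",
]

# Hill order for CHO(Si) compounds: carbon, hydrogen, then the rest
# alphabetically.
_HILL_ORDER = ("C", "H", "O", "Si")


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> count map over the supported elements C, H, O, Si.

    Instances are immutable; addition and subtraction are element-wise, and
    subtraction raises if any count would go negative (you cannot remove a
    water from a molecule that has none).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {el!r}; supported: C, H, O, Si")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n > 0:
                clean[el] = n
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", MappingProxyType(clean))

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-notation string such as ``"C27H50O5"``."""
        import re

        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise ValueError(
                    f"subtraction would leave {left} atoms of {el} in {self}"
                )
            merged[el] = left
        return MolecularFormula(merged)

    def __str__(self) -> str:
        parts = []
        for el in _HILL_ORDER:
            n = self.counts.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


#: One water molecule, lost on ester condensation.
WATER = MolecularFormula({"H": 2, "O": 1})


@dataclass(frozen=True, order=True)
class ChainSpec:
    """A single 3-hydroxy fatty acid chain, written Cn:d in the field.

    ``carbons`` is the chain length n, ``unsaturations`` the number of
    double bonds d.  The hydroxyl sits at carbon 3 (the beta position) in
    every HAA chain; the position is carried explicitly only because the
    GC-EI diagnostic fragment depends on it.
    """

    carbons: int
    unsaturations: int = 0
    hydroxyl_position: int = field(default=3, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 4:
            raise ValueError(f"chain needs >= 4 carbons, got {self.carbons}")
        max_unsat = (self.carbons - 2) // 2
        if not 0 <= self.unsaturations <= max_unsat:
            raise ValueError(
                f"unsaturations for a C{self.carbons} chain must be in "
                f"[0, {max_unsat}], got {self.unsaturations}"
            )
        if self.hydroxyl_position < 2:
            raise ValueError("hydroxyl position must be >= 2")

    @property
    def label(self) -> str:
        """Field notation: ``C10`` for saturated, ``C14:1`` with a double bond."""
        if self.unsaturations:
            return f"C{self.carbons}:{self.unsaturations}"
        return f"C{self.carbons}"

    def __str__(self) -> str:
        return self.label


def hfa_formula(chain: ChainSpec) -> MolecularFormula:
    """Neutral formula of the free 3-hydroxy fatty acid: C_n H_{2n-2d} O_3."""
    return MolecularFormula(
        {"C": chain.carbons, "H": 2 * chain.carbons - 2 * chain.unsaturations, "O": 3}
    )


def haa_formula(a: ChainSpec, b: ChainSpec) -> MolecularFormula:
    """Neutral formula of the HAA ester condensate of two chains.

    Symmetric in its arguments: the ester is formed with loss of one water,
    so the formula is hfa(a) + hfa(b) - H2O regardless of which chain bears
    the free carboxylic acid.
    """
    return hfa_formula(a) + hfa_formula(b) - WATER


def fatty_acid_formula(carbons: int, unsaturations: int = 0) -> MolecularFormula:
    """Neutral formula of a plain (non-hydroxy) fatty acid: C_n H_{2n-2d} O_2.

    Free fatty acids co-elute with HAAs and are the main interference at
    the precursor level.
    """
    if carbons < 2:
        raise ValueError("fatty acid needs >= 2 carbons")
    return MolecularFormula({"C": carbons, "H": 2 * carbons - 2 * unsaturations, "O": 2})


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in Da from the pinned atomic-mass table."""
    return sum(n * MONOISOTOPIC[el] for el, n in f.counts.items())


def nominal_mass(f: MolecularFormula) -> int:
    """Integer (unit-resolution) mass from integer mass numbers."""
    return sum(n * NOMINAL[el] for el, n in f.counts.items())


def mz_deprotonated(f: MolecularFormula, *, nominal: bool = False) -> float:
    """m/z of the deprotonated anion [M-H]- of a neutral formula.

    High-resolution mode (default) subtracts the proton mass from the
    monoisotopic mass and keeps full precision; use
    :func:`haams.masses.round_mz` for four-decimal display.  With
    ``nominal=True`` the unit-resolution value (integer mass minus 1) is
    returned instead.
    """
    if f["H"] < 1:
        raise ValueError(f"{f} has no hydrogen to lose")
    if nominal:
        return float(nominal_mass(f) - 1)
    return monoisotopic_mass(f) - PROTON_MASS


def signed_ppm(measured: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million, full precision."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (measured - theoretical) / theoretical * 1e6


def ppm_deviation(measured: float, theoretical: float) -> float:
    """Absolute ppm deviation, rounded half-up to one decimal for reporting.

    The sign of the deviation is available via :func:`signed_ppm`; the
    reporting convention (<5 ppm acceptance, one decimal) uses magnitudes.
    """
    return round_half_up(abs(signed_ppm(measured, theoretical)), 1)
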