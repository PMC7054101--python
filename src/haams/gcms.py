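"""GC-EI-MS chain confirmation of hydrolyzed, derivatized hydroxy acids.

Hydrolysis of an HAA releases its two 3-hydroxy fatty acids, which are
methylated (FAME) and trimethylsilylated on the hydroxyl before GC.  Under
electron ionization two ions carry the assignment: the [M-15]+ ion (loss of
a methyl radical) fixes chain length, and the TMS-oxycarbenium fragment
spanning the carboxymethyl end through the OTMS carbon fixes the hydroxyl
position -- m/z 175 for the 3-position common to all HAA chains.  Matching
is done at unit resolution, as on quadrupole scan data.  The double-bond
position is never assigned; EI spectra of these derivatives do not resolve
it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formula import ChainSpec, MolecularFormula, hfa_formula, nominal_mass
from .masses import METHYL_RADICAL_NOMINAL
from .msms import Peak

__all__ = [
    "EiEvidence",
    "derivatized_formula",
    "m_minus_15",
    "position_diagnostic_mz",
    "assign_chain_from_ei",
]

_METHYLENE = MolecularFormula({"C": 1, "H": 2})   # methyl ester adds CH2
_TMS = MolecularFormula({"C": 3, "H": 8, "Si": 1})  # Si(CH3)3 replacing the O-H


def derivatized_formula(c: ChainSpec) -> MolecularFormula:
    """Formula of the methyl ester + TMS ether of a hydroxy fatty acid.

    Methylation adds CH2 to the carboxyl; trimethylsilylation replaces the
    hydroxyl hydrogen with Si(CH3)3, a net gain of C3H8Si.
    """
    return hfa_formula(c) + _METHYLENE + _TMS


def m_minus_15(c: ChainSpec) -> int:
    """Nominal m/z of the chain-length-diagnostic [M-15]+ ion."""
    return nominal_mass(derivatized_formula(c)) - METHYL_RADICAL_NOMINAL


def position_diagnostic_mz(hydroxyl_position: int) -> int:
    """Nominal m/z of the fragment that localizes the hydroxy group.

    The TMS-oxycarbenium fragment spans the carboxymethyl carbon through
    the OTMS-bearing carbon: composition C_{p+4}H_{2p+9}O3Si for hydroxyl
    position p, hence m/z 175 for the 3-position.
    """
    if hydroxyl_position < 2:
        raise ValueError("hydroxyl position must be >= 2")
    p = hydroxyl_position
    return nominal_mass(MolecularFormula({"C": p + 4, "H": 2 * p + 9, "O": 3, "Si": 1}))


@dataclass(frozen=True)
class EiEvidence:
    """Peak evidence for one chain assignment from an EI spectrum."""

    chain: ChainSpec
    m15_mz: int
    m15_peak: Peak
    diagnostic_mz: int
    diagnostic_peak: Peak | None  # None: hydroxyl position unconfirmed

    @property
    def position_confirmed(self) -> bool:
        return self.diagnostic_peak is not None


def assign_chain_from_ei(
    peaks: list[Peak],
    window_da: float = 0.3,
    *,
    min_chain: int = 4,
    max_chain: int = 18,
    max_unsaturations: int = 1,
    hydroxyl_position: int = 3,
) -> list[EiEvidence]:
    """Assign chain length (and confirm hydroxyl position) from EI peaks.

    A chain is reported when its [M-15]+ ion matches a peak within
    ``window_da``; the assignment is position-confirmed when the
    position diagnostic (m/z 175 for 3-OH) is also present.  A spectrum
    containing only the diagnostic is unassignable (empty list): the
    diagnostic is common to every 3-hydroxy chain and carries no length
    information.
    """
    if not peaks:
        raise ValueError("peak list is empty")

    def nearest(target: float) -> Peak | None:
        best = min(peaks, key=lambda p: (abs(p.mz - target), p.mz))
        return best if abs(best.mz - target) <= window_da else None

    diag = position_diagnostic_mz(hydroxyl_position)
    diag_peak = nearest(diag)

    out: list[EiEvidence] = []
    for n in range(min_chain, max_chain + 1):
        for d in range(0, min(max_unsaturations, (n - 2) // 2) + 1):
            chain = ChainSpec(n, d, hydroxyl_position=hydroxyl_position)
            target = m_minus_15(chain)
            peak = nearest(target)
            if peak is None:
                continue
            # one peak cannot evidence both chain length and hydroxyl
            # position: the C4 [M-15]+ coincides with the 3-OH diagnostic
            # at m/z 175, so that assignment is suppressed rather than
            # double-counted
            if diag_peak is not None and peak == diag_peak:
                continue
            out.append(EiEvidence(chain, target, peak, diag, diag_peak))
    return out
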