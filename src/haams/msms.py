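"""ESI(-) MS/MS annotation: from a precursor and its ester-cleavage
fragments to ranked congener assignments.

Collision-induced dissociation of a deprotonated HAA is dominated by
cleavage of the ester bond, releasing each constituent 3-hydroxy fatty
acid as its deprotonated free acid.  Observing both chain fragments pins
the chain pair (up to positional exchange); the precursor alone only pins
the total composition N:D.  The annotator makes that evidence hierarchy
explicit: ``both_chains`` > ``one_chain`` > ``precursor_only``.
"""

from __future__ import annotations

import enum
from bisect import bisect_left
from dataclasses import dataclass, field
from functools import lru_cache

from .congeners import (
    CandidateMatch,
    CongenerSpec,
    DEFAULT_CONSTRAINTS,
    EnumerationConstraints,
    enumerate_congeners,
)
from .formula import (
    ChainSpec,
    MolecularFormula,
    fatty_acid_formula,
    hfa_formula,
    mz_deprotonated,
    signed_ppm,
)

__all__ = [
    "Peak",
    "Spectrum",
    "EvidenceLevel",
    "FragmentMatch",
    "AnnotationMatch",
    "predict_fragments",
    "match_fragments",
    "annotate_spectrum",
    "flag_fatty_acid_interference",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """One negative-mode product-ion spectrum: a precursor and its fragments."""

    precursor_mz: float
    peaks: tuple[Peak, ...] = ()
    identifier: str | None = None
    retention_time: float | None = None
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.polarity != "negative":
            raise ValueError("only negative-mode spectra are supported")
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )


class EvidenceLevel(enum.IntEnum):
    """Ordered annotation evidence; higher is stronger."""

    precursor_only = 0
    one_chain = 1
    both_chains = 2


@dataclass(frozen=True)
class FragmentMatch:
    """A predicted chain fragment matched to an observed peak."""

    chain: ChainSpec
    theoretical_mz: float
    peak: Peak
    ppm_error: float  # signed; in unit-resolution mode this is a Da error


@dataclass(frozen=True)
class AnnotationMatch:
    congener: CongenerSpec
    precursor_ppm: float  # signed, full precision
    theoretical_mz: float
    fragment_evidence: tuple[FragmentMatch, ...]
    evidence_level: EvidenceLevel
    #: both chain orders (positional variants) are implied by this evidence
    positional_note: bool = True
    ambiguous: bool = False
    warnings: tuple[str, ...] = ()

    @property
    def abs_ppm(self) -> float:
        return abs(self.precursor_ppm)


@lru_cache(maxsize=None)
def _chain_fragment_mz(chain: ChainSpec, nominal: bool) -> float:
    return mz_deprotonated(hfa_formula(chain), nominal=nominal)


def predict_fragments(c: CongenerSpec, *, nominal: bool = False) -> dict[ChainSpec, float]:
    """Deprotonated m/z of each chain's free hydroxy acid.

    Returns one entry per distinct chain: identical chains predict a single
    fragment mass (the spectrum cannot tell the two ester positions apart).
    """
    return {
        chain: _chain_fragment_mz(chain, nominal) for chain in dict.fromkeys(c.chains)
    }


def _nearest_peak(peaks: tuple[Peak, ...], mz: float) -> Peak | None:
    """Nearest peak by m/z; ties broken toward lower m/z."""
    if not peaks:
        return None
    i = bisect_left([p.mz for p in peaks], mz)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(peaks):
            p = peaks[j]
            if best is None or abs(p.mz - mz) < abs(best.mz - mz) or (
                abs(p.mz - mz) == abs(best.mz - mz) and p.mz < best.mz
            ):
                best = p
    return best


def _within(observed: float, theoretical: float, k: EnumerationConstraints) -> bool:
    if k.unit_resolution:
        return abs(observed - theoretical) <= k.tolerance_da
    return abs(signed_ppm(observed, theoretical)) <= k.tolerance_ppm


def match_fragments(
    s: Spectrum,
    candidates: list[CandidateMatch],
    k: EnumerationConstraints = DEFAULT_CONSTRAINTS,
) -> list[AnnotationMatch]:
    """Match each candidate's predicted chain fragments against the peaks.

    Each predicted fragment is assigned to the nearest peak within
    tolerance (at most one peak per fragment).  Evidence is ``both_chains``
    when every chain of the pair has a matched fragment, ``one_chain`` when
    exactly one does, else ``precursor_only``.
    """
    out: list[AnnotationMatch] = []
    for cand in candidates:
        predicted = predict_fragments(cand.congener, nominal=k.unit_resolution)
        matches: list[FragmentMatch] = []
        matched_chains: set[ChainSpec] = set()
        for chain, theo in predicted.items():
            peak = _nearest_peak(s.peaks, theo)
            if peak is not None and _within(peak.mz, theo, k):
                err = (
                    peak.mz - theo
                    if k.unit_resolution
                    else signed_ppm(peak.mz, theo)
                )
                matches.append(FragmentMatch(chain, theo, peak, err))
                matched_chains.add(chain)
        n_evidenced = sum(1 for ch in cand.congener.chains if ch in matched_chains)
        level = (
            EvidenceLevel.both_chains
            if n_evidenced == 2
            else EvidenceLevel.one_chain
            if n_evidenced == 1
            else EvidenceLevel.precursor_only
        )
        out.append(
            AnnotationMatch(
                congener=cand.congener,
                precursor_ppm=cand.ppm_error,
                theoretical_mz=cand.theoretical_mz,
                fragment_evidence=tuple(matches),
                evidence_level=level,
            )
        )
    return out


def annotate_spectrum(
    s: Spectrum,
    k: EnumerationConstraints = DEFAULT_CONSTRAINTS,
    *,
    evidence_floor: EvidenceLevel = EvidenceLevel.both_chains,
    check_interference: bool = True,
) -> list[AnnotationMatch]:
    """End-to-end annotation of one product-ion spectrum.

    Enumerates congener candidates from the precursor, matches their
    predicted ester-cleavage fragments, and returns annotations sorted by
    evidence level (descending) then absolute precursor ppm error.
    Annotations below ``evidence_floor`` are retained but flagged
    ``ambiguous``; free-fatty-acid precursor interferences attach a
    warning.  No candidate within tolerance gives an empty list.
    """
    candidates = enumerate_congeners(s.precursor_mz, k)
    annotations = match_fragments(s, candidates, k)

    warnings: tuple[str, ...] = ()
    if check_interference:
        ffas = flag_fatty_acid_interference(s.precursor_mz, k)
        if ffas:
            names = ", ".join(str(f) for f in ffas)
            warnings = (
                f"precursor is isobaric with free fatty acid(s) {names}; "
                "false annotation cannot be ruled out",
            )

    annotated = [
        AnnotationMatch(
            congener=a.congener,
            precursor_ppm=a.precursor_ppm,
            theoretical_mz=a.theoretical_mz,
            fragment_evidence=a.fragment_evidence,
            evidence_level=a.evidence_level,
            ambiguous=a.evidence_level < evidence_floor,
            warnings=warnings,
        )
        for a in annotations
    ]
    annotated.sort(
        key=lambda a: (-int(a.evidence_level), a.abs_ppm, a.congener.name)
    )
    return annotated


def flag_fatty_acid_interference(
    precursor_mz: float,
    k: EnumerationConstraints = DEFAULT_CONSTRAINTS,
    *,
    max_carbons: int = 30,
    max_unsaturations: int = 3,
) -> list[MolecularFormula]:
    """Plain fatty acid compositions isobaric with the precursor.

    Free fatty acids (C_nH_{2n-2d}O_2) elute like HAAs on reversed-phase
    columns; an [M-H]- within tolerance of the precursor means a
    fatty-acid peak could masquerade as an HAA.  Returns every such
    composition for n up to ``max_carbons``.
    """
    if precursor_mz <= 0:
        raise ValueError("precursor m/z must be positive")
    hits: list[MolecularFormula] = []
    for n in range(2, max_carbons + 1):
        for d in range(0, min(max_unsaturations, (n - 1) // 2) + 1):
            f = fatty_acid_formula(n, d)
            theo = mz_deprotonated(f, nominal=k.unit_resolution)
            if _within(precursor_mz, theo, k):
                hits.append(f)
    return hits
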