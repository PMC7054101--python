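"""Congener representation, naming and combinatorial enumeration.

A congener is an unordered pair of 3-hydroxy fatty acid chains, written
``Cn[:d]-Cm[:e]``.  The two positional variants (which chain carries the
free carboxylic acid) are indistinguishable in the ester-cleavage spectra
and are represented by a single canonical :class:`CongenerSpec`, shorter
chain first.  Given a measured precursor m/z, :func:`enumerate_congeners`
lists every congener in a bounded chain space whose deprotonated mass fits
within tolerance -- the combinatorial step behind accurate-mass HAA
identification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

from .formula import (
    ChainSpec,
    MolecularFormula,
    haa_formula,
    mz_deprotonated,
    signed_ppm,
)

__all__ = [
    "CongenerSpec",
    "EnumerationConstraints",
    "CandidateMatch",
    "canonical_name",
    "parse_name",
    "chain_splits",
    "enumerate_congeners",
]


@dataclass(frozen=True, order=True)
class CongenerSpec:
    """An unordered chain pair in canonical order.

    Canonical order is shorter chain first; for equal lengths, fewer
    unsaturations first.  ``total_carbons``:``total_unsaturations`` gives
    the N:D shorthand (e.g. "27:1") used at unit resolution, where chain
    splits with the same totals are isobaric.
    """

    chain_a: ChainSpec
    chain_b: ChainSpec

    def __post_init__(self) -> None:
        a, b = sorted(
            (self.chain_a, self.chain_b),
            key=lambda c: (c.carbons, c.unsaturations),
        )
        object.__setattr__(self, "chain_a", a)
        object.__setattr__(self, "chain_b", b)

    @property
    def chains(self) -> tuple[ChainSpec, ChainSpec]:
        return (self.chain_a, self.chain_b)

    @property
    def total_carbons(self) -> int:
        return self.chain_a.carbons + self.chain_b.carbons

    @property
    def total_unsaturations(self) -> int:
        return self.chain_a.unsaturations + self.chain_b.unsaturations

    @property
    def identity(self) -> str:
        """The N:D total-composition shorthand, e.g. ``"27:1"``."""
        return f"{self.total_carbons}:{self.total_unsaturations}"

    @property
    def name(self) -> str:
        return canonical_name(self)

    def formula(self) -> MolecularFormula:
        return haa_formula(self.chain_a, self.chain_b)

    def __str__(self) -> str:
        return self.name


def canonical_name(c: CongenerSpec) -> str:
    """Render the canonical ``Cn-Cm:e`` name (``:d`` only when d > 0)."""
    return f"{c.chain_a.label}-{c.chain_b.label}"


_NAME_RE = re.compile(r"^C(\d+)(?::(\d+))?-C(\d+)(?::(\d+))?$")


def parse_name(s: str) -> CongenerSpec:
    """Parse a ``Cn[:d]-Cm[:e]`` congener name, canonicalizing chain order.

    Raises ``ValueError`` with the failing position for malformed strings
    and propagates chain-validity errors (e.g. an impossible unsaturation
    count).
    """
    m = _NAME_RE.match(s.strip())
    if m is None:
        # report the first character where the grammar breaks
        probe = re.match(r"C\d+(?::\d+)?-?", s.strip())
        pos = probe.end() if probe else 0
        raise ValueError(f"cannot parse congener name {s!r} at position {pos}")
    n1, d1, n2, d2 = (int(g) if g else 0 for g in m.groups())
    return CongenerSpec(ChainSpec(n1, d1), ChainSpec(n2, d2))


@dataclass(frozen=True)
class EnumerationConstraints:
    """Bounds on the chain space searched and the mass-matching tolerance.

    Defaults span the observed congener range (chains C4 through C18:1,
    at most one double bond per chain and two per molecule) with the 5 ppm
    accuracy criterion of high-resolution assignments.  Setting
    ``tolerance_da`` switches to unit-resolution (nominal-mass) matching
    for triple-quadrupole or ion-trap data; exactly one tolerance mode is
    active per query.
    """

    min_chain: int = 4
    max_chain: int = 18
    max_unsat_per_chain: int = 1
    max_total_unsat: int = 2
    tolerance_ppm: float = 5.0
    tolerance_da: float | None = None

    def __post_init__(self) -> None:
        if self.min_chain > self.max_chain:
            raise ValueError("min_chain must not exceed max_chain")
        if self.min_chain < 4:
            raise ValueError("min_chain must be >= 4")
        if self.tolerance_ppm < 0:
            raise ValueError("tolerance_ppm must be >= 0")
        if self.tolerance_da is not None and self.tolerance_da <= 0:
            raise ValueError("tolerance_da must be positive")

    @property
    def unit_resolution(self) -> bool:
        return self.tolerance_da is not None

    def iter_chains(self):
        for n in range(self.min_chain, self.max_chain + 1):
            for d in range(0, min(self.max_unsat_per_chain, (n - 2) // 2) + 1):
                yield ChainSpec(n, d)


DEFAULT_CONSTRAINTS = EnumerationConstraints()


@dataclass(frozen=True)
class CandidateMatch:
    """A congener compatible with a measured precursor mass."""

    congener: CongenerSpec
    theoretical_mz: float
    ppm_error: float  # signed, full precision

    @property
    def abs_ppm(self) -> float:
        return abs(self.ppm_error)


def chain_splits(
    total_carbons: int,
    total_unsaturations: int,
    k: EnumerationConstraints = DEFAULT_CONSTRAINTS,
) -> list[CongenerSpec]:
    """All chain pairs with the given carbon and double-bond totals.

    This resolves a total composition N:D -- all that a precursor mass can
    determine -- into the candidate chain pairs the ester-cleavage
    fragments then discriminate.  Returns the empty list when infeasible.
    """
    if total_unsaturations > k.max_total_unsat:
        return []
    out: set[CongenerSpec] = set()
    for n1 in range(k.min_chain, total_carbons // 2 + 1):
        n2 = total_carbons - n1
        if n2 < n1 or n2 > k.max_chain:
            continue
        for d1 in range(0, k.max_unsat_per_chain + 1):
            d2 = total_unsaturations - d1
            if not 0 <= d2 <= k.max_unsat_per_chain:
                continue
            try:
                out.add(CongenerSpec(ChainSpec(n1, d1), ChainSpec(n2, d2)))
            except ValueError:
                continue  # chain too short for that many double bonds
    return sorted(out)


@lru_cache(maxsize=8)
def _candidate_table(k: EnumerationConstraints) -> tuple[tuple[CongenerSpec, float, float], ...]:
    """Every congener in the constraint space with both theoretical masses.

    Cached per constraint set: the chain space is small (hundreds of
    congeners) and reused across every spectrum of a run.
    """
    chains = list(k.iter_chains())
    seen: set[CongenerSpec] = set()
    rows = []
    for i, a in enumerate(chains):
        for b in chains[i:]:
            if a.unsaturations + b.unsaturations > k.max_total_unsat:
                continue
            cong = CongenerSpec(a, b)
            if cong in seen:
                continue
            seen.add(cong)
            f = cong.formula()
            rows.append((cong, mz_deprotonated(f), mz_deprotonated(f, nominal=True)))
    return tuple(rows)


def enumerate_congeners(
    precursor_mz: float,
    k: EnumerationConstraints = DEFAULT_CONSTRAINTS,
) -> list[CandidateMatch]:
    """All congeners in the constraint space whose [M-H]- fits the precursor.

    High-resolution mode compares monoisotopic deprotonated masses within
    ``tolerance_ppm``; unit-resolution mode compares nominal masses within
    ``tolerance_da``.  Results are sorted by absolute ppm error, then
    canonical name, and carry their theoretical m/z.
    """
    if precursor_mz <= 0:
        raise ValueError("precursor m/z must be positive")
    out: list[CandidateMatch] = []
    for cong, theo_mono, theo_nom in _candidate_table(k):
        if k.unit_resolution:
            if abs(precursor_mz - theo_nom) > k.tolerance_da:
                continue
            out.append(CandidateMatch(cong, theo_nom, signed_ppm(precursor_mz, theo_nom)))
        else:
            ppm = signed_ppm(precursor_mz, theo_mono)
            if abs(ppm) <= k.tolerance_ppm:
                out.append(CandidateMatch(cong, theo_mono, ppm))
    out.sort(key=lambda m: (m.abs_ppm, m.congener.name))
    return out
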