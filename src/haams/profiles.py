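"""Congener-profile bookkeeping and summary statistics.

A congener profile is the relative-abundance table one strain (or one
heterologously expressed acyltransferase) produces: congener -> fraction in
percent.  From it the module derives the statistics used to characterize
chain-length specificity: the abundance-weighted average chain length
(ACL), the set of main congeners, the share of odd-chain material, and a
novelty breakdown of congeners not in a reference list of previously
reported species.

The packaged reference dataset is the seven-plasmid congener table
(columns pPA2, pFLU, pDAD, pANA, pHAL, pAMB, pBUG) of HAAs produced in
E. coli C43(DE3); rows flagged ``new`` were first observed in that
experiment, the rest form the previously-reported reference list.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .congeners import CongenerSpec, parse_name
from .formula import ChainSpec, mz_deprotonated
from .masses import round_half_up

__all__ = [
    "CongenerProfile",
    "ReferenceCongenerList",
    "NoveltyCategory",
    "NoveltyAssessment",
    "FIXTURE_COLUMNS",
    "load_reference_table",
    "fixture_profile",
    "reference_congener_list",
    "normalize_profile",
    "average_chain_length",
    "main_congeners",
    "categorize_novelty",
    "odd_chain_share",
    "profile_report",
]

logger = logging.getLogger(__name__)

FIXTURE_COLUMNS = ("pPA2", "pFLU", "pDAD", "pANA", "pHAL", "pAMB", "pBUG")

#: Observed per-column rounding slack: printed fractions are given to one
#: decimal, so column totals land near but not exactly on 100.
SUM_SLACK = 2.0


@dataclass(frozen=True)
class CongenerProfile:
    """Congener -> fraction (%) for one strain/plasmid."""

    label: str
    entries: Mapping[CongenerSpec, float]
    provenance: str = "measured"  # measured | synthetic | fixture

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("profile must contain at least one congener")
        for c, f in self.entries.items():
            if f < 0:
                raise ValueError(f"negative fraction {f} for {c}")
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def total(self) -> float:
        return sum(self.entries.values())

    def items(self):
        return self.entries.items()


class NoveltyCategory(enum.Enum):
    """Why a congener counts as new relative to a reference list."""

    length_gap_ge4 = "length_gap_ge4"     # chains differ by >= 4 carbons
    new_unsaturation = "new_unsaturation"  # an unsaturated chain not in the reference
    odd_chain = "odd_chain"               # at least one odd chain length


@dataclass(frozen=True)
class NoveltyAssessment:
    known: bool
    categories: frozenset[NoveltyCategory] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ReferenceCongenerList:
    """Previously reported congeners, for novelty categorization."""

    congeners: frozenset[CongenerSpec]

    def __post_init__(self) -> None:
        if not self.congeners:
            raise ValueError("reference list must be non-empty")

    @property
    def chains(self) -> frozenset[ChainSpec]:
        """Every exact chain (n, d) occurring in a reference congener."""
        return frozenset(ch for c in self.congeners for ch in c.chains)

    def __contains__(self, c: CongenerSpec) -> bool:
        return c in self.congeners


def load_reference_table() -> pd.DataFrame:
    """The packaged seven-plasmid congener table, indexed by congener name."""
    with resources.files("haams.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh, index_col="congener")
    return df


def fixture_profile(column: str) -> CongenerProfile:
    """One plasmid column of the packaged table as a profile.

    Fractions are kept exactly as tabulated (they are already percent
    shares; totals differ from 100 by the per-entry rounding).
    """
    df = load_reference_table()
    if column not in FIXTURE_COLUMNS:
        raise KeyError(
            f"unknown fixture column {column!r}; available: {', '.join(FIXTURE_COLUMNS)}"
        )
    col = df[column].dropna()
    entries = {parse_name(name): float(v) for name, v in col.items() if v > 0}
    return CongenerProfile(label=column, entries=entries, provenance="fixture")


def reference_congener_list() -> ReferenceCongenerList:
    """Previously reported congeners = packaged table rows not flagged new."""
    df = load_reference_table()
    known = df.index[df["new"] == 0]
    return ReferenceCongenerList(frozenset(parse_name(n) for n in known))


def normalize_profile(
    raw: Mapping[CongenerSpec, float],
    label: str = "profile",
    *,
    reporting_floor: float = 0.05,
    provenance: str = "measured",
) -> CongenerProfile:
    """Scale raw abundances to percent shares, dropping trace entries.

    Entries below ``reporting_floor`` percent after scaling are dropped
    with a log note, mirroring how trace congeners fall below a reporting
    threshold.  All-zero input is an error.
    """
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    scaled = {c: 100.0 * v / total for c, v in raw.items() if v > 0}
    kept = {c: f for c, f in scaled.items() if f >= reporting_floor}
    dropped = sorted(set(scaled) - set(kept), key=lambda c: c.name)
    if dropped:
        logger.info(
            "%s: dropped %d entr%s below reporting floor %.3g%%: %s",
            label,
            len(dropped),
            "y" if len(dropped) == 1 else "ies",
            reporting_floor,
            ", ".join(c.name for c in dropped),
        )
    if not kept:
        raise ValueError("every entry fell below the reporting floor")
    return CongenerProfile(label=label, entries=kept, provenance=provenance)


def average_chain_length(p: CongenerProfile) -> float:
    """Abundance-weighted mean of the per-molecule mean chain length.

    Each congener contributes (n + m) / 2 weighted by its fraction;
    reported rounded half-up to one decimal, the precision of the
    tabulated values.
    """
    weights = sum(p.entries.values())
    if weights <= 0:
        raise ValueError("profile has zero total abundance")
    acc = sum(f * (c.total_carbons / 2.0) for c, f in p.entries.items())
    return round_half_up(acc / weights, 1)


def main_congeners(p: CongenerProfile, threshold: float = 10.0) -> set[CongenerSpec]:
    """Congeners at or above ``threshold`` percent of the profile."""
    return {c for c, f in p.entries.items() if f >= threshold}


def categorize_novelty(
    c: CongenerSpec, ref: ReferenceCongenerList
) -> NoveltyAssessment:
    """Classify a congener as known or assign its novelty categories.

    A congener absent from the reference list is novel for every rule that
    applies: a chain-length gap of four or more carbons, an unsaturated
    chain (n, d >= 1) never seen in the reference (compared per exact
    chain, not per length), or any odd chain length.
    """
    if c in ref:
        return NoveltyAssessment(known=True)
    cats: set[NoveltyCategory] = set()
    a, b = c.chains
    if abs(a.carbons - b.carbons) >= 4:
        cats.add(NoveltyCategory.length_gap_ge4)
    ref_chains = ref.chains
    if any(ch.unsaturations >= 1 and ch not in ref_chains for ch in c.chains):
        cats.add(NoveltyCategory.new_unsaturation)
    if any(ch.carbons % 2 == 1 for ch in c.chains):
        cats.add(NoveltyCategory.odd_chain)
    return NoveltyAssessment(known=False, categories=frozenset(cats))


def odd_chain_share(
    p: CongenerProfile,
    *,
    novel_only: bool = False,
    ref: ReferenceCongenerList | None = None,
) -> float:
    """Summed fraction (%) of congeners containing an odd-length chain.

    With ``novel_only`` the sum is restricted to congeners absent from
    ``ref`` (required in that case).
    """
    if novel_only and ref is None:
        raise ValueError("novel_only requires a reference list")
    total = 0.0
    for c, f in p.entries.items():
        if not any(ch.carbons % 2 == 1 for ch in c.chains):
            continue
        if novel_only and c in ref:  # type: ignore[operator]
            continue
        total += f
    return round_half_up(total, 1)


def profile_report(
    p: CongenerProfile,
    ref: ReferenceCongenerList | None = None,
    *,
    main_threshold: float = 10.0,
) -> pd.DataFrame:
    """Per-congener report table, most abundant first.

    Columns: congener name, N:D identity, nominal [M-H]- m/z, fraction,
    main-congener flag, known/novelty categories.  The frame's ``attrs``
    carry the profile-level statistics (label, ACL, odd-chain share).
    Serialization is deterministic: fixed column order, stable sort by
    (fraction descending, name).
    """
    if ref is None:
        ref = reference_congener_list()
    rows = []
    mains = main_congeners(p, main_threshold)
    for c, f in p.entries.items():
        assessment = categorize_novelty(c, ref)
        rows.append(
            {
                "congener": c.name,
                "identity": c.identity,
                "mz_nominal": int(mz_deprotonated(c.formula(), nominal=True)),
                "fraction_percent": f,
                "main_congener": c in mains,
                "known": assessment.known,
                "novelty_categories": ";".join(
                    sorted(cat.value for cat in assessment.categories)
                ),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["fraction_percent", "congener"], ascending=[False, True], kind="mergesort"
    )
    df = df.reset_index(drop=True)
    df.attrs["label"] = p.label
    df.attrs["average_chain_length"] = average_chain_length(p)
    df.attrs["odd_chain_share"] = odd_chain_share(p)
    df.attrs["odd_chain_share_novel"] = odd_chain_share(p, novel_only=True, ref=ref)
    return df
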