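"""Gene-synteny classification of acyltransferase candidate loci.

RhlA, the acyltransferase that condenses two 3-hydroxyacyl chains into an
HAA, shares ~44% sequence identity with PhaG, a transacylase of PHA
metabolism -- close enough that sequence similarity alone cannot separate
them.  Their gene neighborhoods can: genuine *rhlA* sits in a glycolipid
operon (with *rhlB*, often *rhlRI*) or in synteny with *rhlC*/a
transporter, whereas *phaG* has a conserved upstream block (uracil-DNA
glycosylase, 3-hydroxyisobutyryl-CoA hydrolase, RsuA) and a tRNA gene
downstream.  This module freezes that inspection as an ordered rule list
over a controlled feature vocabulary, with the product-string -> label
synonym mapping kept as configuration.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "GeneLabel",
    "GeneFeature",
    "GeneNeighborhood",
    "LocusClass",
    "Classification",
    "classify_locus",
    "load_neighborhood",
    "write_neighborhood_gff",
    "DEFAULT_SYNONYMS",
]

logger = logging.getLogger(__name__)


class GeneLabel(str, enum.Enum):
    rhlA_candidate = "rhlA_candidate"
    rhlB = "rhlB"
    rhlC = "rhlC"
    rhlR = "rhlR"
    rhlI = "rhlI"
    transporter = "transporter"
    nodT = "nodT"
    hylD = "hylD"
    methyltransferase = "methyltransferase"
    UDG = "UDG"
    HIB_CoA_hydrolase = "HIB_CoA_hydrolase"
    unknown_function = "unknown_function"
    RsuA = "RsuA"
    tRNA = "tRNA"
    other = "other"


#: Product-string fragments mapped to controlled labels.  Matching is
#: case-insensitive substring; extend or override per annotation source.
DEFAULT_SYNONYMS: dict[str, GeneLabel] = {
    "rhlb": GeneLabel.rhlB,
    "rhamnosyltransferase 1": GeneLabel.rhlB,
    "rhamnosyltransferase i": GeneLabel.rhlB,
    "rhlc": GeneLabel.rhlC,
    "rhamnosyltransferase 2": GeneLabel.rhlC,
    "rhamnosyltransferase ii": GeneLabel.rhlC,
    "rhlr": GeneLabel.rhlR,
    "transcriptional regulator rhl": GeneLabel.rhlR,
    "rhli": GeneLabel.rhlI,
    "autoinducer synthase": GeneLabel.rhlI,
    "transporter": GeneLabel.transporter,
    "efflux": GeneLabel.transporter,
    "permease": GeneLabel.transporter,
    "nodt": GeneLabel.nodT,
    "hlyd": GeneLabel.hylD,
    "hyld": GeneLabel.hylD,
    "methyltransferase": GeneLabel.methyltransferase,
    "uracil-dna glycosylase": GeneLabel.UDG,
    "udg": GeneLabel.UDG,
    "3-hydroxyisobutyryl-coa hydrolase": GeneLabel.HIB_CoA_hydrolase,
    "hydroxyisobutyryl": GeneLabel.HIB_CoA_hydrolase,
    "hib_coa": GeneLabel.HIB_CoA_hydrolase,
    "hypothetical protein": GeneLabel.unknown_function,
    "unknown function": GeneLabel.unknown_function,
    "unknown_function": GeneLabel.unknown_function,
    "pseudouridine synthase": GeneLabel.RsuA,
    "rsua": GeneLabel.RsuA,
    "trna": GeneLabel.tRNA,
}


@dataclass(frozen=True)
class GeneFeature:
    identifier: str
    label: GeneLabel
    strand: str  # "+" or "-"
    position: int  # ordinal along the locus

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GeneNeighborhood:
    """Ordered features around exactly one acyltransferase candidate."""

    features: tuple[GeneFeature, ...]
    window: int = 5

    def __post_init__(self) -> None:
        feats = tuple(sorted(self.features, key=lambda f: f.position))
        if len({f.position for f in feats}) != len(feats):
            raise ValueError("feature ordinals must be unique")
        n_cand = sum(1 for f in feats if f.label is GeneLabel.rhlA_candidate)
        if n_cand != 1:
            raise ValueError(
                f"neighborhood must contain exactly one rhlA_candidate, found {n_cand}"
            )
        if self.window < 1:
            raise ValueError("window must be >= 1")
        object.__setattr__(self, "features", feats)

    @property
    def candidate(self) -> GeneFeature:
        return next(f for f in self.features if f.label is GeneLabel.rhlA_candidate)

    def within_window(self) -> tuple[GeneFeature, ...]:
        c = self.candidate.position
        return tuple(
            f
            for f in self.features
            if f.label is not GeneLabel.rhlA_candidate
            and abs(f.position - c) <= self.window
        )

    def upstream(self) -> tuple[GeneFeature, ...]:
        c = self.candidate.position
        return tuple(f for f in self.within_window() if f.position < c)

    def downstream(self) -> tuple[GeneFeature, ...]:
        c = self.candidate.position
        return tuple(f for f in self.within_window() if f.position > c)


class LocusClass(str, enum.Enum):
    rhlA_glycolipid_operon = "rhlA_glycolipid_operon"
    rhlA_transporter_synteny = "rhlA_transporter_synteny"
    phaG = "phaG"
    unsupported = "unsupported"


@dataclass(frozen=True)
class Classification:
    locus_class: LocusClass
    rule: str  # the single rule that fired, for the audit trail


def classify_locus(n: GeneNeighborhood) -> Classification:
    """Apply the ordered synteny rules; exactly one rule fires.

    1. *rhlB* within the window on the same strand as the candidate ->
       glycolipid operon (the mono-rhamnolipid arrangement).
    2. Otherwise, *rhlC* or a transporter within the window -> transporter
       synteny (possible but unconfirmed RhlA; whether callers accept it
       as RhlA is their policy decision).
    3. Otherwise, the conserved upstream block {UDG, 3-HIB-CoA hydrolase,
       RsuA} together with a downstream tRNA -> *phaG*.
    4. Otherwise unsupported.
    """
    cand = n.candidate
    nearby = n.within_window()
    labels = {f.label for f in nearby}

    rhlB_same_strand = any(
        f.label is GeneLabel.rhlB and f.strand == cand.strand for f in nearby
    )
    if rhlB_same_strand:
        return Classification(
            LocusClass.rhlA_glycolipid_operon,
            "rule 1: rhlB within window on the candidate strand",
        )
    if GeneLabel.rhlB not in labels and (
        GeneLabel.rhlC in labels or GeneLabel.transporter in labels
    ):
        return Classification(
            LocusClass.rhlA_transporter_synteny,
            "rule 2: rhlC/transporter within window, no rhlB",
        )
    up = {f.label for f in n.upstream()}
    down = {f.label for f in n.downstream()}
    if {GeneLabel.UDG, GeneLabel.HIB_CoA_hydrolase, GeneLabel.RsuA} <= up and (
        GeneLabel.tRNA in down
    ):
        return Classification(
            LocusClass.phaG,
            "rule 3: UDG/3-HIB-CoA-hydrolase/RsuA upstream and tRNA downstream",
        )
    return Classification(LocusClass.unsupported, "rule 4: no synteny rule matched")


#: product strings that explicitly mean "no informative annotation"
_EXPLICIT_OTHER = {"", "other", "unclassified"}


def _map_label(product: str, synonyms: dict[str, GeneLabel]) -> GeneLabel | None:
    """Mapped label, or None when the product is genuinely unmappable."""
    text = product.strip().lower()
    if text in _EXPLICIT_OTHER:
        return GeneLabel.other
    for key, label in synonyms.items():
        if key in text:
            return label
    return None


def load_neighborhood(
    path: str | Path,
    candidate_id: str,
    *,
    window: int = 5,
    synonyms: dict[str, GeneLabel] | None = None,
) -> GeneNeighborhood:
    """Load a neighborhood from a GFF3 file or a 4-column TSV.

    GFF3 (via :mod:`gffutils`): gene/CDS/tRNA features ordered by start
    coordinate; the functional label is taken from the ``product`` (or
    ``Name``) attribute through the synonym table.  TSV columns:
    ``identifier  product  strand  position``.  The feature whose ID (or
    identifier column) equals ``candidate_id`` becomes the candidate;
    unmappable products map to ``other`` with a warning.
    """
    path = Path(path)
    syn = DEFAULT_SYNONYMS if synonyms is None else synonyms
    records: list[tuple[str, str, str, int]] = []  # id, product, strand, ordinal

    if path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        feats = [
            f
            for f in db.all_features()
            if f.featuretype in {"gene", "CDS", "tRNA"}
        ]
        feats.sort(key=lambda f: (f.seqid, f.start))
        for i, f in enumerate(feats):
            product = (f.attributes.get("product") or f.attributes.get("Name") or [""])[0]
            records.append((f.id, product, f.strand, i))
    else:
        import csv

        with path.open() as fh:
            reader = csv.reader(fh, delimiter="\t")
            for i, row in enumerate(reader):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 4:
                    raise ValueError(
                        f"{path}: line {i + 1}: expected 4 columns "
                        "(identifier, product, strand, position)"
                    )
                records.append((row[0], row[1], row[2], int(row[3])))

    if not any(r[0] == candidate_id for r in records):
        raise ValueError(f"candidate {candidate_id!r} not found in {path}")

    features = []
    for ident, product, strand, pos in records:
        if ident == candidate_id:
            label = GeneLabel.rhlA_candidate
        else:
            label = _map_label(product, syn)
            if label is None:
                label = GeneLabel.other
                warnings.warn(
                    f"unmappable product {product!r} for {ident}; labelled 'other'",
                    stacklevel=2,
                )
        features.append(GeneFeature(ident, label, strand, pos))
    return GeneNeighborhood(tuple(features), window=window)


def write_neighborhood_gff(
    n: GeneNeighborhood, path: str | Path, *, seqid: str = "locus", gene_span: int = 1000
) -> Path:
    """Serialize a neighborhood as a minimal GFF3 file (toy coordinates)."""
    path = Path(path)
    lines = ["##gff-version 3"]
    for f in n.features:
        start = f.position * gene_span + 1
        end = start + gene_span - 101
        product = f.label.value if f.label is not GeneLabel.other else "unclassified"
        lines.append(
            "\t".join(
                [
                    seqid,
                    "haams",
                    "tRNA" if f.label is GeneLabel.tRNA else "gene",
                    str(start),
                    str(end),
                    ".",
                    f.strand,
                    ".",
                    f"ID={f.identifier};product={product}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path
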