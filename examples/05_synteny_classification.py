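"""Vet acyltransferase candidate loci by gene synteny.

RhlA and PhaG are too similar in sequence to separate by homology alone;
their gene neighborhoods differ.  Classify the four canonical layouts and
show the GFF3 round trip.
"""

import tempfile
from pathlib import Path

from haams import classify_locus, generate_neighborhood, load_neighborhood
from haams.synteny import write_neighborhood_gff

for kind in ("rhlAB_operon", "rhlA_transporter", "phaG_context", "isolated"):
    result = classify_locus(generate_neighborhood(kind))
    print(f"{kind:<18s} -> {result.locus_class.value:<26s} ({result.rule})")

# the same classification from an annotation file
with tempfile.TemporaryDirectory() as tmp:
    gff = write_neighborhood_gff(
        generate_neighborhood("phaG_context"), Path(tmp) / "locus.gff3"
    )
    loaded = load_neighborhood(gff, candidate_id="phaG")
    print(f"\nfrom GFF3: {classify_locus(loaded).locus_class.value}")
# Only a candidate colocalized with rhlB (same strand) counts as a
# glycolipid operon; the conserved UDG/3-HIB-CoA-hydrolase/RsuA block with
# a downstream tRNA marks phaG, and bare candidates stay unsupported.
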