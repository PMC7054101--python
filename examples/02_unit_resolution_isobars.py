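"""Resolve isobaric congeners in a unit-resolution product-ion spectrum.

On a triple quadrupole, the parent at nominal m/z 301 (a 16-carbon HAA)
fragments to 159 plus minor 131/187 -- evidence that both the C8-C8 and the
C6-C10 congeners sit under one precursor mass.
"""

from haams import (
    EnumerationConstraints,
    EvidenceLevel,
    Peak,
    Spectrum,
    annotate_spectrum,
)

unit_res = EnumerationConstraints(tolerance_da=0.5)
spectrum = Spectrum(
    precursor_mz=301.0,
    peaks=(Peak(159.0, 100.0), Peak(131.0, 24.0), Peak(187.0, 22.0)),
    identifier="parent 301",
)

for a in annotate_spectrum(spectrum, unit_res):
    frags = ", ".join(f"{f.theoretical_mz:.0f}" for f in a.fragment_evidence)
    print(
        f"{a.congener.name:<10s} evidence={a.evidence_level.name:<14s} "
        f"fragments matched: [{frags}]"
    )
# The two both_chains annotations show the peak at 301 is a mixture:
# C8-C8 (major fragment 159) plus C6-C10 (fragments 131 and 187).
print(
    "\nco-isolated congeners:",
    ", ".join(
        a.congener.name
        for a in annotate_spectrum(spectrum, unit_res)
        if a.evidence_level is EvidenceLevel.both_chains
    ),
)
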