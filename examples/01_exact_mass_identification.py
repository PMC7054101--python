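"""Identify an HAA congener from high-resolution precursor and fragment masses.

Builds the 27-carbon, one-double-bond HAA from its two chains, computes the
theoretical [M-H]- ions, and annotates the measured spectrum (precursor
453.3592 with ester-cleavage fragments 229.1810 and 241.1811).
"""

from haams import (
    ChainSpec,
    Peak,
    Spectrum,
    annotate_spectrum,
    haa_formula,
    hfa_formula,
    mz_deprotonated,
    ppm_deviation,
)
from haams.masses import round_mz

c13, c14_1 = ChainSpec(13, 0), ChainSpec(14, 1)
haa = haa_formula(c13, c14_1)
theo = round_mz(mz_deprotonated(haa))
print(f"HAA C13-C14:1 neutral formula {haa}, theoretical [M-H]- m/z {theo}")
for chain in (c13, c14_1):
    frag = round_mz(mz_deprotonated(hfa_formula(chain)))
    print(f"  ester-cleavage fragment of {chain.label}: m/z {frag}")
print(f"measured precursor 453.3592 deviates {ppm_deviation(453.3592, theo)} ppm")

spectrum = Spectrum(
    precursor_mz=453.3592,
    peaks=(Peak(229.1810, 820.0), Peak(241.1811, 790.0)),
    identifier="HAA 27:1",
)
top = annotate_spectrum(spectrum)[0]
print(
    f"\ntop annotation: {top.congener.name} ({top.evidence_level.name}); "
    "both chain orders (positional variants) are implied"
)
# Both fragments match within tolerance, so the chain pair is pinned;
# the precursor alone would only fix the 27:1 total composition.
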