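# haams

Identification and profiling of **HAA congeners** — 3-(3-hydroxyalkanoyloxy)alkanoic
acids, the lipid moiety of rhamnolipid biosurfactants — from tandem mass
spectrometry peak lists, plus the gene-synteny criterion that separates genuine
*rhlA* acyltransferase loci from their *phaG* look-alikes.

It is written for analytical chemists and metabolic engineers characterizing
HAA/rhamnolipid producers: given ESI(−) MS/MS spectra it answers *which chain
pairs are in this mixture*; given GC-EI-MS spectra of derivatized hydrolysis
products it confirms chain length and hydroxy position; given a congener
abundance table it computes the chain-specificity statistics used to compare
enzymes; and given a gene neighborhood it vets whether a candidate
acyltransferase is plausibly an RhlA at all.

## The method

An HAA is two 3-hydroxy fatty acids joined by an ester bond. A chain C*n*:*d*
(*n* carbons, *d* double bonds) has composition C*n*H<sub>2n−2d</sub>O₃; the
congener C*n*:*d*-C*m*:*e* is the condensate (sum of the chains minus H₂O),
observed in negative mode as the deprotonated ion [M−H]⁻. Collision-induced
dissociation cleaves the ester bond, releasing each chain as its deprotonated
free acid, so a congener predicts exactly two fragment m/z values satisfying

> f₁ + f₂ = precursor + (m<sub>H₂O</sub> − m<sub>H⁺</sub>) = precursor + 17.0033

The annotator enumerates every chain pair in a bounded space (default C4–C18,
≤1 double bond per chain) whose [M−H]⁻ lies within tolerance of the precursor
(5 ppm high-resolution, or ±0.5 Da unit-resolution), matches the predicted
fragments against the peak list, and ranks candidates by evidence
(`both_chains` > `one_chain` > `precursor_only`), then by mass accuracy.
Positional variants (which chain bears the free acid) are indistinguishable
and reported jointly. Complementary GC-EI evidence uses the [M−15]⁺ ion of
the methylated, trimethylsilylated chain for length and the m/z 175
oxycarbenium fragment for the 3-hydroxy position.

Profile statistics follow the field's conventions: the average chain length is
the abundance-weighted mean of (n+m)/2, main congeners are entries ≥ 10 %, and
congeners absent from a packaged reference list are categorized by what makes
them new (chain-length gap ≥ 4, unreported unsaturated chain, odd chain
length). The synteny classifier applies ordered rules over a gene-label
vocabulary: *rhlB* co-oriented in reach ⇒ glycolipid operon; otherwise
*rhlC*/transporter ⇒ transporter synteny; otherwise the conserved
UDG / 3-HIB-CoA-hydrolase / RsuA upstream block with a downstream tRNA ⇒ *phaG*;
otherwise unsupported.

A seeded synthetic-data module generates every input the pipeline consumes
(spectra with Gaussian ppm mass error and log-normal intensity noise, EI peak
lists, profiles, toy gene neighborhoods), so the whole chain is testable
without instrument data.

## Worked example

```python
from haams import ChainSpec, Peak, Spectrum, annotate_spectrum, haa_formula, mz_deprotonated
from haams.masses import round_mz

print(round_mz(mz_deprotonated(haa_formula(ChainSpec(13, 0), ChainSpec(14, 1)))))
top = annotate_spectrum(Spectrum(453.3592, (Peak(229.1810, 820), Peak(241.1811, 790))))[0]
print(top.congener.name, top.evidence_level.name)
```

prints

```
453.3586
C13-C14:1 both_chains
```

— the 27-carbon, one-double-bond HAA at theoretical [M−H]⁻ 453.3586 (the
measured 453.3592 deviates 1.3 ppm), whose two ester-cleavage fragments at
229.1810 (C13:0) and 241.1811 (C14:1) pin the chain pair; both positional
variants C13-C14:1 / C14:1-C13 are implied. Each script in `examples/`
demonstrates one capability the same way (unit-resolution isobars under a
single precursor, GC-EI chain confirmation, profile statistics for the seven
packaged enzyme profiles, synteny classification, a Monte-Carlo annotation
benchmark). The command-line entry point `haams` exposes the same stages
(`enumerate`, `annotate`, `gc-assign`, `profile`, `synth`, `synteny`) over
MGF/CSV/GFF3 files.

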