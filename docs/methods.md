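# Methods

## Mass model

All observables derive from three composition rules: a 3-hydroxy fatty acid
chain Cn:d is C_nH_{2n−2d}O_3; ester condensation of two chains loses one
H2O; derivatization for GC (methyl ester + trimethylsilyl ether) adds CH2 +
C3H8Si. Masses come from a pinned table (C 12 exact, H 1.00782503,
O 15.99491462, Si 27.97692654) and deprotonation is modelled as neutral
monoisotopic mass minus the proton mass 1.007276 Da — the electron mass is
absorbed by that convention, never tracked separately. Nominal
(unit-resolution) masses use integer mass numbers (C 12, H 1, O 16, Si 28)
and [M−H]⁻ = nominal − 1. Only C, H, O, Si are supported; isotope patterns,
adducts other than [M−H]⁻ and multiple charging are out of scope.

**Display rounding.** Internal arithmetic is full precision. Reported m/z
values are rounded half-up, carried at five decimals and reported at four
(`round_mz`). The successive rounding matters for exactly one boundary: the
deprotonated C27H50O5 ion is 453.35855 at five decimals under every standard
convention (proton subtraction; H-atom-minus-electron; cross-checked against
pyteomics), so strict single-step rounding would print 453.3585 while
reference tables print 453.3586. The two-stage convention mirrors how vendor
software displays five-decimal theoretical masses that are then quoted at
four, and reproduces all reference values. ppm deviations are reported as
magnitudes rounded half-up to one decimal (sign available separately); the
quoted 1.3 ppm for the 27:1 precursor is likewise computed against the
four-decimal displayed theoretical mass.

**Rounding boundary of nominal masses.** Rounding the exact deprotonated
mass equals the nominal value for all congeners up to 35 total carbons; at
the saturated C36 congener (C36H70O5) the accumulated hydrogen mass defect
reaches 0.515 Da and the rounded exact mass sits one unit above nominal.
The tabulated congener range (≤ 32 carbons) is unaffected.

## Enumeration and annotation

The candidate space is the bounded chain set (defaults: chains C4–C18, at
most one double bond per chain, two per molecule — the envelope of the
packaged congener table; all bounds are configuration). Precursor matching
runs in exactly one tolerance mode per query: ppm on monoisotopic masses
(default 5 ppm, the accuracy criterion of modern orbitrap data) or Da on
nominal masses (default 0.5 Da, for triple-quadrupole/ion-trap data).
Fragments are matched nearest-peak within the same tolerance, one peak per
predicted fragment, ties toward lower m/z. Identical chains predict a single
fragment; both chains may be evidenced by that one peak. Ranking is by
evidence level, then |precursor ppm|, then canonical name; intensity is
carried through for reporting but never used for ranking, since mass
accuracy is the discriminating quantity. Annotations below the evidence
floor (default `both_chains`) are retained but flagged ambiguous rather than
dropped. Precursors isobaric with a plain fatty acid C_nH_{2n−2d}O_2
(n ≤ 30, d ≤ 3 by default) attach a warning, since free fatty acids co-elute
with HAAs on reversed-phase columns and can masquerade at the precursor
level.

Congener names use the grammar `Cn[:d]-Cm[:e]`, canonical order shorter
chain first, fewer double bonds first at equal length. A congener stands for
both positional variants; no result ever contains both orderings of one
pair.

## GC-EI assignment

Chains are assigned at unit resolution (default window 0.3 Da, quadrupole
scan data) from two ions: [M−15]⁺ of the FAME/TMS derivative (homolog
spacing 14 Da per CH2, −2 per double bond; d ∈ {0, 1} considered) and the
position diagnostic C_{p+4}H_{2p+9}O3Si (m/z 175 for the 3-position).
Double-bond position is never assigned — EI spectra of these derivatives do
not determine it. One peak cannot serve as both chain-length and position
evidence: the C4 chain's [M−15]⁺ coincides with the 3-OH diagnostic at
m/z 175, so that degenerate assignment is suppressed and C4 is unassignable
from these two ions alone (a real spectrum would need additional ions).

## Profile statistics

Average chain length is Σ f_i (n_i+m_i)/2 / Σ f_i, reported at one decimal.
This weighted mean reproduces five of the seven packaged per-plasmid values
exactly (pPA2 10.5, pFLU 11.6, pDAD 11.8, pHAL 13.8, pAMB 13.7); for pANA
and pBUG the one-decimal tabulated fractions yield 11.0 and 13.9 against
quoted 10.8 and 14.0 — consistent with the originals having been computed on
unrounded raw abundances that the table no longer carries. The main-congener
threshold is 10.0 % inclusive, inferred from which tabulated entries are
emphasized (10.0 qualifies, 8.9 does not); it is a parameter. Normalization
scales to percent and drops entries below a 0.05 % reporting floor with a
log note; tabulated fixture columns are kept verbatim (totals 98.6–99.8,
reflecting per-entry rounding).

Novelty categorization against the packaged reference list (the 30
previously reported congeners of the table; the other 23 are new) applies
every matching rule to a non-reference congener: chain-length gap ≥ 4,
unsaturated chain (n, d ≥ 1) absent from the reference chain set (compared
per exact chain, not per length), odd chain length. The per-chain
unsaturation rule is deliberately conservative: some congeners described as
novel-by-unsaturation in the literature pair two individually known
unsaturated chains and receive only their other categories (or none — being
absent from the reference list is itself the novelty). The novel odd-chain
share of the pAMB column computes to 8.0 % from the tabulated fractions
(quoted elsewhere as 7.7 %, again a pre-rounding artifact).

## Synteny rules

The classifier freezes an expert-inspection criterion as an ordered rule
list over a controlled vocabulary; product-string → label synonyms are
configuration, not code. Rules, first match wins: (1) rhlB within the
window on the candidate's strand (operons are co-oriented) ⇒ glycolipid
operon; (2) rhlC or a transporter in reach with no rhlB ⇒ transporter
synteny — reported as its own class because such loci are plausible but
unconfirmed RhlA, and whether to accept them is the caller's policy;
(3) upstream ⊇ {UDG, 3-HIB-CoA hydrolase, RsuA} with a tRNA downstream ⇒
phaG; (4) unsupported. The window is a gene count (default 5, covering the
relevant flanking genes in known layouts) because no physical colocalization
distance is established; rule precedence guarantees widening the window
never flips an operon call to phaG. Exactly one candidate per neighborhood
is required; the result always names the single fired rule.

## Synthetic data

Mass error is Gaussian in ppm (multiplicative), matching how instrument
accuracy is quoted; σ defaults to 1 ppm, typical of a well-calibrated
high-resolution instrument and one fifth of the matching tolerance.
Intensity noise is log-normal (σ = 0.3) on a base proportional to the
congener's fraction — a stated construction, since no intensity model is
established for these spectra and intensities are not used in ranking.
Each congener gets its own spectrum (the LC dimension separates congeners);
co-elution is simulated explicitly by merging spectra. Fragment detection
probability (default 1) and free-fatty-acid interferent peaks (default 0)
are knobs for degraded-data studies. EI peak lists place [M−15]⁺ and the
position diagnostic with uniform jitter (±0.2 Da) plus optional background.
All stochastic paths require a seed; identical configurations produce
byte-identical serialized outputs.

What the generator does *not* emulate: chromatographic retention and peak
shape, isotope envelopes, in-source fragmentation, detector saturation, and
real EI fragment richness (only the two diagnostic ions plus background are
placed). Passing recovery benchmarks therefore demonstrate the inference
logic under the stated noise model, not robustness to every artifact of
real instrument data.

The Monte-Carlo benchmark (`recovery_rate`) draws congeners uniformly from
the bounded space, simulates their spectra at σ = 1 ppm, annotates at 5 ppm
and scores a trial as recovered when the generating congener ranks first
with both-chain evidence. At these settings the run is 1,000 trials in a
few seconds and recovery is ≥ 99 % — fragment masses of distinct chain
pairs differ by ≥ 2 Da while 5σ mass-error excursions are ~10⁻⁷ events, so
failures are essentially impossible rather than merely rare.

## Numerical and interface choices

Rounding is always decimal half-up, never banker's. Subtracting formulas
never yields negative counts (raises instead). Empty enumeration results
and infeasible chain splits are empty collections, not errors; an
unparseable congener name or spectrum row reports its position. Report
serialization is deterministic (fixed column order, stable mergesort by
descending fraction then name, no timestamps in data files); CLI runs write
the resolved configuration beside their outputs. MGF I/O goes through
pyteomics, GFF3 through gffutils (in-memory db), tables through pandas.
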