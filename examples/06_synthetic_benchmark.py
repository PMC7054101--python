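"""Benchmark annotation accuracy on synthetic spectra.

Simulates single-congener product-ion spectra at 1 ppm mass error and
checks how often annotation at 5 ppm returns the generating congener as
the top hit with both-chain evidence.
"""

from haams import SyntheticConfig, annotate_spectrum, generate_msms_spectra, generate_profile, recovery_rate

# one concrete spectrum, end to end
cfg = SyntheticConfig(profile_source="pPA2", mass_error_ppm=1.0, seed=42)
profile = generate_profile(cfg)
spectra = generate_msms_spectra(profile, cfg)
s = spectra[0]
top = annotate_spectrum(s)[0]
print(
    f"{s.identifier}: precursor {s.precursor_mz:.4f} -> {top.congener.name} "
    f"({top.evidence_level.name}, {top.precursor_ppm:+.1f} ppm)"
)

# Monte-Carlo over random congeners
rate = recovery_rate(500, seed=99, sigma_ppm=1.0)
print(f"\nrecovery rate over 500 random congeners at sigma=1 ppm: {rate:.1%}")
# At 1 ppm accuracy the 5 ppm window essentially never misses a fragment,
# so the generating chain pair is recovered in effectively every trial.
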