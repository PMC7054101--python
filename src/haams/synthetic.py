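"""Synthetic instrument output for every pipeline stage.

The generator emulates the measurement chain the annotator consumes:
ESI(-) product-ion spectra of HAA mixtures (a deprotonated precursor plus
the two ester-cleavage chain fragments, Gaussian mass error quoted in ppm,
log-normal intensity noise, optional co-eluting free-fatty-acid
interferents), GC-EI peak lists of derivatized hydroxy acids, congener
profiles (tabulated fixture columns or random compositions), and toy gene
neighborhoods for the synteny rules.  Every stochastic path draws from a
seeded generator, so identical configurations give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .congeners import (
    CongenerSpec,
    DEFAULT_CONSTRAINTS,
    EnumerationConstraints,
    _candidate_table,
)
from .formula import ChainSpec, fatty_acid_formula, mz_deprotonated
from .gcms import m_minus_15, position_diagnostic_mz
from .msms import EvidenceLevel, Peak, Spectrum, annotate_spectrum, predict_fragments
from .profiles import CongenerProfile, FIXTURE_COLUMNS, fixture_profile
from .synteny import GeneFeature, GeneLabel, GeneNeighborhood

__all__ = [
    "SyntheticConfig",
    "generate_profile",
    "generate_msms_spectra",
    "generate_ei_peaklist",
    "generate_neighborhood",
    "merge_spectra",
    "recovery_rate",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Noise model and source selection for synthetic data.

    ``mass_error_ppm`` is the 1-sigma accuracy of a high-resolution
    instrument (default 1 ppm, comfortably inside a <5 ppm acceptance
    band); ``intensity_sigma`` the log-normal spread of peak intensities;
    ``fragment_detection_prob`` the chance each chain fragment survives
    into the peak list; ``n_interferents`` adds co-eluting free-fatty-acid
    peaks.  ``seed`` is mandatory for any stochastic draw.
    """

    profile_source: str | Mapping[CongenerSpec, float] = "pPA2"
    mass_error_ppm: float = 1.0
    intensity_sigma: float = 0.3
    fragment_detection_prob: float = 1.0
    n_interferents: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mass_error_ppm < 0:
            raise ValueError("mass_error_ppm must be >= 0")
        if self.intensity_sigma < 0:
            raise ValueError("intensity_sigma must be >= 0")
        if not 0 <= self.fragment_detection_prob <= 1:
            raise ValueError("fragment_detection_prob must be in [0, 1]")
        if self.n_interferents < 0:
            raise ValueError("n_interferents must be >= 0")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic generation")
        return np.random.default_rng(self.seed)

    @property
    def stochastic(self) -> bool:
        return (
            self.mass_error_ppm > 0
            or self.intensity_sigma > 0
            or self.fragment_detection_prob < 1
            or self.n_interferents > 0
            or isinstance(self.profile_source, str)
            and self.profile_source == "random"
        )


def generate_profile(
    cfg: SyntheticConfig,
    *,
    congener_pool: Sequence[CongenerSpec] | None = None,
    n_congeners: int = 10,
) -> CongenerProfile:
    """A ground-truth congener profile.

    Fixture mode (``profile_source`` one of the packaged plasmid columns)
    reproduces that column exactly, re-tagged ``synthetic``.  An explicit
    mapping is passed through.  ``"random"`` draws a flat-Dirichlet
    composition over ``n_congeners`` congeners sampled from
    ``congener_pool`` (default: the bounded enumeration space).
    """
    src = cfg.profile_source
    if isinstance(src, Mapping):
        return CongenerProfile("explicit", dict(src), provenance="synthetic")
    if src in FIXTURE_COLUMNS:
        fx = fixture_profile(src)
        return CongenerProfile(fx.label, fx.entries, provenance="synthetic")
    if src == "random":
        rng = cfg.rng()
        if congener_pool is None:
            chains = list(DEFAULT_CONSTRAINTS.iter_chains())
            congener_pool = sorted(
                {
                    CongenerSpec(a, b)
                    for i, a in enumerate(chains)
                    for b in chains[i:]
                    if a.unsaturations + b.unsaturations
                    <= DEFAULT_CONSTRAINTS.max_total_unsat
                }
            )
        n = min(n_congeners, len(congener_pool))
        idx = rng.choice(len(congener_pool), size=n, replace=False)
        fractions = rng.dirichlet(np.ones(n)) * 100.0
        entries = {congener_pool[i]: float(f) for i, f in zip(idx, fractions)}
        return CongenerProfile("random", entries, provenance="synthetic")
    raise ValueError(
        f"unknown profile source {src!r}; available fixtures: "
        + ", ".join(FIXTURE_COLUMNS)
        + ", or 'random', or an explicit mapping"
    )


def _perturb_ppm(mz: float, sigma_ppm: float, rng: np.random.Generator | None) -> float:
    if sigma_ppm == 0 or rng is None:
        return mz
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6)


def generate_msms_spectra(
    p: CongenerProfile,
    cfg: SyntheticConfig,
    k: EnumerationConstraints = DEFAULT_CONSTRAINTS,
) -> list[Spectrum]:
    """One product-ion spectrum per congener of the profile.

    The LC dimension separates congeners, so each gets its own spectrum:
    precursor at the theoretical [M-H]- perturbed by Gaussian ppm error,
    chain fragments likewise (each retained with the configured detection
    probability), intensities proportional to the congener's fraction with
    log-normal noise.  Interferent peaks at free-fatty-acid [M-H]- masses
    are appended when configured.  Co-eluting isomers can be simulated
    afterwards with :func:`merge_spectra`.
    """
    rng = cfg.rng() if cfg.stochastic else None
    spectra: list[Spectrum] = []
    for cong in sorted(p.entries):
        frac = p.entries[cong]
        theo_prec = mz_deprotonated(cong.formula())
        prec = _perturb_ppm(theo_prec, cfg.mass_error_ppm, rng)
        peaks: list[Peak] = []
        for chain, frag_mz in predict_fragments(cong).items():
            if rng is not None and cfg.fragment_detection_prob < 1:
                if rng.random() >= cfg.fragment_detection_prob:
                    continue
            mz = _perturb_ppm(frag_mz, cfg.mass_error_ppm, rng)
            base = max(frac, 1e-3) * 1000.0
            if rng is not None and cfg.intensity_sigma > 0:
                base *= float(np.exp(rng.normal(0.0, cfg.intensity_sigma)))
            peaks.append(Peak(mz, base))
        if cfg.n_interferents > 0:
            assert rng is not None
            for _ in range(cfg.n_interferents):
                n = int(rng.integers(12, 21))
                d = int(rng.integers(0, 2))
                ffa = mz_deprotonated(fatty_acid_formula(n, d))
                peaks.append(
                    Peak(_perturb_ppm(ffa, cfg.mass_error_ppm, rng), 50.0)
                )
        spectra.append(
            Spectrum(
                precursor_mz=prec,
                peaks=tuple(peaks),
                identifier=f"synthetic:{cong.name}",
            )
        )
    return spectra


def merge_spectra(spectra: Sequence[Spectrum], identifier: str | None = None) -> Spectrum:
    """Merge co-eluting spectra sharing (approximately) one precursor."""
    if not spectra:
        raise ValueError("nothing to merge")
    prec = float(np.mean([s.precursor_mz for s in spectra]))
    peaks = tuple(p for s in spectra for p in s.peaks)
    return Spectrum(precursor_mz=prec, peaks=peaks, identifier=identifier)


def generate_ei_peaklist(
    c: ChainSpec,
    *,
    seed: int | None = None,
    jitter_da: float = 0.2,
    n_background: int = 0,
    background_range: tuple[float, float] = (50.0, 500.0),
) -> list[Peak]:
    """EI peak list of one derivatized chain: [M-15]+ and the 3-OH diagnostic.

    Peak positions get +/- uniform(0, ``jitter_da``) jitter (zero with
    ``jitter_da=0``); ``n_background`` uniform-random background peaks are
    added over the scan range.
    """
    rng = np.random.default_rng(seed) if (jitter_da > 0 or n_background > 0) else None
    if (jitter_da > 0 or n_background > 0) and seed is None:
        raise ValueError("a seed is mandatory for stochastic generation")

    def jit(mz: float) -> float:
        if rng is None or jitter_da == 0:
            return mz
        return mz + rng.uniform(-jitter_da, jitter_da)

    peaks = [
        Peak(jit(m_minus_15(c)), 100.0),
        Peak(jit(position_diagnostic_mz(c.hydroxyl_position)), 80.0),
    ]
    for _ in range(n_background):
        assert rng is not None
        peaks.append(Peak(float(rng.uniform(*background_range)), float(rng.uniform(1, 20))))
    return sorted(peaks, key=lambda p: p.mz)


def recovery_rate(
    n_trials: int,
    seed: int,
    *,
    sigma_ppm: float = 1.0,
    detection_prob: float = 1.0,
    k: EnumerationConstraints = DEFAULT_CONSTRAINTS,
) -> float:
    """Monte-Carlo annotation benchmark on single-congener spectra.

    Each trial draws a congener uniformly from the bounded chain space,
    simulates its product-ion spectrum at the given mass-error sigma, and
    annotates it at the configured tolerance.  A trial is a success when
    the generating congener is the top-ranked annotation with both-chain
    fragment evidence.  Returns the success fraction.
    """
    rng = np.random.default_rng(seed)
    pool = sorted(c for c, *_ in _candidate_table(k))
    hits = 0
    for _ in range(n_trials):
        cong = pool[int(rng.integers(len(pool)))]
        cfg = SyntheticConfig(
            profile_source={cong: 100.0},
            mass_error_ppm=sigma_ppm,
            fragment_detection_prob=detection_prob,
            seed=int(rng.integers(2**31)),
        )
        (s,) = generate_msms_spectra(generate_profile(cfg), cfg)
        anns = annotate_spectrum(s, k)
        if (
            anns
            and anns[0].congener == cong
            and anns[0].evidence_level is EvidenceLevel.both_chains
        ):
            hits += 1
    return hits / n_trials


_NEIGHBORHOOD_LAYOUTS: dict[str, list[tuple[str, GeneLabel, str]]] = {
    # rhlAB colocalized with the quorum-sensing regulator/inducer pair
    "rhlAB_operon": [
        ("geneA", GeneLabel.other, "+"),
        ("rhlA", GeneLabel.rhlA_candidate, "+"),
        ("rhlB", GeneLabel.rhlB, "+"),
        ("rhlR", GeneLabel.rhlR, "+"),
        ("rhlI", GeneLabel.rhlI, "+"),
    ],
    # the rhlC/transporter arrangement, no rhlB in reach
    "rhlA_transporter": [
        ("geneA", GeneLabel.other, "-"),
        ("rhlA", GeneLabel.rhlA_candidate, "+"),
        ("tpt", GeneLabel.transporter, "+"),
        ("rhlC", GeneLabel.rhlC, "+"),
    ],
    # conserved upstream block + downstream tRNA around phaG
    "phaG_context": [
        ("udg", GeneLabel.UDG, "+"),
        ("hibch", GeneLabel.HIB_CoA_hydrolase, "+"),
        ("orfU", GeneLabel.unknown_function, "+"),
        ("rsuA", GeneLabel.RsuA, "+"),
        ("phaG", GeneLabel.rhlA_candidate, "+"),
        ("trnX", GeneLabel.tRNA, "+"),
    ],
    # candidate with uninformative flanks
    "isolated": [
        ("geneA", GeneLabel.other, "+"),
        ("geneB", GeneLabel.other, "-"),
        ("rhlA?", GeneLabel.rhlA_candidate, "+"),
        ("geneC", GeneLabel.other, "+"),
    ],
}


def generate_neighborhood(
    kind: str, *, window: int = 5, gff_path=None
) -> GeneNeighborhood:
    """A toy gene neighborhood of the named layout.

    Kinds: ``rhlAB_operon``, ``rhlA_transporter``, ``phaG_context``,
    ``isolated`` -- each classifies to its generating class by
    construction.  With ``gff_path`` the neighborhood is also written as a
    GFF3 file.
    """
    try:
        layout = _NEIGHBORHOOD_LAYOUTS[kind]
    except KeyError:
        raise ValueError(
            f"unknown neighborhood kind {kind!r}; available: "
            + ", ".join(sorted(_NEIGHBORHOOD_LAYOUTS))
        ) from None
    features = tuple(
        GeneFeature(ident, label, strand, i)
        for i, (ident, label, strand) in enumerate(layout)
    )
    n = GeneNeighborhood(features, window=window)
    if gff_path is not None:
        from .synteny import write_neighborhood_gff

        write_neighborhood_gff(n, gff_path)
    return n
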