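"""MS/MS annotation: fragment prediction, evidence assignment, invariants."""

import pytest

from haams import (
    ChainSpec,
    CongenerSpec,
    EnumerationConstraints,
    EvidenceLevel,
    Peak,
    Spectrum,
    annotate_spectrum,
    enumerate_congeners,
    flag_fatty_acid_interference,
    match_fragments,
    mz_deprotonated,
    predict_fragments,
)
from haams.masses import PROTON_MASS, round_mz
from haams.formula import WATER, monoisotopic_mass

WATER_MINUS_PROTON = monoisotopic_mass(WATER) - PROTON_MASS  # 17.0033


def spectrum(precursor, frag_mzs, ident=None):
    return Spectrum(
        precursor_mz=precursor,
        peaks=tuple(Peak(mz, 100.0) for mz in frag_mzs),
        identifier=ident,
    )


class TestPredictFragments:
    def test_mixed_chain_pair(self):
        frags = predict_fragments(CongenerSpec(ChainSpec(13, 0), ChainSpec(14, 1)))
        assert sorted(round_mz(v) for v in frags.values()) == [229.1809, 241.1809]

    def test_identical_chains_single_fragment(self):
        frags = predict_fragments(
            CongenerSpec(ChainSpec(8, 0), ChainSpec(8, 0)), nominal=True
        )
        assert list(frags.values()) == [159.0]

    def test_c6_c10_nominal_pair(self):
        frags = predict_fragments(
            CongenerSpec(ChainSpec(6, 0), ChainSpec(10, 0)), nominal=True
        )
        assert sorted(frags.values()) == [131.0, 187.0]


class TestMatchFragments:
    def test_both_chains_with_printed_ppm(self, defaults):
        s = spectrum(453.3592, [229.1810, 241.1811])
        cands = enumerate_congeners(s.precursor_mz, defaults)
        target = next(
            a
            for a in match_fragments(s, cands, defaults)
            if a.congener.name == "C13-C14:1"
        )
        assert target.evidence_level is EvidenceLevel.both_chains
        errs = sorted(round(abs(f.ppm_error), 1) for f in target.fragment_evidence)
        assert errs == [0.4, 0.8]

    def test_empty_peak_list_gives_precursor_only(self, defaults):
        s = spectrum(453.3592, [])
        for a in match_fragments(s, enumerate_congeners(453.3592, defaults), defaults):
            assert a.evidence_level is EvidenceLevel.precursor_only
            assert a.fragment_evidence == ()

    def test_foreign_fragment_not_matched(self, defaults):
        # C12-C15:1 predicts 215.1652/255.1966; the lone 229.1810 peak
        # is >5 ppm from both, so the candidate stays precursor-only.
        s = spectrum(453.3592, [229.1810])
        cands = enumerate_congeners(s.precursor_mz, defaults)
        a = next(
            m for m in match_fragments(s, cands, defaults) if m.congener.name == "C12-C15:1"
        )
        assert a.evidence_level is EvidenceLevel.precursor_only

    def test_one_chain_level(self, defaults):
        s = spectrum(453.3592, [229.1810])
        cands = enumerate_congeners(s.precursor_mz, defaults)
        a = next(
            m for m in match_fragments(s, cands, defaults) if m.congener.name == "C13-C14:1"
        )
        assert a.evidence_level is EvidenceLevel.one_chain


class TestAnnotateSpectrum:
    def test_fig6a_top_annotation(self, defaults):
        s = spectrum(453.3592, [229.1810, 241.1811])
        top = annotate_spectrum(s, defaults)[0]
        assert top.congener.name == "C13-C14:1"
        assert top.evidence_level is EvidenceLevel.both_chains
        assert top.positional_note  # both chain orders implied
        assert not top.ambiguous

    def test_unit_resolution_isobaric_congeners(self, unit_res):
        s = spectrum(301.0, [159.0, 131.0, 187.0])
        anns = annotate_spectrum(s, unit_res)
        both = {a.congener.name for a in anns if a.evidence_level is EvidenceLevel.both_chains}
        assert both == {"C8-C8", "C6-C10"}

    def test_fragment_free_spectrum_all_ambiguous(self, defaults):
        s = spectrum(453.3592, [])
        anns = annotate_spectrum(s, defaults)
        assert anns and all(a.ambiguous for a in anns)
        assert {a.congener.identity for a in anns} == {"27:1"}

    def test_no_candidate_returns_empty(self, defaults):
        assert annotate_spectrum(spectrum(3000.0, [229.0]), defaults) == []

    def test_deterministic(self, defaults):
        s = spectrum(453.3592, [229.1810, 241.1811])
        a1 = annotate_spectrum(s, defaults)
        a2 = annotate_spectrum(s, defaults)
        assert a1 == a2

    def test_both_chains_ranks_above_weaker_evidence(self, defaults):
        s = spectrum(453.3592, [229.1810, 241.1811])
        levels = [a.evidence_level for a in annotate_spectrum(s, defaults)]
        assert levels == sorted(levels, reverse=True)


class TestComplementarity:
    def test_invariant_across_enumeration_space(self, all_congeners, defaults):
        """For every both_chains annotation of a noise-free spectrum, the
        two matched fragments satisfy f1 + f2 = precursor + (H2O - H+)."""
        checked = 0
        for cong in all_congeners:
            prec = mz_deprotonated(cong.formula())
            frags = list(predict_fragments(cong).values())
            s = spectrum(prec, frags)
            for a in annotate_spectrum(s, defaults):
                if a.evidence_level is not EvidenceLevel.both_chains:
                    continue
                per_chain = {f.chain: f.peak.mz for f in a.fragment_evidence}
                total = sum(per_chain[ch] for ch in a.congener.chains)
                assert total == pytest.approx(
                    a.theoretical_mz + WATER_MINUS_PROTON, abs=1e-4
                )
                checked += 1
        assert checked >= len(all_congeners)  # every congener self-annotates

    def test_printed_worked_example(self):
        assert 229.1809 + 241.1809 == pytest.approx(
            453.3586 + WATER_MINUS_PROTON, abs=1e-4
        )


class TestFattyAcidInterference:
    def test_oleic_acid_flagged(self, defaults):
        hits = flag_fatty_acid_interference(281.2486, defaults)
        assert "C18H34O2" in {str(f) for f in hits}

    def test_haa_271_clean(self, defaults):
        assert flag_fatty_acid_interference(453.3592, defaults) == []

    def test_zero_tolerance_empty_for_inexact_mass(self):
        k = EnumerationConstraints(tolerance_ppm=0.0)
        assert flag_fatty_acid_interference(281.2487, k) == []

    def test_warning_attached_to_annotations(self, defaults):
        # an interfering precursor that is also a valid congener mass
        prec = mz_deprotonated(CongenerSpec(ChainSpec(8, 0), ChainSpec(8, 0)).formula())
        ffas = flag_fatty_acid_interference(prec, defaults)
        anns = annotate_spectrum(spectrum(prec, []), defaults)
        if ffas:
            assert all(a.warnings for a in anns)
        else:
            assert all(not a.warnings for a in anns)
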