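"""Informative sites, 45S allele-frequency profiles, F1 classification."""

import numpy as np
import pytest

from ulvapop import hybrid as hyb
from ulvapop import mapvar as mv
from ulvapop import seq as sq
from ulvapop import simulate as sim
from ulvapop.genome import CircularGenome


def pile_from_counts(length, per_site: dict[int, dict[str, int]], background=None):
    p = mv.Pileup.empty("x", length)
    if background is not None:
        ref, depth = background
        p.counts[sq.encode(ref), np.arange(length)] = depth
    for pos, counts in per_site.items():
        p.counts[:, pos] = 0
        for b, c in counts.items():
            p.counts[sq.BASES.index(b), pos] = c
    return p


def map_45s(panel, strain, genomes=None):
    rd = sim.simulate_strain_reads(panel, strain, genomes, include=("r45s",))["r45s"]
    ref = CircularGenome("r45s_ref", panel.r45s(panel.reference_species), circular=True)
    return mv.map_reads(rd.r1 + rd.r2, ref)


class TestInformativeSites:
    def test_identical_consensuses_empty(self):
        with pytest.warns(UserWarning):
            assert hyb.find_informative_sites("ACGT" * 10, "ACGT" * 10) == []

    def test_planted_fixed_differences_recovered(self, full_panel):
        """The ~65 fixed differences of the most diverged species pair over
        the 5 kb 45S unit are recovered exactly from the consensuses."""
        a = full_panel.r45s("laetevirens")
        b = full_panel.r45s("pseudorotundata")
        sites = hyb.find_informative_sites(a, b)
        truth = full_panel.variant_sites("r45s", "laetevirens", "pseudorotundata")
        assert [s.position for s in sites] == truth.tolist()
        assert 40 <= len(sites) <= 90  # binomial spread around the 65 target

    def test_within_species_polymorphism_excluded(self):
        a, b = "AAAA", "CACA"  # sites 0 and 2 differ
        pile_a = pile_from_counts(4, {0: {"A": 90, "C": 10}, 2: {"A": 100}})
        pile_b = pile_from_counts(4, {0: {"C": 100}, 2: {"C": 100}})
        sites = hyb.find_informative_sites(a, b, [pile_a], [pile_b], fixation_threshold=0.95)
        assert [s.position for s in sites] == [2]


class TestAlleleProfile:
    def test_pure_strain_all_ones(self):
        sites = [hyb.InformativeSite(0, "A", "C"), hyb.InformativeSite(3, "G", "T")]
        p = pile_from_counts(5, {0: {"A": 50}, 3: {"G": 40}})
        prof = hyb.allele_profile(p, sites, "s")
        assert np.allclose(prof.freq_a, 1.0)

    def test_f1_frequencies_near_half(self, unit_panel):
        """Simulated F1 at 1000x 45S coverage: per-site allele-A frequency
        within 0.5 +/- 3 binomial SD (copy + read sampling)."""
        st = sim.StrainSpec(
            "h", "laetevirens", is_hybrid=True, hybrid_parents=("rigida", "laetevirens"),
            cytoplasm_donor="laetevirens", coverage_45s=1000, error_rate=0.0, seed=13,
        )
        g = sim.simulate_strain_genomes(unit_panel, st)
        pile = map_45s(unit_panel, st, g)
        a = unit_panel.r45s("rigida")
        b = unit_panel.r45s("laetevirens")
        sites = hyb.find_informative_sites(a, b)
        prof = hyb.allele_profile(pile, sites, "h")
        n_copies = unit_panel.spec.r45s_copy_number
        for f, d in zip(prof.freq_a, prof.depth):
            sd = np.sqrt(0.25 / d + 0.25 / n_copies)
            assert abs(f - g.parent_a_copy_fraction) <= 4 * sd

    def test_pure_with_errors_stays_low(self, unit_panel):
        st = sim.StrainSpec("p", "laetevirens", coverage_45s=1000, error_rate=0.01, seed=14)
        pile = map_45s(unit_panel, st)
        sites = hyb.find_informative_sites(
            unit_panel.r45s("rigida"), unit_panel.r45s("laetevirens")
        )
        prof = hyb.allele_profile(pile, sites, "p")
        assert np.all(prof.freq_a[prof.usable] <= 0.02)

    def test_all_sites_below_depth_warns(self):
        sites = [hyb.InformativeSite(0, "A", "C")]
        with pytest.warns(UserWarning):
            prof = hyb.allele_profile(mv.Pileup.empty("x", 4), sites, "s")
        assert not prof.usable.any()


class TestClassifyNuclear:
    def _prof(self, freqs, depth=1000):
        n = len(freqs)
        sites = [hyb.InformativeSite(i, "A", "C") for i in range(n)]
        f = np.array(freqs, dtype=float)
        return hyb.AlleleFrequencyProfile("s", sites, np.full(n, depth), f, np.zeros(n))

    def test_all_ones_is_parent_a(self):
        call, _ = hyb.classify_nuclear(self._prof([1.0] * 10))
        assert call == hyb.NUC_A

    def test_all_half_is_heterozygous(self):
        call, _ = hyb.classify_nuclear(self._prof([0.5] * 10))
        assert call == hyb.NUC_HET

    def test_chimera_pattern_is_ambiguous(self):
        call, _ = hyb.classify_nuclear(self._prof([1.0] * 5 + [0.0] * 5))
        assert call == hyb.NUC_AMBIGUOUS

    def test_too_few_sites_ambiguous(self):
        call, detail = hyb.classify_nuclear(self._prof([0.5] * 3))
        assert call == hyb.NUC_AMBIGUOUS and "sites" in detail["reason"]

    def test_consistent_copy_imbalance_still_heterozygous(self):
        # a shared pooled ratio of 0.6 (unbalanced parental rDNA arrays) is
        # tolerated, exactly as the heterozygous band intends
        call, _ = hyb.classify_nuclear(self._prof([0.6] * 10, depth=5000))
        assert call == hyb.NUC_HET

    def test_site_inconsistent_with_pooled_ratio_rejected(self):
        # one site departing from the shared pooled ratio at high depth
        # marks a chimeric/partial pattern, not an F1
        call, detail = hyb.classify_nuclear(self._prof([0.5] * 9 + [0.64], depth=5000))
        assert call == hyb.NUC_AMBIGUOUS
        assert "pooled" in detail["reason"]


class TestHomoplasmy:
    def test_pure_reads_homoplasmic(self):
        a, b = "AAAA", "CCCC"
        pile = pile_from_counts(4, {i: {"A": 30} for i in range(4)})
        assert hyb.check_homoplasmy(pile, a, b) == ("A", True)

    def test_seventy_thirty_mixture_not_homoplasmic(self):
        a, b = "AAAA", "CCCC"
        pile = pile_from_counts(4, {i: {"A": 70, "C": 30} for i in range(4)})
        call, homo = hyb.check_homoplasmy(pile, a, b)
        assert call == "A" and homo is False

    def test_simulated_hybrid_homoplasmic_for_donor(self, unit_panel):
        st = sim.StrainSpec(
            "h", "laetevirens", is_hybrid=True, hybrid_parents=("rigida", "laetevirens"),
            cytoplasm_donor="laetevirens", coverage_cp=20, error_rate=0.002, seed=21,
        )
        g = sim.simulate_strain_genomes(unit_panel, st)
        rd = sim.simulate_strain_reads(unit_panel, st, g, include=("cp",))["cp"]
        ref = unit_panel.cp("laetevirens")
        pile = mv.map_reads(rd.r1 + rd.r2, ref)
        call, homo = hyb.check_homoplasmy(
            pile, unit_panel.cp("rigida").sequence, unit_panel.cp("laetevirens").sequence
        )
        assert call == "B" and homo is True

    def test_no_diagnostic_sites_rejected(self):
        with pytest.raises(ValueError):
            hyb.check_homoplasmy(mv.Pileup.empty("x", 4), "AAAA", "AAAA")


class TestVerdicts:
    def _inputs(self, **over):
        base = dict(
            strain_id="s", nuclear_call=hyb.NUC_A, cp_call="A", mt_call="A",
            cp_homoplasmic=True, mt_homoplasmic=True,
        )
        base.update(over)
        return base

    def test_concordant_pure(self):
        r = hyb.call_hybrid(**self._inputs())
        assert r.verdict == hyb.VERDICT_PURE

    def test_f1_requires_het_and_uniparental_organelles(self):
        r = hyb.call_hybrid(**self._inputs(nuclear_call=hyb.NUC_HET))
        assert r.verdict == hyb.VERDICT_F1
        r2 = hyb.call_hybrid(**self._inputs(nuclear_call=hyb.NUC_HET, cp_homoplasmic=False))
        assert r2.verdict == hyb.VERDICT_AMBIGUOUS

    def test_pure_nuclear_discordant_with_organelles(self):
        r = hyb.call_hybrid(**self._inputs(nuclear_call=hyb.NUC_A, cp_call="B", mt_call="B"))
        assert r.verdict == hyb.VERDICT_DISCORDANT

    def test_summary_counts(self):
        reports, summary = hyb.call_hybrids(
            [self._inputs(), self._inputs(nuclear_call=hyb.NUC_HET)]
        )
        counts = dict(zip(summary.verdict, summary.n_strains))
        assert counts == {hyb.VERDICT_PURE: 1, hyb.VERDICT_F1: 1}


class TestSensitivitySpecificityLight:
    """Small-scale screening properties; the full-size versions run in the
    acceptance suite."""

    def test_no_false_positives_quick(self, unit_panel):
        a = unit_panel.r45s("rigida")
        b = unit_panel.r45s("laetevirens")
        sites = hyb.find_informative_sites(a, b)
        for seed in range(8):
            st = sim.StrainSpec("p", "laetevirens", coverage_45s=1000, error_rate=0.01, seed=300 + seed)
            prof = hyb.allele_profile(map_45s(unit_panel, st), sites, "p")
            call, _ = hyb.classify_nuclear(prof)
            assert call == hyb.NUC_B  # allele B = laetevirens here

    def test_f1_detected_quick(self, unit_panel):
        a = unit_panel.r45s("rigida")
        b = unit_panel.r45s("laetevirens")
        sites = hyb.find_informative_sites(a, b)
        for seed in range(5):
            st = sim.StrainSpec(
                "h", "laetevirens", is_hybrid=True, hybrid_parents=("rigida", "laetevirens"),
                cytoplasm_donor="laetevirens", coverage_45s=150, error_rate=0.01, seed=400 + seed,
            )
            prof = hyb.allele_profile(map_45s(unit_panel, st), sites, "h")
            call, detail = hyb.classify_nuclear(prof)
            assert call == hyb.NUC_HET, detail
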