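"""Mapping, variant calling, consensus and the SNP-density statistics."""

import numpy as np
import pandas as pd
import pytest

from ulvapop import mapvar as mv
from ulvapop import seq as sq
from ulvapop import simulate as sim
from ulvapop.genome import CircularGenome, Gene


def make_ref(rng, n=3000, circular=True, name="ref"):
    return CircularGenome(name, sq.decode(rng.integers(0, 4, n, dtype=np.uint8)), circular, [])


class TestMapping:
    def test_error_free_reads_fully_mapped_no_alt(self, rng):
        ref = make_ref(rng)
        rs = sim.simulate_reads([("m", ref.sequence, True)], 20.0, rng, error_rate=0.0)
        pile = mv.map_reads(rs.r1 + rs.r2, ref)
        assert pile.n_unmapped == 0
        assert pile.n_mapped == 2 * len(rs)
        alt = pile.counts.sum() - pile.counts[ref.codes, np.arange(len(ref))].sum()
        assert alt == 0
        assert abs(pile.depth.mean() - 20) < 2

    def test_single_substituted_read_placement(self, rng):
        ref = make_ref(rng)
        read = list(ref.sequence[100:250])
        read[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[40]]
        pile, pl = mv.map_reads([("r", "".join(read))], ref, record_placements=True)
        assert pl.start.iloc[0] == 100
        assert pl.mismatches.iloc[0] == 1
        pos = 140
        col = pile.counts[:, pos]
        assert col.sum() == 1 and col[ref.codes[pos]] == 0

    def test_placements_match_brute_force_min_mismatch(self, rng):
        """Placements at ~2 SNPs/kb own-species divergence equal an
        all-positions, both-strands minimum-mismatch search."""
        ref = make_ref(rng, 2000)
        strain = ref.codes.copy()
        hit = rng.random(2000) < 0.002
        strain[hit] = (strain[hit] + rng.integers(1, 4, int(hit.sum()), dtype=np.uint8)) % 4
        rs = sim.simulate_reads([("m", sq.decode(strain), True)], 3.0, rng, error_rate=0.005)
        reads = [(f"{n}/1", s) for (n, s) in rs.r1] + [(f"{n}/2", s) for (n, s) in rs.r2]
        _, pl = mv.map_reads(reads, ref, record_placements=True)
        ext = np.concatenate([ref.codes, ref.codes])
        for name, s in reads:
            arr = sq.encode(s)
            best = None
            for strand_i, a in ((0, arr), (1, sq.revcomp_codes(arr))):
                for st in range(len(ref)):
                    mm = int(np.count_nonzero(ext[st : st + arr.size] != a))
                    key = (mm, st, strand_i)
                    if best is None or key < best:
                        best = key
            row = pl[pl.read_id == name].iloc[0]
            got = (int(row.mismatches), int(row.start), 0 if row.strand == "+" else 1)
            assert got == best, name

    def test_high_divergence_read_unmapped(self, rng):
        ref = make_ref(rng)
        junk = sq.decode(rng.integers(0, 4, 150, dtype=np.uint8))
        pile = mv.map_reads([("j", junk)], ref)
        assert pile.n_mapped == 0 and pile.n_unmapped == 1


class TestCalling:
    def _pile(self, ref, pos, counts_by_base):
        p = mv.Pileup.empty(ref.id, len(ref))
        # uniform reference depth 30 elsewhere
        p.counts[ref.codes, np.arange(len(ref))] = 30
        col = np.zeros(4, dtype=np.uint32)
        for b, c in counts_by_base.items():
            col[sq.BASES.index(b)] = c
        p.counts[:, pos] = col
        return p

    def test_all_alt_is_variant(self, rng):
        ref = make_ref(rng, 500)
        alt = "A" if ref.sequence[7] != "A" else "C"
        pile = self._pile(ref, 7, {alt: 30})
        vt = mv.call_variants(pile, ref)
        row = vt[vt.position == 7].iloc[0]
        assert row.call == mv.CALL_VARIANT and row.alt_allele == alt

    def test_balanced_is_heterozygous(self, rng):
        ref = make_ref(rng, 500)
        r = ref.sequence[7]
        alt = "A" if r != "A" else "C"
        pile = self._pile(ref, 7, {r: 15, alt: 15})
        vt = mv.call_variants(pile, ref)
        assert vt[vt.position == 7].iloc[0].call == mv.CALL_HET

    def test_low_depth_is_no_call(self, rng):
        ref = make_ref(rng, 500)
        pile = self._pile(ref, 7, {ref.sequence[7]: 5})
        vt = mv.call_variants(pile, ref)
        assert vt[vt.position == 7].iloc[0].call == mv.CALL_NOCALL


class TestConsensus:
    def test_empty_table_returns_reference(self, rng):
        ref = make_ref(rng, 400)
        cons, logged = mv.build_consensus(ref, mv.call_variants(mv.Pileup.empty(ref.id, 400), ref).iloc[0:0])
        assert cons == ref.sequence and logged == []

    def test_het_tie_keeps_reference(self, rng):
        ref = make_ref(rng, 400)
        alt = "A" if ref.sequence[5] != "A" else "C"
        vt = pd.DataFrame(
            {"position": [5], "ref_allele": [ref.sequence[5]], "alt_allele": [alt],
             "alt_fraction": [0.5], "depth": [30], "call": [mv.CALL_HET]}
        )
        cons, _ = mv.build_consensus(ref, vt)
        assert cons == ref.sequence

    def test_conflicting_rows_rejected(self, rng):
        ref = make_ref(rng, 400)
        vt = pd.DataFrame(
            {"position": [5, 5], "ref_allele": ["A", "A"], "alt_allele": ["C", "G"],
             "alt_fraction": [1.0, 1.0], "depth": [30, 30], "call": [mv.CALL_VARIANT] * 2}
        )
        with pytest.raises(ValueError):
            mv.build_consensus(ref, vt)

    def test_consensus_roundtrip_recovers_strain_truth(self, unit_panel):
        """simulate -> reads -> map -> call -> consensus reproduces the
        strain's true sequence at 20x error-free coverage."""
        st = sim.StrainSpec("s", "fenestrata", coverage_cp=20, error_rate=0.0, seed=3)
        g = sim.simulate_strain_genomes(unit_panel, st)
        rd = sim.simulate_strain_reads(unit_panel, st, g, include=("cp",))["cp"]
        ref = unit_panel.cp("fenestrata")
        pile = mv.map_reads(rd.r1 + rd.r2, ref)
        vt = mv.call_variants(pile, ref)
        cons, _ = mv.build_consensus(ref, vt)
        assert cons == g.cp.sequence


class TestSnpDensity:
    @pytest.mark.parametrize(
        "n,length,expect",
        [
            (5230, 63775, 82.0),
            (5512, 24854, 222.0),
            (2249, 63775, 35.3),
            (2139, 24854, 86.1),
            (5090, 63775, 79.8),
            (391, 63775, 6.1),
            (140, 24854, 5.6),
            (5836, 63775, 91.5),
            (0, 1000, 0.0),
        ],
    )
    def test_printed_table_densities(self, n, length, expect):
        assert mv.snp_density(n, length) == expect

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            mv.snp_density(1, 0)

    def test_half_up_rounding(self):
        assert mv.snp_density(25, 1000) == 25.0
        assert mv.snp_density(125, 10000) == 12.5
        assert mv.snp_density(1250, 10000) == 125.0


class TestCdsExtraction:
    def test_strand_resolution(self, rng):
        ref = make_ref(rng, 500)
        genes = [Gene("p", 10, 40, "+"), Gene("m", 100, 160, "-")]
        g = CircularGenome("g", ref.sequence, True, genes)
        cds = mv.extract_concat_cds(g)
        assert cds[:30] == ref.sequence[10:40]
        assert cds[30:] == sq.revcomp(ref.sequence[100:160])
        assert len(cds) == mv.CdsSet(genes).total_length

    def test_out_of_range_rejected(self, rng):
        g = make_ref(rng, 100)
        with pytest.raises(ValueError):
            mv.extract_concat_cds(g, mv.CdsSet([Gene("x", 50, 200, "+")]))

    def test_full_annotation_length_invariant(self, unit_panel):
        for sp in unit_panel.spec.species:
            g = unit_panel.cp(sp)
            assert len(mv.extract_concat_cds(g)) == unit_panel.spec.cp_cds_total_bp


class TestStats:
    def test_identical_strains_all_zero(self):
        cons = {"a": "ACGT" * 100, "b": "ACGT" * 100}
        labels = {"a": "x", "b": "x"}
        genes = [Gene("g1", 0, 400, "+")]
        df = mv.interspecific_stats(
            cons, labels, {"x": mv.CdsSet(genes)},
            genomes_by_strain={k: CircularGenome(k, v, True, genes) for k, v in cons.items()},
            reference_species="x",
        )
        assert (df.mean_snps == 0).all() and (df.snps_per_kb == 0).all()

    def test_planted_snp_arithmetic(self, rng):
        """3 planted CDS SNPs over a 1,000 bp CDS -> 3.0 SNPs/kb."""
        base = sq.decode(rng.integers(0, 4, 1500, dtype=np.uint8))
        genes = [Gene("g1", 0, 1000, "+")]
        other = list(base)
        for p in (10, 500, 900):
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        cons = {"r": base, "s": "".join(other)}
        labels = {"r": "ref_sp", "s": "other_sp"}
        df = mv.interspecific_stats(
            {}, labels, {sp: mv.CdsSet(genes) for sp in ("ref_sp", "other_sp")},
            genomes_by_strain={k: CircularGenome(k, v, True, genes) for k, v in cons.items()},
            reference_species="ref_sp",
        )
        row = df[df.species == "other_sp"].iloc[0]
        assert row.mean_snps == 3 and row.snps_per_kb == 3.0

    def test_intraspecific_toy_arithmetic(self, rng):
        """3 strains each with one distinct planted SNP on 10 kb:
        0.1 +/- 0.0 SNPs/kb, 3 total variant sites."""
        base = sq.decode(rng.integers(0, 4, 10_000, dtype=np.uint8))
        strains = {}
        for i, p in enumerate((100, 5000, 9000)):
            s = list(base)
            s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            strains[f"s{i}"] = "".join(s)
        df = mv.intraspecific_stats({"sp": strains})
        row = df.iloc[0]
        assert row.snps_per_kb_mean == pytest.approx(0.1)
        assert row.snps_per_kb_sd == pytest.approx(0.0)
        assert row.total_variant_sites == 3

    def test_single_strain_sd_absent(self):
        df = mv.intraspecific_stats({"sp": {"a": "ACGT" * 50}})
        assert np.isnan(df.iloc[0].snps_per_kb_sd)

    def test_identical_intra_zero(self):
        df = mv.intraspecific_stats({"sp": {"a": "ACGT" * 50, "b": "ACGT" * 50}})
        row = df.iloc[0]
        assert row.snps_per_kb_mean == 0 and row.total_variant_sites == 0


def test_truth_vs_pipeline_density_equivalence(unit_panel):
    """Densities computed from the truth table equal densities computed
    through the error-free read pipeline (oracle equivalence)."""
    sp = "gigantea"
    st = sim.StrainSpec("s", sp, coverage_cp=20, error_rate=0.0, seed=7)
    g = sim.simulate_strain_genomes(unit_panel, st)
    rd = sim.simulate_strain_reads(unit_panel, st, g, include=("cp",))["cp"]
    ref = unit_panel.cp(sp)
    pile = mv.map_reads(rd.r1 + rd.r2, ref)
    vt = mv.call_variants(pile, ref)
    called = set(vt[vt.call == mv.CALL_VARIANT].position.tolist())
    truth_pos = set(
        g.intra_variants[g.intra_variants.compartment == "cp"].pos.tolist()
    )
    assert called == truth_pos


def test_vcf_roundtrip(tmp_path, rng):
    ref = make_ref(rng, 300)
    alt = "A" if ref.sequence[5] != "A" else "C"
    vt = pd.DataFrame(
        {"position": [5], "ref_allele": [ref.sequence[5]], "alt_allele": [alt],
         "alt_fraction": [1.0], "depth": [30], "call": [mv.CALL_VARIANT]}
    )
    path = tmp_path / "x.vcf"
    mv.write_vcf(path, vt, ref.id)
    back = mv.read_vcf(path)
    assert back.position.tolist() == [5]
    assert back.alt_allele.tolist() == [alt]
    assert back.call.tolist() == [mv.CALL_VARIANT]
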