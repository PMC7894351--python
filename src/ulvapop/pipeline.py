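"""End-to-end orchestration: simulate -> assemble -> map/call -> cluster ->
stats -> trees -> synteny -> hybrid verdicts, under one seeded config.

The stage order mirrors the analysis of a wild foliose *Ulva* panel: organelle
references are assembled per species, every strain is mapped and called
against both a single common chloroplast reference (for the SNP matrix and
clustering) and its own species reference (for consensus and statistics),
barcode genes assign species names, distance trees are compared across
markers, chloroplast synteny is screened for the clade-splitting inversion,
and 45S allele frequencies are screened for F1 hybrids.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import assembly as asm
from . import clustering as clus
from . import hybrid as hyb
from . import mapvar as mv
from . import phylo
from . import simulate as sim
from . import synteny as syn
from .genome import CircularGenome, write_genomes_fasta


@dataclass
class PipelineConfig:
    """Every stage parameter with a default; round-trips through JSON."""

    scale: str = "unit"          # "unit" (fast) or "full" (printed sizes)
    seed: int = 0
    n_strains: int = 20
    include_hybrid: bool = True
    coverage_cp: float = 20.0
    coverage_mt: float = 20.0
    coverage_45s: float = 300.0
    error_rate: float = 0.002
    # assembly
    run_assembly: bool = True
    k_filter: int = 21
    k_asm: int = 31
    min_kmer_count: int = 3
    max_iterations: int = 10
    # mapping / calling
    k_seed: int = 15
    min_depth: int = 10
    hom_threshold: float = 0.9
    het_band_low: float = 0.2
    het_band_high: float = 0.8
    # clustering
    cluster_method: str = "inconsistency"
    split_z: float = 4.0
    linkage_gap_factor: float = 5.0
    # trees
    bootstrap_reps: int = 200
    # synteny (unit-scale anchor k chosen for anchor density at ~80 SNPs/kb
    # cross-clade divergence on a ~12 kb genome; full scale uses 31)
    synteny_k: int = 0           # 0 -> per-scale default (17 unit, 31 full)
    synteny_max_gap: int = 2000
    synteny_min_anchors: int = 10
    # hybrid detection
    fixation_threshold: float = 0.95
    nuc_het_low: float = 0.35
    nuc_het_high: float = 0.65
    site_majority: float = 0.9
    hybrid_alpha: float = 0.01
    min_informative_sites: int = 5
    max_minor: float = 0.05
    zero_divergence: bool = False  # debugging preset: all densities zero

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def panel_spec(self) -> sim.SpeciesPanelSpec:
        kw = {}
        if self.zero_divergence:
            n = len(sim.SPECIES)
            kw = dict(
                inter_cp_per_kb=np.zeros((n, n)),
                inter_mt_per_kb=np.zeros((n, n)),
                intra_cp_per_kb={s: 0.0 for s in sim.SPECIES},
                intra_mt_per_kb={s: 0.0 for s in sim.SPECIES},
                r45s_fixed_diffs=0,
                inversion_clade=(),
            )
        if self.scale == "unit":
            return sim.SpeciesPanelSpec.unit_scale(**kw)
        return sim.SpeciesPanelSpec(**kw)

    def effective_synteny_k(self) -> int:
        if self.synteny_k:
            return self.synteny_k
        return 17 if self.scale == "unit" else 31

    def assembly_cfg(self) -> asm.AssemblyConfig:
        return asm.AssemblyConfig(
            k_filter=self.k_filter, k_asm=self.k_asm,
            min_kmer_count=self.min_kmer_count, max_iterations=self.max_iterations,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    panel: sim.Panel
    strain_specs: list[sim.StrainSpec]
    truth_species: dict[str, str]
    clusters: clus.ClusterAssignment
    pca: clus.PcaResult
    species_assignment: dict[str, tuple[list[str], float]]
    inter_cp: pd.DataFrame
    inter_mt: pd.DataFrame
    intra_cp: pd.DataFrame
    intra_mt: pd.DataFrame
    tree_agreements: dict[str, dict]
    inversions_cp: list[dict]
    inversions_mt: list[dict]
    clade_partition: dict[str, int]
    hybrid_reports: list[hyb.HybridReport]
    hybrid_summary: pd.DataFrame
    assembly: asm.AssemblyResult | None
    hybrid_pca_position: dict | None

    @property
    def n_f1(self) -> int:
        return sum(1 for r in self.hybrid_reports if r.verdict == hyb.VERDICT_F1)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage; deterministic given ``config.seed``.  When ``outdir``
    is given, stage outputs and a summary are written there."""
    panel = sim.simulate_panel(config.panel_spec(), config.seed)
    strains = sim.default_strain_table(
        panel, config.n_strains, hybrid=config.include_hybrid, seed=config.seed,
        coverage_cp=config.coverage_cp, coverage_mt=config.coverage_mt,
        coverage_45s=config.coverage_45s, error_rate=config.error_rate,
    )
    truth_species = {
        s.strain_id: (s.cytoplasm_donor if s.is_hybrid else s.species_id) for s in strains
    }
    ref_sp = panel.reference_species
    common_cp = panel.cp(ref_sp)
    r45s_ref = CircularGenome("r45s_ref", panel.r45s(ref_sp), circular=True)

    genomes = {s.strain_id: sim.simulate_strain_genomes(panel, s) for s in strains}
    reads = {s.strain_id: sim.simulate_strain_reads(panel, s, genomes[s.strain_id]) for s in strains}

    # --- optional assembly round-trip on one strain ---------------------
    assembly_result = None
    if config.run_assembly:
        first = strains[0]
        rs = reads[first.strain_id]["cp"]
        assembly_result = asm.iterative_assemble(
            rs.r1, rs.r2, [panel.cp(first.species_id).sequence], config.assembly_cfg()
        )

    # --- mapping and calling --------------------------------------------
    het_band = (config.het_band_low, config.het_band_high)
    variant_tables_common: dict[str, pd.DataFrame] = {}
    cons_cp: dict[str, CircularGenome] = {}
    cons_mt: dict[str, CircularGenome] = {}
    piles_cp: dict[str, mv.Pileup] = {}
    piles_mt: dict[str, mv.Pileup] = {}
    piles_45s: dict[str, mv.Pileup] = {}
    cons_45s: dict[str, str] = {}
    for s in strains:
        sid = s.strain_id
        sp = truth_species[sid]
        rd = reads[sid]
        all_cp = rd["cp"].r1 + rd["cp"].r2
        # common reference: SNP matrix substrate
        pile_common = mv.map_reads(all_cp, common_cp, k_seed=config.k_seed)
        variant_tables_common[sid] = mv.call_variants(
            pile_common, common_cp, config.min_depth, config.hom_threshold, het_band
        )
        # own-species references: consensus + stats + homoplasmy
        own_cp = panel.cp(sp)
        pile_cp = pile_common if sp == ref_sp else mv.map_reads(all_cp, own_cp, k_seed=config.k_seed)
        piles_cp[sid] = pile_cp
        vt = mv.call_variants(pile_cp, own_cp, config.min_depth, config.hom_threshold, het_band)
        cseq, _ = mv.build_consensus(own_cp, vt)
        cons_cp[sid] = CircularGenome(f"{sid}_cp", cseq, True, list(own_cp.annotation))
        own_mt = panel.mt(sp)
        all_mt = rd["mt"].r1 + rd["mt"].r2
        pile_mt = mv.map_reads(all_mt, own_mt, k_seed=config.k_seed)
        piles_mt[sid] = pile_mt
        vt_mt = mv.call_variants(pile_mt, own_mt, config.min_depth, config.hom_threshold, het_band)
        mseq, _ = mv.build_consensus(own_mt, vt_mt)
        cons_mt[sid] = CircularGenome(f"{sid}_mt", mseq, True, list(own_mt.annotation))
        # 45S on the common nuclear reference locus
        all_45 = rd["r45s"].r1 + rd["r45s"].r2
        pile_45 = mv.map_reads(all_45, r45s_ref, k_seed=config.k_seed)
        piles_45s[sid] = pile_45
        vt_45 = mv.call_variants(pile_45, r45s_ref, config.min_depth, config.hom_threshold, het_band)
        cons_45s[sid], _ = mv.build_consensus(r45s_ref, vt_45)

    # --- clustering on the common-reference SNP matrix ------------------
    snp_matrix = clus.build_snp_matrix(variant_tables_common)
    pca_res = clus.pca(snp_matrix, n_components=min(5, len(strains) - 1))
    clusters = clus.delimit_clusters(
        snp_matrix, method=config.cluster_method,
        split_z=config.split_z, linkage_gap_factor=config.linkage_gap_factor,
    )

    # --- barcode species assignment -------------------------------------
    barcode_panel = {
        sp: panel.cp(sp).gene_sequence("rbcL") + panel.cp(sp).gene_sequence("tufA")
        for sp in panel.spec.species
    }
    species_assignment: dict[str, tuple[list[str], float]] = {}
    org_species: dict[str, str] = {}
    for sid, g in cons_cp.items():
        bc = g.gene_sequence("rbcL") + g.gene_sequence("tufA")
        labels, ident = clus.assign_species(bc, barcode_panel)
        species_assignment[sid] = (labels, ident)
        org_species[sid] = labels[0]
    for cluster_id in range(1, clusters.n_clusters + 1):
        members = clusters.members(cluster_id)
        if members:
            clusters.species_names[cluster_id] = org_species[members[0]]

    # --- Table 3/4 style statistics --------------------------------------
    cds_by_species = {sp: mv.CdsSet.from_genome(panel.cp(sp)) for sp in panel.spec.species}
    cds_mt_by_species = {sp: mv.CdsSet.from_genome(panel.mt(sp)) for sp in panel.spec.species}
    inter_cp = mv.interspecific_stats(
        {}, org_species, cds_by_species, genomes_by_strain=cons_cp, reference_species=ref_sp
    )
    inter_mt = mv.interspecific_stats(
        {}, org_species, cds_mt_by_species, genomes_by_strain=cons_mt, reference_species=ref_sp
    )
    pure_ids = [s.strain_id for s in strains if not s.is_hybrid]
    by_species_cp = _group_by_species({k: v.sequence for k, v in cons_cp.items() if k in pure_ids}, org_species)
    by_species_mt = _group_by_species({k: v.sequence for k, v in cons_mt.items() if k in pure_ids}, org_species)
    intra_cp = mv.intraspecific_stats(by_species_cp)
    intra_mt = mv.intraspecific_stats(by_species_mt)

    # --- trees across markers --------------------------------------------
    marker_seqs: dict[str, dict[str, str]] = {"rbcl": {}, "tufa": {}, "cds": {}, "45s": {}}
    for sid in cons_cp:
        marker_seqs["rbcl"][sid] = cons_cp[sid].gene_sequence("rbcL")
        marker_seqs["tufa"][sid] = cons_cp[sid].gene_sequence("tufA")
        marker_seqs["cds"][sid] = mv.extract_concat_cds(cons_cp[sid]) + mv.extract_concat_cds(cons_mt[sid])
        marker_seqs["45s"][sid] = cons_45s[sid]
    trees = {}
    for marker, seqs in marker_seqs.items():
        if len(set(seqs.values())) < 2:
            trees[marker] = None
            continue
        if config.bootstrap_reps > 0:
            trees[marker] = phylo.bootstrap_support(seqs, n_reps=config.bootstrap_reps, seed=config.seed + 7)
        else:
            trees[marker] = phylo.nj_tree(phylo.pairwise_distances(seqs))
    tree_agreements = {}
    pure_labels = {sid: org_species[sid] for sid in pure_ids}
    for marker in ("rbcl", "tufa", "45s"):
        if trees[marker] is not None and trees["cds"] is not None:
            tree_agreements[f"{marker}_vs_cds"] = phylo.tree_agreement(
                trees[marker], trees["cds"], species_labels=pure_labels
            )

    # --- synteny ----------------------------------------------------------
    k_syn = config.effective_synteny_k()
    inversions_cp: list[dict] = []
    inversions_mt: list[dict] = []
    clade_partition: dict[str, int] = {ref_sp: 0}
    for sp in panel.spec.species:
        if sp == ref_sp:
            continue
        _, inv_cp = syn.compare_genomes(
            panel.cp(ref_sp), panel.cp(sp), k=k_syn,
            max_gap=config.synteny_max_gap, min_anchors=config.synteny_min_anchors,
        )
        clade_partition[sp] = 1 if inv_cp else 0
        inversions_cp.extend({"species": sp, **d} for d in inv_cp)
        _, inv_mt = syn.compare_genomes(
            panel.mt(ref_sp), panel.mt(sp), k=k_syn,
            max_gap=config.synteny_max_gap, min_anchors=config.synteny_min_anchors,
        )
        inversions_mt.extend({"species": sp, **d} for d in inv_mt)

    # --- hybrid detection -------------------------------------------------
    hybrid_reports, hybrid_summary, hybrid_pca_position = _hybrid_stage(
        config, panel, strains, org_species, cons_45s, piles_45s, piles_cp, piles_mt,
        cons_cp, cons_mt, pure_ids,
    )

    result = PipelineResult(
        config=config, panel=panel, strain_specs=strains, truth_species=truth_species,
        clusters=clusters, pca=pca_res, species_assignment=species_assignment,
        inter_cp=inter_cp, inter_mt=inter_mt, intra_cp=intra_cp, intra_mt=intra_mt,
        tree_agreements=tree_agreements, inversions_cp=inversions_cp,
        inversions_mt=inversions_mt, clade_partition=clade_partition,
        hybrid_reports=hybrid_reports, hybrid_summary=hybrid_summary,
        assembly=assembly_result, hybrid_pca_position=hybrid_pca_position,
    )
    if outdir is not None:
        write_run_outputs(result, Path(outdir))
    return result


def _group_by_species(seqs: Mapping[str, str], labels: Mapping[str, str]) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for sid, s in seqs.items():
        out.setdefault(labels[sid], {})[sid] = s
    return {sp: d for sp, d in out.items() if d}


def _species_45s_consensus(cons_45s, org_species, pure_ids):
    grouped = _group_by_species({k: v for k, v in cons_45s.items() if k in pure_ids}, org_species)
    return {sp: mv._majority_consensus(list(d.values()))[0] for sp, d in grouped.items()}


def _hybrid_stage(
    config, panel, strains, org_species, cons_45s, piles_45s, piles_cp, piles_mt,
    cons_cp, cons_mt, pure_ids,
):
    sp_45s = _species_45s_consensus(cons_45s, org_species, pure_ids)
    # nearest-other species per species by 45S consensus distance
    species_list = [sp for sp in panel.spec.species if sp in sp_45s]
    nearest: dict[str, str] = {}
    for a in species_list:
        best, bd = None, None
        ea = np.frombuffer(sp_45s[a].encode(), dtype=np.uint8)
        for b in species_list:
            if b == a:
                continue
            eb = np.frombuffer(sp_45s[b].encode(), dtype=np.uint8)
            d = int(np.count_nonzero(ea != eb))
            if bd is None or d < bd:
                best, bd = b, d
        nearest[a] = best
    # nuclear nearest species per strain (45S consensus identity)
    nuc_species = {}
    for sid, cseq in cons_45s.items():
        labels, _ = clus.assign_species(cseq, sp_45s)
        nuc_species[sid] = labels[0]
    # species-level organelle consensuses (data-derived) for homoplasmy checks
    sp_cons_cp = {
        sp: mv._majority_consensus([cons_cp[s].sequence for s in pure_ids if org_species[s] == sp])[0]
        for sp in species_list
    }
    sp_cons_mt = {
        sp: mv._majority_consensus([cons_mt[s].sequence for s in pure_ids if org_species[s] == sp])[0]
        for sp in species_list
    }
    # informative sites cache per (A, B) pair, with pooled fixation evidence
    site_cache: dict[tuple[str, str], list[hyb.InformativeSite]] = {}

    def informative(a: str, b: str):
        key = (a, b)
        if key not in site_cache:
            piles_a = [piles_45s[s] for s in pure_ids if org_species[s] == a]
            piles_b = [piles_45s[s] for s in pure_ids if org_species[s] == b]
            site_cache[key] = hyb.find_informative_sites(
                sp_45s[a], sp_45s[b], piles_a, piles_b,
                fixation_threshold=config.fixation_threshold, min_depth=config.min_depth,
            )
        return site_cache[key]

    inputs = []
    profiles = {}
    pair_of = {}
    for s in strains:
        sid = s.strain_id
        a = org_species[sid]
        b = nuc_species[sid] if nuc_species[sid] != a else nearest[a]
        if b is None:  # single-species panel: no partner to test against
            inputs.append(
                dict(strain_id=sid, nuclear_call=hyb.NUC_AMBIGUOUS, cp_call=hyb.VERDICT_AMBIGUOUS,
                     mt_call=hyb.VERDICT_AMBIGUOUS, cp_homoplasmic=False, mt_homoplasmic=False,
                     detail={"reason": "no partner species"})
            )
            continue
        pair_of[sid] = (a, b)
        sites = informative(a, b)
        profile = hyb.allele_profile(piles_45s[sid], sites, sid, min_depth=config.min_depth)
        profiles[sid] = profile
        nuclear_call, detail = hyb.classify_nuclear(
            profile, (config.nuc_het_low, config.nuc_het_high),
            config.site_majority, config.hybrid_alpha, config.min_informative_sites,
        )
        try:
            cp_call, cp_homo = hyb.check_homoplasmy(
                piles_cp[sid], sp_cons_cp[a], sp_cons_cp[b], config.max_minor, config.min_depth
            )
            mt_call, mt_homo = hyb.check_homoplasmy(
                piles_mt[sid], sp_cons_mt[a], sp_cons_mt[b], config.max_minor, config.min_depth
            )
        except ValueError:  # no diagnostic sites (e.g. zero-divergence panel)
            cp_call = mt_call = hyb.VERDICT_AMBIGUOUS
            cp_homo = mt_homo = False
        detail.update(pair=(a, b))
        inputs.append(
            dict(strain_id=sid, nuclear_call=nuclear_call, cp_call=cp_call, mt_call=mt_call,
                 cp_homoplasmic=cp_homo, mt_homoplasmic=mt_homo, detail=detail)
        )
    reports, summary = hyb.call_hybrids(inputs)

    # allele-frequency PCA position of any F1 relative to parental clusters
    hybrid_pca_position = None
    f1 = [r for r in reports if r.verdict == hyb.VERDICT_F1]
    if f1:
        sid = f1[0].strain_id
        a, b = pair_of[sid]
        sites = informative(a, b)
        members = [sid] + [x for x in pure_ids if org_species[x] in (a, b)]
        mat = np.full((len(members), len(sites)), np.nan)
        for i, x in enumerate(members):
            # profiles must share the (a, b) allele polarity, so recompute
            prof = hyb.allele_profile(piles_45s[x], sites, x, min_depth=config.min_depth)
            mat[i] = prof.freq_a
        mat = np.nan_to_num(mat, nan=0.5)
        sm = clus.SnpMatrix(members, np.arange(len(sites)), mat)
        if len(sites) and len(members) >= 3:
            p = clus.pca(sm, n_components=1)
            coords = p.coordinates[:, 0]
            ca = np.mean([coords[i] for i, x in enumerate(members) if x != sid and org_species[x] == a])
            cb = np.mean([coords[i] for i, x in enumerate(members) if x != sid and org_species[x] == b])
            hybrid_pca_position = {
                "strain": sid, "coord": float(coords[0]),
                "centroid_a": float(ca), "centroid_b": float(cb),
                "between": bool(min(ca, cb) < coords[0] < max(ca, cb)),
            }
    return reports, summary, hybrid_pca_position


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------


def write_run_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def save(name: str, text: str) -> None:
        p = outdir / name
        p.write_text(text)
        log.append({"file": name, "sha256": hashlib.sha256(text.encode()).hexdigest()})

    save("config.json", result.config.to_json())
    write_genomes_fasta(outdir / "species_cp.fasta", [result.panel.cp(s) for s in result.panel.spec.species])
    write_genomes_fasta(outdir / "species_mt.fasta", [result.panel.mt(s) for s in result.panel.spec.species])
    save("clusters.tsv", _clusters_tsv(result))
    save("pca.tsv", result.pca.frame().to_csv(sep="\t"))
    save("species_assignment.tsv", _assignment_tsv(result))
    save("inter_cp.tsv", result.inter_cp.to_csv(sep="\t", index=False))
    save("inter_mt.tsv", result.inter_mt.to_csv(sep="\t", index=False))
    save("intra_cp.tsv", result.intra_cp.to_csv(sep="\t", index=False))
    save("intra_mt.tsv", result.intra_mt.to_csv(sep="\t", index=False))
    save("inversions_cp.tsv", pd.DataFrame(result.inversions_cp).to_csv(sep="\t", index=False))
    save("inversions_mt.tsv", pd.DataFrame(result.inversions_mt).to_csv(sep="\t", index=False))
    save("hybrid_reports.tsv", _hybrid_tsv(result))
    save("summary.md", summary_markdown(result))
    (outdir / "run_log.jsonl").write_text("\n".join(json.dumps(e, sort_keys=True) for e in log) + "\n")


def _clusters_tsv(result: PipelineResult) -> str:
    rows = [
        {"strain": s, "cluster": c, "species": result.clusters.species_names.get(c, "")}
        for s, c in result.clusters.labels.items()
    ]
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def _assignment_tsv(result: PipelineResult) -> str:
    rows = [
        {"strain": sid, "species": "|".join(labels), "identity": f"{ident:.4f}"}
        for sid, (labels, ident) in result.species_assignment.items()
    ]
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def _hybrid_tsv(result: PipelineResult) -> str:
    rows = [
        {
            "strain": r.strain_id, "nuclear_call": r.nuclear_call, "cp_call": r.cp_call,
            "mt_call": r.mt_call, "cp_homoplasmic": r.cp_homoplasmic,
            "mt_homoplasmic": r.mt_homoplasmic, "verdict": r.verdict,
        }
        for r in result.hybrid_reports
    ]
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def summary_markdown(result: PipelineResult) -> str:
    lines = ["# Run summary", ""]
    lines.append(f"- strains: {len(result.strain_specs)}")
    lines.append(f"- clusters found: {result.clusters.n_clusters}")
    lines.append(f"- F1 hybrids called: {result.n_f1}")
    lines.append(f"- chloroplast inversions: {len(result.inversions_cp)}")
    lines.append(f"- mitochondrial inversions: {len(result.inversions_mt)}")
    if result.assembly is not None:
        lines.append(
            f"- assembly: converged={result.assembly.converged} "
            f"iterations={result.assembly.iterations_used}"
        )
    for name, agr in result.tree_agreements.items():
        lines.append(f"- tree agreement {name}: RF={agr['rf']} normalized_agreement={agr['normalized_agreement']:.3f}")
    if result.hybrid_pca_position:
        hp = result.hybrid_pca_position
        lines.append(
            f"- hybrid {hp['strain']} allele-frequency PC1 {hp['coord']:.3f} between parental "
            f"centroids ({hp['centroid_a']:.3f}, {hp['centroid_b']:.3f}): {hp['between']}"
        )
    lines.append("")
    lines.append("## Inter-specific SNP density vs reference species (chloroplast CDS)")
    lines.append(result.inter_cp.to_string(index=False))
    lines.append("")
    lines.append("## Intra-specific variation (chloroplast)")
    lines.append(result.intra_cp.to_string(index=False))
    lines.append("")
    return "\n".join(lines)
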