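"""Synthetic sequencing-study generator for foliose Ulva organellar genomics.

Emulates the statistical structure of a six-species foliose *Ulva* panel:
circular chloroplast and mitochondrial genomes on a shared coordinate system,
inter-specific substitution densities on the scale observed between the six
species (up to ~90 chloroplast and ~220 mitochondrial SNPs/kb of coding
sequence), low intra-specific densities (0.03-2 SNPs/kb), a clade-splitting
chloroplast inversion, a multi-copy nuclear 45S rDNA unit with fixed
inter-specific differences, one F1 hybrid strain (heterozygous 45S pool,
uniparental organelles), and Illumina-like 150 bp paired-end reads.

The mutation model is substitution-only (Jukes-Cantor along an additive tree
fitted to the requested density matrix), which keeps every strain and species
on one coordinate frame -- the assumption the downstream ungapped mapper and the
shared-CDS statistics rely on.  The single structural event, the chloroplast
inversion, is applied after substitution and transplants the gene annotation
(coordinates mirrored, strands flipped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import seq as sq
from .genome import CircularGenome, Gene

SPECIES = (
    "laetevirens",
    "rigida",
    "gigantea",
    "australis",
    "fenestrata",
    "pseudorotundata",
)

# Observed inter-specific SNP densities (per kb) of each species against the
# U. laetevirens reference, chloroplast and mitochondrial coding sequence.
_INTER_CP_VS_REF = {"rigida": 6.1, "gigantea": 35.3, "australis": 82.0, "fenestrata": 79.8, "pseudorotundata": 91.5}
_INTER_MT_VS_REF = {"rigida": 5.6, "gigantea": 86.1, "australis": 196.0, "fenestrata": 194.0, "pseudorotundata": 222.0}

# Mean intra-specific SNPs/kb per strain against the species consensus.
_INTRA_CP = {"australis": 1.98, "fenestrata": 0.12, "pseudorotundata": 0.09, "gigantea": 0.38, "rigida": 0.18, "laetevirens": 1.14}
_INTRA_MT = {"australis": 1.05, "fenestrata": 0.05, "pseudorotundata": 0.04, "gigantea": 0.26, "rigida": 0.03, "laetevirens": 1.36}

INVERSION_CLADE = ("australis", "fenestrata", "pseudorotundata")


def jc_expected_mismatch(d: float) -> float:
    """Expected observed per-site mismatch fraction at JC69 distance ``d``."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def jc_distance(p: float) -> float:
    """JC69 distance from an observed mismatch fraction ``p`` (< 0.75)."""
    if p >= 0.75:
        raise ValueError(f"mismatch fraction {p} is saturated under JC69")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _star_matrix(vs_ref_per_kb: dict[str, float], species: Sequence[str]) -> np.ndarray:
    """Full symmetric observed-density matrix implied by a star tree centred
    on the reference species (the first entry of ``species``)."""
    t = np.array([jc_distance(vs_ref_per_kb.get(s, 0.0) / 1000.0) for s in species])
    n = len(species)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = 1000.0 * jc_expected_mismatch(t[i] + t[j])
    return m


def _two_clade_matrix(vs_ref_per_kb: dict[str, float]) -> np.ndarray:
    """Observed-density matrix implied by the resolved two-clade species tree
    ((laetevirens, rigida), gigantea | pseudorotundata, (fenestrata,
    australis)), with leaf distances to the reference species calibrated to
    the observed densities and internal branches a fixed fraction of the
    relevant divergence scale."""
    D = {s: jc_distance(vs_ref_per_kb.get(s, 0.0) / 1000.0) for s in SPECIES}
    a_l = a_r = D["rigida"] / 2.0
    e1 = 0.1 * D["gigantea"]
    b_g = D["gigantea"] - a_l - e1
    # internal-branch shares large enough that every internal edge carries a
    # recoverable number of substitutions even on the shortest barcode
    dmin = min(D["australis"], D["fenestrata"], D["pseudorotundata"])
    e2, e3 = 0.15 * dmin, 0.08 * dmin
    c_p = D["pseudorotundata"] - a_l - e1 - e2
    c_f = D["fenestrata"] - a_l - e1 - e2 - e3
    c_a = D["australis"] - a_l - e1 - e2 - e3
    if min(b_g, c_p, c_f, c_a) < 0:
        return _star_matrix(vs_ref_per_kb, SPECIES)
    # internal nodes: X=(laet,rigida), Y=(X,gig), W=(Y,pseudo,V), V=(fen,aus)
    edges = {
        ("laetevirens", "X"): a_l, ("rigida", "X"): a_r, ("X", "Y"): e1,
        ("gigantea", "Y"): b_g, ("Y", "W"): e2, ("pseudorotundata", "W"): c_p,
        ("W", "V"): e3, ("fenestrata", "V"): c_f, ("australis", "V"): c_a,
    }
    adj: dict[str, dict[str, float]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def path(u: str, v: str) -> float:
        stack = [(u, None, 0.0)]
        while stack:
            cur, par, d = stack.pop()
            if cur == v:
                return d
            for nxt, w in adj[cur].items():
                if nxt != par:
                    stack.append((nxt, cur, d + w))
        raise RuntimeError

    n = len(SPECIES)
    m = np.zeros((n, n))
    for i, a in enumerate(SPECIES):
        for j, b in enumerate(SPECIES):
            if i != j:
                m[i, j] = 1000.0 * jc_expected_mismatch(path(a, b))
    return m


def default_inter_matrix(compartment: str, species: Sequence[str] = SPECIES) -> np.ndarray:
    ref = {"cp": _INTER_CP_VS_REF, "mt": _INTER_MT_VS_REF}[compartment]
    if tuple(species) == SPECIES:
        return _two_clade_matrix(ref)
    return _star_matrix(ref, species)


@dataclass
class SpeciesPanelSpec:
    """Parameters of a simulated species panel.

    Default values reproduce the study conditions at full printed scale:
    genome sizes from the reference species' rows of the annotation summaries
    (chloroplast 103,444 bp, mitochondrion 79,723 bp), common CDS sets of 69
    genes / 63,775 bp (chloroplast) and 29 genes / 24,854 bp (mitochondrion),
    inter-specific densities on the Table-3 scale, intra-specific densities on
    the Table-4 scale, a ~5 kb 45S unit at >=100 copies with 65 fixed
    differences for the most diverged pair, and the chloroplast inversion
    carried by the australis/fenestrata/pseudorotundata clade.
    ``unit_scale()`` gives a 10-20x smaller preset for fast end-to-end runs.
    """

    species: tuple[str, ...] = SPECIES
    cp_length_bp: int = 103_444
    mt_length_bp: int = 79_723
    r45s_length_bp: int = 5_000
    r45s_copy_number: int = 500
    cp_n_genes: int = 69
    cp_cds_total_bp: int = 63_775
    mt_n_genes: int = 29
    mt_cds_total_bp: int = 24_854
    barcode_lengths: tuple[int, int] = (1_428, 1_230)  # rbcL-like, tufA-like
    inter_cp_per_kb: np.ndarray | None = None
    inter_mt_per_kb: np.ndarray | None = None
    intra_cp_per_kb: dict[str, float] = field(default_factory=lambda: dict(_INTRA_CP))
    intra_mt_per_kb: dict[str, float] = field(default_factory=lambda: dict(_INTRA_MT))
    r45s_fixed_diffs: int = 65          # target count for the most diverged pair
    r45s_floor_per_kb: float = 3.0      # per-branch 45S divergence floor (see methods)
    inversion_clade: tuple[str, ...] = INVERSION_CLADE
    inversion_span: tuple[float, float] = (0.45, 0.80)  # fraction of cp gene list
    cds_bias: float = 1.0

    def __post_init__(self):
        if self.inter_cp_per_kb is None:
            self.inter_cp_per_kb = default_inter_matrix("cp", self.species)
        if self.inter_mt_per_kb is None:
            self.inter_mt_per_kb = default_inter_matrix("mt", self.species)
        self.inter_cp_per_kb = np.asarray(self.inter_cp_per_kb, dtype=float)
        self.inter_mt_per_kb = np.asarray(self.inter_mt_per_kb, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.species)
        for name, m in (("inter_cp_per_kb", self.inter_cp_per_kb), ("inter_mt_per_kb", self.inter_mt_per_kb)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} must have a zero diagonal")
            if np.any(m < 0):
                raise ValueError(f"{name} must be non-negative")
            if np.any(m > 1000):
                raise ValueError(f"{name}: densities > 1000/kb are saturated")
        for d in (self.intra_cp_per_kb, self.intra_mt_per_kb):
            if any(v < 0 for v in d.values()):
                raise ValueError("intra densities must be >= 0")
        unknown = set(self.inversion_clade) - set(self.species)
        if unknown:
            raise ValueError(f"inversion clade species not in panel: {unknown}")
        lo, hi = self.inversion_span
        if not (0 < lo < hi <= 1):
            raise ValueError("inversion_span must satisfy 0 < lo < hi <= 1")

    @classmethod
    def unit_scale(cls, **overrides) -> "SpeciesPanelSpec":
        """Scaled-down preset (~12 kb chloroplast) for fast end-to-end runs."""
        defaults = dict(
            cp_length_bp=12_000,
            mt_length_bp=8_000,
            r45s_length_bp=2_500,
            cp_n_genes=12,
            cp_cds_total_bp=7_400,
            mt_n_genes=6,
            mt_cds_total_bp=2_500,
            barcode_lengths=(900, 800),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class StrainSpec:
    """One sequenced strain: species of origin, coverages, error model, seed."""

    strain_id: str
    species_id: str
    is_hybrid: bool = False
    hybrid_parents: tuple[str, str] | None = None  # (parent_A, parent_B), nuclear
    cytoplasm_donor: str | None = None             # must be one of hybrid_parents
    coverage_cp: float = 20.0
    coverage_mt: float = 20.0
    coverage_45s: float = 1000.0
    read_length: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    error_rate: float = 0.002
    r45s_parent_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.is_hybrid != (self.hybrid_parents is not None):
            raise ValueError("hybrid_parents must be set iff is_hybrid")
        if self.is_hybrid:
            if self.cytoplasm_donor not in self.hybrid_parents:
                raise ValueError("cytoplasm_donor must be one of hybrid_parents")
        if min(self.coverage_cp, self.coverage_mt, self.coverage_45s) <= 0:
            raise ValueError("coverages must be > 0")


@dataclass
class Panel:
    """A realized species panel: genomes, truth table, fitted branch lengths."""

    spec: SpeciesPanelSpec
    genomes: dict[str, dict[str, object]]  # species -> {"cp","mt": CircularGenome, "r45s": str}
    truth: pd.DataFrame
    branch_lengths: dict[str, np.ndarray]
    inversion: tuple[int, int] | None
    seed: int

    @property
    def reference_species(self) -> str:
        return self.spec.species[0]

    def cp(self, species: str) -> CircularGenome:
        return self.genomes[species]["cp"]

    def mt(self, species: str) -> CircularGenome:
        return self.genomes[species]["mt"]

    def r45s(self, species: str) -> str:
        return self.genomes[species]["r45s"]

    def variant_sites(self, compartment: str, a: str, b: str) -> np.ndarray:
        """Positions at which species a and b differ (pre-inversion frame for cp)."""
        t = self.truth
        sub = t[t.compartment == compartment]
        da = sub[sub.species == a].set_index("pos").alt_base
        db = sub[sub.species == b].set_index("pos").alt_base
        ref_only_a = da.index.difference(db.index)
        ref_only_b = db.index.difference(da.index)
        both = da.index.intersection(db.index)
        diff_both = both[da.loc[both].values != db.loc[both].values]
        return np.sort(np.concatenate([ref_only_a, ref_only_b, diff_both]).astype(int))


@dataclass
class StrainGenomes:
    """Realized genomes of one strain (organelles + 45S copy pool)."""

    strain_id: str
    cp: CircularGenome
    mt: CircularGenome
    r45s_copies: list[tuple[str, int]]  # (haplotype sequence, copy count)
    intra_variants: pd.DataFrame
    parent_a_copy_fraction: float | None = None

    @property
    def r45s_total_copies(self) -> int:
        return sum(c for _, c in self.r45s_copies)


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------


def _fit_tree(matrix_per_kb: np.ndarray, species: Sequence[str]):
    """Fit an additive tree (neighbor joining on JC-corrected distances)
    reproducing the requested observed-density matrix; exact for matrices
    that are tree-additive (the defaults are, by construction)."""
    from . import phylo

    n = len(species)
    J = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jc_distance(matrix_per_kb[i, j] / 1000.0)
    if n == 1:
        return phylo.Phylogeny({0: {}}, {0: species[0]})
    if n == 2:
        return phylo.Phylogeny({0: {1: J[0, 1]}, 1: {0: J[0, 1]}}, {0: species[0], 1: species[1]})
    return phylo.nj_tree(phylo.DistanceMatrix(list(species), J))


def _scaled_tree(tree, scale: float, leaf_floor: float = 0.0):
    """Copy of a tree with branch lengths scaled; leaf branches floored."""
    from . import phylo

    adj = {
        u: {
            v: max(ln * scale, leaf_floor) if (u in tree.leaf_names or v in tree.leaf_names) else ln * scale
            for v, ln in nbrs.items()
        }
        for u, nbrs in tree.adj.items()
    }
    return phylo.Phylogeny(adj, dict(tree.leaf_names))


def _simulate_along_tree(tree, length: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve a random root sequence down the tree under JC69; returns one
    code array per leaf.  Deterministic given the rng state (children visited
    in sorted node order)."""
    root = min(tree.adj)
    seqs: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 4, length, dtype=np.uint8)
    stack = [(root, -1, root_seq)]
    while stack:
        node, parent, s = stack.pop()
        if node in tree.leaf_names:
            seqs[tree.leaf_names[node]] = s
        for nbr in sorted(tree.adj[node], reverse=True):
            if nbr != parent:
                stack.append((nbr, node, _evolve(s, tree.adj[node][nbr], rng)))
    return seqs


def _evolve(root: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One JC69 branch: per-site substitution with the exact mismatch
    probability for distance ``t``, uniform over the three other bases."""
    p = jc_expected_mismatch(t)
    out = root.copy()
    hit = rng.random(root.size) < p
    k = int(hit.sum())
    if k:
        out[hit] = (out[hit] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
    return out


def _build_annotation(length: int, n_genes: int, cds_total: int, named: Sequence[tuple[str, int]] = ()) -> list[Gene]:
    """Evenly spaced, non-overlapping genes with alternating strands.

    ``named`` entries (e.g. barcode genes) come first with fixed lengths; the
    remaining genes split the rest of the CDS budget as evenly as possible.
    Annotation list order is gene-id order and is identical across species,
    which makes gene-wise CDS concatenation comparable between genomes.
    """
    if cds_total >= length:
        raise ValueError("CDS total must be smaller than genome length")
    named_total = sum(l for _, l in named)
    n_rest = n_genes - len(named)
    if n_rest < 0 or (n_rest == 0 and named_total != cds_total):
        raise ValueError("inconsistent gene budget")
    lengths = [l for _, l in named]
    if n_rest:
        base, extra = divmod(cds_total - named_total, n_rest)
        if base < 1:
            raise ValueError("CDS budget too small for gene count")
        lengths += [base + (1 if i < extra else 0) for i in range(n_rest)]
    names = [n for n, _ in named] + [f"g{i:03d}" for i in range(1, n_rest + 1)]
    spacer, extra_sp = divmod(length - cds_total, n_genes + 1)
    genes = []
    pos = spacer + extra_sp
    for i, (name, glen) in enumerate(zip(names, lengths)):
        genes.append(Gene(name, pos, pos + glen, "+" if i % 2 == 0 else "-"))
        pos += glen + spacer
    return genes


def _inversion_interval(genes: list[Gene], length: int, span: tuple[float, float]) -> tuple[int, int]:
    """Inversion breakpoints placed in intergenic gaps flanking a run of genes."""
    order = sorted(genes, key=lambda g: g.start)
    n = len(order)
    i0 = max(1, int(span[0] * n))
    i1 = min(n - 1, int(span[1] * n)) - 1
    if i1 <= i0:
        raise ValueError("inversion span selects no genes")
    start = (order[i0 - 1].end + order[i0].start) // 2
    end = (order[i1].end + (order[i1 + 1].start if i1 + 1 < n else length)) // 2
    return start, end


def apply_inversion(codes: np.ndarray, genes: list[Gene], start: int, end: int) -> tuple[np.ndarray, list[Gene]]:
    """Reverse-complement ``[start, end)`` and transplant annotations.

    Genes fully inside the segment are mirrored and strand-flipped; genes must
    not straddle a breakpoint.  The returned gene list keeps the original
    (gene-id) order.
    """
    out = codes.copy()
    out[start:end] = sq.revcomp_codes(codes[start:end])
    new = []
    for g in genes:
        if g.end <= start or g.start >= end:
            new.append(g)
        elif g.start >= start and g.end <= end:
            new.append(Gene(g.gene_id, start + end - g.end, start + end - g.start, "-" if g.strand == "+" else "+"))
        else:
            raise ValueError(f"gene {g.gene_id} straddles an inversion breakpoint")
    return out, new


def simulate_panel(spec: SpeciesPanelSpec, seed: int) -> Panel:
    """Simulate species reference genomes plus a truth table of all variants.

    Sequences evolve site-by-site under JC69 along a star tree fitted to the
    requested observed-density matrices, so realized pairwise divergences
    match the request in expectation for every species pair.  The chloroplast
    inversion is applied afterwards to the inversion clade; substitution truth
    is recorded on the shared pre-inversion frame.
    """
    rng_root, rng_cp, rng_mt, rng_45 = [
        np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(4)
    ]
    species = spec.species
    cp_named = [("rbcL", spec.barcode_lengths[0]), ("tufA", spec.barcode_lengths[1])]
    cp_genes = _build_annotation(spec.cp_length_bp, spec.cp_n_genes, spec.cp_cds_total_bp, cp_named)
    mt_genes = _build_annotation(spec.mt_length_bp, spec.mt_n_genes, spec.mt_cds_total_bp)
    inv = _inversion_interval(cp_genes, spec.cp_length_bp, spec.inversion_span) if spec.inversion_clade else None

    tree_cp = _fit_tree(spec.inter_cp_per_kb, species)
    tree_mt = _fit_tree(spec.inter_mt_per_kb, species)
    tree_45 = _r45s_tree(spec, tree_cp)

    lengths = {"cp": spec.cp_length_bp, "mt": spec.mt_length_bp, "r45s": spec.r45s_length_bp}
    rngs = {"cp": rng_cp, "mt": rng_mt, "r45s": rng_45}
    branches = {"cp": tree_cp, "mt": tree_mt, "r45s": tree_45}

    derived: dict[str, dict[str, np.ndarray]] = {}
    truth_rows = []
    for comp, tree in branches.items():
        derived[comp] = _simulate_along_tree(tree, lengths[comp], rngs[comp])
    # truth relative to the reference species (first in the list)
    for comp in branches:
        ref = derived[comp][species[0]]
        for sp in species[1:]:
            d = derived[comp][sp]
            pos = np.nonzero(d != ref)[0]
            for p in pos:
                truth_rows.append((comp, sp, int(p), sq.BASES[ref[p]], sq.BASES[d[p]]))
    truth = pd.DataFrame(truth_rows, columns=["compartment", "species", "pos", "ref_base", "alt_base"])

    genomes: dict[str, dict[str, object]] = {}
    for sp in species:
        cp_codes, genes = derived["cp"][sp], cp_genes
        if inv and sp in spec.inversion_clade:
            cp_codes, genes = apply_inversion(cp_codes, cp_genes, *inv)
        genomes[sp] = {
            "cp": CircularGenome(f"{sp}_cp", sq.decode(cp_codes), True, list(genes)),
            "mt": CircularGenome(f"{sp}_mt", sq.decode(derived["mt"][sp]), True, list(mt_genes)),
            "r45s": sq.decode(derived["r45s"][sp]),
        }
    return Panel(spec=spec, genomes=genomes, truth=truth, branch_lengths=branches, inversion=inv, seed=seed)


def _r45s_tree(spec: SpeciesPanelSpec, tree_cp):
    """45S divergence tree: the organellar tree rescaled so the most diverged
    pair shows ``r45s_fixed_diffs`` differences over the unit, with a
    per-leaf-branch floor so closely related pairs keep a usable number of
    informative sites (rDNA/ITS diverges disproportionately fast at low
    organellar divergence)."""
    taxa = list(tree_cp.leaf_names.values())
    if spec.r45s_fixed_diffs == 0 or len(taxa) < 2:
        return _scaled_tree(tree_cp, 0.0)
    d_max = max(
        tree_cp.path_length(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1 :]
    )
    if d_max == 0:
        return _scaled_tree(tree_cp, 0.0)
    target = jc_distance(spec.r45s_fixed_diffs / spec.r45s_length_bp)
    alpha = target / d_max
    return _scaled_tree(tree_cp, alpha, leaf_floor=spec.r45s_floor_per_kb / 1000.0)


# ---------------------------------------------------------------------------
# Strain simulation
# ---------------------------------------------------------------------------


def _mutate_intra(codes: np.ndarray, per_kb: float, rng: np.random.Generator):
    out = codes.copy()
    hit = rng.random(codes.size) < per_kb / 1000.0
    k = int(hit.sum())
    if k:
        out[hit] = (out[hit] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
    pos = np.nonzero(hit)[0]
    return out, pos


def simulate_strain_genomes(panel: Panel, strain: StrainSpec) -> StrainGenomes:
    """Realize one strain's genomes from the panel.

    Non-hybrid strains derive all compartments from their species with
    intra-specific substitutions at the specified density.  A hybrid strain is
    homoplasmic for the cytoplasm donor's organelles, while its 45S copy pool
    is drawn Binomial(copy_number, r45s_parent_ratio) from parent A's
    haplotype and the remainder from parent B's.
    """
    if strain.species_id not in panel.spec.species:
        raise KeyError(f"unknown species {strain.species_id}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(strain.seed)))
    spec = panel.spec
    rows = []

    if strain.is_hybrid:
        pa, pb = strain.hybrid_parents
        donor = strain.cytoplasm_donor
        cp_src, mt_src = panel.cp(donor), panel.mt(donor)
        intra_cp, intra_mt = spec.intra_cp_per_kb[donor], spec.intra_mt_per_kb[donor]
    else:
        sp = strain.species_id
        cp_src, mt_src = panel.cp(sp), panel.mt(sp)
        intra_cp, intra_mt = spec.intra_cp_per_kb[sp], spec.intra_mt_per_kb[sp]

    cp_codes, cp_pos = _mutate_intra(cp_src.codes, intra_cp, rng)
    mt_codes, mt_pos = _mutate_intra(mt_src.codes, intra_mt, rng)
    for comp, src, codes, pos in (("cp", cp_src, cp_codes, cp_pos), ("mt", mt_src, mt_codes, mt_pos)):
        ref = src.codes
        for p in pos:
            rows.append((comp, int(p), sq.BASES[ref[p]], sq.BASES[codes[p]]))

    n = spec.r45s_copy_number
    frac = None
    if strain.is_hybrid:
        pa, pb = strain.hybrid_parents
        hap_a, _ = _mutate_intra(sq.encode(panel.r45s(pa)), spec.intra_cp_per_kb[pa], rng)
        hap_b, _ = _mutate_intra(sq.encode(panel.r45s(pb)), spec.intra_cp_per_kb[pb], rng)
        k = int(rng.binomial(n, strain.r45s_parent_ratio))
        copies = [(sq.decode(hap_a), k), (sq.decode(hap_b), n - k)]
        frac = k / n
    else:
        hap, _ = _mutate_intra(sq.encode(panel.r45s(strain.species_id)), intra_cp, rng)
        copies = [(sq.decode(hap), n)]

    return StrainGenomes(
        strain_id=strain.strain_id,
        cp=CircularGenome(f"{strain.strain_id}_cp", sq.decode(cp_codes), True, list(cp_src.annotation)),
        mt=CircularGenome(f"{strain.strain_id}_mt", sq.decode(mt_codes), True, list(mt_src.annotation)),
        r45s_copies=copies,
        intra_variants=pd.DataFrame(rows, columns=["compartment", "pos", "ref_base", "alt_base"]),
        parent_a_copy_fraction=frac,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Paired reads plus truth placements (fragment coordinates per pair)."""

    r1: list[tuple[str, str]]
    r2: list[tuple[str, str]]
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.r1)


def n_pairs_for(coverage: float, length: int, read_length: int) -> int:
    """Pairs per molecule: round(coverage * length / (2 * read_length))."""
    return int(math.floor(coverage * length / (2.0 * read_length) + 0.5))


def simulate_reads(
    molecules: Sequence[tuple[str, str, bool]],
    coverage: float,
    rng: np.random.Generator,
    read_length: int = 150,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    error_rate: float = 0.0,
    weights: Sequence[float] | None = None,
    prefix: str = "rd",
) -> ReadSet:
    """Sample paired-end reads uniformly over a set of molecules.

    ``molecules`` are (id, sequence, circular) triples sharing one length (a
    genome, or the copies of a repeat unit); ``weights`` splits the total pair
    budget between them (copy numbers for the 45S pool).  Circular molecules
    are sampled on the doubled sequence so fragments may wrap the origin;
    linear fragments are constrained to fit.  Per-base substitution errors are
    applied at ``error_rate``, uniform over the three other bases.
    """
    lengths = {len(s) for _, s, _ in molecules}
    if len(lengths) != 1:
        raise ValueError("molecules must share one length")
    length = lengths.pop()
    if read_length > length:
        raise ValueError("read_length exceeds molecule length")
    total_pairs = n_pairs_for(coverage, length, read_length)
    if weights is None:
        weights = np.ones(len(molecules))
    w = np.asarray(weights, dtype=float)
    counts = rng.multinomial(total_pairs, w / w.sum()) if len(molecules) > 1 else np.array([total_pairs])

    r1, r2, rows = [], [], []
    pair_no = 0
    for (mol_id, mseq, circular), n_p in zip(molecules, counts):
        if n_p == 0:
            continue
        codes = sq.encode(mseq)
        frag_cap = length if not circular else int(insert_mean + 6 * insert_sd + read_length)
        frag = np.clip(np.rint(rng.normal(insert_mean, insert_sd, n_p)).astype(int), read_length, frag_cap)
        if circular:
            reps = 2 + frag_cap // length
            ext = np.concatenate([codes] * reps)
            starts = rng.integers(0, length, n_p)
        else:
            ext = codes
            starts = (rng.random(n_p) * (length - frag + 1)).astype(int)
        ends = starts + frag
        idx1 = starts[:, None] + np.arange(read_length)
        idx2 = ends[:, None] - read_length + np.arange(read_length)
        m1 = ext[idx1]
        m2 = (3 - ext[idx2])[:, ::-1]
        if error_rate > 0:
            for m in (m1, m2):
                hit = rng.random(m.shape) < error_rate
                k = int(hit.sum())
                if k:
                    m[hit] = (m[hit] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
        for i in range(n_p):
            name = f"{prefix}:{mol_id}:{pair_no}"
            r1.append((name, sq.decode(m1[i])))
            r2.append((name, sq.decode(m2[i])))
            rows.append((name, mol_id, int(starts[i]), int(ends[i])))
            pair_no += 1
    truth = pd.DataFrame(rows, columns=["pair_id", "molecule", "frag_start", "frag_end"])
    return ReadSet(r1, r2, truth)


def simulate_strain_reads(
    panel: Panel,
    strain: StrainSpec,
    genomes: StrainGenomes | None = None,
    include: Sequence[str] = ("cp", "mt", "r45s"),
    contaminant_pairs: int = 0,
) -> dict[str, ReadSet]:
    """Reads for every requested compartment of one strain (plus contaminants).

    Contaminant pairs are sampled from a random non-homologous sequence and
    appended to the chloroplast read set, emulating the bacterial read
    background of a holobiont library.
    """
    if genomes is None:
        genomes = simulate_strain_genomes(panel, strain)
    ss = np.random.SeedSequence([strain.seed, 1])
    rngs = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(4)]
    out: dict[str, ReadSet] = {}
    if "cp" in include:
        out["cp"] = simulate_reads(
            [(genomes.cp.id, genomes.cp.sequence, True)], strain.coverage_cp, rngs[0],
            strain.read_length, strain.insert_mean, strain.insert_sd, strain.error_rate,
            prefix=f"{strain.strain_id}:cp",
        )
    if "mt" in include:
        out["mt"] = simulate_reads(
            [(genomes.mt.id, genomes.mt.sequence, True)], strain.coverage_mt, rngs[1],
            strain.read_length, strain.insert_mean, strain.insert_sd, strain.error_rate,
            prefix=f"{strain.strain_id}:mt",
        )
    if "r45s" in include:
        # the 45S unit sits in a tandem array, so fragments run across unit
        # junctions: sample the unit circularly (uniform depth, as observed
        # for the real high-copy locus)
        mols = [(f"{strain.strain_id}_45s_h{i}", hap, True) for i, (hap, _) in enumerate(genomes.r45s_copies)]
        out["r45s"] = simulate_reads(
            mols, strain.coverage_45s, rngs[2],
            strain.read_length, min(strain.insert_mean, len(mols[0][1]) * 0.6),
            strain.insert_sd, strain.error_rate,
            weights=[c for _, c in genomes.r45s_copies],
            prefix=f"{strain.strain_id}:45s",
        )
    if contaminant_pairs > 0 and "cp" in out:
        rng = rngs[3]
        cont_len = max(2000, int(strain.insert_mean * 4))
        cont = sq.decode(rng.integers(0, 4, cont_len, dtype=np.uint8))
        cov = contaminant_pairs * 2 * strain.read_length / cont_len
        cont_rs = simulate_reads(
            [("contaminant", cont, False)], cov, rng, strain.read_length,
            min(strain.insert_mean, cont_len * 0.4), strain.insert_sd, strain.error_rate,
            prefix=f"{strain.strain_id}:cont",
        )
        out["cp"] = ReadSet(
            out["cp"].r1 + cont_rs.r1,
            out["cp"].r2 + cont_rs.r2,
            pd.concat([out["cp"].truth, cont_rs.truth], ignore_index=True),
        )
    return out


def default_strain_table(
    panel: Panel,
    n_strains: int = 20,
    hybrid: bool = True,
    seed: int = 0,
    **strain_kwargs,
) -> list[StrainSpec]:
    """The study design at panel scale: strains allocated across the six
    species roughly as sampled in the field (laetevirens and rigida dominant),
    plus one F1 hybrid (rigida x laetevirens nucleus, laetevirens cytoplasm).
    """
    weights = {"laetevirens": 38, "rigida": 29, "australis": 16, "fenestrata": 11, "gigantea": 10, "pseudorotundata": 6}
    species = [s for s in panel.spec.species if s in weights] or list(panel.spec.species)
    w = np.array([weights.get(s, 1) for s in species], dtype=float)
    n_pure = n_strains - (1 if hybrid else 0)
    if n_pure < 2 * len(species):
        raise ValueError("need >=2 strains per species for intra-specific statistics")
    # largest-remainder allocation with a floor of 2 strains per species
    alloc = np.full(len(species), 2)
    rest = n_pure - alloc.sum()
    shares = w / w.sum() * rest
    alloc += np.floor(shares).astype(int)
    frac_order = np.argsort(-(shares - np.floor(shares)))
    for j in range(n_pure - alloc.sum()):
        alloc[frac_order[j % len(species)]] += 1
    strains = []
    i = 0
    for sp, k in zip(species, alloc):
        for _ in range(k):
            strains.append(StrainSpec(f"U{i:03d}", sp, seed=seed * 100_000 + i, **strain_kwargs))
            i += 1
    if hybrid:
        strains.append(
            StrainSpec(
                f"U{i:03d}", "laetevirens", is_hybrid=True,
                hybrid_parents=("rigida", "laetevirens"), cytoplasm_donor="laetevirens",
                seed=seed * 100_000 + i, **strain_kwargs,
            )
        )
    return strains
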