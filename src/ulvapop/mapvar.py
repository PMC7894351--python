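"""Read mapping, pileups, variant calling, consensus and SNP statistics.

Mapping is k-mer-seeded ungapped placement: each read (both strands) is
anchored by exact seed matches, candidate placements are scored by mismatch
count, and the best placement's bases are accumulated into a per-position
pileup.  This matches the substitution-only data the simulator produces; for
real data with indels a SAM produced by an external mapper can be imported
instead (``pileup_from_sam``).

Variant calling is a simple explicit-threshold caller on the pileup: depth
gate, homozygous-alternative threshold, and a heterozygous band aimed at
pooled multi-copy loci (the 45S) and mixed signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import seq as sq
from .genome import CircularGenome, Gene

CALL_REF = "ref"
CALL_VARIANT = "variant"
CALL_HET = "heterozygous"
CALL_NOCALL = "no_call"


@dataclass
class Pileup:
    """Per-position base counts (4 x L) for one reference."""

    reference_id: str
    counts: np.ndarray  # uint32, shape (4, L)
    n_mapped: int = 0
    n_unmapped: int = 0

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def empty(cls, reference_id: str, length: int) -> "Pileup":
        return cls(reference_id, np.zeros((4, length), dtype=np.uint32))

    def __add__(self, other: "Pileup") -> "Pileup":
        if other.reference_id != self.reference_id or other.length != self.length:
            raise ValueError("pileups are not on the same reference")
        return Pileup(
            self.reference_id,
            self.counts + other.counts,
            self.n_mapped + other.n_mapped,
            self.n_unmapped + other.n_unmapped,
        )


@dataclass
class CdsSet:
    """The common set of annotated genes, BED semantics, in shared gene order."""

    genes: list[Gene]

    @property
    def total_length(self) -> int:
        return sum(g.length for g in self.genes)

    @classmethod
    def from_genome(cls, genome: CircularGenome) -> "CdsSet":
        return cls(list(genome.annotation))


def _pack_offsets(R: np.ndarray, offsets: Sequence[int], k: int) -> np.ndarray:
    """Packed k-mer codes of matrix rows at the given column offsets."""
    n = R.shape[0]
    K = np.zeros((n, len(offsets)), dtype=np.uint64)
    for j, o in enumerate(offsets):
        c = np.zeros(n, dtype=np.uint64)
        for i in range(k):
            c = (c << np.uint64(2)) | R[:, o + i].astype(np.uint64)
        K[:, j] = c
    return K


def _expand_ranges(lo: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Indices [lo_i, lo_i + counts_i) for every i, concatenated."""
    tot = int(counts.sum())
    if tot == 0:
        return np.empty(0, dtype=np.int64)
    starts = np.cumsum(counts) - counts
    return np.repeat(lo, counts) + (np.arange(tot) - np.repeat(starts, counts))


def map_reads(
    reads: Iterable[tuple[str, str]],
    reference: CircularGenome,
    k_seed: int = 15,
    max_mismatch_frac: float = 0.2,
    record_placements: bool = False,
) -> Pileup | tuple[Pileup, pd.DataFrame]:
    """Place each read by exact-seed anchoring + minimum mismatches.

    Seed k-mers at every k_seed-spaced offset of the read (both strands)
    nominate candidate placements; candidates are scored by mismatch count
    against the (doubled, if circular) reference.  Ties break to the lowest
    reference coordinate, forward strand first on an exact tie.  Reads whose
    best placement exceeds ``max_mismatch_frac`` mismatches are unmapped.
    """
    reads = list(reads)
    L = len(reference)
    counts = np.zeros((4, L), dtype=np.uint32)
    placements: list[tuple] = []
    n_mapped = n_unmapped = 0
    # group reads by length for fully vectorized processing
    by_len: dict[int, list[int]] = {}
    for i, (_, s) in enumerate(reads):
        by_len.setdefault(len(s), []).append(i)
    for rlen, idxs in sorted(by_len.items()):
        if rlen < k_seed or rlen > L:
            n_unmapped += len(idxs)
            continue
        codes_ref = reference.codes
        ext = np.concatenate([codes_ref, codes_ref[: rlen - 1]]) if reference.circular else codes_ref
        kc_ref = sq.kmer_codes(ext, k_seed)
        order = np.argsort(kc_ref, kind="stable")
        sorted_codes = kc_ref[order]
        sorted_pos = order.astype(np.int64)

        R_f = np.stack([sq.encode(reads[i][1]) for i in idxs])
        R_r = (3 - R_f)[:, ::-1]
        offsets = list(range(0, rlen - k_seed + 1, k_seed))
        cand_read, cand_start, cand_strand = [], [], []
        for strand_i, R in ((0, R_f), (1, R_r)):
            K = _pack_offsets(R, offsets, k_seed)
            lo = np.searchsorted(sorted_codes, K.ravel(), side="left")
            hi = np.searchsorted(sorted_codes, K.ravel(), side="right")
            cnt = np.minimum(hi - lo, 64)
            flat_read = np.repeat(np.arange(len(idxs)), len(offsets))
            flat_off = np.tile(np.array(offsets), len(idxs))
            occ_idx = _expand_ranges(lo, cnt)
            if occ_idx.size == 0:
                continue
            starts = sorted_pos[occ_idx] - np.repeat(flat_off, cnt)
            rds = np.repeat(flat_read, cnt)
            valid = (starts >= 0) & (starts + rlen <= ext.size) & (starts < L)
            cand_read.append(rds[valid])
            cand_start.append(starts[valid])
            cand_strand.append(np.full(int(valid.sum()), strand_i, dtype=np.int8))
        if not cand_read:
            n_unmapped += len(idxs)
            continue
        c_read = np.concatenate(cand_read)
        c_start = np.concatenate(cand_start)
        c_strand = np.concatenate(cand_strand)
        # dedupe (read, start, strand)
        key = (c_read.astype(np.int64) * (2 * L + 2) + c_start * 2 + c_strand)
        _, uniq_idx = np.unique(key, return_index=True)
        c_read, c_start, c_strand = c_read[uniq_idx], c_start[uniq_idx], c_strand[uniq_idx]
        # mismatch counts, chunked
        mism = np.empty(c_read.size, dtype=np.int32)
        span = np.arange(rlen)
        chunk = max(1, 4_000_000 // rlen)
        for s0 in range(0, c_read.size, chunk):
            sl = slice(s0, s0 + chunk)
            gather = ext[c_start[sl, None] + span]
            block = np.where((c_strand[sl, None] == 0), R_f[c_read[sl]], R_r[c_read[sl]])
            mism[sl] = np.count_nonzero(gather != block, axis=1)
        # best candidate per read: (mism, start, strand) lexicographic
        order2 = np.lexsort((c_strand, c_start, mism, c_read))
        rr = c_read[order2]
        first = np.ones(rr.size, dtype=bool)
        first[1:] = rr[1:] != rr[:-1]
        sel = order2[first]
        ok = mism[sel] / rlen <= max_mismatch_frac
        chosen = sel[ok]
        n_mapped += int(ok.sum())
        n_unmapped += len(idxs) - int(ok.sum())
        if chosen.size:
            ch_read = c_read[chosen]
            ch_start = c_start[chosen]
            ch_strand = c_strand[chosen]
            pos = (ch_start[:, None] + span) % L
            base = np.where((ch_strand[:, None] == 0), R_f[ch_read], R_r[ch_read])
            np.add.at(counts, (base.ravel(), pos.ravel()), 1)
            if record_placements:
                for rix, st, sd, mm in zip(ch_read, ch_start, ch_strand, mism[chosen]):
                    placements.append((reads[idxs[rix]][0], int(st), "+" if sd == 0 else "-", int(mm)))
    pile = Pileup(reference.id, counts, n_mapped, n_unmapped)
    if record_placements:
        df = pd.DataFrame(placements, columns=["read_id", "start", "strand", "mismatches"])
        return pile, df
    return pile


def pileup_from_sam(path: str, reference: CircularGenome) -> Pileup:
    """Build a pileup from a plain-text SAM of ungapped alignments
    (M-only CIGARs); indel-containing records are skipped with a count."""
    L = len(reference)
    counts = np.zeros((4, L), dtype=np.uint32)
    n_mapped = n_unmapped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag, pos, cigar, seqs = int(f[1]), int(f[3]) - 1, f[5], f[9]
            if flag & 4 or cigar == "*" or not cigar.endswith("M") or not cigar[:-1].isdigit():
                n_unmapped += 1
                continue
            arr = sq.encode(seqs)
            idx = (pos + np.arange(arr.size)) % L
            np.add.at(counts, (arr, idx), 1)
            n_mapped += 1
    return Pileup(reference.id, counts, n_mapped, n_unmapped)


# ---------------------------------------------------------------------------
# Variant calling and consensus
# ---------------------------------------------------------------------------


def call_variants(
    pileup: Pileup,
    reference: CircularGenome,
    min_depth: int = 10,
    hom_threshold: float = 0.9,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> pd.DataFrame:
    """Per-position calls from a pileup.

    Rows are emitted for every position whose call is not ``ref``: variant
    (top non-reference fraction >= hom_threshold), heterozygous (fraction in
    het_band) and no_call (depth < min_depth).  Columns: position, ref_allele,
    alt_allele, alt_fraction, depth, call.
    """
    ref = reference.codes
    depth = pileup.depth.astype(np.int64)
    L = pileup.length
    masked = pileup.counts.astype(np.int64).copy()
    masked[ref, np.arange(L)] = -1
    alt = masked.argmax(axis=0)
    alt_count = masked[alt, np.arange(L)].clip(min=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
    call = np.full(L, CALL_REF, dtype=object)
    call[frac >= hom_threshold] = CALL_VARIANT
    call[(frac >= het_band[0]) & (frac <= het_band[1])] = CALL_HET
    call[depth < min_depth] = CALL_NOCALL
    keep = call != CALL_REF
    idx = np.nonzero(keep)[0]
    return pd.DataFrame(
        {
            "position": idx,
            "ref_allele": [sq.BASES[b] for b in ref[idx]],
            "alt_allele": [sq.BASES[b] if c > 0 else "." for b, c in zip(alt[idx], alt_count[idx])],
            "alt_fraction": frac[idx],
            "depth": depth[idx],
            "call": call[idx],
        }
    )


def build_consensus(reference: CircularGenome, variants: pd.DataFrame) -> tuple[str, list[int]]:
    """Substitute called variants into the reference.

    variant -> alternative allele; heterozygous -> majority base (exact ties
    keep the reference base); no_call -> reference base, position logged.
    Returns (consensus sequence, list of no-call positions).
    """
    if variants.position.duplicated().any():
        raise ValueError("conflicting rows for one position")
    codes = reference.codes.copy()
    logged: list[int] = []
    for row in variants.itertuples(index=False):
        p = int(row.position)
        if row.call == CALL_VARIANT:
            codes[p] = sq.BASES.index(row.alt_allele)
        elif row.call == CALL_HET:
            if row.alt_fraction > 0.5:
                codes[p] = sq.BASES.index(row.alt_allele)
        elif row.call == CALL_NOCALL:
            logged.append(p)
    return sq.decode(codes), logged


# ---------------------------------------------------------------------------
# SNP statistics
# ---------------------------------------------------------------------------


def snp_density(n_snps: int, length_bp: int) -> float:
    """SNPs per kb, printed-table style: half-up rounding to one decimal,
    integers (>= 100) to zero decimals."""
    if length_bp <= 0:
        raise ValueError("length must be > 0")
    dens = Decimal(1000 * n_snps) / Decimal(length_bp)
    if dens >= 100:
        return float(dens.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return float(dens.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def extract_concat_cds(genome: CircularGenome, cds: CdsSet | None = None) -> str:
    """Concatenated coding sequence, strand-resolved, genes in annotation
    (shared gene-id) order -- comparable across genomes that share gene ids
    even when an inversion reordered gene positions."""
    genes = cds.genes if cds is not None else genome.annotation
    out = []
    for g in genes:
        if g.end > len(genome):
            raise ValueError(f"gene {g.gene_id} outside genome")
        s = genome.sequence[g.start : g.end]
        out.append(s if g.strand == "+" else sq.revcomp(s))
    return "".join(out)


def _mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must share coordinates")
    return int(np.count_nonzero(sq.encode(a) != sq.encode(b)))


def interspecific_stats(
    consensuses: Mapping[str, str],
    species_labels: Mapping[str, str],
    cds_by_species: Mapping[str, CdsSet],
    genomes_by_strain: Mapping[str, CircularGenome] | None = None,
    reference_species: str = "laetevirens",
) -> pd.DataFrame:
    """Mean SNP count and density per species against the reference species.

    ``consensuses`` maps strain -> concatenated-CDS sequence (already
    extracted); per strain, CDS mismatches against the reference-species CDS
    consensus are counted, averaged within species, and normalized by the
    concatenated CDS length.
    """
    if genomes_by_strain is not None:
        # convenience path: extract CDS from whole-genome consensuses
        consensuses = {
            sid: extract_concat_cds(g, cds_by_species[species_labels[sid]])
            for sid, g in genomes_by_strain.items()
        }
    missing = set(consensuses) - set(species_labels)
    if missing:
        raise ValueError(f"strains without species labels: {missing}")
    ref_strains = [s for s, sp in species_labels.items() if sp == reference_species and s in consensuses]
    if not ref_strains:
        raise ValueError(f"no strains of reference species {reference_species}")
    ref_cons = _majority_consensus([consensuses[s] for s in ref_strains])[0]
    cds_len = len(ref_cons)
    rows = []
    for species in dict.fromkeys(species_labels.values()):
        sids = [s for s, sp in species_labels.items() if sp == species and s in consensuses]
        if not sids:
            continue
        counts = [_mismatches(consensuses[s], ref_cons) for s in sids]
        mean_count = float(np.mean(counts))
        rows.append(
            {
                "species": species,
                "n_strains": len(sids),
                "mean_snps": mean_count,
                "snps_per_kb": snp_density(int(round(mean_count)), cds_len),
                "cds_length_bp": cds_len,
            }
        )
    return pd.DataFrame(rows)


def _majority_consensus(seqs: Sequence[str]) -> tuple[str, list[int]]:
    """Per-position majority; ties resolve to the first sequence's base
    (positions logged)."""
    mat = np.stack([sq.encode(s) for s in seqs])
    n, L = mat.shape
    counts = np.zeros((4, L), dtype=np.int32)
    for b in range(4):
        counts[b] = (mat == b).sum(axis=0)
    top = counts.max(axis=0)
    arg = counts.argmax(axis=0)
    first = mat[0]
    tie = (counts[first, np.arange(L)] == top) & (arg != first)
    arg[tie] = first[tie]
    logged = np.nonzero((counts == top).sum(axis=0) > 1)[0].tolist()
    return sq.decode(arg.astype(np.uint8)), logged


def intraspecific_stats(
    consensuses_by_species: Mapping[str, Mapping[str, str]],
    length_bp: int | None = None,
) -> pd.DataFrame:
    """Within-species variation: per species, mean +/- SD SNPs/kb per strain
    against the species majority consensus, and the total number of variant
    sites (positions where any strain differs from the species consensus).

    Densities are normalized by the full sequence length supplied (or the
    consensus length).  Species with a single strain report SD as NaN.
    """
    rows = []
    for species, strains in consensuses_by_species.items():
        sids = list(strains)
        seqs = [strains[s] for s in sids]
        cons, _ = _majority_consensus(seqs)
        L = length_bp or len(cons)
        counts = np.array([_mismatches(s, cons) for s in seqs], dtype=float)
        dens = 1000.0 * counts / L
        mat = np.stack([sq.encode(s) for s in seqs])
        total = int(np.count_nonzero((mat != sq.encode(cons)).any(axis=0)))
        rows.append(
            {
                "species": species,
                "n_strains": len(sids),
                "snps_per_kb_mean": float(dens.mean()),
                "snps_per_kb_sd": float(dens.std(ddof=1)) if len(sids) > 1 else math.nan,
                "total_variant_sites": total,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minimal VCF export
# ---------------------------------------------------------------------------


def write_vcf(path: str, variants: pd.DataFrame, reference_id: str) -> None:
    """Minimal single-sample VCF (CHROM, 1-based POS, REF, ALT, INFO DP/AF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_id}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            filt = "PASS" if row.call in (CALL_VARIANT, CALL_HET) else "LowDepth"
            fh.write(
                f"{reference_id}\t{row.position + 1}\t.\t{row.ref_allele}\t{row.alt_allele}\t.\t{filt}\t"
                f"DP={row.depth};AF={row.alt_fraction:.4f};CALL={row.call}\n"
            )


def read_vcf(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(kv.split("=") for kv in f[7].split(";"))
            rows.append(
                {
                    "position": int(f[1]) - 1,
                    "ref_allele": f[3],
                    "alt_allele": f[4],
                    "alt_fraction": float(info["AF"]),
                    "depth": int(info["DP"]),
                    "call": info.get("CALL", CALL_VARIANT),
                }
            )
    return pd.DataFrame(rows)
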