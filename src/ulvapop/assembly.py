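"""Iterative reference-baited de novo organelle assembly.

The loop emulates the multi-step organelle reconstruction used for holobiont
libraries: (1) bait reads by canonical k-mer sharing with a seed reference,
(2) assemble the baited reads with a minimal de Bruijn (unitig) assembler,
(3) test the resulting contig for circularity, then re-bait with the new
contigs and repeat.  Each round lets read overhangs (and their mates, which
are retained jointly) extend the assembly into species-specific sequence that
the seed reference lacks, until a single circular contig is obtained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import seq as sq
from .genome import CircularGenome


@dataclass
class AssemblyConfig:
    k_filter: int = 21          # baiting k-mer size
    min_shared_kmers: int = 2   # per-pair retention threshold
    k_asm: int = 31             # assembly k-mer size
    min_kmer_count: int = 3     # solid k-mer threshold
    max_iterations: int = 10
    min_contig_len: int = 200   # contigs below this are ignored for convergence

    def __post_init__(self):
        if self.k_filter % 2 == 0 or self.k_asm % 2 == 0:
            raise ValueError("k values must be odd")
        if min(self.min_shared_kmers, self.min_kmer_count, self.max_iterations) < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass
class AssemblyResult:
    contigs: list[CircularGenome]
    iterations_used: int
    converged: bool
    reads_retained: list[int] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)

    @property
    def circular_contigs(self) -> list[CircularGenome]:
        return [c for c in self.contigs if c.circular]


# ---------------------------------------------------------------------------
# Read baiting
# ---------------------------------------------------------------------------


def _bait_kmer_array(baits: Sequence[str], k: int) -> np.ndarray:
    parts = [sq.canonical_kmer_codes(sq.encode(b), k) for b in baits if len(b) >= k]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def kmer_filter_reads(
    r1: Sequence[tuple[str, str]],
    r2: Sequence[tuple[str, str]],
    baits: Sequence[str],
    cfg: AssemblyConfig = AssemblyConfig(),
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], np.ndarray]:
    """Retain a read pair iff either mate shares >= ``min_shared_kmers``
    canonical k-mers with the bait set.  Output order is input order.

    Returns (kept_r1, kept_r2, boolean keep mask).
    """
    if not baits:
        raise ValueError("bait set must be non-empty")
    bait = _bait_kmer_array(baits, cfg.k_filter)
    keep = np.zeros(len(r1), dtype=bool)
    if bait.size:
        for i, ((_, s1), (_, s2)) in enumerate(zip(r1, r2)):
            keep[i] = (
                _shared_count(s1, bait, cfg.k_filter) >= cfg.min_shared_kmers
                or _shared_count(s2, bait, cfg.k_filter) >= cfg.min_shared_kmers
            )
    kept1 = [r for r, k in zip(r1, keep) if k]
    kept2 = [r for r, k in zip(r2, keep) if k]
    return kept1, kept2, keep


def _shared_count(read: str, bait_sorted: np.ndarray, k: int) -> int:
    if len(read) < k:
        return 0
    codes = sq.canonical_kmer_codes(sq.encode(read), k)
    idx = np.searchsorted(bait_sorted, codes)
    idx[idx == bait_sorted.size] = 0
    return int(np.count_nonzero(bait_sorted[idx] == codes))


# ---------------------------------------------------------------------------
# de Bruijn unitig assembly
# ---------------------------------------------------------------------------


def _solid_kmers(reads: Sequence[str], k: int, min_count: int) -> set[str]:
    parts = [sq.canonical_kmer_codes(sq.encode(s), k) for s in reads if len(s) >= k]
    if not parts:
        return set()
    codes, counts = np.unique(np.concatenate(parts), return_counts=True)
    return {sq.decode_kmer(int(c), k) for c in codes[counts >= min_count]}


def _successors(kmer: str, solid: set[str]) -> list[str]:
    out = []
    suf = kmer[1:]
    for b in sq.BASES:
        nxt = suf + b
        if sq.canonical(nxt) in solid:
            out.append(nxt)
    return out


def _predecessors(kmer: str, solid: set[str]) -> list[str]:
    return [sq.revcomp(s) for s in _successors(sq.revcomp(kmer), solid)]


def debruijn_assemble(reads: Sequence[str], cfg: AssemblyConfig = AssemblyConfig()) -> list[str]:
    """Unitigs of the compacted graph of solid canonical k-mers.

    Every maximal non-branching path is emitted exactly once, in canonical
    orientation, ordered by length (desc) then lexicographically.  A cyclic
    non-branching component (a clean circular genome) is emitted with its
    first (k-1)-mer repeated at the end, so circularity detection can trim it.
    """
    k = cfg.k_asm
    solid = _solid_kmers(reads, k, cfg.min_kmer_count)
    if not solid:
        return []
    visited: set[str] = set()
    contigs: list[str] = []
    for start in sorted(solid):
        if start in visited:
            continue
        chain = [start]
        chain_canon = {start}
        cyclic = False
        # extend right
        cur = start
        while True:
            succ = _successors(cur, solid)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if len(_predecessors(nxt, solid)) != 1:
                break
            nxt_c = sq.canonical(nxt)
            if nxt_c == start:
                cyclic = True
                break
            if nxt_c in visited or nxt_c in chain_canon:
                break
            chain.append(nxt)
            chain_canon.add(nxt_c)
            cur = nxt
        if not cyclic:
            # extend left
            cur = chain[0]
            left: list[str] = []
            while True:
                pred = _predecessors(cur, solid)
                if len(pred) != 1:
                    break
                prv = pred[0]
                if len(_successors(prv, solid)) != 1:
                    break
                prv_c = sq.canonical(prv)
                if prv_c in visited or prv_c in chain_canon:
                    break
                left.append(prv)
                chain_canon.add(prv_c)
                cur = prv
            chain = left[::-1] + chain
        visited.update(chain_canon)
        # a cyclic chain's string already ends with its first (k-1)-mer,
        # which is exactly the terminal overlap detect_circularity trims
        seqs = chain[0] + "".join(c[-1] for c in chain[1:])
        contigs.append(sq.canonical(seqs))
    contigs = sorted(set(contigs), key=lambda s: (-len(s), s))
    return contigs


def detect_circularity(contig: str, cfg: AssemblyConfig = AssemblyConfig()) -> tuple[bool, str]:
    """Terminal-overlap circularity test.

    A contig whose first and last (k_asm - 1)-mers coincide closes on itself
    in the graph; the duplicated overlap is trimmed and the sequence reported
    in its normalized rotation (lexicographically minimal rotation of the
    canonical strand).  Returns (circular, sequence).
    """
    k = cfg.k_asm
    if len(contig) <= k:
        warnings.warn(f"contig shorter than k_asm ({len(contig)} <= {k}); not circular")
        return False, contig
    if len(contig) > 2 * (k - 1) and contig[: k - 1] == contig[-(k - 1):]:
        core = contig[: -(k - 1)]
        return True, sq.normalize_rotation(core)
    return False, contig


# ---------------------------------------------------------------------------
# Iteration
# ---------------------------------------------------------------------------


def iterative_assemble(
    r1: Sequence[tuple[str, str]],
    r2: Sequence[tuple[str, str]],
    seed_reference: Sequence[str],
    cfg: AssemblyConfig = AssemblyConfig(),
) -> AssemblyResult:
    """Filter -> assemble -> circularity loop, re-baiting with each round's
    contigs, until a single circular contig is obtained or ``max_iterations``
    is reached (in which case ``converged`` is False and the last contig set
    is returned with diagnostics).
    """
    if not seed_reference:
        raise ValueError("seed reference must be non-empty")
    bait = list(seed_reference)
    retained_counts: list[int] = []
    log: list[dict] = []
    contigs: list[str] = []
    flags: list[bool] = []
    for it in range(1, cfg.max_iterations + 1):
        k1, k2, keep = kmer_filter_reads(r1, r2, bait, cfg)
        retained_counts.append(int(keep.sum()))
        reads = [s for _, s in k1] + [s for _, s in k2]
        raw = debruijn_assemble(reads, cfg) if reads else []
        contigs, flags = [], []
        for c in raw:
            circ, norm = detect_circularity(c, cfg)
            contigs.append(norm)
            flags.append(circ)
        big = [(c, f) for c, f in zip(contigs, flags) if len(c) >= cfg.min_contig_len]
        n_circ = sum(1 for _, f in big if f)
        log.append(
            {"iteration": it, "reads_retained": int(keep.sum()), "n_contigs": len(big), "n_circular": n_circ}
        )
        if len(big) == 1 and n_circ == 1:
            out = [CircularGenome(f"contig_{i+1}", c, f, []) for i, (c, f) in enumerate(zip(contigs, flags))]
            return AssemblyResult(out, it, True, retained_counts, log)
        bait = [c for c in contigs if len(c) >= cfg.min_contig_len] or contigs or list(seed_reference)
    out = [CircularGenome(f"contig_{i+1}", c, f, []) for i, (c, f) in enumerate(zip(contigs, flags))]
    return AssemblyResult(out, cfg.max_iterations, False, retained_counts, log)
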