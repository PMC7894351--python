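"""Distance-based phylogenetics: p/JC69 distances, neighbor joining,
site-resampling bootstrap, and Robinson-Foulds tree agreement.

Trees are unrooted, with branch lengths and optional per-edge bootstrap
support, serializable as Newick.  Neighbor joining uses the standard
Q-criterion with deterministic tie-breaking (lexicographically smallest taxon
pair); negative branch-length estimates are clamped to zero with the deficit
moved to the sister branch, preserving path lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import seq as sq


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("matrix must be symmetric")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def pairwise_distances(sequences: Mapping[str, str], model: str = "JC69") -> DistanceMatrix:
    """p-distance or JC69-corrected distance between aligned sequences.

    p = mismatches / compared sites; JC69 = -(3/4) ln(1 - 4p/3), reported as
    NaN (with a warning) when p >= 0.75.
    """
    taxa = list(sequences)
    mats = np.stack([sq.encode(sequences[t]) for t in taxa])
    n = len(taxa)
    D = np.zeros((n, n))
    L = mats.shape[1]
    for i in range(n):
        diff = (mats[i] != mats).sum(axis=1) / L
        D[i] = diff
    if model == "p":
        return DistanceMatrix(taxa, D)
    if model != "JC69":
        raise ValueError(f"unknown model {model!r}")
    sat = D >= 0.75
    np.fill_diagonal(sat, False)
    if sat.any():
        warnings.warn("saturated p-distances (>= 0.75); JC69 undefined, NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(sat, np.nan, -0.75 * np.log(np.clip(1.0 - 4.0 * D / 3.0, 1e-300, None)))
    np.fill_diagonal(J, 0.0)
    return DistanceMatrix(taxa, J)


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """Unrooted tree: adjacency with branch lengths, optional edge support."""

    adj: dict[int, dict[int, float]]
    leaf_names: dict[int, str]
    support: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaf_names.values())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each normalized to the side that does not
        contain the alphabetically first taxon."""
        first = min(self.leaf_names.values())
        n = len(self.leaf_names)
        out: set[frozenset] = set()
        for a, b, _ in self.edges():
            side = self._leaves_beyond(b, a)
            if first in side:
                side = frozenset(set(self.leaf_names.values()) - side)
            if 1 < len(side) < n - 1:
                out.add(frozenset(side))
        return out

    def edges(self):
        seen = set()
        for a, nbrs in self.adj.items():
            for b, ln in nbrs.items():
                if (b, a) not in seen:
                    seen.add((a, b))
                    yield a, b, ln

    def _leaves_beyond(self, node: int, parent: int) -> frozenset:
        stack = [(node, parent)]
        leaves = []
        while stack:
            cur, par = stack.pop()
            if cur in self.leaf_names:
                leaves.append(self.leaf_names[cur])
            for nxt in self.adj[cur]:
                if nxt != par:
                    stack.append((nxt, cur))
        return frozenset(leaves)

    def path_length(self, taxon_a: str, taxon_b: str) -> float:
        name_to_node = {v: k for k, v in self.leaf_names.items()}
        start, goal = name_to_node[taxon_a], name_to_node[taxon_b]
        stack = [(start, -1, 0.0)]
        while stack:
            cur, par, dist = stack.pop()
            if cur == goal:
                return dist
            for nxt, ln in self.adj[cur].items():
                if nxt != par:
                    stack.append((nxt, cur, dist + ln))
        raise ValueError("disconnected tree")

    def is_monophyletic(self, taxa: Sequence[str]) -> bool:
        group = frozenset(taxa)
        n = len(self.leaf_names)
        if len(group) in (1, n):
            return True
        all_taxa = frozenset(self.leaf_names.values())
        for a, b, _ in self.edges():
            side = self._leaves_beyond(b, a)
            if side == group or side == all_taxa - group:
                return True
        return False

    def to_newick(self, with_support: bool = False) -> str:
        root = next(iter(n for n in self.adj if n not in self.leaf_names), None)
        if root is None:
            root = next(iter(self.adj))

        def fmt(node: int, parent: int, blen: float | None) -> str:
            if node in self.leaf_names:
                core = self.leaf_names[node]
            else:
                kids = [fmt(c, node, ln) for c, ln in sorted(self.adj[node].items()) if c != parent]
                label = ""
                if with_support and parent >= 0:
                    side = self._leaves_beyond(node, parent)
                    first = min(self.leaf_names.values())
                    key = side if first not in side else frozenset(set(self.leaf_names.values()) - side)
                    if key in self.support:
                        label = f"{self.support[key]:.3f}"
                core = "(" + ",".join(kids) + ")" + label
            return core if blen is None else f"{core}:{blen:.6f}"

        return fmt(root, -1, None) + ";"


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dist: DistanceMatrix) -> Phylogeny:
    """Standard neighbor joining (Q-criterion).

    Ties in Q break to the lexicographically smallest taxon pair (each
    cluster represented by its smallest member name).  Negative branch
    lengths are clamped to 0 and the deficit moved to the sister branch.
    """
    n0 = len(dist.taxa)
    if n0 < 3:
        raise ValueError("need >= 3 taxa")
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix contains NaN")
    D = dist.values.copy()
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n0)}
    leaf_names = {i: t for i, t in enumerate(dist.taxa)}
    active = list(range(n0))
    rep = {i: dist.taxa[i] for i in range(n0)}  # smallest member name per cluster
    node_of = {i: i for i in range(n0)}
    Dw = {(i, j): D[i, j] for i in range(n0) for j in range(n0) if i < j}

    def d(i, j):
        return Dw[(i, j) if i < j else (j, i)]

    next_node = n0
    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (m - 2) * d(i, j) - r[i] - r[j]
                names = tuple(sorted((rep[i], rep[j])))
                key = (q, names)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = next_node
        next_node += 1
        adj[new] = {}
        adj[new][node_of[i]] = li
        adj[node_of[i]][new] = li
        adj[new][node_of[j]] = lj
        adj[node_of[j]][new] = lj
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d(i, k) + d(j, k) - dij)
            Dw[(min(k, new), max(k, new))] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new]
        rep[new] = min(rep[i], rep[j])
        node_of[new] = new
    i, j = active
    dij = max(d(i, j), 0.0)
    a, b = node_of[i], node_of[j]
    adj[a][b] = dij
    adj[b][a] = dij
    return Phylogeny(adj, leaf_names)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    sequences: Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "JC69",
) -> Phylogeny:
    """Site-resampling bootstrap on the NJ tree.

    Support of each bipartition of the point-estimate tree = fraction of
    replicate trees containing it.  Deterministic given ``seed``.
    """
    taxa = list(sequences)
    mats = np.stack([sq.encode(sequences[t]) for t in taxa])
    n, L = mats.shape
    point = nj_tree(pairwise_distances(sequences, model))
    biparts = point.bipartitions()
    hits = {bp: 0 for bp in biparts}
    rng = np.random.Generator(np.random.PCG64(seed))
    # per-pair per-site difference indicators, for fast resampled distances
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diff = np.stack([(mats[i] != mats[j]) for i, j in pair_idx]).astype(np.float32)
    for _ in range(n_reps):
        counts = np.bincount(rng.integers(0, L, L), minlength=L).astype(np.float32)
        p = (diff @ counts) / L
        D = np.zeros((n, n))
        for (i, j), pv in zip(pair_idx, p):
            D[i, j] = D[j, i] = pv
        if model == "JC69":
            with np.errstate(invalid="ignore"):
                D = np.where(D >= 0.75, 3.0, -0.75 * np.log(np.clip(1.0 - 4.0 * D / 3.0, 1e-300, None)))
            np.fill_diagonal(D, 0.0)
        rep_tree = nj_tree(DistanceMatrix(taxa, D))
        rep_biparts = rep_tree.bipartitions()
        for bp in biparts:
            if bp in rep_biparts:
                hits[bp] += 1
    point.support = {bp: h / n_reps for bp, h in hits.items()}
    return point


# ---------------------------------------------------------------------------
# Tree agreement
# ---------------------------------------------------------------------------


def induced_bipartitions(tree: Phylogeny, subset: Sequence[str]) -> set[frozenset]:
    """Non-trivial bipartitions of the subtree induced by ``subset``."""
    S = frozenset(subset)
    if not S:
        return set()
    first = min(S)
    out: set[frozenset] = set()
    for bp in tree.bipartitions():
        side = frozenset(bp & S)
        if first in side:
            side = frozenset(S - side)
        if 1 < len(side) < len(S) - 1:
            out.add(side)
    return out


def tree_agreement(
    tree_1: Phylogeny,
    tree_2: Phylogeny,
    species_labels: Mapping[str, str] | None = None,
) -> dict:
    """Robinson-Foulds distance, normalized agreement, and (optionally) the
    species-cluster comparison: whether each species is a clade in both trees
    and the RF distance between the trees collapsed to one representative per
    species (0 = identical species-cluster structure)."""
    if set(tree_1.leaf_names.values()) != set(tree_2.leaf_names.values()):
        raise ValueError("leaf sets differ")
    b1, b2 = tree_1.bipartitions(), tree_2.bipartitions()
    rf = len(b1 ^ b2)
    n = len(tree_1.leaf_names)
    denom = 2 * (n - 3)
    out = {
        "rf": rf,
        "normalized_rf": rf / denom if denom > 0 else 0.0,
        "normalized_agreement": 1.0 - (rf / denom if denom > 0 else 0.0),
    }
    if species_labels is not None:
        # monophyly is judged on the trees restricted to the labelled strains,
        # so unlabelled leaves (e.g. a hybrid, legitimately attached inside
        # its cytoplasm donor's clade) do not break species clades
        S = sorted(species_labels)
        first = min(S)
        ind1 = induced_bipartitions(tree_1, S)
        ind2 = induced_bipartitions(tree_2, S)

        def is_clade(biparts: set[frozenset], members: list[str]) -> bool:
            group = frozenset(members)
            if len(group) in (1, len(S) - 1, len(S)):
                return True
            norm = group if first not in group else frozenset(set(S) - group)
            return norm in biparts

        rows = []
        for spp in dict.fromkeys(species_labels.values()):
            members = [t for t, s in species_labels.items() if s == spp]
            rows.append(
                {
                    "species": spp,
                    "n": len(members),
                    "clade_in_tree_1": is_clade(ind1, members),
                    "clade_in_tree_2": is_clade(ind2, members),
                }
            )
        table = pd.DataFrame(rows)
        out["cluster_table"] = table
        out["clusters_are_clades_both"] = bool(
            table.clade_in_tree_1.all() and table.clade_in_tree_2.all()
        )
        reps = sorted(
            min(t for t, s in species_labels.items() if s == spp)
            for spp in dict.fromkeys(species_labels.values())
        )
        i1 = induced_bipartitions(tree_1, reps)
        i2 = induced_bipartitions(tree_2, reps)
        out["cluster_rf"] = len(i1 ^ i2)
        out["same_cluster_membership"] = bool(out["clusters_are_clades_both"] and out["cluster_rf"] == 0)
    return out


def jc69_distance(p: float) -> float:
    """Closed-form JC69 correction of an observed mismatch fraction."""
    if p >= 0.75:
        raise ValueError("saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
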