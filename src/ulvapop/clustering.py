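"""SNP-matrix construction, PCA and species clustering.

The strains x variant-sites genotype matrix is built from per-strain variant
tables against one common reference.  PCA follows the standard population-
genetics normalization: columns centred and scaled by sqrt(p(1-p)) of the
column allele fraction, with heterozygous genotypes coded 0.5 so that an F1
hybrid falls midway between its parents' clusters.

Cluster delimitation is hierarchical (single linkage on SNP-count distance).
Two cut rules are provided: "inconsistency" (default) tests each merge height
against the distribution of merge heights inside its own subtrees, which
remains valid when species differ widely in their intra-specific diversity;
"gap" cuts at the largest relative gap in sorted merge heights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from . import seq as sq
from .mapvar import CALL_HET, CALL_NOCALL, CALL_VARIANT


@dataclass
class SnpMatrix:
    """Genotype codes per strain and variant site: 0 ref, 1 alt, 0.5 het,
    NaN missing (no-call)."""

    strains: list[str]
    positions: np.ndarray
    data: np.ndarray  # float, shape (n_strains, n_sites)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.strains, columns=self.positions)


@dataclass
class PcaResult:
    coordinates: np.ndarray         # (n_strains, n_components)
    explained_variance: np.ndarray  # fractions, non-increasing
    loadings: np.ndarray            # (n_sites, n_components)
    strains: list[str]

    def frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.strains, columns=cols)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    n_clusters: int
    species_names: dict[int, str] = field(default_factory=dict)
    separation_score: float = float("nan")

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster]


def build_snp_matrix(variant_tables: Mapping[str, pd.DataFrame]) -> SnpMatrix:
    """Union of variant positions across strains; deterministic column order
    by position.  A column exists only if at least one strain is non-ref."""
    strains = list(variant_tables)
    pos_set: set[int] = set()
    for vt in variant_tables.values():
        called = vt[vt.call.isin([CALL_VARIANT, CALL_HET])]
        pos_set.update(int(p) for p in called.position)
    positions = np.array(sorted(pos_set), dtype=int)
    data = np.zeros((len(strains), positions.size))
    pos_index = {p: j for j, p in enumerate(positions)}
    for i, s in enumerate(strains):
        for row in variant_tables[s].itertuples(index=False):
            j = pos_index.get(int(row.position))
            if j is None:
                continue
            if row.call == CALL_VARIANT:
                data[i, j] = 1.0
            elif row.call == CALL_HET:
                data[i, j] = 0.5
            elif row.call == CALL_NOCALL:
                data[i, j] = np.nan
    return SnpMatrix(strains, positions, data)


def pca(matrix: SnpMatrix, n_components: int = 5) -> PcaResult:
    """Allele-frequency-normalized PCA of the genotype matrix.

    Columns are centred on the column mean allele fraction p and scaled by
    sqrt(p(1-p)); missing entries are imputed to p (zero after centring).
    The sign of each component is fixed so its largest-magnitude loading is
    positive.  A zero-variance matrix yields zero coordinates with a warning.
    """
    n, m = matrix.shape
    if n < 2:
        raise ValueError("need >= 2 strains")
    n_components = min(n_components, n, max(m, 1))
    if m == 0:
        warnings.warn("empty SNP matrix; zero coordinates")
        return PcaResult(np.zeros((n, n_components)), np.zeros(n_components), np.zeros((0, n_components)), matrix.strains)
    X = matrix.data.copy()
    p = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(p, inds[1])
    scale = np.sqrt(p * (1.0 - p))
    scale[scale == 0] = 1.0
    Z = (X - p) / scale
    if not Z.any():
        warnings.warn("zero-variance SNP matrix; zero coordinates")
        return PcaResult(np.zeros((n, n_components)), np.zeros(n_components), np.zeros((m, n_components)), matrix.strains)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    total = var.sum()
    k = n_components
    coords = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    # sign convention: largest-magnitude loading positive
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1
    return PcaResult(coords, var[:k] / total, loadings, matrix.strains)


# ---------------------------------------------------------------------------
# Cluster delimitation
# ---------------------------------------------------------------------------


def snp_distance_matrix(matrix: SnpMatrix) -> np.ndarray:
    """Pairwise SNP-count distance: sum of |genotype differences| over sites
    observed in both strains."""
    X = matrix.data
    n = X.shape[0]
    D = np.zeros((n, n))
    obs = ~np.isnan(X)
    Xf = np.nan_to_num(X)
    for i in range(n):
        both = obs[i] & obs
        diff = np.abs(Xf[i] - Xf) * both
        D[i] = diff.sum(axis=1)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _condensed(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], 1)
    return D[iu]


def delimit_clusters(
    matrix: SnpMatrix | np.ndarray,
    method: str = "inconsistency",
    split_z: float = 4.0,
    linkage_gap_factor: float = 5.0,
) -> ClusterAssignment:
    """Delimit species clusters on the SNP matrix (or a precomputed distance
    matrix).  The cluster count is emergent, never fixed in advance.

    method="inconsistency": a merge is cut when its height is ``split_z``
    robust standard deviations above the merge heights inside its two
    subtrees, so species whose intra-specific diversity differs by orders of
    magnitude are still separated from their closest neighbour species.
    method="gap": the spec-simple rule -- cut at the largest relative gap in
    sorted merge heights if it exceeds ``linkage_gap_factor``.
    """
    if isinstance(matrix, SnpMatrix):
        strains = matrix.strains
        D = snp_distance_matrix(matrix)
    else:
        D = np.asarray(matrix, dtype=float)
        strains = [f"s{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 2:
        raise ValueError("need >= 2 strains")
    Z = linkage(_condensed(D), method="single")
    if method == "gap":
        labels = _cut_gap(Z, n, linkage_gap_factor)
    elif method == "inconsistency":
        labels = _cut_inconsistency(Z, n, split_z)
    else:
        raise ValueError(f"unknown method {method!r}")
    # relabel clusters deterministically by first-strain appearance
    remap: dict[int, int] = {}
    out = {}
    for s, lab in zip(strains, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[s] = remap[lab]
    k = len(remap)
    return ClusterAssignment(out, k, separation_score=_silhouette(D, np.array([out[s] for s in strains])))


def _cut_gap(Z: np.ndarray, n: int, factor: float) -> np.ndarray:
    heights = np.sort(Z[:, 2])
    eps = max(1e-9, 1e-6 * (heights[-1] if heights[-1] > 0 else 1.0))
    ratios = (heights[1:] + eps) / (heights[:-1] + eps)
    if ratios.size == 0 or ratios.max() < factor:
        warnings.warn("no merge-height gap above factor; one cluster")
        return np.zeros(n, dtype=int)
    i = int(np.argmax(ratios))
    thresh = (heights[i] + heights[i + 1]) / 2.0
    return _cut_at_height(Z, n, thresh)


def _cut_inconsistency(Z: np.ndarray, n: int, split_z: float) -> np.ndarray:
    # Per internal node: heights of *uncut* merges in its subtree (the
    # within-cluster distance scale).  Heights of merges already flagged as
    # between-cluster joins are excluded, so one split does not inflate the
    # scale estimate of merges above it.  SNP-count distances are
    # Poisson-scale, hence the sqrt(mean) floor on the spread estimate.
    pools: list[list[float]] = [[] for _ in range(2 * n - 1)]
    cut = np.zeros(n - 1, dtype=bool)
    for m in range(n - 1):
        a, b, h, _ = Z[m]
        a, b = int(a), int(b)
        inner = pools[a] + pools[b]
        node = n + m
        if not inner:
            pools[node] = [h]  # two singletons: accept
            continue
        mu = float(np.mean(inner))
        sd = float(np.std(inner))
        sd_eff = max(sd, math.sqrt(max(mu, 0.0)), 1.0)
        if (h - mu) / sd_eff > split_z:
            cut[m] = True
            pools[node] = inner
        else:
            pools[node] = inner + [h]
    # descend from the root; an uncut node is a cluster
    labels = np.zeros(n, dtype=int)
    next_label = [0]

    members: list[list[int]] = [[i] for i in range(n)] + [[] for _ in range(n - 1)]
    for m in range(n - 1):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        members[n + m] = members[a] + members[b]

    def assign(node: int) -> None:
        if node < n:
            labels[node] = next_label[0]
            next_label[0] += 1
            return
        m = node - n
        if cut[m]:
            assign(int(Z[m, 0]))
            assign(int(Z[m, 1]))
        else:
            for leaf in members[node]:
                labels[leaf] = next_label[0]
            next_label[0] += 1

    assign(2 * n - 2)
    return labels


def _cut_at_height(Z: np.ndarray, n: int, thresh: float) -> np.ndarray:
    from scipy.cluster.hierarchy import fcluster

    return fcluster(Z, t=thresh, criterion="distance")


def _silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over strains (NaN when a single cluster)."""
    uniq = np.unique(labels)
    if uniq.size < 2:
        return float("nan")
    svals = []
    for i in range(D.shape[0]):
        own = labels == labels[i]
        own[i] = False
        a = D[i, own].mean() if own.any() else 0.0
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        svals.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(svals))


# ---------------------------------------------------------------------------
# Barcode species assignment
# ---------------------------------------------------------------------------


def assign_species(
    barcode: str,
    panel: Mapping[str, str],
) -> tuple[list[str], float]:
    """Assign a species label by maximal identity with a panel of labelled
    reference barcode sequences (equal length assumed; identity = matches /
    compared positions).  Ties report every tied label.
    """
    if not panel:
        raise ValueError("empty reference panel")
    q = sq.encode(barcode)
    best_labels: list[str] = []
    best_ident = -1.0
    for label, ref in panel.items():
        r = sq.encode(ref)
        if r.size != q.size:
            raise ValueError(f"panel entry {label} length mismatch")
        ident = float(np.count_nonzero(q == r)) / q.size
        if ident > best_ident + 1e-12:
            best_labels, best_ident = [label], ident
        elif abs(ident - best_ident) <= 1e-12:
            best_labels.append(label)
    return best_labels, best_ident
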