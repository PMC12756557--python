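"""Ward.D2 agglomerative clustering, Newick export and bootstrap clade support.

The agglomeration follows the ward.D2 convention (as in R's
``hclust(method = "ward.D2")``): the algorithm operates on squared
dissimilarities and reports merge heights on the original distance scale,
updating cluster distances by the Lance–Williams recurrence

    d^2(k, i u j) = ((n_i + n_k) d^2(k, i) + (n_j + n_k) d^2(k, j)
                     - n_k d^2(i, j)) / (n_i + n_j + n_k)

so two singletons merge exactly at their pairwise distance.  Ties in merge
cost are broken deterministically by the lexicographically smallest
(cluster-id, cluster-id) pair, making results platform-independent.

Clade support: sites (matrix columns) are resampled with replacement, the
masked distance and the tree are recomputed, and a clade of the reference
tree is supported by a replicate iff some replicate clade has the identical
leaf set.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree
from sklearn.metrics import adjusted_rand_score

from .distance import DistanceMatrix, VAFMatrix, pairwise_distance


@dataclasses.dataclass
class Dendrogram:
    """Binary merge tree over named leaves.

    ``merges`` lists (node_a, node_b, height, size) in merge order; node ids
    follow the scipy linkage convention (leaves 0..n-1, the t-th merge
    creates node n+t).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a binary dendrogram has exactly n-1 merges")

    @property
    def linkage_matrix(self) -> np.ndarray:
        return np.array(self.merges, dtype=float)

    def clades(self, include_trivial: bool = False) -> list[frozenset[str]]:
        """Leaf sets of internal nodes; trivial clades (singletons, the full
        leaf set) are excluded unless requested."""
        n = len(self.leaves)
        sets: dict[int, frozenset[str]] = {
            i: frozenset([name]) for i, name in enumerate(self.leaves)
        }
        out: list[frozenset[str]] = []
        for t, (a, b, _, _) in enumerate(self.merges):
            sets[n + t] = sets[a] | sets[b]
            out.append(sets[n + t])
        if not include_trivial:
            out = [c for c in out if 1 < len(c) < n]
        return out

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into k clusters by cutting the tree."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValueError(f"k must lie in [1, {n}]")
        labels = cut_tree(self.linkage_matrix, n_clusters=k).ravel()
        return dict(zip(self.leaves, (int(x) for x in labels)))


def ward_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerate a fully defined distance matrix with ward.D2."""
    n = len(dm.samples)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not dm.all_defined:
        raise ValueError(
            "distance matrix has undefined pairs (insufficient co-covered "
            "sites); refusing to cluster"
        )
    # active cluster bookkeeping: ids are scipy-style node ids
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    W = dm.d.astype(float) ** 2  # current squared ward.D2 distances
    merges: list[tuple[int, int, float, int]] = []
    for t in range(n - 1):
        a = len(ids)
        iu = np.triu_indices(a, k=1)
        costs = W[iu]
        best = costs.min()
        # deterministic tie-break: smallest (low-id, high-id) among minima
        tied = np.flatnonzero(costs == best)
        cand = []
        for flat in tied:
            pi, pj = iu[0][flat], iu[1][flat]
            lo, hi = sorted((ids[pi], ids[pj]))
            cand.append((lo, hi, pi, pj))
        lo, hi, pi, pj = min(cand)
        ni, nj = sizes[ids[pi]], sizes[ids[pj]]
        new_id = n + t
        height = float(np.sqrt(max(best, 0.0)))
        merges.append((lo, hi, height, ni + nj))

        # Lance-Williams ward.D2 update against every other active cluster
        keep = [x for x in range(a) if x not in (pi, pj)]
        nk = np.array([sizes[ids[x]] for x in keep], dtype=float)
        new_row = (
            (ni + nk) * W[pi, keep] + (nj + nk) * W[pj, keep] - nk * W[pi, pj]
        ) / (ni + nj + nk) if keep else np.empty(0)

        W = W[np.ix_(keep, keep)]
        W = np.pad(W, ((0, 1), (0, 1)))
        W[-1, :-1] = new_row
        W[:-1, -1] = new_row
        ids = [ids[x] for x in keep] + [new_id]
        sizes[new_id] = ni + nj
    return Dendrogram(leaves=list(dm.samples), merges=merges)


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = set(" \t()[]':;,")


def _newick_label(name: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(t: Dendrogram) -> str:
    """Ultrametric Newick text: branch length = parent merge height minus
    child merge height (leaves sit at height 0)."""
    n = len(t.leaves)
    children: dict[int, tuple[int, int]] = {}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for i, (a, b, h, _) in enumerate(t.merges):
        children[n + i] = (a, b)
        heights[n + i] = h

    def render(node: int, parent_height: float) -> str:
        blen = parent_height - heights[node]
        if node < n:
            return f"{_newick_label(t.leaves[node])}:{blen:.10g}"
        a, b = children[node]
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{blen:.10g}"

    root = n + len(t.merges) - 1
    a, b = children[root]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"


# ---------------------------------------------------------------------------
# bootstrap clade support
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BootstrapResult:
    """Support fraction per reference-tree clade, over ``n_replicates``
    site-resampling replicates (``n_dropped`` of which were unusable)."""

    support: dict[frozenset[str], float]
    n_replicates: int
    n_dropped: int = 0

    def table(self) -> list[tuple[str, float]]:
        rows = [
            (";".join(sorted(clade)), frac) for clade, frac in self.support.items()
        ]
        rows.sort(key=lambda r: (-r[1], r[0]))
        return rows


def bootstrap_support(
    m: VAFMatrix,
    B: int = 1000,
    min_pair_depth: int = 8,
    seed: int | None = None,
    reference: Dendrogram | None = None,
) -> BootstrapResult:
    """Position-bootstrap support for the clades of the reference tree.

    Each replicate resamples site columns with replacement (same count),
    re-applies the per-pair coverage mask on the resampled columns, and
    recomputes distances and the ward.D2 tree.  Replicate r draws from a
    stream keyed by (seed, r), so support values are reproducible and
    independent of evaluation order.  A replicate whose resampled matrix
    leaves some pair with no co-covered site is dropped and counted; more
    than 10% dropped aborts with a diagnostic.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if reference is None:
        reference = ward_cluster(pairwise_distance(m, min_pair_depth=min_pair_depth))
    ref_clades = reference.clades()
    counts = {clade: 0 for clade in ref_clades}
    n_sites = m.vaf.shape[1]
    dropped = 0
    for r in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, r]))
        idx = rng.integers(0, n_sites, size=n_sites)
        sub = m.subset_sites(idx)
        try:
            dm = pairwise_distance(sub, min_pair_depth=min_pair_depth)
            if not dm.all_defined:
                dropped += 1
                continue
            tree = ward_cluster(dm)
        except ValueError:
            dropped += 1
            continue
        rep_clades = set(tree.clades())
        for clade in ref_clades:
            if clade in rep_clades:
                counts[clade] += 1
    if dropped > 0.1 * B:
        raise RuntimeError(
            f"{dropped}/{B} bootstrap replicates had pairs with no co-covered "
            "sites; coverage is too sparse for site resampling"
        )
    used = B - dropped
    support = {clade: c / used for clade, c in counts.items()}
    return BootstrapResult(support=support, n_replicates=B, n_dropped=dropped)


def cut_and_score(
    t: Dendrogram, k: int, truth_labels: dict[str, str] | Sequence[str]
) -> tuple[dict[str, int], float]:
    """Cut the dendrogram into k clusters and score against truth with the
    adjusted Rand index.  ``truth_labels`` may be a dict by leaf name or a
    sequence aligned with ``t.leaves``; leaves absent from a dict are
    ignored in the score (useful to score pure samples only)."""
    part = t.cut(k)
    if isinstance(truth_labels, dict):
        common = [leaf for leaf in t.leaves if leaf in truth_labels]
        pred = [part[leaf] for leaf in common]
        true = [truth_labels[leaf] for leaf in common]
    else:
        if len(truth_labels) != len(t.leaves):
            raise ValueError("truth label sequence length mismatch")
        pred = [part[leaf] for leaf in t.leaves]
        true = list(truth_labels)
    ari = float(adjusted_rand_score(true, pred))
    return part, ari
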