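"""Correlation-based community dendrograms and the agglomerative coefficient.

Sample-by-sample Spearman (or Pearson) correlations of OTU profiles are
turned into dissimilarities (d = 1 - r) and clustered by agglomerative
nesting (AGNES) with average linkage (UPGMA) by default. The agglomerative
coefficient AC — the mean over leaves of 1 minus the ratio of the leaf's
first merge height to the final merge height — summarizes how sharply the
data partition: 0 for equidistant leaves, approaching 1 when early merges
are tight relative to the final join.

The agglomeration is implemented directly (Lance-Williams updates with
deterministic smallest-index tie-breaking) so that merge order is
reproducible across platforms; a generic hierarchical-clustering library
serves as an independent cross-check in the test-suite, not as the
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DendrogramResult",
    "correlation_matrix",
    "cor_to_dissimilarity",
    "agnes",
    "export_newick",
]


@dataclass
class DendrogramResult:
    """Merge history of an agglomerative clustering.

    ``merges`` lists (left, right, height) triples; node ids 0..n-1 are
    leaves, n+k is the cluster created by merge k. ``agglomerative_coefficient``
    is mean_i (1 - h_first(i) / h_final).
    """

    merges: list[tuple[int, int, float]]
    leaf_labels: tuple[str, ...]
    linkage: str
    agglomerative_coefficient: float

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)


def correlation_matrix(values, method: str = "spearman", sample_ids=None) -> np.ndarray:
    """Sample x sample correlation matrix of OTU profiles.

    ``values`` is an (OTUs x samples) matrix (counts, proportions, or a
    RelAbundTable / OtuTable-like object with ``.values`` / ``.counts``).
    Spearman uses mid-ranks for ties. A constant profile has no defined
    rank correlation and raises, naming the sample.
    """
    mat = _as_matrix(values)
    if sample_ids is None:
        sample_ids = [str(j) for j in range(mat.shape[1])]
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if method == "spearman":
        ranked = np.apply_along_axis(stats.rankdata, 0, mat)
        work = ranked
    elif method == "pearson":
        work = mat.astype(float)
    else:
        raise ValueError(f"unknown method: {method!r}")
    sd = work.std(axis=0)
    if (sd == 0).any():
        bad = sample_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"constant profile, correlation undefined: sample {bad!r}")
    r = np.corrcoef(work, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _as_matrix(values) -> np.ndarray:
    for attr in ("values", "counts"):
        v = getattr(values, attr, None)
        if isinstance(v, np.ndarray):
            return v
    return np.asarray(values, dtype=float)


def cor_to_dissimilarity(cor: np.ndarray) -> np.ndarray:
    """d = 1 - r; zero diagonal, symmetric, range [0, 2]."""
    cor = np.asarray(cor, dtype=float)
    if (cor < -1 - 1e-12).any() or (cor > 1 + 1e-12).any():
        raise ValueError("correlations must lie in [-1, 1]")
    d = 1.0 - cor
    np.fill_diagonal(d, 0.0)
    return d


def agnes(dissimilarity, linkage: str = "average", leaf_labels=None) -> DendrogramResult:
    """Agglomerative nesting of a dissimilarity matrix.

    Linkage is ``average`` (UPGMA, the default of the classic AGNES
    routine), ``single`` or ``complete``. Ties in the minimum
    dissimilarity are broken toward the smallest (left, right) index pair,
    making merge order deterministic.
    """
    d = np.array(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("dissimilarity must be square")
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    if (np.diag(d) != 0).any():
        raise ValueError("diagonal must be zero")
    if (d < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage: {linkage!r}")
    if leaf_labels is None:
        leaf_labels = tuple(f"L{i}" for i in range(n))
    leaf_labels = tuple(leaf_labels)
    if len(leaf_labels) != n:
        raise ValueError("leaf_labels length mismatch")

    # active clusters: id -> (size, row index in working matrix)
    ids = list(range(n))  # cluster id per active slot
    sizes = {i: 1 for i in range(n)}
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    merges: list[tuple[int, int, float]] = []
    first_height = np.full(n, np.nan)
    next_id = n
    active = list(range(n))  # indices into work that are live

    while len(active) > 1:
        act = np.array(active)
        sub = work[np.ix_(act, act)]
        iu = np.triu_indices(len(act), 1)
        vals = sub[iu]
        m = vals.min()
        tied = np.flatnonzero(vals <= m + 1e-15)
        # break ties toward the smallest (min id, max id) cluster-id pair
        def key(t):
            a_, b_ = act[iu[0][t]], act[iu[1][t]]
            ida_, idb_ = sorted((ids[a_], ids[b_]))
            return (ida_, idb_)
        t = min(tied, key=key)
        a, b = int(act[iu[0][t]]), int(act[iu[1][t]])
        h = float(work[a, b])
        ida, idb = sorted((ids[a], ids[b]))
        merges.append((ida, idb, float(h)))
        for cid in (ids[a], ids[b]):
            if cid < n and np.isnan(first_height[cid]):
                first_height[cid] = h
        # Lance-Williams update into slot a
        na, nb = sizes[ids[a]], sizes[ids[b]]
        for c in active:
            if c in (a, b):
                continue
            if linkage == "average":
                new = (na * work[a, c] + nb * work[b, c]) / (na + nb)
            elif linkage == "single":
                new = min(work[a, c], work[b, c])
            else:
                new = max(work[a, c], work[b, c])
            work[a, c] = work[c, a] = new
        sizes[next_id] = na + nb
        ids[a] = next_id
        next_id += 1
        active.remove(b)

    final_h = merges[-1][2]
    if final_h <= 0:
        ac = 0.0
    else:
        ac = float(np.mean(1.0 - first_height / final_h))
    return DendrogramResult(
        merges=merges,
        leaf_labels=leaf_labels,
        linkage=linkage,
        agglomerative_coefficient=ac,
    )


def export_newick(dend: DendrogramResult) -> str:
    """Newick string with ultrametric branch lengths.

    Each cluster node sits at half its merge height (so the tip-to-tip
    distance through a node equals the merge height); branch length of a
    child is the parent's height minus the child's height.
    """
    n = dend.n_leaves
    node_height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h) in enumerate(dend.merges):
        node = n + k
        node_height[node] = h / 2.0
        children[node] = (a, b)

    def fmt(node: int, parent_h: float) -> str:
        bl = parent_h - node_height[node]
        if node < n:
            label = dend.leaf_labels[node].replace(" ", "_")
            return f"{label}:{bl:.10g}"
        a, b = children[node]
        return f"({fmt(a, node_height[node])},{fmt(b, node_height[node])}):{bl:.10g}"

    root = n + len(dend.merges) - 1
    a, b = children[root]
    rh = node_height[root]
    return f"({fmt(a, rh)},{fmt(b, rh)});"
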