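"""Unsupervised hierarchical clustering of phenotypic signatures.

Distances are plain Euclidean between Z-score vectors (full 40-entry
signatures, or the 20-entry distal / proximal partial signatures);
agglomeration is bottom-up average linkage (UPGMA). No rescaling of
heights or renormalization of inputs is applied: the Z-scoring of the
signature entries already provides the normalization clustering needs,
and heights stay in Z-distance units for traceability.

Ties between candidate merges are broken lexicographically on the
sorted leaf-label sets of the two clusters, making the dendrogram
deterministic under input permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ohp.core import OhpError
from ohp.signature import Signature

__all__ = [
    "Dendrogram",
    "signature_distance_matrix",
    "average_linkage",
    "write_merge_table",
    "plot_dendrogram",
]


def signature_distance_matrix(
    signatures: list[Signature], subset: str = "full"
) -> np.ndarray:
    """Symmetric Euclidean distance matrix between signatures.

    ``subset`` selects 'full' (all 40 entries), 'distal' or 'proximal'
    (20 entries each). All signatures must share the same parameter
    ordering.
    """
    if not signatures:
        raise OhpError("need at least one signature")
    names = signatures[0].parameter_names
    for sig in signatures[1:]:
        if sig.parameter_names != names:
            raise OhpError(
                f"signature {sig.label!r} has a different parameter ordering"
            )
    idx = signatures[0].subset_indices(subset)
    vectors = np.array([sig.z_values[idx] for sig in signatures])
    diff = vectors[:, None, :] - vectors[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


@dataclass
class Dendrogram:
    """UPGMA merge tree over labelled leaves.

    ``merges`` uses scipy-style node ids: leaf i is node i, the k-th
    merge creates node n_leaves + k. Heights are average inter-cluster
    distances and are non-decreasing (UPGMA is monotone).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]]  # (left, right, height, size)

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise OhpError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [m[2] for m in self.merges]
        if any(h < -1e-12 for h in heights):
            raise OhpError("merge heights must be non-negative")
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise OhpError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy.cluster.hierarchy-compatible linkage matrix."""
        return np.array([[l, r, h, s] for l, r, h, s in self.merges], dtype=float)

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (leaf depth =
        half the root merge height, the standard UPGMA tree)."""
        n = len(self.leaves)
        node_height = {i: 0.0 for i in range(n)}
        subtree = {i: self.leaves[i] for i in range(n)}
        for k, (left, right, height, _size) in enumerate(self.merges):
            h = height / 2.0
            parts = []
            for child in (left, right):
                bl = h - node_height[child]
                parts.append(f"{subtree[child]}:{bl:.6g}")
            node = n + k
            subtree[node] = "(" + ",".join(parts) + ")"
            node_height[node] = h
            del subtree[left], subtree[right]
        return next(iter(subtree.values())) + ";"


def average_linkage(
    dist: np.ndarray, labels: list[str] | None = None
) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix.

    At each step the pair of clusters with minimal average inter-cluster
    distance is merged at that average; after merging A and B, the
    distance to any other cluster C is the size-weighted mean
    (n_A d_AC + n_B d_BC) / (n_A + n_B), which keeps every inter-cluster
    distance the exact mean of its leaf-pair distances.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[1] != n:
        raise OhpError(f"distance matrix must be square, got {dist.shape}")
    if n < 2:
        raise OhpError("clustering needs at least 2 items")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise OhpError("distance matrix must be symmetric")
    if labels is None:
        labels = [f"item{i}" for i in range(n)]
    if len(labels) != n:
        raise OhpError("label count must match matrix size")

    # Active clusters: node id -> (sorted leaf-label tuple, size).
    active: dict[int, tuple[tuple[str, ...], int]] = {
        i: ((labels[i],), 1) for i in range(n)
    }
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), dij in d.items():
            key = (dij, *sorted((active[i][0], active[j][0])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        height = d[(i, j)]
        (leaves_i, size_i), (leaves_j, size_j) = active[i], active[j]
        new_size = size_i + size_j
        new_id = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            d[(k, new_id)] = (size_i * dik + size_j * djk) / new_size
        d = {
            pair: v
            for pair, v in d.items()
            if i not in pair and j not in pair
        }
        del active[i], active[j]
        active[new_id] = (tuple(sorted(leaves_i + leaves_j)), new_size)
        merges.append((i, j, height, new_size))
    return Dendrogram(leaves=list(labels), merges=merges)


def write_merge_table(dendrogram: Dendrogram, path: str | Path) -> Path:
    """Flat merge-table CSV: left, right, height, size (scipy node ids)."""
    df = pd.DataFrame(
        dendrogram.merges, columns=["left", "right", "height", "size"]
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def plot_dendrogram(dendrogram: Dendrogram, path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    fig, ax = plt.subplots(figsize=(6, 4))
    scipy_dendrogram(
        dendrogram.to_linkage_matrix(), labels=dendrogram.leaves, ax=ax,
        leaf_rotation=45,
    )
    ax.set_ylabel("average-linkage height (Z-distance)")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
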