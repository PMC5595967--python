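"""Hierarchical clustering of cell-cycle fingerprints for mechanism grouping.

Distances are plain Euclidean on the raw four-phase percentages; merging is
complete (maximum) agglomerative linkage with fully deterministic
tie-breaking, so dendrograms are bit-reproducible.  The Z-score transform
(per drug, across the four phases) is a display normalization only — it is
applied after clustering, for the heatmap, never before the distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cycleprof.cci import Fingerprint
from cycleprof.errors import ValidationError


@dataclass(frozen=True)
class ClusterTree:
    """Merge history of an agglomerative clustering.

    ``merges[t] = (a, b, height)`` joins cluster ids a < b at the given
    height; leaves are 0..n-1 and merge t creates cluster id n + t (the
    scipy linkage convention).  ``leaf_order`` is the left-to-right
    dendrogram order with the smaller-id subtree drawn first.
    """

    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[int, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.merges) + 1


def distance_matrix(fingerprints: list[Fingerprint]) -> np.ndarray:
    """Pairwise Euclidean distance on raw percentages (never Z-scored)."""
    if len(fingerprints) < 2:
        raise ValidationError("need >= 2 fingerprints")
    x = np.array([fp.as_tuple() for fp in fingerprints], float)
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def complete_linkage(dist: np.ndarray) -> ClusterTree:
    """Agglomerative clustering with maximum inter-cluster distance.

    At each step the globally closest cluster pair merges; exact ties go to
    the lexicographically smallest (a, b) id pair.  Cluster-to-cluster
    distances update by the Lance-Williams rule for complete linkage,
    d(a+b, c) = max(d(a,c), d(b,c)).
    """
    dist = np.asarray(dist, float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[1] != n:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValidationError("distance matrix must be symmetric")
    if (dist < 0).any():
        raise ValidationError("distances must be non-negative")
    if n < 2:
        raise ValidationError("need >= 2 leaves")

    # active cluster id -> {other active id: distance}
    d: dict[int, dict[int, float]] = {
        i: {j: float(dist[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        best = None  # (height, a, b)
        for a in sorted(d):
            for b in sorted(d[a]):
                if b <= a:
                    continue
                h = d[a][b]
                if best is None or h < best[0] or (h == best[0] and (a, b) < best[1:]):
                    best = (h, a, b)
        h, a, b = best
        merges.append((a, b, h))
        children[next_id] = (a, b)
        new_row = {
            c: max(d[a][c], d[b][c]) for c in d if c not in (a, b)
        }
        del d[a], d[b]
        for c in d:
            d[c].pop(a, None)
            d[c].pop(b, None)
            d[c][next_id] = new_row[c]
        d[next_id] = new_row
        next_id += 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    leaf_order = tuple(leaves(next_id - 1))
    return ClusterTree(merges=tuple(merges), leaf_order=leaf_order)


def zscore_transform(matrix, axis: int = 1) -> np.ndarray:
    """Per-row (default) centering/scaling by the sample SD across phases.

    axis=1 standardizes each drug across its four phase values (the
    within-drug reading of "across the four cell cycle phases"); axis=0
    standardizes each phase across drugs.  Zero-variance slices map to
    zeros with a warning rather than NaN.
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[axis] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 entries along the scaled axis")
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance row(s)/column(s) mapped to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    return np.where(np.broadcast_to(flat, z.shape), 0.0, z)


def heatmap_export(
    tree: ClusterTree,
    z: np.ndarray,
    labels: list[str],
    out_prefix: str | None = None,
    phase_names: tuple[str, ...] = ("g1", "s", "g2m", "subg1"),
) -> pd.DataFrame:
    """Leaf-ordered heatmap table, optionally with CSV + figure on disk.

    Rows are permuted by the dendrogram leaf order; the figure uses a
    diverging red (low) -> blue (high) scale.  The ordered numeric table is
    returned (and written) so the plot itself is testable.
    """
    z = np.asarray(z, float)
    if z.shape[0] != tree.n_leaves or z.shape[0] != len(labels):
        raise ValidationError("tree, matrix and labels disagree on the number of drugs")
    if z.shape[1] != len(phase_names):
        raise ValidationError("matrix column count does not match phase names")
    order = list(tree.leaf_order)
    table = pd.DataFrame(z[order], columns=list(phase_names))
    table.insert(0, "compound", [labels[i] for i in order])
    if out_prefix is not None:
        table.to_csv(f"{out_prefix}_matrix.csv", index=False)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, max(2.0, 0.25 * len(order))))
        vmax = float(np.abs(z).max()) or 1.0
        im = ax.imshow(z[order], aspect="auto", cmap="RdBu", vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(len(phase_names)), phase_names)
        ax.set_yticks(range(len(order)), [labels[i] for i in order], fontsize=6)
        fig.colorbar(im, ax=ax, label="Z score")
        fig.tight_layout()
        fig.savefig(f"{out_prefix}_heatmap.png", dpi=150)
        plt.close(fig)
    return table


def tree_to_newick(tree: ClusterTree, labels: list[str]) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    n = tree.n_leaves
    if len(labels) != n:
        raise ValidationError("label count does not match leaf count")
    height = {i: 0.0 for i in range(n)}
    node_str = {i: str(labels[i]) for i in range(n)}
    for t, (a, b, h) in enumerate(tree.merges):
        nid = n + t
        sa = f"{node_str[a]}:{h - height[a]:g}"
        sb = f"{node_str[b]}:{h - height[b]:g}"
        node_str[nid] = f"({sa},{sb})"
        height[nid] = h
    return node_str[2 * n - 2] + ";"
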