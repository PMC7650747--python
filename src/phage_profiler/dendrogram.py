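"""Agglomerative merge trees with Newick export and partition cuts."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster


def _escape_label(name: str) -> str:
    if re.search(r"[\s,():;\[\]']", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


@dataclass
class Dendrogram:
    """A rooted agglomerative clustering tree.

    ``ids`` are the leaf labels in input order; ``linkage`` is a scipy-style
    ``(n-1, 4)`` merge table whose heights are non-decreasing.  A single-leaf
    tree has an empty linkage.
    """

    ids: list[str]
    linkage: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.ids)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate leaf ids")
        if n > 1 and self.linkage.shape != (n - 1, 4):
            raise ValueError(
                f"linkage shape {self.linkage.shape} inconsistent with {n} leaves"
            )
        heights = self.linkage[:, 2]
        if heights.size and np.any(np.diff(heights) < -1e-9 * max(1.0, heights.max())):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """Merge sequence as ``(left, right, height)`` with scipy node numbering."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cut(self, n_clusters: int | None = None, height: float | None = None) -> dict[str, int]:
        """Cut the tree into flat clusters; returns id -> integer label."""
        if (n_clusters is None) == (height is None):
            raise ValueError("supply exactly one of n_clusters / height")
        if self.n_leaves == 1:
            return {self.ids[0]: 1}
        if n_clusters is not None:
            if not 1 <= n_clusters <= self.n_leaves:
                raise ValueError("n_clusters out of range")
            labels = fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        else:
            labels = fcluster(self.linkage, t=height, criterion="distance")
        return {gid: int(lab) for gid, lab in zip(self.ids, labels)}

    def to_newick(self) -> str:
        """Serialise as rooted Newick with branch lengths from merge heights.

        Each branch length is the height difference between a node (leaves at
        height 0) and its parent; the root carries no branch length.
        """
        n = len(self.ids)
        if n == 1:
            return f"{_escape_label(self.ids[0])};"
        node_height = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            node_height[node] = h
            children[node] = (a, b)

        def render(node: int, parent_height: float) -> str:
            bl = _fmt(parent_height - node_height[node])
            if node < n:
                return f"{_escape_label(self.ids[node])}:{bl}"
            a, b = children[node]
            inner = f"({render(a, node_height[node])},{render(b, node_height[node])})"
            return f"{inner}:{bl}"

        root = n + len(self.merges) - 1
        a, b = children[root]
        h = node_height[root]
        return f"({render(a, h)},{render(b, h)});"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")
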