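"""Neighbour-joining trees and site-resampling bootstrap support.

Saitou & Nei agglomeration on a labelled distance matrix; negative branch
lengths are clamped to zero with the deficit moved to the sister branch so
patristic distances of the joined pair are preserved. Bootstrap support
resamples alignment columns with replacement within each locus, rebuilds
the averaged p-distance matrix and counts, per internal bipartition of the
point-estimate tree, the percentage of replicate trees containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import DistanceMatrix, SequenceAlignment
from .popgen import pairwise_p_distance


@dataclass
class _Node:
    name: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.name])  # type: ignore[list-item]
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaves()
        return frozenset(out)


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary root at the last join."""

    taxa: list[str]
    root: _Node
    support: dict[frozenset[str], float] | None = None

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the first taxon."""
        all_taxa = frozenset(self.taxa)
        ref = self.taxa[0]
        out: set[frozenset[str]] = set()

        def visit(node: _Node) -> None:
            for child, _ in node.children:
                side = child.leaves()
                if 1 < len(side) < len(all_taxa) - 1:
                    canon = side if ref not in side else all_taxa - side
                    out.add(canon)
                visit(child)

        visit(self.root)
        return out

    def total_length(self) -> float:
        total = 0.0

        def visit(node: _Node) -> None:
            nonlocal total
            for child, length in node.children:
                total += length
                visit(child)

        visit(self.root)
        return total

    def newick(self, decimals: int = 6) -> str:
        all_taxa = frozenset(self.taxa)
        ref = self.taxa[0]

        def fmt(node: _Node, length: float | None) -> str:
            if not node.children:
                label = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = f"({inner})"
                if self.support is not None and length is not None:
                    side = node.leaves()
                    canon = side if ref not in side else all_taxa - side
                    if canon in self.support:
                        label += f"{self.support[canon]:.0f}"
            if length is None:
                return label
            return f"{label}:{length:.{decimals}f}"

        inner = ",".join(fmt(c, l) for c, l in self.root.children)
        return f"({inner});"


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Neighbour-joining tree from a complete distance matrix.

    Tie-breaking on the Q criterion is deterministic: the pair with the
    lowest (row, column) label indices wins.
    """
    if dm.n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    if not np.isfinite(dm.values).all():
        raise ValueError("missing entries in distance matrix")
    d = dm.values.copy()
    nodes: list[_Node] = [_Node(name=t) for t in dm.labels]
    active = list(range(dm.n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin = deterministic tie-break by lowest (row, col) index
        a, b = np.unravel_index(int(np.argmin(q)), q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_d
        d[active, k] = new_d
        d[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j = active
    final = max(d[i, j], 0.0)
    # attach the remaining branch to whichever side is internal
    if nodes[j].children:
        root = nodes[j]
        root.children.append((nodes[i], final))
    else:
        root = _Node(children=[(nodes[i], final), (nodes[j], 0.0)])
    return PhyloTree(list(dm.labels), root)


def _resample_alignment(
    aln: SequenceAlignment, rng: np.random.Generator
) -> SequenceAlignment:
    cols = rng.integers(0, aln.length, aln.length)
    arr = aln.to_array()[:, cols]
    seqs = [row.tobytes().decode("ascii") for row in arr]
    return SequenceAlignment(aln.locus_id, list(aln.sample_ids), seqs)


def bootstrap_support(
    alns: list[SequenceAlignment],
    n_reps: int = 10_000,
    seed: int | None = None,
) -> PhyloTree:
    """NJ tree on averaged p-distances with bootstrap support (%).

    Sites are resampled with replacement within each locus; support for an
    internal bipartition is the percentage of replicate trees containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dm = pairwise_p_distance(alns)
    tree = neighbor_joining(dm)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep_alns = [_resample_alignment(a, rng) for a in alns]
        rep_dm = pairwise_p_distance(rep_alns)
        rep_tree = neighbor_joining(rep_dm)
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    tree.support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return tree
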