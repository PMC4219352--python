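"""Median-joining haplotype networks.

Construction follows the classic scheme: iteratively build the minimum
spanning network (all links belonging to at least one minimum spanning
tree) under a weighted Hamming distance — transitions cost 1, transversions
cost ``transversion_weight`` (default 2), indels cost the transversion
weight — then add consensus ("median") vectors of triplets drawn from the
current network whenever their inclusion shortens the spanning length,
pruning medians that have become obsolete, until no median helps. Median
vectors represent undetected or extinct intermediate haplotypes and carry
zero observed frequency.

Internally sequences are condensed to their variable sites and encoded as
small integer arrays so distances come from a per-state cost table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .popgen import HaplotypeSet

_TOL = 1e-9
_ALPHABET = "ACGT-"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _cost_table(transversion_weight: float, indel_cost: float) -> np.ndarray:
    table = np.zeros((5, 5))
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == b:
                cost = 0.0
            elif "-" in (a, b):
                cost = indel_cost
            elif is_transition(a, b):
                cost = 1.0
            else:
                cost = transversion_weight
            table[_CODE[a], _CODE[b]] = cost
    return table


def weighted_distance(
    x: str, y: str, transversion_weight: float = 2.0, indel_cost: float | None = None
) -> float:
    """Weighted Hamming distance between two equal-length sequences."""
    if indel_cost is None:
        indel_cost = transversion_weight
    table = _cost_table(transversion_weight, indel_cost)
    xi = np.array([_CODE[c] for c in x])
    yi = np.array([_CODE[c] for c in y])
    return float(table[xi, yi].sum())


def minimum_spanning_network(d: np.ndarray) -> set[tuple[int, int]]:
    """All links contained in at least one minimum spanning tree.

    Kruskal-style sweep: at each distance level, every link joining two
    components of the forest built from strictly smaller levels is kept.
    """
    n = d.shape[0]
    parent = list(range(n))

    def find(u: int) -> int:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    links = sorted(
        ((d[i, j], i, j) for i, j in combinations(range(n), 2)), key=lambda t: t[0]
    )
    edges: set[tuple[int, int]] = set()
    i = 0
    while i < len(links):
        level = links[i][0]
        batch = []
        while i < len(links) and abs(links[i][0] - level) <= _TOL:
            batch.append(links[i])
            i += 1
        keep = [(a, b) for _, a, b in batch if find(a) != find(b)]
        edges.update((min(a, b), max(a, b)) for a, b in keep)
        for a, b in keep:
            parent[find(a)] = find(b)
    return edges


def _mst_length(d: np.ndarray) -> float:
    return float(minimum_spanning_tree(d).sum())


def _median_codes(u: np.ndarray, v: np.ndarray, w: np.ndarray,
                  table: np.ndarray) -> np.ndarray:
    """Per-site consensus of a triplet: majority state; full ties resolved
    toward the state minimizing added weighted length, then by state order."""
    out = u.copy()
    disagree = ~((u == v) & (v == w))
    for j in np.flatnonzero(disagree):
        states = (int(u[j]), int(v[j]), int(w[j]))
        counts = {s: states.count(s) for s in set(states)}
        best = max(counts.values())
        if best >= 2:
            out[j] = next(s for s in states if counts[s] == best)
        else:
            out[j] = min(
                sorted(set(states)),
                key=lambda s: (sum(table[s, t] for t in states), s),
            )
    return out


@dataclass
class HaploNetwork:
    """Observed haplotypes plus inferred median vectors with
    mutation-labelled links."""

    sequences: list[str]             # node index -> full-length sequence
    node_ids: list[str]              # "h1".. observed, "mv1".. median vectors
    frequencies: list[int]           # 0 for median vectors
    is_median: list[bool]
    edges: list[tuple[int, int, int, list[int]]]  # (u, v, n_mutations, sites)
    group_composition: list[dict[str, int]] | None = None

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, nid in enumerate(self.node_ids):
            comp = self.group_composition[i] if self.group_composition else {}
            g.add_node(
                nid,
                frequency=self.frequencies[i],
                is_median=self.is_median[i],
                group_composition=";".join(f"{k}:{v}" for k, v in sorted(comp.items())),
            )
        for u, v, muts, sites in self.edges:
            g.add_edge(
                self.node_ids[u],
                self.node_ids[v],
                mutations=muts,
                sites=";".join(str(s) for s in sites),
            )
        return g


def median_joining_network(
    hset: HaplotypeSet,
    epsilon: float = 0.0,
    transversion_weight: float = 2.0,
    indel_cost: float | None = None,
    max_iterations: int = 200,
) -> HaploNetwork:
    """Median-joining network of a locus' haplotypes.

    ``epsilon`` relaxes the improvement threshold a candidate median must
    beat (0, the usual software default, admits only medians that strictly
    shorten the network).
    """
    observed = list(hset.haplotypes)
    if len(observed) < 2:
        raise ValueError("network needs >= 2 haplotypes")
    if indel_cost is None:
        indel_cost = transversion_weight
    table = _cost_table(transversion_weight, indel_cost)

    length = len(observed[0])
    variable = [j for j in range(length) if len({s[j] for s in observed}) > 1]
    for j in variable:
        states = {s[j] for s in observed}
        if not states <= set(_ALPHABET):
            raise ValueError(
                f"non-nucleotide state at variable site {j}: {sorted(states)}"
            )
    template = observed[0]

    def encode(seq: str) -> np.ndarray:
        return np.array([_CODE[seq[j]] for j in variable], dtype=np.int8)

    def expand(codes: np.ndarray) -> str:
        chars = list(template)
        for pos, j in enumerate(variable):
            chars[j] = _ALPHABET[codes[pos]]
        return "".join(chars)

    coded = [encode(s) for s in observed]
    n_obs = len(coded)

    def dist(x: np.ndarray, y: np.ndarray) -> float:
        return float(table[x, y].sum())

    def full_matrix(items: list[np.ndarray]) -> np.ndarray:
        m = len(items)
        d = np.zeros((m, m))
        for i, j in combinations(range(m), 2):
            d[i, j] = d[j, i] = dist(items[i], items[j])
        return d

    nodes = list(coded)
    d = full_matrix(nodes)
    for _ in range(max_iterations):
        base_len = _mst_length(d)
        msn = minimum_spanning_network(d)
        neighbours: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for a, b in msn:
            neighbours[a].add(b)
            neighbours[b].add(a)
        seen = {arr.tobytes() for arr in nodes}
        candidates: dict[bytes, np.ndarray] = {}
        for u in range(len(nodes)):
            for v, w in combinations(sorted(neighbours[u]), 2):
                m = _median_codes(nodes[u], nodes[v], nodes[w], table)
                key = m.tobytes()
                if key not in seen:
                    candidates.setdefault(key, m)
        best: tuple[float, bytes, np.ndarray] | None = None
        for key, m in candidates.items():
            row = np.array([dist(m, x) for x in nodes])
            trial = np.pad(d, ((0, 1), (0, 1)))
            trial[-1, :-1] = row
            trial[:-1, -1] = row
            delta = _mst_length(trial) - base_len
            if delta < -_TOL + epsilon:
                cand = (delta, key, m)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            break
        nodes.append(best[2])
        row = np.array([dist(best[2], x) for x in nodes[:-1]] + [0.0])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :] = row
        d[:, -1] = row
        # prune medians made obsolete by the newcomer
        changed = True
        while changed:
            changed = False
            current = _mst_length(d)
            for idx in range(len(nodes) - 1, n_obs - 1, -1):
                keep = [i for i in range(len(nodes)) if i != idx]
                sub = d[np.ix_(keep, keep)]
                if _mst_length(sub) <= current + _TOL:
                    nodes = [nodes[i] for i in keep]
                    d = sub
                    current = _mst_length(d)
                    changed = True

    edge_set = minimum_spanning_network(d)

    counts = hset.counts()
    obs_bytes = {arr.tobytes(): i for i, arr in enumerate(coded)}
    node_ids, freqs, medians = [], [], []
    comp: list[dict[str, int]] = []
    sequences = []
    n_median = 0
    for arr in nodes:
        sequences.append(expand(arr))
        key = arr.tobytes()
        if key in obs_bytes:
            idx = obs_bytes[key]
            node_ids.append(f"h{idx + 1}")
            freqs.append(int(counts[idx]))
            medians.append(False)
            if hset.group_counts is not None and f"h{idx + 1}" in hset.group_counts.index:
                row = hset.group_counts.loc[f"h{idx + 1}"]
                comp.append({str(k): int(v) for k, v in row.items() if v > 0})
            else:
                comp.append({})
        else:
            n_median += 1
            node_ids.append(f"mv{n_median}")
            freqs.append(0)
            medians.append(True)
            comp.append({})
    edges = []
    for u, v in sorted(edge_set):
        sites = [
            variable[pos]
            for pos in np.flatnonzero(nodes[u] != nodes[v])
        ]
        edges.append((u, v, len(sites), sites))
    return HaploNetwork(sequences, node_ids, freqs, medians, edges, comp)
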