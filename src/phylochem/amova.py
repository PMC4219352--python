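"""Analysis of molecular variance (AMOVA) and spatial annealing clustering.

Molecular variance is decomposed from squared inter-individual distances
(here: pairwise sequence mismatch counts, the Arlequin convention) into
among-group, among-population-within-group and within-population components
via the standard n-coefficients, yielding the fixation indices Phi_CT,
Phi_SC and Phi_ST. Components may legitimately be negative and are never
clamped.

The spatial procedure (SAMOVA) searches, by simulated annealing over
contiguity-preserving single-site reassignments, for the K-group partition
of sampling sites that maximizes Phi_CT. Contiguity is defined on the
Delaunay triangulation of site coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DistanceMatrix, SequenceAlignment
from .popgen import _pairwise_counts

_EPS = 1e-12


def mismatch_matrix(aln: SequenceAlignment) -> DistanceMatrix:
    """Pairwise mismatch counts (pairwise deletion); the molecular squared
    distance used by the variance decomposition."""
    diff, _ = _pairwise_counts(aln.to_array())
    return DistanceMatrix(list(aln.sample_ids), diff)


@dataclass
class AmovaResult:
    sigma_a: float            # among groups
    sigma_b: float            # among populations within groups
    sigma_c: float            # within populations
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sigma_a": self.sigma_a,
                    "sigma_b": self.sigma_b,
                    "sigma_c": self.sigma_c,
                    "phi_ct": round(self.phi_ct, 2),
                    "phi_sc": round(self.phi_sc, 2),
                    "phi_st": round(self.phi_st, 2),
                    **{f"p_{k}": v for k, v in self.p_values.items()},
                }
            ]
        )


def _as_codes(labels: list[str], mapping: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    missing = [l for l in labels if l not in mapping]
    if missing:
        raise KeyError(f"no assignment for samples: {missing}")
    values = [mapping[l] for l in labels]
    uniq = sorted(set(values))
    index = {u: i for i, u in enumerate(uniq)}
    return np.array([index[v] for v in values]), uniq


def _ssd_within(d2: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    """Sum over levels of (pair sum of d2 within level) / level size."""
    total = 0.0
    for k in range(n_levels):
        idx = np.flatnonzero(codes == k)
        if idx.size > 1:
            total += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return total


def one_level_components(d2: np.ndarray, pop_codes: np.ndarray) -> tuple[float, float, float]:
    """(sigma_a, sigma_c, phi_st) for a single-level design."""
    n = d2.shape[0]
    pops, sizes = np.unique(pop_codes, return_counts=True)
    n_pops = pops.size
    if n_pops < 2:
        raise ValueError("global Phi_ST undefined for a single population")
    ssd_total = d2.sum() / (2.0 * n)
    ssd_within = _ssd_within(d2, pop_codes, n_pops)
    ssd_among = ssd_total - ssd_within
    df_within = n - n_pops
    sigma_c = ssd_within / df_within if df_within > 0 else 0.0
    n_c = (n - (sizes**2).sum() / n) / (n_pops - 1)
    sigma_a = (ssd_among / (n_pops - 1) - sigma_c) / n_c
    total = sigma_a + sigma_c
    phi_st = sigma_a / total if abs(total) > _EPS else 0.0
    return sigma_a, sigma_c, phi_st


def global_phi_st(
    dm: DistanceMatrix,
    populations: dict[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-level AMOVA Phi_ST with a permutation p-value.

    ``dm`` entries are squared molecular distances (mismatch counts). The
    p-value is the proportion of permutations (individuals shuffled among
    populations) with Phi_ST >= observed, with the +1/(N+1) correction.
    """
    d2 = dm.values
    codes, _ = _as_codes(dm.labels, populations)
    _, _, observed = one_level_components(d2, codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        _, _, phi = one_level_components(d2, rng.permutation(codes))
        if phi >= observed - _EPS:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return observed, p


def _two_level_components(
    d2: np.ndarray, pop_codes: np.ndarray, group_of_pop: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """Excoffier-style decomposition for populations nested in groups.

    Returns (sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st).
    """
    n = d2.shape[0]
    n_pops = group_of_pop.size
    group_codes = group_of_pop[pop_codes]
    n_groups = int(group_of_pop.max()) + 1
    pop_sizes = np.bincount(pop_codes, minlength=n_pops).astype(float)
    group_sizes = np.bincount(group_codes, minlength=n_groups).astype(float)
    if (group_sizes == 0).any():
        raise ValueError("empty group in two-level design")

    ssd_total = d2.sum() / (2.0 * n)
    ssd_wp = _ssd_within(d2, pop_codes, n_pops)
    ssd_wg = _ssd_within(d2, group_codes, n_groups)
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_wp = n - n_pops
    df_ap = n_pops - n_groups
    df_ag = n_groups - 1
    if df_ag < 1:
        raise ValueError("two-level design needs >= 2 groups")

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    # per-group sum of squared population sizes
    sum_np2_per_group = np.bincount(
        group_of_pop, weights=pop_sizes**2, minlength=n_groups
    )
    if df_ap > 0:
        n1 = (n - (sum_np2_per_group / group_sizes).sum()) / df_ap
        sigma_b = (ssd_ap_wg / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    n2 = ((sum_np2_per_group / group_sizes).sum() - (pop_sizes**2).sum() / n) / df_ag
    n3 = (n - (group_sizes**2).sum() / n) / df_ag
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3

    total = sigma_a + sigma_b + sigma_c
    phi_ct = sigma_a / total if abs(total) > _EPS else 0.0
    bc = sigma_b + sigma_c
    phi_sc = sigma_b / bc if abs(bc) > _EPS else 0.0
    phi_st = (sigma_a + sigma_b) / total if abs(total) > _EPS else 0.0
    return sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st


def amova_two_level(
    dm: DistanceMatrix,
    populations: dict[str, str],
    groups: dict[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA with the three standard permutation schemes.

    ``groups`` maps population -> group. Permutations: individuals among
    populations within groups (Phi_SC), whole populations among groups
    (Phi_CT), and individuals among populations among groups (Phi_ST).
    """
    d2 = dm.values
    pop_codes, pop_names = _as_codes(dm.labels, populations)
    missing = [p for p in pop_names if p not in groups]
    if missing:
        raise KeyError(f"populations without group: {missing}")
    group_names = sorted({groups[p] for p in pop_names})
    gidx = {g: i for i, g in enumerate(group_names)}
    group_of_pop = np.array([gidx[groups[p]] for p in pop_names])

    sa, sb, sc, pct, psc, pst = _two_level_components(d2, pop_codes, group_of_pop)
    rng = np.random.default_rng(seed)
    exceed = {"phi_ct": 0, "phi_sc": 0, "phi_st": 0}
    group_codes = group_of_pop[pop_codes]
    for _ in range(n_perm):
        # Phi_SC: shuffle individuals among populations within each group
        perm = np.arange(d2.shape[0])
        for g in range(len(group_names)):
            members = np.flatnonzero(group_codes == g)
            perm[members] = members[rng.permutation(members.size)]
        _, _, _, _, v_sc, _ = _two_level_components(
            d2, pop_codes[perm], group_of_pop
        )
        if v_sc >= psc - _EPS:
            exceed["phi_sc"] += 1
        # Phi_CT: shuffle whole populations among groups
        _, _, _, v_ct, _, _ = _two_level_components(
            d2, pop_codes, group_of_pop[rng.permutation(group_of_pop.size)]
        )
        if v_ct >= pct - _EPS:
            exceed["phi_ct"] += 1
        # Phi_ST: shuffle individuals freely
        _, _, _, _, _, v_st = _two_level_components(
            d2, pop_codes[rng.permutation(d2.shape[0])], group_of_pop
        )
        if v_st >= pst - _EPS:
            exceed["phi_st"] += 1
    p_values = {k: (v + 1) / (n_perm + 1) for k, v in exceed.items()}
    return AmovaResult(sa, sb, sc, pct, psc, pst, p_values, n_perm)


# ---------------------------------------------------------------------------
# SAMOVA
# ---------------------------------------------------------------------------


@dataclass
class SpatialPartition:
    K: int
    assignment: dict[str, int]   # site id -> group index
    phi_ct: float
    phi_sc: float
    phi_st: float
    n_reps: int
    n_steps: int
    seed: int | None

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for site, g in self.assignment.items():
            out.setdefault(g, []).append(site)
        return out


class _SamovaState:
    """Aggregated sums allowing fast Phi_CT evaluation of site partitions."""

    def __init__(self, dm: DistanceMatrix, sample_site_map: dict[str, str]):
        site_codes, self.sites = _as_codes(dm.labels, sample_site_map)
        n = dm.n
        n_sites = len(self.sites)
        z = np.zeros((n, n_sites))
        z[np.arange(n), site_codes] = 1.0
        b = z.T @ dm.values @ z          # b[s, t] = sum over i in s, j in t of d2
        self.pair_sums = b
        self.site_sizes = z.sum(axis=0)
        self.n = n
        self.n_sites = n_sites
        self.ssd_total = dm.values.sum() / (2.0 * n)
        self.ssd_wp = float((np.diag(b) / (2.0 * self.site_sizes)).sum())
        self.df_wp = n - n_sites
        self.sigma_c = self.ssd_wp / self.df_wp if self.df_wp > 0 else 0.0
        self.sum_np2 = float((self.site_sizes**2).sum())

    def components(self, grouping: np.ndarray) -> tuple[float, float, float, float, float, float]:
        """Decomposition for a site -> group assignment vector."""
        k = int(grouping.max()) + 1
        g = np.zeros((self.n_sites, k))
        g[np.arange(self.n_sites), grouping] = 1.0
        group_sizes = self.site_sizes @ g
        if (group_sizes == 0).any():
            raise ValueError("empty group")
        gg = g.T @ self.pair_sums @ g
        ssd_wg = float((np.diag(gg) / (2.0 * group_sizes)).sum())
        ssd_ap = ssd_wg - self.ssd_wp
        ssd_ag = self.ssd_total - ssd_wg
        df_ap = self.n_sites - k
        df_ag = k - 1
        sigma_c = self.sigma_c
        sum_np2_per_group = (self.site_sizes**2) @ g
        if df_ap > 0:
            n1 = (self.n - (sum_np2_per_group / group_sizes).sum()) / df_ap
            sigma_b = (ssd_ap / df_ap - sigma_c) / n1
        else:
            sigma_b = 0.0
        n2 = ((sum_np2_per_group / group_sizes).sum() - self.sum_np2 / self.n) / df_ag
        n3 = (self.n - (group_sizes**2).sum() / self.n) / df_ag
        sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
        total = sigma_a + sigma_b + sigma_c
        phi_ct = sigma_a / total if abs(total) > _EPS else 0.0
        bc = sigma_b + sigma_c
        phi_sc = sigma_b / bc if abs(bc) > _EPS else 0.0
        phi_st = (sigma_a + sigma_b) / total if abs(total) > _EPS else 0.0
        return sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st

    def phi_ct(self, grouping: np.ndarray) -> float:
        return self.components(grouping)[3]


def _site_adjacency(site_coords: dict[str, tuple[float, float]], sites: list[str]) -> dict[int, set[int]]:
    from .landscape import build_connectivity

    net = build_connectivity({s: site_coords[s] for s in sites})
    index = {s: i for i, s in enumerate(sites)}
    adj: dict[int, set[int]] = {i: set() for i in range(len(sites))}
    for a, b in net.edges:
        adj[index[a]].add(index[b])
        adj[index[b]].add(index[a])
    return adj


def _connected_after_removal(members: np.ndarray, removed: int, adj: dict[int, set[int]]) -> bool:
    rest = [m for m in members if m != removed]
    if len(rest) <= 1:
        return True
    rest_set = set(rest)
    stack = [rest[0]]
    seen = {rest[0]}
    while stack:
        u = stack.pop()
        for v in adj[u] & rest_set:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(rest)


def _initial_partition(
    n_sites: int, K: int, adj: dict[int, set[int]], rng: np.random.Generator, contiguous: bool
) -> np.ndarray:
    if not contiguous:
        grouping = np.concatenate(
            [np.arange(K), rng.integers(0, K, n_sites - K)]
        )
        return rng.permutation(grouping)
    seeds = rng.choice(n_sites, size=K, replace=False)
    grouping = np.full(n_sites, -1)
    grouping[seeds] = np.arange(K)
    frontier = list(seeds)
    while (grouping == -1).any():
        progressed = False
        for u in rng.permutation(len(frontier)):
            site = frontier[u]
            free = [v for v in adj[site] if grouping[v] == -1]
            if free:
                v = free[int(rng.integers(len(free)))]
                grouping[v] = grouping[site]
                frontier.append(v)
                progressed = True
        if not progressed:
            # disconnected triangulation should not happen; assign leftovers
            grouping[grouping == -1] = rng.integers(0, K, (grouping == -1).sum())
    return grouping


def _candidate_moves(
    grouping: np.ndarray, adj: dict[int, set[int]], contiguous: bool, K: int
) -> list[tuple[int, int]]:
    moves = []
    group_sizes = np.bincount(grouping, minlength=K)
    for site in range(grouping.size):
        src = grouping[site]
        if group_sizes[src] <= 1:
            continue
        if contiguous:
            targets = {int(grouping[v]) for v in adj[site]} - {int(src)}
        else:
            targets = set(range(K)) - {int(src)}
        for dst in targets:
            moves.append((site, dst))
    return moves


def samova(
    dm: DistanceMatrix,
    sample_site_map: dict[str, str],
    site_coords: dict[str, tuple[float, float]],
    K: int,
    n_reps: int = 10,
    n_steps: int = 10_000,
    seed: int | None = None,
    contiguous: bool = True,
) -> SpatialPartition:
    """Best-of-``n_reps`` simulated annealing search for the K-group site
    partition maximizing Phi_CT.

    Moves reassign one site to a (Delaunay-)neighbouring group; the source
    group must stay non-empty and, under the contiguity constraint,
    connected. Geometric cooling; the initial temperature is set from the
    typical move magnitude so most early moves are accepted.
    """
    state = _SamovaState(dm, sample_site_map)
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > state.n_sites:
        raise ValueError(f"K={K} exceeds number of sites ({state.n_sites})")
    adj: dict[int, set[int]] = (
        _site_adjacency(site_coords, state.sites)
        if contiguous
        else {i: set() for i in range(state.n_sites)}
    )
    rng = np.random.default_rng(seed)

    best_phi = -np.inf
    best_grouping: np.ndarray | None = None
    for _ in range(n_reps):
        grouping = _initial_partition(state.n_sites, K, adj, rng, contiguous)
        phi = state.phi_ct(grouping)
        # calibrate initial temperature from typical move magnitude
        deltas = []
        for site, dst in _candidate_moves(grouping, adj, contiguous, K)[:50]:
            trial = grouping.copy()
            trial[site] = dst
            deltas.append(abs(state.phi_ct(trial) - phi))
        t0 = max(np.mean(deltas) if deltas else 1e-3, 1e-6) / np.log(1 / 0.8)
        t_end = 1e-3 * t0
        cool = (t_end / t0) ** (1.0 / max(n_steps, 1))
        temp = t0
        if phi > best_phi:
            best_phi, best_grouping = phi, grouping.copy()
        for _ in range(n_steps):
            moves = _candidate_moves(grouping, adj, contiguous, K)
            if not moves:
                break
            site, dst = moves[int(rng.integers(len(moves)))]
            if contiguous:
                members = np.flatnonzero(grouping == grouping[site])
                if not _connected_after_removal(members, site, adj):
                    temp *= cool
                    continue
            trial = grouping.copy()
            trial[site] = dst
            trial_phi = state.phi_ct(trial)
            delta = trial_phi - phi
            if delta >= 0 or rng.random() < np.exp(delta / max(temp, 1e-300)):
                grouping, phi = trial, trial_phi
                if phi > best_phi:
                    best_phi, best_grouping = phi, grouping.copy()
            temp *= cool

    assert best_grouping is not None
    _, _, _, pct, psc, pst = state.components(best_grouping)
    assignment = {site: int(g) for site, g in zip(state.sites, best_grouping)}
    return SpatialPartition(K, assignment, pct, psc, pst, n_reps, n_steps, seed)


def samova_exhaustive(
    dm: DistanceMatrix,
    sample_site_map: dict[str, str],
    K: int,
) -> tuple[dict[str, int], float]:
    """Exact maximizer of Phi_CT over all (unconstrained) K-group partitions.

    Exponential in the number of sites; intended for small problems.
    """
    state = _SamovaState(dm, sample_site_map)
    n = state.n_sites
    best = (-np.inf, None)

    def partitions(i: int, grouping: list[int], n_used: int):
        if i == n:
            if n_used == K:
                yield np.array(grouping)
            return
        for g in range(min(n_used + 1, K)):
            grouping.append(g)
            yield from partitions(i + 1, grouping, max(n_used, g + 1))
            grouping.pop()

    for grouping in partitions(0, [], 0):
        phi = state.phi_ct(grouping)
        if phi > best[0]:
            best = (phi, grouping.copy())
    assignment = {site: int(g) for site, g in zip(state.sites, best[1])}
    return assignment, best[0]


def samova_scan(
    dm: DistanceMatrix,
    sample_site_map: dict[str, str],
    site_coords: dict[str, tuple[float, float]],
    k_range: range | list[int] = range(2, 46),
    n_reps: int = 10,
    n_steps: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Best partition per K with fixation indices and a singleton-group flag.

    K values where additional groups are single sampling sites are flagged
    with a warning ("little biological sense") but never dropped.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_sites = len({sample_site_map[l] for l in dm.labels})
    for k in k_range:
        if k > n_sites:
            break
        part = samova(
            dm, sample_site_map, site_coords, k,
            n_reps=n_reps, n_steps=n_steps,
            seed=int(rng.integers(2**31 - 1)),
        )
        singleton = any(len(v) == 1 for v in part.groups().values())
        if singleton:
            warnings.warn(f"K={k}: partition contains single-site groups", stacklevel=2)
        rows.append(
            {
                "K": k,
                "phi_ct": part.phi_ct,
                "phi_st": part.phi_st,
                "phi_sc": part.phi_sc,
                "has_singleton_group": singleton,
                "assignment": ";".join(
                    f"{s}={g}" for s, g in sorted(part.assignment.items())
                ),
            }
        )
    return pd.DataFrame(rows)
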