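"""AMOVA decomposition against a brute-force oracle; SAMOVA against
exhaustive partition search."""

import warnings

import numpy as np
import pytest

from conftest import rng_seeds, small_sim_config
from phylochem.amova import (
    AmovaResult,
    amova_two_level,
    global_phi_st,
    mismatch_matrix,
    one_level_components,
    samova,
    samova_exhaustive,
    samova_scan,
)
from phylochem.datatypes import DistanceMatrix, SequenceAlignment
from phylochem.simulate import simulate_dataset


def oracle_two_level(d2, pops, groups):
    """Independent variance-component solve: SSDs by explicit pair loops,
    coefficients from their definitional sums, then a linear system."""
    n = len(pops)
    pop_names = sorted(set(pops))
    group_of = {p: groups[p] for p in pop_names}
    group_names = sorted(set(group_of.values()))

    def ssd(unit_of):
        total = 0.0
        for unit in set(unit_of):
            idx = [i for i in range(n) if unit_of[i] == unit]
            s = sum(d2[i, j] for i in idx for j in idx if i < j)
            total += s / len(idx)
        return total

    ssd_total = sum(d2[i, j] for i in range(n) for j in range(n) if i < j) / n
    ssd_wp = ssd(pops)
    ssd_wg = ssd([group_of[p] for p in pops])
    n_pops, n_groups = len(pop_names), len(group_names)
    sizes = {p: pops.count(p) for p in pop_names}
    gsizes = {g: sum(sizes[p] for p in pop_names if group_of[p] == g)
              for g in group_names}
    sum_g = sum(
        sum(sizes[p] ** 2 for p in pop_names if group_of[p] == g) / gsizes[g]
        for g in group_names
    )
    n1 = (n - sum_g) / (n_pops - n_groups) if n_pops > n_groups else 0.0
    n2 = (sum_g - sum(sizes[p] ** 2 for p in pop_names) / n) / (n_groups - 1)
    n3 = (n - sum(gsizes[g] ** 2 for g in group_names) / n) / (n_groups - 1)
    # linear system: MSD vector = C @ sigma
    msd = np.array([
        (ssd_total - ssd_wg) / (n_groups - 1),
        (ssd_wg - ssd_wp) / (n_pops - n_groups) if n_pops > n_groups else 0.0,
        ssd_wp / (n - n_pops),
    ])
    c = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    if n_pops == n_groups:
        c[1] = [0.0, 1.0, 0.0]
        msd[1] = 0.0
    return np.linalg.solve(c, msd)


def random_design(rng, n_groups=3, pops_per_group=(1, 3), pop_size=(2, 4)):
    pops, groups = [], {}
    pop_id = 0
    for g in range(n_groups):
        for _ in range(rng.integers(*pops_per_group, endpoint=True)):
            name = f"p{pop_id}"
            groups[name] = f"g{g}"
            pops.extend([name] * rng.integers(*pop_size, endpoint=True))
            pop_id += 1
    d = np.triu(rng.integers(0, 9, (len(pops), len(pops))).astype(float), 1)
    return pops, groups, d + d.T


class TestOneLevel:
    def test_fixed_difference_gives_phi_one(self):
        aln = SequenceAlignment(
            "L", list("abcd"), ["AAAA", "AAAA", "AAAT", "AAAT"]
        )
        dm = mismatch_matrix(aln)
        phi, _ = global_phi_st(
            dm, {"a": "p1", "b": "p1", "c": "p2", "d": "p2"}, n_perm=30, seed=0
        )
        assert phi == pytest.approx(1.0)

    def test_panmictic_pool_near_zero(self):
        """Populations drawn from one pool: mean |Phi_ST| small over seeds."""
        values = []
        for seed in rng_seeds(50, base=5):
            rng = np.random.default_rng(seed)
            seqs = ["".join(rng.choice(list("AT"), 20)) for _ in range(40)]
            aln = SequenceAlignment("L", [f"s{i}" for i in range(40)], seqs)
            pops = {f"s{i}": f"p{i % 4}" for i in range(40)}
            codes = np.array([i % 4 for i in range(40)])
            _, _, phi = one_level_components(mismatch_matrix(aln).values, codes)
            values.append(phi)
        assert abs(np.mean(values)) < 0.05

    def test_single_population_undefined(self):
        dm = DistanceMatrix(list("ab"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            global_phi_st(dm, {"a": "p", "b": "p"}, n_perm=10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_ssd_oracle(self, seed):
        """3-population toy equals the definitional SSD decomposition."""
        rng = np.random.default_rng(seed)
        pops = ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3
        d = np.triu(rng.integers(0, 8, (9, 9)).astype(float), 1)
        d = d + d.T
        codes = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        sigma_a, sigma_c, phi = one_level_components(d, codes)
        # oracle: treat as two-level with each population its own group
        groups = {p: p for p in set(pops)}
        exp = oracle_two_level(d, pops, groups)
        assert sigma_a == pytest.approx(exp[0], abs=1e-10)
        assert sigma_c == pytest.approx(exp[2], abs=1e-10)
        assert phi == pytest.approx(exp[0] / (exp[0] + exp[2]), abs=1e-10)


class TestTwoLevel:
    @pytest.mark.parametrize("seed", range(6))
    def test_components_match_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        pops, groups, d = random_design(rng)
        labels = [f"i{i}" for i in range(len(pops))]
        dm = DistanceMatrix(labels, d)
        res = amova_two_level(dm, dict(zip(labels, pops)), groups, n_perm=0)
        exp = oracle_two_level(d, pops, groups)
        assert res.sigma_a == pytest.approx(exp[0], abs=1e-9)
        assert res.sigma_b == pytest.approx(exp[1], abs=1e-9)
        assert res.sigma_c == pytest.approx(exp[2], abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_component_conservation(self, seed):
        """Components recombine into the total variance of the full SSD."""
        rng = np.random.default_rng(seed + 40)
        pops, groups, d = random_design(rng)
        labels = [f"i{i}" for i in range(len(pops))]
        res = amova_two_level(
            DistanceMatrix(labels, d), dict(zip(labels, pops)), groups, n_perm=0
        )
        exp = oracle_two_level(d, pops, groups)
        assert res.sigma_a + res.sigma_b + res.sigma_c == pytest.approx(
            exp.sum(), abs=1e-9
        )

    def test_each_population_own_group_collapses_to_global(self):
        rng = np.random.default_rng(3)
        pops = ["p1"] * 3 + ["p2"] * 4 + ["p3"] * 3
        d = np.triu(rng.integers(0, 7, (10, 10)).astype(float), 1)
        d = d + d.T
        labels = [f"i{i}" for i in range(10)]
        dm = DistanceMatrix(labels, d)
        res = amova_two_level(
            dm, dict(zip(labels, pops)), {p: p for p in set(pops)}, n_perm=0
        )
        codes = np.array([0] * 3 + [1] * 4 + [2] * 3)
        _, _, phi_global = one_level_components(d, codes)
        assert res.phi_ct == pytest.approx(phi_global, abs=1e-10)

    def test_exchangeable_groups_give_zero_phi_ct_on_average(self):
        """When group labels carry no information the among-group component
        averages to zero over random relabellings."""
        rng = np.random.default_rng(8)
        labels = [f"i{i}" for i in range(16)]
        pops = dict(zip(labels, [f"p{i // 4}" for i in range(16)]))
        d = np.triu(rng.integers(0, 6, (16, 16)).astype(float), 1)
        dm = DistanceMatrix(labels, d + d.T)
        phis = []
        for _ in range(30):
            perm = rng.permutation(["g1", "g1", "g2", "g2"])
            groups = {f"p{i}": perm[i] for i in range(4)}
            phis.append(amova_two_level(dm, pops, groups, n_perm=0).phi_ct)
        assert abs(np.mean(phis)) < 0.05


class TestSamova:
    def make_two_deme_data(self, seed=0, n_sites=6, per_site=3):
        """Sites split between two strongly differentiated demes."""
        rng = np.random.default_rng(seed)
        labels, pops, seqs = [], {}, []
        coords = {}
        for s in range(n_sites):
            deme = s < n_sites // 2
            site = f"site{s}"
            coords[site] = (float(s % 3) + rng.uniform(0, .3),
                            (0.0 if deme else 3.0) + rng.uniform(0, .3))
            for i in range(per_site):
                lbl = f"s{s}_{i}"
                labels.append(lbl)
                pops[lbl] = site
                core = "A" * 10 if deme else "A" * 5 + "T" * 5
                seq = list(core)
                j = int(rng.integers(10))
                if rng.random() < 0.5:
                    seq[j] = "C" if seq[j] != "C" else "G"
                seqs.append("".join(seq))
        aln = SequenceAlignment("L", labels, seqs)
        return mismatch_matrix(aln), pops, coords

    def test_k_equals_n_sites_forced_partition(self):
        dm, pops, coords = self.make_two_deme_data()
        part = samova(dm, pops, coords, K=6, n_reps=1, n_steps=10, seed=0)
        assert len(set(part.assignment.values())) == 6
        codes_map = {s: i for i, s in enumerate(sorted(set(pops.values())))}
        codes = np.array([codes_map[pops[l]] for l in dm.labels])
        _, _, phi_global = one_level_components(dm.values, codes)
        assert part.phi_ct == pytest.approx(phi_global, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_search(self, seed):
        """Annealing (contiguity off) attains the exhaustive-search optimum
        over all bipartitions for 6 sites."""
        dm, pops, coords = self.make_two_deme_data(seed=seed)
        exact_assign, exact_phi = samova_exhaustive(dm, pops, K=2)
        part = samova(
            dm, pops, coords, K=2, n_reps=3, n_steps=300, seed=seed,
            contiguous=False,
        )
        assert part.phi_ct == pytest.approx(exact_phi, abs=1e-9)

    def test_two_demes_recovered(self):
        dm, pops, coords = self.make_two_deme_data(seed=2)
        part = samova(dm, pops, coords, K=2, n_reps=3, n_steps=300, seed=1)
        groups = part.groups()
        split = {frozenset(v) for v in groups.values()}
        assert split == {
            frozenset({"site0", "site1", "site2"}),
            frozenset({"site3", "site4", "site5"}),
        }

    def test_monomorphic_scan_zero(self):
        labels = [f"s{i}" for i in range(8)]
        aln = SequenceAlignment("L", labels, ["ACGT" * 3] * 8)
        pops = {l: f"site{i // 2}" for i, l in enumerate(labels)}
        coords = {f"site{i}": (float(i), float(i % 2)) for i in range(4)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = samova_scan(
                mismatch_matrix(aln), pops, coords, k_range=[2, 3],
                n_reps=1, n_steps=30, seed=0,
            )
        assert (scan["phi_ct"] == 0.0).all()

    def test_invalid_k(self):
        dm, pops, coords = self.make_two_deme_data()
        with pytest.raises(ValueError):
            samova(dm, pops, coords, K=7, n_reps=1, n_steps=5)

    def test_three_refugia_plateau_starts_at_k3(self):
        """On K=3 synthetic refugial data: the attained Phi_CT rises from
        K=2 to the true K=3 and the gain from 3 to 4 is smaller than the
        gain from 2 to 3 — the plateau begins at the true group count —
        for a majority of seeds."""
        wins = 0
        rises = 0
        n_seeds = 8
        for seed in rng_seeds(n_seeds, base=77):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds = simulate_dataset(
                    small_sim_config(n_sites=12, n_individuals=48), seed=seed % 2**31
                )
                aln = ds.alignments["locusA"]
                dm = mismatch_matrix(aln)
                site_of = ds.truth.site_of_sample
                coords = ds.samples.site_coords()
                phis = {
                    k: samova(dm, site_of, coords, K=k, n_reps=2, n_steps=250,
                              seed=seed % 2**31).phi_ct
                    for k in (2, 3, 4)
                }
            wins += (phis[3] - phis[2]) > (phis[4] - phis[3])
            rises += phis[3] >= phis[2] - 1e-9
        assert wins > n_seeds / 2
        assert rises > n_seeds / 2


def test_permutation_p_small_for_structured_data():
    aln = SequenceAlignment(
        "L",
        [f"s{i}" for i in range(12)],
        ["A" * 12] * 6 + ["T" * 6 + "A" * 6] * 6,
    )
    pops = {f"s{i}": ("p1" if i < 6 else "p2") for i in range(12)}
    _, p = global_phi_st(mismatch_matrix(aln), pops, n_perm=199, seed=0)
    assert p < 0.05
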