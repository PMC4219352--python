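"""Chemometric battery: filters, transforms, ordination and group tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

from phylochem.chemometrics import (
    _centroid_distances,
    bray_curtis,
    dispersion_test,
    filter_compounds,
    indval,
    nmds,
    permanova,
    transform_standardize,
)
from phylochem.datatypes import ChemProfileMatrix, DistanceMatrix


def profile(rows, compounds=None, samples=None):
    rows = np.asarray(rows, dtype=float)
    compounds = compounds or [f"c{i}" for i in range(rows.shape[1])]
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    return ChemProfileMatrix(pd.DataFrame(rows, index=samples, columns=compounds))


class TestFilter:
    def test_trace_compound_removed_boundary_kept(self):
        chem = profile(
            [[99.85, 0.05, 0.10], [99.85, 0.04, 0.11]],
            compounds=["major", "trace", "boundary"],
        )
        kept = filter_compounds(chem)
        assert kept.compound_ids == ["major", "boundary"]

    def test_engineered_survivors(self):
        """Column-max oracle: 2 of 5 engineered compounds fail the 0.1%."""
        rng = np.random.default_rng(0)
        rows = rng.uniform(1, 40, (4, 5))
        rows[:, 1] = rng.uniform(0, 0.09, 4)
        rows[:, 3] = rng.uniform(0, 0.05, 4)
        rows = rows / rows.sum(1, keepdims=True) * 100
        rows[:, 1] = np.minimum(rows[:, 1], 0.09)
        rows[:, 3] = np.minimum(rows[:, 3], 0.09)
        chem = profile(rows)
        survivors = [
            c for c, keep in zip(chem.compound_ids, rows.max(0) >= 0.1) if keep
        ]
        assert filter_compounds(chem).compound_ids == survivors
        assert len(survivors) == 3

    def test_all_removed_rejected(self):
        chem = profile([[0.01, 0.02]])
        with pytest.raises(ValueError):
            filter_compounds(chem)


class TestTransform:
    def test_matches_hand_computation(self):
        chem = profile([[0.0, 9.0], [9.0, 99.0], [99.0, 9.0]])
        logged = np.log10(np.array([[0, 9], [9, 99], [99, 9]], float) + 1)
        expected = (logged - logged.mean(0)) / logged.std(0, ddof=1)
        out = transform_standardize(chem)
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)

    def test_columns_standardized(self):
        rng = np.random.default_rng(1)
        rows = rng.uniform(0, 50, (6, 4))
        out = transform_standardize(profile(rows)).to_numpy()
        np.testing.assert_allclose(out.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(0, ddof=1), 1.0, atol=1e-12)

    def test_zero_variance_column_flagged(self):
        chem = profile([[50.0, 50.0], [50.0, 50.0], [60.0, 40.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = transform_standardize(profile([[50.0, 0.0], [50.0, 0.0]]))
        np.testing.assert_array_equal(out["c1"], 0.0)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        dm = bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert dm.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        dm = bray_curtis(np.array([[5.0, 0.0], [0.0, 3.0]]))
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rows = np.array([[1.0, 4.0, 2.0], [3.0, 0.0, 1.0], [2.0, 2.0, 2.0]])
        dm = bray_curtis(rows)
        for i in range(3):
            for j in range(3):
                expected = np.abs(rows[i] - rows[j]).sum() / (rows[i] + rows[j]).sum()
                assert dm.values[i, j] == pytest.approx(expected)

    def test_order_invariance_through_pipeline(self):
        rng = np.random.default_rng(2)
        rows = rng.uniform(0, 30, (5, 6))
        chem = profile(rows)
        d1 = bray_curtis(transform_standardize(chem))
        perm_cols = list(rng.permutation(chem.compound_ids))
        perm_rows = list(rng.permutation(chem.sample_ids))
        chem2 = ChemProfileMatrix(chem.data[perm_cols].loc[perm_rows])
        d2 = bray_curtis(transform_standardize(chem2))
        back = d2.submatrix(d1.labels)
        np.testing.assert_allclose(back.values, d1.values, atol=1e-12)


class TestNmds:
    def embeddable(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, (n, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return DistanceMatrix([f"s{i}" for i in range(n)], d)

    def test_embeddable_config_low_stress(self):
        res = nmds(self.embeddable(), k=3, n_runs=8, seed=0)
        assert res.stress < 0.01

    def test_stress_invariant_to_configuration_rotation(self):
        """Stress depends only on configuration distances, which rotation
        preserves; recomputing stress from rotated coordinates matches."""
        from scipy.spatial.distance import pdist, squareform
        from sklearn.isotonic import IsotonicRegression

        dm = self.embeddable(seed=3)
        res = nmds(dm, k=2, n_runs=4, seed=1)
        coords = res.coordinates.to_numpy()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])

        def stress1(conf):
            dhat = squareform(pdist(conf))
            iu = np.triu_indices(dm.n, 1)
            order = np.argsort(dm.values[iu])
            iso = IsotonicRegression().fit_transform(
                dm.values[iu][order], dhat[iu][order]
            )
            num = ((dhat[iu][order] - iso) ** 2).sum()
            return np.sqrt(num / (dhat[iu] ** 2).sum())

        assert stress1(coords @ rot) == pytest.approx(stress1(coords), abs=1e-9)

    def test_best_stress_nonincreasing_in_runs(self):
        dm = self.embeddable(seed=5)
        s_few = nmds(dm, k=2, n_runs=2, seed=9).stress
        s_many = nmds(dm, k=2, n_runs=10, seed=9).stress
        assert s_many <= s_few + 1e-6

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            nmds(self.embeddable(n=5), k=4)


class TestPermanova:
    def test_univariate_anova_equivalence_example(self):
        """{0,1} vs {4,5}: pseudo-F equals the classical one-way ANOVA F=32."""
        x = np.array([0.0, 1.0, 4.0, 5.0])
        d = np.abs(x[:, None] - x[None, :])
        dm = DistanceMatrix(list("abcd"), d)
        res = permanova(dm, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
                        n_perm=10, seed=0)
        assert res.f == pytest.approx(32.0, abs=1e-10)
        assert res.df_between == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_univariate_anova_equivalence_random(self, seed):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=5), rng.normal(size=6), rng.normal(size=4)
        x = np.concatenate([a, b, c])
        labels = [f"s{i}" for i in range(15)]
        groups = dict(zip(labels, ["a"] * 5 + ["b"] * 6 + ["c"] * 4))
        dm = DistanceMatrix(labels, np.abs(x[:, None] - x[None, :]))
        res = permanova(dm, groups, n_perm=10, seed=0)
        assert res.f == pytest.approx(f_oneway(a, b, c).statistic, abs=1e-10)

    def test_matches_skbio(self):
        """Independent cross-check of the pseudo-F against scikit-bio."""
        import skbio

        rng = np.random.default_rng(7)
        rows = rng.uniform(0, 20, (10, 4))
        dm = bray_curtis(rows)
        labels = dm.labels
        grouping = ["g1"] * 5 + ["g2"] * 5
        res = permanova(dm, dict(zip(labels, grouping)), n_perm=10, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, labels), grouping, permutations=9
        )
        assert res.f == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_pairwise_bonferroni(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, 4), rng.normal(5, 1, 4),
                            rng.normal(10, 1, 4)])
        labels = [f"s{i}" for i in range(12)]
        groups = dict(zip(labels, ["a"] * 4 + ["b"] * 4 + ["c"] * 4))
        dm = DistanceMatrix(labels, np.abs(x[:, None] - x[None, :]))
        res = permanova(dm, groups, n_perm=99, seed=1)
        assert res.pairwise is not None and len(res.pairwise) == 3
        assert (res.pairwise["p_bonferroni"] >= res.pairwise["p"] - 1e-12).all()

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(list("abc"), np.array(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        with pytest.raises(ValueError):
            permanova(dm, {"a": "g1", "b": "g2", "c": "g2"})


class TestDispersion:
    def test_two_samples_half_distance_from_centroid(self):
        d = np.array([[0.0, 0.6], [0.6, 0.0]])
        dm = DistanceMatrix(["a", "b"], d)
        dist = _centroid_distances(dm, np.array([0, 0]), 1)
        np.testing.assert_allclose(dist, 0.3, atol=1e-12)

    def test_identical_profiles_zero_variability(self):
        rows = np.vstack([[10.0, 20.0, 70.0]] * 3 + [[30.0, 30.0, 40.0],
                                                     [50.0, 10.0, 40.0]])
        dm = bray_curtis(rows)
        groups = {dm.labels[i]: ("g1" if i < 3 else "g2") for i in range(5)}
        res = dispersion_test(dm, groups, n_perm=19, seed=0)
        assert res.group_variability["g1"] == pytest.approx(0.0, abs=1e-9)

    def test_euclidean_embedding_matches_direct_centroid_distances(self):
        """On Euclidean data, PCoA centroid distances equal raw-space
        distances to the group mean — an independent geometric oracle."""
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(labels, d)
        codes = np.array([0] * 4 + [1] * 4)
        dist = _centroid_distances(dm, codes, 2)
        for g in (0, 1):
            members = pts[codes == g]
            expected = np.linalg.norm(members - members.mean(0), axis=1)
            np.testing.assert_allclose(dist[codes == g], expected, atol=1e-9)

    def test_detects_engineered_dispersion_difference(self):
        """Tight vs loose group: permutation p below 0.05 for most seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tight = rng.normal(0, 0.05, (8, 3))
            loose = rng.normal(0, 2.0, (8, 3))
            pts = np.vstack([tight, loose])
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            labels = [f"s{i}" for i in range(16)]
            dm = DistanceMatrix(labels, d)
            groups = dict(zip(labels, ["t"] * 8 + ["l"] * 8))
            res = dispersion_test(dm, groups, n_perm=99, seed=seed)
            hits += res.p < 0.05
        assert hits >= 9


class TestIndval:
    def test_perfect_indicator_scores_100(self):
        rows = np.array([[5.0, 1.0], [4.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        res = indval(profile(rows), {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"},
                     n_perm=49, seed=0)
        c0 = res.table[(res.table.compound == "c0") & (res.table.group == "g1")]
        assert c0["indval"].iloc[0] == pytest.approx(100.0)

    def test_hand_example(self):
        """Group means {3,1}, presence {2/2, 1/2}: IndVal_A=75, IndVal_B=12.5."""
        rows = np.array([[2.0, 9.0], [4.0, 9.0], [0.0, 9.0], [2.0, 9.0]])
        res = indval(profile(rows), {"s0": "A", "s1": "A", "s2": "B", "s3": "B"},
                     n_perm=9, seed=0)
        tab = res.table[res.table.compound == "c0"].set_index("group")["indval"]
        assert tab["A"] == pytest.approx(75.0)
        assert tab["B"] == pytest.approx(12.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        rows = rng.uniform(0, 10, (6, 4))
        groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        r1 = indval(profile(rows), groups, n_perm=29, seed=5)
        scaled = rows.copy()
        scaled[:, 2] *= 7.5
        r2 = indval(profile(scaled), groups, n_perm=29, seed=5)
        np.testing.assert_allclose(
            r1.table["indval"].to_numpy(), r2.table["indval"].to_numpy(), atol=1e-9
        )

    def test_absent_compound_zero_everywhere(self):
        rows = np.array([[0.0, 5.0], [0.0, 5.0], [0.0, 5.0], [0.0, 5.0]])
        res = indval(profile(rows), {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"},
                     n_perm=9, seed=0)
        assert (res.table[res.table.compound == "c0"]["indval"] == 0.0).all()
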