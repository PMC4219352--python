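"""Compositional chemometrics for marking-secretion profiles.

The battery mirrors standard ecological practice for samples x compounds
relative-amount matrices: discard compounds never reaching 0.1% in any
sample, tame the abundance range with log10(x+1) and per-compound
standardization, compute Bray-Curtis distances, ordinate by non-metric
multidimensional scaling, test group separation with a permutational
MANOVA (pseudo-F on the distance decomposition), compare within-group
spread with a distance-based homogeneity-of-dispersions test, and find
group-diagnostic compounds with indicator values (specificity x fidelity).

Note on the transform: a "log(x-1)" transform is arithmetically impossible
for relative amounts at or below 1%, so the standard log10(x+1) compositional
transform is used here (see the methods documentation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .datatypes import ChemProfileMatrix, DistanceMatrix


def filter_compounds(
    chem: ChemProfileMatrix, threshold: float = 0.1
) -> ChemProfileMatrix:
    """Keep a compound iff its relative amount reaches ``threshold`` (%) in
    at least one sample (boundary inclusive). Rows are not renormalized."""
    keep = chem.data.columns[(chem.data.max(axis=0) >= threshold)]
    if len(keep) == 0:
        raise ValueError("all compounds fall below the detection threshold")
    return ChemProfileMatrix(chem.data[list(keep)])


def transform_standardize(chem: ChemProfileMatrix) -> pd.DataFrame:
    """log10(x+1) then per-compound standardization to mean 0, sd 1
    (sample sd). Zero-variance compounds become all-zero columns with a
    warning."""
    values = chem.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative relative amounts")
    logged = np.log10(values + 1.0)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1) if logged.shape[0] > 1 else np.zeros(logged.shape[1])
    flat = sd <= 1e-15
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance compounds set to zero", stacklevel=2
        )
    out = np.zeros_like(logged)
    cols = ~flat
    out[:, cols] = (logged[:, cols] - mean[cols]) / sd[cols]
    return pd.DataFrame(out, index=chem.data.index, columns=chem.data.columns)


def bray_curtis(matrix: pd.DataFrame | np.ndarray,
                labels: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis distance matrix: sum|x-y| / sum(x+y) over compounds.

    The input may contain negatives (e.g. a standardized matrix); it is then
    shifted by its global minimum so the coefficient is defined. A pair with
    zero total abundance gets distance 0 with a warning.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(values.shape[0])]
    if not np.isfinite(values).all():
        raise ValueError("non-finite values")
    lo = values.min()
    if lo < 0:
        values = values - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(values, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("pairs with zero total abundance; distance set to 0", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


@dataclass
class NmdsResult:
    k: int
    coordinates: pd.DataFrame
    stress: float           # Kruskal stress-1
    n_runs: int
    seed: int | None


def nmds(
    dm: DistanceMatrix, k: int = 3, n_runs: int = 50, seed: int | None = None
) -> NmdsResult:
    """Non-metric MDS (Kruskal stress-1, isotonic regression inside the
    majorization loop), best configuration of ``n_runs`` random starts."""
    if k >= dm.n - 1:
        raise ValueError("k must be smaller than n-1")
    import inspect

    kwargs = dict(
        n_components=k,
        n_init=n_runs,
        max_iter=300,
        random_state=None if seed is None else int(seed) % (2**32),
        normalized_stress=True,
        eps=1e-9,
    )
    params = inspect.signature(MDS).parameters
    if "metric_mds" in params:          # sklearn >= 1.9 naming
        kwargs.update(metric="precomputed", metric_mds=False, init="random")
    else:
        kwargs.update(dissimilarity="precomputed", metric=False)
    model = MDS(**kwargs)
    coords = model.fit_transform(dm.values)
    return NmdsResult(
        k=k,
        coordinates=pd.DataFrame(
            coords, index=dm.labels, columns=[f"axis{i+1}" for i in range(k)]
        ),
        stress=float(model.stress_),
        n_runs=n_runs,
        seed=seed,
    )


@dataclass
class PermanovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    n_permutations: int
    pairwise: pd.DataFrame | None = None   # Bonferroni-adjusted when >2 groups


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from the distance decomposition: among/within sums of
    squares with SS_total = sum d^2 / N and SS_within summed per group."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    return (ss_between / df_b) / (ss_within / df_w)


def permanova(
    dm: DistanceMatrix,
    groups: dict[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
    _pairwise: bool = True,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix.

    p is the proportion of free label permutations with pseudo-F >= observed
    (+1 correction). With more than two groups a Bonferroni-adjusted
    pairwise table is attached.
    """
    labels = dm.labels
    values = [groups[l] for l in labels]
    names = sorted(set(values))
    if len(names) < 2:
        raise ValueError("perMANOVA needs >= 2 groups")
    sizes = {g: values.count(g) for g in names}
    small = [g for g, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"groups of size 1 not allowed: {small}")
    index = {g: i for i, g in enumerate(names)}
    codes = np.array([index[v] for v in values])
    d2 = dm.values**2
    observed = _pseudo_f(d2, codes, len(names))
    rng = np.random.default_rng(seed)
    exceed = sum(
        _pseudo_f(d2, rng.permutation(codes), len(names)) >= observed - 1e-12
        for _ in range(n_perm)
    )
    p = (exceed + 1) / (n_perm + 1)
    pairwise = None
    if len(names) > 2 and _pairwise:
        rows = []
        n_tests = len(names) * (len(names) - 1) // 2
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                sub_labels = [l for l, v in zip(labels, values) if v in (ga, gb)]
                sub = permanova(
                    dm.submatrix(sub_labels), groups, n_perm=n_perm,
                    seed=None if seed is None else seed + 1, _pairwise=False,
                )
                rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "F": sub.f,
                        "p": sub.p,
                        "p_bonferroni": min(sub.p * n_tests, 1.0),
                    }
                )
        pairwise = pd.DataFrame(rows)
    return PermanovaResult(
        f=observed, p=p, df_between=len(names) - 1,
        df_within=dm.n - len(names), n_permutations=n_perm, pairwise=pairwise,
    )


@dataclass
class DispersionResult:
    distances: pd.Series           # per-sample distance to its group centroid
    group_variability: pd.Series   # per-group mean distance ("variability")
    f: float
    p: float
    n_permutations: int


def _centroid_distances(dm: DistanceMatrix, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Distances to group centroids in the principal-coordinate embedding of
    the distance matrix, with the usual imaginary-axis correction for
    negative eigenvalues."""
    n = dm.n
    a = -0.5 * dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    keep = np.abs(eigval) > 1e-10
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    pos = eigval > 0
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, ~pos] * np.sqrt(-eigval[~pos])
    out = np.zeros(n)
    for gidx in range(n_groups):
        members = np.flatnonzero(codes == gidx)
        cr = real[members].mean(axis=0)
        ci = imag[members].mean(axis=0) if imag.size else np.zeros(0)
        dr = ((real[members] - cr) ** 2).sum(axis=1)
        di = ((imag[members] - ci) ** 2).sum(axis=1) if imag.size else 0.0
        out[members] = np.sqrt(np.maximum(dr - di, 0.0))
    return out


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.size
    grand = values.mean()
    ss_b = ss_w = 0.0
    for g in range(n_groups):
        members = values[codes == g]
        ss_b += members.size * (members.mean() - grand) ** 2
        ss_w += ((members - members.mean()) ** 2).sum()
    if ss_w <= 1e-300:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / (n_groups - 1)) / (ss_w / (n - n_groups))


def dispersion_test(
    dm: DistanceMatrix,
    groups: dict[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Multivariate homogeneity of group dispersions.

    Distances to group centroids are computed in principal-coordinate space
    of the distance matrix (negative eigenvalues handled by the imaginary-
    axis correction); the ANOVA F on those distances is compared with its
    permutation distribution under shuffled group labels (centroids and
    distances recomputed each time). The per-group mean distance is the
    "variability" carried forward to the cartography and the regression.
    """
    labels = dm.labels
    values = [groups[l] for l in labels]
    names = sorted(set(values))
    if len(names) < 2:
        raise ValueError("dispersion test needs >= 2 groups")
    index = {g: i for i, g in enumerate(names)}
    codes = np.array([index[v] for v in values])
    dist = _centroid_distances(dm, codes, len(names))
    variability = pd.Series(
        {g: float(dist[codes == index[g]].mean()) for g in names}
    )
    if np.allclose(dist, 0.0):
        warnings.warn("degenerate embedding: all dispersions zero; test skipped",
                      stacklevel=2)
        return DispersionResult(
            pd.Series(dist, index=labels), variability, 0.0, 1.0, 0
        )
    observed = _anova_f(dist, codes, len(names))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        pd_dist = _centroid_distances(dm, perm, len(names))
        if _anova_f(pd_dist, perm, len(names)) >= observed - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return DispersionResult(
        pd.Series(dist, index=labels), variability, observed, p, n_perm
    )


@dataclass
class IndvalResult:
    table: pd.DataFrame  # compound, group, indval, p, significant
    alpha: float

    def significant_counts(self) -> pd.Series:
        """Per group: number of compounds whose best (max) indicator group is
        that group and whose randomization p is below alpha."""
        sig = self.table[self.table["significant"] & self.table["is_max_group"]]
        return sig.groupby("group").size()


def _indval_matrix(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """(n_groups, n_compounds) indicator values = A * B * 100."""
    n_compounds = values.shape[1]
    means = np.zeros((n_groups, n_compounds))
    presence = np.zeros((n_groups, n_compounds))
    for g in range(n_groups):
        block = values[codes == g]
        means[g] = block.mean(axis=0)
        presence[g] = (block > 0).mean(axis=0)
    total = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        specificity = np.where(total > 0, means / np.maximum(total, 1e-300), 0.0)
    return specificity * presence * 100.0


def indval(
    chem: ChemProfileMatrix | pd.DataFrame,
    groups: dict[str, str],
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> IndvalResult:
    """Indicator value analysis on (untransformed) relative amounts.

    IndVal_gc = A_gc * B_gc * 100 with specificity A = group mean abundance
    over the sum of group means and fidelity B = within-group presence
    fraction (> 0). The p-value per compound is the proportion of label
    permutations whose maximum-group IndVal reaches the observed maximum.
    """
    data = chem.data if isinstance(chem, ChemProfileMatrix) else chem
    labels = [str(i) for i in data.index]
    values = data.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundances")
    grouping = [groups[l] for l in labels]
    names = sorted(set(grouping))
    if len(names) < 2:
        raise ValueError("IndVal needs >= 2 groups")
    index = {g: i for i, g in enumerate(names)}
    codes = np.array([index[v] for v in grouping])
    observed = _indval_matrix(values, codes, len(names))
    obs_max = observed.max(axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[1])
    for _ in range(n_perm):
        perm = _indval_matrix(values, rng.permutation(codes), len(names))
        exceed += perm.max(axis=0) >= obs_max - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    best = observed.argmax(axis=0)
    rows = []
    for c, compound in enumerate(data.columns):
        for g, group in enumerate(names):
            rows.append(
                {
                    "compound": str(compound),
                    "group": group,
                    "indval": observed[g, c],
                    "is_max_group": g == best[c],
                    "p": p[c],
                    "significant": bool(p[c] <= alpha),
                }
            )
    return IndvalResult(pd.DataFrame(rows), alpha)


def chemical_pipeline_distances(
    chem: ChemProfileMatrix,
    threshold: float = 0.1,
    mode: str = "standardized",
) -> DistanceMatrix:
    """Filter then Bray-Curtis, either on the transformed-standardized matrix
    (shifted non-negative) or directly on relative amounts (``mode="raw"``)."""
    filtered = filter_compounds(chem, threshold)
    if mode == "standardized":
        return bray_curtis(transform_standardize(filtered))
    if mode == "raw":
        return bray_curtis(filtered.data)
    raise ValueError(f"unknown mode {mode!r}")
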