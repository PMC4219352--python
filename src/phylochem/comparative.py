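"""Cross-data-type correlation layer.

Distance construction (great-circle geographic, binary colour-pattern),
Mantel and partial Mantel matrix-correlation tests with permutation
p-values, and the linear model relating per-group genetic diversity to
chemical-profile variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import DistanceMatrix, SampleTable
from .landscape import haversine_km


def geographic_distance_matrix(samples: SampleTable) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between all samples."""
    df = samples.data
    if df[["lat", "lon"]].isna().any().any():
        bad = df.loc[df[["lat", "lon"]].isna().any(axis=1), "sample_id"].tolist()
        raise ValueError(f"missing coordinates for samples: {bad}")
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(samples.sample_ids, d)


def colour_distance_matrix(samples: SampleTable) -> DistanceMatrix:
    """Binary colour-pattern distance: 0 for a shared pattern, 1 otherwise."""
    labels = samples.data["colour_label"]
    if labels.isna().any():
        bad = samples.data.loc[labels.isna(), "sample_id"].tolist()
        raise ValueError(f"missing colour labels for samples: {bad}")
    arr = labels.to_numpy()
    d = (arr[:, None] != arr[None, :]).astype(float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples.sample_ids, d)


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    one_tailed: bool = True
    n: int = 0


def _check_pair(a: DistanceMatrix, b: DistanceMatrix) -> None:
    if a.labels != b.labels:
        raise ValueError("distance matrices must share the same labels in order")
    if a.n < 4:
        raise ValueError("Mantel test needs >= 4 labels")


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx <= 1e-300 or sy <= 1e-300:
        raise ValueError("degenerate (constant) off-diagonal distances")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    one_tailed: bool = True,
) -> MantelResult:
    """Mantel matrix correlation with simultaneous row/column permutation of B.

    r is the Pearson correlation of the upper-triangle entries; p defaults to
    the one-tailed (upper) permutation probability with the +1 correction.
    """
    _check_pair(a, b)
    av, bv = a.values, b.values
    x = _upper(av)
    observed = _corr(x, _upper(bv))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.n)
        r = _corr(x, _upper(bv[np.ix_(perm, perm)]))
        if one_tailed:
            exceed += r >= observed - 1e-12
        else:
            exceed += abs(r) >= abs(observed) - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    return MantelResult(observed, p, n_perm, one_tailed, a.n)


def mantel_exhaustive(a: DistanceMatrix, b: DistanceMatrix) -> MantelResult:
    """Exact Mantel p over all n! label permutations (small n only)."""
    from itertools import permutations

    _check_pair(a, b)
    x = _upper(a.values)
    observed = _corr(x, _upper(b.values))
    total = exceed = 0
    for perm in permutations(range(a.n)):
        idx = np.array(perm)
        r = _corr(x, _upper(b.values[np.ix_(idx, idx)]))
        exceed += r >= observed - 1e-12
        total += 1
    return MantelResult(observed, exceed / total, total, True, a.n)


def _residual_matrix(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Symmetric matrix of OLS residuals of y's upper triangle on x's."""
    yu, xu = _upper(y), _upper(x)
    slope, intercept = np.polyfit(xu, yu, 1)
    res = yu - (slope * xu + intercept)
    n = y.shape[0]
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = res
    return out + out.T


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel correlation of A and B controlling for C.

    r_AB.C is the first-order partial correlation of upper triangles; the
    permutation p permutes the residual matrix of A on C (rows and columns
    simultaneously) against the residuals of B on C.
    """
    _check_pair(a, b)
    _check_pair(a, c)
    au, bu, cu = _upper(a.values), _upper(b.values), _upper(c.values)
    r_ab = _corr(au, bu)
    r_ac = _corr(au, cu)
    r_bc = _corr(bu, cu)
    if min(1 - r_ac**2, 1 - r_bc**2) <= 1e-12:
        raise ValueError("control matrix perfectly correlated with an input")
    observed = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    res_a = _residual_matrix(a.values, c.values)
    res_b_u = _upper(_residual_matrix(b.values, c.values))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.n)
        r = _corr(_upper(res_a[np.ix_(perm, perm)]), res_b_u)
        exceed += r >= observed - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    return MantelResult(float(observed), p, n_perm, True, a.n)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_slope: float
    n_groups: int
    table: pd.DataFrame


def diversity_variability_regression(
    group_diversity: dict[str, float],
    group_variability: dict[str, float],
    group_sizes: dict[str, int] | None = None,
) -> RegressionResult:
    """Gaussian-identity linear model of chemical variability on genetic
    diversity across geographic groups.

    Groups with only one sample (where either quantity is undefined) are
    excluded before fitting; at least three groups must remain.
    """
    rows = []
    for group in sorted(set(group_diversity) & set(group_variability)):
        if group_sizes is not None and group_sizes.get(group, 0) < 2:
            continue
        x, y = group_diversity[group], group_variability[group]
        if np.isfinite(x) and np.isfinite(y):
            rows.append({"geo_group": group, "diversity": x, "variability": y})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("regression needs >= 3 groups with defined values")
    design = sm.add_constant(table["diversity"].to_numpy())
    fit = sm.GLM(table["variability"].to_numpy(), design,
                 family=sm.families.Gaussian()).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_slope=float(fit.pvalues[1]),
        n_groups=len(table),
        table=table,
    )


def mantel_battery(
    genetic: DistanceMatrix,
    chemical: DistanceMatrix,
    geographic: DistanceMatrix,
    colour: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """The six Mantel and three partial Mantel tests of the comparative layer,
    restricted to the samples shared by all four matrices."""
    common = [l for l in genetic.labels
              if l in set(chemical.labels) & set(geographic.labels) & set(colour.labels)]
    gen = genetic.submatrix(common)
    che = chemical.submatrix(common)
    geo = geographic.submatrix(common)
    col = colour.submatrix(common)
    rng = np.random.default_rng(seed)

    def run(name, a, b):
        res = mantel(a, b, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        return {"test": name, "kind": "mantel", "r": res.r, "p": res.p,
                "n": res.n, "n_perm": n_perm}

    def run_partial(name, a, b, c):
        res = partial_mantel(a, b, c, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        return {"test": name, "kind": "partial_mantel", "r": res.r, "p": res.p,
                "n": res.n, "n_perm": n_perm}

    rows = [
        run("genetic_vs_geographic", gen, geo),
        run("chemical_vs_geographic", che, geo),
        run("colour_vs_geographic", col, geo),
        run("genetic_vs_chemical", gen, che),
        run("genetic_vs_colour", gen, col),
        run("chemical_vs_colour", che, col),
        run_partial("genetic_vs_chemical_given_geography", gen, che, geo),
        run_partial("genetic_vs_colour_given_geography", gen, col, geo),
        run_partial("chemical_vs_colour_given_geography", che, col, geo),
    ]
    return pd.DataFrame(rows)
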