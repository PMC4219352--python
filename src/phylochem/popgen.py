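"""Haplotype collapsing and classical sequence diversity statistics.

Haplotypes are exact sequence matches per locus. Diversity follows Nei:
unbiased haplotype diversity h = n(1 - sum p_i^2)/(n - 1) and nucleotide
diversity pi as the mean pairwise proportion of differing sites, with
pairwise deletion of sites carrying N or a gap in either member of a pair.
A strict molecular clock converts percent divergence to time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DistanceMatrix, OBSERVED_STATES, SequenceAlignment

_OBSERVED = np.array(sorted(OBSERVED_STATES), dtype="S1")


@dataclass
class HaplotypeSet:
    """Distinct sequences at one locus with per-sample assignment."""

    locus_id: str
    haplotypes: list[str]          # haplotype id h{i+1} -> haplotypes[i]
    assignment: dict[str, int]     # sample id -> haplotype index
    group_counts: pd.DataFrame | None = None  # haplotype x geo_group counts

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def counts(self) -> np.ndarray:
        out = np.zeros(len(self.haplotypes), dtype=int)
        for idx in self.assignment.values():
            out[idx] += 1
        return out


def collapse_haplotypes(
    aln: SequenceAlignment, group_of: dict[str, str] | None = None
) -> HaplotypeSet:
    """Collapse an alignment to its distinct sequences.

    Identity is exact string match (the alignments analysed here required no
    indel-aware collapsing); haplotype ids are stable by first occurrence.
    """
    haplotypes: list[str] = []
    index: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        if seq not in index:
            index[seq] = len(haplotypes)
            haplotypes.append(seq)
        assignment[sid] = index[seq]
    group_counts = None
    if group_of is not None:
        rows = [(f"h{assignment[s] + 1}", group_of[s]) for s in aln.sample_ids]
        df = pd.DataFrame(rows, columns=["haplotype", "geo_group"])
        group_counts = df.value_counts().unstack(fill_value=0)
    return HaplotypeSet(aln.locus_id, haplotypes, assignment, group_counts)


def count_parsimony_informative(aln: SequenceAlignment) -> int:
    """Number of sites with >=2 states each present in >=2 sequences.

    Gaps and N are excluded as states.
    """
    arr = aln.to_array()
    n_informative = 0
    for j in range(aln.length):
        col = arr[:, j]
        col = col[np.isin(col, _OBSERVED)]
        if col.size < 4:
            continue
        _, counts = np.unique(col, return_counts=True)
        if (counts >= 2).sum() >= 2:
            n_informative += 1
    return n_informative


def haplotype_diversity(counts: np.ndarray | list[int]) -> float:
    """Nei's unbiased haplotype diversity from haplotype counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2 samples")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def _observed_mask(arr: np.ndarray) -> np.ndarray:
    return np.isin(arr, _OBSERVED)


def _pairwise_counts(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(diff, comp): per-pair mismatch counts and compared-site counts under
    pairwise deletion. Row-chunked to keep memory flat."""
    n = arr.shape[0]
    observed = _observed_mask(arr)
    diff = np.zeros((n, n))
    comp = np.zeros((n, n))
    for i in range(n - 1):
        both = observed[i] & observed[i + 1:]
        mism = (arr[i] != arr[i + 1:]) & both
        diff[i, i + 1:] = mism.sum(axis=1)
        comp[i, i + 1:] = both.sum(axis=1)
    diff += diff.T
    comp += comp.T
    return diff, comp


def nucleotide_diversity(aln: SequenceAlignment) -> float:
    """Mean pairwise proportion of differing sites (substitutions/site)."""
    if aln.n_samples < 2:
        raise ValueError("nucleotide diversity requires n >= 2 samples")
    diff, comp = _pairwise_counts(aln.to_array())
    iu = np.triu_indices(aln.n_samples, k=1)
    d, c = diff[iu], comp[iu]
    usable = c > 0
    if not usable.all():
        warnings.warn(
            f"{(~usable).sum()} pairs share no comparable sites; excluded",
            stacklevel=2,
        )
    if not usable.any():
        raise ValueError("no pair shares comparable sites")
    return float(np.mean(d[usable] / c[usable]))


def pairwise_p_distance(alns: list[SequenceAlignment]) -> DistanceMatrix:
    """Inter-individual p-distance averaged (unweighted) over loci.

    Per locus: mismatches / compared sites with pairwise deletion; the
    multi-locus distance is the mean over loci where both samples are
    present. Pairs sharing no locus get NaN and are reported in a warning.
    """
    if not alns:
        raise ValueError("at least one locus required")
    labels: list[str] = []
    for aln in alns:
        labels.extend(s for s in aln.sample_ids if s not in labels)
    n = len(labels)
    index = {s: i for i, s in enumerate(labels)}
    acc = np.zeros((n, n))
    n_loci = np.zeros((n, n))
    for aln in alns:
        diff, comp = _pairwise_counts(aln.to_array())
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(comp > 0, diff / np.maximum(comp, 1), np.nan)
        idx = np.array([index[s] for s in aln.sample_ids])
        ok = np.isfinite(p)
        sub = np.ix_(idx, idx)
        acc[sub] += np.where(ok, p, 0.0)
        n_loci[sub] += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_loci > 0, acc / np.maximum(n_loci, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    missing = ~np.isfinite(values)
    if missing.any():
        warnings.warn(
            f"{missing.sum() // 2} sample pairs share no locus; distances missing",
            stacklevel=2,
        )
    return DistanceMatrix(labels, values, allow_missing=bool(missing.any()))


def diversity_by_group(
    aln: SequenceAlignment, group_of: dict[str, str]
) -> pd.DataFrame:
    """Per geographic group: n, number of haplotypes, h and pi for one locus.

    Groups with a single sample get NaN diversities (undefined) and a row is
    still emitted so the exclusion is visible downstream.
    """
    rows = []
    groups: dict[str, list[str]] = {}
    for sid in aln.sample_ids:
        groups.setdefault(group_of[sid], []).append(sid)
    for group in sorted(groups):
        members = groups[group]
        sub = aln.subset(members)
        hset = collapse_haplotypes(sub)
        if len(members) >= 2:
            h = haplotype_diversity(hset.counts())
            pi = nucleotide_diversity(sub)
        else:
            h = pi = float("nan")
        rows.append(
            {
                "geo_group": group,
                "locus": aln.locus_id,
                "n": len(members),
                "n_haplotypes": hset.n_haplotypes,
                "h": h,
                "pi": pi,
            }
        )
    return pd.DataFrame(rows)


def mean_pi_over_loci(
    alns: list[SequenceAlignment], group_of: dict[str, str]
) -> dict[str, float]:
    """Per-group nucleotide diversity averaged over the given loci.

    Groups whose diversity is undefined (n < 2) at every locus are omitted.
    """
    tables = pd.concat([diversity_by_group(a, group_of) for a in alns])
    out: dict[str, float] = {}
    for group, block in tables.groupby("geo_group"):
        pis = block["pi"].dropna()
        if len(pis):
            out[str(group)] = float(pis.mean())
    return out


def clock_divergence_time(
    divergence_percent: float, rate_percent_per_myr: float = 2.0
) -> float:
    """Strict-clock conversion of percent sequence divergence to Myr.

    Default rate is the 2%-per-million-years mitochondrial clock commonly
    applied to insects.
    """
    if divergence_percent < 0:
        raise ValueError("divergence must be non-negative")
    if rate_percent_per_myr <= 0:
        raise ValueError("clock rate must be positive")
    return divergence_percent / rate_percent_per_myr
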