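"""Shared domain containers used across the pipeline.

Sequence alignments, sample metadata, compositional chemical profiles,
labelled distance matrices and interpolation surfaces are the five carriers
every analysis stage consumes or produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STATES = frozenset("ACGTN-")
#: nucleotide states that count as observed (gap and N are treated as missing)
OBSERVED_STATES = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised when sequences violate alignment invariants (ragged lengths etc.)."""


class SchemaError(ValueError):
    """Raised when tabular input lacks required columns or violates uniqueness."""


@dataclass
class SequenceAlignment:
    """Per-locus matrix of aligned nucleotide sequences keyed by sample id.

    All sequences must have equal length over the alphabet {A,C,G,T,N,-};
    sample ids must be unique.
    """

    locus_id: str
    sample_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError(f"duplicate sample ids in locus {self.locus_id!r}")
        if not self.sequences:
            raise AlignmentError(f"locus {self.locus_id!r}: empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {self.locus_id!r}: unequal sequence lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise AlignmentError(f"locus {self.locus_id!r}: zero-length alignment")
        bad = set("".join(self.sequences)) - VALID_STATES
        if bad:
            raise AlignmentError(
                f"locus {self.locus_id!r}: invalid states {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_array(self) -> np.ndarray:
        """(n_samples, length) array of single-byte characters."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype="S1"
        ).reshape(self.n_samples, self.length)

    def subset(self, sample_ids: list[str]) -> "SequenceAlignment":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from locus {self.locus_id!r}: {missing}")
        return SequenceAlignment(
            self.locus_id,
            list(sample_ids),
            [self.sequences[index[s]] for s in sample_ids],
        )


REQUIRED_SAMPLE_COLUMNS = ("sample_id", "site_id", "lat", "lon", "geo_group", "colour_label")


@dataclass
class SampleTable:
    """Sample metadata: site coordinates, geographic group and colour label.

    The join key across genetic and chemical data. Extra columns are carried
    through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"sample table missing required columns: {missing}")
        ids = self.data["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise SchemaError(f"duplicate sample ids: {dupes}")
        lat = pd.to_numeric(self.data["lat"], errors="raise")
        lon = pd.to_numeric(self.data["lon"], errors="raise")
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude outside [-180, 180]")
        if (self.data["geo_group"].astype(str).str.len() == 0).any():
            raise SchemaError("empty geo_group label")
        self.data = self.data.assign(lat=lat.astype(float), lon=lon.astype(float))
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def site_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["site_id"]))

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["geo_group"]))

    def colour_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["colour_label"]))

    def site_coords(self) -> dict[str, tuple[float, float]]:
        """site id -> (lon, lat); sites must be internally consistent."""
        out: dict[str, tuple[float, float]] = {}
        for _, row in self.data.iterrows():
            coord = (float(row["lon"]), float(row["lat"]))
            prev = out.setdefault(str(row["site_id"]), coord)
            if prev != coord:
                raise ValueError(f"site {row['site_id']!r} has inconsistent coordinates")
        return out

    def group_barycenters(self) -> dict[str, tuple[float, float]]:
        """geo group -> (lon, lat) barycenter of its sampling places."""
        sites = self.data.drop_duplicates("site_id")
        out = {}
        for group, block in sites.groupby("geo_group"):
            out[str(group)] = (float(block["lon"].mean()), float(block["lat"].mean()))
        return out

    def subset(self, sample_ids: list[str]) -> "SampleTable":
        block = self.data.set_index("sample_id", drop=False).loc[list(sample_ids)]
        return SampleTable(block.reset_index(drop=True))


ROW_SUM_TOLERANCE = 0.5  # percentage points around 100


@dataclass
class ChemProfileMatrix:
    """Samples x compounds matrix of relative amounts (%), compositional.

    Rows whose sum deviates from 100 by more than ``ROW_SUM_TOLERANCE`` are
    flagged (never rejected): partially quantified blends are the normal case
    once rare compounds have been filtered out.
    """

    data: pd.DataFrame
    flagged_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise SchemaError("duplicate sample ids in chemical matrix")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite relative amount")
        if (values < 0).any():
            raise ValueError("negative relative amount")
        self.data = self.data.astype(float)
        sums = values.sum(axis=1)
        off = np.abs(sums - 100.0) > ROW_SUM_TOLERANCE
        self.flagged_rows = [str(s) for s in self.data.index[off]]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def compound_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def subset(self, sample_ids: list[str]) -> "ChemProfileMatrix":
        return ChemProfileMatrix(self.data.loc[list(sample_ids)])


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal.

    ``allow_missing`` permits NaN entries for pairs where the distance is
    undefined (e.g. samples sharing no sequenced locus); such entries are
    reported, and downstream consumers that require complete matrices refuse
    them explicitly.
    """

    labels: list[str]
    values: np.ndarray
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise SchemaError("duplicate labels in distance matrix")
        if not self.allow_missing and not np.isfinite(self.values).all():
            raise ValueError("non-finite distances in a complete matrix")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values) < 0:
                raise ValueError("negative distances")
        if not np.allclose(
            self.values, self.values.T, equal_nan=self.allow_missing, atol=1e-12
        ):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("non-zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def missing_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.isnan(np.triu(self.values, k=1)))
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j) if a < b]

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        index = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise KeyError(f"labels absent from distance matrix: {missing}")
        idx = np.array([index[l] for l in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.allow_missing)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class Surface:
    """Regular lon/lat grid of interpolated values.

    ``origin`` is the lower-left corner (lon, lat) and ``cellsize`` is the
    cell edge in decimal degrees. Cells outside the interpolation domain are
    masked and carry no value.
    """

    origin: tuple[float, float]
    cellsize: float
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.cellsize <= 0:
            raise ValueError("cell size must be positive")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        self.values = np.where(self.mask, np.nan, self.values)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell centers; row 0 is the southernmost row."""
        x0, y0 = self.origin
        lon = x0 + (np.arange(self.n_cols) + 0.5) * self.cellsize
        lat = y0 + (np.arange(self.n_rows) + 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]


def join_report(
    sample_table: SampleTable,
    alignments: dict[str, SequenceAlignment] | None = None,
    chem: ChemProfileMatrix | None = None,
) -> dict[str, list[str]]:
    """Report (never silently drop) samples missing from any joined source.

    Partial overlap between collected, sequenced and chemically profiled
    individuals is the normal case in this kind of survey.
    """
    table_ids = set(sample_table.sample_ids)
    report: dict[str, list[str]] = {}
    for locus_id, aln in (alignments or {}).items():
        report[f"missing_from_{locus_id}"] = sorted(table_ids - set(aln.sample_ids))
        report[f"unknown_in_{locus_id}"] = sorted(set(aln.sample_ids) - table_ids)
    if chem is not None:
        report["missing_from_chemistry"] = sorted(table_ids - set(chem.sample_ids))
        report["unknown_in_chemistry"] = sorted(set(chem.sample_ids) - table_ids)
    for key, samples in report.items():
        if samples:
            warnings.warn(f"{key}: {len(samples)} samples", stacklevel=2)
    return report
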