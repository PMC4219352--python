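"""Readers and writers for the standard formats the pipeline touches.

FASTA (alignments, via Biopython), CSV (sample table, chemical matrix),
Newick (trees), GraphML (haplotype networks, via networkx), ESRI ASCII grid
(surfaces) and TSV with a metadata header (statistics tables).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    AlignmentError,
    ChemProfileMatrix,
    SampleTable,
    SchemaError,
    SequenceAlignment,
    Surface,
)

# IUPAC ambiguity codes other than N are mapped to N on read: the study data
# report no uncertainty in consensus sequences, so these should not occur.
_AMBIGUOUS = "RYSWKMBDHV"
_AMBIG_TABLE = str.maketrans({c: "N" for c in _AMBIGUOUS})


def read_fasta_alignment(path: str | Path, locus_id: str) -> SequenceAlignment:
    """Read an aligned FASTA file into a :class:`SequenceAlignment`.

    Sequences are uppercased; ambiguity codes other than N become N with a
    warning; ragged records raise :class:`AlignmentError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SchemaError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    seqs = []
    ambiguous = 0
    for r in records:
        s = str(r.seq).upper()
        mapped = s.translate(_AMBIG_TABLE)
        ambiguous += sum(a != b for a, b in zip(s, mapped))
        seqs.append(mapped)
    if ambiguous:
        warnings.warn(
            f"{path}: {ambiguous} ambiguity codes mapped to N", stacklevel=2
        )
    return SequenceAlignment(locus_id, ids, seqs)


def write_fasta_alignment(aln: SequenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read the sample metadata CSV (sample_id, site_id, lat, lon, geo_group,
    colour_label; unknown columns preserved)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "site_id": str})
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_chem_matrix(path: str | Path) -> ChemProfileMatrix:
    """Read the samples x compounds relative-amount (%) CSV.

    First column holds sample ids. Rows failing the 100% sum tolerance are
    flagged on the returned object, not rejected.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return ChemProfileMatrix(df)


def write_chem_matrix(chem: ChemProfileMatrix, path: str | Path) -> None:
    chem.data.to_csv(path, index_label="sample_id")


NODATA = -9999.0


def write_surface_ascii(surface: Surface, path: str | Path) -> None:
    """Write a surface as an ESRI ASCII grid (row 0 written northernmost)."""
    x0, y0 = surface.origin
    lines = [
        f"ncols {surface.n_cols}",
        f"nrows {surface.n_rows}",
        f"xllcorner {x0:.6f}",
        f"yllcorner {y0:.6f}",
        f"cellsize {surface.cellsize:.8f}",
        f"NODATA_value {NODATA:g}",
    ]
    grid = np.where(surface.mask, NODATA, surface.values)
    for row in grid[::-1]:
        lines.append(" ".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_surface_ascii(path: str | Path) -> Surface:
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    grid = np.array(
        [[float(v) for v in line.split()] for line in lines[body_start:] if line.strip()]
    )[::-1]
    nodata = header.get("nodata_value", NODATA)
    mask = grid == nodata
    return Surface(
        origin=(header["xllcorner"], header["yllcorner"]),
        cellsize=header["cellsize"],
        values=np.where(mask, np.nan, grid),
        mask=mask,
    )


def write_network_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def write_stats_tsv(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    parameters: dict[str, Any] | None = None,
) -> None:
    """Write a statistics table as TSV with a ``#``-prefixed metadata header
    recording the RNG seed and the parameter set used to produce it."""
    meta = [f"# seed={seed}"]
    for key, value in (parameters or {}).items():
        meta.append(f"# {key}={value}")
    with open(path, "w") as fh:
        fh.write("\n".join(meta) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_stats_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
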