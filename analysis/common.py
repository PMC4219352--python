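"""Shared plumbing for the numbered analysis drivers.

Driver 01 writes the simulated study's input files under
results/study_inputs/; later drivers read them back through the package's
readers, so the whole chain exercises the same I/O surface a real dataset
would use.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

from phylochem import io
from phylochem.simulate import SimulationConfig, simulate_dataset

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
INPUTS = RESULTS / "study_inputs"
SEED = 20240501

# study conditions, down-scaled enough that every driver runs in seconds
STUDY = dict(n_sites=20, n_individuals=100, n_geo_groups=6)
LOCI = ["locusA", "locusB", "locusC", "locusD"]


def ensure_inputs():
    """Simulate and persist the study inputs if they are not on disk yet."""
    INPUTS.mkdir(parents=True, exist_ok=True)
    manifest = INPUTS / "truth.json"
    if not manifest.exists():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = simulate_dataset(SimulationConfig(**STUDY), seed=SEED)
        for locus, aln in ds.alignments.items():
            io.write_fasta_alignment(aln, INPUTS / f"{locus}.fasta")
        io.write_sample_table(ds.samples, INPUTS / "samples.csv")
        io.write_chem_matrix(ds.chem, INPUTS / "chem.csv")
        manifest.write_text(json.dumps({
            "seed": SEED,
            "config": STUDY,
            "lineage_of_sample": ds.truth.lineage_of_sample,
            "majority_lineage_of_site": ds.truth.majority_lineage_of_site(),
            "refugia": ds.truth.config.refugia,
        }, indent=2))
    return load_inputs()


def load_inputs():
    alignments = {
        locus: io.read_fasta_alignment(INPUTS / f"{locus}.fasta", locus)
        for locus in LOCI
    }
    samples = io.read_sample_table(INPUTS / "samples.csv")
    chem = io.read_chem_matrix(INPUTS / "chem.csv")
    truth = json.loads((INPUTS / "truth.json").read_text())
    return alignments, samples, chem, truth
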