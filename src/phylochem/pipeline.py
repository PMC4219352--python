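"""End-to-end orchestration of the analysis stages.

Stage order follows the study workflow: diversity -> population structure
(genes gated by a significant global Phi_ST) -> haplotype networks/trees ->
landscape surfaces -> chemometrics -> comparative tests. Every stochastic
stage derives its stream from the single global seed, all tabular outputs
embed seed and parameters, and a JSON manifest records enough to re-run the
analysis identically.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amova, chemometrics, comparative, haplonet, io, landscape, phylo, popgen
from .datatypes import ChemProfileMatrix, SampleTable, SequenceAlignment, join_report

log = logging.getLogger("phylochem")


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    loci: list[str] = field(default_factory=list)       # locus ids, order fixed
    fasta_paths: dict[str, str] = field(default_factory=dict)
    sample_table_path: str | None = None
    chem_matrix_path: str | None = None
    # stage toggles
    run_popgen: bool = True
    run_structure: bool = True
    run_network: bool = True
    run_landscape: bool = True
    run_chemometrics: bool = True
    run_comparative: bool = True
    # stage parameters
    phi_st_alpha: float = 0.01
    phi_st_floor: float = 0.0
    n_perm_amova: int = 10_000
    samova_k: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6, 7, 8])
    samova_reps: int = 10
    samova_steps: int = 10_000
    bootstrap_reps: int = 100
    idw_a: float = 2.0
    grid_cols: int = 150
    use_residuals: bool = True
    chem_threshold: float = 0.1
    bc_mode: str = "standardized"
    nmds_k: int = 3
    nmds_runs: int = 50
    n_perm_chem: int = 10_000
    n_perm_mantel: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def run_pipeline(
    cfg: PipelineConfig,
    alignments: dict[str, SequenceAlignment] | None = None,
    samples: SampleTable | None = None,
    chem: ChemProfileMatrix | None = None,
) -> dict:
    """Execute the configured stages; returns a report dict (also written as
    ``manifest.json`` in the output directory).

    Inputs may be passed in-memory (as from the simulator) or read from the
    paths in the config.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    report: dict = {"seed": cfg.seed, "parameters": asdict(cfg), "stages": {}}

    if samples is None:
        if cfg.sample_table_path is None:
            raise ValueError("no sample table provided")
        samples = io.read_sample_table(cfg.sample_table_path)
    if alignments is None:
        alignments = {
            locus: io.read_fasta_alignment(path, locus)
            for locus, path in cfg.fasta_paths.items()
        }
    if chem is None and cfg.chem_matrix_path:
        chem = io.read_chem_matrix(cfg.chem_matrix_path)
    loci = cfg.loci or sorted(alignments)
    alignments = {l: alignments[l] for l in loci}
    report["join"] = {
        k: len(v) for k, v in join_report(samples, alignments, chem).items()
    }

    group_of = samples.group_of()
    site_of = samples.site_of()
    site_coords = samples.site_coords()
    gene_dm: dict[str, object] = {}

    if cfg.run_popgen:
        tables = [popgen.diversity_by_group(a, group_of) for a in alignments.values()]
        diversity = pd.concat(tables, ignore_index=True)
        io.write_stats_tsv(diversity, outdir / "diversity.tsv", seed=cfg.seed,
                           parameters={"loci": ",".join(loci)})
        report["stages"]["popgen"] = {"rows": len(diversity)}

    if cfg.run_structure:
        rows, retained = [], []
        for locus, aln in alignments.items():
            dm = amova.mismatch_matrix(aln)
            sub_sites = {s: site_of[s] for s in aln.sample_ids}
            phi, p = amova.global_phi_st(
                dm, sub_sites, n_perm=cfg.n_perm_amova,
                seed=int(rng.integers(2**31 - 1)),
            )
            gene_dm[locus] = (dm, sub_sites)
            keep = p <= cfg.phi_st_alpha and phi >= cfg.phi_st_floor
            if not keep:
                log.warning("locus %s fails the structure gate (phi=%.3f p=%.4f)",
                            locus, phi, p)
            rows.append({"locus": locus, "global_phi_st": phi, "p": p,
                         "retained_for_samova": keep})
            if keep:
                retained.append(locus)
        gate = pd.DataFrame(rows)
        io.write_stats_tsv(gate, outdir / "global_phi_st.tsv", seed=cfg.seed,
                           parameters={"n_perm": cfg.n_perm_amova})
        scans = []
        for locus in retained:
            dm, sub_sites = gene_dm[locus]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scan = amova.samova_scan(
                    dm, sub_sites, site_coords,
                    k_range=[k for k in cfg.samova_k if k <= len(set(sub_sites.values()))],
                    n_reps=cfg.samova_reps, n_steps=cfg.samova_steps,
                    seed=int(rng.integers(2**31 - 1)),
                )
            scan.insert(0, "locus", locus)
            scans.append(scan)
        if scans:
            io.write_stats_tsv(pd.concat(scans, ignore_index=True),
                               outdir / "samova.tsv", seed=cfg.seed,
                               parameters={"reps": cfg.samova_reps,
                                           "steps": cfg.samova_steps})
        report["stages"]["structure"] = {
            "retained_loci": retained,
            "global_phi_st": {r["locus"]: round(r["global_phi_st"], 4) for r in rows},
        }

    if cfg.run_network:
        for locus, aln in alignments.items():
            hset = popgen.collapse_haplotypes(aln, group_of)
            if hset.n_haplotypes >= 2:
                net = haplonet.median_joining_network(hset)
                io.write_network_graphml(net.to_graph(), outdir / f"network_{locus}.graphml")
        tree = phylo.bootstrap_support(
            list(alignments.values()), n_reps=cfg.bootstrap_reps,
            seed=int(rng.integers(2**31 - 1)),
        )
        io.write_newick(tree.newick(), outdir / "nj_tree.nwk")
        report["stages"]["network"] = {"loci": loci, "tree_taxa": len(tree.taxa)}

    genetic_dm = popgen.pairwise_p_distance(list(alignments.values()))
    icfg = landscape.InterpolationConfig(
        a=cfg.idw_a, n_cols=cfg.grid_cols, use_residuals=cfg.use_residuals
    )
    if cfg.run_landscape:
        net = landscape.build_connectivity(site_coords)
        surface, _, _ = landscape.distance_surface(
            net, genetic_dm, site_of, site_coords, icfg
        )
        io.write_surface_ascii(surface, outdir / "genetic_distance_surface.asc")
        pi = popgen.mean_pi_over_loci(list(alignments.values()), group_of)
        div_surface = landscape.diversity_surface(
            pi, samples.group_barycenters(), icfg
        )
        io.write_surface_ascii(div_surface, outdir / "genetic_diversity_surface.asc")
        report["stages"]["landscape"] = {"edges": len(net.edges)}

    chem_dm = None
    variability = None
    if cfg.run_chemometrics and chem is not None:
        chem_f = chemometrics.filter_compounds(chem, cfg.chem_threshold)
        chem_dm = chemometrics.chemical_pipeline_distances(
            chem, cfg.chem_threshold, cfg.bc_mode
        )
        chem_groups = {s: group_of[s] for s in chem_dm.labels if s in group_of}
        ord_res = chemometrics.nmds(
            chem_dm, k=cfg.nmds_k, n_runs=cfg.nmds_runs,
            seed=int(rng.integers(2**31 - 1)),
        )
        io.write_stats_tsv(
            ord_res.coordinates.reset_index(names="sample_id"),
            outdir / "nmds_coordinates.tsv", seed=cfg.seed,
            parameters={"k": cfg.nmds_k, "stress": round(ord_res.stress, 4)},
        )
        perm = chemometrics.permanova(
            chem_dm, chem_groups, n_perm=cfg.n_perm_chem,
            seed=int(rng.integers(2**31 - 1)),
        )
        disp = chemometrics.dispersion_test(
            chem_dm, chem_groups, n_perm=min(cfg.n_perm_chem, 999),
            seed=int(rng.integers(2**31 - 1)),
        )
        variability = disp.group_variability
        iv = chemometrics.indval(
            chem_f.subset(chem_dm.labels), chem_groups,
            seed=int(rng.integers(2**31 - 1)),
        )
        io.write_stats_tsv(iv.table, outdir / "indval.tsv", seed=cfg.seed,
                           parameters={"alpha": iv.alpha})
        io.write_stats_tsv(
            variability.rename("variability").rename_axis("geo_group").reset_index(),
            outdir / "chem_variability.tsv", seed=cfg.seed, parameters={},
        )
        if cfg.run_landscape:
            net = landscape.build_connectivity(site_coords)
            chem_surface, _, _ = landscape.distance_surface(
                net, chem_dm, site_of, site_coords, icfg
            )
            io.write_surface_ascii(chem_surface, outdir / "chem_distance_surface.asc")
            var_surface = landscape.diversity_surface(
                variability.to_dict(), samples.group_barycenters(), icfg
            )
            io.write_surface_ascii(var_surface, outdir / "chem_variability_surface.asc")
        report["stages"]["chemometrics"] = {
            "n_compounds_kept": len(chem_f.compound_ids),
            "nmds_stress": round(ord_res.stress, 4),
            "permanova_f": round(perm.f, 3),
            "permanova_p": perm.p,
            "dispersion_f": round(disp.f, 3),
            "dispersion_p": disp.p,
        }

    if cfg.run_comparative and chem_dm is not None:
        geo = comparative.geographic_distance_matrix(samples)
        colour = comparative.colour_distance_matrix(samples)
        battery = comparative.mantel_battery(
            genetic_dm, chem_dm, geo, colour,
            n_perm=cfg.n_perm_mantel, seed=int(rng.integers(2**31 - 1)),
        )
        io.write_stats_tsv(battery, outdir / "mantel_tests.tsv", seed=cfg.seed,
                           parameters={"n_perm": cfg.n_perm_mantel})
        pi = popgen.mean_pi_over_loci(list(alignments.values()), group_of)
        sizes = samples.data.groupby("geo_group").size().to_dict()
        try:
            reg = comparative.diversity_variability_regression(
                pi, variability.to_dict(), sizes
            )
            report["stages"]["comparative"] = {
                "regression_slope": reg.slope,
                "regression_p": reg.p_slope,
                "mantel": {
                    row["test"]: round(row["r"], 4) for _, row in battery.iterrows()
                },
            }
        except ValueError as exc:
            report["stages"]["comparative"] = {"regression_error": str(exc)}

    (outdir / "manifest.json").write_text(json.dumps(report, indent=2, default=str))
    return report
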