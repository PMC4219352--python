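# phylochem

Comparative phylogeography meets chemical ecology: this package analyses
how glacial-refugium history structures both the genes and the courtship
signals of a widespread species. It was built around the classic
European-bumblebee setting — multi-locus sequence data and male marking
secretion (MMS) profiles collected across the continent — but every stage
works on any dataset with the same shape: per-locus FASTA alignments, a
sample table (site, coordinates, geographic group, colour pattern), and a
samples × compounds relative-amount matrix.

It is aimed at population geneticists and chemical ecologists who want the
whole battery in one reproducible pipeline rather than a chain of GUI
tools (Arlequin, SAMOVA, Network, MATLAB cartography, assorted R scripts).

## What it computes

**Genetic structure.** Haplotype collapsing; Nei's unbiased h and π with
pairwise deletion; parsimony-informative site counts; multi-locus averaged
p-distances; AMOVA fixation indices from squared mismatch distances,

  Φ_CT = σ²_a / σ²_T,  Φ_SC = σ²_b / (σ²_b + σ²_c),  Φ_ST = (σ²_a + σ²_b) / σ²_T,

with permutation p-values; and SAMOVA — simulated annealing over
Delaunay-contiguous K-group partitions of sites maximizing Φ_CT.

**Haplotype relationships.** Median-joining networks under a weighted
Hamming distance (transversions × 2), with inferred median vectors; and
neighbour-joining trees with site-resampling bootstrap support.

**Landscape surfaces.** The connectivity-network cartography: mean
inter-individual distance at Delaunay edge midpoints, optional
residualization on great-circle distance, and inverse-distance-weighted
(1/d², by default) interpolation to a grid; diversity/variability surfaces
from per-group values at group barycenters.

**Chemometrics.** 0.1% compound filter, log10(x+1) + standardization,
Bray–Curtis distances, non-metric MDS (Kruskal stress-1, 50 starts),
perMANOVA pseudo-F with permutation p, multivariate dispersion
(betadisper-style, with the per-group mean distance-to-centroid as "MMS
variability"), and IndVal indicator-compound analysis.

**Comparative layer.** Haversine geographic and binary colour-pattern
distances; six Mantel and three partial Mantel tests; and a Gaussian GLM
of per-group chemical variability on genetic diversity.

**Synthetic data.** `phylochem.simulate` generates refugial worlds —
lineage-structured haplotypes with narrow contact zones, compositional
chemistry with lineage-diagnostic switch compounds and a tunable
genetic–chemical coupling ρ, partially concordant colour labels — with a
full truth record, so the entire pipeline is testable offline.

## Worked example

```python
import phylochem as pc
from phylochem.amova import mismatch_matrix

ds = pc.simulate_dataset(pc.SimulationConfig(n_sites=18, n_individuals=90), seed=42)
aln = ds.alignments["locusA"]
hap = pc.collapse_haplotypes(aln)
print(f"locusA: {aln.n_samples} sequences, {hap.n_haplotypes} haplotypes,"
      f" {pc.count_parsimony_informative(aln)} parsimony-informative sites")

dm = mismatch_matrix(aln)
phi, p = pc.global_phi_st(dm, ds.truth.site_of_sample, n_perm=999, seed=0)
print(f"global Phi_ST = {phi:.2f} (p = {p:.3f})")

part = pc.samova(dm, ds.truth.site_of_sample, ds.samples.site_coords(), K=3,
                 n_reps=5, n_steps=1000, seed=0)
print(f"SAMOVA K=3: Phi_CT = {part.phi_ct:.2f}, Phi_ST = {part.phi_st:.2f},"
      f" Phi_SC = {part.phi_sc:.2f}")

chem_dm = pc.chemometrics.chemical_pipeline_distances(ds.chem)
groups = {s: "G1" if ds.truth.lineage_of_sample[s] == 0 else "G2"
          for s in chem_dm.labels}
res = pc.permanova(chem_dm, groups, n_perm=999, seed=0)
print(f"perMANOVA (lineage 1 vs rest): F = {res.f:.2f}, df = {res.df_between},"
      f" p = {res.p:.3f}")

gen = pc.pairwise_p_distance(list(ds.alignments.values()))
m = pc.mantel(gen, chem_dm, n_perm=999, seed=0)
print(f"Mantel genetic vs chemical: r = {m.r:.2f} (p = {m.p:.3f})")
```

Output:

```
locusA: 90 sequences, 34 haplotypes, 18 parsimony-informative sites
global Phi_ST = 0.91 (p = 0.001)
SAMOVA K=3: Phi_CT = 0.94, Phi_ST = 0.94, Phi_SC = 0.01
perMANOVA (lineage 1 vs rest): F = 22.03, df = 1, p = 0.001
Mantel genetic vs chemical: r = 0.83 (p = 0.001)
```

Read: sites are almost perfectly sorted into the three simulated refugial
lineages (Φ_CT 0.94, recovered at the true K), the secretion profiles
split the first lineage from the rest (F = 22, p ≈ 0.001), and genetic and
chemical divergence are tightly coupled (Mantel r = 0.83) — the pattern
the method battery is designed to detect.

## Analysis scripts

The `analysis/` directory holds numbered drivers that run the pipeline
stage by stage on a simulated study and write their tables and grids under
`results/`:

    01_simulate_study.py      generate the synthetic study and write its inputs
    02_diversity.py           per-group h, π, haplotype counts per locus
    03_structure.py           global Φ_ST gate + SAMOVA K-scan
    04_networks_tree.py       median-joining networks and NJ bootstrap tree
    05_landscape.py           genetic distance/diversity surfaces
    06_chemometrics.py        filter → nMDS → perMANOVA → IndVal → dispersion
    07_comparative.py         Mantel battery and the diversity regression

`phylochem.pipeline.run_pipeline` executes the same stages in one call
from a `PipelineConfig` (YAML-loadable), writing a manifest sufficient to
re-run identically.

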