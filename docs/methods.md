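# Methods

`phylochem` implements a comparative phylogeography workflow for a
European-scale survey of a single species: population-genetic structure
from multi-locus sequence data, spatial clustering of sampling sites,
landscape interpolation of genetic and chemical pattern, compositional
chemometrics of male marking secretions (MMS), and a Mantel-based layer
correlating the genetic, chemical, colour-pattern and geographic distance
structures. This note records the models, the parameter choices that
matter, and what the synthetic data generator does and does not emulate.

## Genetic statistics

Haplotypes are exact sequence matches per locus (the target alignments
require no indel-aware collapsing). Haplotype diversity uses Nei's
unbiased estimator h = n(1 − Σp²)/(n − 1); nucleotide diversity π is the
mean pairwise proportion of differing sites, with pairwise deletion of
sites carrying N or a gap in either member of a pair (the DnaSP-style
default). A site is parsimony-informative when at least two states each
occur in at least two sequences, gaps and N excluded as states.

Inter-individual genetic distance is the p-distance per locus (mismatches
over compared sites, pairwise deletion) averaged unweighted over the loci
in which both individuals were sequenced. Pairs sharing no locus are
reported as missing, never silently imputed.

The strict molecular clock converts percent divergence to time by exact
division (default 2% per million years, the usual insect mitochondrial
rate). Note that exact division maps 9.68% to 4.84 Mya; a published figure
of "~4.9 Mya" for that divergence is a rounding in the source literature
that this package intentionally does not reproduce.

## AMOVA and SAMOVA

Molecular variance is decomposed from squared inter-individual distances;
the squared distance is the raw pairwise mismatch count (the Arlequin
convention). The two-level design (individuals in populations in groups)
uses the standard n-coefficients; variance components may be negative and
are never clamped, so Φ_SC < 0 is reportable. Permutation schemes:
individuals among populations (global Φ_ST); individuals among populations
within groups (Φ_SC); whole populations among groups (Φ_CT); individuals
anywhere (two-level Φ_ST). p-values use the +1/(N+1) correction. Default
10,000 permutations (configurable to 100,000); Φ statistics are rounded to
two decimals in summaries.

SAMOVA searches for the K-group partition of sites maximizing Φ_CT by
simulated annealing over single-site reassignments. Contiguity is enforced
on the Delaunay triangulation of site coordinates (the same connectivity
network the cartography uses): a move must keep the source group connected
and non-empty, and the target group must be a Delaunay neighbour. The
annealing schedule is geometric; the initial temperature is set from the
mean |ΔΦ_CT| of sampled moves so that a typical uphill-or-downhill move is
accepted with probability ≈ 0.8, cooling to 10⁻³ of that value over the
configured steps. Defaults are 10 repetitions of 10,000 steps; the tests
and driver scripts use 2–5 repetitions of a few hundred to a few thousand
steps, which already attain the exhaustive-search optimum on the problem
sizes they run. K values whose best partition contains single-site groups
are flagged, not dropped. Loci are gated into SAMOVA by a significant
global Φ_ST (α = 0.01 by default, with a configurable Φ_ST floor); gated
loci are flagged and excluded by default but never deleted.

## Haplotype networks and trees

The median-joining network iterates: build the minimum spanning network
(every link belonging to at least one minimum spanning tree) under a
weighted Hamming distance — transitions 1, transversions 2 by default,
indels costed as transversions — then add the consensus ("median") vector
of triplets of current nodes whenever its inclusion strictly shortens the
spanning length (epsilon = 0, the common software default), pruning
medians that become redundant, until convergence. Median sites with a
majority state take it; three-way ties resolve toward the state minimizing
added weighted length, then lexicographically. One network is built per
locus. Median vectors carry zero observed frequency.

Neighbour joining follows Saitou–Nei with a deterministic tie-break
(lowest label indices). Negative branch lengths are clamped to zero with
the deficit moved to the sister branch, preserving the joined pair's path
length. Bootstrap support resamples alignment columns with replacement
within each locus and reports the percentage of replicate trees containing
each internal bipartition of the point estimate.

## Landscape surfaces

Distance cartography: mean inter-individual distance per Delaunay edge is
placed at the edge midpoint; optionally the linear trend on great-circle
inter-site distance is removed first (ordinary least squares; residual
surfaces are the default because genetic and geographic distance are
correlated). Inverse-distance-weighted interpolation with weight 1/dᵃ,
a = 2, spreads midpoint values over a regular grid (default 150 columns,
5% bounding-box margin). Diversity/variability surfaces interpolate
per-group values placed at the barycenter of each geographic group's
sampling places. Planar geometry (triangulation, IDW) is computed on an
equirectangular projection about the mean latitude; great-circle distance
is used only as the regression predictor. Cells outside the convex hull of
the sites are masked by default so the surface never extrapolates;
duplicate site coordinates are jittered by ~10⁻⁶ degrees; a grid node
within 10⁻⁹ degrees of a data point takes that point's value exactly.

## Chemometrics

Compounds whose relative amount never reaches 0.1% in any sample are
discarded (boundary inclusive); rows are not renormalized afterwards, so
the filtered matrix remains on the original percent scale. The abundance
transform is log10(x + 1) followed by per-compound standardization to mean
0 and sample-sd 1. (A "log(x − 1)" transform is arithmetically impossible
for relative amounts at or below 1%; log10(x + 1) is the standard
compositional-chemistry choice and is used throughout.) Bray–Curtis
distances are computed on the standardized matrix after shifting it by its
global minimum so the coefficient is defined; computing Bray–Curtis
directly on the untransformed relative amounts is available as
`mode="raw"` — which preprocessing a published analysis used is often
underdetermined, so both routes are exposed and reported.

Ordination is non-metric MDS (Kruskal stress-1, isotonic regression inside
majorization), best of 50 random starts, three dimensions by default.
perMANOVA computes the pseudo-F from the distance decomposition
(SS_total = Σd²/N; within-group SS analogously) with free label
permutation and Bonferroni-adjusted pairwise tests when more than two
groups are compared. The dispersion test embeds the distance matrix by
principal coordinates with the imaginary-axis correction for negative
eigenvalues, measures each sample's distance to its group centroid,
and compares the ANOVA F on those distances against a permutation
distribution in which group labels are shuffled and centroids recomputed;
the per-group mean distance is the "variability" statistic carried into
the cartography and the regression. (A correlation-matrix variant of the
dispersion embedding exists in some published descriptions; the
Bray–Curtis/PCoA route is the primary one here.) IndVal is specificity ×
fidelity × 100 on the untransformed filtered amounts, presence strictly
> 0, with a max-group randomization p per compound at α = 0.05.

## Comparative layer

Geographic distances are great-circle kilometres on a 6371-km sphere.
Colour distance is binary: 0 for a shared colour pattern, 1 otherwise.
Mantel r is the Pearson correlation of upper-triangle entries; p permutes
rows and columns of the second matrix simultaneously, one-tailed upper by
default (the associations under test are positive; a two-tailed flag
exists). The partial Mantel statistic is the first-order partial
correlation; its permutation distribution permutes the residual matrix of
A on C against the residuals of B on C. The diversity–variability model is
a Gaussian-identity GLM (equivalently OLS) of per-group MMS variability on
per-group π averaged over loci, with single-sample groups excluded.

## Synthetic data generator

The generator emulates a refugial survey: K refugia (default three, in a
southern-peninsula / south-eastern / central-northern layout within a
European-style bounding box), ~40 sites scattered around them
(Gaussian scatter, sd 4°), ~250 individuals spread evenly over sites.
Lineage membership of a site is pure outside a contact band and blends
linearly inside it; the band half-width default of 1° was calibrated once
so the simulated global Φ_ST at the main mitochondrial-like locus matches
the strong structure (~0.87) reported for the study system, with contact
confined to narrow zones. Sequences follow a star phylogeny within each
lineage: a shared root, lineage ancestors separated by a fixed number of
substitutions at disjoint sites, and private Poisson mutations per
individual (transition:transversion 2:1 so transversion weighting is
exercised). This keeps pairwise-divergence expectations closed-form:
E[p-distance] = (2·scale)/L within and (2·divergence + 2·scale)/L between
lineages. Individuals outside refugia mutate at a reduced rate (default
×0.3), emulating the diversity loss of post-glacial recolonization.

Chemical profiles mix a lineage mean with the grand mean in proportion to
the coupling parameter ρ (default 0.6), add multiplicative lognormal noise
(σ = 0.35), and renormalize to 100%. One diagnostic compound per lineage
is present only in that lineage — the qualitative switch the real
secretion data show between southern and other populations. Colour labels
agree with lineage with probability 0.9. The truth record retains every
latent assignment; note that the *recoverable* site partition is the
realized majority lineage among sampled individuals, which can differ from
the latent membership argmax at thinly sampled contact sites.

What the generator does not emulate: coalescent genealogies (no shared
polymorphism or incomplete lineage sorting), recombination, migration
beyond contact-band mixing, compound co-occurrence structure, or
measurement error in coordinates. Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of planted
structure, not robustness to every feature of real survey data.

## Problem sizes and determinism

The test suite and the acceptance script run scaled-down studies (10–20
sites, 50–90 individuals, one or two loci of 300–1000 bp) chosen so each
stochastic property is measured over ≥ 20 replicates; the full-scale
default (40 sites / 250 individuals / four loci) is exercised end-to-end
by the acceptance script and the driver scripts. All stochastic routines
take explicit seeds; a pipeline run with a fixed seed is byte-identical,
and every output table embeds its seed and parameters.
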