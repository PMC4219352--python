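"""Generate the synthetic refugial study and persist its input files.

Writes per-locus FASTA alignments, the sample table and the chemical
matrix under results/study_inputs/, together with the latent truth
(lineage assignments, refugium layout) used by later sanity checks.
"""

from common import INPUTS, ensure_inputs

alignments, samples, chem, truth = ensure_inputs()

print(f"wrote study inputs to {INPUTS}")
print(f"  loci: {', '.join(f'{l} ({a.length} bp)' for l, a in alignments.items())}")
print(f"  {len(samples.sample_ids)} individuals over {len(samples.site_coords())} sites,"
      f" {len(set(samples.data['geo_group']))} geographic groups")
print(f"  chemistry: {len(chem.sample_ids)} x {len(chem.compound_ids)} relative amounts")
lineages = set(truth["lineage_of_sample"].values())
print(f"  {len(lineages)} simulated lineages; refugia at {truth['refugia']}")
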