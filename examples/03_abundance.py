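"""Genome-size-normalized relative DNA/mRNA abundance per MAG.

Draws 1e6 DNA and 1e6 mRNA reads from the default community and checks
that size normalization recovers the configured abundances.
"""

from metaregulon import (MagStats, abundance_table, default_community_spec,
                         generate_genomes, simulate_counts)

community = generate_genomes(default_community_spec(), seed=1)
dna_df, mrna_df = simulate_counts(community, seed=2)

gene_to_mag = {g.gene_id: m for m, a in community.annotations.items() for g in a.genes}
mrna_by_mag = mrna_df["mrna_reads"].groupby(mrna_df.index.map(gene_to_mag)).sum()
stats = [MagStats(m, community.annotations[m].genome_size_bp,
                  int(dna_df.loc[m, "dna_reads"]), int(mrna_by_mag[m]))
         for m in community.annotations]

table = abundance_table(stats)
table["true_dna"] = [community.truth.relative_dna[m] for m in table.index]
table["true_mrna"] = [community.truth.relative_mrna[m] for m in table.index]
print(table.round(4).to_string())

# relative_dna and relative_mrna divide each MAG's reads by its genome
# size before normalizing, so they estimate cell-proportional
# abundance.  activity_ratio >> 1 flags members contributing far more
# transcription than their population share.
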