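# metaregulon

Regulon inference across the genomes of a microbial community.

Mixed microbial communities — here modeled on a nitrogen-removal
bioreactor community of metagenome-assembled genomes (MAGs) — respond
to environmental cycling through transcription factors (TFs) of the
CRP/FNR family, which sense oxygen, nitric oxide and carbon signals.
`metaregulon` implements the computational core of a community-wide
("meta-regulon") analysis for users with assembled, annotated MAGs plus
DNA/mRNA read counts:

1. **Binding-site prediction.** For each TF, a position weight matrix
   (PWM) is built from aligned known sites,
   `w[b,i] = ln(f[b,i] / q_b)` with pseudocounted frequencies `f` and
   background `q`. Every window of the 300 bp upstream of each gene is
   scored additively on both strands; windows with score ≥ 4.5 are
   candidate sites, and a second stage retains only hits scoring
   strictly above `mean + 2·SD` of all candidate scores for that TF in
   that MAG. Retained hits define the predicted regulon (optionally
   expanded to whole operons).
2. **TF homolog classification.** CRP/FNR-family candidates are found
   by whole-token descriptor search of product annotations, then
   classified by residue conservation: FNR requires ≥ 4 cysteines (the
   4Fe–4S ligands), DNR a histidine aligned to reference position 139,
   NnrR a tyrosine at reference position 93, CRP/MalR sufficient
   identity over a reference effector-binding domain. Positions are
   transferred through Needleman–Wunsch global alignments; a
   neighbor-joining tree of candidates and references is built from
   alignment-identity distances.
3. **Abundance.** Per MAG, relative DNA and mRNA abundance
   `rel_i = (reads_i / genome_size_i) / Σ_j (reads_j / genome_size_j)`,
   plus per-gene RPKM — exposing members whose transcriptional
   activity is disproportionate to their population size.
4. **Expression clustering.** Regulon-gene time courses (replicates
   averaged, per-gene z-standardized) are clustered with a
   Dirichlet-process mixture of Gaussian processes: each cluster is a
   latent squared-exponential GP trajectory, inference is collapsed
   Gibbs sampling, and the reported partition is the least-squares
   consensus of the posterior similarity matrix.
5. **Synthetic communities.** A generator emits multi-MAG communities
   (FASTA/GFF3/protein FASTA/TSV) with planted binding sites, known
   abundances (including an extreme DNA/mRNA disconnect member), and
   known expression clusters, so the whole pipeline is testable
   against ground truth with no downloads.

## Worked example

```bash
python examples/01_scan_promoters.py
```

```
FNR PWM: width 15, 21.4 bits
threshold-passing hits: 122
retention cutoff (mean + 2 SD): 15.17
retained regulon genes: 14 (11/12 planted sites recovered)
```

One synthetic MAG (200 kb, 36% GC) carries an FNR site in 12 of its
120 promoters. The scan reports 122 windows at the raw threshold —
mostly marginal composition matches — and the retention rule keeps the
14 genes whose best hit stands clear of that pool, recovering 11 of
the 12 planted sites. The other examples cover community simulation,
abundance (`examples/03_abundance.py` recovers a configured
1.3%-DNA/19.7%-mRNA member to four decimals), expression clustering
(ARI 1.0 against planted clusters), and TF classification (each
simulated homolog lands next to its family reference in the NJ tree).

The same stages are available as a CLI
(`metaregulon simulate|build-pwm|scan|regulon|abundance|cluster|classify-tf|run-all`);
`run-all` drives the whole pipeline from a YAML config and writes BED
hit files, regulon/abundance/cluster TSVs and a JSON run manifest.

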