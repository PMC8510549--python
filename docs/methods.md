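# Methods

## PWM construction and scoring

A TF's binding preference is summarized from an ungapped alignment of
known sites as a position weight matrix of natural-log odds,

    w[b,i] = ln( ((c[b,i] + p·q_b) / (N + p)) / q_b )

with count matrix `c`, `N` sites, total pseudocount `p` (default 1,
distributed across bases in proportion to the background `q` — the
posterior mean under a background-centred Dirichlet prior). A window
scores as the sum of its per-base weights; natural log is the default
base because the raw-score threshold of 4.5 used downstream comes from
that convention. Ambiguous `N` bases contribute the column minimum, so
ambiguity can only lower a score, never create a hit. Information
content per column is `Σ_b f·log2(f/q)` bits (the sequence-logo column
height). Reverse-complement scanning uses the complemented, reversed
matrix; the operation is an involution and preserves the probability
normalization `Σ_b exp(w[b,i])·q_b = 1`.

Backgrounds: uniform by default, or estimated (mononucleotide
frequencies) from the pooled promoter set being scanned. Community
genomes span roughly 36–68% GC, so the choice of background is not
cosmetic; see "Retention statistics" below.

## Promoter extraction and the two-stage retention rule

Promoters are the 300 bp upstream of each annotated CDS start
(truncated at contig edges, never trimmed for overlap with neighboring
genes — both documented conventions, configurable). Both strands are
scanned; every window scoring ≥ 4.5 is reported, overlapping hits
included. A palindromic window (equal to its own reverse complement)
is the same physical site on both strands and is reported once, on the
forward strand.

Retention: for one TF within one MAG, the cutoff is
`mean + k·SD` (k = 2, population SD, strict inequality) over all
threshold-passing scores in that pool. The rule is invariant under
affine rescaling of scores and retains nothing from a degenerate
all-equal pool. Sample-SD and k are flags; defaults follow the
population-SD, strict-greater reading.

### Retention statistics and the synthetic fixture

The retention rule presumes a large pool of marginal hits whose bulk
fixes the mean and SD, with genuine sites in the far tail. Under a
background matched to the scanned sequence, the identity
`E_q[exp(score)] = 1` bounds the background hit rate at threshold t by
`exp(-t)` (≈1.1% at 4.5), and for informative motifs (≥ 10 bits) the
realized pool is far smaller — small enough that the planted sites
themselves dominate the pool statistics and push the cutoff into their
own score band. Pools of the size the rule needs arise when motif
composition and genome composition diverge from the scoring
background: AT-rich boxes (like FNR's) scanned with a uniform
background across AT-rich genomes, and vice versa.

The default synthetic community is calibrated — once, then frozen — to
put the rule in that operating regime: five MAGs with GC at the ends
of the observed community range ({0.36, 0.36, 0.64, 0.66, 0.66}), one
TF per MAG whose bundled synthetic motif (15–16 bp, 21–23 bits,
two-base degenerate plus unanimous columns, arrangements chosen to
minimize reverse-complement self-similarity) is composition-matched to
its host genome, 400 genes per MAG, sites planted in 10% of promoters
by sampling from the PWM's pseudocounted column distributions. Under
these conditions retained-gene recall and precision against the
planted truth are ≈ 0.84–0.88 across seeds. A MAG at ~50% GC scanned
with a matched background yields a pool of a dozen hits and near-zero
recall — a genuine property of the mean+2·SD statistic, not an
implementation artifact, and the reason mid-GC members are absent from
the default fixture.

## Abundance

`rel_i = (reads_i/size_i) / Σ_j (reads_j/size_j)` per channel (DNA,
mRNA): read density per base, normalized community-wide, i.e. an
estimate of cell-proportional abundance. The mRNA/DNA ratio
(activity ratio) is reported descriptively and never thresholded.
RPKM uses `count / ((length/1e3)·(library/1e6))` with the library size
defaulting to the per-sample total over MAG genes. The simulator draws
both channels multinomially with MAG-level probabilities proportional
to (true abundance × genome size), so the pipeline's size
normalization is exactly what recovers the configured truth; at 1e6
reads the recovery error is within ±0.01 (multinomial sampling error).

## DP-GP expression clustering

Model: each cluster c has a latent function `f_c ~ GP(0, K_SE)` on the
sampling times (default 3, 7, 13, 27 min); member trajectories are
`f_c + ε`, `ε ~ N(0, σ_n² I)`. The partition prior is a Chinese
restaurant process with concentration α. Defaults: α = 1, σ_f² = 1 and
σ_n² = 0.1 (standardized units), length-scale = half the time span,
500 Gibbs sweeps with 250 burn-in. Hyperparameters are fixed rather
than optimized per sweep — a deliberate divergence from tools that
marginal-likelihood-optimize them, keeping runs deterministic given
the seed; the kernel is configurable.

Preparation: replicates (3 per phase × 2 phases by default) are
averaged per time point, genes missing any time point are dropped,
each gene is z-standardized (constant genes dropped with a warning).
A flag keeps replicates as repeated observations for the GP likelihood
instead of averaging.

Inference: collapsed Gibbs over gene assignments. The GP latent is
integrated analytically — a cluster with n members summing to s has
latent posterior `N(A_n s/σ_n², A_n)`, `A_n = (K⁻¹ + n/σ_n² I)⁻¹`, so
a gene's predictive under a cluster is Gaussian and is cached by n
(all genes share the time design). Sweeps visit genes in lexicographic
id order, making results invariant to input row order. Post-burn-in
partitions accumulate a posterior similarity matrix; the reported
partition is the sampled one minimizing squared distance to that
matrix (MAP-partition option available). Cluster summaries are the
member mean and ±2·SD band per time point, plus individual member
trajectories.

On synthetic data with K ∈ {2,3,4} shape-distinct trajectories
(separations ≥ 3 noise SD), recovery is ARI 1.0 over 10 seeds per K at
desk scale (8 genes per cluster); identical inputs collapse to one
cluster.

## TF classification

Candidates are proteins whose product annotation contains a family
descriptor as a whole token (so "CRISPR" never matches "CRP").
Rules, in priority order FNR > DNR > NnrR > CRP > MalR (structural
residue rules outrank identity rules; configurable):

- FNR: ≥ 4 cysteines (4Fe–4S cluster ligands).
- DNR: His aligned to position 139 of the DNR reference (heme).
- NnrR: Tyr aligned to position 93 of the NnrR reference.
- CRP / MalR: ≥ 30% identity (configurable) over the reference
  effector-binding-domain interval.

Reference positions are transferred through global Needleman–Wunsch
alignments (BLOSUM62, gap open −10, extend −0.5; the aligner's
canonical first alignment gives deterministic tie-breaking).
Position rules additionally require ≥ 20% overall alignment identity —
a conserved-position claim read off an incredible alignment is noise,
and without the gate unrelated sequences pass position rules by chance
at an appreciable rate. The bundled reference proteins are synthetic
stand-ins (constructed to satisfy their family rules; filenames and
headers say so); real reference sequences can be passed anywhere a
reference is accepted.

The NJ tree uses `d = 1 − fractional identity` from the same global
alignments, with deterministic lexicographic tie-breaking in the Q
criterion and unclamped branch lengths; on an additive matrix it
reproduces topology and branch lengths exactly.

## Synthetic data: what it does and does not emulate

The generator produces iid-background genomes at specified GC,
non-overlapping genes on both strands with ≥ 300 bp intergenic
spacing, planted sites sampled from the PWM (uniform strand, uniform
offset, re-sampled on within-promoter collision,
`floor(fraction·n_genes)` genes per MAG), multinomial count tables,
and Gaussian replicate noise around K true cluster trajectories. Its
TF proteins are mutated copies (10% substitutions, rule residues
protected) of the bundled references.

Real data differ in ways the synthetic conditions deliberately ignore:
genomes are not iid (codon structure, repeats, skews), promoters
overlap genes and share regulatory grammar, binding sites co-occur and
overlap, counts are overdispersed relative to multinomial, and
expression noise is not iid Gaussian. Passing the recovery suite
demonstrates the statistical machinery is correct under its stated
model, not that the thresholds transfer to any particular community.
Genome sizes (hundreds of kb) and library sizes (1e6) are desk-scale
choices; planted-site statistics depend on promoter count and motif
information content, not genome length.

## Numerical choices

Kernel matrices get 1e-10–1e-12 jitter before Cholesky; a covariance
that fails after jitter raises with diagnostics. Probability
normalization of PWMs is enforced to 1e-6 on construction; MEME round
trips preserve 6-decimal probabilities (hard zeros become −inf
weights, i.e. strictly forbidden bases). Degenerate cases are defined,
not errors: empty hit pools give an undefined-cutoff prediction,
all-equal score pools retain nothing, constant expression rows are
dropped with a warning. BED output stores raw float scores (documented
dialect) because integer rescaling would destroy the retention
statistic's inputs. All randomness flows through
`numpy.random.default_rng` seeds; identical inputs and seeds give
byte-identical outputs.
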