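"""Synthetic microbial communities with known regulatory ground truth.

The generator emulates the shape of a mixed-community regulon study so
every pipeline stage can be exercised against a known answer:

* several MAGs spanning a wide GC range (the real community spans
  roughly 36-68% GC), each with non-overlapping genes on both strands;
* TF binding sites sampled from a PWM and planted into the 300-bp
  upstream windows of a chosen fraction of genes;
* community DNA and mRNA read counts drawn multinomially so that
  genome-size normalization recovers the configured relative
  abundances, including a deliberate abundance/expression disconnect
  (e.g. a member at 1.3% of the DNA but 19.7% of the mRNA);
* 4-time-point (3, 7, 13, 27 min) expression series in triplicate over
  two phases, with regulon genes split across K true trajectory
  clusters plus Gaussian noise.

Genomes default to a few hundred kb rather than full MAG size, keeping
whole-community runs fast; the planted-site statistics are governed by
promoter count and motif information content, not genome length.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio
from .io import GeneRecord, GenomeAnnotation
from .motif import (BASES, Background, Pwm, SiteAlignment, build_pwm,
                    bundled_site_alignment, reverse_complement, BUNDLED_TFS)
from .classify import ProteinRecord, load_reference_proteins

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MagSpec:
    """Parameters of one synthetic MAG."""

    mag_id: str
    genome_size_bp: int = 200_000
    gc_content: float = 0.5
    n_genes: int = 150
    gene_len_mean: float = 900.0
    gene_len_sd: float = 200.0
    tf_name: str = "FNR"
    planted_fraction: float = 0.1
    relative_dna: float = 0.2
    relative_mrna: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError(f"{self.mag_id}: gc_content must be in (0,1)")
        if not (0 <= self.planted_fraction <= 1):
            raise ValueError(f"{self.mag_id}: planted_fraction must be in [0,1]")


@dataclass
class CommunitySpec:
    """Parameters of the whole synthetic community."""

    mags: list[MagSpec]
    window_bp: int = 300
    dna_library: int = 1_000_000
    mrna_library: int = 1_000_000
    times: tuple = (3.0, 7.0, 13.0, 27.0)
    n_replicates: int = 3
    n_phases: int = 2
    cluster_means: np.ndarray | None = None  # K x len(times); None = 2 defaults
    noise_sd: float = 0.15
    regulon_expression_boost: float = 5.0  # expression weight of regulon genes vs baseline 1

    def __post_init__(self) -> None:
        for tot, name in ((sum(m.relative_dna for m in self.mags), "relative_dna"),
                          (sum(m.relative_mrna for m in self.mags), "relative_mrna")):
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"true {name} values sum to {tot}, not 1")
        if self.cluster_means is None:
            t = np.asarray(self.times, float)
            u = (t - t.min()) / (t.max() - t.min())
            self.cluster_means = np.vstack([2.0 * u - 1.0, 1.0 - 2.0 * u])  # rise vs fall
        self.cluster_means = np.asarray(self.cluster_means, float)
        if self.cluster_means.shape[1] != len(self.times):
            raise ValueError("cluster_means must have one column per time point")


@dataclass
class PlantedSite:
    mag_id: str
    gene_id: str
    tf_name: str
    offset: int      # within the oriented promoter window
    strand: str      # relative to the promoter orientation
    site_seq: str    # as written on the promoter strand


@dataclass
class CommunityTruth:
    """Everything the generator knows that the pipeline must recover."""

    planted_sites: list[PlantedSite] = field(default_factory=list)
    regulons: dict = field(default_factory=dict)        # (tf, mag) -> set of gene ids
    cluster_assignment: dict = field(default_factory=dict)  # gene -> 1-based cluster
    relative_dna: dict = field(default_factory=dict)
    relative_mrna: dict = field(default_factory=dict)


@dataclass
class Community:
    spec: CommunitySpec
    annotations: dict[str, GenomeAnnotation]
    proteins: dict[str, list[ProteinRecord]]
    pwms: dict[str, Pwm]
    truth: CommunityTruth


def default_community_spec(n_mags: int = 5, planted_fraction: float = 0.1) -> CommunitySpec:
    """A community mirroring the study's shape: 5 MAGs with GC at the
    ends of the observed community range (36-66%), one CRP/FNR-family
    TF per MAG with motif composition matched to its host genome
    (AT-rich boxes in AT-rich genomes, GC-rich in GC-rich), and an
    abundance/expression disconnect member at (1.3% DNA, 19.7% mRNA).

    The compositional pairing is what gives each TF a large pool of
    marginal promoter matches under a uniform scanning background; the
    mean + 2 SD retention statistic needs that pool to behave as
    intended (see the methods note)."""
    gcs = [0.36, 0.36, 0.64, 0.66, 0.66][:n_mags]
    tfs = ["FNR", "CRP", "DNR", "NnrR", "MalR"][:n_mags]
    rel_dna = np.array([0.013, 0.32, 0.25, 0.217, 0.20][:n_mags])
    rel_mrna = np.array([0.197, 0.40, 0.15, 0.153, 0.10][:n_mags])
    rel_dna /= rel_dna.sum()
    rel_mrna /= rel_mrna.sum()
    mags = [
        MagSpec(
            mag_id=f"MAG_{i + 1:02d}",
            genome_size_bp=620_000,
            gc_content=gcs[i],
            n_genes=400,
            tf_name=tfs[i],
            planted_fraction=planted_fraction,
            relative_dna=float(rel_dna[i]),
            relative_mrna=float(rel_mrna[i]),
        )
        for i in range(n_mags)
    ]
    return CommunitySpec(mags=mags)


def default_cluster_means(k: int, times=(3.0, 7.0, 13.0, 27.0)) -> np.ndarray:
    """K distinct trajectory shapes on the sampling grid.

    rise, fall, transient peak, transient dip — the qualitative shapes
    a two-phase on/off perturbation produces.  Unit amplitude, so with
    the default noise SD 0.15 the shapes are separated by far more than
    3 noise SDs at their most divergent time points.
    """
    t = np.asarray(times, float)
    u = (t - t.min()) / (t.max() - t.min())
    shapes = [
        2.0 * u - 1.0,                  # monotone rise
        1.0 - 2.0 * u,                  # monotone fall
        1.0 - 2.0 * np.abs(2 * u - 1),  # peak at mid-series
        2.0 * np.abs(2 * u - 1) - 1.0,  # dip at mid-series
    ]
    if not (1 <= k <= len(shapes)):
        raise ValueError(f"k must be 1..{len(shapes)}")
    return np.vstack(shapes[:k])


def _sample_site(pwm: Pwm, rng: np.random.Generator) -> str:
    probs = pwm.probabilities()
    return "".join(BASES[rng.choice(4, p=probs[:, i] / probs[:, i].sum())]
                   for i in range(pwm.width))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _mutated_reference(ref_seq: str, rng: np.random.Generator, rate: float = 0.1) -> str:
    """A TF protein derived from a reference by random substitutions at
    ~`rate` of positions, leaving rule-bearing residues (C, H139, Y93)
    untouched so the family call survives."""
    protected = {92, 138}
    benign = [a for a in _AA if a not in "CHY"]  # never create rule residues
    seq = list(ref_seq)
    for i in range(len(seq)):
        if i in protected or seq[i] == "C":
            continue
        if rng.random() < rate:
            seq[i] = rng.choice([a for a in benign if a != seq[i]])
    return "".join(seq)


_TF_PRODUCTS = {
    "FNR": "Fumarate and nitrate reduction regulatory protein FNR",
    "CRP": "cAMP receptor protein CRP",
    "DNR": "Dissimilatory nitrate respiration regulator DNR",
    "NnrR": "Nitrite and nitric oxide reductase regulator NnrR",
    "MalR": "Maltose regulon regulatory protein MalR",
}


def generate_genomes(spec: CommunitySpec, seed: int) -> Community:
    """Generate genomes, annotations, proteins, PWMs and ground truth.

    Background DNA is iid at each MAG's GC; genes are laid out without
    overlap with >= window_bp intergenic spacing so each promoter is
    independent background sequence.  For every TF a site sampled from
    the PWM's pseudocounted column distributions is written into the
    upstream window of each selected gene (strand uniform); sites are
    re-sampled on placement collision.  floor(planted_fraction *
    n_genes) genes are planted per MAG.
    """
    rng = np.random.default_rng(seed)
    pwms = {tf: build_pwm(bundled_site_alignment(tf)) for tf in
            {m.tf_name for m in spec.mags}}
    references = load_reference_proteins()
    truth = CommunityTruth(
        relative_dna={m.mag_id: m.relative_dna for m in spec.mags},
        relative_mrna={m.mag_id: m.relative_mrna for m in spec.mags},
    )
    annotations: dict[str, GenomeAnnotation] = {}
    proteins: dict[str, list[ProteinRecord]] = {}

    for mag in spec.mags:
        # gene layout: window_bp spacing upstream of every gene
        lengths = np.maximum(
            90, rng.normal(mag.gene_len_mean, mag.gene_len_sd, mag.n_genes)
        ).astype(int)
        lengths -= lengths % 3
        needed = int(lengths.sum() + (mag.n_genes + 1) * (spec.window_bp + 50))
        if needed > mag.genome_size_bp:
            raise ValueError(
                f"{mag.mag_id}: {mag.n_genes} genes of mean {mag.gene_len_mean} bp "
                f"plus promoters need ~{needed} bp > genome {mag.genome_size_bp} bp"
            )
        gc = mag.gc_content
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        genome = rng.choice(list(BASES), size=mag.genome_size_bp, p=p)

        genes: list[GeneRecord] = []
        cursor = spec.window_bp + int(rng.integers(0, 50))
        slack = mag.genome_size_bp - needed
        for gi, glen in enumerate(lengths):
            cursor += int(rng.integers(0, max(1, slack // mag.n_genes)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(
                    gene_id=f"{mag.mag_id}_g{gi + 1:04d}",
                    contig_id=f"{mag.mag_id}_c1",
                    start=cursor,
                    end=cursor + int(glen),
                    strand=strand,
                )
            )
            cursor += int(glen) + spec.window_bp + 50

        # plant TF binding sites in floor(fraction * n) promoters
        pwm = pwms[mag.tf_name]
        n_plant = int(np.floor(mag.planted_fraction * mag.n_genes))
        chosen = rng.choice(mag.n_genes, size=n_plant, replace=False)
        regulon: set[str] = set()
        for gi in sorted(chosen):
            g = genes[gi]
            occupied: list[tuple[int, int]] = []
            while True:
                offset = int(rng.integers(0, spec.window_bp - pwm.width + 1))
                if all(offset + pwm.width <= a or offset >= b for a, b in occupied):
                    break
            occupied.append((offset, offset + pwm.width))
            site = _sample_site(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            on_promoter = site if strand == "+" else reverse_complement(site)
            if g.strand == "+":
                gpos = g.start - spec.window_bp + offset
                genome[gpos:gpos + pwm.width] = list(on_promoter)
            else:
                gpos = g.end + spec.window_bp - offset - pwm.width
                genome[gpos:gpos + pwm.width] = list(reverse_complement(on_promoter))
            truth.planted_sites.append(
                PlantedSite(mag_id=mag.mag_id, gene_id=g.gene_id, tf_name=mag.tf_name,
                            offset=offset, strand=strand, site_seq=on_promoter)
            )
            regulon.add(g.gene_id)
        truth.regulons[(mag.tf_name, mag.mag_id)] = regulon

        # proteins: gene 1 is the MAG's TF (mutated copy of the reference)
        prot_list: list[ProteinRecord] = []
        for gi, g in enumerate(genes):
            if gi == 0:
                seq = _mutated_reference(references[f"{mag.tf_name}_ref"].seq, rng)
                product = _TF_PRODUCTS[mag.tf_name]
            else:
                seq = _random_protein(rng, max(30, g.length // 3 - 1))
                product = "hypothetical protein"
            prot_list.append(ProteinRecord(protein_id=g.gene_id, mag_id=mag.mag_id,
                                           seq=seq, product=product))
            g.product = product
        annotations[mag.mag_id] = GenomeAnnotation(
            mag_id=mag.mag_id, contigs={f"{mag.mag_id}_c1": "".join(genome)}, genes=genes
        )
        proteins[mag.mag_id] = prot_list

    return Community(spec=spec, annotations=annotations, proteins=proteins,
                     pwms=pwms, truth=truth)


def simulate_counts(community: Community, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw community DNA and mRNA read counts.

    DNA reads are multinomial over MAGs with probability proportional to
    relative_dna x genome_size, and mRNA reads multinomial over genes
    with per-MAG totals proportional to relative_mrna x genome_size —
    in both channels the size factor is what genome-size normalization
    divides back out, so the pipeline recovers the configured relative
    abundances.  Within a MAG, mRNA probability is proportional to gene
    expression weight x gene length; regulon genes carry a boosted
    weight so they are a controlled subpopulation.

    Returns (mag_dna_counts, gene_mrna_counts) as single-column frames.
    """
    rng = np.random.default_rng(seed)
    spec = community.spec
    mags = spec.mags

    sizes = np.array([community.annotations[m.mag_id].genome_size_bp for m in mags], float)
    p_dna = np.array([m.relative_dna for m in mags]) * sizes
    p_dna /= p_dna.sum()
    dna = rng.multinomial(spec.dna_library, p_dna)
    dna_df = pd.DataFrame({"dna_reads": dna}, index=[m.mag_id for m in mags])

    gene_ids, p_gene = [], []
    for m, size in zip(mags, sizes):
        ann = community.annotations[m.mag_id]
        regulon = community.truth.regulons.get((m.tf_name, m.mag_id), set())
        w = np.array([
            (spec.regulon_expression_boost if g.gene_id in regulon else 1.0) * g.length
            for g in ann.genes
        ])
        w = w / w.sum() * (m.relative_mrna * size)
        gene_ids.extend(g.gene_id for g in ann.genes)
        p_gene.append(w)
    p_gene = np.concatenate(p_gene)
    p_gene /= p_gene.sum()
    mrna = rng.multinomial(spec.mrna_library, p_gene) if spec.mrna_library > 0 else \
        np.zeros(len(gene_ids), dtype=int)
    mrna_df = pd.DataFrame({"mrna_reads": mrna}, index=gene_ids)
    return dna_df, mrna_df


def simulate_expression(community: Community, seed: int) -> tuple[pd.DataFrame, dict[str, int]]:
    """Replicate-resolved expression series for all regulon genes.

    Each regulon gene is assigned to one of the K true clusters
    (round-robin over the deterministic gene order); every replicate
    value is the cluster mean at that time point plus iid Gaussian
    noise, independently for n_replicates x n_phases replicates.

    Returns a long-form frame (gene_id, time, phase, replicate, value)
    and the true cluster assignment (1-based labels).
    """
    rng = np.random.default_rng(seed)
    spec = community.spec
    K = spec.cluster_means.shape[0]
    genes = sorted(g for reg in community.truth.regulons.values() for g in reg)
    assignment = {g: (i % K) + 1 for i, g in enumerate(genes)}
    community.truth.cluster_assignment = assignment

    rows = []
    for g in genes:
        mean = spec.cluster_means[assignment[g] - 1]
        for phase in range(1, spec.n_phases + 1):
            for rep in range(1, spec.n_replicates + 1):
                noise = rng.normal(0.0, spec.noise_sd, size=len(spec.times))
                for t, mu, e in zip(spec.times, mean, noise):
                    rows.append({"gene_id": g, "time": t, "phase": phase,
                                 "replicate": rep, "value": mu + e})
    return pd.DataFrame(rows), assignment


def write_community(community: Community, outdir, seed: int) -> dict[str, str]:
    """Emit the community as the pipeline's on-disk input formats.

    Per MAG: genome FASTA, gene GFF3, protein FASTA.  Community-wide:
    MEME motif file, DNA/mRNA count TSVs, expression series TSV, and
    truth tables (planted sites, regulons, cluster assignment).
    Returns a manifest of the written paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for mag_id, ann in community.annotations.items():
        fa = outdir / f"{mag_id}.fna"
        mio.write_fasta([mio.SequenceRecord(cid, seq) for cid, seq in ann.contigs.items()], fa)
        gff = outdir / f"{mag_id}.gff3"
        mio.write_gff_genes(ann.genes, gff)
        faa = outdir / f"{mag_id}.faa"
        mio.write_fasta(
            [mio.SequenceRecord(p.protein_id, p.seq, p.product)
             for p in community.proteins[mag_id]], faa)
        paths[f"{mag_id}.fna"] = str(fa)
        paths[f"{mag_id}.gff3"] = str(gff)
        paths[f"{mag_id}.faa"] = str(faa)

    motif_path = outdir / "motifs.meme"
    mio.write_motif_meme(list(community.pwms.values()), motif_path)
    paths["motifs.meme"] = str(motif_path)

    dna_df, mrna_df = simulate_counts(community, seed=seed + 1)
    mio.write_count_table(dna_df, outdir / "dna_counts.tsv")
    mio.write_count_table(mrna_df, outdir / "mrna_counts.tsv")
    paths["dna_counts.tsv"] = str(outdir / "dna_counts.tsv")
    paths["mrna_counts.tsv"] = str(outdir / "mrna_counts.tsv")

    series, assignment = simulate_expression(community, seed=seed + 2)
    series.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    paths["expression.tsv"] = str(outdir / "expression.tsv")

    pd.DataFrame(
        [{"mag_id": s.mag_id, "gene_id": s.gene_id, "tf_name": s.tf_name,
          "offset": s.offset, "strand": s.strand, "site_seq": s.site_seq}
         for s in community.truth.planted_sites]
    ).to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "cluster": c} for g, c in assignment.items()]
    ).to_csv(outdir / "truth_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"mag_id": m.mag_id, "relative_dna": m.relative_dna,
          "relative_mrna": m.relative_mrna} for m in community.spec.mags]
    ).to_csv(outdir / "truth_abundance.tsv", sep="\t", index=False)
    paths["truth_sites.tsv"] = str(outdir / "truth_sites.tsv")
    paths["truth_clusters.tsv"] = str(outdir / "truth_clusters.tsv")
    paths["truth_abundance.tsv"] = str(outdir / "truth_abundance.tsv")
    return paths
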