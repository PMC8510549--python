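"""Genome-size-normalized DNA/mRNA abundance per MAG, and RPKM per gene.

Relative abundance divides each MAG's mapped read count by its genome
size before normalizing across the community, so a small genome with
many reads ranks as abundant per cell rather than per base.  Comparing
the DNA and mRNA versions of this quantity exposes members whose
transcriptional activity is out of proportion to their population size
(e.g. a MAG at ~1.3% of the DNA but ~20% of the mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MagStats:
    mag_id: str
    genome_size_bp: int
    dna_reads: int = 0
    mrna_reads: int = 0

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError(f"{self.mag_id}: genome size must be positive")
        if self.dna_reads < 0 or self.mrna_reads < 0:
            raise ValueError(f"{self.mag_id}: read counts must be >= 0")


def relative_abundance(stats: list[MagStats], channel: str) -> pd.Series:
    """Genome-size-normalized relative abundance of each MAG.

    rel_i = (reads_i / size_i) / sum_j (reads_j / size_j)

    ``channel`` is "dna" or "mrna".  Scale-invariant in the read counts.
    """
    if channel not in ("dna", "mrna"):
        raise ValueError("channel must be 'dna' or 'mrna'")
    reads = np.array([s.dna_reads if channel == "dna" else s.mrna_reads for s in stats],
                     dtype=float)
    sizes = np.array([s.genome_size_bp for s in stats], dtype=float)
    density = reads / sizes
    total = density.sum()
    if total == 0:
        raise ValueError(f"all {channel} read counts are zero; fractions undefined")
    return pd.Series(density / total, index=[s.mag_id for s in stats], name=f"relative_{channel}")


def abundance_table(stats: list[MagStats]) -> pd.DataFrame:
    """Per-MAG relative_dna, relative_mrna and their ratio.

    activity_ratio = relative_mrna / relative_dna is reported as a
    descriptive quantity only, never thresholded.
    """
    dna = relative_abundance(stats, "dna")
    mrna = relative_abundance(stats, "mrna")
    df = pd.DataFrame({"relative_dna": dna, "relative_mrna": mrna})
    with np.errstate(divide="ignore", invalid="ignore"):
        df["activity_ratio"] = df["relative_mrna"] / df["relative_dna"]
    return df


def rpkm(gene_counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase of gene per million mapped reads.

    RPKM[g, s] = count[g, s] / ((length_g / 1000) * (lib_s / 1e6))

    ``library_sizes`` defaults to the per-sample column sums of
    ``gene_counts`` (total reads mapped to MAG genes in that sample).
    """
    missing = gene_counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"genes missing a length: {sorted(missing)[:5]}")
    lengths = gene_lengths.loc[gene_counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = gene_counts.sum(axis=0)
    library_sizes = library_sizes.loc[gene_counts.columns].astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return gene_counts.astype(float).div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)
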