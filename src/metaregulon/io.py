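"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  GFF3 (1-based inclusive) is
converted at the boundary on read and write; BED output is natively
0-based half-open, so BED start = GFF start - 1 and BED end = GFF end.

The BED6 dialect used for predicted binding sites stores the raw
natural-log-odds score as a decimal in column 5 instead of the usual
0-1000 integer, because downstream retention statistics need the exact
scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
import gffutils

from .motif import BASES, Background, Pwm

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """A file violated the expected format."""


@dataclass
class SequenceRecord:
    """A named sequence (DNA contig or protein)."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneRecord:
    """A strand-aware gene model on a contig.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """One MAG: contig sequences plus its gene records."""

    mag_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig_id not in self.contigs:
                raise FormatError(
                    f"gene {g.gene_id} references unknown contig {g.contig_id!r}"
                )
            if g.end > len(self.contigs[g.contig_id]):
                raise FormatError(
                    f"gene {g.gene_id} extends past the end of contig {g.contig_id}"
                )

    @property
    def genome_size_bp(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @classmethod
    def from_files(cls, mag_id: str, fasta_path, gff_path, feature_type: str = "CDS") -> "GenomeAnnotation":
        contigs = {r.id: r.seq for r in read_fasta(fasta_path)}
        genes = read_gff_genes(gff_path, feature_type=feature_type)
        return cls(mag_id=mag_id, contigs=contigs, genes=genes)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased.  DNA records are validated against
    {A,C,G,T,N}; set ``alphabet="protein"`` to skip that check.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: record with empty identifier")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if alphabet == "dna":
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r} contains non-DNA characters {sorted(bad)}"
                )
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def read_gff_genes(path, feature_type: str = "CDS") -> list[GeneRecord]:
    """Read gene models of one feature type from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  The ``ID`` attribute becomes
    ``gene_id``; a ``product`` attribute, when present, is carried along.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        if "ID" not in feat.attributes:
            raise FormatError(f"{path}: {feature_type} feature without ID attribute at "
                              f"{feat.seqid}:{feat.start}-{feat.end}")
        if feat.end < feat.start:
            raise FormatError(f"{path}: feature {feat.id} has end < start")
        product = feat.attributes.get("product", [""])[0]
        genes.append(
            GeneRecord(
                gene_id=feat.attributes["ID"][0],
                contig_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                product=product,
            )
        )
    return genes


def write_gff_genes(genes: Sequence[GeneRecord], path, feature_type: str = "CDS",
                    source: str = "metaregulon") -> None:
    """Write gene records as GFF3, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        source,
                        feature_type,
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED (predicted binding sites)


def write_bed_hits(hits, path) -> None:
    """Write site hits as BED6, sorted by contig then start.

    Column 5 carries the raw log-odds score (decimal), a documented
    deviation from the 0-1000 integer convention.
    """
    rows = sorted(hits, key=lambda h: (h.contig_id, h.genomic_start, h.genome_strand))
    with open(path, "w") as fh:
        fh.write("# BED6 dialect: score column holds raw log-odds (natural log)\n")
        for h in rows:
            fh.write(
                "\t".join(
                    [
                        h.contig_id,
                        str(h.genomic_start),
                        str(h.genomic_start + h.width),
                        f"{h.tf_name}|{h.gene_id}",
                        f"{h.score:.6f}",
                        h.genome_strand,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_motif_meme(path, pseudocount: float = 1.0) -> list[Pwm]:
    """Read PWMs from a MEME minimal motif file.

    MEME stores probability matrices; log-odds weights are recomputed on
    read using the stored background (uniform if the file has none, with
    a logged warning).  Probability rows must sum to 1 within 1e-3.

    The probability matrix is parsed directly from the text so that the
    stored 6-decimal precision survives the round trip.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.startswith("MEME version") for ln in lines):
        raise FormatError(f"{path}: not a MEME minimal motif file (no version line)")

    background = Background(np.full(4, 0.25))
    if any(ln.startswith("Background letter frequencies") for ln in lines):
        i = next(i for i, ln in enumerate(lines)
                 if ln.startswith("Background letter frequencies"))
        tokens = lines[i + 1].split()
        freqs = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
        background = Background(np.array([freqs[b] for b in BASES]))
    else:
        logger.warning("%s: no background line; assuming uniform background", path)

    pwms: list[Pwm] = []
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            name = lines[i].split()[1]
            i += 1
            while i < len(lines) and not lines[i].startswith("letter-probability matrix"):
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {name}: no letter-probability matrix")
            header = dict(
                (k.rstrip("="), v) for k, v in
                zip(lines[i].split()[2::2], lines[i].split()[3::2])
            )
            width = int(header.get("w", 0))
            nsites = int(float(header.get("nsites", 20)))
            rows = []
            for j in range(width):
                vals = lines[i + 1 + j].split()
                if len(vals) != 4:
                    raise FormatError(f"{path}: motif {name}: bad matrix row {j + 1}")
                rows.append([float(v) for v in vals])
            probs = np.array(rows).T  # 4 x width, rows A,C,G,T
            colsums = probs.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > 1e-3):
                raise FormatError(
                    f"{path}: motif {name}: probability columns do not sum to 1 "
                    f"(max deviation {np.max(np.abs(colsums - 1.0)):.2e})"
                )
            pwms.append(
                Pwm.from_probabilities(tf_name=name, probs=probs / colsums,
                                       background=background, nsites=nsites,
                                       pseudocount=pseudocount)
            )
            i += width + 1
        else:
            i += 1
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def write_motif_meme(pwms: Sequence[Pwm], path) -> None:
    """Write PWMs in MEME minimal motif format (probability matrices)."""
    pwms = list(pwms)
    if not pwms:
        raise ValueError("no motifs to write")
    bg = pwms[0].background.freqs
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {q:.6f}" for b, q in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            probs = pwm.probabilities()
            nsites = int(pwm.counts.sum(axis=0)[0]) if pwm.counts is not None else 20
            fh.write(f"MOTIF {pwm.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {nsites} E= 0\n"
            )
            for i in range(pwm.width):
                fh.write(" " + " ".join(f"{probs[b, i]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_count_table(path) -> pd.DataFrame:
    """Read a TSV count table (rows: MAG or gene ids; columns: samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row ids {dupes}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate column ids")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    if not np.allclose(df.values, np.round(df.values)):
        raise FormatError(f"{path}: non-integer counts")
    return df.astype(np.int64)


def write_count_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_operon_table(path) -> dict[str, str]:
    """Read a TSV with columns ``operon_id`` and ``gene_id``; returns
    a gene_id -> operon_id mapping."""
    df = pd.read_csv(path, sep="\t")
    for col in ("operon_id", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: a gene_id appears in more than one operon row")
    return dict(zip(df["gene_id"].astype(str), df["operon_id"].astype(str)))


def write_operon_table(mapping: dict[str, str], path) -> None:
    pd.DataFrame(
        {"operon_id": list(mapping.values()), "gene_id": list(mapping.keys())}
    ).to_csv(path, sep="\t", index=False)
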