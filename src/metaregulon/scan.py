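"""Promoter extraction, PWM scanning, and the two-stage retention rule.

The scan mirrors Patser-style binding-site prediction: take the 300 bp
upstream of each gene's annotated start, score every window on both
strands with the TF's log-odds matrix, and report windows scoring at
least the raw threshold (default 4.5).  A second stage then keeps only
hits scoring strictly above mean + k*SD (default k = 2) of all
threshold-passing scores for that TF within that MAG — the hits that
stand out from the bulk of marginal matches.

Promoters are not trimmed where they overlap upstream genes, and a
promoter truncated at a contig edge is still scanned (truncation only
shrinks the search space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io import GenomeAnnotation, GeneRecord
from .motif import Pwm, reverse_complement, reverse_complement_pwm, score_all_windows

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Knobs of the scan and retention stages.

    window_bp : upstream window length in bp (300 in the tested default)
    score_threshold : minimum reported raw log-odds score (4.5)
    retention_k : SD multiplier of the second-stage cutoff (2.0)
    both_strands : scan the reverse complement too
    expand_operons : grow regulons to whole operons of retained genes
    sample_sd : use the n-1 (sample) SD instead of the population SD
    """

    window_bp: int = 300
    score_threshold: float = 4.5
    retention_k: float = 2.0
    both_strands: bool = True
    expand_operons: bool = False
    sample_sd: bool = False

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.retention_k < 0:
            raise ValueError("retention_k must be >= 0")


@dataclass
class PromoterRegion:
    """The upstream window of one gene, oriented 5'->3' on the gene's strand.

    ``start``/``end`` are the 0-based half-open genomic coordinates of
    the window; ``seq`` is the genome slice, reverse-complemented for
    minus-strand genes.
    """

    gene_id: str
    contig_id: str
    seq: str
    start: int
    end: int
    strand: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SiteHit:
    """One threshold-passing PWM match inside a promoter."""

    tf_name: str
    mag_id: str
    gene_id: str
    offset: int        # 0-based within the promoter (5'->3' of the gene)
    strand: str        # match strand relative to the promoter orientation
    score: float
    width: int
    contig_id: str
    genomic_start: int  # 0-based genomic coordinate of the match
    genome_strand: str  # match strand on the genome


@dataclass
class RegulonPrediction:
    """The retained TF -> gene map for one TF in one MAG."""

    tf_name: str
    mag_id: str
    retained_hits: list[SiteHit]
    genes: set[str]
    retention_cutoff: float | None  # None when there were no hits to pool
    n_scanned_hits: int = 0


def extract_promoters(ann: GenomeAnnotation, cfg: ScanConfig | None = None) -> list[PromoterRegion]:
    """Extract the upstream window of every gene.

    Plus-strand gene starting at s: window [max(0, s-300), s).
    Minus-strand gene ending at e: window [e, min(L, e+300)), reverse-
    complemented so the promoter always reads towards the gene start.
    """
    cfg = cfg or ScanConfig()
    out: list[PromoterRegion] = []
    for g in ann.genes:
        contig = ann.contigs[g.contig_id]
        L = len(contig)
        if g.strand == "+":
            start, end = max(0, g.start - cfg.window_bp), g.start
            seq = contig[start:end]
        else:
            start, end = g.end, min(L, g.end + cfg.window_bp)
            seq = reverse_complement(contig[start:end])
        out.append(
            PromoterRegion(
                gene_id=g.gene_id,
                contig_id=g.contig_id,
                seq=seq,
                start=start,
                end=end,
                strand=g.strand,
                truncated=(end - start) < cfg.window_bp,
            )
        )
    return out


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def scan_promoters(pwm: Pwm, promoters: list[PromoterRegion],
                   cfg: ScanConfig | None = None, mag_id: str = "") -> list[SiteHit]:
    """Score every window of every promoter and report threshold passers.

    Both strands are scanned by default; overlapping hits are all kept.
    A palindromic window (equal to its own reverse complement) matches
    both strands identically at the same offset, so only the forward-
    strand hit is reported for it.
    """
    cfg = cfg or ScanConfig()
    w = pwm.width
    rc_pwm = reverse_complement_pwm(pwm) if cfg.both_strands else None
    hits: list[SiteHit] = []
    for prom in promoters:
        if len(prom.seq) < w:
            continue
        fwd = score_all_windows(pwm, prom.seq)
        rev = score_all_windows(rc_pwm, prom.seq) if rc_pwm is not None else None
        for offset in range(len(prom.seq) - w + 1):
            window = prom.seq[offset:offset + w]
            for strand, scores in (("+", fwd), ("-", rev)):
                if scores is None:
                    continue
                score = float(scores[offset])
                if score < cfg.score_threshold:
                    continue
                if strand == "-" and reverse_complement(window) == window:
                    continue  # palindromic: same physical site as the + hit
                if prom.strand == "+":
                    genomic_start = prom.start + offset
                    genome_strand = strand
                else:
                    genomic_start = prom.end - offset - w
                    genome_strand = _flip(strand)
                hits.append(
                    SiteHit(
                        tf_name=pwm.tf_name,
                        mag_id=mag_id,
                        gene_id=prom.gene_id,
                        offset=offset,
                        strand=strand,
                        score=score,
                        width=w,
                        contig_id=prom.contig_id,
                        genomic_start=genomic_start,
                        genome_strand=genome_strand,
                    )
                )
    return hits


def retain_hits(hits: list[SiteHit], cfg: ScanConfig | None = None,
                tf_name: str | None = None, mag_id: str | None = None) -> RegulonPrediction:
    """Apply the mean + k*SD retention rule to one TF's hits in one MAG.

    The statistic pool is exactly the given hit set.  Retained hits must
    score *strictly* greater than the cutoff, so a degenerate pool with
    SD 0 retains nothing.  The rule is invariant under affine rescaling
    of all scores.
    """
    cfg = cfg or ScanConfig()
    if hits:
        keys = {(h.tf_name, h.mag_id) for h in hits}
        if len(keys) > 1:
            raise ValueError(f"hits span multiple (tf, MAG) pools: {sorted(keys)}")
        tf_name, mag_id = hits[0].tf_name, hits[0].mag_id
        scores = np.array([h.score for h in hits])
        sd = scores.std(ddof=1 if (cfg.sample_sd and len(scores) > 1) else 0)
        cutoff = float(scores.mean() + cfg.retention_k * sd)
        retained = [h for h in hits if h.score > cutoff]
    else:
        logger.info("retain_hits: empty hit pool for tf=%s mag=%s; cutoff undefined",
                    tf_name, mag_id)
        cutoff = None
        retained = []
    return RegulonPrediction(
        tf_name=tf_name or "",
        mag_id=mag_id or "",
        retained_hits=retained,
        genes={h.gene_id for h in retained},
        retention_cutoff=cutoff,
        n_scanned_hits=len(hits),
    )


def expand_operons(pred: RegulonPrediction, operon_map: dict[str, str]) -> RegulonPrediction:
    """Grow the regulon to all members of operons containing a retained gene.

    Retained hits are unchanged; genes absent from the operon table stay
    in the regulon with a logged warning.
    """
    by_operon: dict[str, set[str]] = {}
    for gene, op in operon_map.items():
        by_operon.setdefault(op, set()).add(gene)
    genes = set(pred.genes)
    for g in pred.genes:
        if g not in operon_map:
            logger.warning("expand_operons: gene %s absent from operon table; kept as-is", g)
            continue
        genes |= by_operon[operon_map[g]]
    return replace(pred, genes=genes)


def predict_regulon(pwm: Pwm, ann: GenomeAnnotation, cfg: ScanConfig | None = None,
                    operon_map: dict[str, str] | None = None) -> tuple[RegulonPrediction, list[SiteHit]]:
    """Convenience wrapper: extract promoters, scan, retain, optionally expand.

    Returns the prediction and the full threshold-passing hit list.
    """
    cfg = cfg or ScanConfig()
    promoters = extract_promoters(ann, cfg)
    hits = scan_promoters(pwm, promoters, cfg, mag_id=ann.mag_id)
    pred = retain_hits(hits, cfg, tf_name=pwm.tf_name, mag_id=ann.mag_id)
    if cfg.expand_operons and operon_map is not None:
        pred = expand_operons(pred, operon_map)
    return pred, hits
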