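"""CRP/FNR-family candidate discovery and residue-conservation classification.

Members of the CRP/FNR transcription-factor superfamily sense different
signals (oxygen, nitric oxide, carbon sources) but share a fold, so the
annotation label alone is weak evidence of function.  Classification
here follows structure-informed conservation rules:

* FNR — at least four cysteines, the ligands of the oxygen-sensing
  4Fe-4S cluster;
* DNR — a histidine aligned to position 139 of the Pseudomonas
  aeruginosa PAO1 DNR reference (heme coordination for NO sensing);
* NnrR — a tyrosine aligned to position 93 of the Rhodobacter
  sphaeroides NnrR reference;
* CRP / MalR — sequence identity over the reference effector-binding
  domain above a configurable cutoff (default 30%).

Positions are defined on the reference protein and transferred to a
candidate through a Needleman-Wunsch global alignment with affine gaps.
The bundled reference proteins are synthetic stand-ins that satisfy the
family rules by construction (see ``data/reference_tfs.synthetic.faa``);
users with the real reference sequences can pass them in instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

FAMILY_PRIORITY = ("FNR", "DNR", "NnrR", "CRP", "MalR")
DEFAULT_DESCRIPTORS = ("FNR", "CRP", "DNR", "NnrR", "MalR")


@dataclass
class ProteinRecord:
    protein_id: str
    seq: str
    mag_id: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"{self.protein_id}: empty protein sequence")
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residues {sorted(bad)}")


@dataclass
class ConservationRule:
    """One family's classification rule.

    kind:
      "count-of-residue"   — candidate has >= min_count of ``residue``
      "reference-position" — candidate residue aligned to ``ref_pos``
                             (1-based on ``ref_id``) equals ``residue``
      "domain-identity"    — fractional identity over the reference
                             interval [domain_start, domain_end]
                             (1-based inclusive) >= min_identity
    """

    family: str
    kind: str
    residue: str = ""
    min_count: int = 0
    ref_id: str = ""
    ref_pos: int = 0
    domain_start: int = 0
    domain_end: int = 0
    min_identity: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "count-of-residue":
            if not self.residue or self.min_count < 1:
                raise ValueError(f"{self.family}: count rule needs residue and min_count")
        elif self.kind == "reference-position":
            if not (self.residue and self.ref_id and self.ref_pos >= 1):
                raise ValueError(f"{self.family}: position rule needs residue, ref_id, ref_pos")
            # min_identity acts as an alignment-credibility gate here:
            # a conserved-position claim is only meaningful when the
            # candidate aligns to the reference at all
        elif self.kind == "domain-identity":
            if not (self.ref_id and 1 <= self.domain_start <= self.domain_end
                    and self.min_identity > 0):
                raise ValueError(f"{self.family}: domain rule needs ref_id, interval, cutoff")
        else:
            raise ValueError(f"unknown rule kind {self.kind!r}")


@dataclass
class HomologCall:
    protein_id: str
    family: str  # family label or "unclassified"
    evidence: list[dict] = field(default_factory=list)


class GlobalAlignment(NamedTuple):
    """A pairwise global alignment: gapped strings plus score."""

    aligned_a: str
    aligned_b: str
    score: float


class MappedPosition(NamedTuple):
    """A reference position transferred onto a candidate sequence."""

    candidate_pos: int | None  # 1-based, None when opposite a gap
    residue: str               # "-" when opposite a gap


# ---------------------------------------------------------------------------
# alignment primitives


def _make_aligner(matrix: str = "BLOSUM62", gap_open: float = -10.0,
                  gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(a: str, b: str, matrix: str = "BLOSUM62",
                 gap_open: float = -10.0, gap_extend: float = -0.5) -> GlobalAlignment:
    """Optimal Needleman-Wunsch global alignment with affine gaps.

    The first alignment in the aligner's canonical enumeration order is
    returned, which makes tie-breaking deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return GlobalAlignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                           score=float(aln.score))


def map_reference_position(alignment: GlobalAlignment, ref_pos: int) -> MappedPosition:
    """Transfer a 1-based reference (sequence a) position onto sequence b."""
    ref_len = sum(1 for ch in alignment.aligned_a if ch != "-")
    if not (1 <= ref_pos <= ref_len):
        raise ValueError(f"reference position {ref_pos} outside 1..{ref_len}")
    seen_ref = 0
    seen_cand = 0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if cb != "-":
            seen_cand += 1
        if ca != "-":
            seen_ref += 1
            if seen_ref == ref_pos:
                if cb == "-":
                    return MappedPosition(candidate_pos=None, residue="-")
                return MappedPosition(candidate_pos=seen_cand, residue=cb)
    raise AssertionError("unreachable: ref_pos validated above")


def fractional_identity(alignment: GlobalAlignment) -> float:
    """Identical columns over total alignment columns."""
    cols = len(alignment.aligned_a)
    same = sum(1 for x, y in zip(alignment.aligned_a, alignment.aligned_b)
               if x == y and x != "-")
    return same / cols


def domain_identity(alignment: GlobalAlignment, start: int, end: int) -> float:
    """Fractional identity over the reference interval [start, end], 1-based."""
    seen_ref = 0
    same = 0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if ca != "-":
            seen_ref += 1
            if start <= seen_ref <= end and ca == cb:
                same += 1
    return same / (end - start + 1)


# ---------------------------------------------------------------------------
# candidate discovery and rules

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def find_candidates(proteins: Iterable[ProteinRecord],
                    descriptors: Sequence[str] = DEFAULT_DESCRIPTORS) -> list[ProteinRecord]:
    """Proteins whose product annotation contains a family descriptor.

    Matching is case-insensitive and whole-token, so "CRP" matches
    "cAMP receptor protein (CRP)" but not "CRISPR".  Each protein is
    reported once however many descriptors hit.
    """
    if not descriptors:
        raise ValueError("descriptor list must be non-empty")
    wanted = {d.lower() for d in descriptors}
    out = []
    for p in proteins:
        tokens = {t.lower() for t in _TOKEN_RE.findall(p.product)}
        if tokens & wanted:
            out.append(p)
    return out


def default_rules(min_domain_identity: float = 0.30) -> list[ConservationRule]:
    """The bundled family rules, in priority order (FNR > DNR > NnrR >
    CRP > MalR): structural residue rules outrank identity rules."""
    return [
        ConservationRule(family="FNR", kind="count-of-residue", residue="C", min_count=4),
        ConservationRule(family="DNR", kind="reference-position", residue="H",
                         ref_id="DNR_ref", ref_pos=139, min_identity=0.20),
        ConservationRule(family="NnrR", kind="reference-position", residue="Y",
                         ref_id="NnrR_ref", ref_pos=93, min_identity=0.20),
        ConservationRule(family="CRP", kind="domain-identity", ref_id="CRP_ref",
                         domain_start=10, domain_end=110,
                         min_identity=min_domain_identity),
        ConservationRule(family="MalR", kind="domain-identity", ref_id="MalR_ref",
                         domain_start=120, domain_end=220,
                         min_identity=min_domain_identity),
    ]


def load_reference_proteins() -> dict[str, ProteinRecord]:
    """The bundled synthetic reference proteins, keyed by id."""
    text = (resources.files("metaregulon") / "data" / "reference_tfs.synthetic.faa").read_text()
    refs: dict[str, ProteinRecord] = {}
    pid, desc, chunks = None, "", []
    for line in text.splitlines():
        if line.startswith(">"):
            if pid is not None:
                refs[pid] = ProteinRecord(protein_id=pid, seq="".join(chunks), product=desc)
            head = line[1:].split(None, 1)
            pid = head[0]
            desc = head[1] if len(head) > 1 else ""
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if pid is not None:
        refs[pid] = ProteinRecord(protein_id=pid, seq="".join(chunks), product=desc)
    return refs


def apply_rules(candidate: ProteinRecord, rules: Sequence[ConservationRule] | None = None,
                references: dict[str, ProteinRecord] | None = None) -> HomologCall:
    """Evaluate every rule on a candidate; assign the first passing family.

    The rule list's order is the family priority order.  Evidence for
    every rule (pass/fail, mapped positions, identity percentages) is
    kept on the call for auditability.
    """
    if rules is None:
        rules = default_rules()
    if references is None:
        references = load_reference_proteins()
    evidence: list[dict] = []
    family = "unclassified"
    for rule in rules:
        item: dict = {"family": rule.family, "kind": rule.kind}
        if rule.kind == "count-of-residue":
            count = candidate.seq.count(rule.residue)
            item.update(count=count, required=rule.min_count,
                        passed=count >= rule.min_count)
        else:
            ref = references.get(rule.ref_id)
            if ref is None:
                raise KeyError(f"rule {rule.family}: reference {rule.ref_id!r} not provided")
            aln = global_align(ref.seq, candidate.seq)
            if rule.kind == "reference-position":
                mapped = map_reference_position(aln, rule.ref_pos)
                ident = fractional_identity(aln)
                credible = ident >= rule.min_identity
                item.update(ref_pos=rule.ref_pos, mapped_pos=mapped.candidate_pos,
                            mapped_residue=mapped.residue, required=rule.residue,
                            alignment_identity=round(ident, 4),
                            passed=credible and mapped.residue == rule.residue)
            else:  # domain-identity
                ident = domain_identity(aln, rule.domain_start, rule.domain_end)
                item.update(domain=(rule.domain_start, rule.domain_end),
                            identity=round(ident, 4), required=rule.min_identity,
                            passed=ident >= rule.min_identity)
        evidence.append(item)
        if item["passed"] and family == "unclassified":
            family = rule.family
    return HomologCall(protein_id=candidate.protein_id, family=family, evidence=evidence)


# ---------------------------------------------------------------------------
# neighbor joining


def identity_distance_matrix(records: Sequence[ProteinRecord]) -> tuple[np.ndarray, list[str]]:
    """Pairwise d = 1 - fractional identity from global alignments."""
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i].seq, records[j].seq)
            d[i, j] = d[j, i] = 1.0 - fractional_identity(aln)
    return d, ids


def nj_from_distances(d: np.ndarray, ids: Sequence[str]) -> str:
    """Neighbor joining on a distance matrix; returns unrooted newick.

    On an additive distance matrix NJ recovers the generating topology
    and branch lengths exactly.  Ties in the Q criterion are broken by
    the lexicographically smallest joined pair, so output is
    deterministic.  Branch lengths are not clamped at zero.
    """
    d = np.asarray(d, dtype=float).copy()
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate leaf ids")
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    nodes = list(ids)          # newick fragments
    names = list(ids)          # stable names for tie-breaking
    active = list(range(len(ids)))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: lexicographically smallest joined pair
        best = None
        for a in range(n):
            for b in range(a + 1, n):
                if q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((names[active[a]], names[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (n - 2))
        lj = dij - li
        new = len(nodes)
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        names.append(min(names[i], names[j]))
        # grow the matrix with the new node's distances
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    return f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[k]}:{lk:.10g});"


def nj_tree(records: Sequence[ProteinRecord]) -> str:
    """Neighbor-joining tree of proteins from alignment-identity distances."""
    d, ids = identity_distance_matrix(records)
    return nj_from_distances(d, ids)
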