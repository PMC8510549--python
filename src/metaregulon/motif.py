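"""Position weight matrices and the log-odds scoring primitive.

A PWM summarises an alignment of known binding sites as per-position
log-odds weights ``w[b,i] = ln(f[b,i] / q_b)`` where ``f`` is the
pseudocounted base frequency at position ``i`` and ``q`` the background
distribution.  The score of a window is the sum of the weights of its
bases, the classic additive log-odds statistic used by Patser-style
scanners.  Natural log is the default base because the downstream
raw-score threshold (4.5) comes from that convention.

The total pseudocount (default 1) is distributed across bases in
proportion to the background, so a pseudocounted column is a posterior
mean under a background-centred Dirichlet prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G

_NORM_TOL = 1e-9


class DegenerateMatrixError(ValueError):
    """A zero-probability cell with zero pseudocount."""


@dataclass
class Background:
    """Mononucleotide background distribution over A, C, G, T."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,):
            raise ValueError("background needs exactly four frequencies (A,C,G,T)")
        if np.any(self.freqs <= 0):
            raise ValueError("background frequencies must all be positive")
        if abs(self.freqs.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"background frequencies sum to {self.freqs.sum()}, not 1")

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(cls, seqs: Sequence[str]) -> "Background":
        """Estimate mononucleotide frequencies from pooled sequences.

        Ambiguous bases (N) are ignored.  MAG GC content spans roughly
        36-68%, so estimating the background from the promoters being
        scanned keeps scores comparable across genomes.
        """
        counts = np.zeros(4)
        for s in seqs:
            for b, i in _BASE_INDEX.items():
                counts[i] += s.count(b)
        total = counts.sum()
        if total == 0:
            raise ValueError("no unambiguous bases to estimate a background from")
        # a unit pseudocount avoids zero frequencies on tiny inputs
        return cls((counts + 0.25) / (total + 1.0))

    def __getitem__(self, base: str) -> float:
        return float(self.freqs[_BASE_INDEX[base]])


@dataclass
class SiteAlignment:
    """An ungapped alignment of known binding sites for one TF."""

    tf_name: str
    sites: list[str]

    def __post_init__(self) -> None:
        self.sites = [s.upper() for s in self.sites]
        if len(self.sites) < 2:
            raise ValueError(f"{self.tf_name}: need at least 2 sites, got {len(self.sites)}")
        widths = {len(s) for s in self.sites}
        if len(widths) != 1:
            raise ValueError(f"{self.tf_name}: sites have unequal widths {sorted(widths)}")
        self.width = widths.pop()
        if self.width < 4:
            raise ValueError(f"{self.tf_name}: site width {self.width} < 4")
        for s in self.sites:
            bad = set(s) - set(BASES)
            if bad:
                raise ValueError(f"{self.tf_name}: site {s!r} has non-ACGT characters {sorted(bad)}")

    def count_matrix(self) -> np.ndarray:
        """4 x width base-count matrix."""
        c = np.zeros((4, self.width), dtype=np.int64)
        for s in self.sites:
            for i, b in enumerate(s):
                c[_BASE_INDEX[b], i] += 1
        return c


@dataclass
class Pwm:
    """Per-position natural-log-odds weight matrix with provenance.

    Invariant: for every column i, sum_b exp(weights[b,i]) * q_b == 1,
    i.e. the implied pseudocounted frequencies are a distribution.
    """

    tf_name: str
    weights: np.ndarray  # 4 x width, natural-log odds
    background: Background
    pseudocount: float = 1.0
    counts: np.ndarray | None = None  # 4 x width source counts, if known

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ValueError("weights must be a 4 x width matrix")
        colsums = (np.exp(self.weights) * self.background.freqs[:, None]).sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError(
                "PWM columns do not satisfy probability normalization "
                f"(max deviation {np.max(np.abs(colsums - 1.0)):.2e})"
            )

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def probabilities(self) -> np.ndarray:
        """The 4 x width pseudocounted frequency matrix f = exp(w) * q."""
        return np.exp(self.weights) * self.background.freqs[:, None]

    @classmethod
    def from_probabilities(cls, tf_name: str, probs: np.ndarray,
                           background: Background, nsites: int = 20,
                           pseudocount: float = 1.0) -> "Pwm":
        """Build from an explicit probability matrix (e.g. read from a
        motif file).  Probabilities are taken as-is: a hard zero gives a
        -inf weight, i.e. the base is strictly forbidden at that
        position."""
        probs = np.asarray(probs, dtype=float)
        with np.errstate(divide="ignore"):
            weights = np.log(probs / background.freqs[:, None])
        return cls(tf_name=tf_name, weights=weights, background=background,
                   pseudocount=pseudocount, counts=None)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.weights, axis=0))

    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())


def build_pwm(align: SiteAlignment, background: Background | None = None,
              pseudocount: float = 1.0) -> Pwm:
    """Build a PWM from a binding-site alignment.

    weights[b,i] = ln( ((c[b,i] + p*q_b) / (N + p)) / q_b )

    with ``c`` the count matrix, ``N`` the number of sites, ``p`` the
    total pseudocount and ``q`` the background.  With ``p = 0`` every
    column must contain all four bases or the matrix is degenerate.
    """
    if background is None:
        background = Background.uniform()
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = align.count_matrix()
    n = len(align.sites)
    if pseudocount == 0 and np.any(counts == 0):
        raise DegenerateMatrixError(
            f"{align.tf_name}: zero-count cell with pseudocount 0 would give -inf weight"
        )
    freqs = (counts + pseudocount * background.freqs[:, None]) / (n + pseudocount)
    weights = np.log(freqs / background.freqs[:, None])
    return Pwm(tf_name=align.tf_name, weights=weights, background=background,
               pseudocount=pseudocount, counts=counts)


def information_content(pwm: Pwm) -> tuple[np.ndarray, float]:
    """Per-column information content in bits, and the total.

    IC_i = sum_b f[b,i] * log2(f[b,i] / q_b), the height of column i in
    a sequence logo drawn relative to the background.
    """
    f = pwm.probabilities()
    q = pwm.background.freqs[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / q), 0.0)
    per_column = terms.sum(axis=0)
    return per_column, float(per_column.sum())


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices A=0 C=1 G=2 T=3 N=4."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    table[ord("N")] = 4
    idx = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(idx < 0):
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return idx.astype(np.int64)


def _weights_with_n(pwm: Pwm) -> np.ndarray:
    """5 x width weight matrix where row 4 (N) holds each column's minimum.

    An ambiguous base contributes the most pessimistic weight, so Ns can
    never create a hit that the real sequence would not support.
    """
    return np.vstack([pwm.weights, pwm.weights.min(axis=0)])


def score_window(pwm: Pwm, window: str) -> float:
    """Additive log-odds score of one window of length ``pwm.width``."""
    window = window.upper()
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    w5 = _weights_with_n(pwm)
    idx = _encode(window)
    return float(w5[idx, np.arange(pwm.width)].sum())


def score_all_windows(pwm: Pwm, seq: str) -> np.ndarray:
    """Scores of every window of ``seq``; empty array if seq is shorter
    than the PWM."""
    seq = seq.upper()
    w = pwm.width
    if len(seq) < w:
        return np.empty(0)
    idx = _encode(seq)
    w5 = _weights_with_n(pwm)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return w5[windows, np.arange(w)].sum(axis=1)


def reverse_complement_pwm(pwm: Pwm) -> Pwm:
    """The PWM scoring the reverse complement strand; an involution."""
    weights = pwm.weights[_COMPLEMENT_PERM][:, ::-1].copy()
    counts = None
    if pwm.counts is not None:
        counts = pwm.counts[_COMPLEMENT_PERM][:, ::-1].copy()
    # a non-uniform background is strand-symmetric only if complement-
    # invariant; keep the stored background but complement its order
    bg = Background(pwm.background.freqs[_COMPLEMENT_PERM].copy())
    return Pwm(tf_name=pwm.tf_name, weights=weights, background=bg,
               pseudocount=pwm.pseudocount, counts=counts)


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.upper().translate(comp)[::-1]


def bundled_site_alignment(tf_name: str) -> SiteAlignment:
    """Load one of the packaged synthetic site alignments (FNR, CRP,
    DNR, NnrR, MalR).  These are stand-ins for curated binding-site
    collections; pass your own :class:`SiteAlignment` for real motifs."""
    from importlib import resources

    path = resources.files("metaregulon") / "data" / "sites" / f"{tf_name}.sites.synthetic.txt"
    try:
        text = path.read_text()
    except FileNotFoundError as exc:
        raise KeyError(f"no bundled site alignment for TF {tf_name!r}") from exc
    sites = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return SiteAlignment(tf_name=tf_name, sites=sites)


BUNDLED_TFS = ("FNR", "CRP", "DNR", "NnrR", "MalR")
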