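"""PSSM construction, log-odds scoring, exact null p-values and scanning.

A position-specific scoring matrix assigns each sequence window S a score

    W_s = log2(P(S | motif) / P(S | background)),

the sum of per-position log-odds. The p-value of a score is computed
exactly under the i.i.d. background model by dynamic-programming
convolution of the per-position score distributions on a discretised
score lattice. Scanning reports hits on both strands in forward, 0-based
half-open coordinates, with the stringent p <= 0.0002 cutoff or a
permissive W_s >= 1 rule (a window at least twice as probable under the
motif as under the background).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "PSSM",
    "PSSMHit",
    "NullDistribution",
    "build_pssm",
    "score_window",
    "null_distribution",
    "scan",
    "consensus_match",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PSSM:
    """Log2-odds scoring matrix with its background model.

    ``scores`` has shape (width, 4) in the base order ACGT;
    ``background`` holds strictly positive base probabilities summing
    to 1. Source counts and the pseudocount used, when built from counts,
    are kept for provenance.
    """

    scores: np.ndarray
    background: np.ndarray
    counts: Optional[np.ndarray] = None
    pseudocount: Optional[float] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 4:
            raise ValueError("scores must have shape (width, 4)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if abs(self.background.sum() - 1.0) > 1e-9 or (self.background <= 0).any():
            raise ValueError("background must be strictly positive and sum to 1")

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.scores.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


@dataclass
class PSSMHit:
    """One scored match in forward, 0-based half-open coordinates."""

    sequence_id: str
    start: int
    strand: str            # "+" or "-"
    word: str              # matched word as read on the hit strand
    score: float
    p_value: float

    @property
    def end(self) -> int:
        return self.start + len(self.word)


def build_pssm(counts: Optional[np.ndarray] = None,
               sites: Optional[Sequence[str]] = None,
               pseudocount: float = 1.0,
               background: Optional[np.ndarray] = None) -> PSSM:
    """Build a log2-odds PSSM from a counts table or aligned sites.

    Frequencies are (count + pseudocount/4-share) normalised per column;
    score(pos, base) = log2(freq / background(base)). A zero column with
    zero pseudocount is an error (log of zero).
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if counts is None:
        if not sites:
            raise ValueError("need counts or at least one aligned site")
        w = len(sites[0])
        if any(len(s) != w for s in sites):
            raise ValueError("aligned sites must share one length")
        counts = np.zeros((w, 4))
        for s in sites:
            for i, ch in enumerate(s.upper()):
                if ch not in _BASE_IDX:
                    raise ValueError(f"non-ACGT base {ch!r} in aligned site")
                counts[i, _BASE_IDX[ch]] += 1
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must have shape (width, 4)")
    if pseudocount == 0 and (counts.sum(axis=1) == 0).any():
        raise ValueError("zero count column requires a pseudocount")
    padded = counts + pseudocount * background[None, :]
    if (padded <= 0).any():
        raise ValueError("zero-probability cell; increase the pseudocount")
    freqs = padded / padded.sum(axis=1, keepdims=True)
    scores = np.log2(freqs / background[None, :])
    return PSSM(scores=scores, background=background,
                counts=counts, pseudocount=pseudocount)


def score_window(pssm: PSSM, word: str) -> float:
    """W_s of one window: the sum of per-position log2-odds.

    Raises ``ValueError`` on ambiguous bases; the scanner skips such
    windows and reports the skip count.
    """
    word = word.upper()
    if len(word) != pssm.width:
        raise ValueError(f"word length {len(word)} != matrix width {pssm.width}")
    total = 0.0
    for i, ch in enumerate(word):
        if ch not in _BASE_IDX:
            raise ValueError(f"ambiguous base {ch!r} in window")
        total += pssm.scores[i, _BASE_IDX[ch]]
    return float(total)


@dataclass
class NullDistribution:
    """Exact score distribution of W_s under the i.i.d. background.

    ``grid`` is the discretised score lattice; ``pmf`` its probabilities
    (summing to 1) and ``tail`` the right tail P(W >= s), right-continuous
    and nonincreasing. ``resolution`` is the lattice step in bits.
    """

    grid: np.ndarray
    pmf: np.ndarray
    tail: np.ndarray
    resolution: float

    def p_value(self, score: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """P(W_s >= score) on the lattice.

        The score is snapped to the nearest lattice point (half the
        resolution is the worst-case discretisation error).
        """
        idx = np.round((np.asarray(score, float) - self.grid[0])
                       / self.resolution).astype(int)
        idx = np.clip(idx, 0, len(self.grid) - 1)
        out = self.tail[idx]
        return float(out) if np.isscalar(score) else out


def null_distribution(pssm: PSSM, background: Optional[np.ndarray] = None,
                      resolution: float = 0.01) -> NullDistribution:
    """Exact null of W_s by per-position convolution on a score lattice.

    Every per-position score is rounded to the nearest multiple of
    ``resolution`` bits (so the total rounding error is at most
    width * resolution / 2); the position distributions are convolved
    into the exact distribution of the rounded total score.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    bg = pssm.background if background is None else np.asarray(background, float)
    q = np.round(pssm.scores / resolution).astype(np.int64)   # lattice units
    lo = int(q.min(axis=1).sum())
    hi = int(q.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # start with the first position, then convolve the rest
    offset = lo
    cur = np.zeros(int(q[0].max() - q[0].min()) + 1)
    base0 = int(q[0].min())
    for b in range(4):
        cur[q[0, b] - base0] += bg[b]
    cur_lo = base0
    for pos in range(1, pssm.width):
        step_lo = int(q[pos].min())
        step = np.zeros(int(q[pos].max()) - step_lo + 1)
        for b in range(4):
            step[q[pos, b] - step_lo] += bg[b]
        cur = np.convolve(cur, step)
        cur_lo += step_lo
    pmf[cur_lo - lo:cur_lo - lo + len(cur)] = cur
    grid = (lo + np.arange(len(pmf))) * resolution
    tail = np.cumsum(pmf[::-1])[::-1]
    return NullDistribution(grid=grid, pmf=pmf, tail=tail, resolution=resolution)


def scan(pssm: PSSM, sequences, p_cutoff: Optional[float] = 0.0002,
         score_cutoff: Optional[float] = None,
         both_strands: bool = True,
         null: Optional[NullDistribution] = None) -> list[PSSMHit]:
    """Scan sequences for PSSM matches above threshold.

    ``sequences`` is a dict id -> sequence string, an iterable of
    Biopython ``SeqRecord``s, or a single string. Hits must satisfy
    p <= ``p_cutoff`` (when given) and W_s >= ``score_cutoff`` (when
    given; the permissive rule is ``score_cutoff=1``, i.e.
    P(M) >= 2 P(B)). Reverse-strand hits are reported at their forward
    0-based half-open coordinates. Windows containing ambiguous bases are
    skipped and counted in a log message.
    """
    if p_cutoff is None and score_cutoff is None:
        raise ValueError("need a p-value cutoff or a score cutoff")
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    elif not isinstance(sequences, dict):
        sequences = {rec.id: str(rec.seq) for rec in sequences}
    if null is None and p_cutoff is not None:
        null = null_distribution(pssm)

    w = pssm.width
    hits: list[PSSMHit] = []
    skipped = 0
    for sid, seq in sequences.items():
        seq = str(seq).upper()
        if len(seq) < w:
            logger.warning("sequence %s shorter than matrix width; no hits", sid)
            continue
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", reverse_complement(seq)))
        for strand, s in strands:
            for i in range(len(s) - w + 1):
                word = s[i:i + w]
                try:
                    score = score_window(pssm, word)
                except ValueError:
                    skipped += 1
                    continue
                p = null.p_value(score) if null is not None else 1.0
                if p_cutoff is not None and p > p_cutoff:
                    continue
                if score_cutoff is not None and score < score_cutoff:
                    continue
                start = i if strand == "+" else len(s) - i - w
                hits.append(PSSMHit(sequence_id=sid, start=start, strand=strand,
                                    word=word, score=score, p_value=float(p)))
    if skipped:
        logger.info("%d windows with ambiguous bases skipped", skipped)
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r}")
        allowed = IUPAC[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def consensus_match(sequences, iupac: str = "WATCARNNNNTTR",
                    both_strands: bool = True) -> list[tuple[str, int, str]]:
    """All exact IUPAC-consensus matches, in forward coordinates.

    Returns (sequence id, 0-based start, strand) tuples, including
    overlapping matches.
    """
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    elif not isinstance(sequences, dict):
        sequences = {rec.id: str(rec.seq) for rec in sequences}
    rx = _iupac_regex(iupac)
    w = len(iupac)
    out: list[tuple[str, int, str]] = []
    for sid, seq in sequences.items():
        seq = str(seq).upper()
        for m in rx.finditer(seq):
            out.append((sid, m.start(), "+"))
        if both_strands:
            rc = reverse_complement(seq)
            for m in rx.finditer(rc):
                out.append((sid, len(seq) - m.start() - w, "-"))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out
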