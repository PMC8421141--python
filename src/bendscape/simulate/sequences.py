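"""Background DNA sequences with planted motif instances.

Backgrounds are i.i.d. with a requested AT fraction (A and T equally
likely within the AT mass, likewise C/G). Planted motifs overwrite the
background at stated positions, with IUPAC ambiguity codes resolved
uniformly at random among their allowed bases, so every planted instance
is a concrete A/C/G/T word whose position is recorded as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["IUPAC", "SequenceGroundTruth", "generate_sequences"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class SequenceGroundTruth:
    """Planted-motif records: per sequence, (position, pattern, instance)."""

    planted: dict = field(default_factory=dict)   # seq id -> list of dicts

    def to_json(self, path=None) -> str:
        text = json.dumps(self.planted, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "SequenceGroundTruth":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(planted=payload)


def _resolve_iupac(pattern: str, rng: np.random.Generator) -> str:
    out = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r}")
        allowed = IUPAC[ch]
        out.append(allowed[rng.integers(len(allowed))] if len(allowed) > 1 else allowed)
    return "".join(out)


def generate_sequences(n: int, length_bp: int,
                       at_fraction: float = 0.5,
                       planted: Optional[Sequence[tuple[str, int]]] = None,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None,
                       ) -> tuple[list[SeqRecord], SequenceGroundTruth]:
    """Generate ``n`` background sequences with optional planted motifs.

    ``planted`` lists (motif pattern, position) pairs applied to every
    sequence; patterns may use IUPAC codes, resolved independently per
    sequence. Overlapping planted motifs or motifs that do not fit within
    ``length_bp`` are rejected.
    """
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError("at_fraction must be in [0, 1]")
    planted = list(planted or [])
    intervals = sorted((pos, pos + len(m)) for m, pos in planted)
    for (s0, e0), (s1, e1) in zip(intervals[:-1], intervals[1:]):
        if s1 < e0:
            raise ValueError("planted motifs overlap")
    for m, pos in planted:
        if pos < 0 or pos + len(m) > length_bp:
            raise ValueError(f"motif {m!r} at {pos} does not fit in {length_bp} bp")
    if rng is None:
        rng = np.random.default_rng(seed)

    probs = np.array([at_fraction / 2, (1 - at_fraction) / 2,
                      (1 - at_fraction) / 2, at_fraction / 2])
    bases = np.array(list("ACGT"))
    records: list[SeqRecord] = []
    truth = SequenceGroundTruth()
    for i in range(n):
        seq = rng.choice(bases, size=length_bp, p=probs)
        sid = f"synth_{i}"
        truth.planted[sid] = []
        for pattern, pos in planted:
            instance = _resolve_iupac(pattern, rng)
            seq[pos:pos + len(instance)] = list(instance)
            truth.planted[sid].append(
                {"position": pos, "pattern": pattern, "instance": instance})
        records.append(SeqRecord(Seq("".join(seq)), id=sid, description=""))
    return records, truth
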