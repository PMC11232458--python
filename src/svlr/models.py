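"""Core domain types shared across the caller.

All coordinates are 0-based half-open internally; conversion to the 1-based
coordinates of VCF happens only when records are written out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")

#: CIGAR operation codes as used by BAM (pysam cigartuples).
CIGAR_M, CIGAR_I, CIGAR_D, CIGAR_N, CIGAR_S, CIGAR_H, CIGAR_P, CIGAR_EQ, CIGAR_X = range(9)

_REF_CONSUMING = {CIGAR_M, CIGAR_D, CIGAR_N, CIGAR_EQ, CIGAR_X}
_QUERY_CONSUMING = {CIGAR_M, CIGAR_I, CIGAR_S, CIGAR_EQ, CIGAR_X}

OP_CODE = {"M": CIGAR_M, "I": CIGAR_I, "D": CIGAR_D, "N": CIGAR_N, "S": CIGAR_S,
           "H": CIGAR_H, "P": CIGAR_P, "=": CIGAR_EQ, "X": CIGAR_X}
OP_CHAR = {v: k for k, v in OP_CODE.items()}


def parse_cigar(text: str) -> list[tuple[int, int]]:
    """Parse a CIGAR string into (op_code, length) tuples."""
    out = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            out.append((OP_CODE[ch], int(num)))
            num = ""
    if num:
        raise ValueError(f"trailing digits in CIGAR {text!r}")
    return out


def cigar_to_string(cigar: list[tuple[int, int]]) -> str:
    return "".join(f"{ln}{OP_CHAR[op]}" for op, ln in cigar)


def cigar_reference_span(cigar: list[tuple[int, int]]) -> int:
    return sum(ln for op, ln in cigar if op in _REF_CONSUMING)


def cigar_query_length(cigar: list[tuple[int, int]], include_hard: bool = True) -> int:
    """Full query length implied by a CIGAR (soft clips always, hard clips optional)."""
    total = sum(ln for op, ln in cigar if op in _QUERY_CONSUMING)
    if include_hard:
        total += sum(ln for op, ln in cigar if op == CIGAR_H)
    return total


@dataclass
class SAEntry:
    """One entry of a supplementary-alignment (SA) tag."""

    contig: str
    pos: int  # 0-based
    strand: str
    cigar: list[tuple[int, int]]
    mapq: int
    nm: int = 0


@dataclass
class AlignmentRecord:
    """One parsed alignment line (primary or supplementary)."""

    read_name: str
    contig: str
    ref_start: int
    ref_end: int
    mapq: int
    strand: str
    is_primary: bool
    is_supplementary: bool
    cigar: list[tuple[int, int]]
    edit_distance: Optional[int] = None
    sa_entries: list[SAEntry] = field(default_factory=list)
    read_sequence: Optional[str] = None
    read_length: int = 0

    @property
    def left_clip(self) -> int:
        if self.cigar and self.cigar[0][0] in (CIGAR_S, CIGAR_H):
            return self.cigar[0][1]
        return 0

    @property
    def right_clip(self) -> int:
        if self.cigar and self.cigar[-1][0] in (CIGAR_S, CIGAR_H):
            return self.cigar[-1][1]
        return 0

    @property
    def aligned_length(self) -> int:
        return self.ref_end - self.ref_start

    def query_interval(self) -> tuple[int, int]:
        """Aligned interval on the original-orientation read."""
        left, right = self.left_clip, self.right_clip
        if self.strand == "-":
            left, right = right, left
        return left, self.read_length - right


@dataclass
class Signature:
    """The atomic piece of SV evidence: the (t, c, s, e) quadruple plus provenance.

    For INS the span encodes the inserted length (e = s + length); for TRA the
    mate locus lives in (c2, p2) and the span is degenerate (e = s).
    """

    t: str
    c: str
    s: int
    e: int
    read_name: str
    source: str  # "intra" | "inter"
    length: int
    c2: Optional[str] = None
    p2: Optional[int] = None
    features: Optional[np.ndarray] = None

    @property
    def span(self) -> int:
        return self.e - self.s

    @property
    def midpoint(self) -> float:
        return (self.s + self.e) / 2.0


@dataclass
class SVCall:
    """A reported variant; precursor of one VCF record (two for TRA breakends)."""

    sv_type: str
    contig: str
    pos: int  # 0-based internally
    end: int
    svlen: int
    support: int
    genotype: str = "./."
    gt_quality: int = 0
    ref_support: int = 0
    alt_support: int = 0
    filter: str = "PASS"
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None
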