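"""SV signature extraction from alignment records.

Two evidence channels:

* **intra-alignment**: insertion/deletion gap operations inside one CIGAR,
  each carrying a 25-entry feature vector (global alignment statistics,
  CIGAR-local gap geometry, base-composition statistics);
* **inter-alignment**: the geometry of a read's split alignments (primary +
  supplementary segments ordered along the read), classified by deliberately
  lenient rules — a different contig means a translocation, opposite strands
  an inversion, a reference backtrack a duplication, and otherwise the sign of
  (reference gap − read gap) separates deletions from insertions. Each pair
  carries a 22-entry feature vector; no further heuristic filtering happens
  here — discarding noise is the job of the learned random-forest filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .models import (
    CIGAR_D, CIGAR_EQ, CIGAR_H, CIGAR_I, CIGAR_M, CIGAR_S, CIGAR_X,
    AlignmentRecord, SAEntry, Signature, cigar_query_length,
    cigar_reference_span,
)

DEFAULT_MIN_SIZE = 30
#: spans beyond this are treated as alignment chimeras, not SV evidence
MAX_SV_SIZE = 100_000
#: smallest CIGAR gap considered SV-like (candidates for merging);
#: scattered 1–20 bp indels are sequencing noise, not fragmented SV evidence.
GAP_CANDIDATE_MIN = 20
#: same-type gaps separated by less than this much matched sequence merge.
GAP_MERGE_DISTANCE = 150

#: public schema of the intra-alignment feature vector (order matters; models
#: trained against this schema are only portable while it is unchanged).
INTRA_FEATURES = (
    # global alignment (9)
    "mapq", "left_clip", "right_clip", "ins_op_count", "del_op_count",
    "edit_distance", "read_length", "aligned_fraction", "supp_count",
    # CIGAR-local (6)
    "gap_read_offset", "gap_ref_offset", "gap_length", "gap_type_code",
    "gap_nearest_distance", "gap_count",
    # base distribution (10)
    "read_freq_a", "read_freq_c", "read_freq_g", "read_freq_t",
    "window_freq_a", "window_freq_c", "window_freq_g", "window_freq_t",
    "read_repeat_freq", "window_repeat_freq",
)

#: public schema of the inter-alignment (split read) feature vector.
INTER_FEATURES = (
    # global alignment (8)
    "primary_mapq", "supp_mapq", "primary_aligned_len", "supp_aligned_len",
    "primary_left_clip", "primary_right_clip", "primary_edit_distance",
    "supp_edit_distance",
    # split alignment (9)
    "same_contig", "same_strand", "read_gap", "ref_gap", "gap_difference",
    "read_overlap", "ref_overlap", "sa_count", "inferred_type_code",
    # base distribution (5)
    "read_freq_a", "read_freq_c", "read_freq_g", "read_freq_t",
    "read_repeat_freq",
)

TYPE_CODE = {"DEL": 0, "INS": 1, "DUP": 2, "INV": 3, "TRA": 4}

_REPEAT_RUN = 5


def base_distribution(seq: Optional[str], window: Optional[tuple[int, int]] = None
                      ) -> np.ndarray:
    """Frequencies of A, C, G, T plus the repeated-base frequency of ``seq``.

    The repeated-base frequency is the fraction of positions lying inside a
    homopolymer run of length >= 5. ``N`` counts toward the denominator only.
    An absent or empty sequence yields all zeros (sentinel, never a crash).
    """
    if not seq:
        return np.zeros(5)
    if window is not None:
        lo, hi = max(0, window[0]), min(len(seq), window[1])
        seq = seq[lo:hi]
        if not seq:
            return np.zeros(5)
    seq = seq.upper()
    n = len(seq)
    counts = {b: 0 for b in "ACGT"}
    repeat = 0
    run_start = 0
    for i, b in enumerate(seq):
        if b in counts:
            counts[b] += 1
        if i > 0 and b != seq[i - 1]:
            if i - run_start >= _REPEAT_RUN and seq[run_start] != "N":
                repeat += i - run_start
            run_start = i
    if n - run_start >= _REPEAT_RUN and seq[run_start] != "N":
        repeat += n - run_start
    return np.array([counts["A"] / n, counts["C"] / n, counts["G"] / n,
                     counts["T"] / n, repeat / n])


@dataclass
class _Gap:
    op: int  # CIGAR_I or CIGAR_D
    qpos: int  # read offset (stored orientation) at gap start
    rpos: int  # reference coordinate at gap start
    length: int


def _collect_gaps(rec: AlignmentRecord) -> list[_Gap]:
    gaps = []
    q = 0
    r = rec.ref_start
    for op, ln in rec.cigar:
        if op in (CIGAR_M, CIGAR_EQ, CIGAR_X):
            q += ln
            r += ln
        elif op == CIGAR_I:
            if ln >= GAP_CANDIDATE_MIN:
                gaps.append(_Gap(CIGAR_I, q, r, ln))
            q += ln
        elif op == CIGAR_D:
            if ln >= GAP_CANDIDATE_MIN:
                gaps.append(_Gap(CIGAR_D, q, r, ln))
            r += ln
        elif op in (CIGAR_S, CIGAR_H):
            if op == CIGAR_S:
                q += ln
    return gaps


def _merge_gaps(gaps: list[_Gap]) -> list[_Gap]:
    """Merge adjacent same-type gaps separated by < GAP_MERGE_DISTANCE of match."""
    merged: list[_Gap] = []
    for g in gaps:
        if merged:
            prev = merged[-1]
            if prev.op == g.op:
                sep = (g.rpos - (prev.rpos + (prev.length if prev.op == CIGAR_D else 0))
                       if g.op == CIGAR_D else
                       g.qpos - (prev.qpos + (prev.length if prev.op == CIGAR_I else 0)))
                if 0 <= sep < GAP_MERGE_DISTANCE:
                    if g.op == CIGAR_D:
                        prev.length = g.rpos + g.length - prev.rpos
                    else:
                        prev.length += g.length
                    merged[-1] = prev
                    continue
        merged.append(_Gap(g.op, g.qpos, g.rpos, g.length))
    return merged


def _intra_features(rec: AlignmentRecord, gap: _Gap, gaps: Sequence[_Gap],
                    min_size: int) -> np.ndarray:
    big = [g for g in gaps if g.length >= min_size]
    nearest = min((abs(g.rpos - gap.rpos) for g in big if g is not gap), default=0)
    read_len = max(rec.read_length, 1)
    seq = rec.read_sequence
    read_bd = base_distribution(seq)
    win = (gap.qpos - 100, gap.qpos + (gap.length if gap.op == CIGAR_I else 0) + 100)
    win_bd = base_distribution(seq, win)
    vec = np.array([
        rec.mapq,
        rec.left_clip,
        rec.right_clip,
        sum(1 for op, _ in rec.cigar if op == CIGAR_I),
        sum(1 for op, _ in rec.cigar if op == CIGAR_D),
        rec.edit_distance if rec.edit_distance is not None else 0,
        rec.read_length,
        rec.aligned_length / read_len,
        len(rec.sa_entries),
        gap.qpos,
        gap.rpos - rec.ref_start,
        gap.length,
        0.0 if gap.op == CIGAR_D else 1.0,
        nearest,
        len(big),
        *read_bd[:4],
        *win_bd[:4],
        read_bd[4],
        win_bd[4],
    ], dtype=float)
    assert vec.shape == (len(INTRA_FEATURES),)
    return vec


def extract_intra_signatures(rec: AlignmentRecord, min_size: int = DEFAULT_MIN_SIZE
                             ) -> list[Signature]:
    """DEL/INS signatures from the CIGAR gaps of one alignment record.

    Nearby same-type gaps are merged first (fragmented evidence from noisy
    reads); signatures shorter than ``min_size`` are dropped. The 25-entry
    feature vector is attached to each signature.
    """
    raw = _collect_gaps(rec)
    gaps = _merge_gaps(raw)
    out = []
    for gap in gaps:
        if gap.length < min_size:
            continue
        if gap.op == CIGAR_D:
            sig = Signature(t="DEL", c=rec.contig, s=gap.rpos, e=gap.rpos + gap.length,
                            read_name=rec.read_name, source="intra", length=gap.length)
        else:
            sig = Signature(t="INS", c=rec.contig, s=gap.rpos, e=gap.rpos + gap.length,
                            read_name=rec.read_name, source="intra", length=gap.length)
        sig.features = _intra_features(rec, gap, gaps, min_size)
        out.append(sig)
    return out


# ---------------------------------------------------------------------------
# inter-alignment (split read) signatures


@dataclass
class _Segment:
    qstart: int
    qend: int
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int
    nm: int
    is_primary: bool


def _segment_from_record(rec: AlignmentRecord) -> _Segment:
    qs, qe = rec.query_interval()
    return _Segment(qs, qe, rec.contig, rec.ref_start, rec.ref_end, rec.strand,
                    rec.mapq, rec.edit_distance or 0, rec.is_primary)


def _segment_from_sa(sa: SAEntry, read_length: int) -> _Segment:
    left = sa.cigar[0][1] if sa.cigar[0][0] in (CIGAR_S, CIGAR_H) else 0
    right = sa.cigar[-1][1] if sa.cigar[-1][0] in (CIGAR_S, CIGAR_H) else 0
    if sa.strand == "-":
        left, right = right, left
    return _Segment(left, read_length - right, sa.contig, sa.pos,
                    sa.pos + cigar_reference_span(sa.cigar), sa.strand,
                    sa.mapq, sa.nm, False)


def read_segments(records: Sequence[AlignmentRecord]) -> list[_Segment]:
    """Aligned segments of one read ordered along the original read.

    Actual supplementary records are preferred; SA-tag entries of the primary
    fill in segments missing from the stream (e.g. regional fetches). Ties in
    query start are broken by reference position.
    """
    primary = [r for r in records if r.is_primary]
    if not primary:
        return []
    segs = [_segment_from_record(r) for r in records]
    seen = {(s.contig, s.ref_start, s.strand) for s in segs}
    read_len = primary[0].read_length
    for sa in primary[0].sa_entries:
        key = (sa.contig, sa.pos, sa.strand)
        if key not in seen:
            segs.append(_segment_from_sa(sa, read_len))
            seen.add(key)
    segs.sort(key=lambda s: (s.qstart, s.ref_start))
    return segs


def _pair_signature(prev: _Segment, nxt: _Segment, primary_strand: str,
                    min_size: int) -> Optional[Signature]:
    read_name = ""  # filled by caller
    if prev.contig != nxt.contig:
        s = prev.ref_end if prev.strand == "+" else prev.ref_start
        p2 = nxt.ref_start if nxt.strand == "+" else nxt.ref_end
        return Signature(t="TRA", c=prev.contig, s=s, e=s, read_name=read_name,
                         source="inter", length=0, c2=nxt.contig, p2=p2)
    if prev.strand != nxt.strand:
        # breakpoints in read order: where prev stops and nxt resumes on the
        # reference; for a read entering or leaving an inverted segment these
        # bracket the inversion exactly
        bp_prev = prev.ref_end if prev.strand == "+" else prev.ref_start
        bp_next = nxt.ref_start if nxt.strand == "+" else nxt.ref_end
        s, e = min(bp_prev, bp_next), max(bp_prev, bp_next)
        return Signature(t="INV", c=prev.contig, s=s, e=e,
                         read_name=read_name, source="inter", length=e - s)
    read_gap = nxt.qstart - prev.qend
    if prev.strand == "+":
        ref_gap = nxt.ref_start - prev.ref_end
    else:
        ref_gap = prev.ref_start - nxt.ref_end
    if ref_gap <= -min_size:
        # reference backtrack: the two segments overlap a region duplicated
        # in the sample relative to the reference
        if prev.strand == "+":
            s, e = nxt.ref_start, prev.ref_end
        else:
            s, e = prev.ref_start, nxt.ref_end
        return Signature(t="DUP", c=prev.contig, s=s, e=e, read_name=read_name,
                         source="inter", length=e - s)
    diff = ref_gap - read_gap
    if diff >= min_size:
        if prev.strand == "+":
            s = prev.ref_end
            e = s + diff
        else:
            e = prev.ref_start
            s = e - diff
        return Signature(t="DEL", c=prev.contig, s=s, e=e, read_name=read_name,
                         source="inter", length=diff)
    if -diff >= min_size:
        s = prev.ref_end if prev.strand == "+" else nxt.ref_end
        return Signature(t="INS", c=prev.contig, s=s, e=s - diff,
                         read_name=read_name, source="inter", length=-diff)
    return None


def _inter_features(prev: _Segment, nxt: _Segment, primary: AlignmentRecord,
                    sig_type: str, n_segments: int) -> np.ndarray:
    supp = nxt if not nxt.is_primary else prev
    read_gap = nxt.qstart - prev.qend
    if prev.contig == nxt.contig and prev.strand == nxt.strand == "+":
        ref_gap = nxt.ref_start - prev.ref_end
    elif prev.contig == nxt.contig and prev.strand == nxt.strand == "-":
        ref_gap = prev.ref_start - nxt.ref_end
    else:
        ref_gap = 0
    bd = base_distribution(primary.read_sequence)
    vec = np.array([
        primary.mapq,
        supp.mapq,
        primary.aligned_length,
        supp.ref_end - supp.ref_start,
        primary.left_clip,
        primary.right_clip,
        primary.edit_distance if primary.edit_distance is not None else 0,
        supp.nm,
        1.0 if prev.contig == nxt.contig else 0.0,
        1.0 if prev.strand == nxt.strand else 0.0,
        read_gap,
        ref_gap,
        ref_gap - read_gap,
        max(0, -read_gap),
        max(0, -ref_gap),
        n_segments - 1,
        TYPE_CODE[sig_type],
        *bd,
    ], dtype=float)
    assert vec.shape == (len(INTER_FEATURES),)
    return vec


def extract_inter_signatures(records: Sequence[AlignmentRecord],
                             min_size: int = DEFAULT_MIN_SIZE) -> list[Signature]:
    """Split-read signatures from all alignments of one read.

    Every adjacent pair of aligned segments in read order is classified by the
    lenient rules; one signature per unordered pair, each carrying its
    22-entry feature vector. A read with fewer than two segments yields
    nothing. Translocations are exempt from the length filter (they have no
    length).
    """
    primary = next((r for r in records if r.is_primary), None)
    if primary is None:
        return []
    segs = read_segments(records)
    if len(segs) < 2:
        return []
    out = []
    for prev, nxt in zip(segs, segs[1:]):
        sig = _pair_signature(prev, nxt, primary.strand, min_size)
        if sig is None:
            continue
        if sig.t != "TRA" and not min_size <= sig.length <= MAX_SV_SIZE:
            continue
        sig.read_name = primary.read_name
        sig.features = _inter_features(prev, nxt, primary, sig.t, len(segs))
        out.append(sig)
    return out


def group_reads(records: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_name, []).append(rec)
    return by_read
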