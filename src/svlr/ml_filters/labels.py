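"""Truth-label generation for filter training.

A signature or cluster is labeled with a truth SV's type when its breakpoints
land within ``tol_bp`` of that SV and the length ratio is within
[tol_frac, 1/tol_frac]; everything unmatched is labeled "false". The label is
taken from the matched truth record, so a rule-inferred INS over a true
duplication trains the models to repair the fuzzy INS/DUP boundary.
"""

from __future__ import annotations

from typing import Optional, Sequence

DEFAULT_TOL_BP = 500
DEFAULT_TOL_FRAC = 0.7


def _distance(item_t: str, s: int, e: int, p2: Optional[int],
              truth) -> float:
    if item_t == "TRA" or truth.type == "TRA":
        d = abs(s - truth.s)
        if p2 is not None and truth.p2 is not None:
            d = max(d, abs(p2 - truth.p2))
        return d
    if item_t == "INS" or truth.type == "INS":
        return abs(s - truth.s)
    return max(abs(s - truth.s), abs(e - truth.e))


def match_to_truth(item_t: str, contig: str, s: int, e: int, length: int,
                   truth_svs: Sequence, tol_bp: int = DEFAULT_TOL_BP,
                   tol_frac: float = DEFAULT_TOL_FRAC,
                   p2: Optional[int] = None, c2: Optional[str] = None):
    """Best-matching truth SV for one item, or None."""
    best = None
    best_d = None
    for tv in truth_svs:
        if tv.contig != contig:
            continue
        if tv.type == "TRA" and c2 is not None and tv.c2 != c2:
            continue
        d = _distance(item_t, s, e, p2, tv)
        if d > tol_bp:
            continue
        if tv.type != "TRA" and item_t != "TRA":
            lo, hi = sorted((max(length, 1), max(tv.length, 1)))
            if lo / hi < tol_frac:
                continue
        if best_d is None or d < best_d:
            best, best_d = tv, d
    return best


def generate_labels(items: Sequence, truth_svs: Sequence,
                    tol_bp: int = DEFAULT_TOL_BP,
                    tol_frac: float = DEFAULT_TOL_FRAC) -> list[str]:
    """Label signatures or clusters against a truth set.

    ``items`` need attributes t/c/s/e/length (signatures) or
    t/c/consensus_s/consensus_e/length (clusters). Empty truth labels
    everything "false".
    """
    labels = []
    for it in items:
        s = getattr(it, "consensus_s", None)
        if s is None:
            s, e = it.s, it.e
            p2 = getattr(it, "p2", None)
        else:
            e = it.consensus_e
            p2 = getattr(it, "consensus_p2", None)
        tv = match_to_truth(it.t, it.c, s, e, it.length, truth_svs,
                            tol_bp=tol_bp, tol_frac=tol_frac, p2=p2,
                            c2=getattr(it, "c2", None))
        labels.append(tv.type if tv is not None else "false")
    return labels
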