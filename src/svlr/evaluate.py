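"""Benchmarking helpers: match calls against an implanted truth set.

Matching follows the usual SV-benchmark conventions: breakpoints within a
tolerance (default 500 bp) and lengths within a ratio band (default
0.7-1.43). INS and DUP are treated as interchangeable — insertion-like
evidence for a tandem duplication is a correct detection, the boundary
between the two is genuinely fuzzy in read space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ml_filters.labels import DEFAULT_TOL_BP, DEFAULT_TOL_FRAC
from .models import SVCall
from .synthetic_data import TruthSV

_EQUIV = {"INS": {"INS", "DUP"}, "DUP": {"INS", "DUP"}}


def _types_match(a: str, b: str) -> bool:
    return a == b or b in _EQUIV.get(a, ())


def _call_len(call: SVCall) -> int:
    return abs(call.svlen)


def _matches(call: SVCall, tv: TruthSV, tol_bp: int, tol_frac: float) -> bool:
    if not _types_match(call.sv_type, tv.type):
        return False
    if call.contig != tv.contig:
        return False
    if tv.type == "TRA":
        if call.mate_contig != tv.c2:
            return False
        return (abs(call.pos - tv.s) <= tol_bp
                and abs((call.mate_pos or 0) - (tv.p2 or 0)) <= tol_bp)
    if call.sv_type == "TRA":
        return False
    if tv.type == "INS" or call.sv_type == "INS":
        close = abs(call.pos - tv.s) <= tol_bp
    else:
        close = (abs(call.pos - tv.s) <= tol_bp
                 and abs(call.end - tv.e) <= tol_bp)
    if not close:
        return False
    lo, hi = sorted((max(_call_len(call), 1), max(tv.length, 1)))
    return lo / hi >= tol_frac


@dataclass
class Benchmark:
    n_truth: int
    n_calls: int
    true_positives: int
    matched_truth: int
    recall: float
    precision: float
    f1: float
    breakpoint_errors: dict  # sv type -> list of |pos error| for matched calls


def benchmark_calls(calls: Sequence[SVCall], truth_svs: Sequence[TruthSV],
                    tol_bp: int = DEFAULT_TOL_BP,
                    tol_frac: float = DEFAULT_TOL_FRAC) -> Benchmark:
    matched_truth = set()
    tp = 0
    bp_err: dict[str, list[int]] = {}
    for call in calls:
        hit = None
        for tv in truth_svs:
            if _matches(call, tv, tol_bp, tol_frac):
                hit = tv
                break
        if hit is not None:
            tp += 1
            matched_truth.add(hit.id)
            bp_err.setdefault(hit.type, []).append(abs(call.pos - hit.s))
    recall = len(matched_truth) / len(truth_svs) if truth_svs else 0.0
    precision = tp / len(calls) if calls else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return Benchmark(n_truth=len(truth_svs), n_calls=len(calls),
                     true_positives=tp, matched_truth=len(matched_truth),
                     recall=recall, precision=precision, f1=f1,
                     breakpoint_errors=bp_err)


def median_breakpoint_error(bench: Benchmark, types: Sequence[str]) -> float:
    errs = []
    for t in types:
        errs.extend(bench.breakpoint_errors.get(t, []))
    return float(np.median(errs)) if errs else float("nan")
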