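"""Two-step adaptive clustering of SV signatures.

Step one partitions type-sorted signatures with a greedy 1000 bp spatial-gap
sweep; step two computes, per partition, a similarity score between signature
pairs

    S(i, j) = (pos_dis / lambda + span_dis) / max(span_i, span_j)

where ``pos_dis`` is the distance between signature midpoints, ``span_dis``
the difference of spans, and ``lambda`` an adaptive scale derived from the
partition's local depth LD and the type's global depth GD (mean LD over all
partitions of that type):

    lambda = |GD - LD| / max(GD, LD) + GD,   clamped to >= 1.

Agglomerative average-linkage clustering then merges signatures while the
linkage distance stays below the 0.3 threshold; consensus breakpoints are the
(lower) medians of member coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .models import Signature

DEFAULT_PARTITION_GAP = 1000
DEFAULT_CLUSTER_THRESHOLD = 0.3
#: nominal span (bp) standing in for the undefined span of breakend evidence;
#: sets the breakpoint-resolution scale at which translocation signatures of
#: one junction still merge despite alignment jitter
DEGENERATE_SPAN_NORM = 100


@dataclass
class Partition:
    """First-step coordinate bucket of same-type signatures."""

    t: str
    c: str
    members: list[Signature]
    c2: Optional[str] = None  # translocations partition on the contig pair

    @property
    def ld(self) -> int:
        return len(self.members)


@dataclass
class DepthStats:
    """Per-type global depth: mean partition size (GD) and partition count."""

    gd: dict[str, float] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)


@dataclass
class SignatureCluster:
    """Second-step cluster with median-consensus breakpoints."""

    t: str
    c: str
    members: list[Signature]
    consensus_s: int = 0
    consensus_e: int = 0
    length: int = 0
    c2: Optional[str] = None
    consensus_p2: Optional[int] = None

    @property
    def support(self) -> int:
        return len({m.read_name for m in self.members})


def _lower_median(values: Sequence[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def spatial_distance(i: Signature, j: Signature) -> int:
    """Partitioning distance between consecutive same-type signatures.

    Breakpoint-interval types (DEL/DUP/INV) measure the gap from the end of
    the earlier signature to the start of the later one, clamped at zero when
    the spans overlap (signatures of one event must never be pushed into
    different partitions, whatever the event size); point-anchored types
    (INS/TRA) measure |s_j - s_i|.
    """
    if i.t != j.t:
        raise ValueError(f"mixed signature types {i.t}/{j.t}")
    if i.t in ("INS", "TRA"):
        return abs(j.s - i.s)
    return max(0, j.s - i.e)


def partition_signatures(sigs: Sequence[Signature],
                         partition_gap: int = DEFAULT_PARTITION_GAP) -> list[Partition]:
    """Greedy left-to-right sweep over (contig, start)-sorted one-type signatures.

    A new partition opens when the contig (or, for TRA, the mate contig)
    changes or the spatial distance to the previous signature exceeds
    ``partition_gap``.
    """
    if not sigs:
        return []
    t = sigs[0].t
    key = lambda s: (s.c, s.c2 or "", s.s)
    ordered = list(sigs)
    if any(key(a) > key(b) for a, b in zip(ordered, ordered[1:])):
        raise ValueError("signatures must be sorted by (contig, start)")
    parts: list[Partition] = []
    current: list[Signature] = [ordered[0]]
    for prev, sig in zip(ordered, ordered[1:]):
        if sig.t != t:
            raise ValueError("partition_signatures expects a single SV type")
        new = (sig.c != prev.c or (sig.c2 or "") != (prev.c2 or "")
               or spatial_distance(prev, sig) > partition_gap)
        if new:
            parts.append(Partition(t=t, c=current[0].c, members=current,
                                   c2=current[0].c2))
            current = [sig]
        else:
            current.append(sig)
    parts.append(Partition(t=t, c=current[0].c, members=current, c2=current[0].c2))
    return parts


def global_depth(partitions: Sequence[Partition]) -> DepthStats:
    """Mean local depth per SV type over that type's partitions."""
    stats = DepthStats()
    by_type: dict[str, list[int]] = {}
    for p in partitions:
        by_type.setdefault(p.t, []).append(p.ld)
    for t, lds in by_type.items():
        stats.gd[t] = float(np.mean(lds))
        stats.n[t] = len(lds)
    return stats


def adaptive_lambda(gd: float, ld: float) -> float:
    """Scale balancing locus vs span distance; >= 1 by construction."""
    if gd <= 0 or ld <= 0:
        raise ValueError("depths must be positive")
    raw = abs(gd - ld) / max(gd, ld) + gd
    return max(1.0, raw)


def signature_similarity(i: Signature, j: Signature, lam: float) -> float:
    """Similarity score S(i, j); lower means more alike. Symmetric.

    Degenerate spans (both zero, e.g. translocation evidence) fall back to
    S = pos_dis / (lambda * DEGENERATE_SPAN_NORM): the nominal span plays the
    role of the missing denominator so breakend evidence merges at realistic
    breakpoint jitter. Translocations measure pos_dis across both breakpoints
    (max of the two locus distances).
    """
    if i.t == "TRA":
        pos_dis = max(abs(i.s - j.s), abs((i.p2 or 0) - (j.p2 or 0)))
        return pos_dis / (lam * DEGENERATE_SPAN_NORM)
    span_i = i.e - i.s
    span_j = j.e - j.s
    pos_dis = abs(i.midpoint - j.midpoint)
    span_dis = abs(span_i - span_j)
    denom = max(span_i, span_j)
    if denom <= 0:
        return pos_dis / (lam * DEGENERATE_SPAN_NORM)
    return (pos_dis / lam + span_dis) / denom


def _consensus(t: str, members: list[Signature]) -> SignatureCluster:
    members = sorted(members, key=lambda m: (m.s, m.e))
    cl = SignatureCluster(t=t, c=members[0].c, members=members)
    cl.consensus_s = _lower_median([m.s for m in members])
    cl.consensus_e = _lower_median([m.e for m in members])
    cl.length = _lower_median([m.length for m in members])
    if t == "TRA":
        cl.c2 = members[0].c2
        cl.consensus_p2 = _lower_median([m.p2 or 0 for m in members])
        cl.consensus_e = cl.consensus_s
    return cl


def cluster_partition(p: Partition, stats: DepthStats,
                      threshold: float = DEFAULT_CLUSTER_THRESHOLD
                      ) -> list[SignatureCluster]:
    """Average-linkage clustering of one partition under the adaptive scale.

    Merging continues while the linkage distance is strictly below
    ``threshold``. Output clusters are ordered by consensus start.
    """
    members = p.members
    if len(members) == 1:
        return [_consensus(p.t, list(members))]
    lam = adaptive_lambda(stats.gd[p.t], p.ld)
    n = len(members)
    dm = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            dm[a, b] = dm[b, a] = signature_similarity(members[a], members[b], lam)
    z = linkage(squareform(dm, checks=False), method="average")
    labels = fcluster(z, t=np.nextafter(threshold, 0.0), criterion="distance")
    groups: dict[int, list[Signature]] = {}
    for lab, sig in zip(labels, members):
        groups.setdefault(lab, []).append(sig)
    clusters = [_consensus(p.t, g) for g in groups.values()]
    clusters.sort(key=lambda c: (c.consensus_s, c.consensus_e))
    return clusters


def cluster_all(sigs_by_type: dict[str, list[Signature]],
                partition_gap: int = DEFAULT_PARTITION_GAP,
                threshold: float = DEFAULT_CLUSTER_THRESHOLD
                ) -> tuple[list[SignatureCluster], DepthStats]:
    """Partition + cluster every type; GD is computed genome-wide per type."""
    all_parts: list[Partition] = []
    for t, sigs in sorted(sigs_by_type.items()):
        ordered = sorted(sigs, key=lambda s: (s.c, s.c2 or "", s.s))
        all_parts.extend(partition_signatures(ordered, partition_gap))
    stats = global_depth(all_parts)
    clusters: list[SignatureCluster] = []
    for part in all_parts:
        clusters.extend(cluster_partition(part, stats, threshold))
    return clusters, stats
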