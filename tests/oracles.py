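"""Independent brute-force oracles used by the test suite.

These re-derive expected results by exhaustive computation and must stay
independent of the implementation paths they check (they share only the
pairwise similarity definition, which the equation-level tests pin down
separately against hand-derived values).
"""

import numpy as np

from svlr.clustering import signature_similarity


def brute_force_average_linkage(members, lam, threshold):
    """Exhaustive nearest-pair agglomerative clustering with average linkage.

    Merges the globally closest pair of clusters while the average of the
    original pairwise dissimilarities stays strictly below ``threshold``.
    Returns the final partition as a set of frozensets of member indices.
    """
    n = len(members)
    d = {(a, b): signature_similarity(members[a], members[b], lam)
         for a in range(n) for b in range(a + 1, n)}
    clusters = [[i] for i in range(n)]

    def avg(ca, cb):
        return float(np.mean([d[tuple(sorted((i, j)))] for i in ca for j in cb]))

    while len(clusters) > 1:
        best = min((avg(clusters[a], clusters[b]), a, b)
                   for a in range(len(clusters))
                   for b in range(a + 1, len(clusters)))
        if best[0] >= threshold:
            break
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def random_del_partition(rng, max_n=12):
    """A random same-type partition with continuous coordinates (no ties)."""
    from svlr.models import Signature

    n = int(rng.integers(2, max_n + 1))
    base = float(rng.uniform(1_000, 5_000))
    sigs = []
    for i in range(n):
        s = base + float(rng.normal(0, 300))
        span = abs(float(rng.normal(200, 120))) + 31
        sigs.append(Signature(t="DEL", c="chr1", s=s, e=s + span,
                              read_name=f"r{i}", source="intra",
                              length=int(span)))
    sigs.sort(key=lambda x: x.s)
    return sigs
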