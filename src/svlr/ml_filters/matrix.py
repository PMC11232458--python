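"""Fixed-size feature matrices for clustered intra-alignment signatures.

A cluster becomes a (100, 25) matrix: one row per member signature (ordered
by start coordinate, zero-filled beyond the cluster size, the 100 members
nearest the consensus breakpoint kept for oversized clusters), columns
min-max normalized to [0, 1] with bounds frozen at training time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..clustering import SignatureCluster
from ..signatures import INTRA_FEATURES

CLUSTER_MATRIX_ROWS = 100
N_INTRA = len(INTRA_FEATURES)
AUGMENT_MAX_DEPTH = 20


@dataclass
class ClusterFeatureMatrix:
    values: np.ndarray  # (100, 25) in [0, 1]
    depth: int
    label: Optional[str] = None  # {"DEL", "INS", "false"} or None


def compute_bounds(vectors: np.ndarray) -> np.ndarray:
    """Per-feature (min, max) over a training set; shape (2, n_features)."""
    return np.vstack([vectors.min(axis=0), vectors.max(axis=0)])


def normalize(vectors: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Min-max scale columns to [0, 1]; constant columns map to 0, out-of-bound
    values (inference time) are clipped."""
    lo, hi = bounds[0], bounds[1]
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (vectors - lo) / safe
    scaled = np.where(span > 0, scaled, 0.0)
    return np.clip(scaled, 0.0, 1.0)


def _member_vectors(cluster: SignatureCluster) -> list[np.ndarray]:
    return [m.features for m in cluster.members
            if m.features is not None and m.features.shape == (N_INTRA,)]


def build_cluster_matrix(cluster: SignatureCluster, bounds: np.ndarray,
                         label: Optional[str] = None) -> ClusterFeatureMatrix:
    members = [m for m in cluster.members if m.features is not None]
    if not members:
        raise ValueError("cluster has no feature-bearing members")
    if len(members) > CLUSTER_MATRIX_ROWS:
        members = sorted(
            members, key=lambda m: abs(m.s - cluster.consensus_s)
        )[:CLUSTER_MATRIX_ROWS]
    members = sorted(members, key=lambda m: (m.s, m.e))
    raw = np.vstack([m.features for m in members])
    scaled = normalize(raw, bounds)
    values = np.zeros((CLUSTER_MATRIX_ROWS, N_INTRA))
    values[: len(members)] = scaled
    return ClusterFeatureMatrix(values=values, depth=len(members), label=label)


def augment_low_depth(cluster: SignatureCluster, bounds: np.ndarray,
                      rng_seed: int, label: Optional[str] = None
                      ) -> list[ClusterFeatureMatrix]:
    """Training-time augmentation for low-depth clusters (depth 1..20).

    Each member is used as a starting row and a window smaller than the
    cluster depth is cut out (wrapping within the member list); depth-1
    clusters yield the single untruncated matrix.
    """
    depth = len(cluster.members)
    if not 1 <= depth <= AUGMENT_MAX_DEPTH:
        raise ValueError(f"augmentation applies to depths 1..{AUGMENT_MAX_DEPTH}, "
                         f"got {depth}")
    if depth == 1:
        return [build_cluster_matrix(cluster, bounds, label=label)]
    rng = np.random.default_rng(rng_seed)
    members = sorted(cluster.members, key=lambda m: (m.s, m.e))
    out = []
    for start in range(depth):
        window = int(rng.integers(1, depth))
        picked = [members[(start + k) % depth] for k in range(window)]
        sub = SignatureCluster(t=cluster.t, c=cluster.c, members=picked,
                               consensus_s=cluster.consensus_s,
                               consensus_e=cluster.consensus_e)
        out.append(build_cluster_matrix(sub, bounds, label=label))
    return out
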