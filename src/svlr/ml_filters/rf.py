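"""Random-forest filter for inter-alignment (split read) signatures.

The model classifies each 22-feature vector into
{DEL, INS, DUP, INV, TRA, false}; "false" predictions are removed before
clustering and type predictions override the rule-inferred type (the
INS/DUP boundary in particular is fuzzy). Hyperparameters are grid-searched
over tree depth 2-10, forest size 10-100 and minimum split size 10-100,
selecting the model with the best held-out macro-F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

from ..models import Signature
from .matrix import compute_bounds, normalize

RF_CLASSES = ("DEL", "INS", "DUP", "INV", "TRA", "false")

GRID_DEPTH = (2, 4, 6, 8, 10)
GRID_TREES = (10, 25, 50, 75, 100)
GRID_MIN_SPLIT = (10, 25, 50, 75, 100)


@dataclass
class RFModel:
    model: RandomForestClassifier
    bounds: np.ndarray  # (2, 22)
    heldout_macro_f1: float
    best_params: dict

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        return self.model.predict(normalize(vectors, self.bounds))


def train_rf(vectors: np.ndarray, labels: Sequence[str], seed: int = 0,
             heldout_fraction: float = 0.25) -> RFModel:
    """Grid-searched random forest on min-max normalized vectors.

    Deterministic for a fixed seed: the split, every candidate fit and the
    tie-break (first best in grid order) are all seeded.
    """
    labels = np.asarray(labels)
    present = set(labels)
    missing = [c for c in RF_CLASSES if c not in present]
    if missing:
        warnings.warn(f"classes absent from training data: {missing}")
    if len(present) < 2:
        raise ValueError("training needs at least two classes")
    bounds = compute_bounds(vectors)
    x = normalize(vectors, bounds)
    x_tr, x_val, y_tr, y_val = train_test_split(
        x, labels, test_size=heldout_fraction, random_state=seed,
        stratify=labels)
    best = None
    for depth in GRID_DEPTH:
        for trees in GRID_TREES:
            for min_split in GRID_MIN_SPLIT:
                clf = RandomForestClassifier(
                    n_estimators=trees, max_depth=depth,
                    min_samples_split=min_split, random_state=seed, n_jobs=1)
                clf.fit(x_tr, y_tr)
                score = f1_score(y_val, clf.predict(x_val), average="macro")
                if best is None or score > best[0]:
                    best = (score, clf,
                            {"max_depth": depth, "n_estimators": trees,
                             "min_samples_split": min_split})
    score, clf, params = best
    return RFModel(model=clf, bounds=bounds, heldout_macro_f1=float(score),
                   best_params=params)


def rf_filter(sigs: Sequence[Signature], rf: RFModel) -> list[Signature]:
    """Drop "false"-predicted inter signatures; relabel the rest to the
    predicted type. Signatures without feature vectors pass through."""
    scored = [s for s in sigs if s.features is not None]
    passthrough = [s for s in sigs if s.features is None]
    if not scored:
        return list(sigs)
    preds = rf.predict(np.vstack([s.features for s in scored]))
    kept = list(passthrough)
    for sig, pred in zip(scored, preds):
        if pred == "false":
            continue
        if pred != sig.t:
            if "TRA" in (pred, sig.t):
                # breakend evidence cannot be re-coordinated into a span type
                # (or vice versa); trust the rule-inferred geometry instead
                kept.append(sig)
                continue
            sig.t = pred
            if pred == "INS":
                sig.e = sig.s + sig.length
        kept.append(sig)
    return kept
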