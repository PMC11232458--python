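"""Serialized filter-model bundles.

A bundle directory holds the random forest (joblib), the CNN weights (npz),
and a JSON metadata file carrying the feature schemas, their hashes, the
normalization bounds, the training seed and the package version. Schema
hashes are checked at load time so a bundle trained against a different
feature layout refuses to load.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from typing import Optional

import joblib
import numpy as np

from .. import __version__
from ..signatures import INTER_FEATURES, INTRA_FEATURES
from .cnn import CNNModel, train_cnn
from .rf import RFModel, train_rf


def schema_hash(names) -> str:
    return hashlib.sha256("|".join(names).encode()).hexdigest()[:16]


class SchemaMismatchError(RuntimeError):
    pass


@dataclass
class FilterModelBundle:
    rf: Optional[RFModel] = None
    cnn: Optional[CNNModel] = None
    cnn_bounds: Optional[np.ndarray] = None  # intra-feature bounds, (2, 25)
    seed: int = 0
    platform: str = "ONT"

    def save(self, path: str) -> str:
        os.makedirs(path, exist_ok=True)
        meta = {
            "version": __version__,
            "seed": self.seed,
            "platform": self.platform,
            "intra_schema": list(INTRA_FEATURES),
            "inter_schema": list(INTER_FEATURES),
            "intra_hash": schema_hash(INTRA_FEATURES),
            "inter_hash": schema_hash(INTER_FEATURES),
        }
        if self.rf is not None:
            joblib.dump(self.rf.model, os.path.join(path, "rf.joblib"))
            np.save(os.path.join(path, "rf_bounds.npy"), self.rf.bounds)
            meta["rf"] = {"heldout_macro_f1": self.rf.heldout_macro_f1,
                          "best_params": self.rf.best_params}
        if self.cnn is not None:
            np.savez(os.path.join(path, "cnn.npz"), **self.cnn.state_dict())
            np.save(os.path.join(path, "cnn_bounds.npy"), self.cnn_bounds)
            meta["cnn"] = {"heldout_accuracy": self.cnn.heldout_accuracy,
                           "final_loss": self.cnn.final_loss}
        with open(os.path.join(path, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        return path

    @classmethod
    def load(cls, path: str) -> "FilterModelBundle":
        with open(os.path.join(path, "meta.json")) as fh:
            meta = json.load(fh)
        if meta["intra_hash"] != schema_hash(INTRA_FEATURES) or \
                meta["inter_hash"] != schema_hash(INTER_FEATURES):
            raise SchemaMismatchError(
                "bundle was trained against a different feature schema")
        bundle = cls(seed=meta.get("seed", 0), platform=meta.get("platform", "ONT"))
        rf_path = os.path.join(path, "rf.joblib")
        if os.path.exists(rf_path):
            model = joblib.load(rf_path)
            bounds = np.load(os.path.join(path, "rf_bounds.npy"))
            bundle.rf = RFModel(model=model, bounds=bounds,
                                heldout_macro_f1=meta["rf"]["heldout_macro_f1"],
                                best_params=meta["rf"]["best_params"])
        cnn_path = os.path.join(path, "cnn.npz")
        if os.path.exists(cnn_path):
            rng = np.random.default_rng(0)
            cnn = CNNModel.build(rng)
            with np.load(cnn_path) as state:
                cnn.load_state_dict(dict(state))
            bundle.cnn = cnn
            bundle.cnn_bounds = np.load(os.path.join(path, "cnn_bounds.npy"))
        return bundle


def train_bundle_from_simulation(seed: int = 0, platform: str = "ONT",
                                 n_genomes: int = 2,
                                 spec_overrides: Optional[dict] = None
                                 ) -> FilterModelBundle:
    """Train both filters on labeled evidence from seeded synthetic genomes.

    Runs signature extraction and clustering on simulated noisy alignments,
    labels everything against the implanted truth, and fits the RF (inter
    vectors) and CNN (intra cluster matrices, with low-depth augmentation).
    """
    # imported here to avoid a cycle: the pipeline imports the filters
    from ..pipeline import collect_signatures
    from ..clustering import cluster_all
    from ..synthetic_data import SimulationSpec, simulate_to_files
    from .labels import generate_labels
    from .matrix import AUGMENT_MAX_DEPTH, augment_low_depth, \
        build_cluster_matrix, compute_bounds
    import tempfile

    inter_vectors, inter_labels = [], []
    cnn_matrices = []
    intra_vec_pool = []

    for g in range(n_genomes):
        spec_kwargs = dict(seed=seed + 1000 * g + 17, platform=platform)
        if spec_overrides:
            spec_kwargs.update(spec_overrides)
        spec = SimulationSpec(**spec_kwargs)
        with tempfile.TemporaryDirectory() as tmp:
            bam, _, truth = simulate_to_files(spec, tmp)
            intra, inter = collect_signatures(bam)
        labels = generate_labels(inter, truth.svs)
        for sig, lab in zip(inter, labels):
            inter_vectors.append(sig.features)
            inter_labels.append(lab)
        by_type: dict[str, list] = {}
        for sig in intra:
            by_type.setdefault(sig.t, []).append(sig)
        clusters, _ = cluster_all(by_type)
        intra_clusters = [c for c in clusters if c.t in ("DEL", "INS")]
        cluster_labels = generate_labels(intra_clusters, truth.svs)
        for sig in intra:
            intra_vec_pool.append(sig.features)
        for ci, (cl, lab) in enumerate(zip(intra_clusters, cluster_labels)):
            lab = lab if lab in ("DEL", "INS") else "false"
            cnn_matrices.append((cl, lab, seed + ci))

    bounds = compute_bounds(np.vstack(intra_vec_pool))
    mats = []
    for cl, lab, aug_seed in cnn_matrices:
        if len(cl.members) <= AUGMENT_MAX_DEPTH:
            mats.extend(augment_low_depth(cl, bounds, rng_seed=aug_seed, label=lab))
        else:
            mats.append(build_cluster_matrix(cl, bounds, label=lab))

    rf = train_rf(np.vstack(inter_vectors), inter_labels, seed=seed)
    cnn = train_cnn(mats, seed=seed)
    return FilterModelBundle(rf=rf, cnn=cnn, cnn_bounds=bounds, seed=seed,
                             platform=platform)
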