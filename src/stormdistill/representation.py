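"""Hint-layer representation analysis.

Compares how different models represent the same input patches at the
32-channel penultimate layer: pooled feature vectors, a joint 2-D UMAP
embedding of several models' features, and per-patch Euclidean distances
between matched feature vectors (e.g. teacher vs hint-learned student
against teacher vs plain student — a leftward shift of the former's distance
histogram indicates the hint-learned student represents inputs more like the
teacher).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FeatureSet:
    """Per-patch pooled hint-layer feature vectors for one model."""

    model_name: str
    vectors: np.ndarray  # (n, d)
    patch_ids: np.ndarray  # (n,)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.patch_ids = np.asarray(self.patch_ids)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be (n_patches, d)")
        if self.patch_ids.shape[0] != self.vectors.shape[0]:
            raise ValueError("one patch id per feature vector required")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def extract_features(
    model,
    patches: np.ndarray,
    pooling: str = "mean",
    stride: int = 8,
    patch_ids=None,
    batch_size: int = 16,
) -> FeatureSet:
    """Reduce hint-layer outputs to fixed-dimension vectors.

    ``mean`` pooling takes the global average of each of the 32 channels
    (d = 32); ``strided_flatten`` subsamples the spatial grid every
    ``stride`` pixels and flattens, preserving coarse spatial layout.
    """
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    feats = []
    for i in range(0, x.shape[0], batch_size):
        h = np.asarray(model.forward_hint(x[i : i + batch_size]), dtype=np.float64)
        if pooling == "mean":
            feats.append(h.mean(axis=(2, 3)))
        elif pooling == "strided_flatten":
            feats.append(h[:, :, ::stride, ::stride].reshape(h.shape[0], -1))
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
    vectors = np.concatenate(feats, axis=0)
    if patch_ids is None:
        patch_ids = np.arange(vectors.shape[0])
    name = getattr(model, "name", type(model).__name__)
    return FeatureSet(model_name=name, vectors=vectors, patch_ids=patch_ids)


def embed_models(
    feature_sets: list[FeatureSet],
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Jointly embed several models' feature vectors into 2-D with UMAP.

    Returns a frame with columns ``patch_id``, ``model``, ``u1``, ``u2``;
    label bookkeeping is lossless and the embedding is deterministic for a
    fixed seed.  UMAP is imported lazily (it JIT-compiles on first use).
    """
    if len(feature_sets) < 2:
        raise ValueError("need at least two feature sets to compare")
    dims = {fs.dim for fs in feature_sets}
    if len(dims) != 1:
        raise ValueError(f"feature sets have mismatched dimensions: {sorted(dims)}")
    import umap  # noqa: PLC0415 - deferred: numba compilation is slow

    stacked = np.concatenate([fs.vectors for fs in feature_sets], axis=0)
    labels = np.concatenate([[fs.model_name] * len(fs.patch_ids) for fs in feature_sets])
    ids = np.concatenate([fs.patch_ids for fs in feature_sets])
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, stacked.shape[0] - 1),
        min_dist=min_dist,
        random_state=rng_seed,
    )
    coords = reducer.fit_transform(stacked)
    return pd.DataFrame(
        {"patch_id": ids, "model": labels, "u1": coords[:, 0], "u2": coords[:, 1]}
    )


def pairwise_distances(set_a: FeatureSet, set_b: FeatureSet) -> np.ndarray:
    """Euclidean distance between matched (same patch id) feature vectors."""
    if set_a.dim != set_b.dim:
        raise ValueError(f"feature dimensions differ: {set_a.dim} vs {set_b.dim}")
    if not np.array_equal(set_a.patch_ids, set_b.patch_ids):
        raise ValueError("patch identifiers are misaligned between the two sets")
    return np.linalg.norm(set_a.vectors - set_b.vectors, axis=1)


def distance_shift_summary(dist_hint: np.ndarray, dist_plain: np.ndarray) -> dict:
    """Summarize two matched distance distributions and their shift.

    ``shift_mean``/``shift_median`` are hint minus plain; negative values
    mean the hint-learned student sits closer to the teacher.
    """
    dh = np.asarray(dist_hint, dtype=float)
    dp = np.asarray(dist_plain, dtype=float)
    if dh.size == 0 or dp.size == 0:
        raise ValueError("distance vectors must be nonempty")
    return {
        "hint_mean": float(dh.mean()),
        "hint_median": float(np.median(dh)),
        "plain_mean": float(dp.mean()),
        "plain_median": float(np.median(dp)),
        "shift_mean": float(dh.mean() - dp.mean()),
        "shift_median": float(np.median(dh) - np.median(dp)),
    }
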