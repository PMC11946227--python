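"""Representative-frame selection by k-means clustering of frame descriptors.

Labeling frames for pose-model training is expensive; consecutive video
frames are highly redundant.  Clustering cheap image descriptors and
keeping one frame per cluster yields a small, diverse labeling set.
The descriptor here is a downsampled, intensity-normalized grayscale
thumbnail; the module's core accepts pre-computed descriptor vectors so
no imaging library is required (Pillow is an optional extra used only
by :func:`descriptor_from_image`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import ValidationError


@dataclass(frozen=True)
class FrameDescriptor:
    frame_index: int
    vector: np.ndarray


def descriptor_from_image(image, frame_index: int = 0, side: int = 32) -> FrameDescriptor:
    """Descriptor for one grayscale frame: area-averaged ``side x side``
    thumbnail, flattened and z-scored (constant images map to the zero
    vector)."""
    from PIL import Image  # optional dependency

    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError("image must be a non-empty 2-D grayscale array")
    small = Image.fromarray(arr).resize((side, side), resample=Image.BOX)
    vec = np.asarray(small, dtype=float).ravel()
    sd = vec.std()
    vec = (vec - vec.mean()) / sd if sd > 0 else np.zeros_like(vec)
    return FrameDescriptor(frame_index=int(frame_index), vector=vec)


def select_representatives(
    descriptors: list[FrameDescriptor], k: int, seed: int = 0
) -> list[int]:
    """Pick ``k`` representative frame indices, one per k-means cluster.

    Descriptors are clustered (seeded init, <=300 iterations, tolerance
    1e-4) after sorting by frame index, so the selection is invariant
    to input order; within each cluster the frame nearest the centroid
    is kept.  Returns the selected indices sorted ascending.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(descriptors):
        raise ValidationError(
            f"k={k} exceeds the number of descriptors ({len(descriptors)})"
        )
    descriptors = sorted(descriptors, key=lambda d: d.frame_index)
    X = np.vstack([np.asarray(d.vector, float) for d in descriptors])
    if len({v.shape for v in (d.vector for d in descriptors)}) > 1:
        raise ValidationError("all descriptor vectors must have equal length")
    idx = np.array([d.frame_index for d in descriptors])
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300, tol=1e-4)
    labels = km.fit_predict(X)
    chosen = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        d2 = np.sum((X[members] - km.cluster_centers_[c]) ** 2, axis=1)
        chosen.append(idx[members[np.argmin(d2)]])
    return sorted(int(i) for i in chosen)


def uniform_representatives(frame_indices: list[int], k: int) -> list[int]:
    """Baseline: ``k`` frames evenly spaced along the sequence."""
    if k < 1 or k > len(frame_indices):
        raise ValidationError("k must satisfy 1 <= k <= n")
    ordered = sorted(frame_indices)
    pick = np.linspace(0, len(ordered) - 1, k).round().astype(int)
    return [int(ordered[i]) for i in pick]
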