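"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) used by the
package implementation so that agreement is meaningful.
"""

import numpy as np


def _neighbor_offsets(ndim: int, connectivity: int):
    """All neighbor offsets for the given connectivity."""
    if ndim == 3:
        max_order = {6: 1, 18: 2, 26: 3}[connectivity]
    else:
        max_order = {4: 1, 8: 2}[connectivity]
    offsets = []
    for delta in np.ndindex(*(3,) * ndim):
        d = tuple(x - 1 for x in delta)
        order = sum(abs(x) for x in d)
        if 0 < order <= max_order and max(abs(x) for x in d) == 1:
            offsets.append(d)
    return offsets


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labels by iterative minimum-label propagation.

    Every solid voxel starts with a unique label; labels repeatedly take
    the minimum over their solid neighborhood until a fixpoint, which is
    exactly the flood-fill partition.
    """
    mask = np.asarray(mask).astype(bool)
    labels = np.where(mask, np.arange(1, mask.size + 1).reshape(mask.shape), 0)
    offsets = _neighbor_offsets(mask.ndim, connectivity)
    while True:
        updated = labels.copy()
        for offset in offsets:
            shifted = labels
            for axis, d in enumerate(offset):
                if d:
                    shifted = np.roll(shifted, d, axis=axis)
                    # zero the wrapped border
                    index = [slice(None)] * mask.ndim
                    index[axis] = 0 if d == 1 else -1
                    shifted = shifted.copy()
                    shifted[tuple(index)] = 0
            neighbor_ok = (shifted > 0) & mask
            updated = np.where(neighbor_ok & ((updated == 0) | (shifted < updated)),
                               shifted, updated)
        updated = np.where(mask, updated, 0)
        if np.array_equal(updated, labels):
            break
        labels = updated
    return labels


def flood_fill_trim(mask: np.ndarray, min_size: int, connectivity: int) -> np.ndarray:
    """Oracle for trim_small_clusters: keep clusters with >= min_size voxels."""
    labels = flood_fill_labels(mask, connectivity)
    out = np.zeros_like(labels, dtype=np.uint8)
    for label in np.unique(labels):
        if label == 0:
            continue
        cluster = labels == label
        if cluster.sum() >= min_size:
            out[cluster] = 1
    return out


def greedy_select_oracle(values: np.ndarray, model_ids, sample_ids,
                         threshold: float):
    """Naive re-implementation of the greedy representative selection.

    Recomputes coverage sets from scratch every round; ties broken by
    lowest mean RMSE over the covered set, then id order.
    """
    remaining = set(range(len(sample_ids)))
    rounds = []
    while remaining:
        candidates = []
        for i, mid in enumerate(model_ids):
            covered = frozenset(j for j in remaining if values[i, j] < threshold)
            if covered:
                mean_rmse = float(np.mean([values[i, j] for j in covered]))
                candidates.append((-len(covered), mean_rmse, mid, i, covered))
        if not candidates:
            break
        candidates.sort(key=lambda c: c[:3])
        _, _, _, i, covered = candidates[0]
        rounds.append((model_ids[i], frozenset(sample_ids[j] for j in covered)))
        remaining -= covered
    uncovered = frozenset(sample_ids[j] for j in remaining)
    return rounds, uncovered
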