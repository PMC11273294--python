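"""Shared voxel-overlap accounting between two label grids."""

from __future__ import annotations

import numpy as np

from .volumes import LabelVolume


def as_voxels(vol: LabelVolume | np.ndarray) -> np.ndarray:
    if isinstance(vol, LabelVolume):
        return vol.voxels
    return np.asarray(vol)


def contingency(
    a: LabelVolume | np.ndarray, b: LabelVolume | np.ndarray
) -> tuple[dict[tuple[int, int], int], dict[int, int], dict[int, int]]:
    """Exact co-occurrence counts of positive labels in two same-shape grids.

    Returns ``(pairs, sizes_a, sizes_b)`` where ``pairs[(ia, ib)]`` is the
    intersection voxel count of instance ``ia`` of ``a`` with ``ib`` of ``b``
    (only nonzero intersections are stored) and the size maps give per-ID
    voxel counts. Background (0) is excluded throughout.
    """
    av = as_voxels(a).ravel()
    bv = as_voxels(b).ravel()
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {as_voxels(a).shape} vs {as_voxels(b).shape}")

    ids_a, counts_a = np.unique(av[av > 0], return_counts=True)
    ids_b, counts_b = np.unique(bv[bv > 0], return_counts=True)
    sizes_a = {int(i): int(c) for i, c in zip(ids_a, counts_a)}
    sizes_b = {int(i): int(c) for i, c in zip(ids_b, counts_b)}

    both = (av > 0) & (bv > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        aa = av[both].astype(np.int64)
        bb = bv[both].astype(np.int64)
        stride = int(bb.max()) + 1
        keys, counts = np.unique(aa * stride + bb, return_counts=True)
        for k, c in zip(keys, counts):
            pairs[(int(k // stride), int(k % stride))] = int(c)
    return pairs, sizes_a, sizes_b
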