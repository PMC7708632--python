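"""Shared 6-connected lattice helpers for Potts sampling and ICM."""

from __future__ import annotations

import numpy as np


def neighbor_class_counts(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-voxel count of 6-neighbours carrying each label 1..K.

    Label 0 (outside the mask) and grid faces contribute to no class, so
    mask-boundary voxels simply have fewer neighbours — no padding.
    """
    counts = np.zeros((n_classes,) + labels.shape, dtype=np.uint8)
    for axis in range(labels.ndim):
        for shift in (1, -1):
            rolled = np.roll(labels, shift, axis=axis)
            sl = [slice(None)] * labels.ndim
            sl[axis] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = 0
            for k in range(1, n_classes + 1):
                counts[k - 1] += rolled == k
    return counts


def checkerboard_parities(shape: tuple[int, ...]) -> list[np.ndarray]:
    """Red/black partition: voxels of one parity are mutually non-adjacent
    under 6-connectivity."""
    par = np.indices(shape).sum(axis=0) % 2
    return [par == 0, par == 1]


def neighbor_agreement(labels: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Fraction of 6-connected in-mask voxel pairs sharing a label."""
    if mask is None:
        mask = labels > 0
    agree = 0
    total = 0
    for axis in range(labels.ndim):
        a = [slice(None)] * labels.ndim
        b = [slice(None)] * labels.ndim
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        la, lb = labels[tuple(a)], labels[tuple(b)]
        valid = mask[tuple(a)] & mask[tuple(b)]
        agree += int((la[valid] == lb[valid]).sum())
        total += int(valid.sum())
    return agree / total if total else float("nan")


def pairwise_disagreement(labels: np.ndarray, mask: np.ndarray) -> int:
    """Number of 6-connected in-mask voxel pairs with differing labels."""
    diff = 0
    for axis in range(labels.ndim):
        a = [slice(None)] * labels.ndim
        b = [slice(None)] * labels.ndim
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        valid = mask[tuple(a)] & mask[tuple(b)]
        diff += int((labels[tuple(a)][valid] != labels[tuple(b)][valid]).sum())
    return diff
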