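"""Replication-domain (RD) segmentation and condition comparison.

Pulse-labeled replication domains are segmented from their channel with a
fixed intensity threshold (32/255 of the dtype maximum), touching objects
are separated by a distance-transform watershed whose seed spacing follows
an "object size guide" volume, and objects below a size-exclusion cutoff
(0.005 µm³, the 3D-SIM resolution limit) are removed.  Counts per nucleus
and pooled per-object volume distributions are then compared between
conditions with two-sided Mann–Whitney tests and Holm correction.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .grids import NM_PER_UM, NucleusMask, VoxelGrid
from .stats import holm_adjust, mann_whitney_two_sided

__all__ = [
    "segment_rds",
    "rd_counts_and_volumes",
    "boxplot_summary",
    "compare_conditions",
    "mann_whitney_two_sided",
    "holm_adjust",
]


def _dtype_max(data: np.ndarray) -> float:
    if np.issubdtype(data.dtype, np.integer):
        return float(np.iinfo(data.dtype).max)
    # floating-point channels follow the package's 0..65535 intensity scale
    return 65535.0


def sphere_radius_um(volume_um3: float) -> float:
    """Radius of a sphere of the given volume."""
    return (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def segment_rds(
    rd_channel: VoxelGrid,
    mask: NucleusMask,
    lower: float = 32.0,
    size_guide_um3: float = 0.002,
    min_volume_um3: float = 0.005,
    nucleus_id: int = 1,
    condition: str = "",
) -> pd.DataFrame:
    """Segment replication domains inside a nuclear mask.

    ``lower`` is the fixed threshold on an 8-bit (0..255) scale, applied as
    ``lower/255`` of the channel's dtype maximum.  Returns one row per
    object: ``object_id, nucleus_id, condition, volume_um3, z, y, x``.
    """
    if not mask.data.any():
        raise ValueError("empty nuclear mask")
    img = np.asarray(rd_channel.data, dtype=np.float64)
    if img.shape != mask.data.shape:
        raise ValueError("RD channel and mask shapes differ")
    thr = (lower / 255.0) * _dtype_max(rd_channel.data)
    binary = (img > thr) & mask.data
    cols = ["object_id", "nucleus_id", "condition", "volume_um3", "z", "y", "x"]
    if not binary.any():
        return pd.DataFrame(columns=cols)

    vox_um = np.array(rd_channel.voxel_size) / NM_PER_UM
    voxel_vol = float(np.prod(vox_um))
    dist = ndimage.distance_transform_edt(binary, sampling=vox_um)

    structure = ndimage.generate_binary_structure(img.ndim, 1)
    cc, _ = ndimage.label(binary, structure=structure)
    guide_radius = sphere_radius_um(size_guide_um3)

    # candidate seeds: local maxima of the (lightly smoothed, to break
    # discrete plateaus) distance map, pruned so that no two seeds lie
    # within the size-guide radius (physical distance)
    dist_s = ndimage.gaussian_filter(dist, sigma=1.0)
    peaks = peak_local_max(dist_s, min_distance=1, labels=cc, exclude_border=False)
    order = np.argsort(dist_s[tuple(peaks.T)])[::-1]
    kept: list[np.ndarray] = []
    kept_um: list[np.ndarray] = []
    for i in order:
        p = peaks[i] * vox_um
        if all(np.linalg.norm(p - q) >= guide_radius for q in kept_um):
            kept.append(peaks[i])
            kept_um.append(p)
    markers = np.zeros(img.shape, dtype=np.int32)
    for j, p in enumerate(kept, start=1):
        markers[tuple(p)] = j
    labels = watershed(-dist_s, markers=markers, mask=binary)

    rows = []
    obj_id = 0
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    centroids = ndimage.center_of_mass(binary, labels, ids) if ids.size else []
    for oid, cnt, com in zip(ids, counts, centroids):
        vol = cnt * voxel_vol
        if vol < min_volume_um3:
            continue
        obj_id += 1
        rows.append(
            {
                "object_id": obj_id,
                "nucleus_id": nucleus_id,
                "condition": condition,
                "volume_um3": vol,
                "z": com[0] if len(com) == 3 else np.nan,
                "y": com[-2],
                "x": com[-1],
            }
        )
    return pd.DataFrame(rows, columns=cols)


def rd_counts_and_volumes(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-nucleus object counts and pooled per-object volumes by condition.

    Returns ``(counts, volumes)``: counts has one row per (condition,
    nucleus), volumes is the pooled per-object table per condition.
    """
    if table.empty:
        raise ValueError("empty RD table")
    counts = (
        table.groupby(["condition", "nucleus_id"], sort=True)
        .size()
        .rename("n_objects")
        .reset_index()
    )
    volumes = table[["condition", "nucleus_id", "object_id", "volume_um3"]].copy()
    return counts, volumes


def boxplot_summary(values) -> dict[str, float]:
    """Median, Tukey hinges (inclusive quartiles) and 1.5×IQR whisker limits.

    Matches the boxplot convention: middle line = median, hinges = 25/75%
    quartiles, whiskers extend to the most extreme points within 1.5×IQR
    of the hinges.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no values")
    med = float(np.median(v))
    half = (v.size + 1) // 2  # inclusive convention: median in both halves when n odd
    lower_half = v[:half]
    upper_half = v[-half:]
    q1 = float(np.median(lower_half))
    q3 = float(np.median(upper_half))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    in_lo = v[v >= lo_fence]
    in_hi = v[v <= hi_fence]
    return {
        "median": med,
        "q1": q1,
        "q3": q3,
        "iqr": iqr,
        "whisker_low": float(in_lo[0]) if in_lo.size else q1,
        "whisker_high": float(in_hi[-1]) if in_hi.size else q3,
        "n": int(v.size),
    }


def compare_conditions(table: pd.DataFrame, metric: str = "volume_um3") -> pd.DataFrame:
    """All pairwise Mann–Whitney contrasts between conditions, Holm-adjusted.

    ``metric`` may be ``"volume_um3"`` (pooled per-object volumes) or
    ``"count"`` (per-nucleus object counts).
    """
    if metric == "count":
        counts, _ = rd_counts_and_volumes(table)
        groups = {c: g["n_objects"].to_numpy() for c, g in counts.groupby("condition")}
    else:
        groups = {c: g[metric].to_numpy() for c, g in table.groupby("condition")}
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p = mann_whitney_two_sided(groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b, "U": u, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out
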