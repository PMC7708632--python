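"""Nucleus segmentation, volume and DNA-content measurement, and
degradation-kinetics trace processing.

Nucleus segmentation mirrors a standard object-finding recipe for DAPI
stacks: Gaussian smoothing, automatic (Otsu) thresholding, connected
components, a dilate / fill-holes / erode cycle to close invaginations, then
removal of small objects (< 200 µm³ by default) and of nuclei touching the
XY field border.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grids import NucleusMask, VoxelGrid


def segment_nuclei(
    dapi: VoxelGrid,
    min_volume_um3: float = 200.0,
    smooth_sigma_nm: float = 300.0,
    dilate_erode_iters: int = 15,
    keep_border: bool = False,
) -> list[NucleusMask]:
    """Segment nuclei from a DAPI channel.

    Parameters
    ----------
    dapi
        Single-channel stack (or plane) with physical voxel size.
    min_volume_um3
        Minimum object size; smaller components are dropped.
    smooth_sigma_nm
        Gaussian pre-smoothing, physical units (honours anisotropy).
    dilate_erode_iters
        Iterations for the dilate -> fill holes -> erode cycle.
    keep_border
        If False (default), nuclei touching the XY image border are removed.
    """
    img = np.asarray(dapi.data, dtype=np.float64)
    if img.size == 0 or img.max() == img.min():
        return []
    sigma_vox = [smooth_sigma_nm / v for v in dapi.voxel_size]
    smoothed = ndimage.gaussian_filter(img, sigma=sigma_vox)
    binary = smoothed > threshold_otsu(smoothed)
    if not binary.any():
        return []

    structure = ndimage.generate_binary_structure(img.ndim, 1)
    if dilate_erode_iters > 0:
        # pad so the cycle is symmetric at the image faces (otherwise the
        # erosion eats objects back from faces where dilation was clipped)
        pad = dilate_erode_iters + 1
        binary = np.pad(binary, pad)
        binary = ndimage.binary_dilation(binary, structure, iterations=dilate_erode_iters)
        binary = ndimage.binary_fill_holes(binary)
        binary = ndimage.binary_erosion(binary, structure, iterations=dilate_erode_iters)
        binary = binary[tuple(slice(pad, -pad) for _ in range(binary.ndim))]
    else:
        binary = ndimage.binary_fill_holes(binary)

    labeled, n = ndimage.label(binary, structure=structure)
    voxel_vol = float(np.prod([v / 1000.0 for v in dapi.voxel_size]))
    masks: list[NucleusMask] = []
    nucleus_id = 0
    for i in range(1, n + 1):
        comp = labeled == i
        if comp.sum() * voxel_vol < min_volume_um3:
            continue
        touching = _touches_xy_border(comp)
        if touching and not keep_border:
            continue
        nucleus_id += 1
        masks.append(
            NucleusMask(comp, dapi.voxel_size, nucleus_id=nucleus_id, border_touching=touching)
        )
    return masks


def _touches_xy_border(mask: np.ndarray) -> bool:
    """True if the object reaches the first/last index along Y or X.

    Z truncation is normal in confocal/SIM stacks and is not penalised.
    """
    axes = range(mask.ndim)[-2:]
    for ax in axes:
        first = [slice(None)] * mask.ndim
        last = [slice(None)] * mask.ndim
        first[ax] = 0
        last[ax] = -1
        if mask[tuple(first)].any() or mask[tuple(last)].any():
            return True
    return False


def nuclear_volume(mask: NucleusMask) -> float:
    """Nuclear volume in µm³: voxel count times physical voxel volume."""
    return mask.volume_um3


def modal_background(img: np.ndarray, bins: int = 256) -> float:
    """Modal gray value of a frame, from a 256-bin histogram over its range."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return lo
    hist, edges = np.histogram(img, bins=bins, range=(lo, hi))
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2.0)


def integrated_dna_content(dapi: VoxelGrid, mask: NucleusMask) -> float:
    """Integrated background-subtracted DAPI intensity over a nucleus.

    The background is the modal gray value of the full frame; per-voxel
    background-subtracted intensities are clipped at zero before summing.
    """
    img = np.asarray(dapi.data, dtype=np.float64)
    if img.shape != mask.data.shape:
        raise ValueError("mask and image shapes differ")
    if not mask.data.any():
        return 0.0
    bg = modal_background(img)
    return float(np.clip(img[mask.data] - bg, 0.0, None).sum())


def nucleus_table(dapi: VoxelGrid, masks: list[NucleusMask]) -> pd.DataFrame:
    """Per-nucleus summary: volume, DNA content, border flag."""
    rows = [
        {
            "nucleus_id": m.nucleus_id,
            "volume_um3": nuclear_volume(m),
            "dna_content": integrated_dna_content(dapi, m),
            "border_flag": m.border_touching,
        }
        for m in masks
    ]
    return pd.DataFrame(rows, columns=["nucleus_id", "volume_um3", "dna_content", "border_flag"])


# ---------------------------------------------------------------------------
# degradation-kinetics traces


def filter_and_normalize_traces(
    traces: pd.DataFrame,
    min_start: float = 50.0,
    window: int = 5,
    quantile: float = 0.90,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Start-intensity filter, per-cell normalisation, and fluctuation filter.

    Processing per the standard time-lapse quantitation recipe:

    1. cells whose starting intensity is not above ``min_start`` counts are
       excluded;
    2. each retained trace is normalised to its first value;
    3. each cell's fluctuation is the maximum relative deviation from its own
       centered rolling mean of ``window`` timepoints (truncated at the trace
       ends); cells whose fluctuation strictly exceeds the across-cell
       ``quantile`` (default 90%) are excluded.

    Returns ``(retained, report)``; ``retained`` has an added ``normalized``
    column, ``report`` lists excluded cells with the exclusion reason.
    """
    if traces.empty:
        raise ValueError("need at least one trace")
    traces = traces.sort_values(["cell_id", "t_index"])
    excluded: list[dict] = []

    starts = traces.groupby("cell_id")["intensity"].first()
    low = starts[starts <= min_start].index
    for cid in low:
        excluded.append({"cell_id": cid, "reason": "start_below_min", "value": starts[cid]})
    kept = traces[~traces["cell_id"].isin(low)].copy()
    if kept.empty:
        return kept.assign(normalized=pd.Series(dtype=float)), pd.DataFrame(excluded)

    kept["normalized"] = kept.groupby("cell_id")["intensity"].transform(lambda s: s / s.iloc[0])

    def _fluct(s: pd.Series) -> float:
        roll = s.rolling(window, center=True, min_periods=1).mean()
        return float((np.abs(s - roll) / roll).max())

    fluct = kept.groupby("cell_id")["normalized"].apply(_fluct)
    cutoff = float(np.quantile(fluct.to_numpy(), 0.90 if quantile is None else quantile))
    noisy = fluct[fluct > cutoff].index
    for cid in noisy:
        excluded.append({"cell_id": cid, "reason": "fluctuation_above_quantile", "value": fluct[cid]})
    retained = kept[~kept["cell_id"].isin(noisy)].copy()
    report = pd.DataFrame(excluded, columns=["cell_id", "reason", "value"])
    return retained, report
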