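"""Marker enrichment/depletion over chromatin-compaction classes.

For a segmented marker channel (nuclear speckles, RNA Pol II, H3K27me3, ...)
each marker-positive voxel is mapped onto the compaction class of its
position.  With ``f_k`` the fraction of in-mask voxels in class k (the DAPI
baseline, both normalised to 1) and ``m_k`` the intensity-weighted fraction
of marker signal in class k, the enrichment statistic is the
percentage-point difference

    delta_k = 100 * (m_k - f_k).

Positive values mean over-representation of the marker in class k relative
to a random distribution over the nuclear volume, negative values relative
depletion; the deltas sum to zero by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .grids import NucleusMask, VoxelGrid
from .hmrf import ClassField, class_profile


@dataclass
class MarkerSegmentation:
    """Marker-positive voxels inside the nuclear mask."""

    coords: np.ndarray  # (n, ndim) voxel indices
    intensities: np.ndarray  # (n,)
    threshold: float
    marker: str = ""

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]


@dataclass
class EnrichmentProfile:
    """Per-class enrichment of one marker in one nucleus."""

    dapi_fraction: np.ndarray  # f_k, sums to 1
    marker_fraction: np.ndarray  # m_k, sums to 1
    delta: np.ndarray  # 100 * (m_k - f_k), sums to 0
    nucleus_id: int = 1
    marker: str = ""

    @property
    def n_classes(self) -> int:
        return self.delta.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": np.arange(1, self.n_classes + 1),
                "f": self.dapi_fraction,
                "m": self.marker_fraction,
                "delta": self.delta,
            }
        )


def segment_marker(
    marker: VoxelGrid,
    mask: NucleusMask,
    threshold_factor: float = 1.0,
) -> MarkerSegmentation:
    """Threshold a marker channel inside the nuclear mask.

    The threshold is ``threshold_factor`` times the Otsu threshold of the
    in-mask marker intensities (an automatic, reproducible stand-in for
    semi-automatic interactive thresholding); voxels strictly above it are
    retained with their intensities.
    """
    img = np.asarray(marker.data, dtype=np.float64)
    if img.shape != mask.data.shape:
        raise ValueError("marker grid and mask shapes differ")
    vals = img[mask.data]
    if vals.size == 0:
        raise ValueError("empty nuclear mask")
    if np.all(vals == 0):
        warnings.warn(f"marker channel {marker.channel!r} is all zero inside the mask")
        return MarkerSegmentation(
            np.empty((0, img.ndim), dtype=int), np.empty(0), threshold=0.0, marker=marker.channel
        )
    thr = threshold_factor * float(threshold_otsu(vals))
    sel = mask.data & (img > thr)
    coords = np.argwhere(sel)
    return MarkerSegmentation(coords, img[sel], threshold=thr, marker=marker.channel)


def enrichment_profile(
    seg: MarkerSegmentation,
    field: ClassField,
    intensity_weighted: bool = True,
    nucleus_id: int = 1,
) -> EnrichmentProfile:
    """Per-class percentage-point enrichment of a marker segmentation.

    The DAPI baseline ``f_k`` uses unweighted voxel counts; the marker share
    ``m_k`` is intensity-weighted by default (``intensity_weighted=False``
    switches to plain voxel counting on the marker side as well).
    """
    if seg.n_voxels == 0:
        raise ValueError("no marker signal: empty segmentation")
    K = field.n_classes
    labels = field.labels[tuple(seg.coords.T)]
    if np.any(labels == 0):
        raise ValueError("marker voxels fall outside the class-field mask")
    weights = seg.intensities if intensity_weighted else np.ones(seg.n_voxels)
    sums = np.bincount(labels.astype(int), weights=weights, minlength=K + 1)[1:]
    m = sums / sums.sum()
    f = class_profile(field)
    return EnrichmentProfile(
        dapi_fraction=f,
        marker_fraction=m,
        delta=100.0 * (m - f),
        nucleus_id=nucleus_id,
        marker=seg.marker,
    )


def aggregate_profiles(profiles: list[EnrichmentProfile]) -> pd.DataFrame:
    """Across-nuclei mean ± SEM of the per-class deltas (and mean baseline).

    Calculations are done per nucleus; only the averaging happens here.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    K = profiles[0].n_classes
    if any(p.n_classes != K for p in profiles):
        raise ValueError("profiles have mixed class counts")
    deltas = np.vstack([p.delta for p in profiles])
    fs = np.vstack([p.dapi_fraction for p in profiles])
    n = deltas.shape[0]
    sem = deltas.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(K)
    return pd.DataFrame(
        {
            "class": np.arange(1, K + 1),
            "mean_delta": deltas.mean(axis=0),
            "sem_delta": sem,
            "mean_f": fs.mean(axis=0),
        }
    )
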