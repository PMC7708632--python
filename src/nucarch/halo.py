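"""DNA-halo loop-size quantification.

After high-salt histone extraction, chromatin loops extrude from a residual
nuclear scaffold; on a 2D image the bright scaffold (area As) sits inside a
fainter DNA halo (total area At).  The halo area is Ah = At - As and the
halo radius — the loop-size readout — is R = sqrt(Ah / pi).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .grids import NM_PER_UM, VoxelGrid
from .stats import mann_whitney_two_sided


@dataclass
class HaloMeasurement:
    """Areas (µm²) and derived halo radius (µm) for one cell."""

    At: float
    As: float
    cell_id: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        if self.At < self.As:
            raise ValueError("total area At must be >= scaffold area As")
        if self.As < 0:
            raise ValueError("areas must be non-negative")

    @property
    def Ah(self) -> float:
        return self.At - self.As

    @property
    def R(self) -> float:
        return math.sqrt(self.Ah / math.pi)


def halo_radius(At: float, As: float, cell_id: int = 1, condition: str = "") -> HaloMeasurement:
    """Exact evaluation of Ah = At - As and R = sqrt(Ah/pi)."""
    return HaloMeasurement(At=At, As=As, cell_id=cell_id, condition=condition)


def segment_halo(
    image: VoxelGrid,
    scaffold_mask: np.ndarray | None = None,
    total_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Segment total (At) and scaffold (As) areas from a single-cell image.

    Two-level (three-class) Otsu thresholding replaces the manual outlining
    of the original assay: the lower threshold separates background from
    halo and delimits the total area, the upper one separates halo from the
    bright scaffold.  Both regions are hole-filled.  Externally provided
    masks override either threshold to mimic the manual segmentation path.

    Returns ``(At, As)`` in µm².
    """
    img = np.asarray(image.data, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("halo images must be 2D")
    pixel_area = float(np.prod([v / NM_PER_UM for v in image.voxel_size]))

    if total_mask is None or scaffold_mask is None:
        if img.max() == img.min():
            warnings.warn("uniform blank image: no halo or scaffold found")
            return 0.0, 0.0
        try:
            t_low, t_high = threshold_multiotsu(img, classes=3)
        except ValueError:  # fewer than 3 distinct gray levels: core only
            t_low = t_high = threshold_otsu(img)
        auto_total = ndimage.binary_fill_holes(img > t_low)
        auto_scaffold = ndimage.binary_fill_holes(img > t_high)
        if total_mask is None:
            total_mask = auto_total
        if scaffold_mask is None:
            scaffold_mask = auto_scaffold

    At = float(np.count_nonzero(total_mask)) * pixel_area
    As = float(np.count_nonzero(scaffold_mask)) * pixel_area
    if As > At:
        raise ValueError("inconsistent thresholds: scaffold area exceeds total area")
    return At, As


def measure_halo(
    image: VoxelGrid, cell_id: int = 1, condition: str = ""
) -> HaloMeasurement:
    """Segment one halo image and derive its radius."""
    At, As = segment_halo(image)
    return halo_radius(At, As, cell_id=cell_id, condition=condition)


def compare_halo(groups: dict[str, list[HaloMeasurement]]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum comparison of halo radii."""
    for name, ms in groups.items():
        if not ms:
            raise ValueError(f"condition {name!r} has no measurements")
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra = [m.R for m in groups[a]]
            rb = [m.R for m in groups[b]]
            u, p = mann_whitney_two_sided(ra, rb)
            rows.append({"group_a": a, "group_b": b, "U": u, "p": p})
    return pd.DataFrame(rows)


def measurements_table(measurements: list[HaloMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": m.cell_id,
                "condition": m.condition,
                "At_um2": m.At,
                "As_um2": m.As,
                "Ah_um2": m.Ah,
                "R_um": m.R,
            }
            for m in measurements
        ]
    )
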