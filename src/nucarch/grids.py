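"""Core image containers.

All 3D arrays are indexed ``(z, y, x)`` and 2D arrays ``(y, x)``; physical
voxel dimensions are stored in nanometres in the same axis order.  The default
sampling of 125 nm axially and 40 nm laterally matches 3D-SIM reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NM_PER_UM = 1000.0

#: default SIM-like voxel size in nm, (z, y, x)
DEFAULT_VOXEL_SIZE = (125.0, 40.0, 40.0)


@dataclass
class VoxelGrid:
    """A single-channel intensity grid with physical voxel dimensions.

    Parameters
    ----------
    data
        Intensity array, ``(z, y, x)`` for stacks or ``(y, x)`` for single
        planes.  Floating point on a 0..65535 scale by convention.
    voxel_size
        Physical size of one voxel in nm, one entry per array axis.
    channel
        Channel identity, e.g. ``"DAPI"``, ``"SC35"``, ``"RD"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, ...]
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.data.ndim:
            raise ValueError(
                f"voxel_size has {len(self.voxel_size)} entries for a "
                f"{self.data.ndim}-dimensional grid"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def voxel_volume_um3(self) -> float:
        """Volume (3D) or area (2D) of one voxel in µm³ (µm²)."""
        return float(np.prod([v / NM_PER_UM for v in self.voxel_size]))

    def like(self, data: np.ndarray, channel: str | None = None) -> "VoxelGrid":
        """A new grid sharing this grid's geometry."""
        return VoxelGrid(data, self.voxel_size, self.channel if channel is None else channel)


@dataclass
class NucleusMask:
    """Boolean nuclear mask on a voxel grid.

    ``border_touching`` flags masks whose support reaches the XY image
    border; such nuclei are truncated by the field of view and are excluded
    from population statistics.
    """

    data: np.ndarray
    voxel_size: tuple[float, ...]
    nucleus_id: int = 1
    border_touching: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod([v / NM_PER_UM for v in self.voxel_size]))

    @property
    def volume_um3(self) -> float:
        return self.n_voxels * self.voxel_volume_um3
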