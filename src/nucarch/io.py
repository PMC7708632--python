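"""Readers and writers for the package's on-disk formats.

Images travel as (OME-)TIFF via :mod:`tifffile`; contact matrices as sparse
upper-triangle triplet text (``bin_i<TAB>bin_j<TAB>count``, 0-based bins)
with a chrom.sizes companion; per-bin tracks as bedGraph (0-based,
half-open); loop lists as BEDPE; traces and object tables as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .compartments import ContactMatrix, TrackSet
from .grids import VoxelGrid


# ---------------------------------------------------------------------------
# images


def write_ome_tiff(path, channels: dict[str, VoxelGrid]) -> None:
    """Write a multi-channel Z-stack with channel names and voxel size."""
    names = list(channels)
    grids = [channels[n] for n in names]
    shape0 = grids[0].shape
    if any(g.shape != shape0 for g in grids):
        raise ValueError("all channels must share one grid shape")
    stack = np.stack([g.data for g in grids]).astype(np.float32)
    vz, vy, vx = (grids[0].voxel_size + (1.0,) * 3)[:3]
    metadata = {
        "axes": "CZYX" if stack.ndim == 4 else "CYX",
        "Channel": {"Name": names},
        "PhysicalSizeX": vx / 1000.0,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": vy / 1000.0,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": vz / 1000.0,
        "PhysicalSizeZUnit": "µm",
    }
    tifffile.imwrite(path, stack, metadata=metadata, ome=True)


def read_ome_tiff(path) -> dict[str, VoxelGrid]:
    """Read back a multi-channel stack written by :func:`write_ome_tiff`."""
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        ome = tf.ome_metadata or ""
    import re

    names = re.findall(r'Channel[^>]*Name="([^"]+)"', ome)
    sizes = {ax: float(m) for ax, m in re.findall(r'PhysicalSize([XYZ])="([^"]+)"', ome)}
    if stack.ndim == 3 and len(names) == stack.shape[0]:
        planes = stack
        voxel = (sizes.get("Y", 1.0) * 1000.0, sizes.get("X", 1.0) * 1000.0)
    else:
        planes = stack.reshape((stack.shape[0],) + stack.shape[-3:]) if stack.ndim >= 4 else stack[None]
        voxel = (
            sizes.get("Z", 1.0) * 1000.0,
            sizes.get("Y", 1.0) * 1000.0,
            sizes.get("X", 1.0) * 1000.0,
        )
    if not names:
        names = [f"ch{i}" for i in range(planes.shape[0])]
    return {n: VoxelGrid(planes[i], voxel, n) for i, n in enumerate(names)}


def write_label_tiff(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16), photometric="minisblack")


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# contact matrices


def write_contact_triplets(path, m: ContactMatrix) -> None:
    """Upper-triangle sparse triplet text: ``bin_i<TAB>bin_j<TAB>count``."""
    iu, ju = np.triu_indices(m.n_bins)
    vals = m.matrix[iu, ju]
    keep = vals != 0
    pd.DataFrame({"bin_i": iu[keep], "bin_j": ju[keep], "count": vals[keep]}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_contact_triplets(path, n_bins: int, resolution: int, chrom: str = "chr1") -> ContactMatrix:
    df = pd.read_csv(path, sep="\t", header=None, names=["bin_i", "bin_j", "count"])
    mat = np.zeros((n_bins, n_bins))
    mat[df["bin_i"], df["bin_j"]] = df["count"]
    mat[df["bin_j"], df["bin_i"]] = df["count"]
    return ContactMatrix(mat, resolution=resolution, chrom=chrom)


def write_chrom_sizes(path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            chrom, size = line.split("\t")
            out[chrom] = int(size)
    return out


# ---------------------------------------------------------------------------
# tracks and loops


def write_bedgraph(path, values: np.ndarray, resolution: int, chrom: str) -> None:
    """0-based half-open bedGraph; NaN bins are skipped."""
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(values, dtype=float)):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{i * resolution}\t{(i + 1) * resolution}\t{v:.6g}\n")


def read_bedgraph(path, n_bins: int, resolution: int) -> np.ndarray:
    values = np.full(n_bins, np.nan)
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    values[(df["start"] // resolution).to_numpy()] = df["value"].to_numpy()
    return values


def write_bedpe(path, loops, resolution: int, chrom: str) -> None:
    with open(path, "w") as fh:
        for i, j in loops:
            fh.write(
                f"{chrom}\t{i * resolution}\t{(i + 1) * resolution}\t"
                f"{chrom}\t{j * resolution}\t{(j + 1) * resolution}\n"
            )


def read_bedpe(path, resolution: int) -> list[tuple[int, int]]:
    loops = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        loops.append((int(f[1]) // resolution, int(f[4]) // resolution))
    return loops


def write_trackset(path, tracks: TrackSet) -> None:
    tracks.tracks.to_csv(path, index=False)


def read_trackset(path, resolution: int, chrom: str = "chr1") -> TrackSet:
    return TrackSet(pd.read_csv(path), resolution=resolution, chrom=chrom)
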