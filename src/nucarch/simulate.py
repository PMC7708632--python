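"""Synthetic 3D microscopy scenes with exported ground truth.

Every generator here emulates one class of input the analysis pipeline
consumes, so that each downstream measurement can be validated against a
known truth:

* :func:`generate_nucleus_scene` — a DAPI-like stack whose in-mask voxel
  intensities arise from K equal-variance Gaussian emission classes on a
  spatially coherent Potts label field, with an interchromatin channel
  network (class 1), a compacted heterochromatin rim (high classes), optional
  multilobulated shapes, marker channels with per-class enrichment, and a
  replication-domain channel of spherical foci.
* :func:`generate_halo_scene` — a 2D DNA-halo image (bright scaffold disc
  inside a fainter halo disc) with analytic truth areas.
* :func:`generate_decay_traces` — single-cell degradation time courses with
  exponential responders and a non-responder fraction.

All generators are deterministic for a fixed (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._lattice import checkerboard_parities, neighbor_agreement, neighbor_class_counts
from .grids import DEFAULT_VOXEL_SIZE, NM_PER_UM, VoxelGrid

__all__ = [
    "NoiseModel",
    "MarkerSpec",
    "RdSpec",
    "NucleusSceneSpec",
    "SceneTruth",
    "sample_potts_field",
    "neighbor_agreement",
    "generate_nucleus_scene",
    "generate_halo_scene",
    "generate_decay_traces",
    "DEFAULT_PSF_FWHM",
]

_SQRT8LN2 = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM -> sigma divisor

# ---------------------------------------------------------------------------
# specs


@dataclass
class NoiseModel:
    """Additive Gaussian and/or Poisson photon noise on a channel."""

    gaussian_sd: float = 0.0
    poisson_scale: float | None = None  # counts per intensity unit; None = off

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = img
        if self.poisson_scale:
            out = rng.poisson(np.clip(out, 0, None) * self.poisson_scale) / self.poisson_scale
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass
class MarkerSpec:
    """A marker channel with configurable per-class emission preference.

    ``class_weights[k-1]`` is the relative probability that a voxel of
    compaction class ``k`` carries marker signal; ``density`` is the target
    overall fraction of in-mask voxels that are marker-positive.
    """

    name: str
    class_weights: tuple[float, ...]
    density: float = 0.05
    intensity: float = 20000.0


@dataclass
class RdSpec:
    """Replication-domain channel: spherical foci in an S-phase pattern."""

    pattern: str = "early"  # early | mid | late
    n_objects: int = 30
    mean_volume_um3: float = 0.05
    sigma_log: float = 0.25
    intensity: float = 20000.0
    min_separation_um: float = 0.6


@dataclass
class NucleusSceneSpec:
    """Full specification of one synthetic nucleus scene.

    Defaults emulate 3D-SIM sampling (40 nm lateral / 125 nm axial voxels)
    of a nucleus whose chromatin compaction is discretised into K = 7
    intensity classes of equal emission variance on a Potts label field.
    """

    grid_shape: tuple[int, int, int] = (32, 128, 128)  # (z, y, x)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE  # nm
    n_lobes: int = 1
    lobe_semiaxes_um: tuple[float, float, float] = (1.4, 2.0, 2.0)
    class_means: tuple[float, ...] = tuple(np.linspace(8000.0, 56000.0, 7))
    class_sigma: float = 4000.0  # half the inter-mean gap of the defaults
    potts_beta: float = 1.2
    gibbs_sweeps: int = 30
    rim_thickness: float = 120.0  # nm
    ic_channel_fraction: float = 0.15
    marker_specs: tuple[MarkerSpec, ...] = ()
    rd_spec: RdSpec | None = None
    psf_fwhm: tuple[float, float, float] | None = None  # nm (z, y, x)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_means)

    def validate(self) -> None:
        means = np.asarray(self.class_means, dtype=float)
        if means.size < 2 or np.any(np.diff(means) <= 0):
            raise ValueError("class_means must be strictly increasing with K >= 2")
        if self.class_sigma < 0 or self.potts_beta < 0:
            raise ValueError("class_sigma and potts_beta must be non-negative")
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")
        if not 0.0 <= self.ic_channel_fraction < 1.0:
            raise ValueError("ic_channel_fraction must be in [0, 1)")
        for m in self.marker_specs:
            if len(m.class_weights) != self.n_classes:
                raise ValueError(f"marker {m.name!r}: need {self.n_classes} class weights")
            if any(w < 0 for w in m.class_weights):
                raise ValueError(f"marker {m.name!r}: weights must be >= 0")
        if self.rd_spec is not None and self.rd_spec.pattern not in ("early", "mid", "late"):
            raise ValueError("rd pattern must be early, mid or late")


@dataclass
class SceneTruth:
    """Ground truth exported with every scene."""

    label_field: np.ndarray  # true class per voxel, 0 outside the nucleus
    mask: np.ndarray  # true nuclear mask
    true_class_fractions: np.ndarray  # K values summing to 1
    marker_truth: dict[str, np.ndarray]  # per-marker per-class signal fractions
    rd_truth: pd.DataFrame  # columns: z, y, x (voxels), radius_um, volume_um3


# ---------------------------------------------------------------------------
# Potts sampling (6-connected, checkerboard Gibbs)


def sample_potts_field(
    mask: np.ndarray,
    n_classes: int,
    beta: float,
    sweeps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a K-state Potts label field inside ``mask`` by Gibbs sweeps.

    Uses checkerboard (red/black) updates, which are exact for the
    6-connected neighbourhood: voxels of one parity are conditionally
    independent given the other.  ``beta = 0`` yields i.i.d. uniform labels.
    """
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[mask] = rng.integers(1, n_classes + 1, size=int(mask.sum()), dtype=np.int8)
    if beta == 0 or sweeps == 0:
        return labels
    parities = checkerboard_parities(mask.shape)
    for _ in range(sweeps):
        for par in parities:
            upd = par & mask
            counts = neighbor_class_counts(labels, n_classes)
            logits = beta * counts[:, upd].astype(np.float64)  # (K, n)
            logits -= logits.max(axis=0, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=0, keepdims=True)
            u = rng.random(probs.shape[1])
            new = (u > np.cumsum(probs, axis=0)).sum(axis=0) + 1
            labels[upd] = new.astype(np.int8)
    return labels


# ---------------------------------------------------------------------------
# scene assembly


def _make_lobed_mask(spec: NucleusSceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of ``n_lobes`` ellipsoids, smoothed by morphological closing."""
    shape = spec.grid_shape
    vox_um = np.array(spec.voxel_size) / NM_PER_UM
    semi = np.array(spec.lobe_semiaxes_um, dtype=float)
    extent_um = np.array(shape) * vox_um
    center = extent_um / 2.0

    centers = [center]
    for _ in range(spec.n_lobes - 1):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        # overlapping lobes: offset by ~0.9 of the semi-axis along the direction
        offset = direction * semi * 0.9
        centers.append(center + offset)

    coords = [np.arange(n) * v + v / 2.0 for n, v in zip(shape, vox_um)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    for c in centers:
        d2 = (
            ((zz - c[0]) / semi[0]) ** 2
            + ((yy - c[1]) / semi[1]) ** 2
            + ((xx - c[2]) / semi[2]) ** 2
        )
        mask |= d2 <= 1.0
        if np.any((c - semi) < 0) or np.any((c + semi) > extent_um):
            raise ValueError("nucleus does not fit inside the grid")
    mask = ndimage.binary_closing(mask, structure=ndimage.generate_binary_structure(3, 1), iterations=2)
    if not mask.any():
        raise ValueError("empty nuclear mask; check lobe semi-axes vs grid size")
    return mask


def _carve_scene_labels(
    spec: NucleusSceneSpec, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Potts field + heterochromatin rim + interchromatin channels."""
    K = spec.n_classes
    labels = sample_potts_field(mask, K, spec.potts_beta, spec.gibbs_sweeps, rng)

    # compacted rim: distance-to-boundary below rim_thickness -> classes K-1/K
    # in spatially coherent patches (peripheral heterochromatin is contiguous,
    # not voxel-wise salt and pepper)
    dist_nm = ndimage.distance_transform_edt(mask, sampling=spec.voxel_size)
    rim = mask & (dist_nm <= spec.rim_thickness) & (dist_nm > 0)
    if rim.any():
        patch = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=(1.0, 3.0, 3.0))
        labels[rim] = np.where(patch[rim] > 0, K, K - 1)

    # interchromatin channels: a smooth random field thresholded so that the
    # total class-1 share approaches ic_channel_fraction
    if spec.ic_channel_fraction > 0:
        noise = rng.standard_normal(mask.shape)
        smooth = ndimage.gaussian_filter(noise, sigma=(1.0, 3.0, 3.0))
        candidates = mask & ~rim & (labels != 1)
        n_in = int(mask.sum())
        target = int(round(spec.ic_channel_fraction * n_in))
        have = int((labels[mask] == 1).sum())
        need = min(max(target - have, 0), int(candidates.sum()))
        if need > 0:
            vals = smooth[candidates]
            cut = np.partition(vals, need - 1)[need - 1]
            carve = candidates & (smooth <= cut)
            labels[carve] = 1
    return labels


def _render_rd_channel(
    spec: NucleusSceneSpec,
    labels: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    rd = spec.rd_spec
    assert rd is not None
    K = spec.n_classes
    dist_nm = ndimage.distance_transform_edt(mask, sampling=spec.voxel_size)

    if rd.pattern == "early":
        candidates = np.isin(labels, (2, 3)) & (dist_nm > 3 * spec.rim_thickness)
    elif rd.pattern == "mid":
        candidates = mask & (dist_nm <= 4 * spec.rim_thickness) & (dist_nm > 0)
    else:  # late
        candidates = (labels >= K - 2) & (dist_nm <= 8 * spec.rim_thickness)
    cand_idx = np.argwhere(candidates)
    if cand_idx.shape[0] == 0:
        raise ValueError(f"no candidate positions for RD pattern {rd.pattern!r}")

    vox_um = np.array(spec.voxel_size) / NM_PER_UM
    order = rng.permutation(cand_idx.shape[0])
    centers: list[np.ndarray] = []
    for i in order:
        p = cand_idx[i] * vox_um
        if all(np.linalg.norm(p - c) >= rd.min_separation_um for c in centers):
            centers.append(p)
        if len(centers) == rd.n_objects:
            break

    volumes = rng.lognormal(math.log(rd.mean_volume_um3), rd.sigma_log, size=len(centers))
    radii = (3.0 * volumes / (4.0 * math.pi)) ** (1.0 / 3.0)

    coords = [np.arange(n) * v for n, v in zip(spec.grid_shape, vox_um)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    img = np.zeros(spec.grid_shape, dtype=np.float64)
    rows = []
    for c, r, v in zip(centers, radii, volumes):
        sphere = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
        img[sphere] = rd.intensity
        cz, cy, cx = (c / vox_um).astype(int)
        rows.append({"z": cz, "y": cy, "x": cx, "radius_um": r, "volume_um3": v})
    truth = pd.DataFrame(rows, columns=["z", "y", "x", "radius_um", "volume_um3"])
    return img, truth


def generate_nucleus_scene(
    spec: NucleusSceneSpec,
) -> tuple[dict[str, VoxelGrid], SceneTruth]:
    """Generate all channels of one synthetic nucleus plus its ground truth.

    Returns a dict keyed by channel name (``"DAPI"``, each marker name, and
    ``"RD"`` when an :class:`RdSpec` is present) and the :class:`SceneTruth`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K = spec.n_classes
    means = np.asarray(spec.class_means, dtype=float)

    mask = _make_lobed_mask(spec, rng)
    labels = _carve_scene_labels(spec, mask, rng)

    # DAPI emission: class mean + shared-sigma Gaussian noise
    dapi = np.zeros(spec.grid_shape, dtype=np.float64)
    inm = mask
    dapi[inm] = means[labels[inm] - 1]
    if spec.class_sigma > 0:
        dapi[inm] += rng.normal(0.0, spec.class_sigma, size=int(inm.sum()))

    channels: dict[str, VoxelGrid] = {}
    marker_truth: dict[str, np.ndarray] = {}
    for mspec in spec.marker_specs:
        w = np.asarray(mspec.class_weights, dtype=float)
        wv = np.zeros(spec.grid_shape)
        wv[inm] = w[labels[inm] - 1]
        mean_w = wv[inm].mean()
        if mean_w == 0:
            raise ValueError(f"marker {mspec.name!r}: all realised weights are zero")
        p = np.clip(mspec.density * wv / mean_w, 0.0, 1.0)
        sel = inm & (rng.random(spec.grid_shape) < p)
        img = np.where(sel, mspec.intensity, 0.0)
        img = spec.noise_model.apply(img, rng)
        channels[mspec.name] = VoxelGrid(img, spec.voxel_size, mspec.name)
        counts = np.bincount(labels[sel], minlength=K + 1)[1:].astype(float)
        total = counts.sum()
        marker_truth[mspec.name] = counts / total if total else counts

    rd_truth = pd.DataFrame(columns=["z", "y", "x", "radius_um", "volume_um3"])
    if spec.rd_spec is not None:
        rd_img, rd_truth = _render_rd_channel(spec, labels, mask, rng)
        rd_img = _blur(rd_img, spec)
        rd_img = spec.noise_model.apply(rd_img, rng)
        channels["RD"] = VoxelGrid(rd_img, spec.voxel_size, "RD")

    dapi = _blur(dapi, spec)
    dapi = spec.noise_model.apply(dapi, rng)
    channels["DAPI"] = VoxelGrid(dapi, spec.voxel_size, "DAPI")

    fractions = np.bincount(labels[inm], minlength=K + 1)[1:] / int(inm.sum())
    truth = SceneTruth(
        label_field=labels.astype(np.int16),
        mask=mask,
        true_class_fractions=fractions,
        marker_truth=marker_truth,
        rd_truth=rd_truth,
    )
    return channels, truth


def _blur(img: np.ndarray, spec: NucleusSceneSpec) -> np.ndarray:
    if spec.psf_fwhm is None:
        return img
    sigma_vox = [f / _SQRT8LN2 / v for f, v in zip(spec.psf_fwhm, spec.voxel_size)]
    return ndimage.gaussian_filter(img, sigma=sigma_vox)


#: separable Gaussian PSF matching the stated SIM resolution limit
DEFAULT_PSF_FWHM = (300.0, 120.0, 120.0)  # nm (z, y, x)


# ---------------------------------------------------------------------------
# DNA halo scenes


def generate_halo_scene(
    core_radius_um: float,
    halo_radius_um: float,
    pixel_size_um: float = 0.1,
    noise_sd: float = 0.0,
    core_intensity: float = 50000.0,
    halo_intensity: float = 12000.0,
    background: float = 500.0,
    seed: int = 0,
) -> tuple[VoxelGrid, dict[str, float]]:
    """Render a 2D DNA-halo image: bright scaffold disc inside a fainter halo.

    Returns the image and the analytic truth areas in µm²:
    ``At`` (total = halo disc), ``As`` (scaffold disc), ``Ah = At - As``.
    """
    if not (halo_radius_um >= core_radius_um > 0):
        raise ValueError("need halo_radius >= core_radius > 0")
    rng = np.random.default_rng(seed)
    margin = 2.0  # µm of background around the halo
    half = halo_radius_um + margin
    n = int(math.ceil(2 * half / pixel_size_um))
    c = (np.arange(n) + 0.5) * pixel_size_um - half
    yy, xx = np.meshgrid(c, c, indexing="ij")
    r = np.hypot(yy, xx)
    img = np.full((n, n), background, dtype=np.float64)
    img[r <= halo_radius_um] = halo_intensity
    img[r <= core_radius_um] = core_intensity
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None)
    truth = {
        "At": math.pi * halo_radius_um**2,
        "As": math.pi * core_radius_um**2,
        "Ah": math.pi * (halo_radius_um**2 - core_radius_um**2),
    }
    grid = VoxelGrid(img, (pixel_size_um * NM_PER_UM,) * 2, "halo")
    return grid, truth


# ---------------------------------------------------------------------------
# degradation-kinetics traces


def generate_decay_traces(
    n_cells: int,
    half_life_min: float = 35.0,
    nonresponder_fraction: float = 0.04,
    start_range: tuple[float, float] = (80.0, 400.0),
    noise_sd: float = 0.0,
    n_timepoints: int = 25,
    dt_min: float = 15.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell reporter-degradation time courses.

    Responders decay exponentially with the given half-life; a
    ``nonresponder_fraction`` of cells escapes degradation and stays near its
    starting intensity (the experimentally observed escape fraction is ~4%).
    Sampling interval is ``dt_min`` minutes.

    Returns ``(traces, truth)``: a long-format table with columns
    ``cell_id, t_index, intensity`` and a per-cell truth table with columns
    ``cell_id, start, is_responder``.
    """
    if not 0.0 <= nonresponder_fraction <= 1.0:
        raise ValueError("nonresponder_fraction must be in [0, 1]")
    cols = ["cell_id", "t_index", "intensity"]
    if n_cells == 0:
        return (
            pd.DataFrame(columns=cols),
            pd.DataFrame(columns=["cell_id", "start", "is_responder"]),
        )
    rng = np.random.default_rng(seed)
    starts = rng.uniform(*start_range, size=n_cells)
    responder = rng.random(n_cells) >= nonresponder_fraction
    t = np.arange(n_timepoints) * dt_min
    decay = 2.0 ** (-t / half_life_min)
    values = np.where(responder[:, None], starts[:, None] * decay[None, :], starts[:, None])
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    traces = pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n_cells), n_timepoints),
            "t_index": np.tile(np.arange(n_timepoints), n_cells),
            "intensity": values.ravel(),
        }
    )
    truth = pd.DataFrame(
        {"cell_id": np.arange(n_cells), "start": starts, "is_responder": responder}
    )
    return traces, truth
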