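"""Synthetic binned Hi-C contact data with planted structure.

Generates paired pre-/post-treatment intra-chromosomal contact matrices with

* power-law distance decay (~1/d),
* a planted A/B checkerboard compartment pattern (alternating sign blocks),
* per-bin histone-mark cluster identities whose within-cluster contacts are
  boosted, one cluster of which is multiplied by a stated strengthening
  factor in the post matrix (the cohesin-depletion signature),
* focal loop-pixel enrichment at listed (bin_i, bin_j) pairs,
* histone-mark tracks drawn from per-cluster archetype z-scores plus noise,
* early/late replication tracks tied to the compartment signs (A replicates
  early).

With ``sampling_depth=None`` the matrices are exact expected values, so
constructions like "factor 2 doubles within-cluster contacts" hold exactly;
with a depth, counts are Poisson-sampled at that depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import ContactMatrix, TrackSet

#: the nine histone marks carried by the synthetic track set
MARK_NAMES = (
    "H3K36me3",
    "H3K27ac",
    "H3K4me1",
    "H4K16ac",
    "H3K79me2",
    "H2AZ",
    "H4K20me3",
    "H3K27me3",
    "H3K9me3",
)


def default_cluster_archetypes(k: int = 6, n_marks: int = 9, scale: float = 2.0) -> np.ndarray:
    """Fixed, well-separated per-cluster mean z-score vectors."""
    rng = np.random.default_rng(12345)
    arch = rng.normal(0.0, 1.0, size=(k, n_marks))
    arch -= arch.mean(axis=0)
    norms = np.linalg.norm(arch, axis=1, keepdims=True)
    return scale * arch / norms * np.sqrt(n_marks)


@dataclass
class GenomeSpec:
    """Specification of one synthetic chromosome's contact data."""

    n_bins: int = 200
    resolution: int = 25_000
    chrom: str = "chrS"
    n_clusters: int = 6
    cluster_archetypes: np.ndarray | None = None  # (k, 9) mean z-scores
    compartment_block: int = 10  # bins per alternating A/B block
    compartment_strength: float = 0.6  # same-sign contact boost
    cluster_strength: float = 0.4  # same-cluster contact boost
    strengthen_cluster: int = 4
    strengthen_factor: float = 2.0
    n_loops: int = 20
    loop_strength: float = 4.0
    base_count: float = 100.0
    track_noise_sd: float = 0.3
    sampling_depth: float | None = None  # None = exact expected counts
    seed: int = 0

    def validate(self) -> None:
        if self.n_bins < 2 * self.compartment_block:
            raise ValueError("need at least two compartment blocks")
        if not 1 <= self.strengthen_cluster <= self.n_clusters:
            raise ValueError("strengthen_cluster out of range")
        if self.strengthen_factor <= 0:
            raise ValueError("strengthen_factor must be positive")
        arch = self.archetypes
        if arch.shape != (self.n_clusters, len(MARK_NAMES)):
            raise ValueError(
                f"cluster_archetypes must be ({self.n_clusters}, {len(MARK_NAMES)})"
            )

    @property
    def archetypes(self) -> np.ndarray:
        if self.cluster_archetypes is None:
            return default_cluster_archetypes(self.n_clusters, len(MARK_NAMES))
        return np.asarray(self.cluster_archetypes, dtype=float)


@dataclass
class GenomeTruth:
    """Planted ground truth exported with the contact data."""

    compartment_sign: np.ndarray  # +1 (A) / -1 (B) per bin
    cluster_labels: np.ndarray  # 1..k per bin
    loops: list[tuple[int, int]]
    strengthen_cluster: int
    strengthen_factor: float
    early: np.ndarray = field(default=None)
    late: np.ndarray = field(default=None)


def generate_contact_data(
    spec: GenomeSpec,
) -> tuple[ContactMatrix, ContactMatrix, TrackSet, list[tuple[int, int]], GenomeTruth]:
    """Generate (pre, post, tracks, loops, truth) for one synthetic chromosome."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    k = spec.n_clusters

    # planted structure
    signs = np.where((np.arange(n) // spec.compartment_block) % 2 == 0, 1, -1)
    clusters = rng.integers(1, k + 1, size=n)
    loops = _draw_loops(spec, rng)

    # expected contacts
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    expected = spec.base_count / (1.0 + d)
    expected *= 1.0 + spec.compartment_strength * (np.equal.outer(signs, signs))
    expected *= 1.0 + spec.cluster_strength * (np.equal.outer(clusters, clusters))
    for i, j in loops:
        expected[i, j] *= spec.loop_strength
        expected[j, i] = expected[i, j]

    pre = _realise(expected, spec, rng)
    within = np.equal.outer(clusters, clusters) & (clusters[:, None] == spec.strengthen_cluster)
    expected_post = np.where(within, expected * spec.strengthen_factor, expected)
    post = _realise(expected_post, spec, rng)

    # tracks: histone marks from archetypes, E/L tied to compartments
    arch = spec.archetypes
    marks = arch[clusters - 1] + rng.normal(0.0, spec.track_noise_sd, size=(n, len(MARK_NAMES)))
    early = 100.0 * (1.0 + 0.8 * signs) + rng.normal(0.0, 5.0, size=n)
    late = 100.0 * (1.0 - 0.8 * signs) + rng.normal(0.0, 5.0, size=n)
    early = np.clip(early, 0.0, None)
    late = np.clip(late, 0.0, None)
    tracks = TrackSet(
        tracks=pd.DataFrame(dict(zip(MARK_NAMES, marks.T)) | {"early": early, "late": late}),
        resolution=spec.resolution,
        chrom=spec.chrom,
    )

    truth = GenomeTruth(
        compartment_sign=signs,
        cluster_labels=clusters,
        loops=loops,
        strengthen_cluster=spec.strengthen_cluster,
        strengthen_factor=spec.strengthen_factor,
        early=early,
        late=late,
    )
    cm_pre = ContactMatrix(pre, spec.resolution, spec.chrom)
    cm_post = ContactMatrix(post, spec.resolution, spec.chrom)
    return cm_pre, cm_post, tracks, loops, truth


def _draw_loops(spec: GenomeSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    n = spec.n_bins
    loops: set[tuple[int, int]] = set()
    attempts = 0
    # loops live well off-diagonal so that aggregate windows around them
    # never touch the diagonal or the matrix edge
    d_min, d_max = 25, max(26, n // 3)
    while len(loops) < spec.n_loops and attempts < 100 * spec.n_loops:
        attempts += 1
        i = int(rng.integers(12, n - 12))
        dist = int(rng.integers(d_min, d_max))
        j = i + dist
        if j < n - 12:
            loops.add((i, j))
    return sorted(loops)


def _realise(expected: np.ndarray, spec: GenomeSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.sampling_depth is None:
        return expected
    lam = expected * spec.sampling_depth
    upper = np.triu(rng.poisson(lam).astype(float))
    return upper + np.triu(upper, 1).T
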