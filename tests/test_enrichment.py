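"""Marker enrichment: percentage-point conservation, null calibration, and
planted-enrichment recovery."""

import numpy as np
import pytest

from nucarch.enrichment import (
    MarkerSegmentation,
    aggregate_profiles,
    enrichment_profile,
    segment_marker,
)
from nucarch.grids import NucleusMask, VoxelGrid
from nucarch.hmrf import ClassField, HmrfParams


def _field_from_labels(labels, K=7):
    params = HmrfParams(K, np.arange(1.0, K + 1), 1.0, np.full(K, 1 / K), 0.5)
    return ClassField(np.asarray(labels, dtype=np.int8), params, (100.0, 100.0, 100.0))


def _random_field(rng, shape=(20, 40, 40), K=7, fractions=None):
    labels = np.zeros(shape, dtype=np.int8)
    inm = np.zeros(shape, dtype=bool)
    inm[2:-2, 4:-4, 4:-4] = True
    p = np.full(K, 1 / K) if fractions is None else np.asarray(fractions)
    labels[inm] = rng.choice(np.arange(1, K + 1), size=int(inm.sum()), p=p)
    return _field_from_labels(labels, K), inm


class TestSegmentMarker:
    def test_binary_channel_recovers_positive_voxels(self, rng):
        field, inm = _random_field(rng)
        marker = np.zeros(inm.shape)
        pos = inm & (rng.random(inm.shape) < 0.1)
        marker[pos] = 255.0
        grid = VoxelGrid(marker, (100.0,) * 3, "M")
        mask = NucleusMask(inm, (100.0,) * 3)
        for factor in (0.2, 0.5, 1.0):
            seg = segment_marker(grid, mask, threshold_factor=factor)
            assert seg.n_voxels == int(pos.sum())

    def test_huge_factor_empties_segmentation(self, rng):
        field, inm = _random_field(rng)
        marker = rng.random(inm.shape) * 100
        seg = segment_marker(VoxelGrid(marker, (100.0,) * 3, "M"), NucleusMask(inm, (100.0,) * 3), 1e9)
        assert seg.n_voxels == 0

    def test_all_zero_channel_warns(self, rng):
        _, inm = _random_field(rng)
        with pytest.warns(UserWarning, match="all zero"):
            seg = segment_marker(
                VoxelGrid(np.zeros(inm.shape), (100.0,) * 3, "M"), NucleusMask(inm, (100.0,) * 3)
            )
        assert seg.n_voxels == 0

    def test_generator_marker_recovered_exactly(self):
        from nucarch.simulate import MarkerSpec, NucleusSceneSpec, generate_nucleus_scene

        spec = NucleusSceneSpec(
            grid_shape=(16, 64, 64), lobe_semiaxes_um=(0.7, 1.0, 1.0), seed=21,
            marker_specs=(MarkerSpec("M", (4, 2, 1, 0.5, 0, 0, 0), density=0.08),),
        )
        channels, truth = generate_nucleus_scene(spec)
        seg = segment_marker(channels["M"], NucleusMask(truth.mask, spec.voxel_size))
        expected = np.argwhere(channels["M"].data > 0)
        assert seg.n_voxels == len(expected)
        assert np.array_equal(seg.coords, expected)


class TestEnrichmentProfile:
    def test_uniform_marker_gives_zero_delta(self, rng):
        field, inm = _random_field(rng)
        coords = np.argwhere(inm)
        seg = MarkerSegmentation(coords, np.ones(len(coords)), 0.0, "uniform")
        prof = enrichment_profile(seg, field)
        assert np.allclose(prof.delta, 0.0, atol=1e-9)

    def test_class1_only_marker_forced_deltas(self, rng):
        field, inm = _random_field(rng)
        labels = field.labels
        coords = np.argwhere(inm & (labels == 1))
        seg = MarkerSegmentation(coords, np.ones(len(coords)), 0.0, "ic")
        prof = enrichment_profile(seg, field)
        f = prof.dapi_fraction
        assert prof.delta[0] == pytest.approx(100 * (1 - f[0]))
        assert np.allclose(prof.delta[1:], -100 * f[1:])

    def test_delta_sums_to_zero(self, rng):
        for _ in range(5):
            field, inm = _random_field(rng, fractions=rng.dirichlet(np.ones(7)))
            coords = np.argwhere(inm)
            take = rng.random(len(coords)) < 0.2
            seg = MarkerSegmentation(coords[take], rng.random(int(take.sum())) + 0.1, 0.0, "m")
            prof = enrichment_profile(seg, field)
            assert prof.delta.sum() == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_global_intensity_rescaling(self, rng):
        field, inm = _random_field(rng)
        coords = np.argwhere(inm)[::7]
        intens = rng.random(len(coords)) + 0.5
        a = enrichment_profile(MarkerSegmentation(coords, intens, 0.0, "m"), field)
        b = enrichment_profile(MarkerSegmentation(coords, 123.4 * intens, 0.0, "m"), field)
        assert np.allclose(a.delta, b.delta)

    def test_independent_marker_null_below_one_point(self, rng):
        # a marker independent of the class field: |delta_k| < 1 point
        # at >= 1e5 marker voxels
        field, inm = _random_field(rng, shape=(40, 80, 80))
        coords = np.argwhere(inm)
        take = rng.choice(len(coords), size=120_000, replace=False)
        seg = MarkerSegmentation(coords[take], np.ones(120_000), 0.0, "null")
        prof = enrichment_profile(seg, field)
        assert np.all(np.abs(prof.delta) < 1.0)

    def test_empty_segmentation_raises(self, rng):
        field, _ = _random_field(rng)
        seg = MarkerSegmentation(np.empty((0, 3), dtype=int), np.empty(0), 0.0, "m")
        with pytest.raises(ValueError, match="no marker signal"):
            enrichment_profile(seg, field)

    def test_unweighted_option_ignores_intensities(self, rng):
        field, inm = _random_field(rng)
        coords = np.argwhere(inm)[::11]
        a = enrichment_profile(
            MarkerSegmentation(coords, rng.random(len(coords)) + 0.1, 0.0, "m"),
            field, intensity_weighted=False,
        )
        b = enrichment_profile(
            MarkerSegmentation(coords, np.ones(len(coords)), 0.0, "m"), field
        )
        assert np.allclose(a.delta, b.delta)


class TestAggregate:
    def test_identical_profiles_zero_sem(self, rng):
        field, inm = _random_field(rng)
        coords = np.argwhere(inm)[::5]
        prof = enrichment_profile(MarkerSegmentation(coords, np.ones(len(coords)), 0.0, "m"), field)
        out = aggregate_profiles([prof, prof, prof])
        assert np.allclose(out["sem_delta"], 0.0)

    def test_symmetric_deltas_cancel(self):
        from nucarch.enrichment import EnrichmentProfile

        f = np.full(7, 1 / 7)
        d1 = np.array([10.0, -10, 0, 0, 0, 0, 0])
        p1 = EnrichmentProfile(f, f + d1 / 100, d1)
        p2 = EnrichmentProfile(f, f - d1 / 100, -d1)
        out = aggregate_profiles([p1, p2])
        assert np.allclose(out["mean_delta"], 0.0)

    def test_planted_class1_enrichment_recovered(self, rng):
        # 20 nuclei with the class-1 marker share boosted by +15 points
        deltas = []
        for _ in range(20):
            field, inm = _random_field(rng, shape=(16, 40, 40))
            labels = field.labels
            f1 = (labels[inm] == 1).mean()
            target_m1 = f1 + 0.15
            # per-voxel selection probability giving E[m1] = f1 + 0.15
            p1 = 0.3 * target_m1 / f1
            p_other = 0.3 * (1 - target_m1) / (1 - f1)
            p = np.where(labels == 1, p1, p_other)
            sel = inm & (rng.random(labels.shape) < p)
            coords = np.argwhere(sel)
            prof = enrichment_profile(
                MarkerSegmentation(coords, np.ones(len(coords)), 0.0, "m"), field
            )
            deltas.append(prof.delta)
        out = aggregate_profiles(
            [p for p in map(lambda d: _wrap_profile(d), deltas)]
        )
        assert out["mean_delta"][0] == pytest.approx(15.0, abs=2.0)

    def test_mixed_class_counts_rejected(self):
        from nucarch.enrichment import EnrichmentProfile

        a = EnrichmentProfile(np.full(7, 1 / 7), np.full(7, 1 / 7), np.zeros(7))
        b = EnrichmentProfile(np.full(6, 1 / 6), np.full(6, 1 / 6), np.zeros(6))
        with pytest.raises(ValueError, match="mixed"):
            aggregate_profiles([a, b])


def _wrap_profile(delta):
    from nucarch.enrichment import EnrichmentProfile

    K = len(delta)
    f = np.full(K, 1 / K)
    return EnrichmentProfile(f, f + delta / 100, np.asarray(delta))
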