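"""Generator ground-truth properties: packing, vectors, connectors, rendering."""

import numpy as np
import pytest
from scipy import ndimage, stats

from mtmesh import FiberSpec, generate_connector_graph, generate_cross_section, \
    generate_fiber, generate_mt_vectors, render_volume
from mtmesh.synthetic import PackingInfeasibleError

from oracles import union_find_partition


def _points(cross):
    return np.array([[x, y] for _, x, y in cross])


def _min_pairwise(pts):
    d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    np.fill_diagonal(d, np.inf)
    return d.min()


class TestCrossSection:
    def test_single_mt_sits_at_origin(self):
        assert generate_cross_section(FiberSpec(n_mts=1)) == [(1, 0.0, 0.0)]

    def test_three_mts_at_control_spacing_no_jitter(self):
        # printed control spacing as generator parameter, jitter off
        cross = generate_cross_section(
            FiberSpec(n_mts=3, mean_nn_spacing_nm=56.1, spacing_jitter_nm=0.0)
        )
        assert _min_pairwise(_points(cross)) == pytest.approx(56.1)

    def test_seeded_determinism(self):
        spec = FiberSpec(n_mts=30, rng_seed=1)
        assert generate_cross_section(spec) == generate_cross_section(spec)

    @pytest.mark.parametrize("seed", range(5))
    def test_no_mt_overlap_and_median_spacing(self, seed):
        spec = FiberSpec(n_mts=25, rng_seed=seed)
        pts = _points(generate_cross_section(spec))
        assert _min_pairwise(pts) >= spec.mt_diameter_nm
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        np.fill_diagonal(d, np.inf)
        median_nn = np.median(d.min(axis=1))
        assert abs(median_nn - spec.mean_nn_spacing_nm) <= spec.spacing_jitter_nm

    def test_overdense_spec_signals(self):
        with pytest.raises(PackingInfeasibleError):
            generate_cross_section(FiberSpec(n_mts=10, mean_nn_spacing_nm=20.0))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FiberSpec(n_mts=0)
        with pytest.raises(ValueError):
            FiberSpec(deviant_fraction=1.5)
        with pytest.raises(ValueError):
            FiberSpec(connector_polarity_mix={2: 0.5, 3: 0.4})


class TestMTVectors:
    def test_parallel_fiber_runs_along_z(self):
        spec = FiberSpec(n_mts=10, deviant_fraction=0.0, rng_seed=0)
        cross = generate_cross_section(spec)
        for _, bot, top in generate_mt_vectors(cross, spec):
            u = np.subtract(top, bot)
            u = u / np.linalg.norm(u)
            assert np.allclose(u, [0, 0, 1], atol=1e-12)

    def test_tilted_bundle_angles(self):
        # closed form: all directions identical, each 0.3 rad from z
        spec = FiberSpec(n_mts=12, deviant_fraction=0.0, fiber_tilt=(0.3, 1.0),
                         rng_seed=0)
        cross = generate_cross_section(spec)
        dirs = []
        for _, bot, top in generate_mt_vectors(cross, spec):
            u = np.subtract(top, bot)
            dirs.append(u / np.linalg.norm(u))
        dirs = np.array(dirs)
        assert np.allclose(dirs, dirs[0], atol=1e-12)     # pairwise angles 0
        assert np.arccos(dirs[0, 2]) == pytest.approx(0.3, abs=1e-12)

    def test_deviant_count_is_exact(self):
        spec = FiberSpec(n_mts=11, deviant_fraction=0.5, deviant_polar_max_rad=0.2,
                         rng_seed=5)
        cross = generate_cross_section(spec)
        n_dev = 0
        for _, bot, top in generate_mt_vectors(cross, spec):
            u = np.subtract(top, bot)
            u = u / np.linalg.norm(u)
            if np.arccos(np.clip(u[2], -1, 1)) > 1e-9:
                n_dev += 1
                assert np.arccos(u[2]) <= 0.2 + 1e-9
        assert n_dev == int(np.ceil(11 * 0.5))

    def test_slab_thickness_spanned_exactly(self):
        spec = FiberSpec(n_mts=8, deviant_fraction=0.3, fiber_tilt=(0.2, 0.5),
                         rng_seed=2)
        cross = generate_cross_section(spec)
        for _, bot, top in generate_mt_vectors(cross, spec):
            assert top[2] - bot[2] == pytest.approx(spec.slab_thickness_nm)


class TestConnectorGraph:
    def test_pure_bipolar_mix(self):
        spec = FiberSpec(n_mts=12, connector_polarity_mix={2: 1.0}, rng_seed=1)
        synth = generate_fiber(spec)
        assert all(e.polarity == 2 for e in synth.true_connectors.hyperedges)

    def test_two_mts_single_connector_one_chain(self):
        spec = FiberSpec(n_mts=2, connectors_per_mt=0.5, rng_seed=1,
                         connector_polarity_mix={2: 1.0})
        synth = generate_fiber(spec)
        assert len(synth.true_connectors.hyperedges) == 1
        assert list(synth.true_chain_partition.chain_sizes.values()) == [2]

    def test_polarity_mix_within_binomial_bounds(self):
        mix = {2: 0.8, 3: 0.15, 4: 0.05}
        spec = FiberSpec(n_mts=40, connector_polarity_mix=mix,
                         connectors_per_mt=3.0, rng_seed=9)
        synth = generate_fiber(spec)
        edges = synth.true_connectors.hyperedges
        n = len(edges)
        for k, p in mix.items():
            observed = sum(e.polarity == k for e in edges)
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= observed <= hi

    def test_connectors_prefer_proximal_mts(self, control_fiber):
        pts = {m.mt_id: m.midpoint for m in control_fiber.fiber_model.mts}
        for e in control_fiber.true_connectors.hyperedges:
            members = sorted(e.mt_ids)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    assert np.linalg.norm(pts[a] - pts[b]) <= 105.0

    def test_planted_partition_matches_union_find_oracle(self, control_fiber):
        graph = control_fiber.true_connectors
        oracle = union_find_partition(
            graph.nodes, [e.mt_ids for e in graph.hyperedges]
        )
        part = control_fiber.true_chain_partition
        ours = {}
        for mt, cid in part.chain_of.items():
            ours.setdefault(cid, set()).add(mt)
        assert set(map(frozenset, ours.values())) == set(oracle)


class TestRenderVolume:
    def test_noise_free_background_is_clean(self, small_fiber):
        from mtmesh.connectivity import ConnectorGraph
        empty = ConnectorGraph(fiber_id="e",
                               nodes=small_fiber.fiber_model.mt_ids)
        vol = render_volume(small_fiber.fiber_model, empty, noise_sd=0.0, seed=0)
        outside = vol.mt_labels.labels == 0
        assert np.all(vol.density.values[outside] == 0.0)

    def test_planted_connector_is_connected_and_touches_members(self, small_fiber):
        vol = render_volume(small_fiber.fiber_model,
                            small_fiber.true_connectors, noise_sd=0.0, seed=0)
        assert len(vol.planted_connectors) >= 1
        for pc in vol.planted_connectors:
            mask = np.zeros(vol.density.values.shape, dtype=bool)
            mask[tuple(pc["voxels"].T)] = True
            _, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))
            assert n_comp == 1
            # disjoint from MT labels
            assert np.all(vol.mt_labels.labels[mask] == 0)

    def test_planted_sets_are_mutually_disjoint(self, control_fiber):
        vol = render_volume(control_fiber.fiber_model,
                            control_fiber.true_connectors, noise_sd=0.0, seed=1)
        seen = set()
        for pc in vol.planted_connectors:
            vox = set(map(tuple, pc["voxels"]))
            assert not (vox & seen)
            seen |= vox

    def test_voxel_halving_scales_connector_volume(self, small_fiber):
        v2 = render_volume(small_fiber.fiber_model, small_fiber.true_connectors,
                           voxel_nm=2.0, noise_sd=0.0, seed=0)
        v1 = render_volume(small_fiber.fiber_model, small_fiber.true_connectors,
                           voxel_nm=1.0, noise_sd=0.0, seed=0)
        n2 = sum(len(pc["voxels"]) for pc in v2.planted_connectors)
        n1 = sum(len(pc["voxels"]) for pc in v1.planted_connectors)
        assert n1 == pytest.approx(8 * n2, rel=0.15)   # volume conservation

    def test_bad_voxel_size_rejected(self, small_fiber):
        with pytest.raises(ValueError):
            render_volume(small_fiber.fiber_model, small_fiber.true_connectors,
                          voxel_nm=10.0)
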