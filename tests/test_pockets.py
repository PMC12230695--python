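"""DoG filtering, PSP scanlines, clustering, dilation/merging, ligand bias."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from cavgrid import (
    LabelField,
    LigandSelection,
    PocketParams,
    StructureError,
    VoxelGrid,
    apply_ligand_bias,
    cluster_pockets,
    detect_pockets,
    dilate_and_merge,
    dog_filter,
    filter_small,
    make_shallow_groove,
    psp_events,
)
from cavgrid.pockets import Pocket, seed_mask
from cavgrid.structure_io import extract_ligand
from cavgrid.reference import naive_dog, naive_psp, flood_fill_components, _gauss_kernel_1d

from conftest import make_atom

UNIT_PARAMS = PocketParams(spacing=1.0)


def labels_from_array(mac, spacing=1.0):
    mac = np.asarray(mac, dtype=np.uint8)
    grid = VoxelGrid(origin=(0.0, 0.0, 0.0), spacing=spacing, shape=mac.shape)
    return LabelField(grid=grid, labels=mac)


def random_labels(rng, shape=(9, 9, 9), p=0.4):
    return labels_from_array(rng.random(shape) < p)


class TestDogFilter:
    def test_uniform_solvent_gives_zero(self):
        labels = labels_from_array(np.zeros((8, 8, 8)))
        dog = dog_filter(labels, UNIT_PARAMS)
        np.testing.assert_allclose(dog.values, 0.0, atol=1e-12)

    def test_uniform_macromolecule_gives_zero(self):
        labels = labels_from_array(np.ones((8, 8, 8)))
        dog = dog_filter(labels, UNIT_PARAMS)
        np.testing.assert_allclose(dog.values, 0.0, atol=1e-12)

    def test_solvent_impulse_center_value_matches_kernels(self):
        mac = np.ones((25, 25, 25))
        mac[12, 12, 12] = 0  # single solvent voxel in a macromolecule sea
        dog = dog_filter(labels_from_array(mac), UNIT_PARAMS)
        k_small = _gauss_kernel_1d(UNIT_PARAMS.dog_sigma_small)
        k_large = _gauss_kernel_1d(UNIT_PARAMS.dog_sigma_large)
        expected = k_small[len(k_small) // 2] ** 3 - k_large[len(k_large) // 2] ** 3
        assert dog.values[12, 12, 12] == pytest.approx(expected, abs=1e-9)

    def test_matches_direct_convolution_on_random_grids(self, rng):
        for _ in range(5):
            labels = random_labels(rng)
            dog = dog_filter(labels, UNIT_PARAMS)
            np.testing.assert_allclose(dog.values, naive_dog(labels, UNIT_PARAMS), atol=1e-6)


class TestPspEvents:
    def test_no_macromolecule_gives_zero(self):
        labels = labels_from_array(np.zeros((5, 5, 5)))
        assert (psp_events(labels).counts == 0).all()

    def test_fully_enclosed_center_scores_seven(self):
        mac = np.ones((3, 3, 3))
        mac[1, 1, 1] = 0
        counts = psp_events(labels_from_array(mac)).counts
        assert counts[1, 1, 1] == 7

    def test_macromolecule_voxels_score_zero(self, rng):
        labels = random_labels(rng)
        counts = psp_events(labels).counts
        assert (counts[labels.macromolecule_mask] == 0).all()

    def test_grid_edge_counts_as_open(self):
        # solvent voxel on a face: the axis through the face cannot be flanked
        mac = np.ones((3, 3, 3))
        mac[0, 1, 1] = 0
        counts = psp_events(labels_from_array(mac)).counts
        assert counts[0, 1, 1] == 2  # only the two in-face axes flank it

    def test_matches_exhaustive_scanline_oracle(self, rng):
        for _ in range(5):
            labels = random_labels(rng)
            np.testing.assert_array_equal(psp_events(labels).counts, naive_psp(labels))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(dtype=bool, shape=(6, 6, 6)))
    def test_counts_always_in_range(self, mac):
        counts = psp_events(labels_from_array(mac)).counts
        assert counts.min() >= 0 and counts.max() <= 7


class TestClusterPockets:
    def test_nothing_passes_thresholds(self):
        labels = labels_from_array(np.ones((6, 6, 6)))  # no solvent at all
        dog = dog_filter(labels, UNIT_PARAMS)
        psp = psp_events(labels)
        assert cluster_pockets(dog, psp, labels, UNIT_PARAMS) == []

    def test_separated_blobs_form_two_pockets(self):
        mac = np.ones((9, 9, 9))
        mac[1:3, 1:3, 1:3] = 0
        mac[6:8, 6:8, 6:8] = 0
        labels = labels_from_array(mac)
        params = PocketParams(spacing=1.0, dog_seed_threshold=-10.0, psp_min_count=0)
        dog = dog_filter(labels, params)
        psp = psp_events(labels)
        pockets = cluster_pockets(dog, psp, labels, params)
        assert len(pockets) == 2

    def test_partition_matches_flood_fill_oracle(self, rng):
        for _ in range(5):
            labels = random_labels(rng)
            dog = dog_filter(labels, UNIT_PARAMS)
            psp = psp_events(labels)
            pockets = cluster_pockets(dog, psp, labels, UNIT_PARAMS)
            got = {frozenset(p.index_set()) for p in pockets}
            seeds = seed_mask(dog, psp, labels, UNIT_PARAMS)
            want = {frozenset(c) for c in flood_fill_components(seeds, 26)}
            assert got == want

    def test_seeds_are_solvent_only(self, rng):
        labels = random_labels(rng)
        dog = dog_filter(labels, UNIT_PARAMS)
        psp = psp_events(labels)
        for p in cluster_pockets(dog, psp, labels, UNIT_PARAMS):
            assert labels.solvent_mask[tuple(p.voxel_indices.T)].all()


class TestDilateAndMerge:
    def test_zero_radius_is_identity(self):
        labels = labels_from_array(np.zeros((7, 7, 7)))
        pockets = [Pocket(voxel_indices=np.array([[3, 3, 3]]), seed_count=1)]
        params = PocketParams(spacing=1.0, dilation_radius=0.0)
        out = dilate_and_merge(pockets, labels, params)
        assert len(out) == 1 and out[0].index_set() == {(3, 3, 3)}

    def test_nearby_pockets_merge_through_dilation(self):
        # two single-voxel pockets two voxels apart; radius 1.5*spacing bridges them
        labels = labels_from_array(np.zeros((9, 9, 9)))
        pockets = [
            Pocket(voxel_indices=np.array([[3, 4, 4]]), seed_count=1),
            Pocket(voxel_indices=np.array([[5, 4, 4]]), seed_count=1),
        ]
        params = PocketParams(spacing=1.0, dilation_radius=1.5)
        out = dilate_and_merge(pockets, labels, params)
        assert len(out) == 1
        assert out[0].index_set() >= {(3, 4, 4), (4, 4, 4), (5, 4, 4)}
        assert out[0].seed_count == 2

    def test_growth_is_monotone_and_never_enters_macromolecule(self, rng):
        labels = random_labels(rng, p=0.3)
        solvent_idx = np.argwhere(labels.solvent_mask)
        pockets = [Pocket(voxel_indices=solvent_idx[:1], seed_count=1)]
        params = PocketParams(spacing=1.0, dilation_radius=2.0)
        out = dilate_and_merge(pockets, labels, params)
        merged = set().union(*(p.index_set() for p in out))
        assert pockets[0].index_set() <= merged
        for idx in merged:
            assert labels.solvent_mask[idx]

    def test_output_pockets_are_disjoint(self, rng):
        labels = random_labels(rng, p=0.2)
        solvent_idx = np.argwhere(labels.solvent_mask)
        picks = rng.choice(len(solvent_idx), size=4, replace=False)
        pockets = [Pocket(voxel_indices=solvent_idx[i : i + 1], seed_count=1) for i in picks]
        out = dilate_and_merge(pockets, labels, PocketParams(spacing=1.0, dilation_radius=1.2))
        sets = [p.index_set() for p in out]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]


class TestFilterSmall:
    def test_strict_removal_below_threshold(self):
        # at spacing 0.5 Å: 80, 159, 160, 1200 voxels -> 10, 19.875, 20, 150 Å³
        spacing = 0.5
        pockets = [
            Pocket(voxel_indices=np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], 1),
                   seed_count=n)
            for n in (80, 159, 160, 1200)
        ]
        kept = filter_small(pockets, spacing, min_volume=20.0)
        assert [p.volume(spacing) for p in kept] == [20.0, 150.0]

    def test_empty_input(self):
        assert filter_small([], 0.5, 20.0) == []

    def test_all_above_threshold_unchanged(self):
        pockets = [Pocket(voxel_indices=np.array([[i, 0, 0]]), seed_count=1) for i in range(3)]
        assert filter_small(pockets, 5.0, 20.0) == pockets

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=400), max_size=8))
    def test_retention_rule_is_exactly_volume_ge_threshold(self, sizes):
        spacing = 1.0
        pockets = [
            Pocket(voxel_indices=np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], 1),
                   seed_count=n)
            for n in sizes
        ]
        kept = filter_small(pockets, spacing, min_volume=20.0)
        assert [p.n_voxels for p in kept] == [n for n in sizes if n >= 20]


class TestLigandBias:
    def _ligand_at(self, coords):
        atoms = tuple(
            make_atom(serial=i + 1, name=f"C{i+1}", coords=tuple(c), residue_name="LIG",
                      chain_id="L", residue_number=1, is_hetero=True)
            for i, c in enumerate(np.atleast_2d(coords))
        )
        return LigandSelection(atoms=atoms, selector="LIG:L:1")

    def test_far_ligand_leaves_fields_unchanged(self, rng):
        labels = random_labels(rng)
        params = PocketParams(spacing=1.0, ligand_bias_enabled=True)
        dog = dog_filter(labels, params)
        psp = psp_events(labels)
        ligand = self._ligand_at([100.0, 100.0, 100.0])
        new_dog, new_psp = apply_ligand_bias(dog, psp, ligand, labels.grid, params)
        np.testing.assert_array_equal(new_dog.values, dog.values)
        np.testing.assert_array_equal(new_psp.counts, psp.counts)

    def test_promotion_is_monotone(self, rng):
        labels = random_labels(rng)
        params = PocketParams(spacing=1.0, ligand_bias_enabled=True)
        dog = dog_filter(labels, params)
        psp = psp_events(labels)
        ligand = self._ligand_at([4.0, 4.0, 4.0])
        new_dog, new_psp = apply_ligand_bias(dog, psp, ligand, labels.grid, params)
        assert (new_dog.values >= dog.values).all()
        assert (new_psp.counts >= psp.counts).all()

    def test_shallow_groove_found_only_with_bias(self):
        groove = make_shallow_groove()
        ligand = extract_ligand(groove, "LIG:L:1")
        unbiased = detect_pockets(groove, ligand=ligand)
        assert len(unbiased) == 0
        biased = detect_pockets(
            groove, params=PocketParams(ligand_bias_enabled=True), ligand=ligand
        )
        assert len(biased) >= 1
        # the biased pocket must cover >= 90% of ligand-adjacent solvent voxels
        from cavgrid.pockets import _voxels_near_points

        pts = biased.transform.apply(ligand.coords())
        near = _voxels_near_points(biased.grid, pts, np.full(len(pts), 2.5))
        near &= biased.labels.solvent_mask
        covered = np.zeros(biased.grid.shape, dtype=bool)
        for p in biased.pockets:
            covered |= p.mask(biased.grid.shape)
        assert (near & covered).sum() / near.sum() >= 0.9


class TestDetectPockets:
    def test_hollow_shell_yields_single_cavity_pocket(self, hollow_shell_pockets):
        ps = hollow_shell_pockets
        assert len(ps) == 1
        pocket = ps.pockets[0]
        centroid = ps.voxel_world_coords(pocket).mean(axis=0)
        assert np.linalg.norm(centroid) < 2.0
        analytic = 4.0 / 3.0 * np.pi * 5.0**3
        assert pocket.volume(ps.grid.spacing) == pytest.approx(analytic, rel=0.30)

    def test_results_are_disjoint_solvent_and_large_enough(self, hollow_shell_pockets):
        ps = hollow_shell_pockets
        seen = set()
        for p in ps.pockets:
            voxels = p.index_set()
            assert not voxels & seen
            seen |= voxels
            assert ps.labels.solvent_mask[tuple(p.voxel_indices.T)].all()
            assert p.volume(ps.grid.spacing) >= ps.params.min_volume
        vols = [p.volume(ps.grid.spacing) for p in ps.pockets]
        assert vols == sorted(vols, reverse=True)

    def test_empty_structure_is_an_error(self):
        from cavgrid import Structure

        with pytest.raises((StructureError, ValueError)):
            detect_pockets(Structure([]))
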