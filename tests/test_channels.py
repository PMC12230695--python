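"""Symmetry expansion, periodic clearance, percolation sweep, site radii."""

import numpy as np
import pytest

from cavgrid import (
    MissingSymmetryError,
    ScalarField,
    Structure,
    UnitCell,
    expand_unit_cell,
    local_bottleneck_field,
    make_neck_chamber,
    make_periodic_grid,
    make_tube_crystal,
    periodic_clearance,
    read_ccp4,
    run_channels,
)
from cavgrid.channels import PeriodicGrid
from cavgrid.structure_io import _ops_for_space_group, vdw_radius
from cavgrid.reference import naive_local_bottleneck

from conftest import make_atom, structure_from_points


def p1_structure(points, edge=10.0):
    return structure_from_points(points, unit_cell=UnitCell(edge, edge, edge, 90, 90, 90))


def cubic_grid(n, edge=None):
    edge = float(n) if edge is None else edge
    cell = UnitCell(edge, edge, edge, 90, 90, 90)
    return PeriodicGrid(unit_cell=cell, shape=(n, n, n), target_spacing=edge / n)


class TestExpandUnitCell:
    def test_p1_is_identity_modulo_wrapping(self):
        s = p1_structure([[1.0, 2.0, 3.0], [11.0, 2.0, 3.0]])  # second atom outside cell
        expanded = expand_unit_cell(s)
        assert len(expanded) == 2
        coords = expanded.coords()
        np.testing.assert_allclose(coords[0], [1.0, 2.0, 3.0], atol=1e-9)
        np.testing.assert_allclose(coords[1], [1.0, 2.0, 3.0], atol=1e-9)  # wrapped

    def test_p21_general_position_gives_two_images(self):
        ops = _ops_for_space_group("P 1 21 1")
        cell = UnitCell(10, 12, 14, 90, 90, 90, symmetry_ops=ops, space_group="P 1 21 1")
        s = structure_from_points([[1.0, 2.0, 3.0]], unit_cell=cell)
        expanded = expand_unit_cell(s)
        assert len(expanded) == 2

    def test_p212121_images_match_direct_operator_application(self):
        ops = _ops_for_space_group("P 21 21 21")
        cell = UnitCell(10, 11, 12, 90, 90, 90, symmetry_ops=ops, space_group="P 21 21 21")
        point = np.array([1.3, 2.1, 3.7])
        s = structure_from_points([point], unit_cell=cell)
        expanded = expand_unit_cell(s)
        assert len(expanded) == 4
        frac = cell.fractionalize(point)
        expected = {
            tuple(np.round(cell.orthogonalize((np.array(r) @ frac + np.array(t)) % 1.0), 6))
            for r, t in cell.operator_arrays()
        }
        got = {tuple(np.round(a.xyz, 6)) for a in expanded.atoms}
        assert got == expected

    def test_special_position_deduplicated(self):
        ops = _ops_for_space_group("P 1 21 1")
        cell = UnitCell(10, 12, 14, 90, 90, 90, symmetry_ops=ops, space_group="P 1 21 1")
        # a point on the 2-fold screw axis image coincides with itself
        point = cell.orthogonalize(np.array([0.0, 0.1, 0.0]))
        s = structure_from_points([point + np.array([0.0, 0.0, 0.0])], unit_cell=cell)
        expanded = expand_unit_cell(s)
        # the screw component separates the two images along b, so both remain
        assert len(expanded) == 2

    def test_missing_symmetry_raises(self):
        with pytest.raises(MissingSymmetryError):
            expand_unit_cell(structure_from_points([[0, 0, 0]]))


class TestPeriodicClearance:
    def test_empty_cell_is_capped_everywhere(self):
        # the cap is half the shortest cell edge
        grid = cubic_grid(8, edge=10.0)
        field = periodic_clearance(grid, Structure([]))
        np.testing.assert_allclose(field.values, 5.0)

    def test_single_atom_minimum_image_distances(self):
        grid = cubic_grid(10, edge=10.0)
        s = p1_structure([[0.0, 0.0, 0.0]])
        field = periodic_clearance(grid, s)
        r = vdw_radius("C")
        assert field.values[0, 0, 0] == 0.0  # on the atom: clamped at zero
        # body center: minimum-image distance is sqrt(3)*5
        expected = np.sqrt(3.0) * 5.0 - r
        assert field.values[5, 5, 5] == pytest.approx(min(expected, 5.0))

    def test_invariant_under_lattice_translation(self, rng):
        grid = cubic_grid(8, edge=8.0)
        pts = rng.uniform(0, 8, size=(5, 3))
        base = periodic_clearance(grid, p1_structure(pts, edge=8.0))
        shifted = periodic_clearance(grid, p1_structure(pts + [8.0, -16.0, 8.0], edge=8.0))
        np.testing.assert_allclose(base.values, shifted.values, atol=1e-9)


class TestLocalBottleneck:
    def test_fully_blocked_cell_gives_zero(self):
        grid = cubic_grid(5)
        field = local_bottleneck_field(ScalarField(grid=grid, values=np.zeros((5, 5, 5))))
        assert (field.local_bottleneck == 0).all()

    def test_uniform_open_cell_percolates_at_clearance(self):
        grid = cubic_grid(5)
        field = local_bottleneck_field(ScalarField(grid=grid, values=np.full((5, 5, 5), 2.5)))
        np.testing.assert_allclose(field.local_bottleneck, 2.5)

    def test_matches_bfs_oracle_on_random_periodic_grids(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            grid = cubic_grid(n)
            c = rng.integers(0, 8, size=(n, n, n)).astype(float) * 0.5
            field = local_bottleneck_field(ScalarField(grid=grid, values=c))
            np.testing.assert_allclose(field.local_bottleneck, naive_local_bottleneck(c))

    def test_bounded_by_clearance_pointwise(self, rng):
        n = 7
        grid = cubic_grid(n)
        c = rng.random((n, n, n)) * 3.0
        field = local_bottleneck_field(ScalarField(grid=grid, values=c))
        assert (field.local_bottleneck <= c + 1e-12).all()

    def test_tube_crystal_recovers_radius(self, tube_result):
        spacing = tube_result.field.grid.spacing
        assert tube_result.overall_bottleneck == pytest.approx(4.0, abs=spacing)
        assert tube_result.overall_bottleneck == tube_result.field.local_bottleneck.max()

    def test_constriction_ring_sets_the_bottleneck(self, constricted_tube_result):
        spacing = constricted_tube_result.field.grid.spacing
        assert constricted_tube_result.overall_bottleneck == pytest.approx(2.0, abs=spacing)

    def test_solid_cell_has_zero_bottleneck(self):
        solid = make_tube_crystal(tube_radius=0.0, cell_edge=12.0)
        result = run_channels(solid)
        assert result.overall_bottleneck == 0.0

    def test_overall_invariant_under_lattice_translation(self, tube_structure, tube_result):
        shifted = tube_structure.with_coords(tube_structure.coords() + [20.0, 20.0, -20.0])
        result = run_channels(shifted)
        assert result.overall_bottleneck == pytest.approx(
            tube_result.overall_bottleneck, abs=1e-9
        )


class TestSiteRadii:
    def test_neck_chamber_inner_is_neck_radius(self, neck_chamber_result):
        spacing = neck_chamber_result.field.grid.spacing
        assert neck_chamber_result.inner_site_radius == pytest.approx(2.0, abs=spacing)

    def test_neck_chamber_outer_is_channel_radius(self, neck_chamber_result):
        spacing = neck_chamber_result.field.grid.spacing
        assert neck_chamber_result.outer_site_radius == pytest.approx(5.0, abs=spacing)

    def test_disconnected_chamber_has_zero_inner_radius(self):
        s = make_neck_chamber(chamber_radius=5.0, neck_radius=0.0, channel_radius=5.0,
                              cell_edge=24.0)
        result = run_channels(s, ligand="LIG:L:1")
        assert result.inner_site_radius == 0.0

    def test_wide_neck_approaches_channel_radius(self):
        # neck as wide as the channel: no extra constriction, but the diagonal
        # neck path pays up to ~2 grid steps of 6-connectivity discretization
        s = make_neck_chamber(chamber_radius=5.0, neck_radius=5.0, channel_radius=5.0,
                              cell_edge=24.0)
        result = run_channels(s, ligand="LIG:L:1")
        spacing = result.field.grid.spacing
        assert 5.0 - 2 * spacing <= result.inner_site_radius <= 5.0 + spacing

    def test_no_ligand_leaves_site_radii_unset(self, tube_result):
        assert tube_result.inner_site_radius is None
        assert tube_result.outer_site_radius is None


class TestRunChannels:
    def test_missing_cryst1_is_actionable_error(self):
        with pytest.raises(MissingSymmetryError, match="CRYST1"):
            run_channels(structure_from_points([[0, 0, 0]]))

    def test_ccp4_export_round_trips_field(self, tmp_path, tube_structure):
        path = tmp_path / "channels.ccp4"
        result = run_channels(tube_structure, map_path=path)
        back = read_ccp4(path)
        np.testing.assert_array_equal(
            back.values, result.field.local_bottleneck.astype(np.float32)
        )

    def test_summary_fields(self, neck_chamber_result):
        summary = neck_chamber_result.to_summary()
        assert set(summary) == {
            "overall_bottleneck_A", "inner_site_radius_A", "outer_site_radius_A",
            "grid_shape", "grid_spacing_A",
        }
        assert summary["inner_site_radius_A"] <= summary["outer_site_radius_A"]
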