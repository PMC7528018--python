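"""Density model: MRC round-trips, Gaussian simulation, mirroring, envelopes."""

import gemmi
import numpy as np
import pytest

import stainfit as sf
from stainfit.density import largest_component


class TestMapIO:
    def test_round_trip_preserves_values_voxels_origin(self, small_map, tmp_path):
        path = tmp_path / "m.mrc"
        sf.write_map(small_map, path)
        back = sf.read_map(path)
        np.testing.assert_allclose(back.values, small_map.values, atol=1e-6)
        np.testing.assert_allclose(back.voxel_size, small_map.voxel_size)
        np.testing.assert_allclose(back.origin, small_map.origin)

    def test_round_trip_bitwise_for_float32_values(self, rng, tmp_path):
        vals = rng.random((8, 8, 8)).astype(np.float32).astype(np.float64)
        m = sf.DensityMap(vals, [1, 1, 1], [0, 0, 0])
        sf.write_map(m, tmp_path / "m.mrc")
        back = sf.read_map(tmp_path / "m.mrc")
        assert np.array_equal(back.values, vals)

    def test_origin_from_start_voxel_fields(self, tmp_path):
        # file carrying its origin only in NX/NY/NZSTART: origin = start * voxel
        vals = np.arange(8, dtype=np.float32).reshape(2, 2, 2)
        grid = gemmi.FloatGrid(np.ascontiguousarray(vals.transpose(2, 1, 0)))
        grid.set_unit_cell(gemmi.UnitCell(2 * 1.5, 2 * 1.5, 2 * 1.5, 90, 90, 90))
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header()
        for word, start in zip((5, 6, 7), (4, -2, 3)):
            ccp4.set_header_i32(word, start)
        ccp4.write_ccp4_map(str(tmp_path / "s.mrc"))
        back = sf.read_map(tmp_path / "s.mrc")
        np.testing.assert_allclose(back.origin, np.array([4, -2, 3]) * 1.5)

    def test_truncated_file_is_a_format_error(self, small_map, tmp_path):
        path = tmp_path / "t.mrc"
        sf.write_map(small_map, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="MRC"):
            sf.read_map(path)

    def test_unwritable_path_raises(self, small_map):
        with pytest.raises(OSError):
            sf.write_map(small_map, "/nonexistent-dir/x.mrc")


class TestValidation:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            sf.DensityMap(np.zeros((2, 2)), [1, 1, 1], [0, 0, 0])
        with pytest.raises(ValueError):
            sf.DensityMap(np.zeros((2, 2, 2)), [1, -1, 1], [0, 0, 0])
        bad = np.zeros((2, 2, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            sf.DensityMap(bad, [1, 1, 1], [0, 0, 0])

    def test_simulation_params_bounds(self):
        with pytest.raises(ValueError):
            sf.SimulationParams(resolution=-1)
        with pytest.raises(ValueError):
            sf.SimulationParams(sigma_factor=1.5)


def _single_atom_model(pos=(0.0, 0.0, 0.0)):
    return sf.AtomicModel(
        chains=np.array(["A"], dtype=object), resnums=np.array([1]),
        resnames=np.array(["ALA"], dtype=object), atom_names=np.array(["CA"], dtype=object),
        elements=np.array(["C"], dtype=object), positions=np.array([pos], float),
        weights=np.ones(1),
    )


class TestSimulateMap:
    def test_single_atom_peak_and_sigma_falloff(self):
        params = sf.SimulationParams(resolution=10.0, voxel_size=1.0)
        sim = sf.simulate_map(_single_atom_model(), params)
        kji = np.unravel_index(np.argmax(sim.values), sim.values.shape)
        peak_pos = sim.index_to_position(np.array([kji]))[0]
        assert np.linalg.norm(peak_pos) <= np.linalg.norm(sim.voxel_size) / 2
        # value one sigma along x from the atom
        sigma = params.sigma
        idx = np.rint(sim.position_to_index(np.array([[sigma, 0, 0]]))[0]).astype(int)
        value = sim.values[idx[0], idx[1], idx[2]]
        grid_offset = sim.index_to_position(np.array([idx]))[0]
        expected = np.exp(-np.sum(grid_offset ** 2) / (2 * sigma ** 2))
        assert value == pytest.approx(expected, rel=1e-6)

    def test_two_distant_atoms_are_additive(self):
        params = sf.SimulationParams(resolution=5.0, voxel_size=1.0)
        one = sf.simulate_map(_single_atom_model(), params)
        # > 10 sigma apart and a whole number of voxels, so the two atoms sit
        # identically on the lattice and cannot interfere within the cutoff
        far = 16.0
        both = sf.AtomicModel(
            chains=np.array(["A", "A"], dtype=object), resnums=np.array([1, 2]),
            resnames=np.array(["ALA"] * 2, dtype=object),
            atom_names=np.array(["CA"] * 2, dtype=object),
            elements=np.array(["C"] * 2, dtype=object),
            positions=np.array([[0, 0, 0], [far, 0, 0]], float), weights=np.ones(2),
        )
        sim = sf.simulate_map(both, params)
        assert sim.values.sum() == pytest.approx(2 * one.values.sum(), rel=1e-6)

    def test_grid_sum_matches_gaussian_integral(self):
        # 50-residue chain at 30 A, 4 A voxels: sum = n * (2 pi s^2)^{3/2} / v^3
        chain = sf.make_toy_chain(50, 0.5, seed=3)
        params = sf.SimulationParams(resolution=30.0, voxel_size=4.0)
        sim = sf.simulate_map(chain, params)
        sigma = params.sigma
        expected = 50 * (2 * np.pi * sigma ** 2) ** 1.5 / 4.0 ** 3
        assert sim.values.sum() == pytest.approx(expected, rel=0.01)

    def test_empty_model_rejected(self):
        empty = sf.AtomicModel(
            chains=np.array([], dtype=object), resnums=np.array([], int),
            resnames=np.array([], dtype=object), atom_names=np.array([], dtype=object),
            elements=np.array([], dtype=object), positions=np.zeros((0, 3)),
            weights=np.array([]),
        )
        with pytest.raises(ValueError):
            sf.simulate_map(empty, sf.SimulationParams())


class TestMirrorMap:
    @pytest.mark.parametrize("axis", ["x", "y", "z"])
    def test_involution_and_density_conservation(self, small_map, axis):
        once = sf.mirror_map(small_map, axis)
        assert once.values.sum() == small_map.values.sum()
        twice = sf.mirror_map(once, axis)
        assert np.array_equal(twice.values, small_map.values)
        np.testing.assert_allclose(once.origin, small_map.origin)

    def test_achiral_planar_model_mirror_equals_rotation(self):
        # points in the z=0 plane: the x-mirror of their map equals the map of
        # the model rotated 180 deg about the y axis
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.uniform(-6, 6, 7), rng.uniform(-6, 6, 7), np.zeros(7)])
        pts -= pts.mean(axis=0)
        n = len(pts)
        model = sf.AtomicModel(
            chains=np.array(["A"] * n, dtype=object), resnums=np.arange(1, n + 1),
            resnames=np.array(["ALA"] * n, dtype=object),
            atom_names=np.array(["CA"] * n, dtype=object),
            elements=np.array(["C"] * n, dtype=object), positions=pts, weights=np.ones(n),
        )
        params = sf.SimulationParams(resolution=8.0, voxel_size=1.0)
        base = sf.simulate_map(model, params)
        mirrored = sf.mirror_map(base, "x")
        # mirroring reflects through the plane through the grid center, so the
        # equivalent proper rotation is 180 deg about the y axis line through it
        center_x = base.origin[0] + (base.shape_xyz[0] - 1) / 2 * base.voxel_size[0]
        rot = sf.RigidTransform(np.diag([-1.0, 1.0, -1.0]),
                                np.array([2 * center_x, 0.0, 0.0]))
        rotated = sf.simulate_map(model.transformed(rot), params, like=mirrored)
        assert np.max(np.abs(mirrored.values - rotated.values)) < 1e-6 * base.values.max()

    def test_bad_axis_rejected(self, small_map):
        with pytest.raises(ValueError):
            sf.mirror_map(small_map, "w")


class TestEnvelopes:
    def test_binarize_extremes_and_exact_count(self):
        vals = np.zeros((3, 3, 3))
        vals.flat[[0, 5, 9, 13, 26]] = 0.5  # five voxels above 0.06
        m = sf.DensityMap(vals, [1, 1, 1], [0, 0, 0])
        assert sf.binarize(m, vals.max() + 1).count == 0
        assert sf.binarize(m, vals.min() - 1).count == 27
        assert sf.binarize(m, 0.06).count == 5

    def test_binarize_count_monotone_in_threshold(self, small_map):
        thresholds = np.linspace(small_map.values.min(), small_map.values.max(), 9)
        counts = [sf.binarize(small_map, t).count for t in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_surface_of_single_voxel_is_its_center(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        env = sf.Envelope(mask, 0.5, np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        pts = sf.surface_points(env)
        np.testing.assert_allclose(pts, [[3.0, 3.0, 3.0]])

    def test_surface_of_solid_cube_counts_faces(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[1:6, 1:6, 1:6] = True
        env = sf.Envelope(mask, 0.5, np.ones(3), np.zeros(3))
        assert len(sf.surface_points(env)) == 5 ** 3 - 3 ** 3

    def test_surface_matches_brute_force_neighbor_scan(self, rng):
        mask = rng.random((8, 8, 8)) > 0.6
        mask[3:5, 3:5, 3:5] = True  # guarantee non-empty
        env = sf.Envelope(mask, 0.5, np.ones(3), np.zeros(3))
        got = {tuple(p) for p in sf.surface_points(env)}
        expected = set()
        for k in range(8):
            for j in range(8):
                for i in range(8):
                    if not mask[k, j, i]:
                        continue
                    for dk, dj, di in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                                       (0, 0, 1), (0, 0, -1)):
                        kk, jj, ii = k + dk, j + dj, i + di
                        outside = not (0 <= kk < 8 and 0 <= jj < 8 and 0 <= ii < 8)
                        if outside or not mask[kk, jj, ii]:
                            expected.add((float(i), float(j), float(k)))
                            break
        assert got == expected

    def test_empty_mask_has_no_surface(self):
        env = sf.Envelope(np.zeros((2, 2, 2), bool), 0.5, np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            sf.surface_points(env)

    def test_largest_component_drops_specks(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[1:5, 1:5, 1:5] = True  # 64-voxel blob
        mask[7, 7, 7] = True        # isolated speck
        env = sf.Envelope(mask, 0.5, np.ones(3), np.zeros(3))
        cleaned = largest_component(env)
        assert cleaned.count == 64
        assert not cleaned.mask[7, 7, 7]


class TestSimulationEquivariance:
    def test_grid_aligned_translation_equivariance(self):
        # translating the model by whole voxels shifts the simulation exactly
        chain = sf.make_toy_chain(20, 0.5, seed=2)
        params = sf.SimulationParams(resolution=12.0, voxel_size=2.0)
        base = sf.simulate_map(chain, params)
        shift = np.array([4.0, -6.0, 2.0])  # multiples of the voxel size
        moved = chain.transformed(sf.RigidTransform(np.eye(3), shift))
        shifted_grid = sf.DensityMap(base.values, base.voxel_size, base.origin + shift)
        resim = sf.simulate_map(moved, params, like=shifted_grid)
        np.testing.assert_allclose(resim.values, base.values, atol=1e-12)
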