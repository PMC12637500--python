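"""Density rendering, stitching, interpolation, resampling, and map I/O."""

import copy

import numpy as np
import pytest

from cryoshell.density_builder import (
    DensityConfig,
    DensityGrid,
    Lattice,
    ScatteringTable,
    default_scattering_table,
    ensemble_to_map,
    probability_density,
    read_mrc,
    resample_onto,
    scattering_density,
    stitch,
    trilinear,
    write_mrc,
)
from cryoshell.ensemble_io import AtomSite, ReferenceStructure
from cryoshell.synthetic_fixtures import (
    FixtureSpec,
    make_solvent_ensemble,
    resolve_sites,
)


def _lattice(origin=(0, 0, 0), spacing=0.82, shape=(12, 12, 12)):
    return Lattice(origin=tuple(float(v) for v in origin),
                   spacing=(spacing,) * 3, shape=shape)


def _gauss_profile(element, r2):
    a, b = default_scattering_table().lookup(element)
    amp = a * (4 * np.pi / b) ** 1.5
    return float(np.sum(amp * np.exp(-4 * np.pi ** 2 * r2 / b)))


class TestScatteringDensity:
    def test_peak_at_atom_voxel_and_hard_cutoff(self):
        lat = _lattice(origin=(-4.92, -4.92, -4.92), shape=(13, 13, 13))
        grid = scattering_density((np.zeros((1, 3)), ["O"]), lat)
        assert np.unravel_index(np.argmax(grid.values), grid.values.shape) \
            == (6, 6, 6)
        xs = lat.all_centers_1d()[0]
        dist = np.sqrt(xs[:, None, None] ** 2 + xs[None, :, None] ** 2
                       + xs[None, None, :] ** 2)
        assert np.all(grid.values[dist > 4.0] == 0.0)
        assert np.all(grid.values[dist <= 4.0] > 0.0)

    def test_linearity_two_atoms(self):
        lat = _lattice()
        a = scattering_density((np.array([[2.0, 2.0, 2.0]]), ["O"]), lat)
        b = scattering_density((np.array([[5.0, 5.0, 5.0]]), ["Mg"]), lat)
        both = scattering_density(
            (np.array([[2.0, 2.0, 2.0], [5.0, 5.0, 5.0]]), ["O", "Mg"]), lat)
        assert np.allclose(both.values, a.values + b.values, atol=1e-12)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(5)
        lat = _lattice(shape=(9, 9, 9))
        coords = rng.uniform(0.0, 6.5, size=(20, 3))
        elements = list(rng.choice(["O", "N", "C", "Mg", "K"], size=20))
        grid = scattering_density((coords, elements), lat)
        xs, ys, zs = lat.all_centers_1d()
        expected = np.zeros(lat.shape)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                for k, z in enumerate(zs):
                    v = 0.0
                    for pos, el in zip(coords, elements):
                        r2 = (x - pos[0]) ** 2 + (y - pos[1]) ** 2 \
                            + (z - pos[2]) ** 2
                        if r2 <= 16.0:
                            v += _gauss_profile(el, r2)
                    expected[i, j, k] = v
        scale = np.abs(expected).max()
        assert np.allclose(grid.values, expected, atol=1e-9 * scale)

    def test_unknown_element_named_in_error(self):
        with pytest.raises(KeyError, match="Xx"):
            scattering_density((np.zeros((1, 3)), ["Xx"]), _lattice())

    def test_divisor_scales_to_per_model_average(self):
        lat = _lattice()
        one = scattering_density((np.array([[2.0, 2, 2]]), ["O"]), lat)
        half = scattering_density((np.array([[2.0, 2, 2]]), ["O"]), lat,
                                  divisor=2.0)
        assert np.allclose(half.values, one.values / 2.0, atol=1e-15)


class TestProbabilityDensity:
    def test_single_atom_single_count(self):
        lat = _lattice()
        grid = probability_density((np.array([[2.0, 2.0, 2.0]]), ["O"]), lat)
        assert np.count_nonzero(grid.values) == 1
        assert grid.values.sum() == 1.0

    def test_count_conservation(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0.5, 8.5, size=(40, 3))
        grid = probability_density((coords, ["O"] * 40), _lattice(),
                                   divisor=4.0)
        assert grid.values.sum() * 4.0 == pytest.approx(40.0)

    def test_half_voxel_offset_recount_oracle(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(1.0, 8.0, size=(30, 3))
        for shift in (0.0, 0.41):
            lat = _lattice(origin=(shift, shift, shift))
            grid = probability_density((coords, ["O"] * 30), lat)
            # explicit binning oracle
            expected = np.zeros(lat.shape)
            for pos in coords:
                idx = np.floor((pos - lat.origin_a) / lat.spacing_a
                               + 0.5).astype(int)
                if np.all(idx >= 0) and np.all(idx < np.array(lat.shape)):
                    expected[tuple(idx)] += 1
            assert np.array_equal(grid.values, expected)
            assert grid.values.sum() == 30.0

    def test_atom_outside_grid_not_counted(self):
        grid = probability_density((np.array([[50.0, 0, 0]]), ["O"]),
                                   _lattice())
        assert grid.values.sum() == 0.0


class TestTrilinear:
    def test_voxel_center_identity_and_midpoint(self):
        lat = _lattice(shape=(4, 4, 4))
        rng = np.random.default_rng(8)
        grid = DensityGrid(lat, rng.normal(size=lat.shape))
        assert trilinear(grid, lat.voxel_centers([[1, 2, 1]])) == \
            pytest.approx(grid.values[1, 2, 1], abs=1e-12)
        mid = lat.voxel_centers([[1.5, 2.0, 1.0]])
        assert trilinear(grid, mid) == pytest.approx(
            0.5 * (grid.values[1, 2, 1] + grid.values[2, 2, 1]), abs=1e-12)

    def test_matches_explicit_8corner_formula(self):
        lat = _lattice(shape=(5, 5, 5))
        rng = np.random.default_rng(9)
        grid = DensityGrid(lat, rng.normal(size=lat.shape))
        pts = lat.origin_a + rng.uniform(0.0, 4.0 * 0.82, size=(50, 3))
        got = trilinear(grid, pts)
        for p, g in zip(pts, got):
            f = (p - lat.origin_a) / lat.spacing_a
            i = np.floor(f).astype(int)
            t = f - i
            v = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((t[0] if dx else 1 - t[0])
                             * (t[1] if dy else 1 - t[1])
                             * (t[2] if dz else 1 - t[2]))
                        v += w * grid.values[i[0] + dx, i[1] + dy, i[2] + dz]
            assert g == pytest.approx(v, abs=1e-12)

    def test_outside_hull_rejected(self):
        lat = _lattice(shape=(4, 4, 4))
        grid = DensityGrid(lat, np.ones(lat.shape))
        with pytest.raises(ValueError):
            trilinear(grid, np.array([[-1.0, 0.0, 0.0]]))


class TestResample:
    def test_identity_lattice(self):
        lat = _lattice(shape=(6, 6, 6))
        grid = DensityGrid(lat, np.random.default_rng(10).normal(size=lat.shape))
        out = resample_onto(grid, lat)
        assert np.allclose(out.values, grid.values, atol=1e-12)

    def test_constant_field_stays_constant(self):
        src = DensityGrid(_lattice(shape=(8, 8, 8)), np.full((8, 8, 8), 3.5))
        target = _lattice(origin=(0.3, 0.3, 0.3), spacing=0.5, shape=(6, 6, 6))
        out = resample_onto(src, target)
        assert np.allclose(out.values, 3.5, atol=1e-12)

    def test_downsample_matches_direct_evaluation(self):
        lat = _lattice(shape=(9, 9, 9))
        grid = DensityGrid(lat, np.random.default_rng(11).normal(size=lat.shape))
        target = _lattice(origin=(0.41, 0.41, 0.41), spacing=1.64,
                          shape=(4, 4, 4))
        out = resample_onto(grid, target)
        xs, ys, zs = target.all_centers_1d()
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                for k, z in enumerate(zs):
                    assert out.values[i, j, k] == pytest.approx(
                        trilinear(grid, np.array([[x, y, z]]))[0], abs=1e-12)

    def test_outside_hull_is_zero(self):
        src = DensityGrid(_lattice(shape=(4, 4, 4)), np.ones((4, 4, 4)))
        target = _lattice(origin=(-8.2, -8.2, -8.2), shape=(6, 6, 6))
        out = resample_onto(src, target)
        assert out.values[0, 0, 0] == 0.0


def _point_ref(positions):
    """Reference with one single-P residue at each position (for stitching)."""
    atoms = [AtomSite(element="P", atom_name="P", residue_name="G",
                      residue_index=i + 1, chain_id="A",
                      coords=np.asarray(p, dtype=float), species="RNA")
             for i, p in enumerate(positions)]
    return ReferenceStructure(atoms=atoms)


class TestStitch:
    def test_single_region_passthrough_and_1_over_r_average(self):
        target = _lattice(shape=(5, 5, 5))
        probe = (2, 2, 2)  # voxel center at (1.64, 1.64, 1.64)
        center_xyz = np.asarray(target.voxel_centers([probe]))[0]
        # residue 1 at r=1 from the probe voxel, residue 2 at r=3
        ref = _point_ref([center_xyz + [1.0, 0, 0], center_xyz + [3.0, 0, 0]])
        a = DensityGrid(target, np.full(target.shape, 2.0))
        b = DensityGrid(target, np.full(target.shape, 6.0))
        only_a = stitch([(a, 1)], ref, target)
        assert only_a.values[probe] == pytest.approx(2.0, abs=1e-12)
        both = stitch([(a, 1), (b, 2)], ref, target)
        # weights 1/1 and 1/3 -> (3*2 + 6) / 4
        assert both.values[probe] == pytest.approx(3.0, abs=1e-12)

    def test_equal_distance_gives_arithmetic_mean(self):
        target = _lattice(shape=(5, 5, 5))
        center_xyz = np.asarray(target.voxel_centers([(2, 2, 2)]))[0]
        ref = _point_ref([center_xyz + [2.0, 0, 0], center_xyz - [2.0, 0, 0]])
        a = DensityGrid(target, np.full(target.shape, 1.0))
        b = DensityGrid(target, np.full(target.shape, 5.0))
        out = stitch([(a, 1), (b, 2)], ref, target)
        assert out.values[2, 2, 2] == pytest.approx(3.0, abs=1e-12)

    def test_output_bounded_by_contributing_values(self):
        rng = np.random.default_rng(12)
        target = _lattice(shape=(6, 6, 6))
        ref = _point_ref([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        a = DensityGrid(target, rng.uniform(0, 1, size=target.shape))
        b = DensityGrid(target, rng.uniform(0, 1, size=target.shape))
        out = stitch([(a, 1), (b, 2)], ref, target)
        lo = np.minimum(a.values, b.values)
        hi = np.maximum(a.values, b.values)
        assert np.all(out.values >= lo - 1e-12)
        assert np.all(out.values <= hi + 1e-12)


class TestEnsembleToMap:
    def test_identical_models_equal_single_model(self, ref4):
        spec = FixtureSpec(n_residues=4, n_models=1, seed=7)
        one = make_solvent_ensemble(ref4, spec)
        from cryoshell.ensemble_io import SolventEnsemble
        clones = SolventEnsemble(models=[
            copy.deepcopy(one.models[0]) for _ in range(4)])
        for i, m in enumerate(clones.models):
            m.model_index = i + 1
        a = ensemble_to_map(one, ref4)
        b = ensemble_to_map(clones, ref4)
        assert np.allclose(a.total.values, b.total.values, atol=1e-9)

    def test_species_maps_sum_to_total(self, small_maps):
        total = sum(small_maps[sp].values for sp in small_maps
                    if sp != "total")
        assert np.allclose(small_maps.total.values, total, atol=1e-9)

    def test_planted_sites_produce_peaks_at_site_positions(self, ref12,
                                                           spec12, clean12):
        grid = clean12.total
        sites = resolve_sites(ref12, spec12)
        lat = grid.lattice
        pos = np.array([s.position for s in sites])
        # only well-occupied sites without a close neighbor give a clean
        # single-site peak inside a +-2 voxel patch
        isolated = []
        for i, site in enumerate(sites):
            others = np.delete(pos, i, axis=0)
            nearest = np.min(np.linalg.norm(others - pos[i], axis=1))
            if site.occupancy >= 0.7 and nearest >= 3.5:
                isolated.append(site)
        assert len(isolated) >= 3
        for site in isolated:
            idx = np.round(lat.fractional_index(
                np.asarray(site.position))).astype(int)
            lo = np.maximum(idx - 2, 0)
            hi = np.minimum(idx + 3, np.array(lat.shape))
            patch = grid.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            local_max = np.unravel_index(np.argmax(patch), patch.shape)
            # argmax of the local patch within 1 voxel of the planted site
            assert np.all(np.abs(np.array(local_max) + lo - idx) <= 1)

    def test_bfactors_never_influence_density(self, ref4, small_ensemble):
        perturbed = copy.deepcopy(small_ensemble)
        for model in perturbed.models:
            for atom in model.atoms:
                atom.b_factor = atom.b_factor + 57.0
        a = ensemble_to_map(small_ensemble, ref4)
        b = ensemble_to_map(perturbed, ref4)
        assert np.array_equal(a.total.values, b.total.values)

    def test_probability_method_runs_and_sums(self, ref4, small_ensemble):
        maps = ensemble_to_map(small_ensemble, ref4,
                               DensityConfig(density_method="prob"))
        total = sum(maps[sp].values for sp in maps if sp != "total")
        assert np.allclose(maps.total.values, total, atol=1e-9)
        assert maps.total.values.max() > 0

    def test_subsampling_convergence(self, ref4):
        """Maps from more frames of one distribution are closer to truth."""
        spec_big = FixtureSpec(n_residues=4, n_models=96, seed=21)
        big = ensemble_to_map(make_solvent_ensemble(ref4, spec_big), ref4)
        diffs = []
        for n in (6, 24):
            spec = FixtureSpec(n_residues=4, n_models=n, seed=31)
            sub = ensemble_to_map(make_solvent_ensemble(ref4, spec), ref4)
            diffs.append(np.sqrt(np.mean(
                (sub.total.values - big.total.values) ** 2)))
        assert diffs[1] < diffs[0]


class TestMrcIO:
    def test_round_trip_values_exact(self, tmp_path):
        lat = _lattice(origin=(1.5, -2.25, 3.0), shape=(7, 6, 5))
        values = np.random.default_rng(13).normal(size=lat.shape)
        path = tmp_path / "map.mrc"
        write_mrc(DensityGrid(lat, values), path)
        back = read_mrc(path)
        assert back.lattice.shape == lat.shape
        assert np.allclose(back.lattice.origin_a, lat.origin_a, atol=1e-6)
        assert np.allclose(back.lattice.spacing_a, lat.spacing_a, atol=1e-6)
        # mode-2 maps store 32-bit floats; values must round-trip bit-exactly
        assert np.array_equal(back.values, values.astype(np.float32))
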