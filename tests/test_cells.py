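"""Grid, place, object-vector and border cells, rate maps, sparsity."""

import numpy as np
import pytest

from stnef.cells import (
    RateMap,
    gridness_score,
    grid_cell_population,
    nearest_object_displacement,
    place_cell_population,
    rate_map,
    vector_cell_population,
    wall_displacement,
)
from stnef.populations import static_tuning


@pytest.fixture(scope="module")
def arena():
    return [(-0.9, 0.9), (-0.9, 0.9)]


def dense_scan(step=0.03, lim=0.87):
    g = np.arange(-lim, lim + 1e-9, step)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel()], axis=1)


class TestGridCells:
    def test_requires_hex_space(self, ssp_space_2d):
        with pytest.raises(ValueError):
            grid_cell_population(ssp_space_2d, 5)

    def test_sparsity_bounds(self, hex_space, arena):
        with pytest.raises(ValueError):
            grid_cell_population(hex_space, 5, sparsity=0.0, arena=arena)

    def test_sparsity_by_construction(self, hex_space, arena, rng):
        pop = grid_cell_population(hex_space, 60, sparsity=0.10, arena=arena, seed=0)
        xs = rng.uniform(-0.9, 0.9, (600, 2))
        active = static_tuning(pop, hex_space.encode(xs)) > 0
        assert active.mean() == pytest.approx(0.10, abs=0.03)

    def test_sparsity_monotone_in_bias(self, hex_space, arena, rng):
        xs = rng.uniform(-0.9, 0.9, (400, 2))
        fractions = []
        for sp in (0.05, 0.15, 0.4):
            pop = grid_cell_population(hex_space, 40, sparsity=sp, arena=arena, seed=1)
            fractions.append((static_tuning(pop, hex_space.encode(xs)) > 0).mean())
        assert fractions[0] < fractions[1] < fractions[2]

    def test_activity_is_nonlinearity_of_three_plane_waves(self, hex_space, arena):
        """A grid neuron's current is a linear combination of three plane
        waves (its module's wave triplet): check the encoder's frequency
        support is confined to one triplet."""
        pop = grid_cell_population(hex_space, 10, sparsity=0.2, arena=arena, seed=2)
        for i in range(10):
            spec = np.abs(np.fft.fft(pop.encoders[i]))
            support = np.flatnonzero(spec > 1e-9 * spec.max())
            pos = support[(support > 0) & (support <= hex_space.n_pairs)]
            assert len(pos) == 3
            module = (pos[0] - 1) // 3
            assert np.all((pos - 1) // 3 == module)

    def test_rate_maps_hexagonal(self, hex_space, arena):
        pop = grid_cell_population(hex_space, 15, sparsity=0.15, arena=arena, seed=3)
        pos = dense_scan()
        acts = static_tuning(pop, hex_space.encode(pos))
        maps = rate_map(acts, pos, 1.0, bin_size=0.06)
        scores = np.array([gridness_score(m) for m in maps])
        assert (scores > 0).mean() >= 0.8

    def test_grid_spacing_tracks_module_scale(self, arena):
        """Field spacing scales linearly with the module wavelength."""
        from scipy.ndimage import maximum_filter
        from stnef.ssp import make_encoding_matrix

        spacings, wavelengths = [], []
        for scale in (1.0, 1.5, 2.0):
            space = make_encoding_matrix(
                0, 2, "hex", length_scale=0.15, seed=0, n_scales=1, n_orientations=1,
                scale_range=(scale, scale),
            )
            k = np.linalg.norm(space.module_waves[0, 0])
            window = [(-1.6, 1.6), (-1.6, 1.6)]  # wide enough for the coarsest ring
            sims, axes = space.similarity_grid(space.encode([0.0, 0.0]), window, 161)
            local = (sims == maximum_filter(sims, size=7)) & (sims > 0.5 * sims.max())
            ys, xs = np.nonzero(local)
            pts = np.stack([axes[0][ys], axes[1][xs]], axis=1)
            r = np.linalg.norm(pts, axis=1)
            ring = np.sort(r[r > 0.05])
            spacings.append(ring[0])
            wavelengths.append(4 * np.pi / (np.sqrt(3) * k))
        fit = np.polyfit(wavelengths, spacings, 1)
        pred = np.polyval(fit, wavelengths)
        ss_res = np.sum((spacings - pred) ** 2)
        ss_tot = np.sum((spacings - np.mean(spacings)) ** 2)
        assert 1 - ss_res / ss_tot > 0.9
        np.testing.assert_allclose(spacings, wavelengths, rtol=0.1)


class TestPlaceCells:
    def test_field_centred_at_centre(self, hex_space, arena):
        centres = np.array([[0.3, -0.2], [-0.5, 0.4]])
        pop = place_cell_population(hex_space, centres, sparsity=0.1, arena=arena, seed=4)
        pos = dense_scan()
        acts = static_tuning(pop, hex_space.encode(pos))
        maps = rate_map(acts, pos, 1.0, bin_size=0.05)
        for j, c in enumerate(centres):
            # centroid of the main field (above half max): the hex kernel's
            # side lobes would otherwise bias the whole-map centroid
            m = maps[j]
            r = np.nan_to_num(m.rates)
            main = RateMap(np.maximum(r - 0.5 * r.max(), 0.0), m.occupancy, m.extent)
            centroid = main.centroid()
            assert np.linalg.norm(centroid - c) < 0.2 * hex_space.length_scale
            # rate at centre far exceeds rate three length scales away
            at_centre = static_tuning(pop, hex_space.encode(c))[j]
            far = c + np.array([3 * hex_space.length_scale, 0])
            at_far = static_tuning(pop, hex_space.encode(far))[j]
            assert at_centre > at_far

    def test_distant_centres_near_orthogonal_encoders(self, ssp_space_2d, arena):
        pop = place_cell_population(
            ssp_space_2d, np.array([[-2.0, -2.0], [2.0, 2.0]]), arena=arena, seed=5
        )
        cos = abs(float(pop.encoders[0] @ pop.encoders[1]))
        assert cos < 0.2


class TestVectorCells:
    def test_no_targets_rejected(self, ssp_space_2d):
        with pytest.raises(ValueError):
            vector_cell_population(ssp_space_2d, np.empty((0, 2)))

    def test_object_vector_field_at_fixed_offset(self, ssp_space_2d):
        """The cell fires at its preferred offset from every object, and
        moving an object translates the field with it."""
        offset = np.array([0.4, 0.0])
        pop = vector_cell_population(ssp_space_2d, offset[None, :], sparsity=0.1, seed=6)

        def field_centroid(objects):
            pos = dense_scan(0.05, 1.5)
            disp = np.array([nearest_object_displacement(p, objects) for p in pos])
            acts = static_tuning(pop, ssp_space_2d.encode(disp))
            m = rate_map(acts, pos, 1.0, bin_size=0.08)[0]
            return m.centroid()

        objects = np.array([[0.5, 0.5]])
        c1 = field_centroid(objects)
        np.testing.assert_allclose(c1, objects[0] - offset, atol=0.1)
        shift = np.array([-0.6, 0.3])
        c2 = field_centroid(objects + shift)
        np.testing.assert_allclose(c2 - c1, shift, atol=0.2 * ssp_space_2d.length_scale)

    def test_border_cell_hugs_wall(self, ssp_space_2d):
        wall = (np.array([0.9, -0.9]), np.array([0.9, 0.9]))  # right side
        pref = np.array([[0.15, 0.0]])  # prefers the wall slightly to the right
        pop = vector_cell_population(ssp_space_2d, pref, sparsity=0.15, seed=7)
        pos = dense_scan(0.05)
        disp = np.array([wall_displacement(p, wall) for p in pos])
        acts = static_tuning(pop, ssp_space_2d.encode(disp))
        active = pos[acts[:, 0] > 0]
        assert len(active) > 0
        # activity is a stripe along the right wall: confined in x, spread in y
        assert active[:, 0].min() > 0.25
        assert active[:, 0].mean() > 0.55
        assert active[:, 1].std() > 0.3

    def test_max_range_visibility(self):
        objs = np.array([[1.0, 0.0]])
        assert nearest_object_displacement([0.0, 0.0], objs, max_range=0.5) is None
        d = nearest_object_displacement([0.8, 0.0], objs, max_range=0.5)
        np.testing.assert_allclose(d, [0.2, 0.0])


class TestRateMap:
    def test_uniform_firing_flat_map(self, rng):
        pos = rng.uniform(-1, 1, (2000, 2))
        acts = np.full((2000, 1), 25.0)
        m = rate_map(acts, pos, 0.02, bin_size=0.25)[0]
        assert np.nanstd(m.rates) == pytest.approx(0.0, abs=1e-9)
        assert np.nanmean(m.rates) == pytest.approx(25.0)

    def test_unvisited_bins_invalid(self):
        pos = np.array([[0.1, 0.1], [0.9, 0.9]])
        acts = np.ones((2, 1))
        m = rate_map(acts, pos, 0.1, bin_size=0.2, extent=(0, 1, 0, 1))[0]
        assert np.isnan(m.rates[~m.valid]).all()
        assert (~m.valid).sum() > 0

    def test_halving_bin_size_keeps_centroid(self, hex_space, arena):
        pop = place_cell_population(hex_space, np.array([[0.2, 0.1]]), arena=arena, seed=8)
        pos = dense_scan(0.04)
        acts = static_tuning(pop, hex_space.encode(pos))
        c1 = rate_map(acts, pos, 1.0, bin_size=0.1)[0].centroid()
        c2 = rate_map(acts, pos, 1.0, bin_size=0.05)[0].centroid()
        assert np.linalg.norm(c1 - c2) < 0.1
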