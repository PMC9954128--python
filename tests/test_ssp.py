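"""Spatial Semantic Pointer encoding, binding algebra, and map queries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stnef.ssp import (
    ConceptVocabulary,
    SSPSpace,
    bind,
    build_map,
    make_encoding_matrix,
    make_unitary,
    query_map,
    unbind,
)

coord = st.floats(min_value=-5.0, max_value=5.0, allow_nan=False)


class TestEncoding:
    def test_unit_norm_and_real(self, ssp_space_2d, rng):
        for _ in range(20):
            x = rng.uniform(-4, 4, 2)
            v = ssp_space_2d.encode(x)
            assert v.dtype.kind == "f"
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_origin_is_binding_identity(self, ssp_space_2d):
        v0 = ssp_space_2d.encode(np.zeros(2))
        np.testing.assert_allclose(np.fft.fft(v0), np.ones(ssp_space_2d.d), atol=1e-10)

    def test_self_similarity_one(self, ssp_space_2d):
        v = ssp_space_2d.encode([1.3, -0.4])
        assert v @ v == pytest.approx(1.0, abs=1e-12)

    def test_even_d_rejected(self):
        with pytest.raises(ValueError):
            make_encoding_matrix(100, 2, "random", seed=0)

    def test_bad_m_rejected(self):
        with pytest.raises(ValueError):
            make_encoding_matrix(101, 4, "random", seed=0)

    def test_kernel_shift_invariance(self, ssp_space_2d, rng):
        for _ in range(10):
            x = rng.uniform(-2, 2, 2)
            delta = rng.uniform(-1, 1, 2)
            shift = rng.uniform(-2, 2, 2)
            k1 = ssp_space_2d.encode(x) @ ssp_space_2d.encode(x + delta)
            k2 = ssp_space_2d.encode(x + shift) @ ssp_space_2d.encode(x + shift + delta)
            assert k1 == pytest.approx(k2, abs=1e-10)


class TestBinding:
    @given(x1=coord, y1=coord, x2=coord, y2=coord)
    @settings(max_examples=40, deadline=None)
    def test_homomorphism(self, ssp_space_2d, x1, y1, x2, y2):
        a = ssp_space_2d.encode([x1, y1])
        b = ssp_space_2d.encode([x2, y2])
        target = ssp_space_2d.encode([x1 + x2, y1 + y2])
        np.testing.assert_allclose(bind(a, b), target, atol=1e-10)

    def test_unbind_exact_for_unitary(self, rng):
        u = make_unitary(101, rng)
        a = rng.standard_normal(101)
        np.testing.assert_allclose(unbind(bind(a, u), u), a, atol=1e-12)

    def test_commutative_associative(self, rng):
        a, b, c = (rng.standard_normal(101) for _ in range(3))
        np.testing.assert_allclose(bind(a, b), bind(b, a), atol=1e-10)
        np.testing.assert_allclose(bind(bind(a, b), c), bind(a, bind(b, c)), atol=1e-10)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            bind(np.ones(7), np.ones(9))


class TestKernel:
    def test_1d_kernel_matches_sinc(self):
        space = make_encoding_matrix(301, 1, "random", length_scale=0.5, seed=2)
        dx = np.linspace(-3, 3, 301)[:, None]
        k = space.similarity(space.encode(np.zeros(1)), dx)
        sinc = np.sinc(dx[:, 0] / 0.5)
        assert np.abs(k - sinc).max() < 0.05

    def test_hex_similarity_has_sixfold_symmetry(self):
        # single-module space: summing many orientations would wash the
        # angular structure out
        space = make_encoding_matrix(
            0, 2, "hex", length_scale=0.5, seed=0, n_scales=1, n_orientations=1
        )
        v = space.encode([0.0, 0.0])
        r = 0.8
        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        sims = np.array([space.similarity(v, [r * np.cos(a), r * np.sin(a)]) for a in angles])
        rot60 = np.roll(sims, 2)  # 60 degrees = 2 steps of 30
        np.testing.assert_allclose(sims, rot60, atol=1e-9)
        rot30 = np.roll(sims, 1)
        assert np.abs(sims - rot30).max() > 1e-3

    def test_hex_map_shows_hexagonal_peaks(self):
        """Similarity map of a single hex module has a ring of >= 6 peaks."""
        from scipy.ndimage import maximum_filter

        space = make_encoding_matrix(
            0, 2, "hex", length_scale=0.3, seed=0, n_scales=1, n_orientations=1
        )
        sims, axes = space.similarity_grid(space.encode([0.0, 0.0]), [(-2, 2), (-2, 2)], 161)
        local_max = (sims == maximum_filter(sims, size=9)) & (sims > 0.5 * sims.max())
        ys, xs = np.nonzero(local_max)
        pts = np.stack([axes[0][ys], axes[1][xs]], axis=1)
        r = np.linalg.norm(pts, axis=1)
        ring = pts[(r > 0.05)]
        assert len(ring) >= 6
        # the six nearest ring peaks sit at ~60 degree spacing
        nearest = ring[np.argsort(np.linalg.norm(ring, axis=1))[:6]]
        ang = np.sort(np.mod(np.arctan2(nearest[:, 1], nearest[:, 0]), 2 * np.pi))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        np.testing.assert_allclose(gaps, np.pi / 3, atol=0.15)


class TestDecode:
    def test_roundtrip(self, ssp_space_2d):
        x = np.array([0.62, -1.41])
        x_hat, peak, reliable = ssp_space_2d.decode(ssp_space_2d.encode(x), [(-3, 3), (-3, 3)])
        assert reliable
        np.testing.assert_allclose(x_hat, x, atol=1e-3 * ssp_space_2d.length_scale)
        assert peak == pytest.approx(1.0, abs=1e-6)

    def test_bound_pair_decodes_to_sum(self, ssp_space_2d):
        v = bind(ssp_space_2d.encode([0.5, 0.25]), ssp_space_2d.encode([1.0, -0.75]))
        x_hat, _, _ = ssp_space_2d.decode(v, [(-3, 3), (-3, 3)])
        np.testing.assert_allclose(x_hat, [1.5, -0.5], atol=1e-3)

    def test_noise_robustness(self, rng):
        space = make_encoding_matrix(129, 2, "random", length_scale=0.5, seed=3)
        errs = []
        for _ in range(10):
            x = rng.uniform(-1.5, 1.5, 2)
            noise = rng.standard_normal(129)
            noise *= 0.3 / np.linalg.norm(noise)
            x_hat, _, _ = space.decode(space.encode(x) + noise, [(-2, 2), (-2, 2)])
            errs.append(np.linalg.norm(x_hat - x))
        assert np.median(errs) < 0.1 * space.length_scale

    def test_garbage_flagged_unreliable(self, ssp_space_2d, rng):
        noise = rng.standard_normal(ssp_space_2d.d) * 0.05
        _, _, reliable = ssp_space_2d.decode(noise, [(-2, 2), (-2, 2)])
        assert not reliable


class TestRegionsAndMaps:
    def test_region_point_degenerate(self, ssp_space_2d):
        pt = np.array([[0.4, 0.9]])
        v = ssp_space_2d.encode_region(pt, spacing=0.1)
        np.testing.assert_allclose(v, ssp_space_2d.encode([0.4, 0.9]) * 0.01, atol=1e-12)

    def test_region_similarity_inside_vs_outside(self, ssp_space_2d):
        from shapely.geometry import box

        region = box(-0.5, -0.5, 0.5, 0.5)
        v = ssp_space_2d.encode_region(region)
        ls = ssp_space_2d.length_scale
        inside = [ssp_space_2d.similarity(v, p) for p in ([0, 0], [0.3, 0.2], [-0.4, 0.4])]
        outside = [
            ssp_space_2d.similarity(v, p)
            for p in ([0.5 + 2.5 * ls, 0], [0, -0.5 - 2.5 * ls], [3, 3])
        ]
        assert np.mean(inside) > np.mean(outside)

    def test_region_quadrature_converges(self, ssp_space_2d):
        from shapely.geometry import box

        region = box(-0.4, -0.4, 0.4, 0.4)
        v1 = ssp_space_2d.encode_region(region, spacing=ssp_space_2d.length_scale / 4)
        v2 = ssp_space_2d.encode_region(region, spacing=ssp_space_2d.length_scale / 8)
        assert np.linalg.norm(v1 - v2) / np.linalg.norm(v2) < 0.01

    def _environment(self, _space_unused=None):
        # map queries need headroom above binding crosstalk: use d = 251
        space = make_encoding_matrix(251, 2, "random", length_scale=0.5, seed=11)
        vocab = ConceptVocabulary(space.d, seed=5).add("rat", "cheese", "wall")
        from shapely.geometry import box

        items = [
            ("rat", np.array([-1.0, -0.5])),
            ("cheese", np.array([[1.2, 0.8], [-0.8, 1.1]])),
            ("wall", box(1.6, -2.0, 1.9, 2.0)),
        ]
        return build_map(space, vocab, items), items

    def test_map_query_peaks_at_locations(self, ssp_space_2d):
        env, items = self._environment(ssp_space_2d)
        sims, axes = query_map(env, "rat", [(-2, 2), (-2, 2)], resolution=81)
        iy, ix = np.unravel_index(np.argmax(sims), sims.shape)
        cell = axes[0][1] - axes[0][0]
        assert abs(axes[0][iy] - (-1.0)) <= cell
        assert abs(axes[1][ix] - (-0.5)) <= cell

    def test_cheese_query_two_peaks(self, ssp_space_2d):
        from scipy.ndimage import maximum_filter

        env, items = self._environment(ssp_space_2d)
        sims, axes = query_map(env, "cheese", [(-2, 2), (-2, 2)], resolution=81)
        half = 0.5 * sims.max()
        peaks = (sims == maximum_filter(sims, size=7)) & (sims > half)
        assert peaks.sum() == 2

    def test_absent_concept_below_noise_threshold(self, ssp_space_2d):
        env, _ = self._environment(ssp_space_2d)
        vocab = env.vocab
        vocab.add("dog")
        sims, _ = query_map(env, "dog", [(-2, 2), (-2, 2)], resolution=61)
        assert sims.max() < 3.0 / np.sqrt(ssp_space_2d.d) * np.linalg.norm(env.vector)

    def test_rebuild_check_and_empty_map(self, ssp_space_2d):
        env, _ = self._environment(ssp_space_2d)
        assert env.rebuild_check()
        vocab = ConceptVocabulary(ssp_space_2d.d, seed=5).add("rat")
        empty = build_map(ssp_space_2d, vocab, [])
        np.testing.assert_array_equal(empty.vector, np.zeros(ssp_space_2d.d))

    def test_unknown_concept_rejected(self, ssp_space_2d):
        vocab = ConceptVocabulary(ssp_space_2d.d, seed=5).add("rat")
        with pytest.raises(KeyError):
            build_map(ssp_space_2d, vocab, [("ghost", np.zeros(2))])

    def test_space_json_roundtrip(self, hex_space):
        clone = SSPSpace.from_json(hex_space.to_json())
        np.testing.assert_allclose(clone.A, hex_space.A)
        assert clone.kind == "hex"
        np.testing.assert_allclose(clone.module_waves, hex_space.module_waves)
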