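"""Predicted tuning curves: rate maps, fields, slices, correlograms, decoding."""

import numpy as np
import pytest

from gridmix import (
    HexLattice,
    Plane,
    ProjectionSet,
    autocorrelation_2d,
    conjunctive_rate,
    conjunctive_rate_map,
    decode_posterior,
    encode,
    grid_points,
    ideal_rate,
    ideal_rate_map,
    plane_slice,
    sample_projections,
    threshold_fields,
    wrap_phase,
)
from gridmix.tuning import RateMap

LAT = HexLattice()
A_LIFT = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])  # 2D grid lifted along z


class TestIdealRate:
    def test_peak_at_matching_phase(self):
        assert ideal_rate(np.zeros(3), A_LIFT) == pytest.approx(1.0)
        # φ0 shifted: peak moves to any x with A x = φ0 (mod Λ)
        phi0 = np.array([0.3, 0.4])  # lattice coordinates
        x = np.array([*(LAT.basis @ phi0), 7.0])
        assert ideal_rate(x, A_LIFT, phi0) == pytest.approx(1.0)

    def test_printed_value_at_half_distance(self):
        # d = 0.5 -> exp(-0.25)
        x = np.array([0.5, 0.0, 7.7])
        assert ideal_rate(x, A_LIFT) == pytest.approx(np.exp(-0.25))

    def test_kernel_direction_constant(self, rng):
        A = sample_projections(1, 3, seed=0).matrices[0]
        kernel = np.linalg.svd(A)[2][-1]
        x = rng.normal(size=(50, 3))
        v0 = ideal_rate(x, A)
        for t in (0.7, -2.3):
            assert np.allclose(ideal_rate(x + t * kernel, A), v0, atol=1e-9)

    def test_lattice_periodicity_exact(self, rng):
        A = sample_projections(1, 3, seed=1).matrices[0]
        x = rng.normal(size=(20, 3))
        # move x so that A x gains exactly one lattice vector
        shift = np.linalg.pinv(A) @ LAT.basis[:, 0]
        assert np.allclose(ideal_rate(x + shift, A), ideal_rate(x, A), atol=1e-9)

    def test_translation_covariance(self, rng):
        A = sample_projections(1, 3, seed=2).matrices[0]
        delta = rng.normal(size=3)
        x = rng.normal(size=(30, 3))
        # g(x + δ; φ0) = g(x; φ0 - Aδ): shifting the anchor phase by -Aδ is
        # the same as translating the field by δ
        phi0 = wrap_phase(-(A @ delta), LAT)
        assert np.allclose(
            ideal_rate(x + delta, A), ideal_rate(x, A, phi0), atol=1e-12
        )


class TestConjunctive:
    def test_single_module_identity(self, rng):
        A = sample_projections(1, 3, seed=3).matrices[0]
        x = rng.normal(size=(40, 3))
        assert np.allclose(conjunctive_rate(x, [A]), ideal_rate(x, A))

    def test_bounds(self, rng):
        mats = list(sample_projections(3, 3, seed=4).matrices)
        x = rng.normal(size=(200, 3))
        c = conjunctive_rate(x, mats)
        assert np.all(c > 0) and np.all(c <= 3.0)

    def test_empty_module_list_rejected(self):
        with pytest.raises(ValueError):
            conjunctive_rate(np.zeros((1, 3)), [])

    def test_rank3_fields_localized_in_all_directions(self):
        # sum over 3 modules varies along every single module's kernel
        P = sample_projections(3, 3, seed=5)
        mats = list(P.matrices)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 3))
        for A in mats:
            kernel = np.linalg.svd(A)[2][-1]
            t = np.linspace(-1.0, 1.0, 21)[:, None, None]
            vals = conjunctive_rate(x[None] + t * kernel[None, None], mats)
            assert vals.std(axis=0).max() > 1e-3


class TestThresholdFields:
    def test_constant_map(self):
        rmap = RateMap(np.ones((8, 8)), [0, 0], [1, 1])
        mask, _, n = threshold_fields(rmap)
        assert mask.all() and n == 1

    def test_rel_one_keeps_only_argmax(self):
        v = np.zeros((5, 5))
        v[2, 3] = 1.0
        mask, _, n = threshold_fields(RateMap(v, [0, 0], [1, 1]), rel=1.0)
        assert mask.sum() == 1 and mask[2, 3] and n == 1

    def test_two_equal_bumps(self):
        pts = grid_points([-2, -2], [0.05, 0.05], (81, 81))
        bumps = np.exp(-np.sum((pts - [1.0, 1.0]) ** 2, -1) / 0.05) + np.exp(
            -np.sum((pts + [1.0, 1.0]) ** 2, -1) / 0.05
        )
        _, _, n = threshold_fields(RateMap(bumps, [-2, -2], [0.05, 0.05]), rel=0.8)
        assert n == 2


class TestPlaneSlice:
    def test_identity_slice_reproduces_2d_map(self):
        plane = Plane(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
        sl = plane_slice(plane, extent=3.0, spacing=0.05, A=A_LIFT)
        direct = ideal_rate_map(
            np.eye(2), origin=sl.origin, spacing=sl.spacing, shape=sl.values.shape
        )
        assert np.allclose(sl.values, direct.values, atol=1e-12)

    def test_kernel_plane_gives_stripes(self):
        # plane spanned by the kernel (z) and x: constant along the z axis
        plane = Plane(np.zeros(3), np.array([0, 0, 1.0]), np.array([1.0, 0, 0]))
        sl = plane_slice(plane, extent=3.0, spacing=0.05, A=A_LIFT)
        assert np.allclose(sl.values, sl.values[:1, :], atol=1e-12)
        assert sl.values.std(axis=1).max() > 0.05  # but periodic across stripes

    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            Plane(np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            Plane(np.zeros(3), np.array([2.0, 0, 0]), np.array([0, 1.0, 0]))

    def test_tilt_family_hex_to_bands(self):
        # rotating the slice plane from the response plane toward the kernel
        # direction degrades compact hexagonal fields into elongated bands
        counts = []
        for angle in (0.0, np.pi / 3, np.pi / 2):
            u = np.array([0.0, np.cos(angle), np.sin(angle)])
            plane = Plane(np.zeros(3), np.array([1.0, 0, 0]), u)
            sl = plane_slice(plane, extent=4.0, spacing=4 / 127, A=A_LIFT)
            _, _, n = threshold_fields(sl, rel=0.8)
            counts.append(n)
        assert counts[0] > counts[-1]


@pytest.fixture(scope="module")
def hex_correlogram():
    rmap = ideal_rate_map(np.eye(2), origin=[-3, -3], spacing=6 / 127, shape=(128, 128))
    return autocorrelation_2d(rmap)


class TestAutocorrelation:
    def test_zero_shift_is_one(self, hex_correlogram):
        center = tuple((s - 1) // 2 for s in hex_correlogram.values.shape)
        assert hex_correlogram.values[center] == pytest.approx(1.0)

    def test_point_symmetry(self, hex_correlogram):
        v = hex_correlogram.values
        flipped = v[::-1, ::-1]
        ok = np.isfinite(v) & np.isfinite(flipped)
        assert np.allclose(v[ok], flipped[ok], atol=1e-9)

    def test_sixfold_peak_arrangement(self, hex_correlogram):
        from scipy import ndimage

        v = np.nan_to_num(hex_correlogram.values, nan=-1.0)
        spacing = hex_correlogram.spacing[0]
        maxed = ndimage.maximum_filter(v, size=5)
        peaks = np.argwhere((v == maxed) & (v > 0.3))
        center = (np.array(v.shape) - 1) / 2.0
        offsets = (peaks - center) * spacing
        r = np.linalg.norm(offsets, axis=1)
        ring = offsets[(r > 0.5) & (r < 1.5)]  # first lattice shell (period 1)
        assert len(ring) == 6
        angles = np.sort(np.degrees(np.arctan2(ring[:, 1], ring[:, 0])))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 360]]))
        assert np.all(np.abs(gaps - 60) < 5)

    def test_small_overlap_masked(self):
        rmap = ideal_rate_map(np.eye(2), origin=[0, 0], spacing=0.2, shape=(10, 10))
        ac = autocorrelation_2d(rmap, min_overlap=16)
        assert np.isnan(ac.values[0, 0])  # corner shift: 1-sample overlap


class TestDecodePosterior:
    def grid(self, extent=6.0, res=31, dim=3):
        spacing = extent / (res - 1)
        return [-extent / 2.0] * dim, spacing, (res,) * dim

    def test_true_position_suprathreshold(self):
        P = sample_projections(3, 3, seed=6)
        code = encode(np.zeros(3), P)
        origin, spacing, shape = self.grid()
        post, mask, _ = decode_posterior(code, P, origin, spacing, shape, sigma=0.15)
        center = tuple((s - 1) // 2 for s in shape)
        assert mask[center]
        assert post.values[center] == post.values.max()

    def test_single_module_kernel_continuum(self):
        # one module in 3D: the suprathreshold set spans the whole grid along
        # the kernel direction (ambiguity along the null space)
        A = A_LIFT.reshape(1, 2, 3)
        P = ProjectionSet(A)
        code = encode(np.zeros(3), P)
        origin, spacing, shape = self.grid(extent=1.6, res=17)
        _, mask, _ = decode_posterior(code, P, origin, spacing, shape, sigma=0.15)
        # z axis through the center is entirely suprathreshold
        assert mask[8, 8, :].all()

    def test_blob_count_non_increasing_in_module_count(self):
        P4 = sample_projections(4, 3, seed=2)
        origin, spacing, shape = self.grid(extent=6.0, res=41)
        counts = []
        for M in (1, 2, 3, 4):
            P = ProjectionSet(P4.matrices[:M], seed=2)
            code = encode(np.zeros(3), P)
            _, _, n = decode_posterior(code, P, origin, spacing, shape, sigma=0.15)
            counts.append(n)
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] < counts[0]

    def test_invalid_sigma(self):
        P = sample_projections(2, 2, seed=0)
        code = encode(np.zeros(2), P)
        with pytest.raises(ValueError):
            decode_posterior(code, P, [-1, -1], 0.1, (21, 21), sigma=0.0)


def test_conjunctive_map_matches_pointwise_sum():
    P = sample_projections(2, 3, seed=7)
    rmap = conjunctive_rate_map(list(P.matrices), [-1.0] * 3, 0.25, (9, 9, 9))
    pts = grid_points([-1.0] * 3, [0.25] * 3, (9, 9, 9))
    expected = sum(ideal_rate(pts, A) for A in P.matrices)
    assert np.allclose(rmap.values, expected)
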