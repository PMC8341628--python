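import numpy as np
import pytest
from scipy.spatial import cKDTree

from conftest import random_outline
from efd_oracle import oracle_efd
from sporemorph.efa import (
    EFD,
    NEFD,
    compute_efd,
    nefd_from_vector,
    nefd_to_vector,
    normalize_efd,
    read_nefd_file,
    reconstruct_outline,
    split_sym_asym,
    vector_index_map,
    write_nefd_file,
)
from sporemorph.geometry import ensure_ccw, resample_closed
from sporemorph.simulate import SporeParams, render_polygon


def circle(r=3.0, n=256):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


class TestComputeEFD:
    def test_circle_first_harmonic(self):
        e = compute_efd(circle(3.0), 1)
        np.testing.assert_allclose(e.coeffs[0], [3, 0, 0, 3], atol=1e-3)
        assert abs(e.a0) < 1e-9 and abs(e.c0) < 1e-9

    def test_circle_higher_harmonics_vanish(self):
        e = compute_efd(circle(3.0), 10)
        assert np.abs(e.coeffs[1:]).max() < 1e-3

    def test_ellipse_matches_arc_length_oracle(self):
        # under chord-length parameterization the (5, 2) ellipse's first
        # harmonic is (4.4551, 0, 0, 2.1778), not the axes themselves
        t = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
        ell = np.column_stack([5 * np.cos(t), 2 * np.sin(t)])
        e = compute_efd(ell, 4)
        np.testing.assert_allclose(e.coeffs[0], [4.45523, 0, 0, 2.17791], atol=1e-4)
        assert abs(e.coeffs[0, 1]) < 1e-9 and abs(e.coeffs[0, 2]) < 1e-9

    def test_translation_hits_only_constant_terms(self, capsule):
        e1 = compute_efd(capsule, 20)
        e2 = compute_efd(capsule + [10.0, -7.0], 20)
        np.testing.assert_allclose(e2.coeffs, e1.coeffs, atol=1e-12)
        assert np.isclose(e2.a0 - e1.a0, 10.0) and np.isclose(e2.c0 - e1.c0, -7.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_efd(np.zeros((3, 2)), 5)  # zero perimeter
        with pytest.raises(ValueError):
            compute_efd(circle(), 0)

    def test_oracle_equivalence_on_random_polygons(self):
        # closed form vs brute-force Fourier integration, 20 random outlines
        rng = np.random.default_rng(1234)
        for _ in range(20):
            poly = random_outline(rng)
            closed = compute_efd(poly, 20).coeffs
            brute = oracle_efd(poly, 20)
            rel = np.abs(closed - brute).max() / np.abs(brute).max()
            assert rel < 1e-8


class TestNormalizeEFD:
    def test_exact_ellipse_descriptor(self):
        ne = normalize_efd(EFD(a0=0, c0=0, coeffs=[[5.0, 0.0, 0.0, 2.0]]))
        np.testing.assert_allclose(ne.coeffs[0], [1, 0, 0, 0.4], atol=1e-12)
        assert np.isclose(ne.size_scalar, 5.0)

    def test_constants_and_free_coefficient_count(self, capsule):
        ne = normalize_efd(compute_efd(capsule, 20))
        assert ne.coeffs.size == 80
        assert abs(ne.coeffs[0, 0] - 1) < 1e-9
        assert abs(ne.coeffs[0, 1]) < 1e-9
        assert abs(ne.coeffs[0, 2]) < 1e-9
        assert len(nefd_to_vector(ne, "global")) == 77

    @pytest.mark.parametrize("transform", ["rotate", "scale", "translate", "roll", "refine"])
    def test_invariance(self, bowed_capsule, transform):
        base = normalize_efd(compute_efd(bowed_capsule, 20))
        p = bowed_capsule
        if transform == "rotate":
            ang = np.deg2rad(37)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            p = p @ R.T
        elif transform == "scale":
            p = p * 2.5
        elif transform == "translate":
            p = p + [120.0, -55.0]
        elif transform == "roll":
            p = np.roll(p, 57, axis=0)
        else:  # refine: subdivide every edge, same piecewise-linear curve
            mid = (p + np.roll(p, -1, axis=0)) / 2
            p = np.column_stack([p, mid]).reshape(-1, 2)
        other = normalize_efd(compute_efd(p, 20))
        np.testing.assert_allclose(other.coeffs, base.coeffs, atol=1e-6)

    def test_combined_invariance(self, bowed_capsule):
        base = normalize_efd(compute_efd(bowed_capsule, 20))
        ang = np.deg2rad(211)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        p = np.roll(bowed_capsule @ R.T * 0.3 + [4.0, 9.0], 101, axis=0)
        other = normalize_efd(compute_efd(p, 20))
        np.testing.assert_allclose(other.coeffs, base.coeffs, atol=1e-6)
        assert np.isclose(other.size_scalar, 0.3 * base.size_scalar, rtol=1e-9)

    def test_proximal_end_maps_to_negative_x(self, capsule):
        # the sharper (apiculus) end must sit at negative x after
        # normalization, independent of input orientation
        for ang in (0.0, 1.0, 2.5, 4.0):
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            ne = normalize_efd(compute_efd(capsule @ R.T, 20))
            rec = reconstruct_outline(ne, 400)
            from sporemorph.geometry import turning_angles

            rs = resample_closed(rec, 400)
            kappa = turning_angles(rs)
            sharp_x = rs[np.argmax(kappa), 0]
            assert sharp_x < 0

    def test_near_circular_degenerate_warns(self):
        with pytest.warns(UserWarning, match="near-circular"):
            ne = normalize_efd(compute_efd(circle(3.0, 512), 20))
        # invariants still hold exactly
        assert abs(ne.coeffs[0, 0] - 1) < 1e-9
        assert abs(ne.coeffs[0, 1]) < 1e-9 and abs(ne.coeffs[0, 2]) < 1e-9

    def test_mirror_negates_asymmetric_block(self, bowed_capsule):
        base = normalize_efd(compute_efd(bowed_capsule, 20))
        mirrored = ensure_ccw(np.column_stack([bowed_capsule[:, 0], -bowed_capsule[:, 1]]))
        other = normalize_efd(compute_efd(mirrored, 20))
        sym_a, asym_a = split_sym_asym(base)
        sym_b, asym_b = split_sym_asym(other)
        np.testing.assert_allclose(sym_a, sym_b, atol=1e-6)
        np.testing.assert_allclose(asym_a, -asym_b, atol=1e-6)


class TestReconstruction:
    def test_single_harmonic_nefd_is_exact(self):
        ne = normalize_efd(EFD(a0=0, c0=0, coeffs=[[5.0, 0.0, 0.0, 2.0]]))
        rec = reconstruct_outline(ne, 256, rescale=True)
        t = np.linspace(0, 1, 256, endpoint=False)
        expected = np.column_stack([5 * np.cos(2 * np.pi * t), 2 * np.sin(2 * np.pi * t)])
        np.testing.assert_allclose(rec, expected, atol=1e-9)

    def test_error_nonincreasing_in_harmonics(self, capsule):
        # L2 error at matched arc-length parameters: adding harmonics
        # can only remove energy from the residual
        efd = compute_efd(capsule, 20)
        target = resample_closed(capsule, 2048)  # t=0 at vertex 0, as in the fit
        prev = np.inf
        for h in range(1, 21):
            rec = reconstruct_outline(efd, 2048, n_harmonics=h)
            err = float(np.mean((rec - target) ** 2))
            assert err <= prev + 1e-12
            prev = err

    def test_twenty_harmonics_below_one_percent_of_length(self, bowed_capsule):
        efd = compute_efd(bowed_capsule, 20)
        rec = reconstruct_outline(efd, 1000)
        err = cKDTree(resample_closed(bowed_capsule, 2000)).query(rec)[0].mean()
        assert err < 0.01 * 10.0

    def test_too_few_points_rejected(self, capsule):
        with pytest.raises(ValueError):
            reconstruct_outline(compute_efd(capsule, 5), n_points=8)


class TestCoefficientBlocks:
    def test_block_lengths_at_20_harmonics(self, capsule):
        ne = normalize_efd(compute_efd(capsule, 20))
        sym, asym = split_sym_asym(ne)
        assert len(sym) == 39 and len(asym) == 38
        assert len(nefd_to_vector(ne, "global")) == 77

    def test_single_harmonic_global_vector_is_d1(self):
        ne = normalize_efd(EFD(a0=0, c0=0, coeffs=[[5.0, 0.0, 0.0, 2.0]]))
        vec = nefd_to_vector(ne, "global")
        assert vec.shape == (1,)
        assert np.isclose(vec[0], 0.4)

    def test_symmetric_capsule_has_negligible_asymmetric_block(self):
        sym_capsule = render_polygon(SporeParams(10, 4, taper_p=0.5), 400)
        ne = normalize_efd(compute_efd(sym_capsule, 20))
        sym, asym = split_sym_asym(ne)
        assert np.linalg.norm(asym) < 1e-3 * np.linalg.norm(sym)

    def test_bow_increases_asymmetric_norm(self, bowed_capsule):
        straight = render_polygon(SporeParams(10, 4, taper_p=0.5, apiculus_h=0.3), 300)
        asym_straight = split_sym_asym(normalize_efd(compute_efd(straight, 20)))[1]
        asym_bowed = split_sym_asym(normalize_efd(compute_efd(bowed_capsule, 20)))[1]
        assert np.linalg.norm(asym_bowed) > np.linalg.norm(asym_straight)

    def test_vector_round_trip_through_embedding(self, capsule):
        ne = normalize_efd(compute_efd(capsule, 20))
        for variant in ("global", "symmetric", "asymmetric"):
            vec = nefd_to_vector(ne, variant)
            back = nefd_from_vector(vec, variant, ne)
            np.testing.assert_allclose(back.coeffs, ne.coeffs, atol=1e-12)

    def test_index_map_consistency(self):
        g = vector_index_map(20, "global")
        s = vector_index_map(20, "symmetric")
        a = vector_index_map(20, "asymmetric")
        assert len(g) == 77 and len(s) == 39 and len(a) == 38
        assert set(s) | set(a) == set(g)
        assert set(s) & set(a) == set()


class TestNEFDFile:
    def test_round_trip(self, tmp_path, capsule, bowed_capsule):
        records = [
            ("s1", "img1", normalize_efd(compute_efd(capsule, 20))),
            ("s2", "img1", normalize_efd(compute_efd(bowed_capsule, 20))),
        ]
        path = tmp_path / "nefd.txt"
        write_nefd_file(path, records)
        back = read_nefd_file(path)
        assert [(a, b) for a, b, _ in back] == [("s1", "img1"), ("s2", "img1")]
        for (_, _, x), (_, _, y) in zip(records, back):
            np.testing.assert_array_equal(x.coeffs, y.coeffs)
            assert x.size_scalar == y.size_scalar
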