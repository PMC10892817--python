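"""GASF/GADF encodings against their algebraic closed forms, PAA reduction,
and GAF rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osadetect.errors import ValidationError
from osadetect.gaf_encoder import (GafMatrix, encode_segment, gadf_matrix,
                                   gasf_matrix, paa, render_gaf, rescale_unit)


def random_series(rng, n=32):
    return rng.standard_normal(n) * rng.uniform(0.5, 3.0) + rng.uniform(-2, 2)


class TestRescale:
    def test_endpoints_map_to_plus_minus_one(self):
        rs = rescale_unit(np.array([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(rs.x_tilde, [-1.0, 0.0, 1.0], atol=1e-15)

    def test_min_max_always_hit_endpoints(self, rng):
        for _ in range(20):
            x = random_series(rng)
            rs = rescale_unit(x)
            assert rs.x_tilde[np.argmin(x)] == pytest.approx(-1.0)
            assert rs.x_tilde[np.argmax(x)] == pytest.approx(1.0)

    def test_invariant_to_positive_affine_maps(self, rng):
        x = random_series(rng)
        a, c = 3.7, -2.2
        np.testing.assert_allclose(rescale_unit(x).x_tilde,
                                   rescale_unit(a * x + c).x_tilde, atol=1e-12)

    def test_polar_view_consistent(self, rng):
        rs = rescale_unit(random_series(rng))
        np.testing.assert_allclose(rs.phi, np.arccos(rs.x_tilde))
        assert np.all(np.diff(rs.r) > 0)
        assert rs.r[-1] == pytest.approx(1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError):
            rescale_unit(np.array([3.0, 3.0, 3.0]))


class TestGasf:
    def test_two_point_hand_example(self):
        # x~=[1,0] -> phi=[0, pi/2] -> cos(phi_i+phi_j) = [[1,0],[0,-1]]
        rs = rescale_unit(np.array([1.0, 0.5, 0.0]))
        sub = gasf_matrix(rs).values[np.ix_([0, 1], [0, 1])]
        np.testing.assert_allclose(sub, [[1.0, 0.0], [0.0, -1.0]], atol=1e-12)

    def test_symmetry_and_diagonal_identity(self, rng):
        for _ in range(100):
            rs = rescale_unit(random_series(rng))
            m = gasf_matrix(rs).values
            np.testing.assert_array_equal(m, m.T)
            np.testing.assert_allclose(np.diag(m), 2 * rs.x_tilde ** 2 - 1,
                                       atol=1e-10)

    def test_algebraic_closed_form(self, rng):
        """cos(phi_i+phi_j) == x~x~' - sqrt(1-x~^2)sqrt(1-x~^2)'."""
        for _ in range(100):
            rs = rescale_unit(random_series(rng))
            root = np.sqrt(1.0 - rs.x_tilde ** 2)
            expected = np.outer(rs.x_tilde, rs.x_tilde) - np.outer(root, root)
            np.testing.assert_allclose(gasf_matrix(rs).values, expected,
                                       atol=1e-10)


class TestGadf:
    def test_two_point_hand_example(self):
        rs = rescale_unit(np.array([1.0, 0.5, 0.0]))
        sub = gadf_matrix(rs).values[np.ix_([0, 1], [0, 1])]
        np.testing.assert_allclose(sub, [[0.0, -1.0], [1.0, 0.0]], atol=1e-12)

    def test_antisymmetric_with_zero_diagonal(self, rng):
        for _ in range(100):
            rs = rescale_unit(random_series(rng))
            m = gadf_matrix(rs).values
            np.testing.assert_allclose(m, -m.T, atol=1e-15)
            np.testing.assert_array_equal(np.diag(m), np.zeros(len(rs.x_tilde)))

    def test_algebraic_closed_form(self, rng):
        """sin(phi_i-phi_j) == sqrt(1-x~^2)x~' - x~sqrt(1-x~^2)'."""
        for _ in range(100):
            rs = rescale_unit(random_series(rng))
            root = np.sqrt(1.0 - rs.x_tilde ** 2)
            expected = np.outer(root, rs.x_tilde) - np.outer(rs.x_tilde, root)
            np.testing.assert_allclose(gadf_matrix(rs).values, expected,
                                       atol=1e-10)


def paa_bruteforce(x, m):
    """Independent fractional-bin oracle: explicit overlap-weighted means."""
    n = len(x)
    out = np.empty(m)
    for k in range(m):
        lo, hi = k * n / m, (k + 1) * n / m
        total = 0.0
        for i in range(n):
            overlap = max(0.0, min(i + 1, hi) - max(i, lo))
            total += x[i] * overlap
        out[k] = total / (hi - lo)
    return out


class TestPaa:
    def test_integer_bin_means(self):
        np.testing.assert_allclose(paa(np.array([1.0, 2, 3, 4]), 2), [1.5, 3.5])

    def test_identity_when_m_equals_n(self, rng):
        x = rng.standard_normal(17)
        np.testing.assert_array_equal(paa(x, 17), x)

    @pytest.mark.parametrize("n,m", [(3, 2), (10, 7), (100, 33), (6000, 224)])
    def test_fractional_bins_match_bruteforce(self, rng, n, m):
        x = rng.standard_normal(n)
        np.testing.assert_allclose(paa(x, m), paa_bruteforce(x, m), atol=1e-9)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValidationError):
            paa(np.zeros(5), 6)
        with pytest.raises(ValidationError):
            paa(np.zeros(5), 0)


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=64),
       st.integers(min_value=1, max_value=4))
def test_paa_preserves_the_series_mean(values, divisor):
    """Equal-width (possibly fractional) bins weight every sample equally,
    so the mean of the PAA series equals the mean of the input."""
    x = np.asarray(values)
    m = max(1, len(x) // divisor)
    reduced = paa(x, m)
    assert np.mean(reduced) == pytest.approx(np.mean(x), rel=1e-9, abs=1e-6)


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=64, unique=True))
def test_rescale_range_and_angle_bounds(values):
    rs = rescale_unit(np.asarray(values))
    assert rs.x_tilde.min() >= -1.0 and rs.x_tilde.max() <= 1.0
    assert rs.phi.min() >= 0.0 and rs.phi.max() <= np.pi


class TestRenderGaf:
    def test_zero_matrix_renders_uniform_midpoint(self):
        img = render_gaf(GafMatrix(np.zeros((50, 50)), "GASF"))
        from osadetect.rendering import apply_colormap
        mid = apply_colormap(np.array([[0.5]]))[0, 0]
        np.testing.assert_allclose(img.pixels,
                                   np.broadcast_to(mid, (224, 224, 3)),
                                   atol=1e-6)

    def test_contract_shape_and_range(self, rng):
        rs = rescale_unit(random_series(rng, 224))
        img = render_gaf(gadf_matrix(rs))
        assert img.pixels.shape == (224, 224, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_rotation_equivariance(self, rng):
        # at native 224 resolution no resampling occurs, so a 180-degree
        # matrix rotation rotates the rendered image exactly
        rs = rescale_unit(random_series(rng, 224))
        m = gasf_matrix(rs)
        img = render_gaf(m).pixels
        rot = render_gaf(GafMatrix(np.rot90(m.values, 2), "GASF")).pixels
        np.testing.assert_allclose(np.rot90(img, 2), rot, atol=1e-7)

    def test_full_pipeline_shape_without_post_resize(self, rng):
        x = rng.standard_normal(6000)
        img = encode_segment(x, "GASF")
        assert img.pixels.shape == (224, 224, 3)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValidationError):
            encode_segment(rng.standard_normal(100), "MTF")
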