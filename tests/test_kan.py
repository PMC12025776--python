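"""B-spline basis and Kolmogorov-Arnold layer correctness.

The implementation under test evaluates bases with a vectorized iterative
scheme; the oracle here is an independent naive recursive Cox-de Boor
evaluation (plus scipy's BSpline as a second opinion).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import BSpline

from ppgqc.kan import (
    DomainClampWarning,
    KanLayer,
    SplineSpec,
    bspline_basis,
    bspline_design_matrix,
    init_kan_layer,
    kan_activation,
    kan_forward,
    kan_layer_forward,
    make_knots,
)


def cox_de_boor(x: float, m: int, k: int, t: np.ndarray) -> float:
    """Textbook recursive B-spline evaluation (independent oracle)."""
    if k == 0:
        if t[m] <= x < t[m + 1]:
            return 1.0
        # close the right end of the global domain
        if x == t[-1] and t[m] < t[m + 1] == t[-1]:
            return 1.0
        return 0.0
    total = 0.0
    if t[m + k] > t[m]:
        total += (x - t[m]) / (t[m + k] - t[m]) * cox_de_boor(x, m, k - 1, t)
    if t[m + k + 1] > t[m + 1]:
        total += (t[m + k + 1] - x) / (t[m + k + 1] - t[m + 1]) * cox_de_boor(x, m + 1, k - 1, t)
    return total


def oracle_basis(x: float, spec: SplineSpec) -> np.ndarray:
    t = make_knots(spec)
    return np.array([cox_de_boor(x, m, spec.degree, t) for m in range(spec.n_basis)])


class TestKnots:
    def test_degenerate_single_interval(self):
        spec = SplineSpec(grid_count=1, degree=0)
        assert np.array_equal(make_knots(spec), [0.0, 1.0])
        assert spec.n_basis == 1
        np.testing.assert_allclose(bspline_basis(0.3, spec), [1.0])

    def test_basis_count_from_grid_and_degree(self):
        assert SplineSpec(grid_count=3, degree=5).n_basis == 8

    @given(g=st.integers(1, 12), k=st.integers(0, 6))
    @settings(max_examples=100, deadline=None)
    def test_knots_non_decreasing(self, g, k):
        t = make_knots(SplineSpec(grid_count=g, degree=k))
        assert np.all(np.diff(t) >= 0)
        assert len(t) == g + 2 * k + 1

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SplineSpec(grid_count=0, degree=1)
        with pytest.raises(ValueError):
            SplineSpec(grid_count=2, degree=-1)
        with pytest.raises(ValueError):
            SplineSpec(grid_count=2, degree=1, domain_lo=1.0, domain_hi=0.0)


class TestBasis:
    @pytest.mark.parametrize("g", range(1, 11))
    @pytest.mark.parametrize("k", range(0, 6))
    def test_partition_of_unity_and_nonnegativity(self, g, k):
        spec = SplineSpec(grid_count=g, degree=k)
        x = np.random.default_rng(1000 * g + k).uniform(0, 1, 1000)
        x = np.concatenate([x, [0.0, 1.0]])  # include both boundaries
        b = bspline_design_matrix(x, spec)
        assert np.all(b >= 0)
        np.testing.assert_allclose(b.sum(axis=1), 1.0, atol=1e-9)

    def test_linear_hats_at_interval_midpoint(self):
        spec = SplineSpec(grid_count=4, degree=1)
        b = bspline_basis(0.375, spec)  # midpoint of [0.25, 0.5]
        nonzero = np.nonzero(b)[0]
        assert len(nonzero) == 2
        np.testing.assert_allclose(b[nonzero], [0.5, 0.5])

    def test_at_most_degree_plus_one_nonzero(self, rng):
        spec = SplineSpec(grid_count=6, degree=3)
        for x in rng.uniform(0, 1, 50):
            assert np.count_nonzero(bspline_basis(float(x), spec)) <= spec.degree + 1

    def test_matches_recursive_oracle(self, rng):
        for _ in range(1000):
            g = int(rng.integers(1, 9))
            k = int(rng.integers(0, 6))
            spec = SplineSpec(grid_count=g, degree=k)
            x = float(rng.uniform(0, 1))
            np.testing.assert_allclose(
                bspline_basis(x, spec), oracle_basis(x, spec), atol=1e-10
            )

    def test_matches_scipy_design_matrix(self, rng):
        spec = SplineSpec(grid_count=5, degree=3)
        x = rng.uniform(0, 1, 200)
        ours = bspline_design_matrix(x, spec)
        theirs = BSpline.design_matrix(x, make_knots(spec), spec.degree).toarray()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_local_support(self):
        """Basis m vanishes outside its k+2-knot span [t_m, t_{m+k+1}]."""
        spec = SplineSpec(grid_count=8, degree=2)
        t = make_knots(spec)
        x = np.linspace(0, 1, 401)
        b = bspline_design_matrix(x, spec)
        for m in range(spec.n_basis):
            outside = (x < t[m]) | (x > t[m + spec.degree + 1])
            assert np.all(b[outside, m] == 0)

    def test_out_of_domain_clamps_with_warning(self):
        spec = SplineSpec(grid_count=3, degree=2)
        with pytest.warns(DomainClampWarning):
            b = bspline_basis(1.7, spec)
        np.testing.assert_allclose(b, bspline_basis(1.0, spec))

    def test_derivative_matches_finite_difference(self, rng):
        spec = SplineSpec(grid_count=5, degree=3)
        x = rng.uniform(0.05, 0.95, 100)
        h = 1e-6
        numeric = (
            bspline_design_matrix(x + h, spec) - bspline_design_matrix(x - h, spec)
        ) / (2 * h)
        analytic = bspline_design_matrix(x, spec, derivative=True)
        np.testing.assert_allclose(analytic, numeric, atol=1e-5)


class TestActivationsAndLayers:
    def test_constant_coefficients_give_constant_function(self, rng):
        spec = SplineSpec(grid_count=4, degree=3)
        coeffs = np.full(spec.n_basis, 2.5)
        for x in rng.uniform(0, 1, 20):
            assert kan_activation(float(x), coeffs, spec) == pytest.approx(2.5, abs=1e-9)
        assert kan_activation(0.4, np.zeros(spec.n_basis), spec) == 0.0

    def test_activation_equals_oracle_dot_product(self, rng):
        spec = SplineSpec(grid_count=5, degree=2)
        for _ in range(100):
            coeffs = rng.normal(size=spec.n_basis)
            x = float(rng.uniform(0, 1))
            expected = float(oracle_basis(x, spec) @ coeffs)
            assert kan_activation(x, coeffs, spec) == pytest.approx(expected, abs=1e-10)

    def test_activation_rejects_wrong_length(self):
        spec = SplineSpec(grid_count=3, degree=2)
        with pytest.raises(ValueError):
            kan_activation(0.5, np.zeros(spec.n_basis + 1), spec)

    def test_layer_zero_coefficients_and_constant_edges(self):
        spec = SplineSpec(grid_count=3, degree=2)
        zero = KanLayer(2, 3, spec, np.zeros((3, 2, spec.n_basis)))
        np.testing.assert_array_equal(kan_layer_forward([0.3, 0.7], zero), np.zeros(3))
        const = KanLayer(2, 3, spec, np.full((3, 2, spec.n_basis), 1.5))
        # each edge activation is constant 1.5; outputs sum over 2 inputs
        np.testing.assert_allclose(kan_layer_forward([0.3, 0.7], const), 3.0)

    def test_layer_forward_is_sum_of_edge_activations(self, rng):
        spec = SplineSpec(grid_count=4, degree=3)
        layer = init_kan_layer(2, 1, spec, rng)
        x = rng.uniform(0, 1, 2)
        expected = kan_activation(x[0], layer.coeffs[0, 0], spec) + kan_activation(
            x[1], layer.coeffs[0, 1], spec
        )
        assert kan_layer_forward(x, layer)[0] == pytest.approx(expected, abs=1e-12)

    def test_layer_rejects_dimension_mismatch(self, rng):
        spec = SplineSpec(grid_count=2, degree=1)
        layer = init_kan_layer(3, 2, spec, rng)
        with pytest.raises(ValueError):
            kan_layer_forward(np.zeros(4), layer)

    def test_stack_matches_nested_evaluation(self, rng):
        spec = SplineSpec(grid_count=3, degree=2, domain_lo=-3.0, domain_hi=3.0)
        l1 = init_kan_layer(3, 4, spec, rng)
        l2 = init_kan_layer(4, 1, spec, rng)
        x = rng.uniform(-1, 1, 3)
        nested = kan_layer_forward(kan_layer_forward(x, l1), l2)
        np.testing.assert_allclose(kan_forward(x, [l1, l2]), nested, atol=1e-12)

    def test_stack_zero_coefficients_propagate(self):
        spec = SplineSpec(grid_count=2, degree=1)
        l1 = KanLayer(2, 2, spec, np.zeros((2, 2, spec.n_basis)))
        l2 = KanLayer(2, 1, spec, np.zeros((1, 2, spec.n_basis)))
        np.testing.assert_array_equal(kan_forward([0.5, 0.5], [l1, l2]), [0.0])

    def test_stack_rejects_incompatible_dims(self, rng):
        spec = SplineSpec(grid_count=2, degree=1)
        l1 = init_kan_layer(2, 3, spec, rng)
        l2 = init_kan_layer(4, 1, spec, rng)
        with pytest.raises(ValueError):
            kan_forward([0.1, 0.2], [l1, l2])


def test_single_activation_approximates_sine():
    """Least-squares spline fit of sin(pi x) on [-1, 1]: max error < 0.01.

    This is the approximation property that makes spline edge activations
    expressive enough to serve as learnable nonlinearities.
    """
    spec = SplineSpec(grid_count=10, degree=3, domain_lo=-1.0, domain_hi=1.0)
    x = np.linspace(-1, 1, 2001)
    target = np.sin(np.pi * x)
    design = bspline_design_matrix(x, spec)
    coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
    fitted = design @ coeffs
    assert np.max(np.abs(fitted - target)) < 0.01
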