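"""Kolmogorov-Arnold layers over B-spline bases.

A Kolmogorov-Arnold network (KAN) replaces the fixed nonlinearities of an
MLP with learnable univariate functions living on the *edges* of the layer:
one layer maps an input vector x of length ``n_l`` to an output of length
``n_{l+1}`` by

    out_j = sum_i phi_{j,i}(x_i)

where each edge function phi_{j,i} is a linear combination of B-spline basis
functions over a bounded interval.  Stacking layers composes these maps,
which is the constructive form suggested by the Kolmogorov-Arnold
representation theorem for multivariate continuous functions on a bounded
domain.

The spline space is parametrized by the *grid* G (number of uniform
intervals over the domain), and the polynomial *degree* k of the pieces;
the resulting basis has ``G + k`` functions.  Bases are evaluated with the
Cox-de Boor recursion, vectorized over evaluation points.

Inputs falling outside the spline domain are clamped to the nearest
boundary; the basis is simply extended by its boundary value, which keeps
the bounded-domain premise of the representation intact instead of
extrapolating polynomially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplineSpec",
    "KanLayer",
    "make_knots",
    "bspline_design_matrix",
    "bspline_basis",
    "kan_activation",
    "kan_layer_forward",
    "kan_forward",
    "init_kan_layer",
]


class DomainClampWarning(UserWarning):
    """Raised when an evaluation point is clamped to the spline domain."""


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of the univariate spline space shared by a KAN layer.

    Parameters
    ----------
    grid_count : int
        Number of uniform grid intervals G over the domain (G >= 1).
    degree : int
        Polynomial degree k of the spline pieces (k >= 0).  This is the
        smoothness knob usually advertised as the spline "order".
    domain_lo, domain_hi : float
        Bounds of the interval on which the edge activations live.  The
        default [0, 1] matches Min-Max-scaled pipeline inputs.
    """

    grid_count: int = 3
    degree: int = 5
    domain_lo: float = 0.0
    domain_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_count < 1:
            raise ValueError(f"grid_count must be >= 1, got {self.grid_count}")
        if self.degree < 0:
            raise ValueError(f"degree must be >= 0, got {self.degree}")
        if not self.domain_lo < self.domain_hi:
            raise ValueError(
                f"domain must be a proper interval, got [{self.domain_lo}, {self.domain_hi}]"
            )

    @property
    def n_basis(self) -> int:
        """Dimension of the spline space: G + k."""
        return self.grid_count + self.degree

    @property
    def knots(self) -> np.ndarray:
        return make_knots(self)


def make_knots(spec: SplineSpec) -> np.ndarray:
    """Build the non-decreasing knot sequence for ``spec``.

    Uniform interior knots over [domain_lo, domain_hi] with the two boundary
    knots repeated k extra times (open uniform / clamped layout), so that the
    basis functions sum to one over the whole domain and the spline space has
    exactly G + k dimensions.
    """
    g, k = spec.grid_count, spec.degree
    interior = np.linspace(spec.domain_lo, spec.domain_hi, g + 1)
    return np.concatenate([
        np.full(k, spec.domain_lo),
        interior,
        np.full(k, spec.domain_hi),
    ])


def _clamp(x: np.ndarray, spec: SplineSpec, warn: bool) -> np.ndarray:
    out_of_domain = (x < spec.domain_lo) | (x > spec.domain_hi)
    if np.any(out_of_domain):
        if warn:
            warnings.warn(
                f"{int(np.count_nonzero(out_of_domain))} evaluation point(s) outside "
                f"[{spec.domain_lo}, {spec.domain_hi}] clamped to the boundary",
                DomainClampWarning,
                stacklevel=3,
            )
        x = np.clip(x, spec.domain_lo, spec.domain_hi)
    return x


def _basis_degree_zero(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Indicator bases on the knot intervals, right-closed at the last one."""
    # half-open intervals [t_m, t_{m+1}); the supremum of the domain belongs
    # to the last non-degenerate interval so that bases still sum to one there
    b = ((t[:-1] <= x[:, None]) & (x[:, None] < t[1:])).astype(np.float64)
    at_hi = x == t[-1]
    if np.any(at_hi):
        nondegenerate = np.nonzero(t[1:] > t[:-1])[0]
        b[at_hi, :] = 0.0
        b[at_hi, nondegenerate[-1]] = 1.0
    return b


def bspline_design_matrix(
    x: np.ndarray,
    spec: SplineSpec,
    derivative: bool = False,
    warn: bool = True,
) -> np.ndarray:
    """Evaluate all basis functions (or their first derivatives) at ``x``.

    Parameters
    ----------
    x : array_like
        Evaluation points of any shape; values outside the domain are
        clamped to the boundary.
    derivative : bool
        If True, return d/dx of each basis function instead of its value.
    warn : bool
        Emit :class:`DomainClampWarning` when points are clamped.

    Returns
    -------
    ndarray of shape ``x.shape + (spec.n_basis,)``.
    """
    x = np.asarray(x, dtype=np.float64)
    shape = x.shape
    x = _clamp(x.ravel(), spec, warn)
    t = make_knots(spec)
    k = spec.degree

    if derivative and k == 0:
        return np.zeros(shape + (spec.n_basis,))

    up_to = k - 1 if derivative else k
    b = _basis_degree_zero(x, t)
    for d in range(1, up_to + 1):
        n_funcs = len(t) - 1 - d
        new = np.zeros((x.size, n_funcs))
        for m in range(n_funcs):
            den1 = t[m + d] - t[m]
            den2 = t[m + d + 1] - t[m + 1]
            if den1 > 0:
                new[:, m] += (x - t[m]) / den1 * b[:, m]
            if den2 > 0:
                new[:, m] += (t[m + d + 1] - x) / den2 * b[:, m + 1]
        b = new

    if derivative:
        # d/dx B_{m,k} = k * (B_{m,k-1}/(t_{m+k}-t_m) - B_{m+1,k-1}/(t_{m+k+1}-t_{m+1}))
        out = np.zeros((x.size, spec.n_basis))
        for m in range(spec.n_basis):
            den1 = t[m + k] - t[m]
            den2 = t[m + k + 1] - t[m + 1]
            if den1 > 0:
                out[:, m] += k / den1 * b[:, m]
            if den2 > 0:
                out[:, m] -= k / den2 * b[:, m + 1]
        b = out

    return b.reshape(shape + (spec.n_basis,))


def bspline_basis(x: float, spec: SplineSpec) -> np.ndarray:
    """Values of all ``G + k`` basis functions at the scalar ``x``.

    The values are non-negative, at most ``k + 1`` of them are nonzero, and
    they sum to one (partition of unity).  Out-of-domain points are clamped
    to the boundary with a :class:`DomainClampWarning`.
    """
    return bspline_design_matrix(np.float64(x), spec)


@dataclass
class KanLayer:
    """One Kolmogorov-Arnold layer: a grid of spline edge activations.

    ``coeffs[j, i, m]`` is the coefficient of basis function m in the edge
    activation phi_{j,i} mapping input i to output j.
    """

    in_dim: int
    out_dim: int
    spec: SplineSpec
    coeffs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        expected = (self.out_dim, self.in_dim, self.spec.n_basis)
        if self.coeffs.shape != expected:
            raise ValueError(f"coeffs shape {self.coeffs.shape} != expected {expected}")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must all be finite")

    @property
    def n_parameters(self) -> int:
        return int(self.coeffs.size)


def init_kan_layer(
    in_dim: int,
    out_dim: int,
    spec: SplineSpec,
    rng: np.random.Generator,
    scale: float = 0.1,
) -> KanLayer:
    """Random layer with zero-mean normal coefficients of sd ``scale``.

    Small coefficients keep the initial edge activations, and hence the
    layer's outputs, close to zero.
    """
    coeffs = rng.normal(0.0, scale, size=(out_dim, in_dim, spec.n_basis))
    return KanLayer(in_dim=in_dim, out_dim=out_dim, spec=spec, coeffs=coeffs)


def kan_activation(x: float, edge_coeffs: np.ndarray, spec: SplineSpec) -> float:
    """Evaluate one edge activation phi(x) = sum_m c_m B_m(x)."""
    edge_coeffs = np.asarray(edge_coeffs, dtype=np.float64)
    if edge_coeffs.shape != (spec.n_basis,):
        raise ValueError(
            f"expected {spec.n_basis} coefficients, got shape {edge_coeffs.shape}"
        )
    return float(bspline_design_matrix(np.float64(x), spec) @ edge_coeffs)


def kan_layer_forward(x_vec: np.ndarray, layer: KanLayer) -> np.ndarray:
    """Apply one KAN layer: out_j = sum_i phi_{j,i}(x_i).

    There is no additional fixed output nonlinearity; the learnable edge
    functions are the whole transformation.
    """
    x_vec = np.asarray(x_vec, dtype=np.float64)
    if x_vec.shape != (layer.in_dim,):
        raise ValueError(f"input shape {x_vec.shape} != expected ({layer.in_dim},)")
    basis = bspline_design_matrix(x_vec, layer.spec)  # (in_dim, n_basis)
    return np.einsum("im,oim->o", basis, layer.coeffs)


def kan_forward(x: np.ndarray, layers: list[KanLayer]) -> np.ndarray:
    """Compose a stack of KAN layers left to right."""
    if not layers:
        raise ValueError("need at least one layer")
    for a, b in zip(layers, layers[1:]):
        if a.out_dim != b.in_dim:
            raise ValueError(
                f"incompatible layer dims: {a.out_dim} -> {b.in_dim}"
            )
    out = np.asarray(x, dtype=np.float64)
    for layer in layers:
        out = kan_layer_forward(out, layer)
    return out
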