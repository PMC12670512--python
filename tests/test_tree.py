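"""FunctionTree: projection, arithmetic, inner products, differentiation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mwdmrg.mra import (
    add,
    differentiate,
    get_basis,
    inner,
    load_collection,
    multiply,
    project,
    save_collection,
    zero_tree,
)

L = 8.0


def gaussian(alpha, center=(0.0, 0.0, 0.0)):
    c = np.asarray(center)
    norm = (2.0 * alpha / np.pi) ** 0.75

    def f(X):
        return norm * np.exp(-alpha * np.sum((X - c) ** 2, axis=1))

    return f


def overlap_gaussians(a, b, d):
    """Closed-form overlap of two normalized s Gaussians a distance d apart."""
    na = (2 * a / np.pi) ** 0.75
    nb = (2 * b / np.pi) ** 0.75
    return na * nb * (np.pi / (a + b)) ** 1.5 * np.exp(-a * b / (a + b) * d**2)


# --------------------------------------------------------------------------- #
# projection
# --------------------------------------------------------------------------- #

def test_polynomial_is_exact_on_single_root_node(basis5):
    """A degree-k polynomial has zero wavelet content: the cropped tree is
    the root node alone."""
    def f(X):
        return 1.0 + 0.5 * X[:, 0] - 0.25 * X[:, 1] * X[:, 2] + 0.1 * X[:, 0] ** 3

    t = project(f, basis5, 1e-8, L, initial_depth=1)
    assert t.num_nodes() == 1
    pts = np.array([[0.3, -0.2, 0.5], [1.0, 2.0, -3.0]])
    assert np.abs(t.evaluate(pts) - f(pts)).max() < 1e-10


def test_zero_function_gives_empty_tree(basis5):
    t = project(lambda X: np.zeros(len(X)), basis5, 1e-6, L)
    assert t.norm() == 0.0
    assert t.num_nodes() == 1


@pytest.mark.parametrize("alpha", [0.5, 1.0, 5.0, 50.0])
def test_projection_error_within_precision(basis5, alpha):
    """Norm of the projected Gaussian against an adaptive quadrature oracle."""
    p = 1e-5
    f = gaussian(alpha)
    t = project(f, basis5, p, L)
    # tensor Gauss-Legendre oracle for the squared norm
    x, w = np.polynomial.legendre.leggauss(80)
    half = min(L, 6.0 / np.sqrt(alpha) + 0.5)
    x = x * half
    w = w * half
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    W = w[:, None, None] * w[None, :, None] * w[None, None, :]
    P = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    oracle = float(np.sum(W.ravel() * f(P) ** 2))
    assert abs(t.squared_norm() - oracle) < 10 * p


def test_adaptivity_monotone_in_precision(basis5):
    f = gaussian(3.0)
    sizes = [project(f, basis5, p, L).num_nodes() for p in (1e-6, 1e-4, 1e-2)]
    assert sizes[0] >= sizes[1] >= sizes[2]


def test_nonfinite_function_rejected(basis5):
    def bad(X):
        out = np.ones(len(X))
        out[np.sum(X**2, axis=1) < 0.1] = np.nan
        return out

    with pytest.raises(ValueError, match="non-finite"):
        project(bad, basis5, 1e-4, L)


def test_max_depth_warns_and_caps(basis5):
    f = gaussian(50.0)  # needs depth > 3 at this precision
    with pytest.warns(RuntimeWarning, match="max depth"):
        t = project(f, basis5, 1e-6, L, max_depth=3)
    assert t.depth() <= 3


# --------------------------------------------------------------------------- #
# Parseval / two-scale
# --------------------------------------------------------------------------- #

def test_two_scale_roundtrip_identity(basis5):
    from mwdmrg.mra.tree import filter_down, filter_up

    rng = np.random.default_rng(7)
    s = rng.standard_normal((basis5.n,) * 3)
    assert np.abs(filter_up(basis5, filter_down(basis5, s)) - s).max() < 1e-13


def test_parseval_under_refinement(basis5):
    """Exact refinement redistributes coefficients but preserves the norm."""
    from mwdmrg.mra.tree import filter_down

    t = project(gaussian(2.0), basis5, 1e-5, L)
    key = next(iter(t.leaves))
    kids = filter_down(basis5, t.nodes[key])
    assert abs(np.sum(kids**2) - np.sum(t.nodes[key] ** 2)) < 1e-13


# --------------------------------------------------------------------------- #
# arithmetic
# --------------------------------------------------------------------------- #

def test_add_cancellation_and_scaling(basis5):
    t = project(gaussian(1.0), basis5, 1e-6, L)
    z = add(t, 1.0, t, -1.0)
    assert z.norm() < 1e-10
    zero = zero_tree(basis5, 1e-6, L)
    double = add(t, 2.0, zero, 0.0)
    assert abs(double.norm() - 2.0 * t.norm()) < 1e-9


def test_add_rejects_mismatched_domains(basis5):
    a = project(gaussian(1.0), basis5, 1e-4, L)
    b = project(gaussian(1.0), basis5, 1e-4, 2 * L)
    with pytest.raises(ValueError, match="incompatible"):
        add(a, 1.0, b, 1.0)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(
    a=st.floats(0.5, 8.0),
    b=st.floats(0.5, 8.0),
    w1=st.floats(-2.0, 2.0),
    w2=st.floats(-2.0, 2.0),
)
def test_add_linearity_against_inner_products(a, b, w1, w2):
    """<w1 f + w2 g, h> = w1 <f, h> + w2 <g, h> for random Gaussians."""
    basis = get_basis(5)
    f = project(gaussian(a), basis, 1e-5, L)
    g = project(gaussian(b, (0.4, 0.0, 0.0)), basis, 1e-5, L)
    h = project(gaussian(1.7, (0.0, 0.3, 0.0)), basis, 1e-5, L)
    lhs = inner(add(f, w1, g, w2), h)
    rhs = w1 * inner(f, h) + w2 * inner(g, h)
    assert abs(lhs - rhs) < 1e-5


def test_multiply_zero_and_norm(basis5):
    t = project(gaussian(1.5), basis5, 1e-5, L)
    z = multiply(t, zero_tree(basis5, 1e-5, L))
    assert z.norm() < 1e-12
    # integral of f*f equals ||f||^2
    prod = multiply(t, t)
    one = project(lambda X: np.ones(len(X)), basis5, 1e-6, L)
    assert abs(inner(prod, one) - t.squared_norm()) < 1e-5


def test_multiply_concentric_gaussians_closed_form(basis5):
    a, b = 1.0, 2.5
    f = project(gaussian(a), basis5, 1e-6, L)
    g = project(gaussian(b), basis5, 1e-6, L)
    prod = multiply(f, g)
    one = project(lambda X: np.ones(len(X)), basis5, 1e-6, L)
    assert abs(inner(prod, one) - overlap_gaussians(a, b, 0.0)) < 1e-6


@settings(max_examples=8, deadline=None, derandomize=True)
@given(a=st.floats(0.6, 6.0), b=st.floats(0.6, 6.0), d=st.floats(0.0, 1.5))
def test_inner_offset_gaussians_closed_form(a, b, d):
    basis = get_basis(5)
    f = project(gaussian(a), basis, 1e-6, L)
    g = project(gaussian(b, (d, 0.0, 0.0)), basis, 1e-6, L)
    assert abs(inner(f, g) - overlap_gaussians(a, b, d)) < 1e-5


def test_inner_disjoint_supports_vanishes(basis5):
    f = project(gaussian(30.0, (-3.0, 0.0, 0.0)), basis5, 1e-6, L)
    g = project(gaussian(30.0, (3.0, 0.0, 0.0)), basis5, 1e-6, L)
    assert abs(inner(f, g)) < 1e-8


# --------------------------------------------------------------------------- #
# differentiation
# --------------------------------------------------------------------------- #

def test_derivative_of_constantish_region_vanishes(basis5):
    """The derivative of a polynomial in V_0 (a constant) is the zero tree."""
    t = project(lambda X: np.full(len(X), 2.5), basis5, 1e-8, L, initial_depth=1)
    d = differentiate(t, 0)
    assert d.norm() < 1e-9


def test_kinetic_energy_of_gaussian(basis5):
    """(1/2) sum_axis <d phi, d phi> = 3 alpha / 2 for a normalized Gaussian."""
    alpha = 1.3
    t = project(gaussian(alpha), basis5, 1e-6, L)
    ke = 0.5 * sum(inner(differentiate(t, ax), differentiate(t, ax)) for ax in range(3))
    assert abs(ke - 1.5 * alpha) < 1e-5


def test_integration_by_parts_antisymmetry(basis5):
    f = project(gaussian(1.0), basis5, 1e-6, L)
    g = project(gaussian(2.2, (0.3, -0.2, 0.1)), basis5, 1e-6, L)
    val = inner(differentiate(f, 1), g) + inner(f, differentiate(g, 1))
    assert abs(val) < 1e-6


def test_derivative_of_empty_tree_is_zero(basis5):
    z = zero_tree(basis5, 1e-5, L)
    assert differentiate(z, 2).norm() == 0.0


def test_invalid_axis_rejected(basis5):
    t = project(gaussian(1.0), basis5, 1e-4, L)
    with pytest.raises(ValueError, match="axis"):
        differentiate(t, 3)


# --------------------------------------------------------------------------- #
# checkpoint I/O
# --------------------------------------------------------------------------- #

def test_checkpoint_roundtrip(tmp_path, basis5):
    a = project(gaussian(1.0), basis5, 1e-5, L)
    b = project(gaussian(4.0, (0.5, 0.0, 0.0)), basis5, 1e-5, L)
    path = tmp_path / "orbs.npz"
    save_collection(path, [a, b])
    a2, b2 = load_collection(path)
    assert set(a2.nodes) == set(a.nodes) and a2.leaves == a.leaves
    for key in a.nodes:
        assert np.array_equal(a.nodes[key], a2.nodes[key])
    assert abs(inner(b, b2) - b.squared_norm()) < 1e-12
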