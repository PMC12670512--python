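"""Legendre scaling basis for multiwavelet multiresolution analysis.

The scaling space V_0 on the unit interval is spanned by the k+1 normalized
Legendre polynomials phi_j(x) = sqrt(2j+1) P_j(2x-1), j = 0..k.  Dilation and
translation, phi^n_{j,l}(x) = 2^{n/2} phi_j(2^n x - l), generate the nested
ladder V_0 c V_1 c ... whose orthogonal complements W_n = V_{n+1} - V_n carry
the wavelet (detail) coefficients used for adaptive refinement.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.linalg import null_space


class ScalingBasis:
    """Orthonormal Legendre scaling functions of order ``k`` on (0, 1).

    Parameters
    ----------
    k : int
        Polynomial order; the basis holds ``k + 1`` polynomials per dimension.

    Attributes
    ----------
    quad_x, quad_w : ndarray
        Gauss-Legendre nodes/weights on (0, 1); exact for degree <= 2k + 1.
    H0, H1 : ndarray, shape (k+1, k+1)
        Two-scale (low-pass) filters: ``s_parent = H0 @ s_child0 + H1 @ s_child1``.
    G0, G1 : ndarray, shape (k+1, k+1)
        Wavelet (high-pass) filters, an orthonormal completion of [H0 H1].
    filter : ndarray, shape (2k+2, 2k+2)
        Orthogonal block matrix [[H0, H1], [G0, G1]].
    """

    def __init__(self, k: int):
        if k < 1:
            raise ValueError(f"polynomial order k must be >= 1, got {k}")
        self.k = int(k)
        self.n = self.k + 1

        x01, w01 = np.polynomial.legendre.leggauss(self.n)
        self.quad_x = 0.5 * (x01 + 1.0)
        self.quad_w = 0.5 * w01

        # phi_vals[j, q] = phi_j(x_q) at the quadrature nodes
        self.phi_vals = self.eval_phi(self.quad_x)
        # coefficient <- values:  s_j = sum_q w_q phi_j(x_q) f(x_q)
        self.v2c = self.phi_vals * self.quad_w[None, :]

        self.H0, self.H1 = self._two_scale_filters()
        self.G0, self.G1 = self._wavelet_filters()
        self.filter = np.block([[self.H0, self.H1], [self.G0, self.G1]])

        self.phi_at_0 = self.eval_phi(np.array([0.0]))[:, 0]
        self.phi_at_1 = self.eval_phi(np.array([1.0]))[:, 0]
        self.deriv_A, self.deriv_B, self.deriv_C = self._derivative_blocks()

    # ------------------------------------------------------------------ #

    def eval_phi(self, x: np.ndarray) -> np.ndarray:
        """Evaluate all phi_j at points ``x`` in [0, 1]; shape (k+1, len(x))."""
        x = np.asarray(x, dtype=float)
        t = 2.0 * x - 1.0
        out = np.empty((self.n, x.size))
        for j in range(self.n):
            c = np.zeros(j + 1)
            c[j] = 1.0
            out[j] = np.sqrt(2 * j + 1) * npleg.legval(t.ravel(), c)
        return out.reshape(self.n, *x.shape)

    def eval_dphi(self, x: np.ndarray) -> np.ndarray:
        """Evaluate d(phi_j)/dx on the unit interval; shape (k+1, len(x))."""
        x = np.asarray(x, dtype=float)
        t = 2.0 * x - 1.0
        out = np.empty((self.n, x.size))
        for j in range(self.n):
            c = np.zeros(j + 1)
            c[j] = 1.0
            out[j] = 2.0 * np.sqrt(2 * j + 1) * npleg.legval(t.ravel(), npleg.legder(c))
        return out.reshape(self.n, *x.shape)

    # ------------------------------------------------------------------ #

    def _two_scale_filters(self):
        # H0[j, i] = sqrt(2) * int_0^{1/2} phi_j(x) phi_i(2x) dx
        # evaluated exactly with an order-sufficient Gauss rule.
        x, w = np.polynomial.legendre.leggauss(2 * self.n)
        x = 0.5 * (x + 1.0)
        w = 0.5 * w
        phi_t = self.eval_phi(x)                     # phi_i(t)
        phi_half0 = self.eval_phi(0.5 * x)           # phi_j(t/2)
        phi_half1 = self.eval_phi(0.5 * (x + 1.0))   # phi_j((t+1)/2)
        H0 = (1.0 / np.sqrt(2.0)) * np.einsum("jq,iq,q->ji", phi_half0, phi_t, w)
        H1 = (1.0 / np.sqrt(2.0)) * np.einsum("jq,iq,q->ji", phi_half1, phi_t, w)
        return H0, H1

    def _wavelet_filters(self):
        H = np.hstack([self.H0, self.H1])
        G = null_space(H).T  # (k+1, 2k+2), orthonormal rows orthogonal to H
        # deterministic sign convention: largest-magnitude entry positive
        for row in G:
            idx = int(np.argmax(np.abs(row)))
            if row[idx] < 0:
                row *= -1.0
        return G[:, : self.n].copy(), G[:, self.n :].copy()

    def _derivative_blocks(self):
        """ABGV-style central-difference first derivative on the unit interval.

        Weak form with central (averaged) fluxes at box boundaries:
        c_i = A s_left + B s_self + C s_right (times 2^n / box width in use).
        """
        x, w = np.polynomial.legendre.leggauss(2 * self.n)
        x = 0.5 * (x + 1.0)
        w = 0.5 * w
        phi = self.eval_phi(x)
        dphi = self.eval_dphi(x)
        D = np.einsum("iq,jq,q->ij", dphi, phi, w)  # int phi_i' phi_j
        p0, p1 = self.phi_at_0, self.phi_at_1
        B = 0.5 * np.outer(p1, p1) - 0.5 * np.outer(p0, p0) - D
        C = 0.5 * np.outer(p1, p0)
        A = -0.5 * np.outer(p0, p1)
        return A, B, C


@lru_cache(maxsize=8)
def get_basis(k: int) -> ScalingBasis:
    """Memoized basis factory (the filter construction is pure in ``k``)."""
    return ScalingBasis(k)
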