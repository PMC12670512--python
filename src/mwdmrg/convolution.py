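"""Adaptive convolution with separated kernels in non-standard form.

A :class:`ConvolutionOperator` applies an integral operator with a radial,
sum-of-Gaussians kernel to a :class:`~mwdmrg.mra.FunctionTree`.  The kernel's
separability reduces every 3D block of the operator to tensor products of 1D
Gaussian transition matrices between boxes at the same scale,

    sigma^n_d[i, j] = Int Int phi^n_{i,l}(x) exp(-a (x-y)^2) phi^n_{j,l-d}(y),

and the non-standard (NS) form organizes the application scale by scale: the
input is split into its root scaling part plus per-node wavelet details, each
detail block is convolved at its own scale with a narrow band of displacement
blocks (the vanishing moments of the details make distant blocks negligible),
and the multi-scale output contributions are summed back onto one grid.  This
preserves the adaptivity of the input representation: cost is proportional to
the number of refined nodes, not to a uniform grid at the finest scale.

Sign conventions: the operator is the *pure* kernel convolution.  In
particular the bound-state Helmholtz operator here is convolution with
exp(-mu*r)/(4*pi*r); callers that invert (-nabla^2/2 - e) apply the -2
prefactor themselves.
"""

from __future__ import annotations

import warnings
from typing import Dict, Tuple

import numpy as np

from .kernels import SeparatedKernel, expand_kernel
from .mra.basis import ScalingBasis
from .mra.tree import FunctionTree, apply_axis, apply3, filter_down

_DIRECT_BETA = 4.0  # below this unit-box exponent the quadrature is spectrally exact
_TINY = 1e-18


def _sigma_direct(basis: ScalingBasis, beta: float, pref: float, dmax: int) -> np.ndarray:
    """1D transition matrices by quadrature; returns (2*dmax+1, k+1, k+1).

    Valid when the Gaussian is not narrower than the box (beta <~ 4).
    Entry [dmax + d] couples boxes with translation offset d.
    """
    npts = max(3 * basis.n, 24)
    x, w = np.polynomial.legendre.leggauss(npts)
    x = 0.5 * (x + 1.0)
    w = 0.5 * w
    phi_w = basis.eval_phi(x) * w[None, :]  # (n1, npts)
    ds = np.arange(-dmax, dmax + 1)
    diff = x[:, None] - x[None, :]
    E = np.exp(-beta * (diff[None, :, :] + ds[:, None, None]) ** 2)
    return pref * np.einsum("ip,jq,dpq->dij", phi_w, phi_w, E, optimize=True)


class _TermMatrices:
    """Per-scale 1D transition matrices of one Gaussian term, with upward
    two-scale recursion for scales where the Gaussian is narrower than a box."""

    def __init__(self, basis: ScalingBasis, a_phys: float, L: float):
        self.basis = basis
        self.a = a_phys
        self.L = L
        self._cache: Dict[int, np.ndarray] = {}
        self._dmax: Dict[int, int] = {}

    def beta(self, n: int) -> float:
        return self.a * (2.0 * self.L) ** 2 * 4.0 ** (-n)

    def sigma(self, n: int) -> Tuple[np.ndarray, int]:
        """All displacement matrices at scale ``n``; returns (mats, dmax)."""
        if n in self._cache:
            return self._cache[n], self._dmax[n]
        b = self.beta(n)
        pref = (2.0 * self.L) * 2.0 ** (-n)
        if b <= _DIRECT_BETA:
            dmax = int(np.ceil(1.0 + np.sqrt(np.log(1.0 / _TINY) / max(b, 1e-300))))
            # The band only ever needs to cover the NS application window
            # (parent band <= 12 -> child displacements <= 27); pure
            # scaling<->scaling far-field coupling of smooth terms is handled
            # at the root, not through wide bands.
            dmax = min(dmax, max(2**n, 1), 27)
            mats = _sigma_direct(self.basis, b, pref, dmax)
        else:
            child, cdmax = self.sigma(n + 1)
            dmax = max((cdmax + 1) // 2, 1)
            n1 = self.basis.n
            H0, H1 = self.basis.H0, self.basis.H1
            mats = np.zeros((2 * dmax + 1, n1, n1))

            def cmat(dc):
                if abs(dc) > cdmax:
                    return None
                return child[cdmax + dc]

            for idx, d in enumerate(range(-dmax, dmax + 1)):
                acc = np.zeros((n1, n1))
                for (b1, b2, M) in ((H0, H0, cmat(2 * d)), (H0, H1, cmat(2 * d - 1)),
                                    (H1, H0, cmat(2 * d + 1)), (H1, H1, cmat(2 * d))):
                    if M is not None:
                        acc += b1 @ M @ b2.T
                mats[idx] = acc
        self._cache[n] = mats
        self._dmax[n] = dmax
        return mats, dmax


class ConvolutionOperator:
    """Non-standard-form application of a separated kernel on FunctionTrees.

    Parameters
    ----------
    kernel : SeparatedKernel
        Sum-of-Gaussians kernel expansion.
    basis : ScalingBasis
    L : float
        Domain half-width of the trees this operator acts on.
    prec : float
        Target application accuracy (relative to exact convolution); band
        truncation uses prec/10 so the total application error stays within
        prec.
    """

    def __init__(self, kernel: SeparatedKernel, basis: ScalingBasis, L: float, prec: float):
        diag = 2.0 * (2.0 * L) * np.sqrt(3.0)
        if kernel.mu == 0.0 and kernel.r_max < diag:
            warnings.warn(
                f"kernel range {kernel.r_max:g} below domain diagonal {diag:g}; "
                "re-expanding", RuntimeWarning,
            )
            kernel = expand_kernel(kernel.mu, kernel.eps, kernel.r_min, diag)
        self.kernel = kernel
        self.basis = basis
        self.L = float(L)
        self.prec = float(prec)
        self._terms = [
            _TermMatrices(basis, float(a), self.L) for a in kernel.exponents
        ]
        self._coeffs = np.asarray(kernel.coeffs, dtype=float)
        # screening floor for operator blocks, in units of a unit-norm input
        self._floor = self.prec * 1e-3
        # per-scale NS blocks: {n: list of (c_t, Tmats, col_s, col_w)} where
        # Tmats[j] is the (2k+2)^2 block for displacement d = j - dmax
        self._ns_cache: Dict[int, list] = {}
        self._root_cache: np.ndarray | None = None

    # ------------------------------------------------------------------ #

    def _ns_blocks(self, n: int) -> list:
        """Wavelet-augmented operator blocks at parent scale ``n``.

        Per Gaussian term: grow the displacement band until the block norms
        fall below the screening floor; skip a term entirely at scales where
        even its d = 0 wavelet response is negligible (long-range terms look
        polynomial on fine boxes and act only through coarser scales / root).
        """
        if n in self._ns_cache:
            return self._ns_cache[n]
        basis = self.basis
        n1 = basis.n
        F = basis.filter
        floor = self._floor
        out = []
        for c, term in zip(self._coeffs, self._terms):
            sig, cdmax = term.sigma(n + 1)
            zero = np.zeros((n1, n1))

            def cmat(dc):
                if abs(dc) > cdmax:
                    return zero
                return sig[cdmax + dc]

            def build(d):
                M2 = np.block(
                    [[cmat(2 * d), cmat(2 * d - 1)], [cmat(2 * d + 1), cmat(2 * d)]]
                )
                T = F @ M2 @ F.T
                # block norms: A s<-s, B w<-s, C s<-w, D w<-w
                return T, (
                    np.linalg.norm(T[:n1, :n1]),
                    np.linalg.norm(T[n1:, :n1]),
                    np.linalg.norm(T[:n1, n1:]),
                    np.linalg.norm(T[n1:, n1:]),
                )

            T0, nb0 = build(0)
            ref = max(nb0)
            wmax0 = max(nb0[1:])
            # every kept channel touches at least one wavelet block in some
            # dimension; a term whose wavelet blocks are negligible acts only
            # through the telescoped smooth channel (root)
            if c * wmax0 * ref**2 < floor * 1e-2:
                continue
            hard_max = min(max(2**n, 1), 12)
            pos = [(T0, nb0)]
            for d in range(1, hard_max + 1):
                T, nb = build(d)
                # stop when both the pure wavelet channels at this offset and
                # the cross channel (wavelet at 0, smooth column at d) die out
                if (c * max(nb[1:]) * ref**2 < floor * 1e-2
                        and c * wmax0 * max(nb) * ref < floor * 1e-2):
                    break
                pos.append((T, nb))
            dmax = len(pos) - 1
            # negative displacements are transposes of positive ones
            Ts = [p[0].T for p in pos[:0:-1]] + [p[0] for p in pos]
            nbs = np.empty((4, 2 * dmax + 1))
            for j, T in enumerate(Ts):
                nbs[0, j] = np.linalg.norm(T[:n1, :n1])
                nbs[1, j] = np.linalg.norm(T[n1:, :n1])
                nbs[2, j] = np.linalg.norm(T[:n1, n1:])
                nbs[3, j] = np.linalg.norm(T[n1:, n1:])
            out.append((c, dmax, np.array(Ts), nbs))
        self._ns_cache[n] = out
        return out

    def _root_block(self) -> np.ndarray:
        """Scale-0, displacement-0 scaling-scaling matrices per term."""
        if self._root_cache is None:
            mats = []
            for term in self._terms:
                sig, dmax = term.sigma(0)
                mats.append(sig[dmax])
            self._root_cache = np.array(mats)
        return self._root_cache

    # ------------------------------------------------------------------ #

    def __call__(self, tree: FunctionTree) -> FunctionTree:
        return self.apply(tree)

    def apply(self, tree: FunctionTree) -> FunctionTree:
        """Convolve the kernel with ``tree``; pure kernel, no prefactor."""
        basis = self.basis
        n1 = basis.n
        F = basis.filter
        normf = tree.norm()
        out_p = min(tree.p, self.prec)
        if normf == 0.0:
            from .mra.tree import zero_tree

            return zero_tree(basis, out_p, self.L)

        # ---- telescoped multiscale application ----
        # T = P_0 T P_0 + sum_n [P_{n+1} T P_{n+1} - P_n T P_n]; each scale-n
        # term equals Q T Q + Q T P + P T Q and is evaluated exactly on the
        # child-basis cubes of the scale-n boxes (full wavelet-augmented
        # blocks minus the pure smooth->smooth channel, which telescopes to
        # the root).  Every tree node participates at its own scale: internal
        # nodes with scaling + detail content, leaves with their scaling
        # block only (their virtual children carry no detail).  All non-root
        # channels touch a wavelet block on at least one side, so they are
        # banded in displacement and the application cost follows the
        # adaptive grid.
        by_scale: Dict[int, list] = {}
        for key in tree.nodes:
            by_scale.setdefault(key[0], []).append(key)

        cutoff = 0.1 * self.prec * normf
        contribs: Dict[Tuple[int, int, int, int], np.ndarray] = {}

        # telescoped smooth part: pure scaling channel applied at the root
        root_s = tree.nodes[tree.root]
        sroot = self._root_block()
        acc = np.zeros((n1, n1, n1))
        for c, S in zip(self._coeffs, sroot):
            acc += c * apply3(S, root_s)
        root_out = acc

        for n, keys in sorted(by_scale.items()):
            # wavelet-augmented child-basis cubes: internal nodes carry
            # scaling + detail, leaves only their scaling block (sss slot)
            cubes = np.zeros((len(keys), 2 * n1, 2 * n1, 2 * n1))
            for i, key in enumerate(keys):
                if key in tree.leaves:
                    cubes[i, :n1, :n1, :n1] = tree.nodes[key]
                    continue
                kid = np.empty((2, 2, 2, n1, n1, n1))
                for b1 in range(2):
                    for b2 in range(2):
                        for b3 in range(2):
                            kid[b1, b2, b3] = tree.nodes[
                                (n + 1, 2 * key[1] + b1, 2 * key[2] + b2, 2 * key[3] + b3)
                            ]
                cube = kid.transpose(0, 3, 1, 4, 2, 5).reshape(2 * n1, 2 * n1, 2 * n1)
                cubes[i] = apply3(F, cube)

            # per-component norms (s/w split per dimension)
            comp = np.empty((len(keys), 2, 2, 2))
            for a1, sl1 in enumerate((slice(0, n1), slice(n1, 2 * n1))):
                for a2, sl2 in enumerate((slice(0, n1), slice(n1, 2 * n1))):
                    for a3, sl3 in enumerate((slice(0, n1), slice(n1, 2 * n1))):
                        comp[:, a1, a2, a3] = np.sqrt(
                            np.sum(cubes[:, sl1, sl2, sl3] ** 2, axis=(1, 2, 3))
                        )
            comp_w = comp.copy()
            comp_w[:, 0, 0, 0] = 0.0   # detail input components
            s_norm = comp[:, 0, 0, 0]  # smooth input component

            lkeys = np.array(keys, dtype=np.int64)  # (N, 4)
            size = 2**n
            for c, dmax, Ts, nbs in self._ns_blocks(n):
                A, B, C, D = nbs  # s<-s, w<-s, s<-w, w<-w per displacement
                cn = np.stack([A + B, C + D])  # column norms (s-in, w-in)
                if c * cn.max() ** 3 * comp.max() < cutoff:
                    continue
                # bound: detail inputs against full columns, plus the smooth
                # input against everything except the telescoped pure s<-s
                # channel
                est = c * np.einsum("nabc,ax,by,cz->nxyz", comp_w, cn, cn, cn)
                cs = cn[0]
                smooth = (
                    np.multiply.outer(np.multiply.outer(cs, cs), cs)
                    - np.multiply.outer(np.multiply.outer(A, A), A)
                )
                est += c * np.multiply.outer(s_norm, smooth)
                sel = np.argwhere(est > cutoff)
                if len(sel) == 0:
                    continue
                # sort rows so displacement groups are contiguous in the same
                # (x, y, z)-major order that np.unique returns
                order = np.lexsort((sel[:, 3], sel[:, 2], sel[:, 1]))
                sel = sel[order]
                dvecs, starts = np.unique(sel[:, 1:], axis=0, return_index=True)
                splits = np.split(sel[:, 0], starts[1:])
                for dvec, idxs in zip(dvecs, splits):
                    d = dvec - dmax
                    lx = lkeys[idxs, 1] + d[0]
                    ly = lkeys[idxs, 2] + d[1]
                    lz = lkeys[idxs, 3] + d[2]
                    ok = (
                        (lx >= 0) & (lx < size)
                        & (ly >= 0) & (ly < size)
                        & (lz >= 0) & (lz < size)
                    )
                    if not np.any(ok):
                        continue
                    idxs = idxs[ok]
                    lx, ly, lz = lx[ok], ly[ok], lz[ok]
                    Tx, Ty, Tz = Ts[dvec[0]], Ts[dvec[1]], Ts[dvec[2]]
                    sub = cubes[idxs]
                    nn, two = len(idxs), 2 * n1
                    Z = np.matmul(Tx, sub.reshape(nn, two, two * two))
                    Z = np.matmul(Ty, Z.reshape(nn, two, two, two))
                    Z = c * np.matmul(Z, Tz.T)
                    # remove the pure smooth->smooth channel (telescoped)
                    sss = np.ascontiguousarray(sub[:, :n1, :n1, :n1])
                    W = np.matmul(Tx[:n1, :n1], sss.reshape(nn, n1, n1 * n1))
                    W = np.matmul(Ty[:n1, :n1], W.reshape(nn, n1, n1, n1))
                    W = c * np.matmul(W, Tz[:n1, :n1].T)
                    Z[:, :n1, :n1, :n1] -= W
                    for i in range(len(idxs)):
                        k = (n, int(lx[i]), int(ly[i]), int(lz[i]))
                        if k in contribs:
                            contribs[k] += Z[i]
                        else:
                            contribs[k] = Z[i].copy()

        # ---- back-transform and assemble the multi-scale output ----
        pieces: Dict[Tuple[int, int, int, int], np.ndarray] = {(0, 0, 0, 0): root_out}
        for (n, lx, ly, lz), cube in contribs.items():
            cube = apply3(F.T, cube)
            kid = cube.reshape(2, n1, 2, n1, 2, n1).transpose(0, 2, 4, 1, 3, 5)
            for b1 in range(2):
                for b2 in range(2):
                    for b3 in range(2):
                        k = (n + 1, 2 * lx + b1, 2 * ly + b2, 2 * lz + b3)
                        if k in pieces:
                            pieces[k] += kid[b1, b2, b3]
                        else:
                            pieces[k] = kid[b1, b2, b3].copy()

        return _tree_from_pieces(pieces, basis, out_p, self.L)


def _tree_from_pieces(pieces, basis, p, L) -> FunctionTree:
    """Sum per-scale scaling-coefficient pieces into one FunctionTree."""
    out = FunctionTree(basis, p, L)
    n1 = basis.n
    nodeset = set(pieces)
    # close under ancestors and complete sibling octets
    stack = list(pieces)
    while stack:
        n, x, y, z = stack.pop()
        if n == 0:
            continue
        parent = (n - 1, x >> 1, y >> 1, z >> 1)
        for b1 in range(2):
            for b2 in range(2):
                for b3 in range(2):
                    sib = (n, (x >> 1) * 2 + b1, (y >> 1) * 2 + b2, (z >> 1) * 2 + b3)
                    nodeset.add(sib)
        if parent not in nodeset:
            nodeset.add(parent)
            stack.append(parent)
    nodeset.add((0, 0, 0, 0))

    children_of = {}
    for key in nodeset:
        n, x, y, z = key
        if n > 0:
            children_of.setdefault((n - 1, x >> 1, y >> 1, z >> 1), []).append(key)

    zero = np.zeros((n1, n1, n1))

    def rec(key, inherited):
        total = inherited + pieces.get(key, zero)
        kids = children_of.get(key)
        if kids:
            down = filter_down(basis, total)
            for ck in kids:
                b = (ck[1] & 1, ck[2] & 1, ck[3] & 1)
                rec(ck, down[b])
            out.nodes[key] = zero.copy()
        else:
            out.nodes[key] = total
            out.leaves.add(key)

    rec((0, 0, 0, 0), np.zeros((n1, n1, n1)))
    out.rebuild_internal()
    out.crop()
    return out


# --------------------------------------------------------------------------- #
# factories
# --------------------------------------------------------------------------- #

def poisson_operator(basis: ScalingBasis, L: float, prec: float) -> ConvolutionOperator:
    """Convolution with the Poisson kernel 1/(4*pi*r) on [-L, L]^3."""
    r_min = 2.0 * L * 2.0**-14
    r_max = 2.0 * (2.0 * L) * np.sqrt(3.0)
    kern = expand_kernel(0.0, min(prec * 1e-2, 1e-7), r_min, r_max)
    return ConvolutionOperator(kern, basis, L, prec)


def helmholtz_operator(
    mu: float, basis: ScalingBasis, L: float, prec: float
) -> ConvolutionOperator:
    """Convolution with the bound-state Helmholtz kernel exp(-mu*r)/(4*pi*r).

    This is the Green's function of (-nabla^2 + mu^2); the orbital update uses
    mu = sqrt(-2*e) to invert (-nabla^2/2 - e) with e < 0.
    """
    if mu <= 0:
        raise ValueError(f"bound-state Helmholtz operator needs mu > 0, got {mu}")
    r_min = 2.0 * L * 2.0**-14
    r_max = 2.0 * (2.0 * L) * np.sqrt(3.0)
    kern = expand_kernel(mu, min(prec * 1e-2, 1e-7), r_min, r_max)
    return ConvolutionOperator(kern, basis, L, prec)
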