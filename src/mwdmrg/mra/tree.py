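"""Adaptive multiwavelet representation of real functions on a cube.

A :class:`FunctionTree` stores scaling coefficients on a full octree over the
domain [-L, L]^3.  Every node holds the (k+1)^3 block of scaling coefficients
of the function's projection onto that box; refinement is driven by the local
wavelet norm, so the discarded detail stays below ``p * ||f|| * 2^(-n/2)`` on
each dropped node.  The basis is orthonormal in physical L2, hence the squared
norm of the function is the sum of squared leaf coefficients (Parseval).
"""

from __future__ import annotations

import warnings
from typing import Callable, Dict, Iterable, Tuple

import numpy as np

from .basis import ScalingBasis, get_basis

NodeKey = Tuple[int, int, int, int]  # (scale n, lx, ly, lz)

DEFAULT_MAX_DEPTH = 20


# --------------------------------------------------------------------------- #
# small tensor helpers
# --------------------------------------------------------------------------- #

def apply_axis(M: np.ndarray, block: np.ndarray, axis: int) -> np.ndarray:
    """Contract matrix ``M`` with ``block`` along one axis of a 3D block.

    Specialized matmul forms: the generic tensordot/moveaxis pair dominates
    runtime when called on hundreds of thousands of small blocks.
    """
    if axis == 0:
        n = block.shape[0]
        return (M @ block.reshape(n, -1)).reshape(M.shape[0], *block.shape[1:])
    if axis == 1:
        return np.matmul(M, block)  # batched over the leading axis
    return block @ M.T


def apply3(M: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Apply the same matrix along all three axes."""
    for ax in range(3):
        block = apply_axis(M, block, ax)
    return block


def filter_down(basis: ScalingBasis, s: np.ndarray) -> np.ndarray:
    """Exact refinement of a parent block into its 8 children.

    Returns array of shape (2, 2, 2, k+1, k+1, k+1); ``out[b1,b2,b3]`` is the
    scaling block of child ``(2l + b)``.
    """
    n1 = basis.n
    H = (basis.H0.T, basis.H1.T)
    out = np.empty((2, 2, 2, n1, n1, n1))
    for b1 in range(2):
        t1 = apply_axis(H[b1], s, 0)
        for b2 in range(2):
            t2 = apply_axis(H[b2], t1, 1)
            for b3 in range(2):
                out[b1, b2, b3] = apply_axis(H[b3], t2, 2)
    return out


def filter_up(basis: ScalingBasis, children: np.ndarray) -> np.ndarray:
    """Exact coarsening: parent scaling block from the 8 child blocks."""
    H = (basis.H0, basis.H1)
    n1 = basis.n
    s = np.zeros((n1, n1, n1))
    for b1 in range(2):
        for b2 in range(2):
            for b3 in range(2):
                t = apply_axis(H[b1], children[b1, b2, b3], 0)
                t = apply_axis(H[b2], t, 1)
                s += apply_axis(H[b3], t, 2)
    return s


# --------------------------------------------------------------------------- #

class FunctionTree:
    """Adaptive multiwavelet representation of a real function on [-L, L]^3."""

    def __init__(self, basis: ScalingBasis, p: float, L: float):
        self.basis = basis
        self.p = float(p)
        self.L = float(L)
        self.nodes: Dict[NodeKey, np.ndarray] = {}
        self.leaves: set = set()

    # -- structural helpers ------------------------------------------------ #

    @property
    def root(self) -> NodeKey:
        return (0, 0, 0, 0)

    def scale_factor(self, n: int) -> float:
        """Jacobian factor linking unit-box quadrature to physical coefficients."""
        return (2.0 * self.L) ** 1.5 * 2.0 ** (-1.5 * n)

    def is_leaf(self, key: NodeKey) -> bool:
        return key in self.leaves

    def children(self, key: NodeKey) -> Iterable[NodeKey]:
        n, lx, ly, lz = key
        for b1 in range(2):
            for b2 in range(2):
                for b3 in range(2):
                    yield (n + 1, 2 * lx + b1, 2 * ly + b2, 2 * lz + b3)

    def num_nodes(self) -> int:
        return len(self.nodes)

    def depth(self) -> int:
        return max((k[0] for k in self.nodes), default=0)

    def copy(self) -> "FunctionTree":
        t = FunctionTree(self.basis, self.p, self.L)
        t.nodes = {k: v.copy() for k, v in self.nodes.items()}
        t.leaves = set(self.leaves)
        return t

    def _check_compatible(self, other: "FunctionTree"):
        if self.basis.k != other.basis.k or self.L != other.L:
            raise ValueError(
                f"incompatible trees: (k={self.basis.k}, L={self.L}) vs "
                f"(k={other.basis.k}, L={other.L})"
            )

    # -- norms ------------------------------------------------------------- #

    def squared_norm(self) -> float:
        return float(sum(np.vdot(self.nodes[k], self.nodes[k]).real for k in self.leaves))

    def norm(self) -> float:
        return float(np.sqrt(max(self.squared_norm(), 0.0)))

    # -- coefficient access ------------------------------------------------ #

    def coeffs_at(self, key: NodeKey) -> np.ndarray:
        """Scaling block of this function's projection on box ``key``.

        Exact if the box is at or below a stored node (two-scale refinement
        from the nearest ancestor); zero outside the domain.
        """
        n, lx, ly, lz = key
        if lx < 0 or ly < 0 or lz < 0 or lx >= 2**n or ly >= 2**n or lz >= 2**n:
            return np.zeros((self.basis.n,) * 3)
        if key in self.nodes:
            return self.nodes[key]
        # walk up to the nearest stored ancestor, then refine back down
        path = []
        kk = key
        while kk not in self.nodes:
            if kk[0] == 0:
                return np.zeros((self.basis.n,) * 3)
            n_, x, y, z = kk
            path.append((x & 1, y & 1, z & 1))
            kk = (n_ - 1, x >> 1, y >> 1, z >> 1)
        s = self.nodes[kk]
        for b in reversed(path):
            s = filter_down(self.basis, s)[b]
        return s

    # -- evaluation -------------------------------------------------------- #

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the represented function at physical points (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(pts))
        if not self.nodes:
            return out
        u_all = (pts + self.L) / (2.0 * self.L)
        for i, u in enumerate(u_all):
            if np.any(u < 0.0) or np.any(u > 1.0):
                continue
            key = self.root
            while key not in self.leaves:
                if key not in self.nodes:
                    break
                n, lx, ly, lz = key
                t = u * 2 ** (n + 1)
                bx = min(int(t[0]) - 2 * lx, 1)
                by = min(int(t[1]) - 2 * ly, 1)
                bz = min(int(t[2]) - 2 * lz, 1)
                key = (n + 1, 2 * lx + max(bx, 0), 2 * ly + max(by, 0), 2 * lz + max(bz, 0))
            if key not in self.nodes:
                continue
            n, lx, ly, lz = key
            loc = u * 2**n - np.array([lx, ly, lz])
            loc = np.clip(loc, 0.0, 1.0)
            px = self.basis.eval_phi(np.array([loc[0]]))[:, 0]
            py = self.basis.eval_phi(np.array([loc[1]]))[:, 0]
            pz = self.basis.eval_phi(np.array([loc[2]]))[:, 0]
            out[i] = np.einsum("ijk,i,j,k->", self.nodes[key], px, py, pz) / self.scale_factor(n)
        return out

    # -- restructuring ----------------------------------------------------- #

    def rebuild_internal(self):
        """Recompute every internal node's block from its leaves (exact)."""
        by_scale: Dict[int, list] = {}
        for key in self.nodes:
            by_scale.setdefault(key[0], []).append(key)
        n1 = self.basis.n
        # bottom-up sweep: children are processed before their parents
        for n in sorted(by_scale, reverse=True):
            for key in by_scale[n]:
                if key in self.leaves:
                    continue
                kids = np.empty((2, 2, 2, n1, n1, n1))
                for b1 in range(2):
                    for b2 in range(2):
                        for b3 in range(2):
                            kids[b1, b2, b3] = self.nodes[
                                (key[0] + 1, 2 * key[1] + b1, 2 * key[2] + b2, 2 * key[3] + b3)
                            ]
                self.nodes[key] = filter_up(self.basis, kids)

    def crop(self, p: float | None = None) -> "FunctionTree":
        """Merge leaf octets whose wavelet norm is below the threshold (in place)."""
        p = self.p if p is None else p
        normf = self.norm()
        if normf == 0.0:
            self.nodes = {self.root: np.zeros((self.basis.n,) * 3)}
            self.leaves = {self.root}
            return self
        changed = True
        while changed:
            changed = False
            parents = {}
            for leaf in self.leaves:
                n, x, y, z = leaf
                if n == 0:
                    continue
                parents.setdefault((n - 1, x >> 1, y >> 1, z >> 1), []).append(leaf)
            for par, kids in parents.items():
                if len(kids) != 8:
                    continue
                # wavelet norm as a direct difference (no cancellation of
                # large squared norms)
                down = filter_down(self.basis, self.nodes[par])
                w2 = sum(
                    float(np.sum((self.nodes[c] - down[c[1] & 1, c[2] & 1, c[3] & 1]) ** 2))
                    for c in kids
                )
                thr = p * normf * 2.0 ** (-0.5 * par[0])
                if np.sqrt(max(w2, 0.0)) < thr:
                    for c in kids:
                        del self.nodes[c]
                        self.leaves.discard(c)
                    self.leaves.add(par)
                    changed = True
        return self


def zero_tree(basis: ScalingBasis, p: float, L: float) -> FunctionTree:
    t = FunctionTree(basis, p, L)
    t.nodes[t.root] = np.zeros((basis.n,) * 3)
    t.leaves = {t.root}
    return t


# --------------------------------------------------------------------------- #
# projection
# --------------------------------------------------------------------------- #

def project(
    f: Callable[[np.ndarray], np.ndarray],
    basis: ScalingBasis | int,
    p: float,
    L: float,
    initial_depth: int = 2,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> FunctionTree:
    """Adaptively project a pointwise-evaluable function onto the MW basis.

    ``f`` must accept an (N, 3) array of physical coordinates and return N
    values.  The local error estimator is the one-level-deeper residual: a
    node's children are projected by quadrature and the node is refined while
    the implied wavelet norm exceeds ``p * ||f|| * 2^(-n/2)``.
    """
    if isinstance(basis, int):
        basis = get_basis(basis)
    tree = FunctionTree(basis, p, L)
    n1 = basis.n
    quad_cache: Dict[NodeKey, np.ndarray] = {}

    def children_quad(key: NodeKey) -> np.ndarray:
        """Direct quadrature of the 8 child blocks of ``key``; (2,2,2,n1,n1,n1)."""
        if key in quad_cache:
            return quad_cache[key]
        n, lx, ly, lz = key
        nc = n + 1
        coords = []
        for l in (lx, ly, lz):
            c = ((2 * l + np.arange(2)[:, None]) + basis.quad_x[None, :]) / 2.0**nc
            coords.append(c.reshape(-1))  # (2*q,) ordered (b, q)
        U = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)  # (2q,2q,2q,3)
        X = U * (2.0 * L) - L
        vals = np.asarray(f(X.reshape(-1, 3)), dtype=float).reshape(U.shape[:3])
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals.reshape(-1)))[0][0]
            loc = X.reshape(-1, 3)[bad]
            raise ValueError(f"non-finite function value at {loc}")
        q = n1
        s = vals.reshape(2, q, 2, q, 2, q).transpose(0, 2, 4, 1, 3, 5)
        for ax in (3, 4, 5):
            s = np.moveaxis(np.tensordot(basis.v2c, s, axes=(1, ax)), 0, ax)
        s = s * tree.scale_factor(nc)
        quad_cache[key] = s
        return s

    # norm estimate from a uniform pre-pass at initial_depth
    pre_keys = [
        (initial_depth, x, y, z)
        for x in range(2**initial_depth)
        for y in range(2**initial_depth)
        for z in range(2**initial_depth)
    ]
    norm2 = 0.0
    for key in pre_keys:
        kids = children_quad(key)
        norm2 += float(np.sum(kids * kids))
    normf = np.sqrt(norm2)
    if normf == 0.0:
        return zero_tree(basis, p, L)

    capped = [False]

    def build(key: NodeKey) -> np.ndarray:
        n = key[0]
        kids = children_quad(key)
        s = filter_up(basis, kids)
        w2 = float(np.sum((kids - filter_down(basis, s)) ** 2))
        thr = p * normf * 2.0 ** (-0.5 * n)
        want_refine = np.sqrt(max(w2, 0.0)) > thr or n < initial_depth
        if want_refine and n + 1 >= max_depth:
            capped[0] = True
            want_refine = False
        if want_refine:
            child_blocks = np.empty((2, 2, 2, n1, n1, n1))
            for b1 in range(2):
                for b2 in range(2):
                    for b3 in range(2):
                        ck = (n + 1, 2 * key[1] + b1, 2 * key[2] + b2, 2 * key[3] + b3)
                        child_blocks[b1, b2, b3] = build(ck)
            s = filter_up(basis, child_blocks)
        else:
            tree.leaves.add(key)
        tree.nodes[key] = s
        return s

    build(tree.root)
    if capped[0]:
        warnings.warn(
            f"projection refinement capped at max depth {max_depth}; "
            "requested precision may not be met",
            RuntimeWarning,
        )
    tree.crop(p)
    return tree


# --------------------------------------------------------------------------- #
# arithmetic
# --------------------------------------------------------------------------- #

def _union_nodeset(a: FunctionTree, b: FunctionTree) -> set:
    return set(a.nodes) | set(b.nodes)


def _union_leaf_blocks(a: FunctionTree, b: FunctionTree):
    """Yield (key, A_block, B_block) over the union leaf cover of two trees."""
    union = _union_nodeset(a, b)

    def rec(key, blk_a, blk_b):
        n, x, y, z = key
        child0 = (n + 1, 2 * x, 2 * y, 2 * z)
        if child0 in union:
            da = None if key in a.nodes and not a.is_leaf(key) else filter_down(a.basis, blk_a)
            db = None if key in b.nodes and not b.is_leaf(key) else filter_down(b.basis, blk_b)
            for b1 in range(2):
                for b2 in range(2):
                    for b3 in range(2):
                        ck = (n + 1, 2 * x + b1, 2 * y + b2, 2 * z + b3)
                        ca = a.nodes[ck] if da is None else da[b1, b2, b3]
                        cb = b.nodes[ck] if db is None else db[b1, b2, b3]
                        yield from rec(ck, ca, cb)
        else:
            yield key, blk_a, blk_b

    ra = a.nodes.get(a.root, np.zeros((a.basis.n,) * 3))
    rb = b.nodes.get(b.root, np.zeros((b.basis.n,) * 3))
    yield from rec(a.root, ra, rb)


def add(a: FunctionTree, w1: float, b: FunctionTree, w2: float) -> FunctionTree:
    """Linear combination ``w1*a + w2*b`` on the union grid, re-thresholded."""
    a._check_compatible(b)
    out = FunctionTree(a.basis, min(a.p, b.p), a.L)
    for key, ba, bb in _union_leaf_blocks(a, b):
        out.nodes[key] = w1 * ba + w2 * bb
        out.leaves.add(key)
    _fill_ancestors(out)
    out.rebuild_internal()
    out.crop()
    return out


def _fill_ancestors(tree: FunctionTree):
    n1 = tree.basis.n
    for key in list(tree.leaves):
        n, x, y, z = key
        while n > 0:
            n, x, y, z = n - 1, x >> 1, y >> 1, z >> 1
            if (n, x, y, z) in tree.nodes:
                break
            tree.nodes[(n, x, y, z)] = np.zeros((n1, n1, n1))
    if tree.root not in tree.nodes:
        tree.nodes[tree.root] = np.zeros((n1, n1, n1))


def inner(a: FunctionTree, b: FunctionTree) -> float:
    """L2 inner product <a, b>, exact on the union of the two grids."""
    a._check_compatible(b)
    tot = 0.0
    for _, ba, bb in _union_leaf_blocks(a, b):
        tot += float(np.sum(ba * bb))
    return tot


def multiply(a: FunctionTree, b: FunctionTree) -> FunctionTree:
    """Pointwise product, computed on the union grid refined one extra level.

    The product of two order-k polynomials exceeds order k, so each union leaf
    is refined once before quadrature re-projection; the result is then
    re-thresholded at the tree precision.
    """
    a._check_compatible(b)
    basis = a.basis
    out = FunctionTree(basis, min(a.p, b.p), a.L)
    P2V = basis.phi_vals.T  # values <- coeffs
    for key, ba, bb in _union_leaf_blocks(a, b):
        n = key[0]
        ka = filter_down(basis, ba)
        kb = filter_down(basis, bb)
        sf = out.scale_factor(n + 1)
        for b1 in range(2):
            for b2 in range(2):
                for b3 in range(2):
                    va = apply3(P2V, ka[b1, b2, b3]) / sf
                    vb = apply3(P2V, kb[b1, b2, b3]) / sf
                    s = apply3(basis.v2c, va * vb) * sf
                    ck = (n + 1, 2 * key[1] + b1, 2 * key[2] + b2, 2 * key[3] + b3)
                    out.nodes[ck] = s
                    out.leaves.add(ck)
    _fill_ancestors(out)
    out.rebuild_internal()
    out.crop()
    return out


def differentiate(a: FunctionTree, axis: int) -> FunctionTree:
    """Weak first derivative along ``axis`` (0, 1 or 2), central-flux stencil.

    Fluxes are one-sided at the domain walls, so a globally constant function
    differentiates to exactly zero; for the decaying functions this package
    works with the wall treatment is immaterial.  Differentiating an
    empty/zero tree returns a zero tree.

    Before applying the stencil the grid is balanced along the axis: a leaf
    whose same-scale neighbor is refined deeper is split (exactly, by
    two-scale refinement) until its axis neighbors are no finer.  Without
    this, the flux terms would read the neighbor's coarse-scale projection,
    whose edge trace carries the full local representation error.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    basis = a.basis
    out = FunctionTree(basis, a.p, a.L)
    if not a.nodes:
        return zero_tree(basis, a.p, a.L)

    work = a.copy()
    queue = list(work.leaves)
    while queue:
        leaf = queue.pop()
        if leaf not in work.leaves:
            continue
        n, lx, ly, lz = leaf
        e = [0, 0, 0]
        e[axis] = 1
        for sgn in (-1, 1):
            nb = (n, lx + sgn * e[0], ly + sgn * e[1], lz + sgn * e[2])
            if nb in work.nodes and nb not in work.leaves:
                kid = filter_down(basis, work.nodes[leaf])
                work.leaves.discard(leaf)
                for b1 in range(2):
                    for b2 in range(2):
                        for b3 in range(2):
                            ck = (n + 1, 2 * lx + b1, 2 * ly + b2, 2 * lz + b3)
                            work.nodes[ck] = kid[b1, b2, b3]
                            work.leaves.add(ck)
                            queue.append(ck)
                # splitting may expose coarser axis-neighbors to finer boxes
                for sgn2 in (-1, 1):
                    nb2 = (n, lx + sgn2 * e[0], ly + sgn2 * e[1], lz + sgn2 * e[2])
                    if nb2 in work.leaves:
                        queue.append(nb2)
                break

    A, B, C = basis.deriv_A, basis.deriv_B, basis.deriv_C
    for leaf in work.leaves:
        n, *l = leaf
        scale = 2.0**n / (2.0 * a.L)
        e = [0, 0, 0]
        e[axis] = 1
        blk = apply_axis(B, work.nodes[leaf], axis)
        # one-sided fluxes at the domain walls (exterior value undefined, not
        # zero): a globally constant function then has an exactly zero
        # derivative; decaying functions are unaffected
        size = 2**n
        if l[axis] > 0:
            left = work.coeffs_at((n, l[0] - e[0], l[1] - e[1], l[2] - e[2]))
            blk += apply_axis(A, left, axis)
        else:
            p0 = basis.phi_at_0
            blk -= apply_axis(0.5 * np.outer(p0, p0), work.nodes[leaf], axis)
        if l[axis] < size - 1:
            right = work.coeffs_at((n, l[0] + e[0], l[1] + e[1], l[2] + e[2]))
            blk += apply_axis(C, right, axis)
        else:
            p1 = basis.phi_at_1
            blk += apply_axis(0.5 * np.outer(p1, p1), work.nodes[leaf], axis)
        out.nodes[leaf] = scale * blk
        out.leaves.add(leaf)
    _fill_ancestors(out)
    out.rebuild_internal()
    out.crop()
    return out


# --------------------------------------------------------------------------- #
# checkpoint I/O
# --------------------------------------------------------------------------- #

def save_collection(path, trees: list, labels: list | None = None):
    """Binary checkpoint for a FunctionTree collection (orbital restart files).

    Layout (single ``.npz``): scalar header arrays ``k``, ``p``, ``L``,
    ``count``; per tree ``i``: ``keys_i`` (int64, shape (n_nodes, 4), rows are
    (scale, lx, ly, lz)), ``leaf_i`` (bool mask over the same rows) and
    ``coef_i`` (float64, shape (n_nodes, k+1, k+1, k+1)).
    """
    arrays = {
        "k": np.array(trees[0].basis.k),
        "p": np.array(trees[0].p),
        "L": np.array(trees[0].L),
        "count": np.array(len(trees)),
    }
    if labels is not None:
        arrays["labels"] = np.array(labels)
    for i, t in enumerate(trees):
        keys = sorted(t.nodes)
        arrays[f"keys_{i}"] = np.array(keys, dtype=np.int64).reshape(len(keys), 4)
        arrays[f"leaf_{i}"] = np.array([k in t.leaves for k in keys])
        arrays[f"coef_{i}"] = np.stack([t.nodes[k] for k in keys])
    np.savez(path, **arrays)


def load_collection(path) -> list:
    data = np.load(path, allow_pickle=False)
    basis = get_basis(int(data["k"]))
    p = float(data["p"])
    L = float(data["L"])
    trees = []
    for i in range(int(data["count"])):
        t = FunctionTree(basis, p, L)
        keys = data[f"keys_{i}"]
        leaf = data[f"leaf_{i}"]
        coef = data[f"coef_{i}"]
        for row, isleaf, blk in zip(keys, leaf, coef):
            key = tuple(int(v) for v in row)
            t.nodes[key] = blk.copy()
            if isleaf:
                t.leaves.add(key)
        trees.append(t)
    return trees
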