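"""Matrix product operator / matrix product state engine.

The second-quantized chemical Hamiltonian

    H = sum_ij h_ij sum_s a+_{i,s} a_{j,s}
      + 1/2 sum_ijkl g_ijkl sum_{s,t} a+_{i,s} a+_{j,t} a_{l,t} a_{k,s}

is encoded as an MPO over M spatial-orbital sites of local dimension 4
(|0>, |up>, |dn>, |updn>), with fermionic statistics handled by Jordan-Wigner
parity operators inside the site matrices.  The ground state is found by
two-site DMRG; particle-number and spin-projection sectors are fixed by an
in-sector initial state plus quadratic penalty terms added to the sweep
Hamiltonian (the reported energy is always the expectation of the bare H).

Energy gradients dE/dh_ij = <E_ij> and dE/dg_ijkl = <e_ijkl> are extracted by
"cutting holes" in the energy network: the MPS-MPO-MPS contraction with one
coefficient's operator content isolated, evaluated with cached partial
environments.  A dense statevector RDM route is kept as an independent
cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np


from .fci import determinant_to_site_index, sector_determinants

D = 4  # local dimension

# ---- site-local operators (basis |0>, |up>, |dn>, |updn>) ---- #
A_UP = np.zeros((D, D))
A_UP[0, 1] = 1.0
A_UP[2, 3] = 1.0
A_DN = np.zeros((D, D))
A_DN[0, 2] = 1.0
A_DN[1, 3] = -1.0
PARITY = np.diag([1.0, -1.0, -1.0, 1.0])
IDENT = np.eye(D)
N_OP = np.diag([0.0, 1.0, 1.0, 2.0])
SZ_OP = np.diag([0.0, 0.5, -0.5, 0.0])


def fermion_string(M: int, ops: Sequence[Tuple[int, bool]]) -> List[np.ndarray]:
    """Site matrices of a product of fermionic operators with JW parities.

    ``ops`` lists (spin_orbital, dagger) in operator order (leftmost first);
    spin orbital 2*m + s lives on site m.  Returns M site matrices whose
    ordered tensor product (with implied parity strings) equals the operator.
    """
    mats = [IDENT.copy() for _ in range(M)]
    touched = [False] * M
    for so, dag in ops:
        m, s = divmod(so, 2)
        local = (A_UP if s == 0 else A_DN)
        if dag:
            local = local.T
        for site in range(m):
            mats[site] = mats[site] @ PARITY
            touched[site] = True
        mats[m] = mats[m] @ local
        touched[m] = True
    return [mat if t else None for mat, t in zip(mats, touched)]


# --------------------------------------------------------------------------- #
# MPO
# --------------------------------------------------------------------------- #

class MPO:
    """List of tensors W[m] with shape (chi_l, chi_r, d_out, d_in)."""

    def __init__(self, tensors: List[np.ndarray]):
        self.W = tensors

    @property
    def n_sites(self) -> int:
        return len(self.W)

    def bond_dims(self) -> List[int]:
        return [w.shape[1] for w in self.W[:-1]]

    def to_dense(self) -> np.ndarray:
        """Contract to the full 4^M x 4^M matrix (tests / small M only)."""
        T = self.W[0][0]  # (chi, d, d')
        for w in self.W[1:]:
            T = np.einsum("xab,xycd->yacbd", T, w)
            s = T.shape
            T = T.reshape(s[0], s[1] * s[2], s[3] * s[4])
        return T[0]


def mpo_from_strings(M: int, strings: List[Tuple[float, List[np.ndarray]]]) -> MPO:
    """Stack coefficient-weighted operator strings into a bond-K MPO."""
    K = len(strings)
    tensors = []
    for m in range(M):
        chi_l = 1 if m == 0 else K
        chi_r = 1 if m == M - 1 else K
        W = np.zeros((chi_l, chi_r, D, D))
        for k, (coeff, mats) in enumerate(strings):
            mat = mats[m] if mats[m] is not None else IDENT
            if m == 0:
                mat = coeff * mat
            il = 0 if chi_l == 1 else k
            ir = 0 if chi_r == 1 else k
            W[il, ir] += mat
        tensors.append(W)
    return MPO(tensors)


def mpo_add(a: MPO, b: MPO) -> MPO:
    out = []
    M = a.n_sites
    for m in range(M):
        wa, wb = a.W[m], b.W[m]
        cl = 1 if m == 0 else wa.shape[0] + wb.shape[0]
        cr = 1 if m == M - 1 else wa.shape[1] + wb.shape[1]
        W = np.zeros((cl, cr, D, D))
        if m == 0:
            W[:, : wa.shape[1]] = wa
            W[:, wa.shape[1]:] = wb
        elif m == M - 1:
            W[: wa.shape[0], :] = wa
            W[wa.shape[0]:, :] = wb
        else:
            W[: wa.shape[0], : wa.shape[1]] = wa
            W[wa.shape[0]:, wa.shape[1]:] = wb
        out.append(W)
    return MPO(out)


def mpo_compress(mpo: MPO, tol: float = 1e-14) -> MPO:
    """Exact-rank reduction by two SVD sweeps (deduplication, no loss > tol)."""
    W = [w.copy() for w in mpo.W]
    M = len(W)
    # left -> right
    for m in range(M - 1):
        cl, cr, _, _ = W[m].shape
        mat = W[m].transpose(0, 2, 3, 1).reshape(cl * D * D, cr)
        U, s, Vt = np.linalg.svd(mat, full_matrices=False)
        keep = max(1, int(np.sum(s > tol * max(s[0], 1e-300))))
        U, s, Vt = U[:, :keep], s[:keep], Vt[:keep]
        W[m] = U.reshape(cl, D, D, keep).transpose(0, 3, 1, 2)
        W[m + 1] = np.einsum("ab,bcde->acde", np.diag(s) @ Vt, W[m + 1])
    # right -> left
    for m in range(M - 1, 0, -1):
        cl, cr, _, _ = W[m].shape
        mat = W[m].transpose(0, 1, 2, 3).reshape(cl, cr * D * D)
        U, s, Vt = np.linalg.svd(mat, full_matrices=False)
        keep = max(1, int(np.sum(s > tol * max(s[0], 1e-300))))
        U, s, Vt = U[:, :keep], s[:keep], Vt[:keep]
        W[m] = Vt.reshape(keep, cr, D, D)
        W[m - 1] = np.einsum("abde,bc->acde", W[m - 1], U @ np.diag(s))
    return MPO(W)


def hamiltonian_strings(h: np.ndarray, g: np.ndarray):
    """Operator strings of the chemical Hamiltonian (coefficient, site mats)."""
    M = h.shape[0]
    strings = []
    for i in range(M):
        for j in range(M):
            if abs(h[i, j]) < 1e-15:
                continue
            for s in (0, 1):
                strings.append(
                    (h[i, j], fermion_string(M, [(2 * i + s, True), (2 * j + s, False)]))
                )
    for i in range(M):
        for j in range(M):
            for k in range(M):
                for l in range(M):
                    if abs(g[i, j, k, l]) < 1e-15:
                        continue
                    for s in (0, 1):
                        for t in (0, 1):
                            strings.append(
                                (
                                    0.5 * g[i, j, k, l],
                                    fermion_string(
                                        M,
                                        [
                                            (2 * i + s, True),
                                            (2 * j + t, True),
                                            (2 * l + t, False),
                                            (2 * k + s, False),
                                        ],
                                    ),
                                )
                            )
    return strings


def build_mpo(h: np.ndarray, g: np.ndarray, chunk: int = 256, tol: float = 1e-14) -> MPO:
    """Hamiltonian MPO from (h, g); exact up to deduplication of bond states.

    Raises on asymmetric inputs: h must be symmetric and g must carry the
    8-fold real-orbital symmetry the integrals guarantee.
    """
    M = h.shape[0]
    if not np.allclose(h, h.T, atol=1e-10):
        raise ValueError("h must be symmetric")
    for perm in ((2, 1, 0, 3), (0, 3, 2, 1), (1, 0, 3, 2)):
        if not np.allclose(g, g.transpose(perm), atol=1e-10):
            raise ValueError("g must have the 8-fold real-orbital symmetry")

    strings = hamiltonian_strings(h, g)
    if not strings:
        strings = [(0.0, [None] * M)]
    acc = None
    for start in range(0, len(strings), chunk):
        part = mpo_from_strings(M, strings[start: start + chunk])
        acc = part if acc is None else mpo_add(acc, part)
        acc = mpo_compress(acc, tol)
    return acc


def penalty_mpo(M: int, N: int, sz2: int, weight: float) -> MPO:
    """weight * [(N_hat - N)^2 + (Sz_hat - Sz)^2] as an MPO."""
    strings = []
    sz = 0.5 * sz2
    for a in range(M):
        for b_ in range(M):
            if a == b_:
                continue
            mats = [None] * M
            mats[a] = N_OP.copy()
            mats[b_] = N_OP.copy()
            strings.append((weight, mats))
            mats2 = [None] * M
            mats2[a] = SZ_OP.copy()
            mats2[b_] = SZ_OP.copy()
            strings.append((weight, mats2))
    for a in range(M):
        mats = [None] * M
        mats[a] = N_OP @ N_OP - 2.0 * N * N_OP
        strings.append((weight, mats))
        mats2 = [None] * M
        mats2[a] = SZ_OP @ SZ_OP - 2.0 * sz * SZ_OP
        strings.append((weight, mats2))
    const = [None] * M
    const[0] = (N**2 + sz**2) * IDENT
    strings.append((weight, const))
    out = None
    for start in range(0, len(strings), 256):
        part = mpo_from_strings(M, strings[start: start + 256])
        out = part if out is None else mpo_add(out, part)
        out = mpo_compress(out)
    return out


def _one_site(M, a, op):
    mats = [None] * M
    mats[a] = op.copy()
    return mats


def number_mpo(M: int) -> MPO:
    return mpo_compress(
        mpo_from_strings(M, [(1.0, _one_site(M, a, N_OP)) for a in range(M)])
    )


def sz_mpo(M: int) -> MPO:
    return mpo_compress(
        mpo_from_strings(M, [(1.0, _one_site(M, a, SZ_OP)) for a in range(M)])
    )


# --------------------------------------------------------------------------- #
# MPS
# --------------------------------------------------------------------------- #

class MPS:
    """List of tensors A[m] with shape (chi_l, d, chi_r)."""

    def __init__(self, tensors: List[np.ndarray]):
        self.A = tensors

    @property
    def n_sites(self) -> int:
        return len(self.A)

    def bond_dims(self) -> List[int]:
        return [a.shape[2] for a in self.A[:-1]]

    def to_dense(self) -> np.ndarray:
        T = self.A[0][0]  # (d, chi)
        for a in self.A[1:]:
            T = np.einsum("...x,xdy->...dy", T, a)
        return T.reshape(-1)

    def norm(self) -> float:
        return float(np.sqrt(max(self.overlap(self), 0.0)))

    def overlap(self, other: "MPS") -> float:
        E = np.ones((1, 1))
        for a, b_ in zip(self.A, other.A):
            E = np.einsum("lm,ldr->mdr", E, a)
            E = np.einsum("mdr,mds->rs", E, b_)
        return float(E[0, 0])

    @classmethod
    def from_dense(cls, vec: np.ndarray, M: int, chi_max: int = 10**9,
                   tol: float = 1e-14) -> "MPS":
        tensors = []
        psi = vec.reshape(1, -1)
        for m in range(M - 1):
            chi_l = psi.shape[0]
            psi = psi.reshape(chi_l * D, -1)
            U, s, Vt = np.linalg.svd(psi, full_matrices=False)
            keep = max(1, min(chi_max, int(np.sum(s > tol * max(s[0], 1e-300)))))
            tensors.append(U[:, :keep].reshape(chi_l, D, keep))
            psi = (s[:keep, None] * Vt[:keep])
        tensors.append(psi.reshape(psi.shape[0], D, 1))
        return cls(tensors)


def random_sector_mps(M: int, N: int, sz2: int, seed: int = 0,
                      chi_max: int = 10**9) -> MPS:
    """Random superposition of in-sector determinants, as an exact MPS."""
    dets = sector_determinants(M, N, sz2)
    rng = np.random.default_rng(seed)
    vec = np.zeros(D**M)
    amps = rng.standard_normal(len(dets))
    for det, amp in zip(dets, amps):
        vec[determinant_to_site_index(det, M)] = amp
    vec /= np.linalg.norm(vec)
    return MPS.from_dense(vec, M, chi_max=chi_max)


def mpo_expectation(mps: MPS, mpo: MPO) -> float:
    """<psi|O|psi> / <psi|psi>."""
    E = np.ones((1, 1, 1))  # (bra, op, ket)
    for a, w in zip(mps.A, mpo.W):
        E = np.einsum("xyz,xav->yzav", E, a)
        E = np.einsum("yzav,ywab->zvwb", E, w)
        E = np.einsum("zvwb,zbu->vwu", E, a)
    return float(E[0, 0, 0]) / mps.overlap(mps)


# --------------------------------------------------------------------------- #
# two-site DMRG
# --------------------------------------------------------------------------- #

@dataclass
class DmrgConfig:
    schedule: List[Tuple[int, int]] = field(
        default_factory=lambda: [(16, 2), (32, 2), (64, 2)]
    )
    tol: float = 1e-9
    seed: int = 0
    penalty: float = 25.0
    max_extra_sweeps: int = 12
    svd_tol: float = 1e-13


@dataclass
class GroundState:
    mps: MPS
    energy: float
    n_electrons: int
    sz2: int
    sweep_energies: List[float]
    converged: bool
    n_sweeps: int
    number_expectation: float
    sz_expectation: float


def _left_env_step(E, a, w, b):
    E = np.einsum("xyz,xav->yzav", E, a)
    E = np.einsum("yzav,ywab->zvwb", E, w)
    return np.einsum("zvwb,zbu->vwu", E, b)


def _right_env_step(E, a, w, b):
    E = np.einsum("xyz,vax->yzva", E, a)
    E = np.einsum("yzva,wyab->zvwb", E, w)
    return np.einsum("zvwb,ubz->vwu", E, b)


def dmrg_ground_state(
    mpo: MPO, N: int, sz2: int = 0, cfg: DmrgConfig | None = None
) -> GroundState:
    """Variational ground-state search in the (N, Sz) sector.

    The sweep Hamiltonian is the input MPO plus quadratic number/spin
    penalties; the initial state is an in-sector random determinant
    superposition and the local Lanczos solves are seeded with the current
    tensor, so the sector is preserved to roundoff throughout.  The reported
    energy is the bare-MPO expectation of the final state.
    """
    cfg = cfg or DmrgConfig()
    M = mpo.n_sites
    if N > 2 * M or N < 0:
        raise ValueError(f"infeasible sector: N={N} with M={M} orbitals")
    sector_determinants(M, N, sz2)  # validates (N, sz2)

    if M == 1:
        return _single_site_ground_state(mpo, N, sz2)

    H = mpo
    if cfg.penalty > 0:
        H = mpo_compress(mpo_add(mpo, penalty_mpo(M, N, sz2, cfg.penalty)))

    chi0 = cfg.schedule[0][0]
    mps = random_sector_mps(M, N, sz2, seed=cfg.seed, chi_max=chi0)
    # pad schedule with extra sweeps at the final bond dimension; convergence
    # is only declared during the final-bond-dimension phase
    schedule = list(cfg.schedule) + [(cfg.schedule[-1][0], 1)] * cfg.max_extra_sweeps
    chi_final = cfg.schedule[-1][0]

    # right-canonicalize
    for m in range(M - 1, 0, -1):
        chi_l, d, chi_r = mps.A[m].shape
        mat = mps.A[m].reshape(chi_l, d * chi_r)
        U, s, Vt = np.linalg.svd(mat, full_matrices=False)
        mps.A[m] = Vt.reshape(-1, d, chi_r)
        mps.A[m - 1] = np.einsum("ldr,rk->ldk", mps.A[m - 1], U * s)
    nrm = np.linalg.norm(mps.A[0])
    mps.A[0] = mps.A[0] / nrm

    # environments
    Renv = [None] * (M + 1)
    Renv[M] = np.ones((1, 1, 1))
    for m in range(M - 1, -1, -1):
        Renv[m] = _right_env_step(Renv[m + 1], mps.A[m], H.W[m], mps.A[m])
    Lenv = [None] * (M + 1)
    Lenv[0] = np.ones((1, 1, 1))

    energies: List[float] = []
    sweep_count = 0
    converged = False
    E_last = np.inf
    for chi, n_sw in schedule:
        for _ in range(n_sw):
            E_sweep = np.inf
            # left -> right
            for m in range(M - 1):
                E_sweep = _two_site_update(mps, H, Lenv, Renv, m, chi, cfg, "LR")
            # right -> left
            for m in range(M - 2, -1, -1):
                E_sweep = _two_site_update(mps, H, Lenv, Renv, m, chi, cfg, "RL")
            energies.append(E_sweep)
            sweep_count += 1
            if chi >= chi_final and abs(E_sweep - E_last) < cfg.tol:
                converged = True
                E_last = E_sweep
                break
            E_last = E_sweep
        if converged:
            break
    if not converged:
        warnings.warn(
            f"DMRG not converged to {cfg.tol:g} after {sweep_count} sweeps "
            f"(last |dE| = {abs(E_sweep - E_last):g}); returning best state",
            RuntimeWarning,
        )

    nrm2 = mps.overlap(mps)
    mps.A[0] = mps.A[0] / np.sqrt(nrm2)
    energy = mpo_expectation(mps, mpo)
    n_exp = mpo_expectation(mps, number_mpo(M))
    sz_exp = mpo_expectation(mps, sz_mpo(M))
    return GroundState(
        mps=mps,
        energy=float(energy),
        n_electrons=N,
        sz2=sz2,
        sweep_energies=energies,
        converged=converged,
        n_sweeps=sweep_count,
        number_expectation=float(n_exp),
        sz_expectation=float(sz_exp),
    )


def _two_site_update(mps, H, Lenv, Renv, m, chi, cfg, direction):
    A1, A2 = mps.A[m], mps.A[m + 1]
    chi_l = A1.shape[0]
    chi_r = A2.shape[2]
    L, R = Lenv[m], Renv[m + 2]
    W1, W2 = H.W[m], H.W[m + 1]
    theta0 = np.einsum("ldr,rek->ldek", A1, A2).reshape(-1)
    dim = theta0.size

    def matvec(v):
        # H_eff theta, contracted pairwise (BLAS-backed throughout):
        # th(z,b,e,k) R(u,v,k) W2(w,v,c,e) W1(y,w,a,b) L(x,y,z) -> (x,a,c,u)
        th = v.reshape(chi_l, D, D, chi_r)
        t = np.tensordot(th, R, axes=(3, 2))            # (z,b,e,u,v)
        t = np.tensordot(t, W2, axes=([2, 4], [3, 1]))  # (z,b,u,w,c)
        t = np.tensordot(t, W1, axes=([1, 3], [3, 1]))  # (z,u,c,y,a)
        t = np.tensordot(t, L, axes=([0, 3], [2, 1]))   # (u,c,a,x)
        return t.transpose(3, 2, 1, 0).reshape(-1)

    if dim <= 64:
        Hd = np.array([matvec(np.eye(dim)[:, i]) for i in range(dim)]).T
        w, V = np.linalg.eigh(0.5 * (Hd + Hd.T))
        E0, theta = float(w[0]), V[:, 0]
    else:
        E0, theta = _lanczos_ground(matvec, theta0, tol=min(cfg.tol * 0.3, 3e-10))

    th = theta.reshape(chi_l * D, D * chi_r)
    U, s, Vt = np.linalg.svd(th, full_matrices=False)
    keep = max(1, min(chi, int(np.sum(s > cfg.svd_tol * max(s[0], 1e-300)))))
    U, s, Vt = U[:, :keep], s[:keep], Vt[:keep]
    s = s / np.linalg.norm(s)
    if direction == "LR":
        mps.A[m] = U.reshape(chi_l, D, keep)
        mps.A[m + 1] = (s[:, None] * Vt).reshape(keep, D, chi_r)
        Lenv[m + 1] = _left_env_step(Lenv[m], mps.A[m], H.W[m], mps.A[m])
    else:
        mps.A[m + 1] = Vt.reshape(keep, D, chi_r)
        mps.A[m] = (U * s).reshape(chi_l, D, keep)
        Renv[m + 1] = _right_env_step(Renv[m + 2], mps.A[m + 1], H.W[m + 1], mps.A[m + 1])
    return E0


def _lanczos_ground(matvec, v0, tol: float = 3e-10, max_steps: int = 200):
    """Smallest eigenpair by Lanczos with full reorthogonalization.

    Deterministic given ``v0``; stops when the estimated eigenpair residual
    ||H theta - E theta|| (= beta_k * |last Ritz component|) drops below
    ``tol``, which bounds the eigenvector error by tol / gap.
    """
    v = v0 / np.linalg.norm(v0)
    basis = [v]
    alphas: List[float] = []
    betas: List[float] = []
    E_cur = np.inf
    theta_small = np.array([1.0])
    for step in range(max_steps):
        w = matvec(basis[-1])
        a = float(basis[-1] @ w)
        alphas.append(a)
        w = w - a * basis[-1]
        if betas:
            w = w - betas[-1] * basis[-2]
        # full reorthogonalization (small Krylov spaces; keeps it stable)
        for b_ in basis:
            w = w - (b_ @ w) * b_
        T = np.diag(alphas)
        if betas:
            T = T + np.diag(betas, 1) + np.diag(betas, -1)
        evals, evecs = np.linalg.eigh(T)
        E_cur = float(evals[0])
        theta_small = evecs[:, 0]
        nrm = np.linalg.norm(w)
        residual = nrm * abs(theta_small[-1])
        if residual < tol or nrm < 1e-13 or len(basis) >= v0.size:
            break
        betas.append(nrm)
        basis.append(w / nrm)
    theta = np.zeros_like(v0, dtype=float)
    for coef, b_ in zip(theta_small, basis):
        theta += coef * b_
    theta /= np.linalg.norm(theta)
    return E_cur, theta


def _single_site_ground_state(mpo: MPO, N: int, sz2: int) -> GroundState:
    Hd = mpo.to_dense()
    dets = sector_determinants(1, N, sz2)
    idx = [determinant_to_site_index(d_, 1) for d_ in dets]
    sub = Hd[np.ix_(idx, idx)]
    w, V = np.linalg.eigh(0.5 * (sub + sub.T))
    vec = np.zeros(D)
    vec[idx] = V[:, 0]
    mps = MPS([vec.reshape(1, D, 1)])
    E = float(w[0])
    n_exp = float(vec @ N_OP @ vec)
    sz_exp = float(vec @ SZ_OP @ vec)
    return GroundState(mps, E, N, sz2, [E], True, 1, n_exp, sz_exp)


# --------------------------------------------------------------------------- #
# gradient extraction
# --------------------------------------------------------------------------- #

@dataclass
class GradientTensors:
    dE_dh: np.ndarray  # <E_ij>          (M x M)
    dE_dg: np.ndarray  # <e_ijkl>        (M^4)


class _StringEvaluator:
    """<psi|string|psi> with cached identity environments (hole-cutting)."""

    def __init__(self, mps: MPS):
        self.mps = mps
        M = mps.n_sites
        self.L = [np.ones((1, 1))]
        for m in range(M):
            E = np.einsum("lm,ldr->mdr", self.L[-1], mps.A[m])
            self.L.append(np.einsum("mdr,mds->rs", E, mps.A[m]))
        self.R = [np.ones((1, 1))]
        for m in range(M - 1, -1, -1):
            E = np.einsum("rs,ldr->lds", self.R[-1], mps.A[m])
            self.R.append(np.einsum("lds,mds->lm", E, mps.A[m]))
        self.R = self.R[::-1]  # R[m] closes sites m..M-1 already contracted
        self.norm2 = float(self.L[-1][0, 0])

    def value(self, mats: List[np.ndarray]) -> float:
        sites = [m for m, mat in enumerate(mats) if mat is not None]
        if not sites:
            return self.norm2
        a, b_ = sites[0], sites[-1]
        E = self.L[a]
        for m in range(a, b_ + 1):
            mat = mats[m] if mats[m] is not None else IDENT
            A = self.mps.A[m]
            T = np.einsum("lm,ldr->mdr", E, A)
            T = np.einsum("mdr,ed->mer", T, mat)
            E = np.einsum("mer,mes->rs", T, A)
        return float(np.einsum("rs,rs->", E, self.R[b_ + 1]))


def extract_gradients(state: GroundState, method: str = "hole") -> GradientTensors:
    """Energy gradients dE/dh = <E_ij>, dE/dg = <e_ijkl> from the MPS.

    method="hole": per-coefficient contraction of the energy network with the
    coefficient's operator content isolated, using cached partial
    environments.  method="rdm": dense statevector reconstruction and
    explicit spin-free RDM evaluation (independent cross-check; M <= 8).
    """
    mps = state.mps
    M = mps.n_sites
    nrm2 = mps.overlap(mps)
    if abs(nrm2 - 1.0) > 1e-10:
        warnings.warn(
            "unnormalized state passed to extract_gradients; normalizing",
            RuntimeWarning,
        )
        mps = MPS([a.copy() for a in mps.A])
        mps.A[0] = mps.A[0] / np.sqrt(nrm2)

    if method == "rdm":
        return _gradients_from_dense(mps, M)
    if method != "hole":
        raise ValueError(f"unknown gradient method: {method!r}")

    ev = _StringEvaluator(mps)
    gamma = np.zeros((M, M))
    for i in range(M):
        for j in range(i, M):
            val = sum(
                ev.value(fermion_string(M, [(2 * i + s, True), (2 * j + s, False)]))
                for s in (0, 1)
            )
            gamma[i, j] = gamma[j, i] = val

    # X[(i,k),(j,l)] = <E_ik E_jl>; symmetric under ((i,k),(j,l)) -> ((l,j),(k,i))
    X = np.full((M, M, M, M), np.nan)
    for i in range(M):
        for k in range(M):
            for j in range(M):
                for l in range(M):
                    if not np.isnan(X[i, k, j, l]):
                        continue
                    val = sum(
                        ev.value(
                            fermion_string(
                                M,
                                [
                                    (2 * i + s, True),
                                    (2 * k + s, False),
                                    (2 * j + t, True),
                                    (2 * l + t, False),
                                ],
                            )
                        )
                        for s in (0, 1)
                        for t in (0, 1)
                    )
                    X[i, k, j, l] = val
                    X[l, j, k, i] = val
    Gamma = X.transpose(0, 2, 1, 3).copy()  # <E_ik E_jl> indexed [i,j,k,l]
    for j in range(M):
        Gamma[:, j, j, :] -= gamma
    return GradientTensors(dE_dh=gamma, dE_dg=Gamma)


def _gradients_from_dense(mps: MPS, M: int) -> GradientTensors:
    from .fci import _apply_annihilate, _apply_create  # shared bit kernels

    vec = mps.to_dense()
    dim = D**M
    # map site-basis index -> bitmask determinant amplitudes
    full = np.zeros(1 << (2 * M))
    for idx in range(dim):
        rem = idx
        mask = 0
        for m in range(M - 1, -1, -1):
            loc = rem % 4
            rem //= 4
            if loc in (1, 3):
                mask |= 1 << (2 * m)
            if loc in (2, 3):
                mask |= 1 << (2 * m + 1)
        full[mask] += vec[idx]

    def apply_E(v, i, j):
        out = np.zeros_like(v)
        nz = np.nonzero(v)[0]
        for mask in nz:
            for s in (0, 1):
                m1, s1 = _apply_annihilate(int(mask), 2 * j + s)
                if s1 == 0:
                    continue
                m2, s2 = _apply_create(m1, 2 * i + s)
                if s2 == 0:
                    continue
                out[m2] += s1 * s2 * v[mask]
        return out

    Ev = {}
    for a in range(M):
        for b_ in range(M):
            Ev[(a, b_)] = apply_E(full, a, b_)
    gamma = np.empty((M, M))
    for i in range(M):
        for j in range(M):
            gamma[i, j] = float(full @ Ev[(i, j)])
    Gamma = np.empty((M, M, M, M))
    for i in range(M):
        for j in range(M):
            for k in range(M):
                for l in range(M):
                    val = float(Ev[(k, i)] @ Ev[(j, l)])
                    if j == k:
                        val -= gamma[i, l]
                    Gamma[i, j, k, l] = val
    return GradientTensors(dE_dh=gamma, dE_dg=Gamma)


def energy_from_gradients(h: np.ndarray, g: np.ndarray, grads: GradientTensors) -> float:
    """Reconstruction identity: E = sum h*dE_dh + 1/2 sum g*dE_dg."""
    return float(np.sum(h * grads.dE_dh) + 0.5 * np.sum(g * grads.dE_dg))
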