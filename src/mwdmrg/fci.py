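"""Dense full-CI oracle in a fixed (N, Sz) sector.

Independent validation backend for the DMRG engine: builds the second-quantized
Hamiltonian explicitly over occupation-number (bitstring) determinants with
Jordan-Wigner sign bookkeeping, diagonalizes it densely, and evaluates the
spin-free one- and two-body reduced density matrices from the eigenvector.

Spin-orbital ordering: spatial orbital m with spin sigma maps to index
2*m + sigma (sigma = 0 for up, 1 for down); determinants are bitmasks over
these indices with the standard ascending-order creation convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Tuple

import numpy as np


def sector_determinants(M: int, N: int, sz2: int) -> List[int]:
    """All bitmask determinants with N electrons and 2*Sz = sz2."""
    n_up = (N + sz2) // 2
    n_dn = (N - sz2) // 2
    if n_up < 0 or n_dn < 0 or n_up + n_dn != N or n_up > M or n_dn > M:
        raise ValueError(f"infeasible sector N={N}, 2Sz={sz2} for M={M} orbitals")
    dets = []
    for ups in combinations(range(M), n_up):
        up_mask = sum(1 << (2 * m) for m in ups)
        for dns in combinations(range(M), n_dn):
            mask = up_mask + sum(1 << (2 * m + 1) for m in dns)
            dets.append(mask)
    return sorted(dets)


def _apply_annihilate(mask: int, so: int) -> Tuple[int, int]:
    """a_so |mask>; returns (new_mask, sign) with sign 0 if vanishing."""
    bit = 1 << so
    if not mask & bit:
        return 0, 0
    sign = -1 if bin(mask & (bit - 1)).count("1") % 2 else 1
    return mask ^ bit, sign


def _apply_create(mask: int, so: int) -> Tuple[int, int]:
    bit = 1 << so
    if mask & bit:
        return 0, 0
    sign = -1 if bin(mask & (bit - 1)).count("1") % 2 else 1
    return mask | bit, sign


def apply_excitation(vec: np.ndarray, dets: List[int], index: dict,
                     i: int, j: int) -> np.ndarray:
    """Spin-free excitation E_ij = sum_sigma a+_{i,sigma} a_{j,sigma}."""
    out = np.zeros_like(vec)
    for col, mask in enumerate(dets):
        amp = vec[col]
        if amp == 0.0:
            continue
        for s in (0, 1):
            m1, s1 = _apply_annihilate(mask, 2 * j + s)
            if s1 == 0:
                continue
            m2, s2 = _apply_create(m1, 2 * i + s)
            if s2 == 0:
                continue
            out[index[m2]] += s1 * s2 * amp
    return out


def build_hamiltonian(h: np.ndarray, g: np.ndarray, dets: List[int]) -> np.ndarray:
    """Dense sector Hamiltonian sum h a+a + 1/2 sum g a+a+aa."""
    M = h.shape[0]
    index = {d: c for c, d in enumerate(dets)}
    dim = len(dets)
    H = np.zeros((dim, dim))

    for col, mask in enumerate(dets):
        # one-body
        for j in range(M):
            for s in (0, 1):
                m1, s1 = _apply_annihilate(mask, 2 * j + s)
                if s1 == 0:
                    continue
                for i in range(M):
                    if h[i, j] == 0.0:
                        continue
                    m2, s2 = _apply_create(m1, 2 * i + s)
                    if s2 == 0:
                        continue
                    H[index[m2], col] += h[i, j] * s1 * s2
        # two-body: 1/2 g_ijkl a+_{i,s} a+_{j,t} a_{l,t} a_{k,s}
        for k in range(M):
            for s in (0, 1):
                mk, sk = _apply_annihilate(mask, 2 * k + s)
                if sk == 0:
                    continue
                for l in range(M):
                    for t in (0, 1):
                        ml, sl = _apply_annihilate(mk, 2 * l + t)
                        if sl == 0:
                            continue
                        for j in range(M):
                            mj, sj = _apply_create(ml, 2 * j + t)
                            if sj == 0:
                                continue
                            for i in range(M):
                                gv = g[i, j, k, l]
                                if gv == 0.0:
                                    continue
                                mi, si = _apply_create(mj, 2 * i + s)
                                if si == 0:
                                    continue
                                H[index[mi], col] += 0.5 * gv * sk * sl * sj * si
    return H


@dataclass
class FCIResult:
    energy: float
    vector: np.ndarray
    dets: List[int]
    gamma: np.ndarray   # 1-RDM <E_ij>
    Gamma: np.ndarray   # 2-RDM <e_ijkl> = <E_ik E_jl> - delta_jk <E_il>


def fci_oracle(h: np.ndarray, g: np.ndarray, N: int, sz2: int = 0) -> FCIResult:
    """Ground state and spin-free RDMs by explicit diagonalization.

    Parameters
    ----------
    h, g : arrays
        One-body (M x M) and two-body (M^4) integrals, real.
    N : int
        Electron count.
    sz2 : int
        Twice the spin projection (integer).
    """
    M = h.shape[0]
    if M > 8:
        raise ValueError("dense FCI oracle limited to M <= 8 orbitals")
    dets = sector_determinants(M, N, sz2)
    H = build_hamiltonian(h, g, dets)
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    vec = V[:, 0]
    E = float(w[0])

    index = {d: c for c, d in enumerate(dets)}
    Evec = {}
    for a in range(M):
        for b_ in range(M):
            Evec[(a, b_)] = apply_excitation(vec, dets, index, a, b_)
    gamma = np.empty((M, M))
    for i in range(M):
        for j in range(M):
            gamma[i, j] = float(vec @ Evec[(i, j)])
    Gamma = np.empty((M, M, M, M))
    for i in range(M):
        for j in range(M):
            for k in range(M):
                for l in range(M):
                    # <E_ik E_jl> = <E_ki psi | E_jl psi>
                    val = float(Evec[(k, i)] @ Evec[(j, l)])
                    if j == k:
                        val -= gamma[i, l]
                    Gamma[i, j, k, l] = val
    return FCIResult(E, vec, dets, gamma, Gamma)


def determinant_to_site_index(mask: int, M: int) -> int:
    """Map a bitmask determinant to the flat index of the 4^M site basis.

    Site-local basis order (|0>, |up>, |dn>, |updn>); site 0 is the slowest
    index.  The ascending-spin-orbital creation convention makes the
    amplitude sign +1 for every determinant.
    """
    idx = 0
    for m in range(M):
        up = (mask >> (2 * m)) & 1
        dn = (mask >> (2 * m + 1)) & 1
        idx = idx * 4 + up + 2 * dn
    return idx
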