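"""Orbital-basis integrals from multiwavelet orbitals and a molecular geometry.

Conventions (all quantities in Hartree atomic units, orbitals real):

* one-body:  h_ij = 1/2 sum_axis <d phi_i, d phi_j> + <phi_i, v phi_j>, with
  v the (attractive, smoothed) nuclear potential -sum_a Z_a / |r - R_a|;
* two-body:  g_ijkl = Int phi_i(r) phi_j(r') (1/|r-r'|) phi_l(r') phi_k(r),
  i.e. chemists' (ik|jl); it is evaluated through the pair potentials
  g^jl(r) = Int phi_j(r') phi_l(r') / |r-r'| dr', each a single Poisson
  convolution of an orbital product;
* overlap:   s_ij = <phi_i, phi_j>.

The g tensor is invariant under the 8-fold real-orbital symmetry group
(i<->k, j<->l, (ik)<->(jl)); only unique entries are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.special import erf

from .convolution import ConvolutionOperator, poisson_operator
from .mra.basis import ScalingBasis, get_basis
from .mra.tree import FunctionTree, add, differentiate, inner, multiply, project

ANGSTROM_TO_BOHR = 1.8897259886

_ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
]
ELEMENT_Z = {sym: z for z, sym in enumerate(_ELEMENTS) if z > 0}


# --------------------------------------------------------------------------- #

@dataclass
class Molecule:
    """Nuclear framework: symbols, charges Z_a and positions R_a (bohr)."""

    symbols: List[str]
    charges: List[int]
    positions: np.ndarray  # (n_atoms, 3), bohr
    net_charge: int = 0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if any(z < 1 or int(z) != z for z in self.charges):
            raise ValueError("nuclear charges must be positive integers")
        self.charges = [int(z) for z in self.charges]

    @property
    def n_electrons(self) -> int:
        return sum(self.charges) - self.net_charge

    @classmethod
    def from_atoms(cls, atoms: Sequence[Tuple[str, Sequence[float]]], net_charge=0):
        syms, Zs, pos = [], [], []
        for sym, xyz in atoms:
            if sym not in ELEMENT_Z:
                raise ValueError(f"unknown element symbol: {sym!r}")
            syms.append(sym)
            Zs.append(ELEMENT_Z[sym])
            pos.append(xyz)
        return cls(syms, Zs, np.array(pos, dtype=float), net_charge)

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for a in range(len(self.charges)):
            for b_ in range(a + 1, len(self.charges)):
                r = np.linalg.norm(self.positions[a] - self.positions[b_])
                e += self.charges[a] * self.charges[b_] / r
        return e


@dataclass
class OrbitalSet:
    """A finite set of real multiwavelet orbitals sharing basis metadata."""

    orbitals: List[FunctionTree]

    def __len__(self):
        return len(self.orbitals)

    def __getitem__(self, i):
        return self.orbitals[i]

    @property
    def basis(self) -> ScalingBasis:
        return self.orbitals[0].basis

    @property
    def p(self) -> float:
        return self.orbitals[0].p

    @property
    def L(self) -> float:
        return self.orbitals[0].L

    def overlap(self) -> np.ndarray:
        M = len(self)
        s = np.empty((M, M))
        for i in range(M):
            for j in range(i, M):
                s[i, j] = s[j, i] = inner(self.orbitals[i], self.orbitals[j])
        return s


@dataclass
class IntegralSet:
    """h (M x M), g (M^4) and s (M x M) in a given orbital set; Hartree."""

    h: np.ndarray
    g: np.ndarray
    s: np.ndarray
    core_energy: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_orbitals(self) -> int:
        return self.h.shape[0]


# --------------------------------------------------------------------------- #
# nuclear potential
# --------------------------------------------------------------------------- #

def _smoothed_u(rho: np.ndarray) -> np.ndarray:
    """Regularized 1/r profile: u(rho)/c -> 1/r outside the smoothing region."""
    rho = np.asarray(rho, dtype=float)
    small = rho < 1e-8
    safe = np.where(small, 1.0, rho)
    u = erf(safe) / safe + (1.0 / (3.0 * np.sqrt(np.pi))) * (
        np.exp(-(safe**2)) + 16.0 * np.exp(-4.0 * safe**2)
    )
    # rho -> 0 limit: 2/sqrt(pi) + 17/(3 sqrt(pi))
    u0 = 2.0 / np.sqrt(np.pi) + 17.0 / (3.0 * np.sqrt(np.pi))
    return np.where(small, u0, u)


def smoothing_lengths(mol: Molecule, p: float) -> np.ndarray:
    """Per-nucleus smoothing parameter c giving an energy error ~ p."""
    Z = np.array(mol.charges, dtype=float)
    return (p / (0.00435 * Z**5)) ** (1.0 / 3.0)


def nuclear_potential(
    mol: Molecule,
    basis: ScalingBasis | int,
    p: float,
    L: float,
    max_depth: int = 20,
) -> FunctionTree:
    """Smoothed attractive nuclear potential -sum_a Z_a u(r_a/c_a)/c_a.

    The smoothing parameter per nucleus is chosen from the precision and the
    nuclear charge so that the induced energy error per nucleus stays at the
    order of ``p``; the potential is negative everywhere and bounded, which
    caps the refinement depth a bare 1/r would not.
    """
    if isinstance(basis, int):
        basis = get_basis(basis)
    cs = smoothing_lengths(mol, p)
    pos = mol.positions
    if np.any(np.abs(pos) > L - np.max(cs)):
        raise ValueError("nucleus too close to (or outside) the domain boundary")

    Z = np.array(mol.charges, dtype=float)

    def v(X):
        out = np.zeros(len(X))
        for a in range(len(Z)):
            r = np.linalg.norm(X - pos[a], axis=1)
            out -= Z[a] / cs[a] * _smoothed_u(r / cs[a])
        return out

    return project(v, basis, p, L, initial_depth=2, max_depth=max_depth)


# --------------------------------------------------------------------------- #
# integrals
# --------------------------------------------------------------------------- #

def kinetic_matrix(orbs: OrbitalSet) -> np.ndarray:
    """T_ij = 1/2 sum_axis <d phi_i, d phi_j> (weak first derivatives)."""
    M = len(orbs)
    grads = [[differentiate(orbs[i], ax) for ax in range(3)] for i in range(M)]
    T = np.zeros((M, M))
    for i in range(M):
        for j in range(i, M):
            val = 0.5 * sum(inner(grads[i][ax], grads[j][ax]) for ax in range(3))
            T[i, j] = T[j, i] = val
    return T


def compute_one_body(orbs: OrbitalSet, v: FunctionTree) -> np.ndarray:
    """h_ij = T_ij + <phi_i, v phi_j>, explicitly symmetrized."""
    M = len(orbs)
    h = kinetic_matrix(orbs)
    vphi = [multiply(v, orbs[j]) for j in range(M)]
    V = np.empty((M, M))
    for i in range(M):
        for j in range(M):
            V[i, j] = inner(orbs[i], vphi[j])
    h += 0.5 * (V + V.T)
    return 0.5 * (h + h.T)


def compute_pair_potential(
    orbs: OrbitalSet, j: int, l: int, poisson: ConvolutionOperator | None = None
) -> FunctionTree:
    """Pair potential g^jl(r) = Int phi_j phi_l / |r - r'| (symmetric in j, l).

    The Poisson operator is the pure kernel 1/(4 pi r); the physical Coulomb
    potential therefore carries the 4 pi factor applied here.
    """
    if poisson is None:
        poisson = poisson_operator(orbs.basis, orbs.L, orbs.p)
    rho = multiply(orbs[j], orbs[l])
    out = poisson.apply(rho)
    for key in out.nodes:
        out.nodes[key] = out.nodes[key] * (4.0 * np.pi)
    return out


def compute_two_body(
    orbs: OrbitalSet, poisson: ConvolutionOperator | None = None
) -> np.ndarray:
    """Full g tensor via pair potentials; only unique entries are evaluated.

    g_ijkl = <phi_i phi_k, g^jl>; with rho_ik = phi_i phi_k computed once per
    (i, k) pair and reused, the cost is M(M+1)/2 Poisson applications plus
    O(M^4 / 8) grid inner products.
    """
    if poisson is None:
        poisson = poisson_operator(orbs.basis, orbs.L, orbs.p)
    M = len(orbs)
    pairs = [(i, k) for i in range(M) for k in range(i, M)]
    rho = {}
    for (i, k) in pairs:
        rho[(i, k)] = multiply(orbs[i], orbs[k])
    pot = {}
    for (j, l) in pairs:
        out = poisson.apply(rho[(j, l)])
        for key in out.nodes:
            out.nodes[key] = out.nodes[key] * (4.0 * np.pi)
        pot[(j, l)] = out

    g = np.zeros((M, M, M, M))
    for pi, (i, k) in enumerate(pairs):
        for (j, l) in pairs[pi:]:
            val = inner(rho[(i, k)], pot[(j, l)])
            for (a, b) in ((i, k), (k, i)):
                for (c, d) in ((j, l), (l, j)):
                    g[a, c, b, d] = val
                    g[c, a, d, b] = val
    return g


def build_integrals(
    orbs: OrbitalSet,
    mol: Molecule,
    v: FunctionTree | None = None,
    poisson: ConvolutionOperator | None = None,
) -> IntegralSet:
    """Assemble s, h, g and the nuclear-repulsion core energy."""
    if v is None:
        v = nuclear_potential(mol, orbs.basis, orbs.p, orbs.L)
    s = orbs.overlap()
    h = compute_one_body(orbs, v)
    g = compute_two_body(orbs, poisson)
    return IntegralSet(h=h, g=g, s=s, core_energy=mol.nuclear_repulsion())


def rotate_integrals(h: np.ndarray, g: np.ndarray, U: np.ndarray):
    """Transform (h, g) to the rotated orbitals phi'_i = sum_j U_ij phi_j."""
    h2 = U @ h @ U.T
    g2 = np.einsum("ai,bj,ck,dl,ijkl->abcd", U, U, U, U, g, optimize=True)
    return h2, g2


# --------------------------------------------------------------------------- #
# FCIDUMP
# --------------------------------------------------------------------------- #

def write_fcidump(path, ints: IntegralSet, n_electrons: int, ms2: int = 0):
    """Write integrals in FCIDUMP format (chemists' notation, 1-based).

    The file stores (pq|rs) entries, i.e. our g[p, r, q, s]; permutation
    symmetry is used so only canonical quadruples appear.
    """
    M = ints.n_orbitals
    with open(path, "w") as fh:
        fh.write(
            f"&FCI NORB={M},NELEC={n_electrons},MS2={ms2},\n"
            f"  ORBSYM={','.join(['1'] * M)},\n"
            "  ISYM=1,\n"
            "&END\n"
        )
        thresh = 0.0
        for p in range(M):
            for q in range(p + 1):
                pq = p * (p + 1) // 2 + q
                for r in range(p + 1):
                    for s_ in range(r + 1):
                        rs = r * (r + 1) // 2 + s_
                        if rs > pq:
                            continue
                        val = ints.g[p, r, q, s_]  # (pq|rs)
                        if abs(val) > thresh:
                            fh.write(
                                f"{val:23.16e} {p+1:4d} {q+1:4d} {r+1:4d} {s_+1:4d}\n"
                            )
        for p in range(M):
            for q in range(p + 1):
                fh.write(f"{ints.h[p, q]:23.16e} {p+1:4d} {q+1:4d}    0    0\n")
        fh.write(f"{ints.core_energy:23.16e}    0    0    0    0\n")


def read_fcidump(path) -> Tuple[IntegralSet, int, int]:
    """Read an FCIDUMP file; returns (IntegralSet, n_electrons, ms2)."""
    import re

    with open(path) as fh:
        text = fh.read()
    header, _, body = text.partition("&END")
    if not body:
        header, _, body = text.partition("/")
    m = re.search(r"NORB\s*=\s*(\d+)", header)
    M = int(m.group(1))
    nelec = int(re.search(r"NELEC\s*=\s*(\d+)", header).group(1))
    ms2_m = re.search(r"MS2\s*=\s*(-?\d+)", header)
    ms2 = int(ms2_m.group(1)) if ms2_m else 0

    h = np.zeros((M, M))
    g = np.zeros((M, M, M, M))
    core = 0.0
    for line in body.strip().splitlines():
        parts = line.split()
        if len(parts) != 5:
            continue
        val = float(parts[0])
        p, q, r, s_ = (int(x) for x in parts[1:])
        if p == 0:
            core = val
        elif r == 0:
            h[p - 1, q - 1] = h[q - 1, p - 1] = val
        else:
            p, q, r, s_ = p - 1, q - 1, r - 1, s_ - 1
            # (pq|rs) -> g[p, r, q, s] plus its 8 symmetry images
            for (a, b) in ((p, q), (q, p)):
                for (c, d) in ((r, s_), (s_, r)):
                    g[a, c, b, d] = val
                    g[c, a, d, b] = val
    s = np.eye(M)
    return IntegralSet(h=h, g=g, s=s, core_energy=core), nelec, ms2
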