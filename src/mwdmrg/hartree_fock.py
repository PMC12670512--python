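"""Closed-shell restricted Hartree-Fock by integral-equation iteration.

Independent determinant-limit oracle for the orbital optimizer: N/2 doubly
occupied orbitals are iterated through the canonical bound-state Helmholtz
fixed point

    phi_i = -2 G_{mu_i} [ v phi_i + (2J - K) phi_i + couplings ],
    mu_i = sqrt(-2 eps_i),

with J and K built from pair potentials (Poisson convolutions of orbital
products).  The total energy is

    E = 2 sum_i h_ii + sum_ij (2 (ii|jj) - (ij|ij)) + E_nuc.

This solver shares the multiwavelet stack but none of the DMRG/Lagrangian
machinery; agreement with the optimizer at M = N/2 validates the latter's
single-determinant limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .convolution import helmholtz_operator, poisson_operator
from .integrals import Molecule, OrbitalSet, compute_one_body, nuclear_potential
from .mra.basis import get_basis
from .mra.tree import FunctionTree, add, inner, multiply
from .orbital_opt import initial_guess, lowdin, _scaled_copy


@dataclass
class HartreeFockResult:
    energy: float
    orbital_energies: np.ndarray
    orbitals: OrbitalSet
    energies: List[float] = field(default_factory=list)
    converged: bool = False


def hartree_fock(
    mol: Molecule,
    k: int = 9,
    p: float = 1e-5,
    L: float = 32.0,
    delta: float = 1e-6,
    max_iter: int = 50,
) -> HartreeFockResult:
    """Restricted closed-shell SCF at MW precision ``p``; N must be even."""
    N = mol.n_electrons
    if N % 2:
        raise ValueError("restricted Hartree-Fock requires an even electron count")
    n_occ = N // 2
    basis = get_basis(k)
    v = nuclear_potential(mol, basis, p, L)
    poisson = poisson_operator(basis, L, p)
    e_nuc = mol.nuclear_repulsion()

    orbs = lowdin(initial_guess(mol, n_occ, basis, p, L))

    energies: List[float] = []
    eps = np.zeros(n_occ)
    e_prev = np.inf
    converged = False
    for it in range(max_iter):
        # pair potentials (ij) -> 4*pi * Poisson[phi_i phi_j]
        pots = {}
        rho = {}
        for i in range(n_occ):
            for j in range(i, n_occ):
                rho[(i, j)] = multiply(orbs[i], orbs[j])
                t = poisson.apply(rho[(i, j)])
                for key in t.nodes:
                    t.nodes[key] = t.nodes[key] * (4.0 * np.pi)
                pots[(i, j)] = t

        h = compute_one_body(orbs, v)
        gmat = np.zeros((n_occ, n_occ, n_occ, n_occ))
        pairs = [(i, j) for i in range(n_occ) for j in range(i, n_occ)]
        for pi, (i, j) in enumerate(pairs):
            for (a, b) in pairs[pi:]:
                val = inner(rho[(i, j)], pots[(a, b)])
                for (x, y) in ((i, j), (j, i)):
                    for (c, d) in ((a, b), (b, a)):
                        gmat[x, c, y, d] = val
                        gmat[c, x, d, y] = val
        # E = 2 sum h_ii + sum_ij (2 (ii|jj) - (ij|ij))
        energy = 2.0 * np.trace(h) + e_nuc
        for i in range(n_occ):
            for j in range(n_occ):
                energy += 2.0 * gmat[i, j, i, j] - gmat[i, j, j, i]
        energies.append(float(energy))
        if it > 0 and abs(energy - e_prev) < delta:
            converged = True
            break
        e_prev = energy

        # Fock matrix in the occupied space: F = h + 2J - K
        F = h.copy()
        for i in range(n_occ):
            for j in range(n_occ):
                for a in range(n_occ):
                    F[i, j] += 2.0 * gmat[i, j, a, a] - gmat[i, a, a, j]
        eps, C = np.linalg.eigh(0.5 * (F + F.T))
        orbs = OrbitalSet(
            [_combine(orbs, C[:, i]) for i in range(n_occ)]
        )  # canonical orbitals
        # rebuild pair potentials in the canonical basis for the update
        pots = {}
        for i in range(n_occ):
            for j in range(i, n_occ):
                r = multiply(orbs[i], orbs[j])
                t = poisson.apply(r)
                for key in t.nodes:
                    t.nodes[key] = t.nodes[key] * (4.0 * np.pi)
                pots[(i, j)] = t

        new_orbs = []
        for i in range(n_occ):
            if eps[i] >= -1e-3:
                warnings.warn(
                    f"non-negative orbital energy {eps[i]:.3f}; flooring", RuntimeWarning
                )
                eps[i] = -0.05
            src = multiply(v, orbs[i])
            for j in range(n_occ):
                pj = pots[(min(i, j), max(i, j))]
                pjj = pots[(j, j)]
                src = add(src, 1.0, multiply(pjj, orbs[i]), 2.0)   # Coulomb
                src = add(src, 1.0, multiply(pj, orbs[j]), -1.0)   # exchange
            G = helmholtz_operator(np.sqrt(-2.0 * eps[i]), basis, L, p)
            t = G.apply(src)
            for key in t.nodes:
                t.nodes[key] = t.nodes[key] * (-2.0)
            new_orbs.append(t)
        orbs = lowdin(OrbitalSet(new_orbs))
    if not converged:
        warnings.warn(
            f"Hartree-Fock not converged to {delta:g} Ha in {max_iter} iterations",
            RuntimeWarning,
        )
    return HartreeFockResult(
        energy=energies[-1],
        orbital_energies=eps,
        orbitals=orbs,
        energies=energies,
        converged=converged,
    )


def _combine(orbs: OrbitalSet, coefs: np.ndarray) -> FunctionTree:
    acc = None
    for j, c in enumerate(coefs):
        if abs(c) < 1e-14:
            continue
        acc = _scaled_copy(orbs[j], c) if acc is None else add(acc, 1.0, orbs[j], c)
    return acc
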