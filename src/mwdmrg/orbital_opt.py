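"""Self-consistent orbital optimization with DMRG energies and gradients.

Each iteration of the optimization loop:

1. builds the integrals (s, h, g) in the current orbitals;
2. solves for the correlated ground state by DMRG and extracts the energy
   gradients dE/dh = gamma and dE/dg = Gamma (spin-free RDMs);
3. symmetrizes the gradients and forms the Lagrange multiplier matrix that
   enforces orbital orthonormality;
4. rotates to the basis diagonalizing the symmetrized one-body gradient
   (natural orbitals, eigenvalues Lambda = occupation numbers), which
   decouples the stationarity conditions;
5. updates every orbital by applying the bound-state Helmholtz Green's
   function with exponent mu_m = sqrt(-2 eps'_mm / Lambda_m) to its source
   term (nuclear potential + two-body mean field + off-diagonal multiplier
   couplings);
6. Loewdin-orthonormalizes the updated set and re-thresholds.

The loop stops when the total energy changes by less than delta between
iterations.

Factor convention.  The energy is E = sum h*gamma + (1/2) sum g*Gamma, so the
true partial derivative of E with respect to an individual g_ijkl coefficient
is Gamma_ijkl / 2 (the Hamiltonian carries the global 1/2).  All stationarity
equations below use this derivative; concretely the multiplier matrix is

    eps_bar_mn = sum_j dE1_mj h_nj + sum_jkl Gammabar_mjkl g_njkl

and the two-body source term is (1/Lambda_m) sum U_mi Gammabar_ijkl g^jl
phi_k.  In the single-determinant limit (M = N/2) these reduce exactly to the
canonical restricted Hartree-Fock equations, which is the correctness anchor
for the convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Tuple

import numpy as np

from .convolution import helmholtz_operator, poisson_operator
from .dmrg import (
    DmrgConfig,
    GradientTensors,
    GroundState,
    build_mpo,
    dmrg_ground_state,
    extract_gradients,
)
from .integrals import (
    IntegralSet,
    Molecule,
    OrbitalSet,
    compute_one_body,
    nuclear_potential,
)
from .mra.basis import ScalingBasis, get_basis
from .mra.tree import FunctionTree, add, inner, multiply, project, zero_tree


# --------------------------------------------------------------------------- #
# dataclasses
# --------------------------------------------------------------------------- #

@dataclass
class SymmetrizedGradients:
    dE1: np.ndarray  # symmetric M x M
    dE2: np.ndarray  # M^4 with the two-body transposition symmetry


@dataclass
class MultiplierSet:
    eps_bar: np.ndarray    # symmetrized multipliers, M x M
    eps_prime: np.ndarray  # rotated multipliers U eps_bar U^T
    U: np.ndarray          # orthogonal rotation, rows are new orbitals
    Lambda: np.ndarray     # eigenvalues of dE1, descending


@dataclass
class IterationRecord:
    energy: float
    delta_e: float
    kernel_coeffs: np.ndarray
    dmrg_sweeps: int
    fallback_used: bool


@dataclass
class OptimizationState:
    orbitals: OrbitalSet
    integrals: IntegralSet | None
    energies: List[float] = field(default_factory=list)
    history: List[IterationRecord] = field(default_factory=list)
    converged: bool = False
    delta: float = 1e-5
    ground_state: GroundState | None = None

    @property
    def energy(self) -> float:
        return self.energies[-1] if self.energies else np.nan

    @property
    def iterations(self) -> int:
        return len(self.energies)


class PositiveCoefficientError(RuntimeError):
    """A Helmholtz kernel coefficient eps'_mm/Lambda_m failed to be negative
    and the level-shift fallback was disabled."""


@dataclass
class OptConfig:
    """Knobs of the self-consistent loop (energies in Hartree)."""

    delta: float = 1e-5          # energy convergence threshold
    max_iter: int = 40
    p: float = 1e-5              # MW precision
    k: int = 9                   # polynomial order
    L: float = 32.0              # domain half-width (bohr)
    dmrg: DmrgConfig = field(default_factory=DmrgConfig)
    gradient_method: str = "hole"
    coeff_threshold: float = -0.01   # fallback trigger for eps'_mm/Lambda_m
    coeff_floor: float = -0.05       # level-shift floor (Ha)
    allow_fallback: bool = True      # level-shift on non-negative coefficients
    lambda_cut: float = 1e-10        # degenerate-occupation guard


# --------------------------------------------------------------------------- #
# algebra steps
# --------------------------------------------------------------------------- #

def symmetrize(raw: GradientTensors) -> SymmetrizedGradients:
    """Symmetrized gradients: dE1 = (A + A^T)/2 and the four-term two-body
    average over the transpositions (1,0,3,2), (2,1,0,3), (1,2,3,0)."""
    A = raw.dE_dh
    B = raw.dE_dg
    dE1 = 0.5 * (A + A.T)
    dE2 = 0.25 * (
        B
        + B.transpose(1, 0, 3, 2)
        + B.transpose(2, 1, 0, 3)
        + B.transpose(1, 2, 3, 0)
    )
    return SymmetrizedGradients(dE1=dE1, dE2=dE2)


def multipliers(sg: SymmetrizedGradients, ints: IntegralSet) -> np.ndarray:
    """Orthonormality multipliers from the stationarity projection.

    eps_bar_mn = sum_j dE1_mj h_nj + 2 sum_jkl dE2_mjkl g_njkl, explicitly
    symmetrized.  ``sg`` must hold the true energy derivatives (dE2 is the
    symmetrized Gamma/2); in the single-orbital closed-shell case this gives
    eps_bar = 2(h + J) = twice the restricted Hartree-Fock orbital energy.
    """
    e = sg.dE1 @ ints.h.T + 2.0 * np.einsum(
        "mjkl,njkl->mn", sg.dE2, ints.g, optimize=True
    )
    return 0.5 * (e + e.T)


def diagonalize_and_rotate(
    sg: SymmetrizedGradients,
    ints: IntegralSet,
    orbs: OrbitalSet,
    lambda_cut: float = 1e-10,
) -> Tuple[MultiplierSet, OrbitalSet, np.ndarray]:
    """Natural-orbital rotation: diagonalize dE1, rotate orbitals and h.

    Returns the multiplier set (with Lambda sorted descending and a
    deterministic row-sign convention), the rotated orbitals and the rotated
    one-body matrix.  The two-body gradient is deliberately not rotated; the
    update contracts it against rows of U.
    """
    eps_bar = multipliers(sg, ints)
    lam, V = np.linalg.eigh(sg.dE1)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    U = V[:, order].T  # rows: new orbitals in terms of old
    for row in U:
        idx = int(np.argmax(np.abs(row)))
        if row[idx] < 0:
            row *= -1.0
    if np.any(np.abs(lam) < lambda_cut):
        raise ValueError(
            f"near-zero occupation eigenvalue(s) {lam}: the gradient-diagonal "
            "update is singular; reduce the orbital count or perturb the guess"
        )
    eps_prime = U @ eps_bar @ U.T
    h_rot = U @ ints.h @ U.T
    rotated = rotate_orbitals(orbs, U)
    ms = MultiplierSet(eps_bar=eps_bar, eps_prime=eps_prime, U=U, Lambda=lam)
    return ms, rotated, h_rot


def rotate_orbitals(orbs: OrbitalSet, U: np.ndarray) -> OrbitalSet:
    """phi'_i = sum_j U_ij phi_j as fresh trees."""
    M = len(orbs)
    out = []
    for i in range(M):
        acc = None
        for j in range(M):
            if abs(U[i, j]) < 1e-14:
                continue
            acc = (
                _scaled_copy(orbs[j], U[i, j])
                if acc is None
                else add(acc, 1.0, orbs[j], U[i, j])
            )
        if acc is None:
            acc = zero_tree(orbs.basis, orbs.p, orbs.L)
        out.append(acc)
    return OrbitalSet(out)


def _scaled_copy(tree: FunctionTree, w: float) -> FunctionTree:
    out = tree.copy()
    for key in out.nodes:
        out.nodes[key] = out.nodes[key] * w
    return out


def lowdin(orbs: OrbitalSet) -> OrbitalSet:
    """Symmetric (Loewdin) orthonormalization phi <- sum (s^{-1/2})_ij phi_j."""
    s = orbs.overlap()
    w, V = np.linalg.eigh(s)
    if w[0] <= 0 or w[-1] / w[0] > 1e10:
        raise ValueError(
            f"overlap matrix ill-conditioned (eigenvalues {w}): orbitals are "
            "linearly dependent"
        )
    s_inv_half = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    out = rotate_orbitals(orbs, s_inv_half)
    for t in out.orbitals:
        t.crop()
    return out


# --------------------------------------------------------------------------- #
# orbital update
# --------------------------------------------------------------------------- #

def update_orbital(
    m: int,
    rotated: OrbitalSet,
    unrotated: OrbitalSet,
    ms: MultiplierSet,
    sg: SymmetrizedGradients,
    v: FunctionTree,
    pair_pots: Dict[Tuple[int, int], FunctionTree],
    cfg: OptConfig,
) -> Tuple[FunctionTree, float, bool]:
    """One bound-state Helmholtz update of rotated orbital ``m``.

    Returns (new orbital, kernel coefficient eps'_mm/Lambda_m, fallback?).
    The source is v phi'_m + (1/Lambda_m)[2 sum_jkl (sum_i U_mi dE2_ijkl)
    g^jl phi_k - sum_{j != m} eps'_mj phi'_j], with dE2 the true symmetrized
    two-body derivative; the Green's function carries exponent
    mu = sqrt(-2 eps'_mm/Lambda_m) and the overall -2 prefactor is applied
    here.  When the coefficient is insufficiently negative the documented
    level-shift fallback floors it and moves the residual into the source.
    """
    M = len(rotated)
    lam = ms.Lambda[m]
    coeff = ms.eps_prime[m, m] / lam
    fallback = coeff > cfg.coeff_threshold
    if fallback and not cfg.allow_fallback:
        report = "; ".join(
            f"orbital {j}: eps'/Lambda = {ms.eps_prime[j, j] / ms.Lambda[j]:+.6f}"
            for j in range(M)
        )
        raise PositiveCoefficientError(
            f"kernel coefficient of orbital {m} is {coeff:+.6f} "
            f"(threshold {cfg.coeff_threshold}); per-orbital report: {report}"
        )
    shift = cfg.coeff_floor if fallback else coeff

    # C[j, l, k] = sum_i U_mi dE2_ijkl
    C = np.einsum("i,ijkl->jkl", ms.U[m], sg.dE2, optimize=True)

    source = multiply(v, rotated[m])
    for k in range(M):
        pot = None
        for j in range(M):
            for l in range(M):
                wjl = C[j, l, k]
                if abs(wjl) < 1e-12:
                    continue
                gp = pair_pots[(min(j, l), max(j, l))]
                pot = (
                    _scaled_copy(gp, wjl) if pot is None else add(pot, 1.0, gp, wjl)
                )
        if pot is not None:
            source = add(source, 1.0, multiply(pot, unrotated[k]), 2.0 / lam)
    for j in range(M):
        if j == m or abs(ms.eps_prime[m, j]) < 1e-12:
            continue
        source = add(source, 1.0, rotated[j], -ms.eps_prime[m, j] / lam)
    if fallback:
        source = add(source, 1.0, rotated[m], coeff - shift)

    mu = np.sqrt(-2.0 * shift)
    G = helmholtz_operator(mu, rotated.basis, rotated.L, rotated.p)
    new = G.apply(source)
    for key in new.nodes:
        new.nodes[key] = new.nodes[key] * (-2.0)
    return new, float(coeff), bool(fallback)


# --------------------------------------------------------------------------- #
# initial guess
# --------------------------------------------------------------------------- #

def initial_guess(
    mol: Molecule, M: int, basis: ScalingBasis, p: float, L: float
) -> OrbitalSet:
    """Deterministic analytic starting orbitals.

    One normalized s-type Gaussian per nucleus (exponent scaled with Z^2),
    then polynomial-times-Gaussian functions cycling over nuclei and the
    factors (x, y, z, x^2, ...) until M functions exist; the set is
    Loewdin-orthonormalized by the caller.
    """
    n_at = len(mol.charges)
    funcs: List[Callable] = []
    polys = [
        lambda d: np.ones(len(d)),
        lambda d: d[:, 0],
        lambda d: d[:, 1],
        lambda d: d[:, 2],
        lambda d: d[:, 0] ** 2,
        lambda d: d[:, 1] ** 2,
        lambda d: d[:, 2] ** 2,
        lambda d: d[:, 0] * d[:, 1],
        lambda d: d[:, 1] * d[:, 2],
        lambda d: d[:, 0] * d[:, 2],
    ]
    idx = 0
    while len(funcs) < M:
        a = idx % n_at
        ply = polys[(idx // n_at) % len(polys)]
        alpha = 0.2709 * mol.charges[a] ** 2
        if idx // n_at >= 1:
            alpha = 0.5 * alpha  # diffuse the polynomial shells
        center = mol.positions[a]

        def f(X, alpha=alpha, center=center, ply=ply):
            d = X - center
            return ply(d) * np.exp(-alpha * np.sum(d**2, axis=1))

        funcs.append(f)
        idx += 1
    trees = []
    for f in funcs:
        t = project(f, basis, p, L)
        nrm = t.norm()
        for key in t.nodes:
            t.nodes[key] = t.nodes[key] / nrm
        trees.append(t)
    return OrbitalSet(trees)


# --------------------------------------------------------------------------- #
# main loop
# --------------------------------------------------------------------------- #

def optimize(
    mol: Molecule,
    M: int,
    cfg: OptConfig | None = None,
    orbitals: OrbitalSet | None = None,
    callback: Callable | None = None,
) -> OptimizationState:
    """Run the full MRA + DMRG self-consistent orbital optimization.

    Parameters
    ----------
    mol : Molecule
    M : int
        Number of orbitals (>= ceil(N/2)).
    cfg : OptConfig
    orbitals : OrbitalSet, optional
        Restart orbitals; the analytic guess is used when absent.
    callback : callable, optional
        Invoked as ``callback(state)`` after every iteration.
    """
    cfg = cfg or OptConfig()
    N = mol.n_electrons
    if M < (N + 1) // 2:
        raise ValueError(f"M={M} cannot hold {N} electrons (need M >= ceil(N/2))")
    sz2 = N % 2
    basis = get_basis(cfg.k)

    v = nuclear_potential(mol, basis, cfg.p, cfg.L)
    poisson = poisson_operator(basis, cfg.L, cfg.p)
    e_nuc = mol.nuclear_repulsion()

    if orbitals is None:
        orbitals = initial_guess(mol, M, basis, cfg.p, cfg.L)
    orbs = lowdin(orbitals)

    state = OptimizationState(orbitals=orbs, integrals=None, delta=cfg.delta)
    e_prev = np.inf
    for it in range(cfg.max_iter):
        # ---- integrals ----
        pair_pots: Dict[Tuple[int, int], FunctionTree] = {}
        rho: Dict[Tuple[int, int], FunctionTree] = {}
        for i in range(M):
            for k in range(i, M):
                rho[(i, k)] = multiply(orbs[i], orbs[k])
                pot = poisson.apply(rho[(i, k)])
                for key in pot.nodes:
                    pot.nodes[key] = pot.nodes[key] * (4.0 * np.pi)
                pair_pots[(i, k)] = pot
        g = np.zeros((M, M, M, M))
        pairs = [(i, k) for i in range(M) for k in range(i, M)]
        for pi, (i, k) in enumerate(pairs):
            for (j, l) in pairs[pi:]:
                val = inner(rho[(i, k)], pair_pots[(j, l)])
                for (a, b) in ((i, k), (k, i)):
                    for (c, d) in ((j, l), (l, j)):
                        g[a, c, b, d] = val
                        g[c, a, d, b] = val
        h = compute_one_body(orbs, v)
        s = orbs.overlap()
        ints = IntegralSet(h=h, g=g, s=s, core_energy=e_nuc)

        # ---- DMRG + gradients ----
        mpo = build_mpo(h, g)
        gs = dmrg_ground_state(mpo, N, sz2, cfg.dmrg)
        raw = extract_gradients(gs, method=cfg.gradient_method)
        energy = gs.energy + e_nuc

        # ---- stationarity algebra ----
        sg = symmetrize(GradientTensors(raw.dE_dh, 0.5 * raw.dE_dg))
        ms, rotated, _h_rot = diagonalize_and_rotate(
            sg, ints, orbs, lambda_cut=cfg.lambda_cut
        )

        # ---- orbital updates ----
        new_orbs = []
        coeffs = np.empty(M)
        fallback_any = False
        for m in range(M):
            # note: dE2 passed to the update is the symmetrized 1/2*Gamma
            phi_new, coeff, fb = update_orbital(
                m, rotated, orbs, ms, sg, v, pair_pots, cfg
            )
            new_orbs.append(phi_new)
            coeffs[m] = coeff
            fallback_any = fallback_any or fb

        orbs = lowdin(OrbitalSet(new_orbs))

        delta_e = energy - (e_prev if np.isfinite(e_prev) else energy)
        state.orbitals = orbs
        state.integrals = ints
        state.ground_state = gs
        state.energies.append(float(energy))
        state.history.append(
            IterationRecord(
                energy=float(energy),
                delta_e=float(delta_e),
                kernel_coeffs=coeffs.copy(),
                dmrg_sweeps=gs.n_sweeps,
                fallback_used=fallback_any,
            )
        )
        if callback is not None:
            callback(state)
        if it > 0 and abs(energy - e_prev) < cfg.delta:
            state.converged = True
            break
        e_prev = energy
    if not state.converged:
        warnings.warn(
            f"orbital optimization not converged to {cfg.delta:g} Ha in "
            f"{cfg.max_iter} iterations",
            RuntimeWarning,
        )
    return state
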