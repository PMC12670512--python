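"""Shared fixtures: reduced-precision bases and the heavy session-scoped runs."""

import numpy as np
import pytest

from mwdmrg.dmrg import (
    DmrgConfig,
    build_mpo,
    dmrg_ground_state,
    extract_gradients,
)
from mwdmrg.fci import fci_oracle
from mwdmrg.integrals import Molecule
from mwdmrg.mra import get_basis


def random_hg(rng, M, scale=1.0):
    """Random symmetric h and g with the full real-orbital 8-fold symmetry
    (i<->k, j<->l, and (ik)<->(jl) pair exchange in chemists' (ik|jl))."""
    h = rng.standard_normal((M, M)) * scale
    h = 0.5 * (h + h.T)
    g = rng.standard_normal((M,) * 4) * scale
    g = 0.5 * (g + g.transpose(2, 1, 0, 3))
    g = 0.5 * (g + g.transpose(0, 3, 2, 1))
    g = 0.5 * (g + g.transpose(1, 0, 3, 2))
    return h, g


@pytest.fixture(scope="session")
def basis5():
    return get_basis(5)


@pytest.fixture(scope="session")
def basis7():
    return get_basis(7)


@pytest.fixture(scope="session")
def dmrg_instances():
    """Random second-quantized problems with DMRG and FCI solutions.

    Twenty instances spanning M = 4..6 orbitals and N = 2..6 electrons,
    solved at saturating bond dimension; used by the DMRG/gradient
    correctness checks.
    """
    rng = np.random.default_rng(2024)
    sizes = [4] * 12 + [5] * 5 + [6] * 3
    out = []
    for i, M in enumerate(sizes):
        N = int(rng.integers(2, 7))
        sz2 = N % 2
        h, g = random_hg(rng, M)
        mpo = build_mpo(h, g)
        gs = dmrg_ground_state(mpo, N, sz2, DmrgConfig(seed=i))
        grads = extract_gradients(gs, method="hole")
        ref = fci_oracle(h, g, N, sz2)
        out.append(
            dict(M=M, N=N, sz2=sz2, h=h, g=g, gs=gs, grads=grads, fci=ref)
        )
    return out


@pytest.fixture(scope="session")
def hydrogen():
    return Molecule.from_atoms([("H", (0.0, 0.0, 0.0))])


@pytest.fixture(scope="session")
def helium():
    return Molecule.from_atoms([("He", (0.0, 0.0, 0.0))])


@pytest.fixture(scope="session")
def h2():
    # 1.4 bohr internuclear distance, along z
    return Molecule(
        symbols=["H", "H"],
        charges=[1, 1],
        positions=np.array([[0.0, 0.0, -0.7], [0.0, 0.0, 0.7]]),
    )


@pytest.fixture(scope="session")
def h_atom_full(hydrogen):
    """Hydrogen-atom optimization at k = 7, p = 1e-5, delta = 1e-5, L = 32."""
    from mwdmrg.orbital_opt import OptConfig, optimize

    cfg = OptConfig(k=7, p=1e-5, delta=1e-5, L=32.0, max_iter=30)
    return optimize(hydrogen, M=1, cfg=cfg)


@pytest.fixture(scope="session")
def determinant_limit_runs(helium, h2):
    """He and H2 at M = N/2: optimizer state and Hartree-Fock oracle result."""
    from mwdmrg.hartree_fock import hartree_fock
    from mwdmrg.orbital_opt import OptConfig, optimize

    out = {}
    for name, mol in (("He", helium), ("H2", h2)):
        cfg = OptConfig(k=5, p=1e-4, delta=1e-5, L=32.0, max_iter=30)
        state = optimize(mol, M=1, cfg=cfg)
        hf = hartree_fock(mol, k=5, p=1e-4, L=32.0, delta=1e-5, max_iter=30)
        out[name] = (state, hf)
    return out


@pytest.fixture(scope="session")
def m1_coarse_runs(helium, h2):
    """He and H2 with M = 1 at the same reduced precision as the M = 2 runs,
    for precision-consistent energy comparisons."""
    from mwdmrg.orbital_opt import OptConfig, optimize

    out = {}
    for name, mol in (("He", helium), ("H2", h2)):
        cfg = OptConfig(k=5, p=1e-3, delta=1e-4, L=32.0, max_iter=25)
        out[name] = optimize(mol, M=1, cfg=cfg)
    return out


@pytest.fixture(scope="session")
def m2_fixtures(helium, h2):
    """He and H2 with M = 2 orbitals at reduced precision (regression runs)."""
    from mwdmrg.orbital_opt import OptConfig, optimize

    out = {}
    for name, mol in (("He", helium), ("H2", h2)):
        cfg = OptConfig(k=5, p=1e-3, delta=1e-4, L=32.0, max_iter=25)
        out[name] = optimize(mol, M=2, cfg=cfg)
    return out
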