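"""Run orchestration: configuration, geometry input, artifacts, exit codes.

A run reads an XYZ geometry (Angstrom; converted to bohr internally), builds
the run configuration, executes the requested mode and writes its artifacts
into the output directory:

* ``trace.csv``      -- per-iteration energy trace (iter, E, dE, min kernel
  coefficient, DMRG sweeps);
* ``summary.json``   -- final energy, iteration count, kernel coefficients,
  convergence flag, configuration echo;
* ``orbitals.npz``   -- multiwavelet orbital checkpoint (restartable);
* ``final.fcidump``  -- integrals of the final orbitals.

Exit codes: 0 converged; 2 DMRG failure; 3 positive-kernel-coefficient abort;
4 not converged within the iteration budget.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import List, Optional

import numpy as np

from .dmrg import (
    DmrgConfig,
    build_mpo,
    dmrg_ground_state,
    energy_from_gradients,
    extract_gradients,
)
from .integrals import (
    ANGSTROM_TO_BOHR,
    ELEMENT_Z,
    Molecule,
    build_integrals,
    read_fcidump,
    write_fcidump,
)
from .mra.basis import get_basis
from .mra.tree import load_collection, save_collection
from .orbital_opt import (
    OptConfig,
    PositiveCoefficientError,
    initial_guess,
    lowdin,
    optimize,
)

EXIT_OK = 0
EXIT_DMRG_FAILURE = 2
EXIT_POSITIVE_COEFF = 3
EXIT_NOT_CONVERGED = 4


# --------------------------------------------------------------------------- #
# geometry input
# --------------------------------------------------------------------------- #

def read_xyz(path) -> Molecule:
    """Standard XYZ file: count line, comment, ``El x y z`` per atom (Angstrom).

    Coordinates are converted to bohr.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: malformed atom-count line: {lines[0]!r}")
    atoms = []
    for ln, line in enumerate(lines[2: 2 + n_atoms], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: malformed atom line: {line!r}")
        sym = parts[0].capitalize()
        if sym not in ELEMENT_Z:
            raise ValueError(f"{path}:{ln}: unknown element symbol {parts[0]!r}")
        xyz = [float(x) * ANGSTROM_TO_BOHR for x in parts[1:4]]
        atoms.append((sym, xyz))
    if len(atoms) != n_atoms:
        raise ValueError(
            f"{path}: header announces {n_atoms} atoms, found {len(atoms)}"
        )
    return Molecule.from_atoms(atoms)


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

@dataclass
class RunConfig:
    geometry: str = ""
    mode: str = "optimize"       # optimize | dmrg-only | integrals-only
    n_orbitals: int = 1
    n_electrons: Optional[int] = None   # derived from geometry when absent
    net_charge: int = 0
    precision: float = 1e-5
    order: int = 9
    delta: float = 1e-5
    box: float = 32.0
    max_iter: int = 40
    dmrg_schedule: List[List[int]] = field(
        default_factory=lambda: [[16, 2], [32, 2], [64, 2]]
    )
    dmrg_tol: float = 1e-9
    seed: int = 0
    out_dir: str = "mwdmrg_out"
    fcidump: str = ""            # input FCIDUMP for dmrg-only mode

    def validate(self):
        if self.mode not in ("optimize", "dmrg-only", "integrals-only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("precision", "delta", "box", "dmrg_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.order < 1 or self.max_iter < 1 or self.n_orbitals < 1:
            raise ValueError("order, max_iter and n_orbitals must be >= 1")
        if self.mode == "dmrg-only":
            if not self.fcidump:
                raise ValueError("dmrg-only mode requires an fcidump path")
        elif not self.geometry:
            raise ValueError(f"mode {self.mode!r} requires a geometry path")
        return self

    def opt_config(self) -> OptConfig:
        return OptConfig(
            delta=self.delta,
            max_iter=self.max_iter,
            p=self.precision,
            k=self.order,
            L=self.box,
            dmrg=DmrgConfig(
                schedule=[tuple(x) for x in self.dmrg_schedule],
                tol=self.dmrg_tol,
                seed=self.seed,
            ),
        )


def parse_config_file(path) -> RunConfig:
    """Flat ``key: value`` (or ``key = value``) run configuration."""
    cfg = RunConfig()
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in (":", "="):
                if sep in line:
                    key, _, val = line.partition(sep)
                    break
            else:
                raise ValueError(f"{path}:{ln}: expected 'key: value', got {raw!r}")
            key = key.strip().replace("-", "_")
            val = val.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"{path}:{ln}: unknown configuration key {key!r}")
            current = getattr(cfg, key)
            if key == "dmrg_schedule":
                setattr(cfg, key, [[int(x) for x in pair.split("x")]
                                   for pair in val.split(",")])
            elif isinstance(current, bool):
                setattr(cfg, key, val.lower() in ("1", "true", "yes"))
            elif isinstance(current, int) or (current is None and key == "n_electrons"):
                setattr(cfg, key, int(val))
            elif isinstance(current, float):
                setattr(cfg, key, float(val))
            else:
                setattr(cfg, key, val)
    return cfg.validate()


# --------------------------------------------------------------------------- #
# run modes
# --------------------------------------------------------------------------- #

def run(config: RunConfig) -> int:
    """Execute a configured run; returns the process exit code."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    if config.mode == "dmrg-only":
        return _run_dmrg_only(config)
    mol = read_xyz(config.geometry)
    if config.net_charge:
        mol.net_charge = config.net_charge
    if config.mode == "integrals-only":
        return _run_integrals_only(config, mol)
    return _run_optimize(config, mol)


def _run_optimize(config: RunConfig, mol: Molecule) -> int:
    cfg = config.opt_config()
    trace_path = os.path.join(config.out_dir, "trace.csv")
    with open(trace_path, "w") as fh:
        fh.write("iter,energy,delta_e,min_kernel_coeff,dmrg_sweeps\n")

    def callback(state):
        rec = state.history[-1]
        with open(trace_path, "a") as fh:
            fh.write(
                f"{state.iterations},{rec.energy:.12f},{rec.delta_e:.3e},"
                f"{rec.kernel_coeffs.min():.8f},{rec.dmrg_sweeps}\n"
            )
        save_collection(
            os.path.join(config.out_dir, "orbitals.npz"),
            state.orbitals.orbitals,
        )

    try:
        state = optimize(mol, config.n_orbitals, cfg, callback=callback)
    except PositiveCoefficientError as exc:
        _write_summary(config, {"status": "positive-coefficient-abort",
                                "detail": str(exc)})
        return EXIT_POSITIVE_COEFF

    write_fcidump(
        os.path.join(config.out_dir, "final.fcidump"),
        state.integrals,
        mol.n_electrons,
        ms2=mol.n_electrons % 2,
    )
    summary = {
        "status": "converged" if state.converged else "not-converged",
        "energy": state.energy,
        "iterations": state.iterations,
        "kernel_coefficients": state.history[-1].kernel_coeffs.tolist(),
        "energies": state.energies,
        "n_orbitals": config.n_orbitals,
        "n_electrons": mol.n_electrons,
        "nuclear_repulsion": mol.nuclear_repulsion(),
    }
    _write_summary(config, summary)
    return EXIT_OK if state.converged else EXIT_NOT_CONVERGED


def _run_integrals_only(config: RunConfig, mol: Molecule) -> int:
    basis = get_basis(config.order)
    orbs = lowdin(
        initial_guess(mol, config.n_orbitals, basis, config.precision, config.box)
    )
    ints = build_integrals(orbs, mol)
    write_fcidump(
        os.path.join(config.out_dir, "integrals.fcidump"),
        ints,
        mol.n_electrons,
        ms2=mol.n_electrons % 2,
    )
    save_collection(os.path.join(config.out_dir, "orbitals.npz"), orbs.orbitals)
    _write_summary(
        config,
        {
            "status": "ok",
            "n_orbitals": config.n_orbitals,
            "nuclear_repulsion": mol.nuclear_repulsion(),
        },
    )
    return EXIT_OK


def _run_dmrg_only(config: RunConfig) -> int:
    ints, nelec, ms2 = read_fcidump(config.fcidump)
    if config.n_electrons is not None:
        nelec = config.n_electrons
    cfg = DmrgConfig(
        schedule=[tuple(x) for x in config.dmrg_schedule],
        tol=config.dmrg_tol,
        seed=config.seed,
    )
    mpo = build_mpo(ints.h, ints.g)
    try:
        gs = dmrg_ground_state(mpo, nelec, ms2, cfg)
    except Exception as exc:  # infeasible sector, non-convergence escalations
        _write_summary(config, {"status": "dmrg-failure", "detail": str(exc)})
        return EXIT_DMRG_FAILURE
    grads = extract_gradients(gs)
    np.savez(
        os.path.join(config.out_dir, "gradients.npz"),
        dE_dh=grads.dE_dh,
        dE_dg=grads.dE_dg,
    )
    summary = {
        "status": "converged" if gs.converged else "dmrg-not-converged",
        "energy_electronic": gs.energy,
        "energy_total": gs.energy + ints.core_energy,
        "core_energy": ints.core_energy,
        "n_sweeps": gs.n_sweeps,
        "number_expectation": gs.number_expectation,
        "sz_expectation": gs.sz_expectation,
        "energy_reconstruction": energy_from_gradients(ints.h, ints.g, grads),
    }
    _write_summary(config, summary)
    return EXIT_OK if gs.converged else EXIT_DMRG_FAILURE


def _write_summary(config: RunConfig, payload: dict):
    payload = dict(payload)
    payload["config"] = asdict(config)
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(payload, fh, indent=2)


def restart_orbitals(path):
    """Load an orbital checkpoint written by a previous run."""
    from .integrals import OrbitalSet

    return OrbitalSet(load_collection(path))
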