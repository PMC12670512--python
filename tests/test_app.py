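"""Geometry input, configuration, run orchestration and the CLI."""

import json
import os

import numpy as np
import pytest
from click.testing import CliRunner

from mwdmrg.app import (
    EXIT_OK,
    RunConfig,
    parse_config_file,
    read_xyz,
    run,
)
from mwdmrg.cli import main
from mwdmrg.integrals import ANGSTROM_TO_BOHR


# --------------------------------------------------------------------------- #
# XYZ input
# --------------------------------------------------------------------------- #

def test_read_xyz_single_hydrogen(tmp_path):
    path = tmp_path / "h.xyz"
    path.write_text("1\ncomment\nH 0.0 0.0 0.0\n")
    mol = read_xyz(path)
    assert mol.charges == [1]
    assert mol.n_electrons == 1
    assert np.allclose(mol.positions, 0.0)


def test_read_xyz_unit_conversion(tmp_path):
    path = tmp_path / "h2.xyz"
    path.write_text("2\nH2 molecule\nH 0 0 0\nH 0 0 0.7414\n")
    mol = read_xyz(path)
    d = np.linalg.norm(mol.positions[1] - mol.positions[0])
    assert abs(d - 0.7414 * ANGSTROM_TO_BOHR) < 1e-10
    assert abs(d - 1.4011) < 1e-3


def test_read_xyz_malformed_count_line(tmp_path):
    path = tmp_path / "bad.xyz"
    path.write_text("not_a_number\ncomment\nH 0 0 0\n")
    with pytest.raises(ValueError, match="count"):
        read_xyz(path)


def test_read_xyz_unknown_element(tmp_path):
    path = tmp_path / "bad.xyz"
    path.write_text("1\nc\nQq 0 0 0\n")
    with pytest.raises(ValueError, match="unknown element"):
        read_xyz(path)


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

def test_parse_config_file(tmp_path):
    geo = tmp_path / "h.xyz"
    geo.write_text("1\nc\nH 0 0 0\n")
    conf = tmp_path / "run.conf"
    conf.write_text(
        f"geometry: {geo}\n"
        "n_orbitals: 2\n"
        "precision = 1e-3\n"
        "order: 5\n"
        "# comment line\n"
        "dmrg_schedule: 8x2,16x2\n"
    )
    cfg = parse_config_file(conf)
    assert cfg.n_orbitals == 2
    assert cfg.precision == 1e-3
    assert cfg.dmrg_schedule == [[8, 2], [16, 2]]


def test_config_validation_errors(tmp_path):
    conf = tmp_path / "bad.conf"
    conf.write_text("mode: optimize\nprecision: -1\n")
    with pytest.raises(ValueError):
        parse_config_file(conf)
    conf.write_text("unknown_key: 3\n")
    with pytest.raises(ValueError, match="unknown configuration key"):
        parse_config_file(conf)


# --------------------------------------------------------------------------- #
# run modes (coarse settings)
# --------------------------------------------------------------------------- #

@pytest.fixture(scope="module")
def h_run(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("run")
    geo = tmp / "h.xyz"
    geo.write_text("1\nhydrogen\nH 0 0 0\n")
    cfg = RunConfig(
        geometry=str(geo),
        n_orbitals=1,
        precision=1e-3,
        order=5,
        delta=1e-4,
        out_dir=str(tmp / "out"),
        max_iter=20,
    )
    code = run(cfg)
    return cfg, code


def test_optimize_mode_artifacts(h_run):
    cfg, code = h_run
    assert code == EXIT_OK
    out = cfg.out_dir
    assert os.path.exists(os.path.join(out, "trace.csv"))
    assert os.path.exists(os.path.join(out, "orbitals.npz"))
    assert os.path.exists(os.path.join(out, "final.fcidump"))
    summary = json.load(open(os.path.join(out, "summary.json")))
    assert summary["status"] == "converged"
    assert abs(summary["energy"] + 0.5) < 5e-3


def test_dmrg_only_reproduces_final_energy(h_run, tmp_path):
    """dmrg-only on the round-tripped FCIDUMP reproduces the optimize-mode
    final DMRG energy to 1e-8."""
    cfg, _ = h_run
    summary = json.load(open(os.path.join(cfg.out_dir, "summary.json")))
    dcfg = RunConfig(
        mode="dmrg-only",
        fcidump=os.path.join(cfg.out_dir, "final.fcidump"),
        out_dir=str(tmp_path / "dmrg_out"),
    )
    assert run(dcfg) == EXIT_OK
    s2 = json.load(open(os.path.join(dcfg.out_dir, "summary.json")))
    assert abs(s2["energy_total"] - summary["energy"]) < 1e-8
    grads = np.load(os.path.join(dcfg.out_dir, "gradients.npz"))
    assert abs(np.trace(grads["dE_dh"]) - 1.0) < 1e-10


def test_rerun_is_bit_identical(h_run, tmp_path):
    cfg, _ = h_run
    cfg2 = RunConfig(**{**cfg.__dict__, "out_dir": str(tmp_path / "out2")})
    assert run(cfg2) == EXIT_OK
    t1 = open(os.path.join(cfg.out_dir, "trace.csv")).read()
    t2 = open(os.path.join(cfg2.out_dir, "trace.csv")).read()
    assert t1 == t2


def test_integrals_only_mode(tmp_path):
    geo = tmp_path / "h.xyz"
    geo.write_text("1\nhydrogen\nH 0 0 0\n")
    cfg = RunConfig(
        geometry=str(geo),
        mode="integrals-only",
        n_orbitals=1,
        precision=1e-3,
        order=5,
        out_dir=str(tmp_path / "out"),
    )
    assert run(cfg) == EXIT_OK
    assert os.path.exists(os.path.join(str(tmp_path / "out"), "integrals.fcidump"))


# --------------------------------------------------------------------------- #
# CLI
# --------------------------------------------------------------------------- #

def test_cli_check_command(tmp_path):
    geo = tmp_path / "h.xyz"
    geo.write_text("1\nc\nH 0 0 0\n")
    conf = tmp_path / "run.conf"
    conf.write_text(f"geometry: {geo}\nn_orbitals: 1\n")
    runner = CliRunner()
    result = runner.invoke(main, ["check", str(conf)])
    assert result.exit_code == 0
    assert "configuration ok" in result.output


def test_cli_check_rejects_bad_config(tmp_path):
    conf = tmp_path / "bad.conf"
    conf.write_text("precision: -2\n")
    runner = CliRunner()
    result = runner.invoke(main, ["check", str(conf)])
    assert result.exit_code == 1


def test_scan_driver_emits_one_row_per_geometry(tmp_path):
    runner = CliRunner()
    result = runner.invoke(
        main,
        [
            "scan", "H,H", "--distances", "0.6,0.9", "-M", "1",
            "-p", "1e-2", "-k", "4", "--delta", "1e-2", "--max-iter", "8",
            "-o", str(tmp_path),
        ],
    )
    assert result.exit_code == 0, result.output
    lines = open(tmp_path / "scan.csv").read().strip().splitlines()
    assert len(lines) == 3  # header + one row per distance
    d0 = [float(x) for x in lines[1].split(",")]
    d1 = [float(x) for x in lines[2].split(",")]
    assert d0[0] == 0.6 and d1[0] == 0.9
    assert d0[1] < 0 and d1[1] < 0  # bound molecule at both separations


def test_cli_help_lists_commands():
    runner = CliRunner()
    result = runner.invoke(main, ["--help"])
    assert result.exit_code == 0
    for cmd in ("run", "dmrg", "check", "scan"):
        assert cmd in result.output
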