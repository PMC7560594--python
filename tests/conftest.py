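"""Shared fixtures: built duplexes, lesioned sites, and tiny PDB fixtures."""

from __future__ import annotations

import numpy as np
import pytest

import ncpdyn as nd

SEQ15 = "GCGCATATATGCGCG"


def make_structure(records, coords):
    """Build a Structure from (name, res_name, chain, res_id, element) rows."""
    records = list(records)
    n = len(records)
    return nd.Structure(
        serial=np.arange(1, n + 1),
        name=np.array([r[0] for r in records], dtype=object),
        res_name=np.array([r[1] for r in records], dtype=object),
        chain_id=np.array([r[2] for r in records], dtype=object),
        res_id=np.array([r[3] for r in records], dtype=int),
        element=np.array([r[4] for r in records], dtype=object),
        mass=np.array([nd.structure.mass_of(r[4]) for r in records]),
        coords=np.asarray(coords, dtype=float),
    )


@pytest.fixture(scope="session")
def synth_cfg():
    return nd.SynthConfig(sequence=SEQ15, lesion_position=7,
                          orphan_position=8)


@pytest.fixture(scope="session")
def duplex15(synth_cfg):
    return nd.build_bdna(synth_cfg)


@pytest.fixture(scope="session")
def site15(synth_cfg):
    return nd.duplex_site_spec(synth_cfg)


@pytest.fixture(scope="session")
def lesioned15(duplex15, site15):
    return nd.apply_lesion(duplex15, site15.lesion, "AP")


@pytest.fixture(scope="session")
def static_traj(lesioned15):
    """Single-frame trajectory of the lesioned duplex."""
    return nd.Trajectory(lesioned15, lesioned15.coords[None])


PDB_3ATOM = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500  -1.250   0.125  1.00  0.00           C
ATOM      3  C   ALA A   1      -3.375   4.000   5.625  1.00  0.00           C
END
"""


def multi_model_pdb(n_models: int, drop_atom_in_model: int | None = None) -> str:
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        body = PDB_3ATOM.strip().splitlines()[:-1]  # drop END
        if drop_atom_in_model == m:
            body = body[:-1]
        lines.extend(body)
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_3atom(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(PDB_3ATOM)
    return p


@pytest.fixture(scope="session")
def tail_protein():
    """H2A-tail-like fixture: N-terminal A12, K13 (with NZ), R29."""
    rows = [
        ("N", "ALA", "P", 12, "N"), ("CA", "ALA", "P", 12, "C"),
        ("C", "ALA", "P", 12, "C"), ("O", "ALA", "P", 12, "O"),
        ("N", "LYS", "P", 13, "N"), ("CA", "LYS", "P", 13, "C"),
        ("NZ", "LYS", "P", 13, "N"),
        ("N", "ARG", "P", 29, "N"), ("CA", "ARG", "P", 29, "C"),
        ("NE", "ARG", "P", 29, "N"), ("NH1", "ARG", "P", 29, "N"),
        ("NH2", "ARG", "P", 29, "N"),
    ]
    rng = np.random.default_rng(3)
    return make_structure(rows, rng.normal(0, 5, (len(rows), 3)))
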