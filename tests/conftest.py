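import numpy as np
import pytest

from mses.structmodel import AtomRecord, Structure
from mses.synthetic import ToyComplexSpec, make_two_domain_complex


THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.729   6.768  -4.123  1.00  0.00           C
END
"""


def _ca_chain_pdb(chain_id: str, n_res: int, start_serial: int = 1, spacing: float = 3.8,
                  offset=(0.0, 0.0, 0.0), start_res: int = 1) -> str:
    lines = []
    for i in range(n_res):
        x = offset[0] + i * spacing
        lines.append(
            f"ATOM  {start_serial + i:5d}  CA  GLY {chain_id}{start_res + i:4d}    "
            f"{x:8.3f}{offset[1]:8.3f}{offset[2]:8.3f}  1.00  0.00           C"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def ten_residue_pdb(tmp_path):
    p = tmp_path / "ten.pdb"
    p.write_text(_ca_chain_pdb("A", 10) + "END\n")
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    text = _ca_chain_pdb("A", 10) + _ca_chain_pdb("B", 7, start_serial=11, offset=(0, 5.0, 0)) + "END\n"
    p = tmp_path / "two_chain.pdb"
    p.write_text(text)
    return p


@pytest.fixture
def complex_pdb(tmp_path):
    """Two 10-residue chains plus a 5-residue binder chain."""
    text = (
        _ca_chain_pdb("A", 10)
        + _ca_chain_pdb("B", 10, start_serial=11, offset=(0, 6.0, 0))
        + _ca_chain_pdb("C", 5, start_serial=21, offset=(0, 3.0, 6.0))
        + "END\n"
    )
    p = tmp_path / "complex.pdb"
    p.write_text(text)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def small_complex():
    """A small two-domain/binder complex shared across tests."""
    return make_two_domain_complex(
        ToyComplexSpec(beads_per_domain=10, beads_binder=8, linker_beads=5, seed=11)
    )


def random_structure(rng, n=8) -> Structure:
    atoms = [
        AtomRecord(i + 1, "CA", "GLY", "A", i + 1, tuple(rng.normal(0, 5, 3)), "C")
        for i in range(n)
    ]
    return Structure(atoms)
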