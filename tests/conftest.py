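import numpy as np
import pytest

from coevomc import cgmodel, energetics, fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def helix_chain():
    return fixtures.make_toy_chain(8, "helix")


@pytest.fixture
def default_params():
    return energetics.EnergyParams()


@pytest.fixture
def big_box():
    return cgmodel.BoxSpec("cube", 50.0)


@pytest.fixture
def toy_pdb(tmp_path):
    """Hand-written three-residue PDB (GLY, ALA, SER) with known side chains."""
    records = [
        # resname, resi, atom, element, x, y, z
        ("GLY", 1, "N", "N", 0.000, 0.000, 0.000),
        ("GLY", 1, "CA", "C", 1.458, 0.000, 0.000),
        ("GLY", 1, "C", "C", 2.009, 1.420, 0.000),
        ("GLY", 1, "O", "O", 1.400, 2.300, 0.600),
        ("ALA", 2, "N", "N", 3.332, 1.536, 0.000),
        ("ALA", 2, "CA", "C", 4.120, 2.770, 0.100),
        ("ALA", 2, "C", "C", 5.600, 2.520, 0.300),
        ("ALA", 2, "O", "O", 6.100, 1.400, 0.200),
        ("ALA", 2, "CB", "C", 3.800, 3.600, 1.300),
        ("SER", 3, "N", "N", 6.300, 3.600, 0.600),
        ("SER", 3, "CA", "C", 7.750, 3.520, 0.800),
        ("SER", 3, "C", "C", 8.400, 4.900, 0.900),
        ("SER", 3, "O", "O", 7.800, 5.900, 1.200),
        ("SER", 3, "CB", "C", 8.200, 2.700, 2.000),
        ("SER", 3, "OG", "O", 9.600, 2.500, 2.000),
    ]
    lines = []
    for serial, (res, ri, name, el, x, y, z) in enumerate(records, start=1):
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {res} A{ri:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {el:>2s}"
        )
    lines += ["TER", "END"]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
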