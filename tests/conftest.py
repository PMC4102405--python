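import numpy as np
import pytest

from thermocurve.structures import ProteinStructure, Residue


def atom_line(serial, name, resname, chain, resseq, xyz, occ=1.0,
              altloc=" ", record="ATOM", element=None):
    x, y, z = xyz
    element = element or name[0]
    return (f"{record:<6s}{serial:5d} {name:>4s}{altloc}{resname:>3s} "
            f"{chain}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
            f"  0.00          {element:>2s}")


@pytest.fixture
def three_res_pdb():
    """ALA-GLY-SER minimal chain with interleaved waters."""
    lines = [
        atom_line(1, "N", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        atom_line(2, "CA", "ALA", "A", 1, (1.458, 0.0, 0.0)),
        atom_line(3, "C", "ALA", "A", 1, (2.0, 1.4, 0.0)),
        atom_line(4, "O", "ALA", "A", 1, (3.0, 1.5, 0.5)),
        atom_line(5, "CB", "ALA", "A", 1, (1.0, 2.0, 3.0)),
        atom_line(6, "O", "HOH", "A", 90, (9.0, 9.0, 9.0), record="HETATM"),
        atom_line(7, "N", "GLY", "A", 2, (2.5, 2.5, 0.0)),
        atom_line(8, "CA", "GLY", "A", 2, (5.0, 5.0, 5.0)),
        atom_line(9, "C", "GLY", "A", 2, (3.5, 3.5, 1.0)),
        atom_line(10, "O", "HOH", "A", 91, (8.0, 8.0, 8.0), record="HETATM"),
        atom_line(11, "N", "SER", "A", 3, (4.0, 4.0, 1.5)),
        atom_line(12, "CA", "SER", "A", 3, (5.0, 4.5, 2.0)),
        atom_line(13, "C", "SER", "A", 3, (6.0, 5.0, 2.5)),
        atom_line(14, "CB", "SER", "A", 3, (5.5, 3.0, 2.5)),
        atom_line(15, "OG", "SER", "A", 3, (6.5, 3.2, 3.5)),
        "END",
    ]
    return "\n".join(lines) + "\n"


def make_protein(aa_centers, pid="toy", **meta):
    """Structure from a list of (aa_type, center_xyz); centers become the
    single side-chain atom of each residue."""
    residues = []
    for k, (aa, xyz) in enumerate(aa_centers):
        residues.append(Residue(
            index=k + 1,
            aa_type=aa,
            backbone_coords={"CA": np.asarray(xyz, dtype=float)},
            side_chain_coords=np.asarray([xyz], dtype=float),
        ))
    return ProteinStructure(id=pid, chain="A", residues=residues, **meta)


@pytest.fixture
def make_toy_protein():
    return make_protein
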