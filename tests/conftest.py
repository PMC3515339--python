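import numpy as np
import pytest

from evosig.alignment import Alignment
from evosig.structure import StructureModel, StructureResidue


@pytest.fixture
def toy_alignment():
    """Small trimmed alignment with reference 'ref' and no gaps in it."""
    return Alignment(
        ids=["ref", "s1", "s2", "s3"],
        seqs=["ACDE", "ACDE", "AC-E", "GCDE"],
        reference_id="ref",
        column_map=np.arange(1, 5),
    )


def make_alignment(seqs, reference_id=None, trimmed=True):
    ids = [f"s{i}" for i in range(len(seqs))]
    if reference_id is not None:
        ids[0] = reference_id
    return Alignment(
        ids=ids,
        seqs=list(seqs),
        reference_id=reference_id,
        column_map=np.arange(1, len(seqs[0]) + 1) if trimmed else None,
    )


def make_structure(points, sequence=None):
    """StructureModel from per-residue atom coordinate lists."""
    from Bio.Data.IUPACData import protein_letters_1to3

    residues = []
    for i, atoms in enumerate(points):
        letter = sequence[i] if sequence else "G"
        residues.append(
            StructureResidue(
                chain_id="A",
                number=i + 1,
                insertion_code="",
                name=protein_letters_1to3.get(letter, "Gly").upper(),
                coords=np.atleast_2d(np.asarray(atoms, dtype=float)),
            )
        )
    return StructureModel(residues=residues, chain_id="A", source="test")


GLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  H   GLY A   1       0.500   0.900   0.000  1.00  0.00           H
ATOM      6  N   GLY A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.500   2.700   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.100   1.600   0.000  1.00  0.00           O
ATOM     10  N   GLY A   3       6.200   3.800   0.000  1.00  0.00           N
ATOM     11  CA  GLY A   3       7.600   3.900   0.000  1.00  0.00           C
ATOM     12  C   GLY A   3       8.300   5.200   0.000  1.00  0.00           C
ATOM     13  O   GLY A   3       7.700   6.300   0.000  1.00  0.00           O
HETATM   14  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
HETATM   15  O   HOH A 102      21.000  21.000  21.000  1.00  0.00           O
TER
END
"""


@pytest.fixture
def gly_pdb(tmp_path):
    path = tmp_path / "gly.pdb"
    path.write_text(GLY_PDB)
    return path
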