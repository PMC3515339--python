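"""PDB structures, minimum heavy-atom distances and sequence mapping.

Residue-residue distance is the minimum Euclidean distance between any
two heavy (non-hydrogen) atoms of the two residues, in Angstrom.  Note
this "closest approach" distance does not satisfy the triangle
inequality, and none is assumed downstream.

Reference alignment positions rarely share numbering with PDB residues,
so :func:`map_alignment_to_structure` aligns the reference sequence
globally against the sequence read off the structure and maps positions
through the aligned pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .alignment import Alignment
from .errors import InputError, MappingError, ReferenceNotFoundError, ValidationError

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
_3TO1["MSE"] = "M"  # selenomethionine treated as methionine

#: mappings covering less than this fraction of the reference are rejected
MIN_MAPPING_COVERAGE = 0.30
#: aligned pairs must be at least this identical, else sequences are unrelated
MIN_MAPPING_IDENTITY = 0.30


@dataclass
class StructureResidue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    coords: np.ndarray  # (n_heavy_atoms, 3), Angstrom

    @property
    def one_letter(self) -> str:
        return _3TO1.get(self.name.upper(), "X")


@dataclass
class StructureModel:
    """Ordered heavy-atom coordinates for one chain of one model."""

    residues: list[StructureResidue]
    chain_id: str
    source: str = ""

    def __post_init__(self) -> None:
        for res in self.residues:
            if len(res.coords) == 0:
                raise ValidationError(
                    f"residue {res.name} {res.number} has no heavy atoms"
                )

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of minimum heavy-atom distances (Angstrom)."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance matrix must be square")
        self.distances = d

    @property
    def n(self) -> int:
        return self.distances.shape[0]


@dataclass
class PositionMapping:
    """Partial, injective map: 1-based reference position -> residue index."""

    mapping: dict[int, int]
    coverage: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValidationError("position mapping must be injective")

    def inverse(self) -> dict[int, int]:
        return {v: k for k, v in self.mapping.items()}


def _pick_altloc(atom):
    """Highest-occupancy conformer of a (possibly disordered) atom."""
    if atom.is_disordered():
        children = atom.disordered_get_list()
        best = max(children, key=lambda a: (a.get_occupancy() or 0.0))
        # max() keeps the first of tied occupancies, matching the contract
        return best
    return atom


def read_structure(path: str | Path, chain: str, model: int = 0) -> StructureModel:
    """Read one chain of one model from a PDB file.

    Keeps amino-acid residues (HETATM excluded except selenomethionine,
    treated as MET), drops waters and hydrogens, and resolves alternate
    locations to the highest-occupancy conformer (ties: first listed).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise InputError(f"{path}: no models")
    mdl = models[model if model < len(models) else 0]
    chain_ids = [c.id for c in mdl]
    if chain not in chain_ids:
        raise ReferenceNotFoundError(
            f"{path}: chain {chain!r} absent (have {chain_ids})"
        )
    residues: list[StructureResidue] = []
    for res in mdl[chain]:
        hetflag, resseq, icode = res.id
        name = res.get_resname().strip().upper()
        if hetflag != " " and name != "MSE":
            continue  # waters and other heteroatoms
        if name not in _3TO1:
            continue
        coords = []
        for atom in res:
            a = _pick_altloc(atom)
            element = (a.element or "").strip().upper()
            if element in ("H", "D"):
                continue
            if not element and a.get_name().lstrip("0123456789").startswith("H"):
                continue
            coords.append(a.get_coord())
        if not coords:
            continue
        residues.append(
            StructureResidue(
                chain_id=chain,
                number=resseq,
                insertion_code=icode.strip(),
                name=name,
                coords=np.asarray(coords, dtype=float),
            )
        )
    if not residues:
        raise InputError(f"{path}: chain {chain} has no amino-acid residues")
    return StructureModel(residues=residues, chain_id=chain, source=str(path))


def min_heavy_atom_distances(s: StructureModel) -> DistanceMatrix:
    """Minimum heavy-atom distance between every residue pair, in Angstrom."""
    coords = np.concatenate([r.coords for r in s.residues], axis=0)
    sizes = np.array([len(r.coords) for r in s.residues])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    atom_d = cdist(coords, coords)
    by_row = np.minimum.reduceat(atom_d, starts, axis=0)
    d = np.minimum.reduceat(by_row, starts, axis=1)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(distances=d)


def map_alignment_to_structure(
    aln: Alignment, s: StructureModel
) -> PositionMapping:
    """Map reference positions onto structure residues by global alignment.

    Needleman-Wunsch with match +1, mismatch -1, gap open -5, gap extend
    -0.5.  Every aligned (identical or substituted) pair contributes a
    mapping entry.  Coverage below 30% of the reference, or fewer than
    30% identical residues among the aligned pairs, raises
    :class:`MappingError` (the latter catches unrelated sequences that a
    global aligner would still pair up end to end).
    """
    if not aln.is_trimmed:
        raise ValidationError("mapping requires a trimmed alignment")
    ref = aln.reference_sequence
    struct_seq = s.sequence
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    best = aligner.align(ref, struct_seq)[0]
    mapping: dict[int, int] = {}
    for (r0, r1), (s0, s1) in zip(*best.aligned):
        for k in range(r1 - r0):
            mapping[r0 + k + 1] = s0 + k
    coverage = len(mapping) / len(ref)
    if coverage < MIN_MAPPING_COVERAGE:
        raise MappingError(
            f"alignment-to-structure coverage {coverage:.2f} below "
            f"{MIN_MAPPING_COVERAGE:.2f}"
        )
    identical = sum(
        1 for pos, ridx in mapping.items() if ref[pos - 1] == struct_seq[ridx]
    )
    identity = identical / len(mapping)
    if identity < MIN_MAPPING_IDENTITY:
        raise MappingError(
            f"aligned-pair identity {identity:.2f} below "
            f"{MIN_MAPPING_IDENTITY:.2f}; sequences likely unrelated"
        )
    return PositionMapping(
        mapping=mapping,
        coverage=coverage,
        meta={"score": best.score, "identity": identity, "structure": s.source},
    )


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    """Export as TSV: ``i<TAB>j<TAB>distance`` for i < j (1-based indices)."""
    with open(path, "w") as fh:
        fh.write("# i\tj\tmin_heavy_atom_distance_A\n")
        for i in range(d.n):
            for j in range(i + 1, d.n):
                fh.write(f"{i + 1}\t{j + 1}\t{d.distances[i, j]:.4f}\n")
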