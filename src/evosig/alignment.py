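"""Multiple sequence alignments, per-residue score vectors and annotations.

The central object is :class:`Alignment`: a rectangular block of gapped
sequences with a designated reference sequence.  All downstream scores are
indexed by *reference positions* — 1-based indices into the ungapped
reference — so an alignment must be trimmed with :func:`trim_to_reference`
(removing every column where the reference carries a gap) before any
scoring.  This mirrors the usual pre-treatment of Pfam family alignments
against the family member whose 3D structure is known.

Redundancy reduction uses a deterministic greedy (Hobohm-1 style) sweep:
the reference is always kept, then sequences are admitted in input order
iff their identity to every already-kept sequence is below the threshold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import AlignIO

from .errors import (
    InputError,
    ParseError,
    ReferenceNotFoundError,
    ValidationError,
)

GAP = "-"
#: canonical amino-acid order used for every frequency vector in the package
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
#: integer code for "gap or non-standard residue" in encoded alignments
GAP_CODE = 20

# B/Z/X and the rare U/O are collapsed onto the gap code: they are too
# ambiguous/rare to support frequency estimates and would inflate the
# alphabet otherwise.
_NONSTANDARD = set("BZXUOJ")

Orientation = Literal["higher_better", "lower_better"]


@dataclass
class Alignment:
    """A rectangular gapped alignment with an optional designated reference.

    Parameters
    ----------
    ids:
        Sequence identifiers, in alignment order.
    seqs:
        Gapped sequences (uppercase, ``-`` for gaps), all of equal length.
    reference_id:
        Identifier of the reference sequence, if designated.
    column_map:
        For trimmed alignments: 1-based reference position of every
        alignment column.  ``None`` until :func:`trim_to_reference` runs.
    """

    ids: list[str]
    seqs: list[str]
    reference_id: str | None = None
    column_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValidationError("alignment contains no sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValidationError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and seqs differ in count")
        if self.reference_id is not None and self.ids.count(self.reference_id) != 1:
            raise ReferenceNotFoundError(
                f"reference {self.reference_id!r} occurs "
                f"{self.ids.count(self.reference_id)} times"
            )

    # -- basic views -------------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    @property
    def is_trimmed(self) -> bool:
        return self.column_map is not None

    @property
    def reference_index(self) -> int:
        if self.reference_id is None:
            raise ReferenceNotFoundError("no reference designated")
        return self.ids.index(self.reference_id)

    @property
    def reference_sequence(self) -> str:
        """Gapped reference row (gap-free once trimmed)."""
        return self.seqs[self.reference_index]

    def encoded(self) -> np.ndarray:
        """(n_sequences, n_columns) uint8 matrix; 0..19 amino acids, 20 gap.

        Non-standard residues (B, Z, X, U, O, J) are mapped to the gap code.
        """
        table = np.full(128, GAP_CODE, dtype=np.uint8)
        for aa, i in AA_INDEX.items():
            table[ord(aa)] = i
        flat = np.frombuffer("".join(self.seqs).encode("ascii"), dtype=np.uint8)
        return table[flat].reshape(self.n_sequences, self.n_columns)


@dataclass
class CatalyticAnnotation:
    """Set of annotated catalytic residues, as 1-based reference positions."""

    positions: frozenset[int]
    source_label: str = ""

    def labels(self, length: int) -> np.ndarray:
        """Binary label vector over reference positions 1..length."""
        y = np.zeros(length, dtype=np.int8)
        for p in self.positions:
            y[p - 1] = 1
        return y


@dataclass
class ScoreVector:
    """One real score per reference position, tagged with its orientation.

    ``values[i]`` scores reference position ``i + 1``; NaN marks a missing
    value.  ``orientation`` records whether larger values mean more
    functionally important (``higher_better``) or the score is rank-like
    with the best rank being the smallest number (``lower_better``, the
    Evolutionary Trace convention).
    """

    method_name: str
    values: np.ndarray
    orientation: Orientation = "higher_better"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("score values must be one-dimensional")
        if self.orientation not in ("higher_better", "lower_better"):
            raise ValidationError(f"bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def oriented_values(self) -> np.ndarray:
        """Values on a higher-is-better scale (rank-like scores negated)."""
        if self.orientation == "lower_better":
            return -self.values
        return self.values


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(
    path: str | Path,
    format: Literal["fasta", "stockholm"] = "fasta",
    reference_id: str | None = None,
) -> Alignment:
    """Read a FASTA or Stockholm alignment.

    Residues are uppercased and both ``.`` and ``-`` are normalized to a
    single gap symbol.  The returned alignment is untrimmed (no column map).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise InputError(f"empty alignment file: {path}")
    try:
        msa = AlignIO.read(io.StringIO(text), format)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    seqs = [_normalize(str(rec.seq)) for rec in msa]
    return Alignment(ids=ids, seqs=seqs, reference_id=reference_id)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as gapped FASTA."""
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def read_score_table(
    path: str | Path,
    orientation: Orientation = "higher_better",
    length: int | None = None,
    method_name: str | None = None,
) -> ScoreVector:
    """Read a two-column ``pos<TAB>score`` table into a :class:`ScoreVector`.

    Lines starting with ``#`` are comments; a single non-numeric header row
    is tolerated.  Positions are 1-based reference positions; positions not
    listed are flagged missing (NaN).  Duplicate positions are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    entries: dict[int, float] = {}
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected two columns")
        try:
            pos = int(parts[0])
            score = float(parts[1])
        except ValueError:
            if not header_seen and not entries:
                header_seen = True
                continue
            raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}")
        if pos < 1:
            raise ParseError(f"{path}:{lineno}: position must be >= 1")
        if pos in entries:
            raise ParseError(f"{path}:{lineno}: duplicate position {pos}")
        entries[pos] = score
    if not entries:
        raise InputError(f"{path}: no score rows")
    L = length if length is not None else max(entries)
    if max(entries) > L:
        raise ValidationError(
            f"{path}: position {max(entries)} exceeds length {L}"
        )
    values = np.full(L, np.nan)
    for pos, score in entries.items():
        values[pos - 1] = score
    return ScoreVector(
        method_name=method_name or path.stem,
        values=values,
        orientation=orientation,
    )


def write_score_table(score: ScoreVector, path: str | Path, header: Iterable[str] = ()) -> None:
    """Write a score vector in the same TSV dialect `read_score_table` accepts."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write(f"# method={score.method_name} orientation={score.orientation}\n")
        for i, v in enumerate(score.values, start=1):
            if not np.isnan(v):
                fh.write(f"{i}\t{v:.10g}\n")


def read_annotation(path: str | Path, L_ref: int, source_label: str = "") -> CatalyticAnnotation:
    """Read a whitespace/comma separated list of 1-based catalytic positions."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    tokens: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0]
        tokens.extend(line.replace(",", " ").split())
    if not tokens:
        raise InputError(f"{path}: no annotated positions (need at least one)")
    positions = set()
    for tok in tokens:
        try:
            pos = int(tok)
        except ValueError:
            raise ParseError(f"{path}: non-integer position {tok!r}")
        if not 1 <= pos <= L_ref:
            raise ValidationError(
                f"{path}: position {pos} outside [1, {L_ref}]"
            )
        positions.add(pos)
    return CatalyticAnnotation(frozenset(positions), source_label or path.stem)


# ---------------------------------------------------------------------------
# Trimming and redundancy reduction
# ---------------------------------------------------------------------------

def trim_to_reference(aln: Alignment, reference_id: str | None = None) -> Alignment:
    """Remove every column where the reference sequence carries a gap.

    The surviving columns map 1:1 onto reference positions ``1..L_ref``
    (recorded in ``column_map``); other sequences keep whatever gaps they
    have in the retained columns.  Idempotent.
    """
    ref_id = reference_id or aln.reference_id
    if ref_id is None:
        raise ReferenceNotFoundError("no reference designated for trimming")
    if ref_id not in aln.ids:
        raise ReferenceNotFoundError(f"reference {ref_id!r} not in alignment")
    ref_seq = aln.seqs[aln.ids.index(ref_id)]
    keep = [i for i, c in enumerate(ref_seq) if c != GAP]
    if not keep:
        raise ValidationError("reference sequence is entirely gaps")
    seqs = ["".join(s[i] for i in keep) for s in aln.seqs]
    return Alignment(
        ids=list(aln.ids),
        seqs=seqs,
        reference_id=ref_id,
        column_map=np.arange(1, len(keep) + 1),
    )


def pairwise_identity(s1: str, s2: str) -> float:
    """Fraction of identical residues between two gapped sequences.

    Denominator: columns where at least one of the two sequences is
    non-gap (so insertions in either sequence dilute identity).  Columns
    gapped in both are ignored entirely.  Returns 0.0 when no column is
    comparable.
    """
    if len(s1) != len(s2):
        raise ValidationError(
            f"sequences differ in length ({len(s1)} vs {len(s2)})"
        )
    comparable = 0
    matches = 0
    for a, b in zip(s1, s2):
        ga, gb = a == GAP, b == GAP
        if ga and gb:
            continue
        comparable += 1
        if not ga and not gb and a == b:
            matches += 1
    return matches / comparable if comparable else 0.0


def _identity_to_many(seq_codes: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Vectorized `pairwise_identity` of one encoded row against many."""
    gap_a = seq_codes == GAP_CODE
    gap_b = others == GAP_CODE
    comparable = (~(gap_a[None, :] & gap_b)).sum(axis=1)
    matches = ((seq_codes[None, :] == others) & ~gap_a[None, :] & ~gap_b).sum(axis=1)
    out = np.zeros(len(others))
    nz = comparable > 0
    out[nz] = matches[nz] / comparable[nz]
    return out


def identity_matrix(aln: Alignment) -> np.ndarray:
    """Full pairwise identity matrix (diagonal 1)."""
    codes = aln.encoded()
    n = aln.n_sequences
    mat = np.eye(n)
    for i in range(n - 1):
        row = _identity_to_many(codes[i], codes[i + 1:])
        mat[i, i + 1:] = row
        mat[i + 1:, i] = row
    return mat


def reduce_redundancy(aln: Alignment, identity_threshold: float) -> Alignment:
    """Greedy redundancy reduction at the given fractional identity.

    The reference (if designated) is processed first and therefore always
    kept; remaining sequences are visited in input order and kept iff their
    identity to every already-kept sequence is strictly below the
    threshold.  Guarantees that no kept pair reaches the threshold.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValidationError("identity threshold must be in (0, 1]")
    if not aln.is_trimmed:
        raise ValidationError("redundancy reduction requires a trimmed alignment")
    codes = aln.encoded()
    order = list(range(aln.n_sequences))
    if aln.reference_id is not None:
        ref = aln.reference_index
        order.remove(ref)
        order.insert(0, ref)
    kept: list[int] = []
    for idx in order:
        if not kept:
            kept.append(idx)
            continue
        ids_to_kept = _identity_to_many(codes[idx], codes[kept])
        if np.all(ids_to_kept < identity_threshold):
            kept.append(idx)
    kept_sorted = sorted(kept)
    return Alignment(
        ids=[aln.ids[i] for i in kept_sorted],
        seqs=[aln.seqs[i] for i in kept_sorted],
        reference_id=aln.reference_id,
        column_map=None if aln.column_map is None else aln.column_map.copy(),
    )
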