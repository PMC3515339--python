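"""The unit of evaluation: one protein family with everything attached.

A :class:`FamilyRecord` bundles a trimmed alignment, a structure for the
reference sequence, the catalytic-residue annotation, and a cache of
named per-residue score vectors.  Distance matrix and position mapping
are computed lazily and memoized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import Alignment, CatalyticAnnotation, ScoreVector
from .errors import ValidationError
from .structure import (
    DistanceMatrix,
    PositionMapping,
    StructureModel,
    map_alignment_to_structure,
    min_heavy_atom_distances,
)


@dataclass
class FamilyRecord:
    family_id: str
    alignment: Alignment
    structure: StructureModel | None = None
    annotation: CatalyticAnnotation | None = None
    scores: dict[str, ScoreVector] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    _mapping: PositionMapping | None = field(default=None, repr=False)
    _distances: DistanceMatrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.alignment.is_trimmed:
            raise ValidationError(f"{self.family_id}: alignment must be trimmed")
        if self.annotation is not None:
            L = self.alignment.n_columns
            bad = [p for p in self.annotation.positions if not 1 <= p <= L]
            if bad:
                raise ValidationError(
                    f"{self.family_id}: annotated positions {bad} outside [1, {L}]"
                )

    @property
    def length(self) -> int:
        return self.alignment.n_columns

    @property
    def mapping(self) -> PositionMapping:
        if self._mapping is None:
            if self.structure is None:
                raise ValidationError(f"{self.family_id}: no structure attached")
            self._mapping = map_alignment_to_structure(self.alignment, self.structure)
        return self._mapping

    @property
    def distances(self) -> DistanceMatrix:
        if self._distances is None:
            if self.structure is None:
                raise ValidationError(f"{self.family_id}: no structure attached")
            self._distances = min_heavy_atom_distances(self.structure)
        return self._distances

    def add_score(self, score: ScoreVector) -> None:
        if len(score) != self.length:
            raise ValidationError(
                f"{self.family_id}: score {score.method_name!r} length "
                f"{len(score)} != {self.length}"
            )
        self.scores[score.method_name] = score

    def labels(self):
        if self.annotation is None:
            raise ValidationError(f"{self.family_id}: no annotation attached")
        return self.annotation.labels(self.length)
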