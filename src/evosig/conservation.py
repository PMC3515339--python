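"""Per-column conservation as Kullback-Leibler relative entropy.

A column's conservation is the KL divergence (in bits) between the
column's amino-acid distribution and a background distribution of amino
acids in the sequence universe:

    C_i = sum_a p_a(i) * log2( p_a(i) / q_a )

with the convention 0*log(0) = 0.  A fully conserved column against a
uniform background scores log2(20) ~ 4.32 bits; a column distributed like
the background scores 0.  Gaps are excluded from the column counts, and
sequence weights (e.g. the inverse-cluster-size weights used for mutual
information) may be supplied; by default all sequences weigh equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .alignment import AA_ALPHABET, AA_INDEX, Alignment, GAP_CODE, ScoreVector
from .errors import DegenerateColumnError, InputError, ParseError, ValidationError

#: columns with more gaps than this fraction are flagged (but still scored)
GAP_FLAG_FRACTION = 0.5


@dataclass
class BackgroundFrequencies:
    """Background amino-acid frequencies in :data:`AA_ALPHABET` order."""

    frequencies: np.ndarray
    label: str = "background"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (20,):
            raise ValidationError("background must have exactly 20 frequencies")
        if np.any(self.frequencies <= 0):
            raise ValidationError("background frequencies must be strictly positive")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValidationError("background frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        return cls(np.full(20, 1.0 / 20.0), label="uniform")

    @classmethod
    def from_tsv(cls, path: str | Path, normalize: bool = True) -> "BackgroundFrequencies":
        """Load an ``aa<TAB>frequency`` table (20 rows, '#' comments).

        Tables are renormalized to sum exactly to 1 unless ``normalize``
        is disabled (published composition tables are typically rounded).
        """
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such file: {path}")
        freqs = np.full(20, np.nan)
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'aa<TAB>frequency'")
            aa = parts[0].upper()
            if aa not in AA_INDEX:
                raise ParseError(f"{path}:{lineno}: unknown amino acid {aa!r}")
            if not np.isnan(freqs[AA_INDEX[aa]]):
                raise ParseError(f"{path}:{lineno}: duplicate amino acid {aa}")
            try:
                freqs[AA_INDEX[aa]] = float(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric frequency")
        if np.any(np.isnan(freqs)):
            missing = [a for a in AA_ALPHABET if np.isnan(freqs[AA_INDEX[a]])]
            raise ParseError(f"{path}: missing amino acids {missing}")
        if normalize:
            freqs = freqs / freqs.sum()
        return cls(freqs, label=path.stem)

    @classmethod
    def default(cls) -> "BackgroundFrequencies":
        """The packaged Swiss-Prot-derived composition table."""
        src = resources.files("evosig.data") / "background_frequencies.tsv"
        with resources.as_file(src) as path:
            return cls.from_tsv(path)


@dataclass
class ColumnProfile:
    """Weighted amino-acid frequencies of one alignment column."""

    frequencies: np.ndarray  # length 20, sums to 1 when effective_count > 0
    effective_count: float  # total weight of non-gap entries
    gap_fraction: float


def _weights_array(aln: Alignment, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return np.ones(aln.n_sequences)
    w = np.asarray(weights, dtype=float)
    if w.shape != (aln.n_sequences,):
        raise ValidationError(
            f"need one weight per sequence ({aln.n_sequences}), got shape {w.shape}"
        )
    if np.any(w <= 0):
        raise ValidationError("sequence weights must be positive")
    return w


def _column_counts(
    codes: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted residue counts per column.

    Returns (counts[L, 20], non_gap_weight[L], gap_fraction[L]).
    """
    n, L = codes.shape
    counts = np.zeros((L, 20))
    for a in range(20):
        counts[:, a] = ((codes == a) * weights[:, None]).sum(axis=0)
    non_gap = counts.sum(axis=1)
    gap_fraction = (codes == GAP_CODE).mean(axis=0)
    return counts, non_gap, gap_fraction


def column_profile(
    aln: Alignment,
    col: int,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.0,
) -> ColumnProfile:
    """Weighted amino-acid profile of reference position ``col`` (1-based).

    p_a = (pseudocount + sum_s w_s [s has a at col])
          / (20*pseudocount + total non-gap weight).
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if not 1 <= col <= aln.n_columns:
        raise ValidationError(f"column {col} outside [1, {aln.n_columns}]")
    w = _weights_array(aln, weights)
    codes = aln.encoded()[:, col - 1]
    counts = np.array([w[codes == a].sum() for a in range(20)])
    non_gap_weight = counts.sum()
    if non_gap_weight == 0 and pseudocount == 0:
        raise DegenerateColumnError(
            f"column {col} is entirely gaps and pseudocount is 0"
        )
    denom = 20 * pseudocount + non_gap_weight
    freqs = (counts + pseudocount) / denom
    return ColumnProfile(
        frequencies=freqs,
        effective_count=non_gap_weight,
        gap_fraction=float((codes == GAP_CODE).mean()),
    )


def kl_conservation(
    aln: Alignment,
    background: BackgroundFrequencies | None = None,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.0,
) -> ScoreVector:
    """Kullback-Leibler conservation score per reference position, in bits.

    The returned vector is oriented higher-is-better.  Columns whose gap
    fraction exceeds 50% are still scored but listed in
    ``meta['flagged_gappy']``; per-column gap fractions are in
    ``meta['gap_fraction']``.  All-gap columns score NaN (with pseudocount
    0 there is no distribution to compare).
    """
    if not aln.is_trimmed:
        raise ValidationError("conservation requires a trimmed alignment")
    bg = background if background is not None else BackgroundFrequencies.default()
    w = _weights_array(aln, weights)
    codes = aln.encoded()
    counts, non_gap, gap_fraction = _column_counts(codes, w)
    denom = 20 * pseudocount + non_gap
    values = np.full(aln.n_columns, np.nan)
    ok = denom > 0
    p = np.zeros_like(counts)
    p[ok] = (counts[ok] + pseudocount) / denom[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / bg.frequencies[None, :])
    terms[p == 0] = 0.0  # 0 * log 0 convention
    values[ok] = terms[ok].sum(axis=1)
    if pseudocount == 0:
        values[non_gap == 0] = np.nan
    flagged = np.flatnonzero(gap_fraction > GAP_FLAG_FRACTION) + 1
    return ScoreVector(
        method_name="C",
        values=values,
        orientation="higher_better",
        meta={
            "gap_fraction": gap_fraction,
            "flagged_gappy": flagged.tolist(),
            "pseudocount": pseudocount,
            "background": bg.label,
        },
    )
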