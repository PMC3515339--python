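"""Pairwise mutual information, permutation Z-scores and cumulative MI.

Covariation between two alignment columns i, j is measured as mutual
information over their weighted joint amino-acid distribution,

    MI(i, j) = sum_ab p_ab log2( p_ab / (p_a p_b) ),

estimated from the sequences that are non-gap at both columns, with
inverse-cluster-size sequence weights (sequences single-linkage clustered
at 62% identity by default) and a small pseudocount lambda added to every
cell of the 20x20 joint count table to stabilize low counts.

Raw MI is biased by finite sampling and phylogeny, so significance is
calibrated with a column-shuffling null: residues are permuted
independently within each column (gap placement preserved), MI is
recomputed for each permutation, and each pair gets a Z-score against its
own null mean and standard deviation.  The per-residue *cumulative* MI
(cMI) is then the sum of a residue's MI values over the pairs whose
Z-score clears a threshold (default 6.5) — the residue's total share of
significant coevolution signal.

Implementation note: the whole L x L x 21 x 21 joint count tensor is
built in one weighted ``bincount`` over pair codes, which keeps the
permutation loop affordable for alignments of a few hundred sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .alignment import Alignment, GAP_CODE, ScoreVector, identity_matrix
from .errors import ValidationError

#: default pseudocount added to each joint count cell
DEFAULT_LAMBDA = 0.05
#: default Z-score cut-off for a pair to count toward cMI
DEFAULT_Z_THRESHOLD = 6.5
#: default number of column permutations for the null
DEFAULT_N_PERMUTATIONS = 100
#: pairs with fewer jointly non-gap sequences than this are not scored
DEFAULT_MIN_COVERAGE = 20


@dataclass
class SequenceWeights:
    """Inverse-cluster-size sequence weights.

    Sequences are single-linkage clustered at ``clustering_identity``;
    each sequence weighs 1/(size of its cluster), so a family dominated
    by near-duplicates is not counted many times over.
    """

    weights: np.ndarray
    clustering_identity: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any((self.weights <= 0) | (self.weights > 1)):
            raise ValidationError("weights must lie in (0, 1]")


@dataclass
class MIResult:
    """Symmetric pairwise MI and permutation Z-score matrices.

    ``mi`` and ``z`` are L x L with NaN on the diagonal and on pairs
    flagged missing (insufficient joint coverage; Z additionally NaN when
    the null standard deviation is zero).
    """

    mi: np.ndarray
    z: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return self.mi.shape[0]


def sequence_weights(
    aln: Alignment, clustering_identity: float = 0.62
) -> SequenceWeights:
    """Single-linkage cluster at >= ``clustering_identity``; weight 1/|cluster|."""
    if not 0.0 < clustering_identity <= 1.0:
        raise ValidationError("clustering identity must be in (0, 1]")
    ident = identity_matrix(aln)
    adj = csr_matrix(ident >= clustering_identity)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return SequenceWeights(
        weights=1.0 / sizes[labels], clustering_identity=clustering_identity
    )


# ---------------------------------------------------------------------------
# joint-count kernel
# ---------------------------------------------------------------------------

def _joint_counts(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted joint count tensor of shape (L, L, 20, 20).

    Cell [i, j, a, b] holds the summed weight of sequences carrying
    residue a at column i and residue b at column j; gapped entries drop
    out, so each pair's counts automatically run over the sequences
    non-gap at both columns.  Computed as X^T diag(w) X on the sparse
    one-hot expansion of the alignment — O(N L^2) for N sequences.
    """
    n, L = codes.shape
    nongap = codes != GAP_CODE
    rows, cols = np.nonzero(nongap)
    data = weights[rows]
    colidx = cols * 20 + codes[rows, cols]
    X = csr_matrix((data, (rows, colidx)), shape=(n, L * 20))
    C = (X.T @ X).toarray()
    return np.ascontiguousarray(
        C.reshape(L, 20, L, 20).transpose(0, 2, 1, 3)
    )


def _mi_from_counts(counts: np.ndarray, lam: float) -> np.ndarray:
    """MI matrix (bits) from a (L, L, 20, 20) joint count tensor; lambda-smoothed."""
    total = counts.sum(axis=(2, 3)) + 400.0 * lam
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (counts + lam) / total[:, :, None, None]
        pa = p.sum(axis=3)
        pb = p.sum(axis=2)
        log_term = np.log2(p) - np.log2(pa)[:, :, :, None] - np.log2(pb)[:, :, None, :]
        contrib = np.where(p > 0, p * log_term, 0.0)
    mi = contrib.sum(axis=(2, 3))
    mi[total <= 0] = np.nan
    return mi


def apply_apc(mi: np.ndarray) -> np.ndarray:
    """Average-product correction: MI(i,j) - MI(i,.)MI(.,j) / MI(.,.).

    Subtracts the background/phylogenetic component estimated from row
    and column means; corrected values can be negative.
    """
    m = np.where(np.isfinite(mi), mi, 0.0)
    counts = np.isfinite(mi).sum(axis=1)
    row_mean = np.divide(
        m.sum(axis=1), counts, out=np.zeros_like(counts, dtype=float),
        where=counts > 0,
    )
    overall = row_mean[counts > 0].mean() if (counts > 0).any() else 0.0
    if overall == 0:
        return mi.copy()
    corrected = mi - np.outer(row_mean, row_mean) / overall
    corrected[~np.isfinite(mi)] = np.nan
    return corrected


def mi_matrix(
    aln: Alignment,
    weights: SequenceWeights | np.ndarray | None = None,
    lam: float = DEFAULT_LAMBDA,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    apc: bool = False,
) -> MIResult:
    """All-pairs mutual information over reference positions.

    Pairs with fewer than ``min_coverage`` jointly non-gap sequences (and
    always fewer than 2) are flagged missing (NaN).  The diagonal is NaN.
    Significance calibration runs through permutation Z-scores
    (:func:`mi_zscores`); the average-product correction is off by
    default but available via ``apc`` (note APC-corrected values can be
    negative).
    """
    if not aln.is_trimmed:
        raise ValidationError("MI requires a trimmed alignment")
    if aln.n_columns < 2:
        raise ValidationError("MI requires at least two columns")
    if lam < 0:
        raise ValidationError("pseudocount lambda must be >= 0")
    codes = aln.encoded()
    w = _resolve_weights(aln, weights)
    joint = _joint_counts(codes, w)
    mi = _mi_from_counts(joint, lam)
    coverage = _joint_coverage(codes)
    mi[coverage < max(min_coverage, 2)] = np.nan
    np.fill_diagonal(mi, np.nan)
    if apc:
        mi = apply_apc(mi)
    return MIResult(
        mi=mi,
        z=None,
        params={
            "lambda": lam,
            "min_coverage": min_coverage,
            "apc": apc,
            "weights_identity": getattr(weights, "clustering_identity", None),
        },
    )


def _resolve_weights(
    aln: Alignment, weights: SequenceWeights | np.ndarray | None
) -> np.ndarray:
    if weights is None:
        return np.ones(aln.n_sequences)
    w = weights.weights if isinstance(weights, SequenceWeights) else np.asarray(weights, float)
    if w.shape != (aln.n_sequences,):
        raise ValidationError("one weight per sequence required")
    return w


def _joint_coverage(codes: np.ndarray) -> np.ndarray:
    """Number of sequences non-gap at both columns, for every column pair."""
    nongap = (codes != GAP_CODE).astype(np.float64)
    return nongap.T @ nongap


def _permute_within_columns(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle residues within each column among its non-gap rows."""
    out = codes.copy()
    n, L = codes.shape
    for j in range(L):
        col = codes[:, j]
        idx = np.flatnonzero(col != GAP_CODE)
        if len(idx) > 1:
            out[idx, j] = col[rng.permutation(idx)]
    return out


def mi_zscores(
    aln: Alignment,
    result: MIResult,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    weights: SequenceWeights | np.ndarray | None = None,
) -> MIResult:
    """Fill the permutation Z-score matrix of an :class:`MIResult`.

    The null shuffles residues independently within each column (gap
    placement preserved) and recomputes the full MI matrix per
    permutation.  z = (MI_obs - mean_null) / sd_null; pairs whose null
    standard deviation is zero (e.g. fully conserved columns) get NaN.
    Deterministic given ``seed``.
    """
    if n_permutations < 2:
        raise ValidationError("need at least 2 permutations")
    codes = aln.encoded()
    w = _resolve_weights(aln, weights)
    lam = result.params.get("lambda", DEFAULT_LAMBDA)
    L = aln.n_columns
    rng = np.random.default_rng(seed)
    acc = np.zeros((L, L))
    acc2 = np.zeros((L, L))
    use_apc = bool(result.params.get("apc"))
    for _ in range(n_permutations):
        perm = _permute_within_columns(codes, rng)
        mi_null = _mi_from_counts(_joint_counts(perm, w), lam)
        if use_apc:
            mi_null = apply_apc(mi_null)
        acc += mi_null
        acc2 += mi_null * mi_null
    mean = acc / n_permutations
    var = acc2 / n_permutations - mean * mean
    var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (result.mi - mean) / sd
    z[sd == 0] = np.nan
    np.fill_diagonal(z, np.nan)
    params = dict(result.params)
    params.update({"n_permutations": n_permutations, "seed": seed})
    return MIResult(mi=result.mi, z=z, params=params)


def cumulative_mi(
    result: MIResult, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> ScoreVector:
    """Cumulative MI per residue: sum of its MI over significant pairs.

    cMI_i = sum over j != i with z[i, j] > z_threshold of MI(i, j).
    Residues with no significant partner score 0.
    """
    if result.z is None:
        raise ValidationError("Z-scores not computed; run mi_zscores first")
    passing = np.where(
        np.isfinite(result.z) & (result.z > z_threshold) & np.isfinite(result.mi),
        result.mi,
        0.0,
    )
    values = passing.sum(axis=1)
    return ScoreVector(
        method_name="cMI",
        values=values,
        orientation="higher_better",
        meta={"z_threshold": z_threshold, **result.params},
    )


def write_mi_table(result: MIResult, path) -> None:
    """Write the upper-triangle MI/Z table as ``i<TAB>j<TAB>mi<TAB>z``."""
    z = result.z
    with open(path, "w") as fh:
        fh.write("# i\tj\tmi\tz\n")
        L = result.n_positions
        for i in range(L):
            for j in range(i + 1, L):
                if np.isnan(result.mi[i, j]):
                    continue
                zval = "nan" if z is None or np.isnan(z[i, j]) else f"{z[i, j]:.6g}"
                fh.write(f"{i + 1}\t{j + 1}\t{result.mi[i, j]:.6g}\t{zval}\n")
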