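"""Per-family ROC evaluation, binomial sign tests and method concordance.

Predictive performance for catalytic-residue detection is measured per
family: annotated catalytic residues are positives, everything else
negative.  AUC uses the Mann-Whitney formulation (ties get half credit);
AUC0.1 integrates the ROC curve up to a false-positive rate of 0.1
(specificity 1 down to 0.9) and is reported on a normalized [0, 1] scale
(area / 0.1), so an uninformative score gives 0.05 and a perfect one 1.
Methods are ranked against each other with a one-tailed exact binomial
sign test over per-family AUC wins, excluding ties, and their mutual
overlap is summarized as per-family Spearman rank correlations averaged
over families, clustered with average linkage on 1 - SCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import UndefinedMetricError, ValidationError
from .family import FamilyRecord


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != len(labels):
        raise ValidationError("labels must be binary 0/1")
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined with {n_pos} positives and {n_neg} negatives"
        )
    return n_pos, n_neg


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    (concordant pairs + 0.5 * tied pairs) / (P * N), computed through
    average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    if np.any(~np.isfinite(scores)):
        raise ValidationError("scores must be finite (drop missing first)")
    n_pos, n_neg = _check_classes(labels)
    ranks = stats.rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points of the empirical ROC curve, tie groups collapsed.

    Starts at (0, 0) and ends at (1, 1); tied scores form a single
    vertex, so the curve runs diagonally through tie blocks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # keep only the last index of each tied-score block
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    return fpr, tpr


def partial_auc(
    scores: Sequence[float], labels: Sequence[int], fpr_max: float = 0.1
) -> float:
    """Normalized partial AUC: trapezoidal ROC area over FPR [0, fpr_max] / fpr_max.

    With fpr_max = 0.1 this is the high-specificity summary AUC0.1; an
    uninformative score gives 0.05 and a perfect one 1.0.
    ``partial_auc(..., 1.0)`` equals :func:`roc_auc`.
    """
    if not 0 < fpr_max <= 1:
        raise ValidationError("fpr_max must be in (0, 1]")
    fpr, tpr = roc_curve(np.asarray(scores, float), np.asarray(labels))
    # interpolate the curve at fpr_max, then trapezoid
    cut = np.searchsorted(fpr, fpr_max, side="right")
    fx = fpr[:cut]
    ty = tpr[:cut]
    if fx[-1] < fpr_max:
        # linear interpolation on the segment crossing fpr_max
        i = cut - 1
        if i + 1 < len(fpr):
            frac = (fpr_max - fpr[i]) / (fpr[i + 1] - fpr[i])
            ty = np.r_[ty, tpr[i] + frac * (tpr[i + 1] - tpr[i])]
            fx = np.r_[fx, fpr_max]
    area = np.trapezoid(ty, fx)
    return float(area / fpr_max)


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    precision: float


def operating_point(
    scores: Sequence[float], labels: Sequence[int], sensitivity_target: float
) -> OperatingPoint:
    """Highest score threshold reaching the target sensitivity.

    Predictions are positive where score >= threshold.  Scanning
    candidate thresholds from the most to the least stringent, the first
    one with sensitivity >= target is reported together with the
    specificity and precision achieved there.
    """
    if not 0 < sensitivity_target <= 1:
        raise ValidationError("sensitivity target must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_classes(labels)
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        sens = tp / n_pos
        if sens >= sensitivity_target:
            fp = int((pred & (labels == 0)).sum())
            return OperatingPoint(
                threshold=float(thr),
                sensitivity=sens,
                specificity=1.0 - fp / n_neg,
                precision=tp / (tp + fp) if tp + fp else 0.0,
            )
    raise ValidationError(
        f"sensitivity {sensitivity_target} unreachable"
    )  # pragma: no cover - sens=1 always reachable at min threshold


@dataclass
class SignTestResult:
    p_value: float | None
    n_wins: int
    n_losses: int
    n_ties: int

    @property
    def n_informative(self) -> int:
        return self.n_wins + self.n_losses


def binomial_sign_test(
    aucs_A: Sequence[float], aucs_B: Sequence[float]
) -> SignTestResult:
    """One-tailed exact binomial sign test that method A beats method B.

    Per-family comparisons; ties excluded.  p = P(X >= wins | n, 1/2)
    where n counts non-tied families.  All-tie input yields p = None.
    """
    a = np.asarray(aucs_A, dtype=float)
    b = np.asarray(aucs_B, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValidationError("need two equal-length non-empty vectors")
    wins = int((a > b).sum())
    losses = int((a < b).sum())
    ties = len(a) - wins - losses
    n = wins + losses
    if n == 0:
        return SignTestResult(p_value=None, n_wins=0, n_losses=0, n_ties=ties)
    p = float(stats.binom.sf(wins - 1, n, 0.5))
    return SignTestResult(p_value=p, n_wins=wins, n_losses=losses, n_ties=ties)


@dataclass
class FamilyEvaluation:
    family_id: str
    method: str
    auc: float
    auc01: float
    n_positives: int
    n_negatives: int


def evaluate_family(fam: FamilyRecord, method: str) -> FamilyEvaluation:
    """AUC and AUC0.1 of one cached score against the family annotation."""
    if method not in fam.scores:
        raise ValidationError(f"{fam.family_id}: no cached score {method!r}")
    score = fam.scores[method]
    y = fam.labels()
    s = score.oriented_values()
    ok = np.isfinite(s)
    n_pos, n_neg = _check_classes(y[ok])
    return FamilyEvaluation(
        family_id=fam.family_id,
        method=method,
        auc=roc_auc(s[ok], y[ok]),
        auc01=partial_auc(s[ok], y[ok], 0.1),
        n_positives=n_pos,
        n_negatives=n_neg,
    )


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceMatrix:
    """Mean per-family Spearman correlation between methods, with spread."""

    methods: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_families: np.ndarray
    min_shared_positions: int = 3


def spearman_concordance(
    families: list[FamilyRecord],
    methods: list[str],
    min_shared_positions: int = 3,
) -> ConcordanceMatrix:
    """Per-method-pair Spearman rho, averaged over families.

    For each family and method pair, rho is computed on the reference
    positions where both scores are non-missing (average ranks on ties);
    families contributing fewer than ``min_shared_positions`` shared
    positions are skipped for that pair.  Rank-like scores are compared
    on their negated (higher-is-better) scale.
    """
    K = len(methods)
    mean = np.full((K, K), np.nan)
    sd = np.full((K, K), np.nan)
    nfam = np.zeros((K, K), dtype=int)
    for i in range(K):
        mean[i, i] = 1.0
        sd[i, i] = 0.0
        nfam[i, i] = len(families)
    for i in range(K):
        for j in range(i + 1, K):
            rhos = []
            for fam in families:
                if methods[i] not in fam.scores or methods[j] not in fam.scores:
                    continue
                a = fam.scores[methods[i]].oriented_values()
                b = fam.scores[methods[j]].oriented_values()
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() < min_shared_positions:
                    continue
                rho = stats.spearmanr(a[ok], b[ok]).statistic
                if np.isfinite(rho):
                    rhos.append(rho)
            if rhos:
                mean[i, j] = mean[j, i] = float(np.mean(rhos))
                sd[i, j] = sd[j, i] = float(np.std(rhos, ddof=0))
                nfam[i, j] = nfam[j, i] = len(rhos)
    return ConcordanceMatrix(
        methods=list(methods),
        mean=mean,
        sd=sd,
        n_families=nfam,
        min_shared_positions=min_shared_positions,
    )


@dataclass
class MethodDendrogram:
    methods: list[str]  # sorted order used for clustering
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.methods[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def cluster_methods(c: ConcordanceMatrix) -> MethodDendrogram:
    """Average-linkage clustering of methods on distance 1 - SCC.

    Methods are sorted by name before clustering so that equal-distance
    merges resolve deterministically.
    """
    order = sorted(range(len(c.methods)), key=lambda i: c.methods[i])
    methods = [c.methods[i] for i in order]
    m = c.mean[np.ix_(order, order)].copy()
    m = np.where(np.isnan(m), 0.0, m)
    dist = 1.0 - m
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return MethodDendrogram(methods=methods, linkage_matrix=Z)
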