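"""Catalytic-likeliness score: weighted combination of conservation
with proximity scores, and simplex grid search under cross-validation.

The combined score of residue i is

    S_i = (1 - sum_k w_k) * C_i + sum_k sign_k * w_k * X_{k,i}

with weights w_k >= 0 on the simplex (sum <= 1), C the per-family
min-max normalized conservation, and X_k the normalized added features
(proximity scores, external method scores).  sign_k is -1 for rank-like
components supplied raw (Evolutionary Trace ranks, where the best rank
is the smallest number) and +1 otherwise; features already negated by
the proximity module enter with +1.

Weights are optimized by exhaustive enumeration of the simplex grid at a
fixed step (default 0.05), maximizing mean per-family AUC, with 5-fold
cross-validation over families to estimate generalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alignment import ScoreVector
from .errors import UndefinedMetricError, ValidationError
from .family import FamilyRecord


@dataclass
class CombinedModel:
    """Component names, signs and simplex weights of a combined score."""

    components: list[tuple[str, int]]  # (score name, sign in {+1, -1})
    weights: list[float]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights):
            raise ValidationError("one weight per component required")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-12) or w.sum() > 1 + 1e-9:
            raise ValidationError(
                f"weights must be >= 0 and sum <= 1, got {self.weights}"
            )
        for name, sign in self.components:
            if sign not in (1, -1):
                raise ValidationError(f"sign for {name!r} must be +1 or -1")

    @property
    def conservation_weight(self) -> float:
        return 1.0 - float(np.sum(self.weights))


def minmax_normalize(score: ScoreVector) -> ScoreVector:
    """Per-family [0, 1] normalization: (x - min) / (max - min).

    Computed over non-missing values; a constant vector maps to all 0.5
    (it carries no ranking information either way).  Rank-like scores are
    negated first so that 1 is always "most important".
    """
    values = score.oriented_values()
    finite = np.isfinite(values)
    if not finite.any():
        raise ValidationError(f"{score.method_name}: all values missing")
    lo = values[finite].min()
    hi = values[finite].max()
    out = np.full_like(values, np.nan)
    if hi > lo:
        out[finite] = (values[finite] - lo) / (hi - lo)
    else:
        out[finite] = 0.5
    return ScoreVector(
        method_name=score.method_name,
        values=out,
        orientation="higher_better",
        meta={**score.meta, "normalized": True},
    )


def combined_score(
    C: ScoreVector,
    model: CombinedModel,
    components: dict[str, ScoreVector],
) -> ScoreVector:
    """Evaluate the combined score S for one family.

    All inputs are expected per-family normalized (see
    :func:`minmax_normalize`).  A missing component value at a position
    makes S missing there.
    """
    L = len(C)
    S = model.conservation_weight * C.values.copy()
    for (name, sign), w in zip(model.components, model.weights):
        if name not in components:
            raise ValidationError(f"component {name!r} not supplied")
        x = components[name]
        if len(x) != L:
            raise ValidationError(f"component {name!r} length mismatch")
        S = S + sign * w * x.values
    label = " + ".join(
        [f"{model.conservation_weight:.2g} {C.method_name}"]
        + [
            f"{'-' if s < 0 else ''}{w:.2g} {n}"
            for (n, s), w in zip(model.components, model.weights)
        ]
    )
    return ScoreVector(
        method_name=label, values=S, orientation="higher_better"
    )


def simplex_grid(n_components: int, step: float) -> list[tuple[float, ...]]:
    """All weight vectors with entries in {0, step, 2*step, ...} summing <= 1.

    Enumerated in lexicographic order, which fixes tie-breaking in the
    grid search.
    """
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValidationError(f"step {step} does not divide 1")
    grid = []
    for combo in itertools.product(range(n_steps + 1), repeat=n_components):
        if sum(combo) <= n_steps:
            grid.append(tuple(round(c * step, 10) for c in combo))
    return grid


@dataclass
class GridSearchResult:
    weights: tuple[float, ...]  # full-data optimum
    full_data_auc: float
    cv_mean_auc: float
    fold_weights: list[tuple[float, ...]]
    fold_test_auc: list[float]
    components: list[tuple[str, int]]
    step: float
    seed: int
    folds: int


def _family_design(
    fam: FamilyRecord,
    conservation_name: str,
    components: list[tuple[str, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(C vector, component matrix with signs applied, labels), normalized."""
    C = minmax_normalize(fam.scores[conservation_name]).values
    X = np.column_stack(
        [sign * minmax_normalize(fam.scores[name]).values for name, sign in components]
    )
    return C, X, fam.labels()


def _mean_auc(
    designs: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    weights: np.ndarray,
) -> float:
    from .evaluation import roc_auc

    w_c = 1.0 - weights.sum()
    aucs = []
    for C, X, y in designs:
        S = w_c * C + X @ weights
        ok = np.isfinite(S)
        try:
            aucs.append(roc_auc(S[ok], y[ok]))
        except UndefinedMetricError:
            continue
    if not aucs:
        raise UndefinedMetricError("no family yields a defined AUC")
    return float(np.mean(aucs))


def grid_search_weights(
    families: list[FamilyRecord],
    components: list[tuple[str, int]],
    conservation_name: str = "C",
    step: float = 0.05,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive simplex grid search for combination weights.

    Per cross-validation split, the weights maximizing mean per-family
    AUC on the training families are selected and their AUC on the held
    out families recorded; the headline weights are the argmax over all
    families.  Fold assignment shuffles families once with ``seed`` and
    cuts the shuffled list into ``folds`` contiguous folds.  Ties between
    weight vectors break toward the lexicographically first.
    """
    if len(families) < folds:
        raise ValidationError(f"need >= {folds} families for {folds}-fold CV")
    designs = [_family_design(f, conservation_name, components) for f in families]
    grid = [np.asarray(w) for w in simplex_grid(len(components), step)]

    def argmax(subset: list[int]) -> tuple[np.ndarray, float]:
        sub = [designs[i] for i in subset]
        best_w, best_auc = None, -np.inf
        for w in grid:
            auc = _mean_auc(sub, w)
            if auc > best_auc + 1e-12:
                best_w, best_auc = w, auc
        return best_w, best_auc

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(families))
    fold_ids = np.array_split(order, folds)
    fold_weights: list[tuple[float, ...]] = []
    fold_test: list[float] = []
    for k in range(folds):
        test = list(fold_ids[k])
        train = [i for j in range(folds) if j != k for i in fold_ids[j]]
        w_k, _ = argmax(train)
        fold_weights.append(tuple(float(x) for x in w_k))
        fold_test.append(_mean_auc([designs[i] for i in test], w_k))
    full_w, full_auc = argmax(list(range(len(families))))
    return GridSearchResult(
        weights=tuple(float(x) for x in full_w),
        full_data_auc=full_auc,
        cv_mean_auc=float(np.mean(fold_test)),
        fold_weights=fold_weights,
        fold_test_auc=fold_test,
        components=list(components),
        step=step,
        seed=seed,
        folds=folds,
    )
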