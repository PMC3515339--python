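"""High-level orchestration: load family directories, score them, and
reproduce the standard analysis tables (proximity threshold scan,
combined-model cross-validation, method concordance)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import read_alignment, read_annotation, trim_to_reference
from .coevolution import (
    cumulative_mi,
    mi_matrix,
    mi_zscores,
    sequence_weights,
)
from .combine import CombinedModel, combined_score, grid_search_weights, minmax_normalize
from .conservation import BackgroundFrequencies, kl_conservation
from .errors import InputError
from .evaluation import (
    binomial_sign_test,
    cluster_methods,
    evaluate_family,
    spearman_concordance,
)
from .family import FamilyRecord
from .proximity import ProximityParams, optimize_threshold, proximity_score
from .structure import read_structure


def load_family_dir(
    path: str | Path, chain: str = "A", reference_id: str | None = None
) -> FamilyRecord:
    """Load one family directory (alignment.fasta, structure.pdb, catalytic.txt)."""
    d = Path(path)
    aln_path = d / "alignment.fasta"
    if not aln_path.exists():
        raise InputError(f"{d}: no alignment.fasta")
    aln = read_alignment(aln_path, "fasta", reference_id=reference_id)
    if aln.reference_id is None:
        aln.reference_id = aln.ids[0]
    aln = trim_to_reference(aln)
    structure = None
    pdb = d / "structure.pdb"
    if pdb.exists():
        structure = read_structure(pdb, chain=chain)
    annotation = None
    ann = d / "catalytic.txt"
    if ann.exists():
        annotation = read_annotation(ann, aln.n_columns)
    return FamilyRecord(
        family_id=d.name,
        alignment=aln,
        structure=structure,
        annotation=annotation,
        provenance={"dir": str(d)},
    )


def load_benchmark(path: str | Path) -> list[FamilyRecord]:
    """Load every family listed in a benchmark manifest.json."""
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    return [
        load_family_dir(
            root / entry["dir"],
            chain=entry.get("chain", "A"),
            reference_id=entry.get("reference_id"),
        )
        for entry in manifest
    ]


def compute_standard_scores(
    fam: FamilyRecord,
    background: BackgroundFrequencies | None = None,
    lam: float = 0.05,
    n_permutations: int = 100,
    z_threshold: float = 6.5,
    weights_identity: float = 0.62,
    seed: int = 0,
    use_sequence_weights: bool = False,
) -> FamilyRecord:
    """Attach conservation (C) and cumulative MI (cMI) scores to a family.

    Sequence weighting for MI is optional (inverse-cluster-size at 62%
    identity); uniform weights are the default since the synthetic star
    phylogeny produces no redundancy to down-weight.
    """
    weights = sequence_weights(fam.alignment, weights_identity) if use_sequence_weights else None
    fam.add_score(kl_conservation(fam.alignment, background))
    mi = mi_matrix(fam.alignment, weights=weights, lam=lam)
    mi = mi_zscores(fam.alignment, mi, n_permutations=n_permutations, seed=seed, weights=weights)
    fam.add_score(cumulative_mi(mi, z_threshold=z_threshold))
    return fam


def attach_proximity(
    fam: FamilyRecord, source: str, threshold: float, include_self: bool = True
) -> str:
    """Cache p(source) at the given threshold; returns the cached name."""
    params = ProximityParams(threshold=threshold, include_self=include_self)
    prox = proximity_score(fam.scores[source], fam.distances, fam.mapping, params)
    fam.add_score(prox)
    return prox.method_name


@dataclass
class BenchmarkReport:
    threshold_table: pd.DataFrame  # method x threshold mean AUC + best t
    model_table: pd.DataFrame  # combined models: weights, AUC, AUC0.1
    per_family: pd.DataFrame  # family x method AUC / AUC0.1
    concordance: pd.DataFrame  # method x method mean Spearman rho
    dendrogram_newick: str
    sign_tests: pd.DataFrame


def evaluate_benchmark(
    families: list[FamilyRecord],
    methods: tuple[str, ...] = ("C", "cMI"),
    step: float = 0.05,
    folds: int = 5,
    seed: int = 0,
) -> BenchmarkReport:
    """Run the full analysis on scored families.

    1. scan the distance grid for each method's proximity score and keep
       the best threshold;
    2. grid-search combination weights (5-fold CV) for conservation plus
       the proximity scores, and tabulate AUC / AUC0.1 per model;
    3. per-family Spearman concordance between all scores, with an
       average-linkage dendrogram;
    4. one-tailed binomial sign tests of every model against
       conservation alone.
    """
    rows = []
    best_t: dict[str, float] = {}
    for m in methods:
        scan = optimize_threshold(families, m)
        best_t[m] = scan.best_threshold
        rows.append({"method": f"p({m})", **{f"{t:g}A": v for t, v in scan.table.items()},
                     "best_t": scan.best_threshold})
    threshold_table = pd.DataFrame(rows).set_index("method")

    prox_names = []
    for m in methods:
        for fam in families:
            name = attach_proximity(fam, m, best_t[m])
        prox_names.append(name)

    # conservation-only baseline
    model_rows = []
    base_aucs = []
    base_aucs01 = []
    for fam in families:
        ev = evaluate_family(fam, "C")
        base_aucs.append(ev.auc)
        base_aucs01.append(ev.auc01)
    model_rows.append(
        {"model": "C", "weights": "", "auc": float(np.mean(base_aucs)),
         "auc01": float(np.mean(base_aucs01)), "cv_auc": np.nan}
    )

    sign_rows = []
    combos = [[p] for p in prox_names]
    if len(prox_names) > 1:
        combos.append(list(prox_names))
    for combo in combos:
        comps = [(p, 1) for p in combo]
        gs = grid_search_weights(
            families, comps, conservation_name="C", step=step, folds=folds, seed=seed
        )
        model = CombinedModel(components=comps, weights=list(gs.weights))
        aucs, aucs01 = [], []
        for fam in families:
            comp_scores = {p: minmax_normalize(fam.scores[p]) for p in combo}
            S = combined_score(minmax_normalize(fam.scores["C"]), model, comp_scores)
            fam.add_score(S)
            ev = evaluate_family(fam, S.method_name)
            aucs.append(ev.auc)
            aucs01.append(ev.auc01)
        label = " + ".join([f"{model.conservation_weight:.2g} C"] +
                           [f"{w:.2g} {p}" for p, w in zip(combo, gs.weights)])
        model_rows.append(
            {"model": label, "weights": gs.weights, "auc": float(np.mean(aucs)),
             "auc01": float(np.mean(aucs01)), "cv_auc": gs.cv_mean_auc}
        )
        st = binomial_sign_test(aucs, base_aucs)
        sign_rows.append(
            {"model": label, "baseline": "C", "wins": st.n_wins,
             "losses": st.n_losses, "ties": st.n_ties, "p_value": st.p_value}
        )

    all_methods = list(dict.fromkeys(["C", *methods, *prox_names]))
    per_family_rows = []
    for fam in families:
        for m in all_methods:
            ev = evaluate_family(fam, m)
            per_family_rows.append(
                {"family": fam.family_id, "method": m, "auc": ev.auc,
                 "auc01": ev.auc01, "n_positives": ev.n_positives,
                 "n_negatives": ev.n_negatives}
            )
    conc = spearman_concordance(families, all_methods)
    concordance = pd.DataFrame(conc.mean, index=conc.methods, columns=conc.methods)
    dendro = cluster_methods(conc)

    return BenchmarkReport(
        threshold_table=threshold_table,
        model_table=pd.DataFrame(model_rows).set_index("model"),
        per_family=pd.DataFrame(per_family_rows),
        concordance=concordance,
        dendrogram_newick=dendro.to_newick(),
        sign_tests=pd.DataFrame(sign_rows),
    )
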