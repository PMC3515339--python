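# Methods

## Scope and data model

`evosig` operates on *families*: a trimmed multiple sequence alignment
with a designated reference sequence, a 3D structure for that
reference, and a set of annotated catalytic residues. All scores are
vectors over 1-based reference positions (the CSA/PDB convention).
Alignments are trimmed by deleting every column in which the reference
carries a gap, so reference positions are contiguous; other sequences
keep their gaps in the surviving columns.

## Conservation

Per-column conservation is the Kullback–Leibler relative entropy of the
weighted column amino-acid distribution against a background
distribution, in bits (base-2 logarithm; the base is a convention
choice — bits are standard for information scores). The packaged
background is the Swiss-Prot amino-acid composition, renormalized to
sum to one; any 20-row `aa<TAB>frequency` table can be substituted.
Defaults: pseudocount 0 and uniform sequence weights (conservation is
normally computed on the full-redundancy alignment, where counts are
large); both are configurable, including sharing the MI weights.
Columns with more than 50% gaps are scored but flagged rather than
dropped — gap treatment is left to the caller. All-gap columns score
NaN at pseudocount 0. Non-standard residues (B, Z, X, U, O, J) are
treated as gaps everywhere to avoid inflating the alphabet.

## Coevolution

Pairwise MI uses weighted joint frequencies over the sequences non-gap
at both columns, smoothed by adding λ = 0.05 to every cell of the
20×20 joint count table. Sequence weights are 1/(cluster size) after
single-linkage clustering at 62% identity — the standard redundancy
correction for MI estimation; uniform weights are the default in the
synthetic setting (a star phylogeny has no redundancy structure to
down-weight). Identity between gapped sequences counts matches over
columns where at least one sequence is non-gap, which penalizes indels
mildly.

Finite alignments inflate raw MI, so significance is calibrated by a
permutation null: residues are shuffled independently within each
column (gap placement preserved — marginals and gap structure are
exactly conserved), the full MI matrix is recomputed per permutation,
and each pair is scored as Z = (MI − mean_null)/sd_null. The default
is 100 permutations; validation runs in this repository use 25–30,
because the planted-pair Z margins are tens of standard deviations and
the reduced null sample changes only runtime. Pairs whose null is
degenerate (e.g. fully conserved columns, sd = 0) get an undefined Z.
Pairs covered by fewer than 20 jointly non-gap sequences are flagged
missing rather than scored — the MI estimate is too unstable there.

Cumulative MI is cMI_i = Σ MI(i,j) over the partners j with
Z(i,j) > 6.5. The 6.5 cut-off, λ = 0.05 and permutation count follow
the established cMI methodology and remain configurable. An optional
average-product correction (APC) is available on the MI matrix (off by
default — the Z-score calibration already absorbs the background
component; note APC-corrected MI can be negative, and when enabled the
permutation null is APC-corrected as well).

The joint-count kernel builds the full L×L×20×20 count tensor as
XᵀWX on a sparse one-hot expansion of the alignment (O(N·L²)), which
keeps the permutation loop affordable: one permutation of a
500-sequence, 100-column family costs ~0.3 s on one core.

## Structure and proximity

Residue–residue distance is the minimum Euclidean distance between any
two heavy (non-hydrogen, including side-chain) atoms, in Å. This
closest-approach distance violates the triangle inequality by
construction; nothing downstream assumes it. Structures are read from
PDB files: first model, one chain, waters and heteroatoms excluded
except selenomethionine (treated as methionine), alternate locations
resolved to the highest-occupancy conformer (ties: first listed).

Reference positions are mapped onto structure residues by global
Needleman–Wunsch (match +1, mismatch −1, gap open −5, extend −0.5) of
the reference sequence against the sequence read off the structure.
Both aligned identities and substitutions map; the mapping is rejected
if it covers <30% of the reference or if <30% of aligned pairs are
identical (a global aligner pairs even unrelated equal-length sequences
end to end, so coverage alone cannot catch a wrong structure).
Unresolved residues simply receive no proximity contribution and are
flagged missing in proximity output.

The proximity score of residue i sums a per-residue score over all
mapped residues j with d_ij < t (strict inequality, per the defining
formula). The residue's own score is included by default: d_ii = 0
satisfies the distance condition literally, though the prose reading
("residues located within a certain distance *from* the residue") is
ambiguous — `include_self` is exposed as a flag. Rank-like
(lower-is-better) inputs are negated before summation so proximity
output is uniformly higher-is-better. The threshold is optimized on
the fixed grid {3,…,12} Å by maximizing mean per-family AUC, ties
resolved toward the smaller threshold.

## Combination

Each component (and conservation itself) is min–max normalized to
[0, 1] per family before weighting; normalizing conservation the same
way as the added features keeps weights comparable across families
(whether the original protocol normalized conservation too is
unknowable from its description; this is the symmetric choice).
Constant vectors normalize to all-0.5 — they carry no ranking
information either way. The combined score is
S = (1 − Σw_k)·C + Σ_k sign_k·w_k·X_k with weights on the simplex;
sign_k = −1 for rank-like components supplied raw, +1 otherwise (the
proximity module already negates rank inputs, in which case the sign
is +1 and the model records which convention applied).

Weights come from exhaustive enumeration of the simplex grid at step
0.05 (every published optimum of this kind of weighting is a multiple
of 0.05), maximizing mean per-family AUC. Ties break toward the
lexicographically first weight vector — consequently, when a component
saturates the objective (AUC 1), the search reports the *smallest*
weight achieving the maximum, not the largest. Cross-validation
shuffles families once with the given seed into 5 contiguous folds;
per fold, weights are fit on the training families and scored on the
held-out ones; the headline weights are the full-data argmax.

## Evaluation

AUC is the Mann–Whitney statistic (ties half credit). AUC0.1
integrates the empirical ROC curve (tie groups form diagonal segments)
from FPR 0 to 0.1 and divides by 0.1, so the reported value lives on
[0, 1] with chance level 0.05; the simple ratio is used rather than
McClish standardization for transparency. Overall performance is the
unweighted mean of per-family AUCs. Operating points report
specificity and precision at the most stringent score threshold whose
sensitivity reaches the target. Method ranking uses the one-tailed
exact binomial sign test over per-family AUC wins, ties excluded
(p = P(X ≥ wins | n, ½)); all-tie comparisons are reported as
undefined rather than given a p-value. Concordance is the per-family
Spearman rank correlation on positions where both methods are
non-missing (≥3 shared positions required), averaged unweighted over
families with its standard deviation; methods are clustered by
average linkage on 1 − SCC, with method names sorted beforehand so
equal-height merges resolve deterministically.

## Synthetic families

The generator draws sequences i.i.d. given the column model (a star
phylogeny — no tree structure in v1; tree-shaped generation is a noted
extension). Column types: background (i.i.d. from the background
distribution), conserved (one residue, per-sequence mutation rate
0.05), coevolving pairs (two concordant residue combinations with
probability = coupling strength 0.9, otherwise independent background
draws), and SDP-like columns (sequences split into groups, one fixed
residue per group). Catalytic residues get weakly conserved columns
(mutation rate 0.2 by default, or plain background columns when that
rate is set to None), so conservation is an informative but imperfect
predictor — the regime in which structural integration has something
to add. Defaults (500 sequences × 100 columns, 8 conserved, 5
coevolving pairs, 4 SDP columns in 3 groups, 3 catalytic residues)
describe a mid-sized enzymatic family.

The toy structure has one pseudo-atom per residue (min heavy-atom
distance then degenerates gracefully to point distance and the
geometry stays fully controllable): non-signal residues lie on a
jittered chain, each catalytic residue sits at an isolated centre, and
the planted signal columns are placed 3.2 Å (just above heavy-atom
contact distance — closer would be a clash) to radius − 0.2 Å from
their centre, with every non-neighbour guaranteed ≥ radius + 2 Å from
every centre. Ground truth (column roles, neighbour assignments) is
written to a truth JSON so tests never reverse-engineer the generator.

What the generator does *not* emulate: phylogenetic correlation
between sequences (the classic confounder of MI), gaps, real side-chain
geometry and packing, realistic family-size distributions, or
correlated annotation errors. Passing tests therefore demonstrate that
the estimators recover the signals they target under a clean
generative model — not field performance on real families. One
realistic confound is retained deliberately: SDP columns genuinely
share mutual information with each other (group structure), so they
compete with planted pairs for top Z-scores; pair-recovery checks use
configs without SDP columns, while the benchmark-level evaluations
keep them.

## Validation problem sizes

The stochastic validation suite uses: 20 families of 500×100 for
planted-pair and conserved-column recovery (25 permutations); 20
replicates of 150×60 for threshold recovery at radius 6 Å; a
20-family jittered benchmark at default size for the
combined-vs-conservation sign test. The acceptance script runs 10
recovery families and a 12-family benchmark at the same sizes.

## Known limitations

- Redundancy reduction is greedy (Hobohm-1 style, reference first,
  then input order): deterministic and order-stable, but membership of
  the reduced set is not bit-compatible with any particular external
  clustering tool.
- Single chain, single model; no mmCIF, no assemblies, no
  solvent-accessibility terms.
- No direct-coupling / pseudolikelihood coevolution models and no
  tree-aware MI corrections.
- Per-family weighting of the combined score is global (one weight
  vector for the whole collection), matching the published protocol.
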