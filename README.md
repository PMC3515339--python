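# evosig

Disentangling evolutionary signals in protein families — conservation,
coevolution and specificity — and turning them into structure-aware
predictions of catalytic residues.

## The problem

A multiple sequence alignment (MSA) of an enzyme family superimposes
several distinct evolutionary signals:

- **conservation** — columns under purifying selection across the whole
  family;
- **coevolution** — column pairs whose residues mutate in a correlated,
  compensatory fashion;
- **specificity determining positions (SDPs)** — columns conserved
  *within* functional subgroups but different *between* them.

Catalytic residues (CR) are only partially explained by any single
signal: they are often just moderately conserved, but their spatial
neighbourhood in the 3D structure is rich in conserved and coevolving
positions. `evosig` computes the individual signals, projects any
per-residue score through the structure, combines the pieces into a
single catalytic-likeliness score, and evaluates everything per family
with ROC statistics.

## The model

Per reference position *i* (1-based positions in the ungapped reference
sequence of a trimmed family alignment):

- **Conservation** `C_i = Σ_a p_a(i) log2(p_a(i)/q_a)` — Kullback–Leibler
  relative entropy (bits) of the column's amino-acid distribution
  against a background distribution `q` (Swiss-Prot composition by
  default).
- **Coevolution** — pairwise mutual information
  `MI(i,j) = Σ_ab p_ab log2(p_ab/(p_a p_b))` with inverse-cluster-size
  sequence weights and a pseudocount λ = 0.05; significance from a
  within-column permutation null (Z-scores); **cumulative MI**
  `cMI_i = Σ_{j: Z(i,j) > 6.5} MI(i,j)`.
- **Proximity scores** `p(X)_i = Σ_{j: d_ij < t} X_j`, where `d_ij` is the
  minimum heavy-atom distance (Å) between residues i and j and `t` is
  picked from the grid 3–12 Å by maximizing mean per-family AUC.
- **Combined score** `S_i = (1 − Σ_k w_k)·C_i + Σ_k ±w_k·X_{k,i}` over
  per-family min–max normalized components (minus sign for rank-like
  inputs such as Evolutionary Trace ranks, where the best rank is the
  smallest number); weights found by exhaustive simplex grid search
  (step 0.05) under 5-fold cross-validation over families.
- **Evaluation** — per-family AUC and normalized partial AUC up to FPR
  0.1 (AUC0.1), one-tailed exact binomial sign tests excluding ties,
  and per-family Spearman concordance between methods with
  average-linkage clustering.

External method outputs (rvET/ivET/SDPfox/XDET and the like) are
ingested as generic `pos<TAB>score` tables with an explicit
orientation, so they flow through the same proximity/combination
machinery.

A synthetic-family generator produces complete benchmarks — alignments
with planted conserved, coevolving and SDP columns, toy structures
whose catalytic neighbourhoods concentrate the planted signal, and
annotations — so the whole pipeline is testable without any downloads.

## Worked example

```bash
evosig simulate --outdir bench --n-families 5 --n-sequences 200 --length 60 --seed 7
evosig evaluate --benchmark bench --outdir report --n-permutations 25 --seed 7
cat report/model_performance.tsv
```

which prints (tab-separated; values from this exact invocation):

```
# evosig 0.1.0
# seed=7 n_permutations=25 step=0.05 folds=5
model	weights	auc	auc01	cv_auc
C		0.7517983176331634	0.06551724137931034	
0 C + 1 p(C)	(1.0,)	0.9946428571428572	0.9464285714285715	0.9928571428571429
0.3 C + 0.7 p(cMI)	(0.7,)	0.9174891251116296	0.4146079998847694	0.9174891251116296
0 C + 0.65 p(C) + 0.35 p(cMI)	(0.65, 0.35)	0.9973214285714285	0.9732142857142858	0.9929187192118226
```

Read: conservation alone ranks catalytic residues with mean per-family
AUC 0.75 and does poorly at high specificity (AUC0.1 0.066 — chance is
0.05); summing conservation or cumulative MI over each residue's 3D
neighbourhood lifts AUC above 0.91; the combination of both proximity
signals reaches AUC 0.997 / AUC0.1 0.973 on these five synthetic
families. `report/threshold_scan.tsv` holds the 3–12 Å grid (e.g. p(C)
peaks at 6 Å with AUC 0.995, exactly the planted neighbourhood
radius), `report/sign_tests.tsv` the per-family win/loss sign tests
against conservation alone, and `report/concordance.tsv` +
`report/method_dendrogram.nwk` the between-method Spearman structure.

The same operations are available as a library:

```python
from evosig import (GeneratorConfig, generate_family, kl_conservation,
                    mi_matrix, mi_zscores, cumulative_mi)

fam = generate_family(GeneratorConfig(seed=1))
fam.add_score(kl_conservation(fam.alignment))
mi = mi_zscores(fam.alignment, mi_matrix(fam.alignment), n_permutations=50, seed=1)
fam.add_score(cumulative_mi(mi))
```

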