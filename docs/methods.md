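# Methods

## Problem and approach

Mass-spectrometry screens of tumor versus adjacent normal tissue return a
few hundred differentially expressed proteins (DEPs), a list that is noisy,
platform-dependent, and blind to molecules whose importance is structural
rather than quantitative.  This package implements an integrative
alternative: the DEPs seed a protein-protein interaction (PPI) network,
every node of the expanded network is characterized by seven topological
indexes, the indexes are fused by an orthogonal factor model into a single
composite, and the top-ranked "structurally dominant nodes" (SDNs) are
evaluated — head-to-head against DEP-, differential-gene- (DEG-) and
union-based (CF) molecule sets — as features of RBF-SVM classifiers on
two-class clinical cohorts, with a random-gene-set permutation null.

## Network construction

Seeds are expanded to their first-degree neighbors using only interaction
records at or above a confidence grade (default 5 on a 1–5 ordinal scale).
The node set is every mapped seed plus every neighbor reached through a
retained record; the edge set is **induced**: every retained edge with both
endpoints inside that node set, not only the seed-incident star.  The
induced rule is order-independent and matches the notion of an "extended"
network with internal connectivity.  Gene symbols are uppercased and
whitespace-stripped on ingestion; self-interactions and duplicate pairs are
dropped.  Supplying seeds that match no record is an error, not an empty
graph.

Whole-network statistics: density is reported as the *fraction* of realized
node pairs, E/(N(N−1)/2).  (At the scale our acceptance check reproduces —
6392 nodes, 22 604 edges — this fraction is 0.0011, i.e. 0.11%; a source
that prints "0.0011%" for the same counts has mislabeled the fraction as a
percentage.)  The degree-distribution exponent is the least-squares slope
of log₁₀ frequency on log₁₀ degree over observed degrees ≥ 1 — simple and
adequate for descriptive use; a Clauset-style MLE is available via
`method="mle"`.  The small-world index is (C/C_rand)/(L/L_rand) with the
Erdős–Rényi baselines C_rand = ⟨k⟩/n and L_rand = ln n / ln⟨k⟩; path
statistics are computed on the largest connected component, whose coverage
is reported alongside.

## The seven topology indexes

Per node, in fixed column order: degree; unnormalized shortest-path
betweenness; semi-local centrality; local clustering coefficient; k-shell
(core) index; PageRank (damping 0.85, tolerance 1e−10); eigenvector
centrality (principal adjacency eigenvector, unit Euclidean norm).
Semi-local centrality is the three-level neighborhood sum
CL(v) = Σ_{u∈Γ(v)} Q(u), Q(u) = Σ_{w∈Γ(u)} N(w), with N(w) the number of
distinct nodes within distance 2 of w.  On disconnected inputs the
eigenvector measure is computed on the largest component and set to zero
elsewhere; PageRank's teleportation handles global mass.  Eigenvector
power iteration runs on A + I, which preserves the principal eigenvector
while breaking the ±λ symmetry of bipartite spectra that stalls plain
iteration.  Normalization choices (betweenness unnormalized, eigenvector
unit-norm) are immaterial downstream because every column is z-scored
before fusion.

## Factor-model fusion and the SDN score

The seven index columns are standardized (population scaling, 1/n) and the
correlation matrix R = ZᵀZ/n is decomposed by principal-component
extraction: loadings are eigenvectors scaled by the square roots of their
eigenvalues.  The factor count m is the smallest number whose cumulative
explained-variance proportion reaches `min_cumulative` (default 0.95).
Loadings are varimax-rotated — the default orthogonal rotation, consistent
with an orthogonal factor model; per-factor contributions (column sums of
squared loadings over p = 7) are recomputed after rotation, and their sum
is rotation-invariant.  Each factor's sign is fixed so the degree column
loads non-negatively, making "larger score = more topologically dominant"
and rendering the composite invariant to eigenvector sign flips.  Factor
scores use the regression (Thomson) estimator F = Z R⁺ A; Bartlett scores
are available.  The composite SDN score is the variance-contribution-
weighted sum of factor scores, Σⱼ (cⱼ/Σc) Fⱼ; a Euclidean-norm composite
is available behind a flag since either reading is compatible with ranking
"according to the values of F1 and F2".  Ranking is descending with
lexicographic tie-break; the top k (default 50) are flagged as SDNs.

Degenerate inputs fail loudly: a constant index column (e.g. k-shell on a
tree) aborts standardization naming the offending measure, and fewer
observations than variables is rejected.

## Differential expression and set statistics

Probe-level matrices are filtered (probes missing in > 20% of samples
dropped, remaining gaps imputed at the probe mean), normalized against a
reference array (each array's median shifted to the first array's median —
the simplest reading of reference-array normalization; quantile
normalization is a flag), and collapsed to one row per gene by the log-scale
mean.  DEGs: Welch two-sample t-test per gene with Benjamini–Hochberg
q-values; selected iff p < 1e−4 and q < 1e−4 by default.  Zero-variance
genes receive p = 1 rather than NaN so totals stay deterministic.  DEPs:
selected iff ≥ 2 unique peptides and fold change ≥ 1.5 or ≤ 1/1.5;
boundaries inclusive.  Direction concordance between platforms is a 2×2
up/down cross-table over the overlap with a two-sided Fisher exact p.
Enrichment of a query set in annotated terms uses the upper-tail
hypergeometric p with BH adjustment and a default significance cut of
adjusted p < 1e−4.

## Classifiers and the permutation null

Feature sets of at most 50 molecules are taken per source: DEGs by
ascending p, DEPs by |log₂ fold|, SDNs by composite score, and CF as their
ordered union.  The classifier is an RBF-kernel SVM.  Hyperparameters
(C ∈ {0.1, 1, 10, 100}; γ over 5 log-spaced values in [1/(50d), 1/d]) are
tuned once on the full feature set by leave-one-out (or k-fold)
cross-validated accuracy; re-tuning at every elimination step would multiply
cost for no clear inferential gain.  Recursive feature elimination then
removes one feature per iteration, ranking by the change in the SVM dual
objective ½ αᵀYKYα when the feature is removed from the kernel
(K^(−f) = K·exp(γ(x_f−x'_f)²) for the RBF kernel) — the kernel-space
generalization of the linear weight-magnitude rule, which is also available.
The cross-validated accuracy of every intermediate subset is recorded; the
signature is the subset with the best accuracy, ties resolved toward fewer
features.  Evaluation reports accuracy, sensitivity, specificity and AUC
(positive class = lexicographically later label) per cohort and on
predictions pooled across cohorts ("meta"); per-cohort averaging is a flag.
Cohorts missing a signature gene have it imputed at the training mean with
a logged warning.  The permutation null draws B random gene sets of the
same size from the common-gene universe, runs each through the same
train/evaluate path, and reports p = (r+1)/(B+1) with r the number of null
metrics at or above the observed — the add-one form never reports zero.

## Synthetic data: what it emulates and what it does not

The generators provide ground-truthed stand-ins for the pipeline's three
real input families.  `gen_scalefree_network` draws a power-law degree
sequence (inverse-CDF on 1..√n, exponent default 1.8 — the regime observed
in large human PPI maps), pairs stubs by the configuration model and
simplifies; the recovered log-log slope is within ±0.3 of the request at
n ≥ 2000.  `gen_seeded_interactions` samples seeds preferentially from
high-degree nodes (mimicking the bias of proteins detectable by MS) and
grades edges, recording the exact subnetwork a grade-5 expansion must
reproduce.  `gen_expression` emits two-class log-intensity matrices with a
planted signature of alternating-sign standardized effects plus i.i.d.
Gaussian noise; `gen_fold_table` plants up/down proteins at the 1.5-fold,
2-peptide boundaries with a background strictly inside.  All generators are
pure functions of parameters and seed.

These emulations are deliberately idealized: expression noise is i.i.d.
Gaussian with no array effects, probe families, or gene-gene correlation;
the planted signature is independent of network topology except where the
demonstration bundle plants part of it on hub genes; the interaction graph
has no annotation bias or false-positive structure.  Passing tests
therefore certify the algorithms' correctness and calibration under the
stated statistical model, not classifier performance on real cohorts — the
original study's printed accuracies require its external expression data
sets and the interaction database of record, which users can supply through
the same file interfaces.

## Problem sizes and numerical choices

The bundled demonstration pipeline uses a 400-node network, 40 seeds,
30-sample training and two 20-sample test cohorts, top-15 feature sets and
a 10–20-set permutation null, chosen so a complete run finishes in tens of
seconds while every stage exercises the same code paths as a full-scale
analysis.  The acceptance script additionally fits the factor model on a
2000-node network and verifies count identities at the published screen's
margins (1567 proteins, 119 up + 125 down).  Simulation-based checks use
50–200 replicates.  Tolerances: PageRank and power iteration stop at
1e−10 L1 change with a 10 000-iteration cap; varimax at 1e−8 relative
criterion change; standardization and contribution identities are asserted
at 1e−9.  Ties anywhere (ranking, RFE elimination, feature ordering) break
deterministically — lexicographically by symbol or by first index — so a
fixed seed fixes every reported number.

## Known limitations

Betweenness on large networks is O(nm) (exact Brandes); the 6000-node scale
of a real expansion takes minutes, not seconds.  The factor count selected
on a real PPI topology profile need not be 2 — it is whatever reaches the
cumulative-contribution target.  The reference-array normalization is a
median shift, not a full invariant-set method.  The permutation null
retrains on each draw but reuses the tuned hyperparameter grid ranges, not
per-draw grids.  Meta-analysis is pooled prediction, which weights cohorts
by size; the averaging alternative is provided but not default.
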