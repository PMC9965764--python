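# Methods

This note documents the models, conventions and numerical choices behind
`chemophen`, in the order the pipeline applies them.

## Feature-table conditioning

Raw MS1 feature tables are samples × features intensity matrices with
per-feature ion mode, m/z (Da), retention time (s) and an MS2-acquired flag,
and per-sample taxon/replicate labels.  Conditioning:

- **RT filter.** Features with `rt < rt_max` are kept (strict inequality);
  default `rt_max = 1020 s`, the end of the usable chromatographic window.
- **Log transform.** `x → ln(1 + x)`.  The offset makes imputed zeros and
  true zeros coincide at 0 and avoids −∞.  No base is assumed anywhere
  downstream: switching to a base-b logarithm rescales every Euclidean
  distance by the constant 1/ln b, so complete-linkage topologies, Mantel
  and cophenetic correlations are provably base-invariant.  Double
  application is a state error (`transformed` flag on the table).
- **Presence/absence.** A value is *present* iff it is ≥ 10⁻⁸ % of the
  median of all non-zero raw intensities ("less than" the threshold means
  absent).  The median is global rather than per-feature — the simpler
  reading, and it makes presence calls invariant to rescaling the whole
  table.  An all-zero table has no defined median and is rejected.
- **Ion-mode join.** The positive- and negative-mode tables (same samples,
  feature ids prefixed `pos_`/`neg_`) are joined after comparing the medians
  and variances of their non-zero entries; the relative deviation
  `|a − b| / ((a + b)/2)` of either statistic beyond 10% sets a prominent
  warning flag but does not abort — the check is reported as a gate, and the
  caller decides.  The deviation is computed on the scale of the tables
  being joined (the pipeline joins log-scale tables and records that).

## Projection to class and descriptor spaces

Each annotated feature carries exactly one ontology class, hence one
root-to-class path in the single-parent ontology.  The class table is
`C[s, c] = Σ_f A[s, f]` over annotated features whose path contains `c`,
restricted to the requested level (`most_specific`, `superclass` = the
child of the root on the path, or `all`).  This one definition reproduces
both the subclass and the superclass analyses; by construction a parent's
`all`-level value equals the sum over its children plus the features
annotated at the parent itself (tested as an invariant).  The descriptor
table is the plain product `D = A · X` with no weighting or normalisation.
The abundance scale entering projections is whatever the caller supplies;
the pipeline uses the log-scale table, matching the order of operations in
the conditioning chain.  Candidate annotations reduce to one row per
feature: the maximal-score candidate when scores exist, otherwise rank 1;
ties break by lower rank, then lexicographically smaller structure id.

## Chemodiversity

Richness counts present entries; Shannon `H′` is computed in nats over the
positive entries (the cited ecology definitions are base-free up to a
constant, and Pielou's `J = H′/ln richness` cancels the base entirely);
`J` is undefined (returned as NaN, logged) for richness < 2.  A variable is
*unique* to a taxon when present in ≥ 1 of its replicates and in 0
replicates of every other taxon; the stricter all-replicates rule is an
option.  Group comparisons use one-way ANOVA (scipy) with Tukey HSD
adjusted pairwise p-values (statsmodels).

## PLS-DA marker selection

The classifier is PLS2 (NIPALS, via scikit-learn's `PLSRegression`) of the
one-hot class matrix on column-centered, unit-scaled variables.  Constant
columns receive zero weight but are not dropped, keeping variable indices
stable.  The component count is chosen in `1..max_components` (default cap
5, further capped by the data rank) by cross-validated accuracy, ties going
to fewer components.  The CV scheme is the same for selection and
evaluation: k = min(10, smallest class size × number of classes, number of
samples) folds, built by dealing each class's shuffled members round-robin
— a literal stratified k-fold is impossible when k exceeds the smallest
class (e.g. 10 folds on 4 taxa × 3 replicates), and using one scheme for
both stages means the selected component count is the one that actually
cross-validates best under the folds it will be judged by.

Variable importance is the VIP score
`VIP_j = √(p · Σ_a SSY_a (w_{ja}/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = q_a² · t_aᵀt_a` the response variance component a explains; the
per-class variant weighs components by the class's own `SSY_{k,a}`.  VIP is
used because it is standard, closed-form and carries a testable
normalisation (`Σ_j VIP_j² = p` for every class column, enforced to 1e-8).
Markers are variables *strictly above* the empirical 0.995 quantile
(linear interpolation) of their class column, per class, unioned with
per-class provenance; a pooled variant (quantile of the row-wise maximum)
is available.  Note the arithmetic consequence: with p variables the rule
can select only ~⌈0.005·p⌉ per class, so on small simulated tables the
selected set is much smaller than a generously planted marker set — the
rule is a top-of-distribution cut, not a complete-recovery procedure.

Evaluation reports pooled CV accuracy A, the R² of the full model's one-hot
fit (1 − SSE/SST), and one-vs-rest ROC/PR areas from the CV-pooled
continuous scores, macro-averaged across classes.

## Trees and congruence

The chemotaxonomic tree is the complete-linkage dendrogram of Euclidean
distances between taxon profiles (replicates aggregated by mean; median
optional).  The agglomeration assigns merge heights as node heights, so the
dendrogram is exactly ultrametric; equal-distance merges break ties by the
lexicographically smallest label pair, making topologies deterministic.

Cophenetic convention: dendrograms use the LCA merge height (half the
tip-to-tip path length of the ultrametric tree); phylograms read from
Newick use plain path lengths.  Each tree contributes distances in its own
convention — both are valid dissimilarities and Pearson correlation absorbs
the scale.

Congruence with a reference phylogeny is reported two ways, deliberately
different: the **Mantel statistic M** correlates the raw chemical distance
matrix with the reference's cophenetic matrix (lower triangles, diagonal
excluded), permutation-tested by jointly permuting rows/columns of the
second matrix with `p = (1 + #{M* ≥ M}) / (n_perm + 1)` (999 permutations
by default; an exhaustive mode enumerates all n! relabelings for small n);
the **cophenetic correlation c** correlates the two trees' cophenetic
vectors over shared tips.  M sees the data-space distances before
clustering distorts them; c sees only the trees.  A tree-vs-tree Mantel
would be identical to c and is therefore not what `compare_to_reference`
computes.  Zero-variance cophenetic vectors (star trees) yield NaN, logged.
Newick branch lengths that are absent default to 1.0 (logged) so cophenetic
distances stay defined.

## Image spectra and dbRDA

Trait extraction drops exactly the pure-black (0,0,0) and pure-white
(255,255,255) 8-bit pixels — the two backgrounds manual segmentation
produces — and histograms the remaining pixels per channel into 256
normalised bins; the trait vector is the 768-long concatenation.  dbRDA:
distance matrix → Gower double-centering → principal coordinates (negative
eigenvalues are dropped, their relative mass logged; Euclidean input
produces none) → least-squares projection of the coordinates onto the
centered constraints.  The constrained-inertia fraction equals the
multivariate least-squares R² when the distance is Euclidean (the classical
RDA identity), which is the module's primary test oracle.  Forward
selection greedily adds the candidate with the largest inertia gain if its
permutation p (response rows permuted, 199 permutations) is ≤ α = 0.05; an
adjusted-R² stopping rule was considered and not implemented, the
permutation rule being the simpler and directly testable choice.  envfit
regresses a variable on the first two axis scores and reports R² with a
permutation p.

## Synthetic data

The generator emulates the statistical structure the analysis assumes.  Log
intensity of feature f in replicate r of taxon t:

    L = μ₀ + u_f + b_{t,f} + m_{t,f} + ε

with μ₀ = ln 1e5 (a realistic detector-count scale), u_f ~ N(0, 1) a shared
per-feature baseline (the constant core metabolome), b Brownian motion
along the species tree with variance σ_b² per unit branch length (on the
log scale, so species effects are fold-changes and scale-free), m = ln 4
for planted markers (a 4-fold specific elevation), and ε ~ N(0, σ_e²)
replicate noise.  Intensities are exp(L); entries are zeroed independently
at the missing rate (MCAR).  Defaults: 4 taxa × 3 replicates (the emulated
study design), 300 features, σ_b = 0.5 per unit branch (phylogenetic
divergence of the same order as the marker effect, so both tree structure
and individual markers are recoverable), σ_e = 0.3, missing rate 0.02
(residual missingness after the upstream ≥ 70%-detection peak filtering
such tables have already passed), 40% negative-mode features (matching the
roughly 40/60 negative/positive split of typical dual-mode acquisitions),
60% of features annotated.  Retention times are drawn inside the retained
analytic window (30–1000 s); RT filtering is exercised on constructed
fixtures instead.  The tree is a uniformly random sequential-join topology
with unit branches unless supplied as Newick.  The ontology fixture has
three levels (root → 4 superclasses → 12 leaf classes); annotated features
get uniform random leaf classes, and descriptors are the class's mean
vector (entries ~ N(0, 2²)) plus unit noise.  Reference images have mean
channel values affine in the sample's mean log abundance over three
designated leaf classes (offset 40, slope 8, pixel noise sd 2, values
clipped into [1, 254]) with pure-black/white border rows, so doubling a
designated class's abundance shifts the matching channel by ≈ slope × ln 2.

What the generator does *not* emulate: adducts/isotopes/in-source fragments
(feature redundancy), intensity-dependent dropout, RT drift, batch effects,
annotation errors, or correlated descriptor noise.  Passing tests therefore
demonstrate that the statistical machinery recovers planted structure under
the stated model, not that any particular real dataset will behave as
cleanly.

## Determinism and problem sizes

All randomness flows from explicit integer seeds; the pipeline derives
per-stage substreams from one global seed and the stage name, so re-running
a stage or toggling an unrelated one never changes results, and identical
runs are byte-identical (no timestamps in provenance sidecars).  Test and
acceptance problem sizes (hundreds of features, 10–20 simulation seeds,
hundreds of permutations) are chosen so the whole suite runs in well under
a minute of simulation time while keeping the stochastic checks' pass
bands (e.g. topology recovery in ≥ 18/20 seeds) meaningfully tight.

## Known limitations

- The empirical-quantile marker rule caps how many planted markers can be
  selected on small tables (see above); recall against a large planted set
  is structurally low even when every selected variable is genuine.
- dbRDA drops negative PCoA eigenvalues rather than applying a Lingoes/
  Cailliez correction; with the default Euclidean distance none arise.
- The Mantel permutation test at 4 taxa has only 24 distinct relabelings,
  so p-values are coarse; the exhaustive mode makes that explicit.
- `anova_tukey` assumes exchangeable replicates; no mixed-effects structure.
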