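# Methods

## The problem

High-parameter flow and mass cytometry experiments measure tens of markers on
10⁴–10⁷ cells per patient sample. The standard question is differential
abundance: which cell populations change between two clinical groups? There
are two classical ways to quantify a population's abundance in a sample:

* **%total** — the population's cell count divided by all cells in the
  sample;
* **%parent** — its count divided by the count of its *parent* population,
  the quantity a manual gating analyst reads off a 2-D gate.

The two answer different hypotheses. %total is sensitive to genuine absolute
shifts but also to fluctuations in unrelated compartments (a granulocyte
bloom shrinks every other population's %total). %parent conditions away
everything outside the parent, isolating the split between a population and
its siblings. `treekor` computes and tests both, on every node of a
data-derived tree of cell populations.

## Pipeline

1. **Normalization** (`preprocess`). Raw intensities are transformed with
   `asinh(x / cofactor)`, cofactor 5 (the CyTOF standard; flow data often
   uses 150, configurable). Optional subsampling (`fraction`, default 1)
   retains `round(f·n)` events, stratified per sample by default,
   round-half-to-even.
2. **Over-clustering** (`clustering`). A self-organizing map on a
   rectangular grid (default 10×10 = 100 units) quantizes the cells; each
   occupied unit becomes a cluster. Over-clustering deliberately exceeds the
   number of real cell types so rare populations are not absorbed;
   redundant clusters are re-aggregated by the tree. Training: online
   updates, codebook initialized from randomly drawn events, Euclidean
   distance, learning rate decaying linearly 0.05 → 0.01, Gaussian
   neighborhood with width decaying linearly from `max(grid dims)/2` to
   0.3 grid units (truncated at three widths). The end width is below one
   grid step: with a wider endpoint prototypes never decouple and contract
   toward the global mean; the small endpoint lets each unit converge to a
   local prototype after the ordering phase. The inner loop is numba-compiled
   and fully deterministic for a fixed seed. Precomputed labels (manual
   gates, a prior clustering) can replace the SOM.
3. **Hierarchy** (`hierarchy`). Per-cluster median marker expressions are
   scaled per marker (min–max to [0,1] by default; z-score available) and a
   tree is built over the clusters:
   * *agglomerative* — average, Ward, single, complete, or McQuitty/WPGMA
     linkage on Euclidean distances (via `scipy.cluster.hierarchy`),
     strictly binary with merge heights;
   * *HOPACH-style divisive* — at each node, PAM partitions the items for
     each candidate child count `k = 2..min(K, m−1)` (default K = 5) and the
     `k` minimizing the **median split silhouette** (MSS) wins, ties to the
     smallest `k`. MSS: each group of size ≥ 3 is re-split by PAM at the
     sub-`k` maximizing average silhouette; the group's score is the median
     member silhouette under that sub-split (groups of size ≤ 2 score 0);
     MSS is the median of group scores — low when groups have no crisp
     internal structure left. PAM itself is exact (exhaustive medoid
     search) whenever `C(m,k) ≤ 5000` and classic BUILD+SWAP with
     lowest-index tie-breaks otherwise, so trees are deterministic.
     The original HOPACH's ordering, collapsing and bootstrap steps are out
     of scope; only the ≤K-children/MSS core is needed to build the tree.

   A known property of the MSS-minimizing rule with the size ≤ 2 → 0
   convention: partitions with small groups score low, so on data whose
   clusters are quantization bins of a continuum (exactly what a SOM
   produces) the divisive splits tend to be flat and fragmented near the
   bottom rather than deeply nested. This is not harmful for the %parent
   analysis — what matters is that coherent populations appear as single
   nodes with phenotypically sensible parents — but it is why the
   synthetic benchmark tracks populations with an explicit node-matching
   step rather than assuming topological identity with the truth.
4. **Proportions** (`proportions`). Leaf counts per sample come from the
   cluster assignment; internal counts are children sums. %total divides by
   the root count, %parent by the direct parent's count (root ≡ 1). A zero
   parent count yields a *missing* value, not 0 — a ratio with an empty
   denominator asserts nothing. The telescoping identity
   `%total(v) = Π %parent` along the root→v path holds wherever defined and
   is enforced by tests. Ancestor-relative proportions (`parent_depth > 1`)
   exist as an option but default off.
5. **Testing** (`testing`). Every non-root node is tested twice against the
   binary condition — once per quantification. Default Welch two-sample t
   (pooled by flag); Wilcoxon rank-sum available (exact when combined
   n ≤ 20 and untied, tie/continuity-corrected normal approximation
   otherwise). Proportions are tested raw by default; a logit transform is
   available as a flag (values clipped to [1e-6, 1−1e-6], so exact zeros
   become large negative outliers — prefer the default or Wilcoxon when
   zero counts are common). Missing values are dropped pairwise per node.
   BH-FDR is applied separately within the %total and %parent families,
   since they are distinct hypothesis families. Statistic sign convention: first
   condition level in metadata order minus the second.
6. **Classification benchmark** (`evaluation`). Each quantification's node
   × sample matrix becomes a feature set for predicting the condition:
   random forest (500 trees, bagging fraction 0.632, √p features per
   split; LightGBM's rf mode as the engine for speed, with scikit-learn
   stratified 5-fold CV × 20 repetitions), scored by balanced accuracy
   averaged over folds within each repetition. Missing %parent entries are
   imputed with the training fold's per-feature median. Feature sets are
   ranked by mean (ties: lower sd, then a fixed feature-set order).
7. **Visualization** (`viz`). (i) the tree with node glyphs colored by the
   %total statistic and each node's incoming edge by its %parent statistic,
   on one shared symmetric diverging scale, beside a heatmap of scaled leaf
   medians in depth-first leaf order; (ii) a per-node scatter of the two
   statistics with identity line; (iii) a rank-paired Q-Q plot of
   −log₁₀ p between the two families (base-10 logs, truncated to the
   shorter family). SVG by default; every figure writes a CSV sidecar of
   its plotted coordinates so content is testable.

## Synthetic ground truth

The generator (`synthetic`) draws cohorts from a known cell-type tree by
nested compositional sampling: at each internal node every sample draws its
child split from a Dirichlet centred on the node's base proportions
(concentration = sampling precision), cells cascade down multinomially, and
each cell's markers are Gaussian around its leaf type's mean on the arcsinh
scale, mapped back to the raw scale with `sinh(x)·cofactor` so the
pipeline's own transform reproduces the intended geometry. Realized split
draws are recorded, so realized %parent/%total satisfy the telescoping
identity exactly.

Condition effects are a logit shift of one split proportion in group 2:

* `parent` scale — shift the effect node's share of its direct parent:
  a pure %parent signal;
* `total` scale — shift the effect node's depth-1 ancestor's share at the
  root: moves its %total, leaves its %parent untouched.

The default cohort (`paper_like`) is a 3-level tree with 12 leaf types, 8
markers, 10 samples per group and 2,000 cells per sample — small enough for
CI, large enough that 100 SOM clusters meaningfully over-cluster it. Marker
patterns are hierarchical, as in real panels: three one-hot lineage markers
plus a lineage gradient dominate, two markers separate the mid-level
branches, one marker separates sister leaves, one is uninformative. Sister
leaves are therefore nearest, lineages farthest, and a hierarchy built on
cluster medians recovers the nesting. In the `parent_effect` scenario the
top-level lineage composition is made highly variable (root concentration 4,
emulating the large compositional swings seen across patients) while the
effect node is a minor subpopulation (25 % of its parent, echoing activated
subsets such as HLA-DR+CD38+ T cells) whose split shifts by 1.0 on the
logit scale (≈ 0.25 → 0.47). Under these conditions the node's %parent
separates the groups at ≈ 3.5 within-group sd while its %total gap stays
near 1 sd — the regime where parent-relative quantification is the only
reliable detector. All scenario parameters are fixed constants of the
package, not tuning knobs.

What the generator does **not** emulate: spillover/compensation artifacts,
debris and doublets, batch effects, heavy-tailed or zero-inflated marker
noise, correlated markers within a cell type, and cell-type trees deeper
than three levels. Passing tests therefore demonstrate correctness of the
machinery and the qualitative %parent phenomenon under idealized
compositional noise, not performance on raw instrument data.

## Numerical and design choices

* **Seeds.** One top-level seed fans out into per-stage seeds
  (subsampling, SOM, CV, synthesis) through `numpy.random.SeedSequence`
  spawn keys; full runs are bit-reproducible (checked by running the CLI
  twice and comparing bytes).
* **Ties.** Nearest-unit assignment, PAM swaps/medoid sets, and MSS k
  selection all break ties toward the lowest index / smallest k.
* **Degenerate inputs.** Zero-variance test inputs give (0, 1) when means
  agree; groups with < 2 usable samples give missing results rather than
  errors; samples with zero cells at the root are an error (they indicate
  broken input, not a statistical edge case).
* **Scaling choice.** Min–max per marker across clusters is the default
  because it matches the bounded color scale of the heatmap and weights
  every marker equally; z-score is available when outlier clusters would
  otherwise compress the range.
* **Why FDR per family.** %total and %parent of the same node are different
  null hypotheses; pooling them into one correction would trade power
  between families in an uninterpretable way.
* **FCS support.** A minimal FCS 3.1 reader/writer (list mode, float32/64,
  both byte orders, `$PnN` names) is built in; compensation keywords are
  ignored because inputs are assumed pre-processed.
* **Problem sizes.** The bundled checks use the `paper_like` cohort sizes;
  Monte-Carlo properties use 100–2,000 simulated cohorts (type-I error uses
  500 cells per sample), chosen to keep Monte-Carlo error well below the
  asserted margins.

## Known limitations

* The divisive tree is *methodologically* HOPACH-like (≤K children chosen
  by MSS) but not guaranteed topologically identical to the R
  implementation (which adds ordering and collapsing refinements).
* The Wilcoxon tie path is the corrected normal approximation; exact
  permutation p-values under heavy ties on very small samples can differ
  by up to ~0.1.
* Balanced accuracy of a single small cohort is an optimistic random
  variable under the null (chance compositional separations generalize
  across CV folds); chance-level claims are meaningful only averaged over
  cohorts.
* No covariates, paired designs, or >2 outcome groups.
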