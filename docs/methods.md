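# Methods

## Model overview and assumptions

`ptsarank` ranks diseases by their likelihood of causing psychological
trauma and social avoidance, under the working hypothesis that diseases
with similar molecular bases cause similar psychological outcomes. The
pipeline has four stages — gene-network disease similarity, disease-graph
assembly with binary protein features, a spectral graph-convolutional
encoder, and a second-order gradient-boosted tree classifier — evaluated by
a leave-one-positive-out scheme. The key assumptions:

* the gene functional network's log-likelihood scores (LLS) are comparable
  after a single global min–max rescaling (normalization is relative to the
  whole network, not per gene);
* a disease is adequately summarized by its annotated gene set; set-to-set
  similarity uses the best-match-average, which rewards each gene's single
  strongest counterpart rather than average connectivity;
* unknown diseases can be treated as negatives during supervised steps
  (standard positive-unlabeled pragmatics; scores are therefore relative
  rankings, not calibrated probabilities of causing PTSA).

## Normalization variants

The LLS normalization is exposed in two modes. `corrected` is the standard
min–max form `(LLS − min)/(max − min)`, bounded in [0, 1] and monotone, and
is the default everywhere. `as_printed` evaluates `(LLS − min)/(max − LLS)`,
a variant that circulates in applied write-ups; it is non-monotone,
unbounded near the maximum, and singular at `LLS = max`, so it cannot
serve as a normalization. It is retained behind a flag for fidelity
audits only and raises an explicit error on the singular input.

## Tunable parameters

| Parameter | Default | Units / range | Rationale |
|---|---|---|---|
| `min_diseases` (protein filter) | 100 | diseases | keeps only panel proteins annotated broadly enough to generalize; the surviving panel size is data-dependent, never hard-coded |
| `edge_threshold` | 0.0 | similarity | dense weighted graph by default; most similarities in realistic data are small, so sparsification is available but not imposed |
| GCN `hidden_dim` | 64 | dimensions | embedding width; 8–16 suffices at desk scale |
| GCN `epochs` / `lr` | 400 / 0.2 | — | full-batch gradient descent; this pairing converges far enough to separate classes while keeping the loss trace monotone non-increasing on the bundled scenarios (verified by test) |
| GCN `self_loops` | on | — | propagation uses `Â = A + I`; without self-loops a node's own features are discarded by the kernel. A flag disables this for the literal one-hop operator |
| boosting `n_rounds` / `max_depth` | 50 / 3 | — | conventional small-tree boosting for a ~100-sample regime |
| boosting `learning_rate` | 0.1 | — | shrinkage; loss non-increase over rounds is tested |
| `λ` (leaf shrinkage) | 1.0 | — | quadratic leaf-weight penalty |
| `γ` (leaf penalty) | 0.0 | per leaf | splits accepted whenever gain > 0; raise to prune |
| `min_child_hessian` | 1e-3 | hessian mass | guards against splits isolating near-zero-curvature samples |
| `feature_mode` | `embedding` | — | what the booster sees: GCN hidden activations (default), `raw` protein features, or `concat` of both |

## The encoder and its training objective

One GCN layer computes `H' = σ(D̂^{-1/2} Â D̂^{-1/2} H W)`. Degree-0 nodes
take the zero-row convention: their kernel rows/columns and normalized-
Laplacian diagonal entries are zero rather than raising an error, so
isolated diseases flow through the pipeline with their own (unsmoothed,
here zeroed) contribution. The training objective is softmax cross-entropy
over labeled nodes only, minimized by full-batch gradient descent from
Glorot-initialized weights with a mandatory seed. Masked (held-out) nodes
participate in propagation but not in the loss — that is how test nodes are
embedded per fold without label leakage, and a test verifies that
scrambling a fold's test labels before masking changes no held-out score.

The encoder's supervision is a design choice: nothing in the method forces
the GCN to be trained at all (an untrained smoother would also mix
features), but a supervised encoder concentrates embedding variance along
the label-relevant direction, which is what the downstream booster needs.
The Chebyshev polynomial basis and the first-order spectral filter are
exposed as standalone, tested operators; the trained model deliberately
uses only the first-order (K = 1, λ_max = 2) collapse — higher-order
convolutions are out of scope.

## Boosting details

Exact greedy split search enumerates every feature and every midpoint
between consecutive distinct sorted values; there is no histogram
approximation, no subsampling, and no sparse-aware default direction
(absent features are literal zeros in the binary encoding). Equal-gain ties
resolve to the lowest feature index, then the lowest threshold, making fits
bit-reproducible. Margins start at 0, so first-round leaves are Newton
steps at p = 0.5. The classical one-dimensional gradient-boosting recipes
for {−1, +1} labels (half-log-odds initialization, ratio-form leaf values)
are provided as reference operations; the production classifier is the
second-order form throughout. A test verifies the whole fit path agrees
with the reference `xgboost` library to float32 precision under matched
hyperparameters.

## Evaluation scheme

With `P` known positives, the unknowns are shuffled into `P` near-equal
groups (sizes differ by at most 1 — the group sizes are a choice, as only
the group *count* is canonical) and fold `t` tests positive `t` plus group
`t`. Per fold, the GCN is refit on the masked graph and the booster on the
training nodes; a `reuse_global_embedding` flag skips the per-fold GCN
refit for exploratory speed and is explicitly documented as leaky. PR-AUC
uses the average-precision step convention (no linear interpolation), which
matters on skewed label sets; ROC-AUC is the tie-aware rank-sum form. Both
are cross-checked against O(n²) enumeration oracles and scikit-learn.

In ranking mode the decision threshold (default 0.5) is exposed rather
than targeting any particular number of flagged diseases: how many
candidates clear the threshold is a property of the data.

## What the synthetic generator emulates — and what it does not

The generator plants the positive class through the same two channels the
pipeline exploits: positives draw a `signal_strength` fraction of their
genes from a small shared pool (raising their pairwise similarity), and a
`signal_strength`-scaled fraction of proteins is enriched in positives
(`p = 0.1 → 0.5` at full signal under the defaults). At
`signal_strength = 0` both channels vanish and LOOCV AUC sits at chance —
tested. The default enrichment is deliberately moderate: it emulates the
regime where sparse annotations alone rank positives reasonably (good AUC)
but leave hard false positives near the top (depressed AUPR), so the
relational channel has complementary information to contribute. One master
seed spawns independent per-generator substreams, so adding a generator
never perturbs earlier outputs.

Not emulated: the heavy-tailed degree distribution of real gene functional
networks (edges are uniform Erdős–Rényi with uniform LLS weights), the
heavy-tailed protein-annotation frequency spectrum, ontology-induced
correlation between related disease terms, and any particular histogram of
the real similarity matrix. Passing tests therefore demonstrate that the
machinery recovers planted structure of the stated kind — not that real
disease data contains such structure.

## Clinical instruments

SADS: 28 binary items (14 avoidance + 14 distress), total above 9 flags
clinically relevant avoidance/distress. SES (Rosenberg): 10 items on a
1–4 scale, total 10–40; published cuts leave 25 unassigned between "low"
(< 25) and "moderate" (26–32), and 25 is assigned to *low* here so the
categories partition the range. The standard instrument reverse-scores
five items; the survey this module mirrors does not mention reverse coding,
so none is applied by default and a `reverse_coded` flag restores standard
scoring. The chi-square is Pearson's without continuity correction; the
one-sample t from printed summaries carries a documented caveat that
summaries rounded to two decimals can shift the statistic by ~0.01.

## Numerical choices and degenerate inputs

* Similarity of a disease with itself is exactly 1 by construction (every
  best-match term is 1); the matrix path and the naive pairwise path agree
  to 1e-12 and the matrix is exactly symmetric by assignment.
* Genes annotated to diseases but absent from the network contribute 1 to
  their own match and 0 elsewhere — no error, since real annotation sets
  always exceed network coverage.
* `log` underflow in the GCN loss is guarded by a 1e-12 floor; softmax is
  max-shifted.
* Empty gene sets, single-class label vectors, all-same-label GBDT
  initializations, zero-residual leaf values, zero contingency margins and
  out-of-range questionnaire items all raise explicit `ValueError`s.

## Problem sizes

Desk-scale defaults are 123 diseases / 23 positives / 300 genes / 64
proteins, for which the full per-fold-refit LOOCV runs in seconds; the
graph-assembly path is shape-checked up to 2387 nodes × 523 features, the
scale of the motivating real-data use. These sizes are the package's own
benchmark conditions.

## Known limitations

* The GCN is a fixed two-layer architecture with gradient descent; no
  early stopping, validation split, or adaptive optimizers.
* Boosting is binary, exact-greedy, single-threaded; quadratic-ish split
  search is fine at hundreds of samples, not at millions.
* Scores are ranking scores, not calibrated risks; the positive-unlabeled
  setting biases probabilities downward.
* The similarity stage is O(n² · m²) in diseases × set sizes; thousands of
  diseases are fine, beyond that the gene-similarity lookup should be
  sparsified.
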