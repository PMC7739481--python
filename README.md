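# ptsarank

Prioritizing diseases likely to cause **psychological trauma and social
avoidance (PTSA)**. Surviving a severe disease often leaves psychological
sequelae — avoidance of social contact, distress, low self-esteem — but only
a small number of diseases are *known* to do so, and surveying patients for
every candidate disease is prohibitively expensive. `ptsarank` treats the
problem as semi-supervised node classification on a disease graph: diseases
with similar molecular bases are hypothesized to cause similar psychological
outcomes, so a few known PTSA-causing diseases can be propagated through a
molecular similarity structure to rank every other disease.

## Method

**Disease similarity from a gene functional network.** Each gene–gene
interaction carries a log-likelihood score (LLS), min–max normalized over
the network:

```
LLS_N(g_i, g_j) = (LLS(g_i, g_j) − LLS_min) / (LLS_max − LLS_min)
```

Gene similarity is `sim(g_i, g_j) = 1` if `i = j`, `LLS_N` if the edge
exists, else 0. A gene-to-set association is the best match
`F(G, g) = max_{g' ∈ G} sim(g, g')`, and two diseases with gene sets `G_1`,
`G_2` get the best-match-average similarity

```
sim(G_1, G_2) = ( Σ_{g ∈ G_1} F(G_2, g) + Σ_{g ∈ G_2} F(G_1, g) ) / (|G_1| + |G_2|)
```

**Disease graph.** Nodes are diseases, weighted edges are the pairwise
similarities, and each node carries a binary feature vector over a protein
panel (1 iff the protein is annotated to the disease; only proteins
annotated to at least `min_diseases` diseases are kept).

**Graph convolutional encoder.** A two-layer GCN propagates features with
the symmetric normalized adjacency (self-loops added):

```
H^(l+1) = σ( D̂^(−1/2) Â D̂^(−1/2) H^(l) W^(l) ),   Â = A + I
```

trained full-batch on cross-entropy over the labeled nodes. The hidden
activations are the node embeddings: each disease's encoding combines its
own protein profile with those of its similar diseases.

**Second-order gradient boosting.** A from-scratch boosted-CART classifier
consumes the embeddings. Each round fits a regression tree to the gradient
`g = p − y` and hessian `h = p(1 − p)` of the logistic loss, choosing exact
greedy splits by the regularized gain

```
Gain = ½ ( G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ) ) − γ
```

with leaf weights `w* = −G/(H+λ)`.

**Evaluation.** Leave-one-positive-out cross-validation: one fold per known
positive, each paired with a disjoint near-equal group of unknown diseases;
encoder and classifier are refit per fold with the test labels masked, and
ROC-AUC / PR-AUC (average-precision convention) are computed on the pooled
held-out scores. A ranking mode trains on all positives plus a random
negative sample and scores every unlabeled disease.

A synthetic-scenario generator plants the positive class through both
information channels (shared genes among positives; label-informative
proteins) so the full pipeline is testable without any external database.
The `clinical` module adds the questionnaire scoring rules (SADS, Rosenberg
SES) and the recomputable summary statistics of the accompanying
breast-cancer survey.

## Worked example

```python
from ptsarank import (
    SimulationConfig, PipelineConfig, GcnConfig, BoostingConfig, run_loocv,
)
from ptsarank.synthetic import simulate_disease_graph

config = SimulationConfig(n_diseases=123, n_positives=23, signal_strength=0.9, seed=1)
graph = simulate_disease_graph(config)
print(f"{graph.n_nodes} diseases, {graph.features.shape[1]} protein features, "
      f"{int(graph.labels.sum())} known positives")

pipe = PipelineConfig(gcn=GcnConfig(hidden_dim=16), boosting=BoostingConfig(n_rounds=30))
report = run_loocv(graph, pipe, seed=1)
print(f"GCN-encoded pipeline: ROC-AUC={report.roc_auc:.3f}  PR-AUC={report.pr_auc:.3f}")

raw = run_loocv(graph, PipelineConfig(gcn=pipe.gcn, boosting=pipe.boosting,
                                      feature_mode="raw"), seed=1)
print(f"raw-feature boosting: ROC-AUC={raw.roc_auc:.3f}  PR-AUC={raw.pr_auc:.3f}")
```

prints

```
123 diseases, 64 protein features, 23 known positives
GCN-encoded pipeline: ROC-AUC=0.944  PR-AUC=0.864
raw-feature boosting: ROC-AUC=0.847  PR-AUC=0.541
```

The scenario plants 23 positive diseases that share genes (hence cluster in
the similarity graph) and carry moderately enriched protein annotations.
Boosting on raw protein features alone ranks positives well overall
(ROC-AUC 0.85) but produces many false positives near the top of the list
(PR-AUC 0.54); encoding the graph first lifts both, and most visibly the
precision-recall area — the relational channel is what separates the
hard negatives.

The clinical statistics are one call each:

```python
from ptsarank.clinical import SummaryStats, chi_square_contingency, one_sample_t_from_summary
chi2, df = chi_square_contingency([[9, 54, 28, 8], [172, 130, 152, 177], [11, 8, 12, 7]])
t, tdf = one_sample_t_from_summary(SummaryStats(12.87, 5.71, 192, 8.03))
# chi2 = 66.870 (df 6); t = 11.745 (df 191)
```

A `ptsarank` console script exposes each stage (`simulate`, `similarity`,
`build-graph`, `gcn`, `boost`, `evaluate`, `rank`, `clinical-stats`) and a
`run` command that executes the whole pipeline from a YAML/JSON config; see
`ptsarank --help`.

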