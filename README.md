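# safer-synergy

Dose-level drug-combination synergy prediction with sub-hypergraph
attention networks.

Most synergy predictors collapse a whole dose-response matrix into one
average synergy score per (drug A, drug B, cell line) triplet, which
throws away exactly the information a clinician needs: *at which doses*
a combination is synergistic. This package classifies each individual
dose combination as synergistic or antagonistic, using the Loewe
additivity score thresholded at ±10 as the label, and keeps the model
interpretable through attention weights over gene sets.

## Model

Biological structure enters as two hypergraphs, each stored as a binary
incidence matrix `H ∈ {0,1}^{|V|×|E|}`:

* **gene-set hypergraph** — nodes are gene sets (TF-target collections
  or pathways), hyperedges are genes, so a gene ties together every set
  containing it;
* **drug hypergraph** — hyperedges are drugs over two node types:
  k-mer SMILES substrings (default k = 9) and the gene sets overlapping
  a drug's associated genes.

Message passing alternates dual attention for k layers. With
`s(p,g) = tanh(W [h_V(g) ; h_E(p)])` the attention-ready state of an
incident (edge, node) pair and `c` a learned context vector,

    a_E(p,g) = softmax over g'∈p  of  cᵀ s(p,g')      (hyperedge attention)
    a_V(g,p) = softmax over p'∋g  of  cᵀ s(p',g)      (node attention)
    h_E^k(p) = ReLU( Σ_{g∈p}  a_E(p,g) · h_V^{k-1}(g) )
    h_V^k(g) = ReLU( Σ_{p∋g}  a_V(g,p) · h_E^{k-1}(p) )

A *subject* — one drug-drug-cell sample at one dose pair — selects the
sub-hypergraph of nodes where its feature row `F_j` is nonzero. Cell
features are ssGSEA normalized enrichment scores scaled by the summed
(log-transformed) dose; drug-pair features put each drug's dose on its
own substructure and gene-set nodes. Subgraph attention

    a_G(j,g) = softmax over g∈G_j  of  F_{jg} · bᵀ h_V^k(g)
    h_G(j)   = ReLU( Σ_g a_G(j,g) · h_V^k(g) )

yields one embedding per subject; the cell and drug-pair embeddings are
concatenated with one-hot dose and phenotype covariates and passed
through batch-norm plus a two-layer ELU network (hidden width 200,
dropout 0.2 / 0.3) to a synergy logit trained with BCE-with-logits.

Around the model, the package implements the matching data curation
(replicate averaging, SMILES-based drug unification, additive and
non-inhibitory exclusion, Loewe binarization, gene-set size filtering),
leakage-free grouped cross-validation, per-triplet and IC50
dose-quadrant evaluation, and a Mann-Whitney/Benjamini-Hochberg
analysis of attention weights that flags gene sets differentially
weighted between synergistic and antagonistic samples.

## Worked example

The synthetic-study generator plants a dose-dependent synergy signal on
designated causal gene sets, so the whole pipeline can be exercised and
verified end to end:

```python
from safer.synthetic import SyntheticSpec
from safer.workflow import run_planted_experiment

result = run_planted_experiment(SyntheticSpec(seed=7))
print(f"held-out AUROC       {result.overall_auroc:.3f}")
pt = result.per_triplet["auroc"]
print(f"per-triplet AUROC    {pt.mean:.3f} +/- {pt.sd:.3f}  ({pt.n_groups} triplets)")
print(f"baseline AUPRC       {result.baseline_auprc:.3f}")
top = result.attention_report.results[0]
print(f"top attention node   {top.node}  (adjusted p = {top.p_adjusted:.2e})")
print(f"planted causal sets  {result.dataset.causal_sets}")
```

prints

```
held-out AUROC       1.000
per-triplet AUROC    0.998 +/- 0.016  (106 triplets)
baseline AUPRC       0.485
top attention node   SET00  (adjusted p = 8.91e-04)
planted causal sets  ['SET00', 'SET01', 'SET04']
```

The model recovers the planted labels on a held-out fold whose triplets
were never seen in training, beats the most-prevalent-label baseline at
the per-triplet level (a constant predictor scores 0.5 there), and the
attention analysis ranks a truly causal gene set first.

The same stages are available from the shell: `safer synth`, `safer
curate`, `safer featurize`, `safer train`, `safer evaluate`, `safer
explain` (see `safer --help`).

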