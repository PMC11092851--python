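# Methods

## Problem and labels

The unit of prediction is a single dose combination: (drug A, drug B,
cell line, dose A, dose B). Labels come from the Loewe additivity
score: > 10 is synergistic (1), < −10 antagonistic (0). A sample whose
Loewe score lies inside the band — possible when another synergy score
carried it past the additive filter — is excluded as indeterminate
rather than forced into a class.

## Curation pipeline

Raw dose-level records pass through, in order: (1) drug-name
unification — names sharing one SMILES string map to one canonical id
(the lexicographically first name) and the pair is ordered so (A,B) and
(B,A) coincide, with doses following their drug; (2) replicate
averaging over identical (triplet, dose pair) groups — all four synergy
scores and the inhibition are replaced by arithmetic means and study
tags are merged; (3) removal of non-cancer screens by a configurable
study-tag blacklist (default: malaria, SARS-COV-2); (4) additive
exclusion when *all four* of BLISS, HSA, LOEWE and ZIP lie in the
closed interval [−10, 10]; (5) exclusion of fully-synergistic samples
(all four scores > 10) with negative %inhibition, which indicate
growth rather than killing; (6) Loewe binarization. Averaging precedes
the filters; each removal is attributed to exactly one rule and the
stage counts in the report reconcile, which the tests check by
construction. The pipeline is idempotent and order-independent.

Gene-set collections are size-filtered before use: sets whose size
falls outside mean ± one standard deviation of all set sizes are
dropped. The sample standard deviation (n − 1) is used and the interval
is closed, so equal-sized collections survive intact.

## Featurization

**ssGSEA.** Per sample, genes are rank-normalized (average ranks scaled
to 10000·rank/n) and sorted descending. A set's enrichment score is the
summed difference between the weighted in-set running CDF (step
|v|^0.25, normalized over the set) and the uniform out-of-set running
CDF. Scores are min-max normalized by the range of the entire ES matrix.
This matches the conventional single-sample GSEA implementation, and
the test suite checks agreement with `gseapy` to 1e-6 on a random
fixture. Enrichment uses no labels, so it is computed once rather than
per fold.

**Dose scale.** Raw concentrations span orders of magnitude; all dose
injection and dose one-hot vocabularies use t(d) = log10(d + 1). Zero
dose maps to zero signal and injection is linear in each transformed
dose.

**Cell features.** F_row = (t(doseA) + t(doseB)) × NES over the
gene-set hypergraph nodes.

**Drug-pair features.** Each drug's transformed dose is placed on its
own nodes (k-mer tokens of its SMILES plus gene sets overlapping its
associated genes); a node shared by both drugs receives the sum.
SMILES shorter than k contribute the whole string as a single token.
Overlap between a drug's genes and a gene set is binary — any shared
gene makes the drug incident to that set node.

**Covariates.** One-hot blocks for dose A, dose B (distinct transformed
concentrations seen in training), tissue, gender and age decade.
Vocabularies are built on the training folds only; unseen categories
encode to an all-zero block.

**Hypergraph orientation.** The gene-set hypergraph uses sets as nodes
and genes as hyperedges, so the subgraph attention ranges over gene
sets and the attention analysis reports set-level hits; a flag
transposes the construction for users who want gene-level nodes.

## Model

Implemented on a small reverse-mode automatic-differentiation core over
numpy (`safer.autodiff`), whose gradients are validated against central
finite differences in the test suite. Each hypergraph has its own
attention parameter set (shared parameters across the two very
different node vocabularies would force one geometry onto both).

Choices the architecture leaves open, resolved as follows:

* attention-ready state s = tanh(W·[h_node; h_edge]) with one W and one
  context vector c per hypergraph, shared across layers;
* initial node embeddings are a learned table; initial hyperedge
  embeddings are the mean of their incident nodes;
* k = 2 message-passing layers by default (configurable);
* the subject representation is the per-subject subgraph embedding
  h_G(j) (the stack of these forms the batch matrix);
* optimizer Adam with a cosine learning-rate schedule decaying to zero
  over the epoch budget; weight decay 1e-5.

Defaults follow the tuned values: FNN hidden width 200, dropout 0.2
after the subgraph layer and 0.3 inside the head, ELU activations,
batch normalization on the concatenated input. Embedding width d
defaults to 32, which is ample for the toy-scale studies the package
ships with; all of these sit in `ModelConfig` and a checkpoint stores
the full parameter state.

Training minimizes BCE-with-logits; the checkpoint with the best
validation AUPRC is kept. A single seed drives initialization, batch
shuffling and dropout, and the same seed reproduces the training
history bitwise. Single-class training folds are rejected.

## Evaluation

Splits are grouped k-fold on the canonical triplet key: distinct
triplets are shuffled and dealt round-robin, so no triplet ever spans
train and test and fold sizes (in triplets) differ by at most one.

AUPRC is step-wise average precision with descending-score ties
processed as one threshold block; this makes a constant predictor score
exactly the positive prevalence, so the most-prevalent-label baseline
is analytic. AUROC uses the Mann-Whitney convention with tied pairs
counting 0.5, pinning any constant predictor at exactly 0.5. Both are
delegated to scikit-learn, which implements exactly these conventions,
and are verified against exhaustive brute-force oracles on small
instances.

Per-triplet metrics recompute each metric within a triplet's dose
combinations and average across triplets; groups where a metric is
undefined (no positives for AUPRC, one class for AUROC) are skipped and
counted. Dose quadrants compare each dose to the drug's IC50 in that
cell line: strictly above is "high", equal counts as "low"; samples
missing an IC50 are excluded and counted, and the four quadrants
partition the covered samples.

## Attention-weight analysis

Weighted subgraphs are the elementwise product of eval-mode attention
weights (final checkpoint) and subject feature values, so they vanish
off the subject's support. Within a pool (one triplet across its dose
combinations, or one drug pair across cell lines) each supported node's
weights are compared between synergistic and antagonistic samples with
a two-sided Mann-Whitney U test — exact null distribution up to a
combined n of 20 without ties, tie-corrected normal approximation
otherwise — followed by Benjamini-Hochberg adjustment; nodes with
adjusted p < 0.05 are reported with their direction. Pools for
reporting are chosen by per-triplet AUPRC (ties broken by sample
count): interpretation is most meaningful where the model actually
separates the classes.

## Synthetic studies

The generator emulates the shapes of a dose-level combination screen:
i.i.d. log-normal expression, random gene sets whose sizes straddle the
size filter, random SMILES-like strings over a 7-character alphabet
(chemical validity is irrelevant to k-mer mechanics), square dose grids
spanning 0.1–100 concentration units, per-(drug, cell) IC50s, and cell
phenotypes. A designated subset of retained gene sets is causal; the
noise-free logit is effect_size × meanNES_causal(cell) × (t(doseA) +
t(doseB) − center) with the grid-average dose sum as center, so the
signal changes sign along the dose axis and a triplet genuinely
switches class with dose — the regime the model exists for. Loewe is
10 × logit (so the ±10 thresholds correspond to |logit| = 1) and the
other scores are noisy copies. Fractions of records are overwritten as
additive, non-inhibitory or non-cancer, or duplicated as replicates, to
exercise every curation rule. Defaults: 120 genes, 30 sets (3 causal),
10 cells, 12 drugs, 4×4 grid, effect size 15, noise sd 0.3 — roughly
10,500 records, of which about half survive curation.

What passing on this data does and does not show: it demonstrates that
the implementation recovers a planted dose-dependent signal through the
full pipeline and that the attention analysis localizes it, not that
the architecture attains any particular accuracy on real screens, whose
expression covariance, chemistry and synergy-score noise the generator
does not model.

## Numerical notes and limitations

Softmaxes are computed with a detached per-slice max shift (softmax is
shift-invariant); every attention weight vector sums to 1 within 1e-6.
Empty hyperedges, isolated nodes, all-zero subject rows and single-class
pools are errors, not silent degeneracies. The end-to-end experiment
and acceptance checks use the toy study sizes above with 20–30 epochs
of full-batch-shuffled minibatch Adam; these sizes were chosen so a
complete run finishes in well under a minute on one CPU core while
leaving hundreds of test triplets. The package runs entirely on CPU;
very large hypergraphs (tens of thousands of nodes) would need a
sparse-incidence attention implementation that is out of scope here.
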