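# regionfp — region-specific propagation of protein function labels

Most protein function prediction transfers Gene Ontology (GO) labels
between whole proteins, even though many molecular functions — DNA
binding, metal coordination, catalysis — live in specific regions of the
chain. `regionfp` is a library (plus a thin CLI) for localizing
protein-level GO annotations to protein *regions*: continuous stretches of
sequence delimited by a consensus over typed feature annotations
(domains, families, signal peptides, transmembrane segments, disorder).
It is aimed at computational biologists who have InterProScan output and
GO annotation files and want region-resolved function predictions, or who
want to study which GO terms are region-specific at all.

## The model

Proteins are *groups*, regions are *instances*. Each region `i` is a
TF-IDF vector `x_i` in one of four feature spaces (3-mers, keywords,
InterPro entry IDs, member-database signature IDs) and is scored by a
logistic model

    ŷ_i = 1 / (1 + exp(−θᵀ x_i)),

with the protein score the max over its regions, `Ŷ_k = max_{i⊂r_k} ŷ_i`
(a protein has a function if at least one region does). For each GO term
an independent θ minimizes a four-term group-instance cost function:

    J(θ) = 1/N_p   Σ_k Δ(Ŷ_k, Y_k)                      protein-level fit
         + w₁/N_r² Σ_i Σ_j κ(x_i, x_j) Δ(ŷ_i, ŷ_j)      similar regions, similar scores
         + w₂/N_r⁺ Σ_{i∈r⁺} Δ(ŷ_i, y_i)                 known region anchors
         + λ/N_p   ‖θ‖²                                  ridge

where Δ is the square loss, κ is the cosine similarity between region
vectors thresholded at the 95th percentile of a random region sample, and
r⁺ is the (sparse, often empty) set of regions with known positive labels
from signature-to-GO mappings. Training is minibatch SGD with momentum,
seeded from an L2-regularized logistic regression on whole-protein
features — which simultaneously serves as the *whole-protein baseline*
the region model is compared against.

## Worked example

```python
from regionfp import build_regions
from regionfp.synthetic_fixtures import generate_annotation_fixture

protein, annotations = generate_annotation_fixture()
for r in build_regions(protein, annotations):
    print(r.index, r.start, r.end, r.origin_type.value)
```

prints

```
1 1 249 Domain
2 250 338 Unassigned
3 339 402 Domain
4 403 511 Unassigned
```

i.e. a 511-residue protein with two annotated domains (1–249, 339–402)
becomes **four** regions — the two domains plus two unannotated stretches
that remain first-class prediction units. Running
`python examples/03_train_planted_model.py` trains the model on a
200-protein synthetic corpus with a planted region-specific function and
5% label noise and prints

```
region-level AUPR against structure-derived binding labels:
  region-specific model : 1.0000
  whole-protein baseline: 0.9719
```

the area under the precision–recall curve for ranking the truly
functional regions: the whole-protein baseline is misled by
family-level vocabulary shared across all regions of a protein, while the
region-trained model localizes the signal. The other scripts in
`examples/` walk through boundary building, the feature spaces and
kernel, and the bootstrap/Wilcoxon evaluation protocol.

The `regionfp` CLI exposes the same pipeline as shell commands
(`simulate`, `regions`, `featurize`, `train`, `predict`, `evaluate`); see
`regionfp --help`.

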