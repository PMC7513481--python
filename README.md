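# dpddi

Link prediction on drug-drug interaction (DDI) networks. `dpddi`
implements DPDDI, a deep predictor that needs **no drug properties**: it
learns each drug's embedding from the topology of the interaction network
itself with a two-layer graph-convolutional autoencoder, aggregates two
embeddings into one pair feature vector, and classifies pairs with a
five-layer feed-forward network. It is aimed at computational
pharmacologists screening candidate co-prescriptions when fingerprints,
targets or ATC annotations are incomplete or unavailable.

## The model in brief

Let A be the m×m symmetric binary adjacency of the DDI network and
Â = D̃^(−1/2)(A + I)D̃^(−1/2) its self-looped symmetric normalization. The
feature extractor

    Z = ReLU( Â · ReLU( Â · H⁰ · W⁰ ) · W¹ )        (H⁰ = I without node features)

is trained full-batch with Adam to reconstruct A through the inner-product
decoder q(a_ij) = σ(z_i·z_j) under a positive-weighted cross-entropy, where
the positive class is up-weighted by W_pos = #unlabeled / #annotated pairs
to counteract network sparsity. Pair vectors [z_i, z_j] (concatenation;
summation and inner product are available for ablation) feed a
256→128→64→32→2 ReLU/softmax classifier trained on annotated pairs versus
sampled unlabeled pairs. Evaluation is 10 × 5-fold cross-validation with a
90/10 train/validation split of held-in folds and a leak-free encoder
adjacency (held-out edges are never visible during embedding).

## Worked example

Everything is runnable without external data via the built-in
planted-community generator:

```python
from dpddi import DPDDI, BENCHMARK_SBM, generate_sbm_network
from dpddi.benchmarks import FIXTURE_ENCODER, FIXTURE_PREDICTOR

net = generate_sbm_network(BENCHMARK_SBM)      # 200 drugs, 4 communities
model = DPDDI(net, operator="concatenation", ratio=1,
              encoder_config=FIXTURE_ENCODER,
              predictor_config=FIXTURE_PREDICTOR)
res = model.fit(seed=5)
print(res.summary())
print(res.rank_novel(top_k=5).to_frame(net.drug_ids))
```

```
DPDDI results (dpddi 0.1.0)
  network: 200 drugs, 1731 interactions (sparsity 8.7%)
  positive weight W_pos = 10.50
  embeddings: 200 x 32
  operator: concatenation; negatives per positive: 1 (1731 sampled)
  encoder loss: 1.2655 -> 1.0559 over 300 epochs
  predictor loss: 0.6791 -> 0.5390 over 140 epochs
  seed: 5
  drug_id_1 drug_id_2     score  rank
0      D000      D001  0.755455     1
1      D000      D002  0.755455     2
2      D000      D004  0.755455     3
3      D000      D005  0.755455     4
4      D000      D007  0.755455     5
```

The summary reports the class imbalance the reconstruction loss corrects
(W_pos ≈ 10.5: unlabeled pairs outnumber interactions ten to one), both
training traces, and the top-ranked *unobserved* pairs — the case-study
output: every listed pair is absent from the input network, and the score
is the predicted interaction probability. All the top pairs here lie inside
the same planted community, as they should; the heavily regularized
classifier assigns many within-community pairs an identical saturated
score, and tied scores rank in deterministic pair-index order (ranking
metrics count ties half-weight, so they are unaffected).

Cross-validated evaluation and the ablations use the same objects:

```python
report = model.cross_validate(n_runs=1, seed=1)
print(report.summary())          # AUC/AUPR/ACC/P/R/F1 per fold + grand mean
```

A `dpddi` console script wraps the library for shell use
(`dpddi simulate|train|evaluate|predict --help`), writing TSV/JSON
artifacts plus a provenance record (config hash, seed, version) per run.

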