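# xgbcda

Prediction of circRNA–disease associations from heterogeneous similarity
networks with gradient-boosted-tree leaf embeddings.

Circular RNAs (circRNAs) are covalently closed transcripts increasingly
implicated in cancer and other diseases, but experimentally confirming a
circRNA–disease link is slow and expensive. This package ranks unknown
(circRNA, disease) pairs by how likely they are to be associated, given a
catalog of known associations, circRNA expression profiles and a
disease–disease semantic similarity matrix. It is aimed at computational
biologists triaging candidate associations before experimental follow-up.

## Method

Let `A` be the binary circRNA × disease association matrix, with rows
`y_c` (circRNA interaction profiles) and columns `y_d`.

1. **Similarity networks.** circRNA expression similarity is Pearson
   correlation binarized at 0.4 (`CS_EP(i,j) = 1` iff `r > 0.4`). The
   Gaussian interaction-profile (GIP) kernel is
   `K(i,j) = exp(−γ‖y_i − y_j‖²)` with bandwidth
   `γ = γ′ / ((1/n) Σ‖y_i‖²)`, `γ′ = 1`. The integrated circRNA similarity
   CS keeps `CS_EP` wherever it is nonzero and falls back to the GIP
   kernel; disease similarity DS fuses the semantic matrix with the
   disease-axis GIP kernel the same way.
2. **Pair features.** For each endpoint of a candidate pair: mean and
   10-bin histogram of its similarity scores, neighbor count and
   degree/closeness/betweenness centrality in the graph that links nodes
   whose similarity exceeds the global mean, and mean + histogram of its
   10 most-similar neighbors. The pair additionally carries its row of `W`
   and column of `H` from a rank-8 non-negative factorization `A ≈ WH`.
3. **Leaf embedding.** A first XGBoost classifier is fit on these
   features; each sample is re-encoded by the leaf it reaches in every
   tree (one-of-K per tree) and the encoding is concatenated with the
   original features.
4. **Final model and evaluation.** A second XGBoost classifier
   (learning_rate 0.1, 463 trees, depth 5, min_child_weight 4, gamma 1)
   is trained on the stacked features. Known associations are balanced
   with an equal number of sampled unknown pairs and evaluated by
   stratified k-fold cross-validation (ACC, AUC, PRE, REC, F1).

A synthetic benchmark generator plants matched circRNA/disease group
blocks in all three input tables so the whole pipeline can be exercised
without any external download.

## Worked example

```sh
python examples/05_cross_validation.py
```

```
fold      ACC      AUC      PRE      REC       F1
   1 0.815789 0.847645 0.852941 0.763158 0.805556
   2 0.750000 0.845914 0.731707 0.789474 0.759494
   3 0.697368 0.749307 0.702703 0.684211 0.693333
   4 0.760000 0.857041 0.777778 0.736842 0.756757
   5 0.773333 0.876956 0.717391 0.891892 0.795181
mean 0.759298 0.835373 0.756504 0.773115 0.762064

mean AUC 0.835: probability a held-out true association outranks a sampled unknown pair
permuted-label mean AUC 0.482: chance level, as it should be
```

On a 100 × 30 synthetic benchmark the pipeline reaches mean fivefold AUC
0.835 — a randomly chosen held-out true association outscores a random
unknown pair about 84% of the time — while destroying the labels drops it
to chance, confirming the score reflects planted structure rather than an
artifact of the protocol. The other scripts in `examples/` walk through
simulation, similarity construction, feature engineering, the leaf
embedding and candidate ranking; each prints the quantities it computes.

A thin CLI wraps the same functions:

```sh
xgbcda --seed 7 simulate --out data/
xgbcda --seed 7 cv --assoc data/associations.tsv --expr data/expression.tsv \
       --dsim data/disease_similarity.tsv --folds 5 --out metrics.json
xgbcda --seed 7 predict --assoc data/associations.tsv --expr data/expression.tsv \
       --dsim data/disease_similarity.tsv --score-threshold 0.9 --top 20
```

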