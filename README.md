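# crfalign

Pairwise global alignment of a query protein to a template protein with
first- and second-order conditional random fields (CRFs), for the alignment
step of template-based structure modeling.

An alignment is a monotone path on the `(Lq+1) x (Lt+1)` lattice from the
dummy corner `(0, 0)` to `(Lq, Lt)`, each step labelled match (`M`), query
insertion (`Iq`) or template insertion (`It`).  The CRF scores a label
pattern at lattice position `(x, y)` with

    Psi^{t->u->v}(x, y) = exp( phi^v(x, y) + phi^{u->v}(x, y) + chi^{t->u->v}(x, y) )

where `phi` (node), `phi^{u->v}` (edge) and — at order 2 — `chi` (triple)
are log-factors: small neural networks (one hidden layer of 12 tanh units,
no bias) fed the concatenation of per-label feature vectors, or single
trainable constants for label patterns too rare in training (empirical
frequency below 0.002).  There are 12 log-factors at order 1 (3 node + 9
edge) and 39 at order 2 (+27 triples).  The probability of an alignment `A`
is the normalized product of its scores,

    p(A | qt, theta) = (1 / Z) * prod_i Psi(x_i, y_i),

with the partition function `Z` computed exactly by a forward–backward
algorithm over 3 (order 1) or 9 (order 2) suffix-pattern terms per lattice
cell, entirely in the log domain.  Training minimizes the L2-regularized
mean negative log-likelihood of reference alignments by full-batch gradient
descent with momentum (defaults `l2 = 0.001`, `eta = 0.01`, `gamma = 0.5`,
100 epochs), selecting the epoch with the best validation accuracy.
Decoding replaces the forward sums with maximizations (Viterbi) and
backtracks the single best global alignment.

Per-residue features follow the template-based-modeling standard: a match
is scored by profile–profile inner product (PSFM·PSSM), BLOSUM50
substitution score, and secondary-structure and solvent-accessibility match
scores; insertions by a context hydropathy count, relative solvent
accessibility (for the query estimated as `RSA = 10 p(B) + 42 p(M) + 100
p(E)`) and the 3-state secondary-structure class.  A synthetic-data module
generates query–template pairs with planted reference alignments and
label-correlated feature grids — including a gap-extension signal carried
by label *triples* — so the whole pipeline runs with no external programs
or downloads.  See `docs/methods.md` for the model account and design
choices.

## Worked example

```sh
crfalign simulate --out-dir data --seed 7
# wrote 45 pairs to data (seed 7)

crfalign train --data-dir data --order 2 --seed 7 \
    --model-out model2.json --history-out hist2.tsv --quiet
# selected epoch 9 (validation accuracy 92.80%)
# model written to model2.json

crfalign align --model model2.json --pair data/pair_037.features.tsv --out aln.tsv
# alignment of 22x30 pair written to aln.tsv (log score 81.0696)

crfalign eval --predicted aln.tsv --reference data/pair_037.ref.tsv
# pairs: 1  per-pair accuracy: 100.00%  per-residue accuracy: 100.00%
```

`simulate` writes 45 synthetic pairs (30 train / 5 validation / 10 test)
with feature grids, reference alignment TSVs and a manifest.  `train` fits
a second-order CRF; the history file traces the loss and the
reference-dependent accuracies per epoch (here epoch 0: loss 43.1, training
accuracy 3.0%; epoch 99: loss 1.45, training accuracy 96.5%) and the model
snapshot is taken at the epoch with the best validation accuracy.  `align`
Viterbi-decodes a held-out pair — the log score is the decoded path's
cumulative log `Psi` — and `eval` reports the percentage of query residues
whose predicted template partner agrees with the reference alignment, both
averaged per pair and pooled per residue.

The library mirrors the CLI: `simulate_dataset`, `train`, `viterbi_decode`,
`reference_dependent_accuracy` and friends are importable from `crfalign`.

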