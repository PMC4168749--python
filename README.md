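# funcnet

Composite functional-network construction and gene prioritisation by label
propagation — a standalone engine for guilt-by-association gene function
prediction.

Given an organism's genome table, a collection of weighted evidence networks
(co-expression, physical interactions, shared protein domains, ...) and a
query gene list, `funcnet`:

1. resolves and autocompletes gene names against the organism's synonym index;
2. assigns each selected network a weight — equal, group-balanced, or
   *query-adaptive* (networks whose edges track the query's internal
   structure are up-weighted, uninformative ones driven to zero);
3. builds a composite network as the weighted sum of symmetric-normalized
   source networks, collapsing multi-edges by summation while retaining
   per-edge provenance (source network, group, original weight, publication);
4. scores every gene in the genome by label propagation from the query; and
5. ranks related genes and attributes (e.g. protein domains), emits at most
   one display edge per evidence group per gene pair, and annotates result
   sets by hypergeometric enrichment.

Users can define their own organisms from a tab-delimited genome file, import
tab-delimited edge lists and expression profiles (converted to sparse
co-expression networks), and benchmark prediction quality by k-fold
cross-validation. Networks persist as compact binary sparse matrices.
Non-biological networks (e.g. social networks) work unchanged.

## The model

Source networks are symmetric non-negative adjacencies `W_k` over the gene
universe. Each is degree-normalized, `W̄_k = D_k^{-1/2} W_k D_k^{-1/2}`, and
combined with weights `α_k ≥ 0`:

    W* = Σ_k α_k W̄_k

Query genes get label `y_i = 1`, all others `y_i = 0`, and scores `f` solve
the Gaussian-field system

    (I + λ L̄) f = y,   L̄ = D̄ − W*

with `D̄` the diagonal of composite row sums and `λ > 0` the smoothing
strength (default 1). The system is symmetric positive definite and solved by
conjugate gradients; scores satisfy `0 ≤ f_i ≤ 1` and reduce to `f = y` at
`λ = 0`. Query-adaptive `α` comes from non-negative least squares with an
intercept and ridge penalty, regressing the pair target (1 for query–query
pairs, 0 for query–non-query pairs) on `(W̄_1[pair], …, W̄_m[pair])`.

## Worked example

`examples/query_related_genes.py` builds a synthetic organism (200 genes, 4
planted functional modules of 30 genes, three evidence networks) and queries
with 5 members of module 1:

```
network weights (query-adaptive):
  co-expression-1              0.749
  physical-interaction-1       0.114
  shared-protein-domains-1     0.136

top related genes (gene, score, planted module):
  G0015    0.1002   module 1
  G0020    0.0962   module 1
  G0019    0.0904   module 1
  ...

mean score, unqueried module members: 0.0690
mean score, genes outside the module: 0.0027
```

All ten top-ranked genes are unqueried members of the planted module, and the
adaptive weighting has concentrated on the most informative evidence network.
The 25-fold score gap between module members and outsiders is the
guilt-by-association signal. `examples/cross_validation.py` reports 5-fold
cross-validated AUROC 1.000 on each planted module annotation, and
`examples/cli_workflow.sh` walks the same pipeline through the command line
(`funcnet import-organism / import-network / import-profile / query /
crossval`).

## Command line

```
funcnet import-organism genome.tsv --db DB
funcnet import-network edges.tsv --db DB --name ppi --group physical-interaction
funcnet import-profile profile.tsv --db DB --top-k 50
funcnet query --genes list.txt --db DB --weighting adaptive --related 20 --out OUT
funcnet crossval --db DB --term-file annotations.tsv --folds 5 --seed 1 --out cv.json
funcnet enrich --genes list.txt --db DB --term-file annotations.tsv --out enrich.tsv
funcnet make-fixture --out DIR [--spec spec.json] [--seed N]
```

Outputs are a node table (gene, score, is_query), an edge table of display
edges with per-source provenance, and a JSON bundle embedding the full run
configuration, so identical runs are byte-for-byte identical.

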