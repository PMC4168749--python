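# Methods

## Problem setting

`funcnet` predicts gene function by association: genes that are densely
connected to a query list in a composite functional network are likely to
share function with it. The engine is organism-agnostic — the gene universe,
networks, and profiles are all user-supplied — and all computation happens on
sparse symmetric matrices indexed against the universe.

## Identifier index

A genome table (one row per gene: primary ID, then synonyms) defines the
universe; indices are dense `0..n-1` in file order. Matching is
case-insensitive, because gene symbol capitalisation is inconsistent across
sources, and a synonym claimed by two different genes is a hard error rather
than first-wins: a silently misassigned synonym would corrupt every matrix
row attributed to it. Autocompletion is a case-insensitive prefix scan of the
in-memory index, sorted lexicographically; for the database sizes this
package targets a scan is fast enough that no inverted index is needed.

## Network store and normalization

Source networks are symmetric, non-negative, zero-diagonal sparse matrices.
Edge-list import sums duplicate pairs (consistent with the collapse-by-sum
semantics of composite construction), drops self-edges (the propagation
system handles the diagonal through its identity term), and skips — but
counts and reports — unresolvable gene names. A zero-weight row is dropped;
a negative weight is an error.

Before weighting or combination every network is normalized as
`W̄ = D^{-1/2} W D^{-1/2}` with `D` the diagonal of weighted degrees. This
bounds the spectral radius of each `W̄` by 1 (so the propagation system stays
well conditioned for any convex combination), and stops dense or
heavy-weighted networks from dominating the composite purely through scale.
Isolated genes keep zero rows.

Persistence is a little-endian binary format (`GMNW`, version 1): header,
upper-triangle CSR arrays (int64 indices, float64 values), then a
length-prefixed JSON metadata block. Only the upper triangle is stored —
symmetry makes the lower half redundant — and float64 weights round-trip bit
for bit. Truncation, bad magic, or a dimension mismatch with the universe
are detected before any partial network is returned. The format is a
documented stand-in of this package's own design; it makes no attempt to
read any other tool's files.

## Co-expression conversion

Expression profiles (genes × samples, ≥ 2 samples, duplicates averaged,
missing values rejected) are converted to networks by pairwise Pearson
correlation. Zero-variance genes get no edges; correlations ≤ 0 are dropped
(the adjacency contract is non-negative, and negative co-expression is a
different evidence type); each gene keeps its `k` largest-correlation
partners and a pair survives if either endpoint selects it. The default
`k = 50` mirrors common co-expression practice: it keeps genome-scale
networks sparse (≤ `k·n` edges) while retaining module structure. Edge
weight is the correlation itself, so weights lie in (0, 1]. Ties in the
top-k selection break deterministically by gene index.

## Network weighting

Three methods, selectable per query:

- **equal** — `α_k = 1/m`. Baseline.
- **group** — each evidence group receives `1/(#groups)`, split equally
  inside the group. Protects against one category contributing many
  redundant networks.
- **query-adaptive** (default) — non-negative least squares with intercept
  and ridge. Rows of the design are gene pairs touching the query: target
  `t = 1` if both endpoints are query genes, `t = 0` if exactly one is;
  predictors are the pairs' normalized weights in each network. The
  intercept is unconstrained (implemented as a difference of two
  non-negative columns so a single NNLS call solves the whole system); the
  ridge penalty (default `1e-3`, exposed as a flag) applies to the network
  coefficients only and stabilizes collinear networks — in particular it
  forces near-equal splits across duplicated networks instead of arbitrary
  tie-breaking. Coefficients are rescaled to sum to 1. If every coefficient
  is clipped to zero (no network carries query-pair signal) the method falls
  back to equal weights with a warning. Queries of fewer than 2 genes carry
  no co-membership signal, so the pipeline falls back to equal weights for
  them as well.

The pair design enumerates `O(|q|·n)` rows, which is cheap for interactive
query sizes; this keeps the estimator exactly testable against an
independently enumerated NNLS oracle.

## Composite network and display collapse

`W* = Σ_k α_k W̄_k`, with every nonzero pair retaining a provenance record
per contributing network: name, group, original (raw) edge weight,
normalized weight, and `α_k`. Zero-weight networks are excluded from both
the sum and the provenance. For display, the multi-edges of each gene pair
collapse to at most one edge per evidence group; the display weight is the
within-group sum of `α`-scaled normalized weights (so the per-pair display
weights sum exactly to the composite entry), while the per-source
annotations expose the raw weights and publication text. `combine()`
therefore takes the raw networks and normalizes internally: the raw values
must be in hand for provenance, and normalizing an already-normalized
network would change it.

## Label propagation

Scores solve `(I + λ(D̄ − W*)) f = y` with `y` the 0/1 query labels. The
matrix is symmetric positive definite for any `λ ≥ 0`, so conjugate
gradients converge unconditionally; because the off-diagonal is
non-positive and row sums equal 1 plus the label term, the solution obeys
`0 ≤ f_i ≤ 1` (maximum principle), equals `y` exactly at `λ = 0`, and
leaves isolated genes at their label value (enforced exactly after the
solve, against float round-off). Defaults: `λ = 1`, relative residual
tolerance `1e-10`, iteration cap `10·n`; at these settings the iterative
solution matches a dense direct solve to ~1e-10 on instances up to n = 50,
comfortably inside the 1e-8 equivalence the tests assert.
Non-convergence raises an error carrying the achieved residual — it is
never silently accepted.

Ranking returns non-query genes with positive score, descending, ties broken
by ascending universe index for deterministic output; `N = 0` is legal and
connects the query genes only. Attribute nodes (e.g. protein domains) are
ranked by the sum of scores of the result genes carrying them — a
score-weighted incidence sum of this package's own design — so attributes
shared by several high-scoring genes dominate attributes carried by one.

## Evaluation

Cross-validation splits a term's member genes into `k` seeded folds
(default 5). Each fold's retained members form the query; held-out members
are ranked against all genes outside the term. Held-out genes stay in the
network (transductive evaluation — the setting propagation actually runs
in). AUROC uses the Mann–Whitney rank statistic with midrank ties, so an
all-zero score vector scores exactly 0.5; precision@k uses k = held-out
count. Enrichment is the one-sided hypergeometric upper tail with
Benjamini–Hochberg FDR across tested terms — the field-standard choice for
over-representation tables.

## Synthetic data generator

The generator emulates the modular co-functionality structure functional
networks exhibit, with one seeded random stream driving everything
(networks, profile, attributes), so runs are reproducible bit for bit.

- **Networks**: planted partition. Within-module pairs get an edge with
  probability 0.4 and weight Uniform(0.5, 1); all other pairs with
  probability 0.02 and weight Uniform(0, 0.3).
- **Defaults**: 200 genes, 4 modules of 30 (120 module genes, 80
  background), three networks — one each in co-expression,
  physical-interaction, and shared-protein-domains.
- **Profile**: 20 samples; each module has a latent N(0,1) per-sample
  factor; member genes load on it with coefficient 1.0 plus N(0, 0.5²)
  noise (background genes are pure noise). This yields within-module
  Pearson correlations around 0.8 — strong but realistic module
  co-expression — so correlation-based conversion can recover
  co-membership.
- **Attributes**: one domain-like attribute per module, carried by module
  members with probability 0.8 and by others with probability 0.02.
- **Annotations**: one term per module, exactly the member genes.

What passing tests on these fixtures show: the pipeline recovers planted
modular signal through weighting, combination, and propagation. What they do
not show: behaviour under heavy-tailed degree distributions, batch effects,
missing data, or annotation noise — real functional genomics data has all
four, and the fixtures have none.

## Numerical and design choices

- Problem sizes in tests and the acceptance script (n ≤ 250, 20 seeds,
  100 random solver instances) were chosen to exercise every code path at
  desk scale; all complete in seconds.
- Binary weights are float64 specifically so round-trip tests can assert
  bit-exact equality.
- Tie-breaks are deterministic everywhere (universe index for genes, name
  for attributes, column index for top-k), making whole output bundles
  byte-for-byte reproducible.
- Degenerate inputs: empty queries, unresolvable-only gene lists,
  single-sample profiles, all-self-edge networks, truncated binaries, and
  empty post-filter databases are all hard errors with specific messages;
  unresolvable names inside otherwise-valid inputs are skipped and
  reported, never silently dropped.
- The subset concept (core / open-license) is carried as two boolean flags
  on network metadata and applied as a filter; no licensing logic beyond
  the flag is attempted.

## Known limitations

- The query-adaptive estimator is a documented regression formulation, not
  a reimplementation of any particular production weighting; it reproduces
  the qualitative behaviour (informative networks up, uninformative to
  zero) with an exactly testable spec.
- Scores are reported raw, not post-normalized to sum to 1.
- Spearman or mutual-information co-expression, missing-value imputation,
  GO-DAG-aware annotation propagation, and negative-label propagation
  variants are out of scope.
- Networks must fit in memory; there is no streaming path.
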