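# Methods

`netprio` implements seven guilt-by-association gene-prioritization
algorithms over protein–gene interaction (PGI) networks and disease–gene
heterogeneous networks, plus the evaluation harness used to compare them.
This note records the models, the parameter choices that matter, what the
synthetic fixtures do and do not emulate, and the numerical decisions taken
where the design was genuinely open.

## Data model

A PGI network is a simple undirected graph `G = (V, E)` over opaque string
node ids, stored as an ordered node list plus a sparse symmetric 0/1
adjacency matrix `A` with zero diagonal; degrees `k` are row sums and
`m = |E|`. Scored edge tables (e.g. STRING-style confidence columns) are
filtered with a caller-supplied threshold at load time; self-loops and
duplicate edges collapse. No id mapping to external ontologies is attempted.

The heterogeneous network adds a bipartite gene–disease association (GDA)
matrix `A_PD` (n×d) and a disease–disease similarity matrix `A_DD` (d×d),
assembled into the expanded block matrix

    A_expand = [ A      A_PD ]
               [ A_PD'  A_DD ]

so propagation and embedding methods can treat genes and diseases as one
graph.

Ranking is tie-aware throughout: tied scores receive the average of the
positions they span (so the rank sum over `n` candidates is always
`n(n+1)/2`, and equal-degree genes share a fractional rank under the degree
baseline). Rank 1 is best.

## Prioritizers

**Random walk with restart (RWR).** With `W = A D_k^{-1}` the
column-normalized adjacency and `p_0` uniform over the seed genes, iterate
`p_t = (1−r) W p_{t−1} + r p_0` until `‖p_t − p_{t−1}‖_1 < 1e−8`
(iteration cap 10 000). The converged probabilities are the scores. The
restart probability `r` defaults to 0.5; the benchmarking grid 0.1–0.9 in
steps of 0.2 is available via configuration. Zero-degree ("dangling")
columns would leak probability, so the mass sitting on zero-degree nodes is
redistributed to `p_0` each step — total probability stays 1 and isolated
non-seed nodes receive score 0. The converged vector agrees with the dense
closed form `r (I − (1−r)W)^{-1} p_0` to well below 1e−6 on graphs without
dangling nodes (tested).

**RWRH.** The same iteration on `A_expand`, column-normalized as one
matrix. The restart vector places all mass uniformly on seed genes by
default; an option moves a configurable fraction onto the query-disease
node. Gene-block entries of the converged vector are the scores; with empty
GDA/similarity layers this reduces exactly to RWR (block independence).
Whether the original formulation normalized per layer with a jump
probability is not determinable from its description; whole-matrix
normalization is used and documented here.

**Node2vec (N2V / N2VH).** Second-order random walks (return weight `1/p`,
distance-1 weight 1, distance-2 weight `1/q`) are sampled per node —
defaults 20 walks of length 80, `p = q = 1`; grids (20, 40, 80),
(40, 80, 160) and (0.5, 1, 2) are supported. Walks feed a skip-gram
negative-sampling model (walks as sentences, nodes as words). The trainer
is a single-threaded numba kernel — linear learning-rate decay from 0.025,
5 negative samples, unigram^0.75 noise distribution — so results are
bit-reproducible under a fixed seed. Window 10 and 5 epochs are package
defaults (the source benchmark does not state them); dimension `d`
defaults to 128 (grid 64/128/256). A gene's score is its maximum cosine
similarity to any seed vector; seeds score exactly 1 by definition. N2VH is
the identical procedure run on the expanded heterogeneous graph, reporting
gene-layer scores. Walks that reach a dead end terminate early rather than
restart; zero-degree start nodes are skipped with a warning.

**DIAMOnD.** Stepwise module growth: at each step, for every non-seed node
adjacent to the current module `S_t`, compute the hypergeometric point
probability of observing exactly `k_st` of its `k` links inside `S_t`
(population `n`); absorb the node with the lowest probability. The
implementation follows the printed point-mass form ("connecting exactly");
the original upper-tail variant is available via `tail=True`. Seed
weighting `α > 1` inflates the counts by `(α−1)|S|` and `(α−1)k_s`, which
keeps the expression a hypergeometric pmf and reduces to the plain form at
`α = 1`. Ties break toward higher `k_st`, then lexicographic node id
(deterministic, logged). Rank = selection step; growth stops at 5000 steps
by default and unselected genes are reported "na" (averaged tail ranks can
be forced when a complete ranking is required, e.g. for hits@10%).

**GenePanda.** Degree-adjusted distances `d_adj(i,j) = d_ij / √(k_i k_j)`
from all-pairs BFS; score(i) = mean distance to the whole network minus
mean distance to the seeds (higher is better). Computed on the largest
connected component — curated PGI networks are essentially one component —
and every seed must lie in it; nodes outside are unranked.

**IDLP.** Dual label propagation learns a gene–disease score matrix `Y`
(genes × diseases, plus one appended query-disease column that is 1 at seed
rows). Per iteration: `A* = A_norm + γ Y Yᵀ`, then
`Y = β (I − α A*)^{-1} A_PD`; mirror update on the disease side with
`A_DD* = A_DD_norm + γ' Yᵀ Y` and `Y = β' A_PD (I − α' A_DD*)^{-1}`.
`A_norm`, `A_DD_norm` are symmetric normalizations `K^{-1/2} A K^{-1/2}`.
Two printed forms of the update ("β(I − α)A*⁻¹A_PD", "β′A_PD(I − α′A_DD*)")
are dimension-inconsistent with the label-propagation literature; the
readings above are the default and the literal printed forms are available
behind `literal=True` for comparison. `Y` is initialized uniform(0,1) from
a recorded seed; 20 iterations are run (fixed count, following the source
protocol) with the per-iteration change `‖Y_t − Y_{t−1}‖_F` logged.
Defaults `α = α' = 0.5`, `β = β' = 1`, `γ = γ' = 0.1`.

*Stability re-normalization.* With a fixed `A_norm` the feedback term
`γ Y Yᵀ` can push the spectral radius of `α A*` above 1, at which point
`(I − α A*)^{-1}` amplifies rather than smooths and the iteration settles
into an oscillation instead of a fixed point. The package therefore
re-applies symmetric normalization (by absolute row sums) to `A*` and
`A_DD*` each iteration before solving — propagation on the *updated*
network uses that network's own normalization. This bounds the propagation
operator's spectral radius by 1 and yields geometric convergence of the
per-iteration change. `renormalize=False` restores the raw update.

**Degree baseline.** Score = degree; seed-independent by construction.

## Evaluation harness

**LOOCV.** Each seed gene is left out in turn; the algorithm runs with the
remaining seeds and the left-out gene's rank is the fold result. On
heterogeneous networks the (query disease, left-out gene) association edge
is removed for the fold and the input is never mutated (bitwise-restore
checked in tests). Remaining seeds are excluded from the candidate ranking
(standard practice; configurable). Median/mean are taken over available
folds with the midpoint convention for even counts; "na" folds (e.g.
DIAMOnD genes never absorbed) are reported as such and also counted.

**Random-seed experiments.** Repeated trials with uniformly drawn seed sets
(default 1000 trials × 10 seeds; any size configurable) expose
seed-independent structure: per-node median ranks are correlated with
degree (Spearman) and binned into degree deciles. A strongly negative
correlation is the degree-bias signature of propagation methods; embedding
scores show much weaker association.

**GWAS validation.** SNPs map to genes by position (same chromosome, within
the 1-based inclusive gene region ± 1000 bp flank; BED input is converted
on read; one SNP may map to several overlapping genes). All SNPs in the top
200 ranked genes are pooled and Benjamini–Hochberg adjusted ("FDR-adjusted"
is realized as BH; recorded in output metadata). Per gene, the indicator
vector of SNPs with adjusted p < 0.05 is submitted to a one-sample t-test
against 0; test p < 0.05 validates the gene. The test is degenerate for
constant indicator vectors, so these are decided deterministically:
all-zero → not validated; all-one (including a single passing SNP) →
validated. Genes with no mapped SNPs are excluded from the denominator and
logged. Externally confirmed genes are additionally summarized by median
rank and hits within the top 10% of predictions.

**Two-community modularity.** `Q = sᵀBs/(4m)` with `s_i = −1` inside the
pathway, `+1` outside, and `B_ij = A_ij − k_i k_j/(2m)` off-diagonal. The
implemented default zeroes `B`'s diagonal exactly as the formulation prints
it — note this makes `Q` nonzero even for an empty pathway
(`Q = Σk_i²/(8m²)`) — and a `standard_diagonal` flag restores the Newman
form. `Q` is invariant under complementing the pathway.

## Synthetic fixtures

The generators produce desk-scale stand-ins for curated networks, with all
randomness funnelled through one recorded seed:

- *Gene network:* Barabási–Albert preferential attachment (default 500
  nodes, 3 edges per arrival) reproduces the heavy-tailed degree
  distribution of real PGI networks; planted modules (default one 30-node
  module, within-module edge probability 0.5) overlay Bernoulli cliques as
  ground-truth functional modules.
- *Heterogeneous layers:* background GDA entries at density 0.01 over 20
  background diseases plus a query disease associated with 10 genes of the
  planted module (the seed set); disease similarities at density 0.1, with
  the query disease unconnected in the similarity layer.
- *GWAS tables:* per-gene SNPs with null p ~ U(0,1) and planted-gene p
  ~ U(0, 1e−8), positions uniform in the flanked gene region, over
  non-overlapping synthetic gene coordinates.

These fixtures deliberately do **not** emulate database-specific edge
semantics, literature-curation degree bias, linkage disequilibrium between
SNPs, or realistic GWAS effect-size distributions. Tests passing on them
demonstrate algorithmic correctness and the qualitative behaviours the
benchmark is designed to expose (planted-module recovery, degree bias,
FDR arithmetic) — not performance on real curated networks.

## Problem sizes and numerical choices

Test and benchmark runs use desk-scale problems chosen as the package's own
defaults: oracle comparisons on random graphs with ≤ 200 nodes
(tolerances 1e−6 iterative-vs-closed-form, 1e−12 for combinatorial and
distance oracles), planted-module recovery on 500-node fixtures over 20
seeded replicates, degree-bias diagnostics with 200 trials × 10 seeds, and
embedding hyperparameters at the small end of the tuning grids
(20 walks × length 40, d = 64, window 5, 3 epochs) for diagnostics.
Degenerate inputs are handled explicitly: empty seed sets, edgeless graphs
and asymmetric matrices are errors; zero-degree nodes are retained in the
node set but excluded from propagation mass; constant rank vectors make the
degree–rank correlation undefined (reported as NaN).

## Known limitations

- The skip-gram trainer is single-threaded by design (determinism over
  speed); embedding very large networks is slow compared to multi-threaded
  word2vec implementations.
- IDLP materializes dense n×n matrices; it is intended for networks up to a
  few thousand genes in this implementation.
- The GWAS gene test inherits the degeneracies of a t-test on indicator
  vectors (documented above); no LD-aware or gene-based association testing
  is attempted.
- GenePanda is undefined across components; the largest-component
  restriction is a documented convention, not part of the original score.
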