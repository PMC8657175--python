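# Methods

## The model

`rcrnet` treats a curated body of causal biology as a *signed two-layer
network* and scores perturbation experiments against it.

The **functional layer** (backbone) is a directed graph over gene symbols.
Each edge comes from a causal statement in a BEL subset — terms `p()`
(protein), `r()` (mRNA), `act()` (molecular activity), `comp()` (complex),
`ma()` (activity annotation); relations `increases`/`decreases` and their
`directly*` variants. Entity forms are collapsed to the gene level for
topology (scoring is per node, not per molecular form) and retained as
statement metadata. A complex subject with *k* members contributes *k*
edges sharing the statement's sign and directness. Statements asserting
the same ordered pair with the same sign merge, pooling one evidence
entry per statement. The same pair asserted with *both* signs is a
curation conflict: the library's default is a hard error naming the
evidence on both sides, because curation errors must surface. The
packaged curated table contains exactly one such conflict (MAPK14→CASP8,
asserted as an indirect activation by one source and a direct kinase-level
repression by another); the packaged loader resolves it with the
`keep_direct` policy — the direct, mechanistic statement wins — which is
the only resolution that uses statement structure rather than a vote.

The **terminal layer** maps each backbone node to a set of signed
downstream genes derived from knocking that node down: a gene moving by
more than 0.5 log2 units at p < 0.01 enters the set with sign
−sign(log2FC) (a gene that falls when its regulator falls is activated by
it). The terminal genes are the measurable proxy for a node's activity,
which is the central assumption of reverse causal reasoning: expression
of a node's downstream transcripts reflects the node's function, without
equating the node's own mRNA with its activity.

### Contextualization rules

Knockdowns are first gated on efficiency (target log2FC < −1, p < 0.05);
inefficient knockdowns are excluded from edge decisions (configurable to
warn-only) and reported. For each curated edge u→v with sign *s* and an
efficient knockdown of *u*:

* the edge is **removed** iff v moved in the direction of +s with
  |log2FC| > 1 and p < 0.05 (significant evidence against the curated
  direction). Only the source's knockdown is consulted — causality is
  directional.
* a **data-driven edge** u→v (sign −sign(log2FC), direct, provenance
  `data_driven`) is added when a backbone node v moves significantly with
  no existing curated edge. Since filtering runs first, a removed curated
  edge can be replaced by a data-driven edge of the opposite sign — the
  same observation that contradicted the curation supports the
  replacement.

The two threshold pairs differ by purpose and are separate configuration
keys: edge decisions use (1, 0.05); the terminal layer uses (0.5, 0.01).
Raw p-values are thresholded, matching the convention of the upstream
differential-expression tooling this pipeline consumes; a
Benjamini–Hochberg option exists in the API but defaults off.

## NPA-style scoring

The published network-perturbation-amplitude methodology defines its
statistics inside a dedicated R package; `rcrnet` implements a
self-contained *data-anchored signed-graph smoothing* formulation with
the same contract: signed per-node coefficients, a non-negative
network-level score, confidence intervals and a permutation p-value. It
is deliberately not a bit-compatible reimplementation of any existing
package.

Given a profile (gene → log2FC vs control), node u's terminal score is
t_u = mean over measured terminal genes g of sign(u→g)·log2FC(g), with
weight w_u = number of genes measured (0 when none, leaving the node
unanchored). Backbone coefficients minimize

    J(f) = Σ_{(u,v)∈E} (f_u − s_uv f_v)² + λ Σ_u w_u (f_u − t_u)²

λ defaults to 1; w_u uses the *measured* terminal-set size so that
well-measured nodes anchor harder, and so the objective reduces to the
plain |terminal(u)| weighting whenever the profile covers the layer. J is
a positive-definite quadratic on every weakly connected component
containing an anchored node (the signed-Laplacian nullspace requires
full-support switching vectors, which the anchor term kills), so the
minimizer is the unique solution of one dense symmetric linear system per
component; unanchored components are set to zero and reported.
Coefficients are not clipped to [−1, 1]: their scale is inherited from
the data.

The network amplitude is mean_E (f_u + s_uv f_v)²/4 — zero exactly when
every edge is maximally incoherent with its sign or all coefficients
vanish, and scaling the profile by c scales it by c² (coefficients are
linear in the profile; negating the profile negates every coefficient and
preserves the amplitude).

Uncertainty: percentile bootstrap (2.5/97.5) resampling each node's
measured terminal genes with replacement and re-solving; at least 100
replicates are enforced because shorter bootstrap runs make percentile
intervals degenerate. The network p-value permutes the profile's gene
labels and uses the add-one estimator (1 + #{perm ≥ obs})/(n_perm + 1),
so it lives on the lattice {1/(n+1), …, 1} and is uniform under an
exchangeable null. All resampling requires an explicit seed.

## Agreement statistics

Coefficients binarize as activation (> 0) or repression (< 0); an exact
zero carries no direction and is *excluded* by default (a `positive`
policy exists for sensitivity analysis). Excluded nodes never contribute
zeros to any average — results that would have no usable comparison are
undefined and skipped.

*Concordance* of an upstream node u: fraction of its one-edge downstream
neighbours whose observed sign equals u·e. *Coherence* of a directed
path: the same per-edge agreement, with the upstream state re-read from
the observations at every step — this follows the definition that the
upstream "changes as we move one edge down the path". A root-anchored
variant (expectation = root state × product of edge signs) is available
behind a flag for sensitivity analysis; the two disagree exactly when an
intermediate observation breaks the chain.

Both rates are reported as Cohen's κ = (observed − expected)/(1 −
expected) with expected agreement fixed at 0.5, the chance level of a
binary direction call; hence κ = 2·rate − 1 identically, and averaging κ
across units equals recomputing κ from the averaged rate.

Agreement distributions are compared to a baseline of i.i.d. uniform ±1
node states (one fresh state per replicate, rates recomputed on the same
structures) using the one-sided two-sample KS statistic D+ =
sup_t (ECDF_baseline(t) − ECDF_sample(t)), clamped at 0 — positive when
observed agreement is stochastically larger than chance. The p-value is
the asymptotic one-sided bound exp(−2D²nm/(n+m)) on the unscaled
statistic. A scaled variant multiplies D+ by √(nm/(n+m)); the unscaled
statistic is bounded by 1, while the scaled one is what grows with sample
size (values like 2 or 3 are possible) and is the variant the pipeline
reports in its summaries.

## Path model

All simple directed paths ending at the target node are enumerated by
depth-bounded reverse traversal (deterministic, lexicographic order).
The length bound is explicit (default 4 edges) because simple-path counts
explode combinatorially through hub nodes; reported path counts are
always relative to the bound. Paths are ranked by mean coherence over the
drugs for which they are defined (ties: shorter path, then lexicographic)
and the union of the top 5 paths with mean coherence > 0.6 forms the
extracted model, each edge annotated with the maximum mean coherence of
the retained paths through it.

## Synthetic data

The generator emulates the three inputs the pipeline consumes, on any
backbone (the packaged curated network by default), with every planted
quantity recorded:

* **Knockdowns** — target log2FC = −2 (a realistic siRNA depth, well
  below the −1 efficiency cutoff); curated downstream responses of
  −s·effect_size; planted terminal genes (default 20 per node, random
  signs) responding with −sign·effect_size; null genes (default 100) pure
  noise. P-values come from a two-sided z-test against the known Gaussian
  noise model, so they are exactly uniform for null genes and the
  pipeline's p < 0.05 / p < 0.01 cutoffs behave as designed rather than
  being sampled ad hoc.
* **Drug profiles** — each drug assigns ±1 activities to a few nodes,
  propagates one step along backbone edges with attenuation 0.5 (the
  minimal structure that makes coherence a non-trivial discriminator),
  and emits terminal-gene responses of activity × sign × effect_size plus
  noise. A `planted` map can pin specific node/sign assignments, e.g. to
  drive a drug strictly through one pathway.
* **Growth** — GRmax per drug and dose in [−1, 1.3], with an exact
  fraction of drugs ineffective (all doses ≥ 1) to exercise the strict
  GRmax < 1 efficacy filter.

Defaults: effect_size 1.5 log2 units and noise_sd 0.1. Real knockdown
responses span several log2 units, and a true effect must clear the
|log2FC| > 1 edge-decision cutoff with margin to be detectable at all —
an effect exactly at the cutoff would be detected half the time by noise
symmetry. An optional `inverted_edges` list generates wrong-direction
responses for chosen edges, emulating curation errors so conflict
filtering can be validated against truth.

What the generator does **not** emulate: microarray probe structure,
L1000 landmark/inferred gene distinctions, correlated noise between
genes, off-network regulation, or realistic expression marginals.
Passing recovery tests therefore demonstrates the pipeline's statistical
machinery is correct and calibrated under its own assumptions, not that
those assumptions hold in any particular real dataset.

## Numerical and design choices

* Linear systems are solved with dense LAPACK (`numpy.linalg.solve`);
  the backbone has tens of nodes, so sparsity is irrelevant.
* Bootstrap CIs are clamped to contain the point estimate, keeping the
  invariant ci_low ≤ coefficient ≤ ci_high even in pathological resamples.
* Tie-breaks everywhere are deterministic (sorted node names, path
  length, lexicographic node sequences); reruns with identical inputs
  and seeds are byte-identical.
* Free-text entity names resolve through a shipped, user-replaceable
  alias table (e.g. "ets-Domain Protein Elk-4" → SAP1A); namespace
  prefixes such as `HGNC:` (including stray bare colons) are stripped.
* The curated table's two index-column/statement mismatches are resolved
  in favour of the statement text, which carries the evidence; the index
  columns are informational.
* Conflict adjudication beyond the mechanical rule (context, evidence
  strength, effect size) is inherently manual; the pipeline surfaces a
  kept/removed/added report for that review instead of guessing.

## Problem sizes

The test suite and the acceptance script run the recovery experiments at
deliberately compact sizes — tens of seeds, 5–20 terminal genes per node,
a few drugs per replicate — chosen so the statistical claims (≥ 95% sign
recovery, ≥ 90% top-ranking of the planted pathway, exact noiseless
reconstruction) are measured at meaningful replication while the whole
suite stays fast enough to run habitually.

## Known limitations

* The scorer is NPA-*style*; its coefficient scale is not comparable to
  the published NPA package's O/K statistics.
* Simple-path enumeration is exponential in the worst case; the length
  bound is the only guard.
* Agreement assumes binary directions; magnitude information is used
  only through the sign of coefficients.
* The KS p-value is asymptotic and conservative for tiny samples; exact
  small-sample p-values are out of scope.
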