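# Methods

`multimorbinet` quantifies how strongly two or three diseases share
molecular mechanisms *within individual cell types*, using only an
interactome, a gene × cell-type expression compendium, disease gene sets
and a pathway catalog. This note documents the model, the defaults, and the
design decisions that were genuinely open, in enough detail to re-derive
every computation.

## Pipeline model

1. **Common universe.** All analysis happens on the genes present in both
   the interactome and the expression matrix; disease and pathway sets are
   intersected with this universe and empty sets dropped.
2. **Specificity.** Each gene's profile is normalized as
   `e_{g,c} = (E_{g,c} − M_g) / MAD_g` with `M_g` the cross-cell median and
   `MAD_g` the raw median absolute deviation (no 1.4826 consistency
   factor — the normalization is a display of relative deviation, not a
   normal-theory sigma estimate). Gene `g` is *c-specific* when
   `|e_{g,c}| ≥ k · IQR(e_{g,·})` with `k = 1.5`, the classical Tukey-fence
   multiplier. The multiplicative reading (`k × IQR`, not `IQR + k`) is the
   fence convention of the robust-statistics literature this rule descends
   from. The IQR is computed on the signed normalized values with
   linear-interpolation ("type 7") quantiles — fixed so results are exactly
   reproducible; the threshold is compared against the absolute value.
   Genes with `MAD = 0` are excluded (division undefined, and a constant
   profile carries no signal); a retained gene with `IQR = 0` is never
   called. Note that `MAD_g` cancels from the call: the rule is equivalent
   to `|E_{g,c} − M_g| ≥ k · IQR(E_{g,·})`, so specificity is scale-free
   per gene.
3. **Cell networks.** The c-specific network is the interactome subgraph
   induced by *edges* joining two c-specific genes; specific genes with no
   specific interaction partner are dropped. Disease-gene enrichment per
   network is a one-sided Fisher exact test (equivalently the
   hypergeometric upper tail) over the restricted universe, BH-adjusted
   jointly across all (cell type, disease) pairs — the widest, most
   conservative family, since the original family is not recoverable.
4. **Pathway catalog.** Hierarchical catalogs are cut at one depth
   (default 3) and redundancy-filtered: while any surviving pair has
   Sorensen-Dice overlap `2|A∩B|/(|A|+|B|)` strictly above 0.5, the
   currently worst pair loses its smaller member (ties: the
   lexicographically later id). Greedy worst-pair-first with deterministic
   tie-breaks makes the result order-independent. Pathway "connectivity"
   within a cell network has no canonical definition, so two are emitted
   side by side: the internal edge count and the fraction of in-network
   pathway genes with at least one internal edge.

## Seed propagation

Disease genes present in a cell network are seeds. The scorer is a
truncated geometric proximity diffusion:

    score(g) = Σ_{t ∈ seeds} λ^{d(g,t)},   contributions beyond
    d > repetitions × iterations are zero

with decay `λ = 0.5` and horizon `repetitions × iterations = 3 × 2 = 6`
(the reach a local message-passing scheme with those loop counts would
have). This form was chosen over accumulate-and-renormalize neighbor
averaging because it *provably* satisfies the property that defines
guilt-by-association prioritization — with a single seed, scores are
non-increasing in shortest-path distance on every graph (verified by brute
force over all connected graphs with ≤ 6 nodes in the test suite), while
neighbor-averaging schemes violate it on graphs where a distance-2 node
has many distance-1 neighbors. The scorer is deterministic and equivariant
under graph automorphisms; summation over seeds preserves the multi-seed
"connectivity to the disease genes" reading (a gene adjacent to several
seeds outranks a gene adjacent to one). A random-walk-with-restart scorer
(restart 0.5, power iteration to 1e-10) ships as a pluggable substitute
for robustness checks; it is not used by any default path.

Scores are z-standardized over the cell network's genes (population SD;
constant score vectors are flagged degenerate and given z = 0) and the
top-scoring set is `S = {g : z_g ≥ z_cutoff}` with default
`z_cutoff = 1.0`. The cutoff was an open design choice; 1.0 was selected
because it yields |S|/N fractions of roughly 6–20% on desk-scale networks,
the same scale as the worked arithmetic the score definitions are anchored
to (13/225 ≈ 5.8% and 47/225 ≈ 20.9%), whereas z ≥ 2 produces 2–5-gene
sets on ~100-node networks, quantizing MS in steps of ~0.25 and starving
the pathway statistics. A threshold rule (rather than top-k) is essential:
it lets |S| vary across random seed placements, which the perturbation
null requires to be non-degenerate.

## Multimorbidity Score

`MS = 2|S1 ∩ S2| / (|S1| + |S2|)` for a disease pair; for a triple the
generalized Sorensen-Dice `3|S1∩S2∩S3| / (|S1|+|S2|+|S3|)` is the default
and the mean of the three pairwise scores is available as a variant.
MS = 0 means detached mechanisms, MS = 1 identical ones; an empty S makes
MS 0 with a degeneracy flag.

**Permutation test.** Each disease's seeds are replaced by a random gene
set of equal size drawn within log2 degree bins of the cell network
(degree-matched null: hubs reach more of the network, so uniform
resampling would confound proximity with hubness). A bin with fewer
candidates than needed widens to the whole network with a logged warning.
Propagation and top-set selection are re-run per permutation and
`p = (1 + #{MS_perm ≥ MS_obs}) / (1 + n_perm)` (add-one estimator: never
0, ties count toward the null). All permutation loops take an explicit RNG
or seed.

## Perturbation Score and mechanisms

Two PS variants ship because two readings of the score coexist and they
are *not* equivalent:

* **printed** (default): `PS = (n_p^net / n_p^total) / (|S| / N)` — the
  worked-arithmetic form. It depends on S only through |S|; under its
  null, variation comes entirely from |S| across random-seed runs.
* **overlap**: `PS = (|p ∩ S| / |S|) / (n_p^net / N)` — the fraction of
  top-scoring genes that are pathway members relative to the pathway's
  share of the network.

The overlap variant is the one that carries pathway-specific signal and is
what mechanism discovery uses (and what the pipeline defaults to for its
PS stage); the printed variant is retained as the definitional default of
`perturbation_score` because it reproduces the published arithmetic
exactly. The null for either variant re-runs propagation from
degree-matched random seed sets, and a pathway with null p < α (default
0.05) for ≥ 2 diseases in the same cell type is called a candidate
mechanism, reported as the maximal significant disease combination.

## Candidate genes

A gene in ≥ 2 diseases' top-scoring sets of the same cell type (3 for the
triple) is a candidate; its score for a combination is the arithmetic mean
of its propagation z-scores over that combination's diseases, with the
cell network's full score vector as the standardization population.
Candidates are ranked by the mean of their available combination scores
(ties: lexicographic on gene symbol) and flagged *novel* when absent from
every input disease gene set.

## Synthetic data: what it emulates and why it looks the way it does

The generator produces the full input quartet with ground truth:

* **Interactome** — Barabási–Albert preferential attachment (default
  n = 500 genes, mean degree 6) or a rewired power-law configuration
  model; always simple and connected. Mean degree 6 keeps induced cell
  networks above the percolation threshold so they have a coherent giant
  component, as real cell-type networks do.
* **Expression** — per-gene log-normal baseline (log-mean 6, log-sd 1);
  technical noise is *uniform* (bounded), variance-matched at
  `noise_sd × baseline` (default 0.1). Uniform rather than normal noise is
  deliberate: with only 8 cell-type columns, the finite-sample IQR is
  noisy enough that normal tails push the specificity rule's
  false-positive rate above the generator's intended ≤ 5% contract;
  bounded noise keeps the planted/unplanted contrast clean while leaving
  the rule's small-sample behavior visible.
* **Specificity structure** — each gene is specific in exactly
  `round(frac_specific × n_cells)` cell types (default 2 of 8), shifted up
  by `specificity_effect` (default 8) multiples of its noise scale. The
  cap at 2 columns is a hard constraint of the IQR rule itself at 8
  columns: a gene elevated in ≥ 3 of 8 columns inflates its own upper
  quartile so much that it can never be called, at any effect size.
* **Disease modules** — connected neighborhoods grown by degree-penalized
  (1/degree) frontier sampling from a low-degree anchor; default 3
  diseases × 25 genes with a shared connected core of
  `round(overlap × size)` genes (default overlap 0.3). Degree-penalized
  growth matters: uniform frontier growth drifts into hubs, and hub-heavy
  modules are exactly what the degree-matched null also reaches, erasing
  the planted contrast. `overlap = 0` gives disjoint modules from separate
  anchors, `overlap = 1` identical ones.
* **Pathways** — random background gene sets with depth labels cycling
  1/2/3, redundant companions (80% subsets, Dice > 0.5) to exercise the
  filter, and a planted pathway sampled from inside the module union
  (core included) at depth 3.
* **Scenario assembly** — module and planted-pathway genes are specific to
  the first `n_multimorbid_cells` cell types (default 2); all other genes
  get random cell assignments. With `n_multimorbid_cells = 0` the truth
  records no planted multimorbidity (null scenario).

What the generator does **not** emulate: array-platform effects, sample-
level replication and filtering, correlated (co-regulated) noise,
disease gene sets with literature ascertainment bias, or catalogs with
realistic nested hierarchy. Passing the recovery tests therefore shows the
pipeline is correct and well-calibrated under clean planted structure; it
does not certify performance on real compendia.

## Statistical verification performed by the test suite

* Fisher/hypergeometric p-values match exhaustive combinatorial
  enumeration to 1e-10 on every 2×2 table with universe ≤ 60; Dice and
  three-way MS match brute-force set enumeration.
* Under null scenarios whose observed seeds are drawn from the
  degree-matched null itself (500 replicates, 200 permutations, 500-gene
  networks), both the MS and the (printed-variant) PS tests reject at
  α = 0.05 within 5% ± 2% — the add-one estimator with integer-valued
  statistics is mildly conservative, which keeps rates at or just below
  nominal, never above.
* At the generator defaults (module overlap 0.3, 3 diseases, 8 cell
  types, 2 planted multimorbid cell types), the planted cell types attain
  the top-2 MS ranks and the planted pathway is called a mechanism
  (overlap variant) in ≥ 90% of 50 replicates.
* Single-seed distance monotonicity is brute-forced over the full atlas
  of connected graphs with ≤ 6 nodes.

Problem sizes in the heavy tests (500 genes, 200 permutations, 500 null
replicates, 50 recovery replicates) are the package's chosen desk-scale
study conditions; the batch propagation backend (`propagate_batch`)
computes shortest paths once per seed-gene union, so a full permutation
test costs little more than a single propagation.

## Numerical conventions and degenerate inputs

* Quantiles: linear interpolation (type 7) everywhere.
* z-standardization: population SD (ddof 0); constant vectors → z = 0,
  flagged.
* Odds ratios: sample OR with Haldane–Anscombe +0.5 on any zero cell
  (log OR always finite).
* Permutation p-values: add-one, ties toward the null, never 0.
* Empty seed set → all-zero scores → empty S → MS 0 (flagged); pathway
  with no in-network gene → PS undefined (flagged row, no p-value).
* Redundancy-filter tie on size removes the lexicographically later id;
  worst-pair ties resolve to the lexicographically smallest pair.
* Edge direction never exists; edges are canonical sorted tuples; merged
  networks record per-edge source tags.

## Known limitations

* The propagation scorer is a documented reimplementation of the
  guilt-by-association idea, not a line-for-line reproduction of any
  published prioritizer's internals; absolute score values are not
  comparable across scorers, only the induced rankings and sets.
* The printed PS variant cannot distinguish pathways within a (cell,
  disease) pair — by construction every pathway in the same network gets
  the same null p. Use the overlap variant for any pathway-level claim.
* MS permutation p-values test overlap *given* the network and seed
  degrees; in small dense networks where the disease modules dominate the
  topology, random degree-matched seeds also produce overlapping top sets,
  so a high MS can carry a modest p. Rank cell types by MS, judge
  significance by p, and do not conflate the two.
* Gene identity is by bare symbol; identifier mapping and cross-species
  orthology are upstream concerns.
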