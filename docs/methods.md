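# Methods

## Model

walkscreen scores each protein in a weighted, undirected PPI network by its
proximity to a seed set under a random walk with restart, then prunes the
high-probability genes with three independent screens.  The underlying
assumptions are the usual guilt-by-association ones: disease proteins
cluster in the interactome, interaction confidence scores are comparable
across edges, and functional similarity (shared GO terms / pathways) is
evidence of shared disease involvement.

### Propagation

The walk updates P ← (1 − c)·T·P + c·P₀ with T the column-normalized
adjacency: T[v, u] = S(u, v) / Σₓ S(u, x).  This is the only normalization
under which the update keeps P a probability distribution, with mass flowing
out of each node in proportion to edge confidence.  Raw integer scores
(0–1000] are used as weights without rescaling — column normalization makes
the scale irrelevant, and keeping the native scale lets the interaction
screen use STRING's 900 cutoff directly.

* **Restart probability c** (default 0.8, range (0, 1]): the weight of the
  known genes relative to network smoothing.  High c keeps probability mass
  near the seeds; c = 1 returns P₀ itself.
* **Convergence**: iteration stops when the L1 norm of the update difference
  drops below the tolerance (default 10⁻⁶).  The norm is configurable
  (`l1`/`l2`/`linf`); L1 is the default because the iterate is a probability
  vector and L1 changes are directly interpretable as redistributed mass.
  Hitting `max_iter` (default 10,000) raises an error rather than returning
  a silently truncated result.
* **Dangling nodes**: an isolated node has a zero transition column; the
  mass the operator would lose there is re-injected through the restart
  term, so ΣP = 1 at every iteration (asserted to 10⁻⁹ in tests).  On any
  connected input this path is inert.
* **Seeds**: the restart vector is uniform, 1/|mapped seeds| per seed.
  Requested seeds absent from the network are dropped with a warning and the
  vector renormalized — the walk must start from a distribution regardless
  of upstream curation problems.
* **Selection**: non-seed genes with probability strictly greater than 10⁻⁵
  (seeds are known, hence never "novel"); ranked by probability descending
  with identifier ties broken ascending so reports are byte-reproducible.

### Screening cascade

1. **Permutation test.**  Random seed sets of the real size are drawn
   uniformly without replacement from all network nodes — no degree
   matching, and the real seeds and the candidates themselves stay in the
   sampling pool.  Each set is propagated with identical settings, and
   p(g) is the fraction of permutations whose probability of g strictly
   exceeds the real one (ties count in g's favour).  P-values are therefore
   multiples of 1/n_permutations; an optional conservative estimator
   (Θ+1)/(n+1) avoids exact zeros.  Pass rule: p < 0.05, strict.

   A consequence worth knowing at small scale: because a candidate can
   itself be drawn into a permutation seed set (probability
   seed_set_size/N per permutation) and a self-draw essentially always
   produces an exceedance, every p-value acquires a floor near
   seed_set_size/N.  On the 200-node benchmark with 10 seeds that floor is
   ≈ 0.05, making the screen markedly conservative there; at interactome
   scale (≈ 100 seeds in ≈ 20,000 nodes) it is ≈ 0.005 and immaterial.
   The p-value bulk above the floor is approximately uniform under null
   seeds (median ≈ 0.5, asserted in tests).

2. **Interaction test.**  MIS(g) = max over seeds of the stored edge score,
   0 for seed pairs with no edge; pass if MIS ≥ 900 (inclusive — 900 is
   STRING's "highest confidence" boundary).  The argmax seed partner is
   reported; ties resolve to the lexicographically smallest seed ID.

3. **Enrichment test.**  MES(g) = max over seeds of the direction cosine
   between annotation feature vectors; the cosine of a zero vector with
   anything is defined as 0, so unannotated genes fail this screen with a
   logged warning instead of erroring.  Pass if MES > 0.8, strict.

All candidates are reported with all scores and per-stage flags — not only
the passers — so each stage's effect is auditable, and the inferred flag is
the conjunction of the three.

### Feature vectors

The enrichment literature leaves the encoding of FV(g) open; two are
provided:

* **binary** (default): entry t is 1 iff the gene is annotated to term t.
  Deterministic, fast, and testable without downloads.  GO true-path
  propagation (annotate every is_a/part_of ancestor) is applied when an OBO
  ontology is supplied; the ontology must be acyclic along those relations.
* **neighbor_enrichment**: entry t is max(0, −log₁₀ p) with p the exact
  hypergeometric upper-tail probability of the overlap between the gene's
  direct neighbors and the term's gene set.  The sampling universe is all
  network nodes (not all annotated genes), which is recorded in output
  metadata; this choice keeps the universe independent of annotation
  coverage.

GO and KEGG term spaces are concatenated into one vector; cosines are
invariant to per-vector positive scaling, so mixing binary blocks is safe.
Terms annotating no gene are pruned before vector construction — they only
pad dimensions and cannot change any cosine.

## Synthetic benchmark

The planted-module generator is a stochastic block model: 200 nodes in two
equal communities, within-community edge probability 0.25 versus 0.02
between, within-community scores drawn uniformly from [800, 1000] (straddling
the 900 cutoff) versus [100, 400] between, 10 seed genes drawn from one
community, and 10 annotation terms per community carried with fidelity 0.9
(foreign terms with the complementary rate).  Equal within/between
probabilities give the no-signal null model.  Generation retries until the
seed community is connected, then errors.  Everything is driven by one
`rng_seed`, so stochastic assertions run on fixed draws.

What it emulates: community structure around a disease module, a bimodal
confidence-score distribution, annotation coherence within the module.  What
it does not: STRING's heavy-tailed degree distribution, the GO DAG's depth
and term-size skew, correlated annotation/interaction evidence, or
literature bias in seed curation.  Passing the planted-recovery tests shows
the cascade recovers a module whose signal matches the generator's
assumptions — it does not certify performance on real interactomes.

Two benchmark behaviors are structural rather than statistical, and tests
acknowledge them: with between-community scores capped at 400, no
cross-community gene can pass the MIS screen, so inferred precision for the
seed community is 1.0 by construction whenever the inferred set is
non-empty; and the small inferred set means the equal-sized top propagation
ranks are also pure seed-community, so screening cannot *strictly* improve
on them at this scale.

## Problem sizes and numerical choices

Test and benchmark runs use 50–200-node graphs, 20–500 permutations and
tolerances of 10⁻⁶–10⁻¹³; the propagation itself is a sparse matrix–vector
loop and handles interactome scale (2·10⁴ nodes, 10⁶ edges) in seconds per
walk.  Permutation probability vectors are streamed into per-gene exceedance
counters, never materialized as an N × n_permutations matrix.  The iterative
fixed point is validated against a dense closed-form solve
P = c·(I − (1−c)·(T + P₀dᵀ))⁻¹·P₀ (d the dangling indicator) to 10⁻⁸ L∞,
and against networkx personalized PageRank as a second, library-independent
cross-check.

Degenerate inputs: duplicate directed edge records collapse (conflicting
scores are corrupt input, not averaged); self-loops are dropped with a
warning; empty seed sets, zero permutations and out-of-range thresholds are
configuration errors raised before any compute.  Node order is first
appearance in the input file and is recorded, so repeated runs with the same
config and RNG seed are byte-identical apart from the manifest timestamp.

## Known limitations

* Results at interactome scale depend on the STRING release and the GO/KEGG
  release used to build vectors; the binary encoding with different
  annotation snapshots will shift MES values and hence inferred counts.
* The permutation null is not degree-matched; hubs can earn small p-values
  from topology alone (this is deliberate — it mirrors the published
  procedure — but a degree-stratified null would be stricter).
* The empirical p-value floor described above makes the permutation screen
  conservative whenever the seed set is a non-negligible fraction of the
  network.
* No multiple-testing correction is applied beyond the raw p < 0.05 cut.
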