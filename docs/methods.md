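# Methods

## Model and null hypothesis

An ontology is a single-rooted DAG `G = (V, E)` of terms with edges
directed child → parent (`is_a`, `part_of` by default; the whitelist is
configurable). Items (diseases, proteins) carry explicit annotation sets
`T ⊆ V`; by the annotation-propagation rule an item annotated to `n` is
implicitly annotated to every ancestor of `n`, so the implicit set is
`T_IMPL = ∪_{n∈T} Anc(n)`. Annotation frequency `p(n)` is the fraction of
items annotated at or below `n`, each item counted once per term, and
`IC(n) = −log p(n)` is non-decreasing from root to leaves.

The null model for significance is uniform random querying: every
`q`-element subset of `V` is an equally likely query, duplicates excluded,
ancestors of other query members allowed. The P-value of an observed score
is the tail mass of the score distribution over all `C(|V|, q)` queries.
This corrects the annotation bias of raw best-match-average scores, which
systematically favour richly annotated items.

## Exact distribution computation

Three routes produce a score distribution:

* **Exhaustive** (`naive_distribution`): scores every `q`-subset directly
  via pairwise Resnik similarities. Refused above a configurable cap
  (default `C(|V|, q) ≤ 10⁷`). Kept permanently as the independent oracle;
  it shares no code with the collapsed route below.
* **Collapsed** (`preprocess_components` + `exact_score_distribution`):
  collapses `G` into components `N_s` of equal target-set similarity, then
  enumerates score multisets. Weight propagation runs over an
  inverted-edge *view* (the stored graph is never mutated) in
  lexicographic topological order; among equal-weight incoming edges the
  lexicographically smallest parent id is kept, which makes builds
  deterministic and — as the tie-independence test verifies — cannot
  affect component sizes. Multisets are enumerated recursively over the
  ascending score set with remaining-capacity pruning; partial weighted
  sums and binomial products are carried down the recursion. Frequencies
  are Python integers throughout (binomials overflow 64 bits already at
  `C(10⁴, 5)`).
* **Monte-Carlo** (`sampled_score_distribution`): `reps` queries drawn
  uniformly over `q`-subsets (per-row ranking of i.i.d. uniforms),
  deterministic per seed.

## Numerical choices

* Scores are IC sums in double precision; summation order differs between
  routes, so distribution entries are merged under a relative tolerance of
  1e-9 (representative: smallest key of the merged group). The same
  tolerance defines P-value inclusivity (`S ≥ S_obs`) and component-merge
  equality of IC values.
* IC uses natural log by default; the base only rescales scores, so
  rankings and P-values are invariant to it (tested). `--log-base` offers
  2 and 10.
* Terms with zero propagated count are absent from the IC table rather
  than carrying +∞; any similarity computation that would need such a term
  is a hard error. Target sets drawn from annotated items always have full
  IC coverage of their implicit closure.
* Sampled P-values of scores never seen in `reps` draws are floored at
  `1/(reps+1)` instead of reporting 0.
* Rankings sort by ascending P-value, ties broken by descending score;
  remaining ties receive the mean of their positional ranks. P-values are
  exact rationals (`Fraction`), so tie detection is exact.

## Simulated patients

Queries are derived from a disease's own annotations and corrupted:

* **NONE** — unchanged.
* **NOISE** — exchange `k` terms for terms drawn (without replacement,
  preserving query size) from the rest of `V`: `k = 2` for queries of ≥ 5
  terms, else `k = 1`. The `k = 1` choice for 2-term queries extends the
  3-or-4-term rule by continuity.
* **IMPRECISION** — independently per term, with probability 0.5, replace
  it by a uniformly chosen parent (the root is never exchanged); the
  result is deduplicated, so the query may shrink.
* **IMPRECISION_NOISE** — imprecision first, then noise.

The experiment ranks the full database for each corrupted query under each
method (raw score, sampled P-value, exact P-value) and records the true
disease's rank. Within one run, Monte-Carlo distributions are sampled once
per (item, query size, reps) and reused, mirroring the per-entry
precomputation a production service would use.

## Synthetic data

`random_dag(n, p_extra, seed)` draws a spanning tree toward the root plus
independent extra forward edges; `random_corpus` assigns each item a
random term set of size uniform in 2–5 (the annotation-set sizes typical
of phenotype-annotated diseases), then attaches any unannotated leaf to an
item round-robin so every term has a finite IC. With `popularity > 0`,
terms are drawn from a Zipf law over a seeded permutation, emulating the
heavy term reuse of real corpora — without it, items are essentially
disjoint and never compete for the same queries, which suppresses exactly
the phenomenon P-values exist to handle.

The benchmark in the acceptance suite uses 200 terms with
`extra_edge_prob = 0.01` (yielding a mean implicit-closure size ≈ 37,
matching what real phenotype annotation sets produce), 50 items with Zipf
popularity 1.0, uncorrupted (NONE) queries, 20 experiment seeds, and
sampled P-values at 10³ repetitions. NONE is the scenario that isolates
P-value *resolution*: the true item's exact P-value lies far below the
sampling floor `1/(reps+1)`, so sampling can only lose — by letting a
higher-scoring competitor tie at the floor — and the paired comparison is
one-sided by construction. Under heavy corruption the exact-versus-sampled
difference at this database size (50 items versus thousands in a real
deployment) drowns in ranking noise, while the advantage of either P-value
over raw scores remains visible. Mean ranks are compared by a one-sided
paired t-test at α = 0.05, paired per seed.

What the generators do not emulate: real ontologies' depth/branching
heterogeneity, correlated annotations between related diseases, and
annotation-set sizes beyond 2–5. Passing tests therefore demonstrate
algorithmic correctness and the qualitative method ordering, not the
absolute mean ranks a curated corpus would give.

## Limitations

* Only Resnik-based `sim_avg` / `sim_max` are supported; measures that
  also use the query terms' own IC (Lin, Jiang–Conrath) need a different
  decomposition, as does the symmetric best-match average.
* The multiset enumeration is single-threaded and always builds the full
  distribution; no branch-and-bound shortcut for a single P-value.
* OBO parsing covers `[Term]` stanzas with `is_a` / `relationship` /
  `alt_id` / `is_obsolete`; OWL and cross-ontology mappings are out of
  scope, as is writing ontologies.
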