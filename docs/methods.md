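# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `modex`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model representation

A model is an ordered table of elements. Each element has a number of
discrete levels (default 2, Boolean), a positive and a negative influence
expression over element names (identifiers, `AND`, `OR`, `NOT`,
parentheses; a bare comma list is read as OR of its items), and one initial
value per scenario. The induced graph G_BM has an edge v_i → v_j whenever
v_i appears in v_j's expressions; the edge's sign is the side of the rule it
appears in.

File dialect: TSV with a fixed header. Model columns are `Element`,
`Positive Regulators`, `Negative Regulators`, `Levels` (optional) and one or
more `Initial <scenario-id>` columns; matching is case-insensitive with
common aliases. CE sets are TSV edge lists (`Regulator`, `Sign`, `Target`,
optional `Provenance`, `Score`); exact duplicate triples are collapsed with
provenance concatenated. Property files carry `id`, `Formula`,
`Goal probability` columns. Element names are trimmed and internal
whitespace becomes `_`; CE names are matched to model names by
case-insensitive exact comparison only — synonym resolution and database
grounding are a text-mining concern and out of scope here, so mismatches
surface as new nodes rather than being guessed.

### Update semantics

An element *fires* iff its positive expression is true AND its negative
expression is false, where a variable is truthy when its state is > 0.
Two boundary cases need a convention:

* no regulators at all → the element holds its state (an input);
* only negative regulators → the positive side defaults to true, so the
  element is active iff no inhibitor is active. This makes a pure
  self-repressor (`NOT A` for A) the expected negation oscillator under
  synchronous update.

Multi-level elements move one increment per update toward 0 or levels−1;
Boolean elements therefore switch in a single update. Rule *revision* for
elements with more than two levels (min/max composition) is deliberately
not implemented — multi-level states are simulated, but new regulators are
always composed with OR.

## Extended graph and return paths

G_new is the union of G_BM and the CE edges, with per-node and per-edge
origin labels (BM / CE / both). CE edges are classified by how many
endpoints lie in V_BM: (i) both, (ii) one, (iii) none.

A *return path* is a chain of CE edges starting and ending at baseline
nodes. Design choices:

* Paths are **simple** (no repeated node). The search is then finite, and a
  simple path suffices to witness connectivity. A consequence adopted
  consistently in both the enumerator and the boolean existence check: a
  walk that closes back onto its own start node does not count as a return.
* A single category-(i) edge is a return path of length 1.
* Edge signs are carried but ignored for path existence; signs matter at
  rule-revision time, not for connectivity.
* Existence checking is forward reachability per start node, not full
  enumeration (enumeration is exponential and only needed in tests, where
  it is cross-checked against brute force).
* Return-path interiors are CE-only; baseline edges do not participate.
  Baseline nodes may appear as interior nodes.

## Markov clustering

From-scratch MCL on the undirected, unweighted, self-looped adjacency of
G_new (direction is dropped for clustering only; dynamics reintroduce it).

* Expansion power q = 2 (standard), configurable.
* Inflation r: default 4.0; values outside [1.1, 10] warn. Granularity
  grows with r. For desk-scale graphs (tens of nodes) the suitable range
  sits lower than for literature-scale networks; the fixture benchmarks and
  the acceptance script use r = 2.0, at which a 10–20 node model typically
  yields 1–4 clusters instead of near-singletons.
* Numerical hygiene: entries below `prune_threshold` (default 1e−5) are
  zeroed during inflation and the column renormalized; a column emptied by
  pruning has its largest pre-prune entry restored to 1 (logged). Setting
  the threshold to 0 recovers the pure algorithm.
* Convergence: L∞ norm of the change between successive matrices below
  1e−6, capped at 100 iterations (non-convergence returns best-effort
  clusters with a flag).
* Cluster extraction: attractors are rows carrying support in the converged
  matrix; each column joins the attractor with its largest entry (ties to
  the smallest node index), and attractors connected in the converged
  support are merged into one attractor system so a periodic attractor pair
  is one cluster, not two. Extraction is deterministic; node ordering is
  lexicographic throughout.

Clusters that contain only baseline nodes are retained in the partition but
yield no candidate (they contribute no CE edges).

## Candidate assembly

Every individual cluster and every unordered pair is considered. The CE
edges attached to a cluster union are those with both endpoints in the
union, or one endpoint in the union and the other in V_BM — except that a
category-(i) edge (both endpoints already in the baseline) must have both
endpoints inside the union; a baseline-to-baseline shortcut spanning two
clusters belongs to their merged pair only. Entries whose edges form a
return path become candidate models: the verbatim baseline plus the entry's
CE edges.

* New elements default to 2 levels and initial value 0 (inactive) in every
  scenario — the conservative choice; overridable.
* A CE edge duplicating an existing same-sign regulation is skipped
  silently (revision is therefore idempotent); an edge opposing an existing
  regulation is skipped with a warning — contradiction resolution is a
  separate problem and intentionally out of scope.
* Node overlap for a merged pair is computed on the union, consistent with
  treating the pair as a single cluster.
* Merging stops at pairs; triples would explode the candidate count.

## Simulation

Two schemes: `synchronous` (all elements update from the previous state;
deterministic) and `random_asynchronous` (default; each step one uniformly
chosen element updates). Randomness flows from one integer seed; run k of a
batch uses substream seed + k, so batches are reproducible run-by-run.
Defaults: 100 steps, 200 runs — both config-mandatory in spirit: every
entry point validates that the trace length covers the property horizon
rather than silently truncating.

## BLTL checking

Formulas: atoms `element cmp constant` (`=`, `<`, `>`, `<=`, `>=`),
`not`/`and`/`or`, and bounded `F[k]`, `G[k]`, infix `U[k]`. Precedence:
`U` loosest, then `or` < `and` < `not`/`F`/`G` (prefix operators bind their
immediate subformula). The goal probability is a separate column, never
part of the formula text.

Evaluation is at trace position 0 (properties describe behavior from a
scenario's initial state). The required horizon is computed structurally
(F[k]φ and G[k]φ need k + h(φ); U[k] needs k + max of its operands) and
enforced. Estimation is fixed-sample: all runs are generated, the satisfied
fraction is reported with the two-sided Chernoff–Hoeffding half-width
ε = sqrt(ln(2/α) / 2N) at α = 0.05. Sequential hypothesis testing was
deliberately not used: fixed-sample is simpler, embarrassingly parallel,
trivially deterministic under a seed, and the half-width tells users how
many runs buy how much precision.

## Scoring and recommendation

ε_t = |p_t − P_t|; ε_avg is their mean; σ = 1 − ε_avg;
δ-score = 100 · #{t : ε_t ≤ δ}/|T| (δ default 0.3); joint p̃ = Π p_t under
an explicit independence assumption, isolated in one function
(`joint_probability`) so a different composition rule is a one-line change.
Metrics are min-max normalized across the candidate set (a constant metric
normalizes to all-1.0); "none" mode gives raw values. All per-metric
winners are reported (ties included) and the recommended set is their
union. The pipeline's single "top" candidate is the σ-best with ties broken
toward the fewest added edges (parsimony), then lexicographic id.

A property whose elements are absent from V_BM ∪ V_CE is flagged
`unsatisfiable-input` and excluded from scoring — no candidate could ever
satisfy it, and silently scoring it would only add a constant penalty. A
property whose elements exist somewhere in the input but not in a given
candidate is recorded as NaN for that candidate and excluded from its
aggregates (counted as `n_unsupported` in the report) rather than being
assigned an invented estimate.

## Synthetic fixtures

The generator emulates the ablation style of model-extension benchmarks:

* **Golden model**: a random signed digraph over n elements (default 12)
  with a weakly connected spanning backbone plus extra edges at density
  0.15, ~75% positive signs; rules are OR over positive regulators with
  AND-NOT over negatives — the same composition the assembler produces, so
  structural recovery implies dynamic recovery. Initial values are random
  Booleans in one scenario.
* **Baseline**: the golden model minus a *connected* set of ablated edges
  (grown from a seed edge through shared endpoints — a missing pathway
  region, not scattered edges), chosen so no node is orphaned.
* **CE set**: exactly the ablated edges plus optional decoys. Every decoy
  touches at least one fresh node (so it can neither duplicate nor
  contradict golden structure); `disconnected` decoys live entirely among
  fresh nodes and can never form a return path, `connected` ones hang off
  the baseline, `mixed` alternates.
* **Properties**: `F[s1]G[s2](x = 1)` with s1 = 5n (asynchronous updates
  touch each element about once per n steps, so 5n lets a depth-~5 cascade
  settle) and s2 = 5. Goal probabilities are *measured* on the golden model
  (200 runs), so P_t lands anywhere in [0,1]. Elements are chosen as the
  direct targets of the ablated edges first — the behaviors the missing
  links control, which is what a modeler would write requirements about —
  then by the largest golden-versus-baseline estimate gap.

What the fixtures do **not** emulate: machine-reading noise (entity
grounding errors, hedged or misread events), synonymy between element
names, multi-level dynamics, and literature-scale CE sets (hundreds of
edges). Passing the fixture benchmarks therefore demonstrates the
machinery — clustering, filtering, assembly, checking, scoring — under
clean inputs of modest size, not robustness to reader noise.

## Problem sizes and numerics

The test suite and acceptance script run 8–20-element fixtures, 200–2000
simulation runs, and trace lengths of 45–105 steps; the full suite
completes in well under a minute on one CPU. MCL uses dense numpy
matrices — graphs here are far below the size where sparsity matters.
Probabilistic assertions in tests use three-standard-error bands (or the
Hoeffding width) around exactly enumerated or independently re-measured
values, with all randomness seeded.

## Known limitations

* OR-composition only for rule revision; no min/max synthesis for
  multi-level elements.
* Contradictory CE edges are skipped, not reconciled.
* The joint probability's independence assumption is wrong whenever
  properties share elements; it is a ranking heuristic, not a calibrated
  probability.
* Return paths are simple; regulatory loops that revisit a node are
  witnessed only through their simple sub-paths.
* Candidate enumeration is quadratic in the cluster count and each
  candidate costs one simulation batch per scoring pass; the O(N_C · N_P)
  checking cost is the practical ceiling, mitigated by sharing one trace
  batch across all properties of a candidate.
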