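# modex

Extension and recommendation of discrete executable network models from
candidate interaction sets.

## The problem

Modelers of cell signaling (and other causal systems) maintain *executable*
models: directed networks whose nodes are proteins, genes, chemicals or
processes, each carrying a discrete state variable and an update rule over
its positive and negative regulators. Literature mining and interaction
databases yield large sets of *candidate events* (CEs) — signed directed
edges such as "A activates B" — that might extend a trusted baseline model.
Adding all of them at once destroys the model; testing them one at a time is
combinatorially hopeless, and most candidates are not even connected to the
model. `modex` automates the middle path: it selects *clusters* of connected
candidate interactions that re-enter the baseline model, builds candidate
models from them, and recommends the ones whose simulated dynamics best match
a set of desired behaviors.

It is a library for Python users (with a thin `modex` command-line wrapper)
aimed at systems-biology modelers who curate discrete/Boolean models and
want literature-derived extensions vetted against dynamic requirements.

## The method

Given a baseline model G_BM(V_BM, E_BM), a CE set E_CE, and properties
*t* ∈ *T* with goal probabilities P_t:

1. **Union graph.** Form G_new with V_new = V_BM ∪ V_CE and
   E_new = E_BM ∪ E_CE. Each CE edge falls in category (i) (both endpoints
   in V_BM), (ii) (one), or (iii) (neither).
2. **Markov clustering (MCL).** Cluster G_new's undirected, self-looped
   adjacency by alternating *expansion* (matrix power q) and *inflation*
   (entry-wise power r with column renormalization) on the column-stochastic
   matrix until it stops changing. The inflation parameter r sets cluster
   granularity. Each cluster C_l splits into its baseline part C_l^BM and
   new part C_l^CE, with node overlap NO_l = |C_l^BM| / |C_l|.
3. **Return-path filter and assembly.** Every individual cluster and every
   unordered cluster pair whose CE edges form a *return path* — a chain of
   CE edges leaving one baseline node and re-entering the model at another —
   yields a candidate model (CM): the full baseline plus the cluster's CE
   edges, nothing removed. New positive regulators extend update rules with
   OR (`x_B = f(x_C, x_D) OR x_A`); an element is active iff its positive
   expression holds and its negative expression does not.
4. **Simulation and checking.** Each CM is simulated stochastically
   (random asynchronous update by default); Bounded LTL properties such as
   `F[s1]G[s2](x = 1)` are evaluated on the traces, giving a satisfaction
   estimate p_t with a Chernoff–Hoeffding error half-width.
5. **Scoring.** Per CM: property error ε_t = |p_t − P_t|, average error
   ε_avg, σ-score = 1 − ε_avg, δ-score = % of properties with ε_t ≤ δ,
   joint probability p̃ = Π p_t, plus NO. Metrics are min-max normalized
   across CMs; per-metric winners (ties included) form the recommended set —
   different metrics can legitimately disagree.

## Worked example

`examples/04_score_and_recommend.py` ablates 3 interactions from a
12-element synthetic golden model, offers them back as the CE set, and runs
the full pipeline (every example is runnable as `python examples/04_....py`):

```
golden model: 12 elements, 27 interactions
baseline: 24 interactions (3 ablated)
CE set: 3 candidate interactions
properties (goal probabilities measured on the golden model):
  t1: F[60]G[5](N01 = 1)   P_t = 0.945
  ...
clusters: 1, candidates passing the return-path filter: 1
candidate  eps_avg  sigma  delta_score  joint  node_overlap  recommended
       C0      0.0    1.0        100.0  0.221           1.0         True
baseline eps_avg for comparison: 0.241
recommended: ['C0']
```

The candidate restores all three ablated interactions: its average property
error drops from the baseline's 0.241 to 0.0, so σ = 1.0 and every property
sits within δ = 0.3 of its goal (δ-score 100%). With decoy interactions in
the CE set (`examples/05_ablation_recovery.py`) the pipeline stays selective,
adopting a small fraction of the offered edges while cutting baseline error
by ~81%.

The other examples cover graph construction and return paths (01), MCL
granularity versus r (02), and statistical checking of a stochastic race
against its exact probability (03).

## Command line

```bash
modex fixtures --out fix/ --n-elements 12 --n-removed 3 --seed 1
modex run --model fix/baseline.tsv --ce fix/ce.tsv --properties fix/properties.tsv \
          --out results/ --inflation 2.0 --seed 1
modex sweep --model fix/baseline.tsv --ce fix/ce.tsv --properties fix/properties.tsv \
            --out sweep/ --r-values 1.5,2,4,6
```

Exit codes: 0 success, 2 no cluster forms a return path, 3 invalid input.
All inputs are TSV; see `docs/methods.md` for the dialects.

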