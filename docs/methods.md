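# Methods

## Scope and model

`dgmod` maximizes Newman modularity on simple, undirected, unweighted
graphs. Weights present in input files are ignored (with a logged
warning), self-loops are rejected, and duplicate edges collapse. This
matters in practice: the karate-club network is often distributed with
Zachary's interaction weights, and the weighted faction modularity
(0.3914) differs from the unweighted value (0.3582) this package and its
tests compute. Disconnected inputs are accepted; components simply
agglomerate independently.

Modularity uses the standard normalization L = m (edge count):
Q(S) = Σ_c [l_c/L − (k_c/2L)²]. This is the only reading under which the
all-in-one partition scores exactly 0 and the merge gain
ΔQ = 2(e_ij − a_i a_j) with e_ij, a_i as edge *fractions* equals the true
Q difference — an identity the test suite enforces to 1e−12 per merge and
1e−9 over long randomized move sequences.

## The search

The DGM search interleaves exploitation (one best positive-ΔQ merge per
iteration, ties broken by the smallest community-id pair) with stochastic
exploration over `T = round(iter_multiplier · n)` iterations:

| parameter | default | meaning |
|---|---|---|
| `p_comm` | 0.05 | per-iteration probability of a community disassembly |
| `p_node` | 0.05 | per-iteration probability of a node disassembly |
| `iter_multiplier` | 30 | iteration budget per node (n=34 → 1020 iterations) |
| `n_restarts` | 1 | independent restarts; restart r reseeds with seed+r |
| `escape_node_share` | 0.9 | fine/coarse mix of forced escapes (below) |
| `exploit_to_convergence` | off | exhaust all positive merges per exploitation step |

A node disassembly breaks the chosen node out as a singleton and splits
the remainder of its community into connected components; a community
disassembly dissolves every member into a singleton. Both update all
tallies incrementally and may lower Q; the search reports the best
(Q, partition) snapshot seen anywhere, across restarts.

### Behavior at local optima

When exploitation is drawn but no positive merge exists, the iteration
would be wasted. The committed policy performs a *forced escape*: with
probability `escape_node_share` (0.9) a single node is broken out using
the configured node strategy; otherwise one uniformly random community is
dissolved. This split is a deliberate design for a case the search
definition leaves open, and both ingredients are load-bearing:

* Fine escapes make the stall phase an implicit single-node local search.
  Breaking node v out of its community and letting the next merge reattach
  it is exactly an optimal relocation of v (at a local optimum the only
  positive merges involve v's singleton, and the best of them is the best
  placement of v). On the karate network the last stretch toward the
  optimum (0.4156 → 0.4172 → 0.4188 → 0.4198) is precisely such a chain of
  relocations, which coarse kicks alone never produce.
* Coarse random kicks are the only way out of basins that single-node
  relocations cannot exit (the karate search otherwise stalls permanently
  at Q = 0.4020, whose three communities all reform deterministically
  after any single-node perturbation).

With 5%/5% exploration, the default budget and 50 restarts, the search
reaches the known karate optimum (Q = 0.4198, four communities) in every
trial batch we measured (~8–10% of individual restarts attain it). Forced
escapes are disabled when `p_node = p_comm = 0`, so that configuration
reduces exactly to the deterministic greedy baseline.

### Strategy semantics

Node strategies: `random` picks a uniform member of a uniform multi-node
community; `weak` picks uniformly among nodes with k_ext ≥ k_int ≥ 2 (the
inclusive boundary makes borderline nodes eligible; the k_int ≥ 2 floor
keeps barely-attached leaves from dominating); `low_embeddedness` takes
the global minimum of k_int/k_v with uniform tie-breaks; `non_triad`
considers only communities with more than 4 members and picks uniformly
among members of no internal triangle. Scoring is global across all
eligible communities.

Community strategies: `random` uniform among multi-node communities;
`low_density` argmin internal edge density; `low_tpr` argmin triad
participation ratio; `high_conductance` argmax conductance. `weak`
considers only communities that *fail* the weak-sense community test
(2·l_c ≤ m_out, i.e. summed internal degree not exceeding summed external
degree) and takes the smallest l_c − m_out among them; if every community
passes the test it selects nothing. The eligibility gate is essential at
scale: without it the strategy dismantles one healthy community every ~20
iterations and a 250-node search never converges, scoring *below* the
greedy baseline at high mixing.

All argmin/argmax ties break uniformly from the seeded stream; selections
with empty candidate sets are logged no-ops that still consume an
iteration, keeping T the sole budget knob. Identical (graph, config) input
yields an identical result object, and extending the budget can only
improve the best (the longer run replays the shorter one as a prefix).

## Evaluation

NMI is computed from the co-membership contingency table as
2·I(U;V)/(H(U)+H(V)) (any log base; the ratio is base-invariant), clamped
to [0,1] against float fuzz. Degenerate cases: two single-community
partitions are identical (NMI 1); one trivial vs one non-trivial partition
yields 0, which the formula produces naturally (zero mutual information
over a positive entropy). The implementation is cross-checked against
scikit-learn's arithmetic-mean NMI in the tests.

`mean_internal_density` averages per-community densities unweighted and
skips singletons (whose density is undefined); this convention reproduces
the karate faction value 0.2463.

## Synthetic benchmarks

`generate_planted` emulates LFR-style planted-partition graphs: community
sizes from a truncated power law (exponent β, default sizes 20–50), node
degrees from a truncated power law (exponent γ, truncated to [2, n/10],
lower cutoff solved so the continuous mean matches `avg_degree`, default
10), and each node's stubs split internal/external by the mixing parameter
μ. Wiring is configuration-model stub pairing with rejection of
self-loops, duplicates and (externally) same-community pairs; after
bounded reshuffles a few unmatched stubs are dropped, so instances report
their *realized* μ (within 0.05 of the target at n = 250 by contract, and
typically within 0.015). High-internal-degree nodes are assigned to
communities large enough to host them.

What this generator does **not** emulate: degree–community-size
correlations of the published LFR algorithm, overlapping communities,
weights, or exact bit-compatibility with any external LFR implementation.
Passing tests on these instances therefore demonstrate behavior on
well-specified planted structure, not on every real-network pathology.
Table-style sweep assertions are consequently directional (modularity
non-increasing in μ; DGM ≥ greedy; NMI high at low mixing) rather than
point matches, since exact values are instance-specific.

## Problem sizes and numerical choices

The test and acceptance workloads use the bundled 34-node karate network
(50 restarts for the optimum check, 20 restarts per grid cell), 50 random
connected graphs with n ≤ 8 checked against an exhaustive set-partition
oracle (Bell(8) = 4140 partitions), ≥10⁴ randomized moves for gain
consistency on graphs with n ≤ 50, and 250-node planted-partition
instances with five replicates per μ — sizes chosen so the full suite
exercises every claim in well under a minute each while matching the
study conditions stated above.

Floating-point policy: Q is accumulated incrementally from exact integer
tallies scaled by 1/(2L); drift over thousands of moves stays far below
the 1e−9 consistency tolerance. Tie comparisons use exact float equality,
which is well-defined here because tied scores arise from identical
integer ratios.

## Known limitations

* The exploration layer is designed for the modest scales of the study
  conditions (n up to a few thousand); the lazy best-merge scan is
  O(pairs) per iteration and no heap optimization is attempted.
* Only undirected, unweighted, non-overlapping community detection is
  supported.
* `escape_node_share` interacts with landscape structure; on networks very
  unlike the benchmarks (e.g. near-bipartite or star-dominated graphs) a
  different fine/coarse mix could explore better.
* NMI is reported without chance correction; for partitions with very many
  tiny communities adjusted variants would be more conservative.
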