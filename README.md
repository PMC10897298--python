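# dgmod — greedy modularity community detection with disassembly exploration

`dgmod` detects communities (modules) in undirected, unweighted networks —
protein–protein interaction networks, metabolic networks, social networks —
by maximizing Newman modularity. It implements the classic CNM-style greedy
agglomeration as a deterministic baseline and augments it with a stochastic
**disassembly** exploration layer (the DGM search): at random points the
search breaks a node out of its community or dissolves a whole community,
letting the greedy phase rebuild a better partition and escape the local
optima that pure agglomeration gets trapped in.

## The model

For a partition *S* of a graph with *L* edges, where community *c* has
internal edge count *l_c* and summed member degree *k_c*, modularity is

    Q(S) = Σ_c [ l_c/L − (k_c/(2L))² ]

Merging communities *i* and *j* changes Q by exactly ΔQ = 2(e_ij − a_i a_j),
with e_ij the fraction of edges joining *i* and *j* and a_i = k_i/(2L);
`dgmod` maintains these tallies incrementally so every merge and every
disassembly updates Q exactly (checked against from-scratch recomputation
at 1e−9 in the test suite).

The search runs `T = round(30·n)` iterations from the all-singleton state.
Each iteration is, with probability 5%, a community disassembly; with 5%, a
node disassembly; otherwise one best positive-gain merge. The result is the
best partition seen anywhere along the trajectory, optionally best over
independent seeded restarts. Disassembly targets are chosen by named
strategies — nodes: `random`, `weak`, `low_embeddedness`, `non_triad`;
communities: `random`, `weak`, `low_density`, `low_tpr`,
`high_conductance` — driven by the community-quality metrics implemented in
`dgmod.metrics` (embeddedness, internal edge density, triad participation
ratio, conductance, internal/external edge balance).

Partitions are compared with normalized mutual information,
NMI(U,V) = 2·I(U;V)/(H(U)+H(V)), and benchmark instances come from a seeded
planted-partition generator with power-law degrees and community sizes and
a tunable mixing parameter μ.

## Worked example

The Zachary karate-club network ships with the package (34 nodes, 78 edges,
plus the historical two-faction split as ground truth).

```bash
$ dgmod greedy --input karate.txt
Q=0.3807 communities=3

$ dgmod detect --input karate.txt --community-strategy weak \
    --node-strategy random --seed 1 --restarts 50 --output dgm.tsv
best_Q=0.4198 communities=4

$ dgmod evaluate dgm.tsv factions.tsv --input karate.txt
NMI=0.5878
Q_a=0.4198
Q_b=0.3582

$ dgmod metrics --input karate.txt --membership dgm.tsv
community	n_s	l_c	m_out	density	tpr	conductance	balance
0	11	23	14	0.4182	0.9091	0.2333	9
1	5	6	4	0.6000	0.6000	0.2500	2
2	12	21	14	0.3182	0.9167	0.2500	7
3	6	7	10	0.4667	0.5000	0.4167	-3
```

Reading: the deterministic greedy baseline stops at Q = 0.3807 with three
communities. The DGM search (weak-community + random-node disassembly,
best of 50 restarts) escapes that optimum and finds the four-community
partition with Q = 0.4198 — the known maximum-modularity split of this
network. Its NMI of 0.59 against the two-faction ground truth reflects
that the topological optimum subdivides both factions; the faction split
itself scores Q = 0.3582. The per-community table shows each detected
module's size, internal/boundary edges, density, triad participation,
conductance and edge balance.

The same library surface is available in Python:

```python
from dgmod import load_fixture, run_dgm, DGMConfig

g, factions = load_fixture("karate")
result = run_dgm(g, DGMConfig(seed=1, n_restarts=50))
print(result.best_q, len(result.best_partition))  # 0.41979..., 4
```

Synthetic benchmarks mirror the planted-partition experiment: `dgmod synth`
writes one instance (edge list + ground-truth membership), `dgmod sweep`
generates instances across μ values and reports greedy vs DGM modularity
and NMI against the planted communities in a TSV.

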