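# Methods

## The similarity measure

Both network methods share one similarity measure between an input gene set
and a pathway. The input genes are mapped onto the nodes of an undirected,
unweighted gene network; unmapped genes are dropped with a warning (the
effective seed set is the mapped subset). Seeds receive indicator value 1 —
not 1/|seeds| — so similarity scores scale with the seed count; downstream
z-scores are invariant to this because every null seed set is size-matched.

The random walk with restart iterates `S_n = (1−p)·M·S_{n−1} + p·V` from
`S_0 = V`. `M` is column-stochastic: column *j* is uniform over the
neighbours of *j*, and isolated nodes (retained, never removed) get an
all-zero column, so their stationary value is exactly `p·V(i)`. Because
`(1−p)M` contracts the L1 norm by at least `1−p` per step, the iteration
converges geometrically to the unique fixed point
`S = p(I − (1−p)M)^{-1}V`, and on isolate-free networks total mass is
conserved (`sum(S) = sum(V)`), which the tests assert to 1e-8.

A pathway's similarity score is the arithmetic mean of `S` over its
*network-mapped* members. Averaging over mapped members only (rather than
counting unmapped members as zero) is a deliberate choice: unmapped genes
have no node value, and mixing structural zeros into the mean would conflate
annotation coverage with network proximity. Pathways with zero mapped
members are unscorable and reported separately rather than ranked.

### Numerical choices

- Restart probability `p = 0.5` by default; valid range (0, 1).
- Convergence: L1 residual < 1e-10 or 1000 iterations (at `p = 0.5` the
  contraction reaches 1e-10 in ~33 iterations). Non-convergence flags the
  profile rather than raising.
- `rwr_closed_form` performs the dense linear solve as an independent oracle;
  it is guarded to ≤ 2000 nodes and is for validation, not production.
- Null ensembles propagate all permutation seed vectors as columns of one
  matrix iterate — per column this is the identical recurrence, verified
  against one-at-a-time runs to 1e-12.

## Randomization backgrounds

**Random gene sets** are drawn uniformly without replacement from the
network's nodes — the most literal size-matched background. A degree-matched
mode (sample each reference gene's replacement from its degree-decile bin) is
available behind a flag but off by default, since the plain method's null is
uniform.

**Rewired networks** use double-edge swaps: pick edges {a,b} and {c,d},
replace with {a,d} and {c,b} unless a self-loop or duplicate would result.
`swap_factor × |E|` successful swaps are performed (default factor 10, a
standard mixing heuristic), within a bounded attempt budget; graphs with no
valid swap at all (single edge, stars) are returned unchanged with a
warning. Degree sequences are preserved exactly by construction and asserted
exactly in tests. Rewired networks keep the original node ordering, so
pathway index arithmetic carries over unchanged.

The same `n_perm` random gene sets are reused across the original and all
rewired networks. This makes the correction term `C_i = RN_i − mean_j(RR_ji)`
a paired, per-replicate difference, which is the default. The alternative
reading — subtracting the grand mean of RR as one scalar — has the same
mean(C) but a different spread; it is available as `rr_grand_mean=True`.
With no rewiring at all, DR equals DN and C is identically zero, so the
corrected z-score degenerates — by design: the correction removes signal
explained by the real network's overlap structure.

## Significance and ranking

z-scores use the sample (n−1) standard deviation and convert to one-sided
upper-tail normal p-values (`1 − Φ(z)`; 1.65 ↔ ~0.05, which pins down the
one-sided convention). Ranking is by descending z (ORA: ascending p), ties
broken lexicographically by pathway identifier for determinism. A
zero-variance null makes z undefined: such pathways are flagged
`degenerate`, reported with z = 0 and p = 1, and placed after all
well-defined pathways.

No multiple-testing correction is applied by default — the raw 1.65 / 0.05
cutoffs are the method's published operating point. Benjamini–Hochberg
adjusted p-values are available behind `--bh`; when enabled, ORA's
significance flag switches to the adjusted p while the network methods keep
the z cutoff.

The ORA universe defaults to the network's node set (keeping the three
methods on the same gene universe); the union of annotated genes is available
as an option.

## Synthetic benchmarks

The generator emulates a PPI network + pathway annotation at desk scale with
exact ground truth: a planted-partition graph of 300 nodes with five modules
of 20 (within-module edge probability 0.8, background 0.02), each module
registered as a pathway, plus 20 size-matched random decoy pathways. Input
sets take a chosen fraction of their genes from a causal module and the rest
from the module's direct network neighbours ("hidden" mode) or from uniform
background ("noise" mode). The hidden mode with zero overlap reproduces the
regime the network correction exists for: ORA's p-value for the causal
pathway is exactly 1, while the corrected z-score still separates it from
decoys (p_in = 0.9, p_out = 0.01 for that benchmark).

What the generator does **not** emulate: scale-free degree structure, hub
proteins, annotation bias, overlapping pathways, or noisy/missing edges of
real interactome data. Passing benchmarks therefore demonstrates the
machinery (propagation, nulls, calibration, ranking) under a clean planted
truth, not performance on any real interactome.

Benchmark problem sizes used throughout the test suite and the acceptance
script — `n_perm = 200`, `n_nets = 3`, 20–100 trials — are the package's
desk-scale defaults for synthetic validation; production defaults remain
`n_perm = 1000`, `n_nets = 10`.

## Reproducibility

A single integer seed drives everything: sub-streams for gene-set sampling
and rewiring are spawned deterministically from it, and the same seed with
the same inputs yields byte-identical output files.

## Known limitations

- Unweighted, undirected networks only; exact-string gene identifiers (no
  alias or cross-namespace mapping).
- The normal conversion of permutation z-scores is an approximation; very
  large z values imply p-values far beyond what 200–1000 permutations can
  empirically resolve.
- NetPEA′'s correction assumes rewired networks destroy module structure
  while preserving degrees; on very dense or very small graphs rewiring
  mixes poorly and the correction weakens.
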