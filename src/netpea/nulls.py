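"""Randomization backgrounds: random gene sets and rewired networks.

Two null models drive significance assessment:

* size-matched gene sets drawn uniformly (without replacement) from the
  network's nodes — randomizing *what* is asked;
* degree-preserving rewired networks produced by repeated double-edge swaps —
  randomizing *where* genes sit while every node keeps its exact degree.

For the network-corrected z-score four score blocks are needed per pathway:
``DN`` (real input, real network), ``DR`` (real input, each rewired network),
``RN`` (each random set, real network) and ``RR`` (each random set, each
rewired network).  The same random gene sets are reused across the original
and all rewired networks, so ``RN - mean_j(RR_j)`` is a paired per-replicate
difference.

All similarity scores for one network are computed in a single batched RWR
run (every seed vector a column), which is arithmetically identical to
propagating the sets one at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genesets import GeneSet, InputGeneSet
from .network import GeneNetwork
from .propagation import (
    DEFAULT_MAX_ITERATIONS,
    DEFAULT_TOLERANCE,
    pathway_score_matrix,
    rwr_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsembles",
    "sample_random_gene_set",
    "rewire_network",
    "build_null_ensembles",
]

DEFAULT_SWAP_FACTOR = 10


def sample_random_gene_set(
    network: GeneNetwork,
    size: int,
    rng: np.random.Generator,
    match_degrees_of: Sequence[str] | None = None,
) -> InputGeneSet:
    """Uniform sample of ``size`` distinct network nodes.

    With ``match_degrees_of`` (a reference gene list, e.g. the real input),
    sampling is degree-matched instead: nodes are binned by degree decile and
    each reference gene is replaced by a uniform draw from its own bin.  The
    default, uniform mode is the standard background.
    """
    n = network.n_nodes
    if not 1 <= size <= n:
        raise ValueError(f"size must be in [1, {n}], got {size}")
    if match_degrees_of is None:
        picks = rng.choice(n, size=size, replace=False)
        genes = tuple(network.nodes[i] for i in picks)
    else:
        genes = _degree_matched_sample(network, match_degrees_of, rng)
    return InputGeneSet(genes=genes, mapped=genes)


def _degree_matched_sample(
    network: GeneNetwork, reference: Sequence[str], rng: np.random.Generator
) -> tuple[str, ...]:
    deg = network.degree
    edges = np.quantile(deg, np.linspace(0, 1, 11))
    bins = np.searchsorted(edges[1:-1], deg, side="right")
    by_bin: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins == b) for b in np.unique(bins)
    }
    chosen: set[int] = set()
    for g in reference:
        b = int(bins[network.index[g]])
        pool = by_bin[b]
        for _ in range(100):
            i = int(pool[rng.integers(len(pool))])
            if i not in chosen:
                chosen.add(i)
                break
        else:  # tiny bin exhausted; fall back to uniform
            while True:
                i = int(rng.integers(network.n_nodes))
                if i not in chosen:
                    chosen.add(i)
                    break
    return tuple(network.nodes[i] for i in sorted(chosen))


def rewire_network(
    network: GeneNetwork,
    rng: np.random.Generator,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
) -> GeneNetwork:
    """Degree-preserving randomization by double-edge swaps.

    Performs ``swap_factor * n_edges`` successful swaps: pick two edges
    {a,b} and {c,d}, replace them with {a,d} and {c,b} unless that would
    create a self-loop or a duplicate edge.  The attempt budget is bounded;
    graphs admitting no valid swap at all (a single edge, a star) are
    returned unchanged with a warning.  Node order, and hence the node
    indexing shared with the original, is preserved.
    """
    m = network.n_edges
    if m < 2:
        logger.warning("rewiring skipped: fewer than 2 edges")
        return network
    target = swap_factor * m
    if target == 0:
        return network
    idx = network.index
    edge_list = [tuple(sorted((idx[a], idx[b]))) for a, b in sorted(network.edges)]
    edge_set = set(edge_list)
    successes = 0
    budget = max(100 * target, 1000)
    # draw randomness in blocks; a pure-python loop over single draws is slow
    block = 4096
    pos = block
    while successes < target and budget > 0:
        if pos >= block:
            picks = rng.integers(0, m, size=(block, 2))
            flips = rng.random(block) < 0.5
            pos = 0
        e1, e2 = int(picks[pos, 0]), int(picks[pos, 1])
        flip = bool(flips[pos])
        pos += 1
        budget -= 1
        if e1 == e2:
            continue
        a, b = edge_list[e1]
        c, d = edge_list[e2]
        if flip:
            c, d = d, c
        # propose {a,d} and {c,b}
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edge_list[e1])
        edge_set.discard(edge_list[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edge_list[e1] = new1
        edge_list[e2] = new2
        successes += 1
    if successes == 0:
        logger.warning("no valid double-edge swap found; network returned unchanged")
        return network
    if successes < target:
        logger.warning(
            "rewiring stopped after %d of %d swaps (attempt budget exhausted)",
            successes,
            target,
        )
    nodes = network.nodes
    return GeneNetwork.from_edges(
        ((nodes[i], nodes[j]) for i, j in edge_list), extra_nodes=nodes
    )


@dataclass
class NullEnsembles:
    """Similarity-score blocks for significance assessment.

    Shapes (``n_path`` scorable pathways, ``n_nets`` rewired networks,
    ``n_perm`` random gene sets): ``dn (n_path,)``, ``dr (n_path, n_nets)``,
    ``rn (n_path, n_perm)``, ``rr (n_path, n_nets, n_perm)``.
    """

    pathway_names: tuple[str, ...]
    dn: np.ndarray
    dr: np.ndarray
    rn: np.ndarray
    rr: np.ndarray

    @property
    def n_perm(self) -> int:
        return self.rn.shape[1]

    @property
    def n_nets(self) -> int:
        return self.dr.shape[1]


def build_null_ensembles(
    network: GeneNetwork,
    rewired_networks: Sequence[GeneNetwork],
    pathways: Sequence[GeneSet],
    input_set: InputGeneSet,
    n_perm: int,
    rng: np.random.Generator,
    restart_probability: float = 0.5,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    degree_matched: bool = False,
) -> NullEnsembles:
    """Score the real input and ``n_perm`` random sets on the original and
    every rewired network.

    ``pathways`` must already be mapped to ``network`` and scorable.  The
    rewired networks must share the original's node set and order (as
    produced by :func:`rewire_network`), so one pathway-averaging operator
    and one seed matrix serve all networks.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if input_set.mapped is None:
        input_set = input_set.map_to(network)
    size = len(input_set.mapped)

    seeds = np.empty((network.n_nodes, 1 + n_perm))
    seeds[:, 0] = network.indicator(input_set.mapped)
    for k in range(n_perm):
        rand = sample_random_gene_set(
            network,
            size,
            rng,
            match_degrees_of=input_set.mapped if degree_matched else None,
        )
        seeds[:, 1 + k] = network.indicator(rand.mapped)

    P = pathway_score_matrix(network, [s.mapped for s in pathways])

    def score_on(net: GeneNetwork) -> np.ndarray:
        values, _, _, converged = rwr_matrix(
            net, seeds, restart_probability, tolerance, max_iterations
        )
        if not converged:
            logger.warning("RWR did not converge within %d iterations", max_iterations)
        return P @ values

    real = score_on(network)
    n_path = len(pathways)
    n_nets = len(rewired_networks)
    dr = np.empty((n_path, n_nets))
    rr = np.empty((n_path, n_nets, n_perm))
    for j, net in enumerate(rewired_networks):
        s = score_on(net)
        dr[:, j] = s[:, 0]
        rr[:, j, :] = s[:, 1:]
    return NullEnsembles(
        pathway_names=tuple(s.name for s in pathways),
        dn=real[:, 0],
        dr=dr,
        rn=real[:, 1:],
        rr=rr,
    )
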