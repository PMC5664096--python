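"""Synthetic benchmark scenarios with planted pathway modules.

A planted-partition graph stands in for a real protein-interaction network
annotated with pathways: the first ``n_modules * module_size`` nodes are
partitioned into dense modules (edge probability ``p_in`` within a module)
over a sparse background (``p_out`` for every other pair, including
background--background).  Each module is registered as a pathway, and decoy
pathways of matched size are drawn uniformly from all nodes, so the ground
truth — which pathway an input gene set is causally tied to — is exact.

Input gene sets are derived from a chosen causal module: a fraction of the
genes is taken from the module itself, the remainder from the module's direct
network neighbours (hidden-signal mode — the regime where overlap-based tests
are blind but network proximity still carries the signal) or from uniform
background (noise mode).

Everything is generated from a single numpy Generator, so a scenario is
exactly reproducible from its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genesets import GeneSet, GeneSetCollection, InputGeneSet, write_gene_list
from .network import GeneNetwork, write_edge_list

logger = logging.getLogger(__name__)

__all__ = ["ScenarioParams", "SyntheticScenario", "generate_scenario", "make_input_set"]


@dataclass(frozen=True)
class ScenarioParams:
    """Generation parameters; defaults give the desk-scale benchmark."""

    n_nodes: int = 300
    n_modules: int = 5
    module_size: int = 20
    p_in: float = 0.8
    p_out: float = 0.02
    n_decoys: int = 20

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_nodes:
            raise ValueError("modules do not fit into the node count")
        if not (0.0 <= self.p_out <= 1.0 and 0.0 <= self.p_in <= 1.0):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out")
        if self.module_size < 1 or self.n_modules < 1:
            raise ValueError("need at least one module of size >= 1")


@dataclass
class SyntheticScenario:
    """A generated network + pathway collection with known planted truth."""

    network: GeneNetwork
    pathways: GeneSetCollection  # already mapped to the network
    modules: dict[str, tuple[str, ...]]  # pathway id -> planted node set
    params: ScenarioParams
    seed: int
    decoy_names: tuple[str, ...] = field(default_factory=tuple)

    def write(self, directory: str | Path) -> None:
        """Emit edge list + GMT + per-module input lists in CLI formats."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_edge_list(self.network, directory / "network.tsv")
        self.pathways.to_gmt(directory / "pathways.gmt")
        for name, members in self.modules.items():
            write_gene_list(members, directory / f"input_{name}.txt")


def generate_scenario(
    params: ScenarioParams | None = None, seed: int = 0
) -> SyntheticScenario:
    """Draw a planted-partition scenario from ``seed``.

    Module pathways are named ``PLANTED_k``, decoys ``DECOY_k``.  At least
    one edge is guaranteed (a degenerate empty draw gets one forced
    within-module edge).  Background nodes may be isolated; they are retained.
    """
    params = params or ScenarioParams()
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = params.n_nodes
    names = [f"G{i:04d}" for i in range(n)]

    membership = np.full(n, -1)
    for m in range(params.n_modules):
        lo = m * params.module_size
        membership[lo : lo + params.module_size] = m

    iu, ju = np.triu_indices(n, k=1)
    same = (membership[iu] >= 0) & (membership[iu] == membership[ju])
    probs = np.where(same, params.p_in, params.p_out)
    mask = rng.random(iu.size) < probs
    if not mask.any():
        mask[np.flatnonzero(same)[0] if same.any() else 0] = True
    edges = [(names[i], names[j]) for i, j in zip(iu[mask], ju[mask])]
    network = GeneNetwork.from_edges(edges, extra_nodes=names)

    sets: list[GeneSet] = []
    modules: dict[str, tuple[str, ...]] = {}
    for m in range(params.n_modules):
        lo = m * params.module_size
        members = tuple(names[lo : lo + params.module_size])
        pid = f"PLANTED_{m + 1:02d}"
        modules[pid] = members
        sets.append(GeneSet(pid, f"planted module {m + 1}", members))
    decoys = []
    for d in range(params.n_decoys):
        picks = rng.choice(n, size=params.module_size, replace=False)
        pid = f"DECOY_{d + 1:02d}"
        decoys.append(pid)
        sets.append(
            GeneSet(pid, f"random decoy {d + 1}", tuple(names[i] for i in sorted(picks)))
        )
    pathways = GeneSetCollection(sets).map_to(network)
    return SyntheticScenario(
        network=network,
        pathways=pathways,
        modules=modules,
        params=params,
        seed=seed,
        decoy_names=tuple(decoys),
    )


def make_input_set(
    scenario: SyntheticScenario,
    causal_id: str,
    overlap_fraction: float,
    size: int,
    rng: np.random.Generator,
    mode: str = "hidden",
) -> InputGeneSet:
    """Derive an input gene set tied to one planted module.

    ``round(overlap_fraction * size)`` genes come from the causal module;
    the remainder from the module's direct network neighbours (``mode=
    "hidden"``) or from uniform non-module background (``mode="noise"``).
    Falls back to background (with a warning) when there are not enough
    neighbour candidates.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if size < 1:
        raise ValueError("size must be >= 1")
    if mode not in ("hidden", "noise"):
        raise ValueError("mode must be 'hidden' or 'noise'")
    module = scenario.modules[causal_id]
    n_core = round(overlap_fraction * size)
    if n_core > len(module):
        raise ValueError("overlap portion exceeds module size")
    core = [module[i] for i in sorted(rng.choice(len(module), n_core, replace=False))]
    n_rest = size - n_core
    chosen = list(core)
    if n_rest:
        module_set = set(module)
        if mode == "hidden":
            pool = sorted(
                {
                    nb
                    for g in module
                    for nb in scenario.network.neighbors(g)
                }
                - module_set
                - set(core)
            )
        else:
            pool = []
        if len(pool) < n_rest:
            if mode == "hidden":
                logger.warning(
                    "only %d neighbour candidates for %d slots; topping up "
                    "from background",
                    len(pool),
                    n_rest,
                )
            chosen += pool
            n_rest -= len(pool)
            background = sorted(
                set(scenario.network.nodes) - module_set - set(chosen)
            )
            picks = rng.choice(len(background), n_rest, replace=False)
            chosen += [background[i] for i in sorted(picks)]
        else:
            picks = rng.choice(len(pool), n_rest, replace=False)
            chosen += [pool[i] for i in sorted(picks)]
    return InputGeneSet(genes=tuple(chosen), mapped=tuple(chosen))
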