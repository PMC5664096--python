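"""Enrichment statistics and the end-to-end analysis pipeline.

Three methods are provided:

``netpea``
    z = (D - mean(R)) / std(R), where D is the pathway's similarity score to
    the real input and R the scores of size-matched random gene sets on the
    real network.

``netpea-prime``
    z = ((DN - mean(DR)) - mean(C)) / std(C) with C_i = RN_i - mean_j(RR_ji),
    the network-corrected variant: the rewired-network scores subtract the
    part of a pathway's signal explained by direct overlap alone, promoting
    pathways reachable through interactions.

``ora``
    classical over-representation: upper-tail hypergeometric probability of
    the observed input/pathway overlap, with the network's node set as the
    default universe.

z-scores are converted to one-sided upper-tail normal p-values; pathways with
z above 1.65 (p ~ 0.05) are flagged significant.  Standard deviations use the
sample (n-1) convention.  A zero-variance null makes the z-score undefined:
the op-level functions return NaN, and the pipeline reports such pathways
with z = 0, p = 1, a ``degenerate`` flag, ranked after all well-defined ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSetCollection, InputGeneSet
from .network import GeneNetwork
from .nulls import (
    DEFAULT_SWAP_FACTOR,
    build_null_ensembles,
    rewire_network,
)
from .propagation import DEFAULT_MAX_ITERATIONS, DEFAULT_TOLERANCE

__all__ = [
    "EnrichmentParams",
    "EnrichmentResult",
    "netpea_zscore",
    "netpea_prime_zscore",
    "z_to_p",
    "ora_pvalue",
    "run_enrichment",
    "METHODS",
]

METHODS = ("netpea", "netpea-prime", "ora")

#: z cutoff matching a one-sided p-value of ~0.05
DEFAULT_CUTOFF = 1.65


def netpea_zscore(d: float, r: Sequence[float]) -> float:
    """Permutation z-score of a similarity score against its random-set null.

    Returns NaN when the null has zero variance (z undefined).
    """
    r = np.asarray(r, dtype=float)
    if r.size < 2:
        raise ValueError("null vector needs at least 2 replicates")
    sd = r.std(ddof=1)
    if sd == 0.0:
        return math.nan
    return float((d - r.mean()) / sd)


def netpea_prime_zscore(
    dn: float,
    dr: Sequence[float],
    rn: Sequence[float],
    rr: np.ndarray,
    grand_mean: bool = False,
) -> float:
    """Network-corrected z-score.

    ``rr`` has shape (n_nets, n_perm) with the same replicate ordering as
    ``rn``.  In the default paired mode the correction is per replicate,
    C_i = RN_i - mean_j(RR_ji); with ``grand_mean=True`` a single scalar
    mean(RR) is subtracted instead (same mean, different spread).  Returns
    NaN when std(C) is zero.
    """
    dr = np.asarray(dr, dtype=float)
    rn = np.asarray(rn, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if dr.size < 1:
        raise ValueError("need at least one rewired-network score")
    if rn.size < 2:
        raise ValueError("null vector needs at least 2 replicates")
    if rr.shape != (dr.size, rn.size):
        raise ValueError(f"rr must have shape {(dr.size, rn.size)}, got {rr.shape}")
    c = rn - (rr.mean() if grand_mean else rr.mean(axis=0))
    sd = c.std(ddof=1)
    if sd == 0.0:
        return math.nan
    return float(((dn - dr.mean()) - c.mean()) / sd)


def z_to_p(z: float) -> float:
    """One-sided upper-tail standard-normal p-value, 1 - Phi(z)."""
    return float(stats.norm.sf(z))


def ora_pvalue(
    overlap: int, input_size: int, pathway_size: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P[X >= overlap].

    X counts pathway genes in a uniform draw of ``input_size`` genes from a
    universe of ``universe_size`` genes of which ``pathway_size`` belong to
    the pathway.
    """
    if not (0 <= overlap <= min(input_size, pathway_size)):
        raise ValueError("overlap exceeds input or pathway size")
    if max(input_size, pathway_size) > universe_size:
        raise ValueError("set sizes exceed the universe")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, pathway_size, input_size))


@dataclass(frozen=True)
class EnrichmentParams:
    """Tunable analysis parameters (defaults follow the published settings)."""

    restart_probability: float = 0.5
    n_perm: int = 1000
    n_nets: int = 10
    swap_factor: int = DEFAULT_SWAP_FACTOR
    cutoff: float = DEFAULT_CUTOFF
    tolerance: float = DEFAULT_TOLERANCE
    max_iterations: int = DEFAULT_MAX_ITERATIONS
    rr_grand_mean: bool = False
    degree_matched: bool = False
    bh: bool = False
    min_size: int | None = None
    max_size: int | None = None
    ora_universe: str = "network"  # or "gmt": union of annotated genes

    def validate(self) -> None:
        if not 0.0 < self.restart_probability < 1.0:
            raise ValueError("restart probability must lie in (0, 1)")
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        if self.n_nets < 0 or self.swap_factor < 0:
            raise ValueError("n_nets and swap_factor must be non-negative")
        if self.ora_universe not in ("network", "gmt"):
            raise ValueError("ora_universe must be 'network' or 'gmt'")


_COLUMNS = [
    "pathway_id",
    "description",
    "size",
    "mapped_size",
    "overlap",
    "similarity",
    "zscore",
    "pvalue",
    "rank",
    "significant",
    "degenerate",
]


@dataclass
class EnrichmentResult:
    """Ranked per-pathway results plus run metadata."""

    method: str
    table: pd.DataFrame
    params: EnrichmentParams
    seed: int
    unscorable: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def ranking(self) -> tuple[str, ...]:
        return tuple(self.table["pathway_id"])

    def significant(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["significant"], "pathway_id"])

    def rank_of(self, pathway_id: str) -> int:
        row = self.table.loc[self.table["pathway_id"] == pathway_id, "rank"]
        if row.empty:
            raise KeyError(pathway_id)
        return int(row.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# method: {self.method}\n")
            fh.write(f"# seed: {self.seed}\n")
            fh.write(f"# n_perm: {self.params.n_perm}\n")
            fh.write(f"# n_nets: {self.params.n_nets}\n")
            fh.write(f"# restart_p: {self.params.restart_probability}\n")
            fh.write(f"# cutoff: {self.params.cutoff}\n")
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            if self.unscorable:
                fh.write(f"# unscorable: {','.join(self.unscorable)}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnrichmentResult":
        path = Path(path)
        meta: dict[str, str] = {}
        with path.open() as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                body_start = i + 1
            else:
                break
        from io import StringIO

        table = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
        params = EnrichmentParams(
            restart_probability=float(meta.get("restart_p", 0.5)),
            n_perm=int(meta.get("n_perm", 1000)),
            n_nets=int(meta.get("n_nets", 10)),
            cutoff=float(meta.get("cutoff", DEFAULT_CUTOFF)),
        )
        unscorable = tuple(
            x for x in meta.get("unscorable", "").split(",") if x
        )
        return cls(
            method=meta.get("method", "unknown"),
            table=table,
            params=params,
            seed=int(meta.get("seed", 0)),
            unscorable=unscorable,
            metadata=meta,
        )


def _rank_and_flag(
    df: pd.DataFrame, method: str, cutoff: float, bh: bool
) -> pd.DataFrame:
    """Sort, assign ranks 1..n and the significance flag.

    Network methods sort by descending z (ORA by ascending p); degenerate
    pathways go last; ties break lexicographically by pathway id.
    """
    if method == "ora":
        df = df.sort_values(
            by=["degenerate", "pvalue", "pathway_id"],
            ascending=[True, True, True],
            kind="mergesort",
        )
    else:
        df = df.sort_values(
            by=["degenerate", "zscore", "pathway_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if bh and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    if method == "ora":
        pcol = "p_adjusted" if bh and "p_adjusted" in df else "pvalue"
        df["significant"] = (df[pcol] <= 0.05) & ~df["degenerate"]
    else:
        df["significant"] = (df["zscore"] > cutoff) & ~df["degenerate"]
    cols = _COLUMNS + (["p_adjusted"] if "p_adjusted" in df else [])
    return df[cols]


def run_enrichment(
    network: GeneNetwork,
    pathways: GeneSetCollection,
    input_set: InputGeneSet,
    method: str = "netpea",
    params: EnrichmentParams | None = None,
    seed: int = 0,
) -> EnrichmentResult:
    """End-to-end analysis: map, propagate, build nulls, score and rank.

    The ``seed`` drives every source of randomness (random gene sets and
    network rewiring) through deterministically derived sub-streams; the
    same seed and inputs reproduce the result exactly.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    params = params or EnrichmentParams()
    params.validate()

    if params.min_size is not None or params.max_size is not None:
        pathways = pathways.filter_by_size(params.min_size, params.max_size)
    mapped_sets = pathways.map_to(network)
    input_mapped = input_set.map_to(network)
    scorable = mapped_sets.scorable()
    unscorable = tuple(s.name for s in mapped_sets.unscorable())
    input_genes = set(input_mapped.mapped)

    records: dict[str, list] = {c: [] for c in _COLUMNS if c not in ("rank", "significant")}

    def add(s, similarity, z, p, degenerate):
        records["pathway_id"].append(s.name)
        records["description"].append(s.description)
        records["size"].append(len(s.members))
        records["mapped_size"].append(len(s.mapped))
        records["overlap"].append(len(input_genes.intersection(s.mapped)))
        records["similarity"].append(similarity)
        records["zscore"].append(z)
        records["pvalue"].append(p)
        records["degenerate"].append(degenerate)

    if method == "ora":
        if params.ora_universe == "gmt":
            universe = set()
            for s in mapped_sets:
                universe.update(s.members)
            universe &= set(network.nodes)
        else:
            universe = set(network.nodes)
        n_universe = len(universe)
        n_input = len(input_genes & universe)
        for s in scorable:
            members = set(s.mapped) & universe
            k = len(input_genes & members)
            p = ora_pvalue(k, n_input, len(members), n_universe) if members else 1.0
            add(s, math.nan, math.nan, p, degenerate=not members)
    else:
        rng_sets, rng_wire = _substreams(seed)
        rewired: list[GeneNetwork] = []
        if method == "netpea-prime":
            if params.n_nets < 1:
                raise ValueError("netpea-prime requires n_nets >= 1")
            rewired = [
                rewire_network(network, rng_wire, params.swap_factor)
                for _ in range(params.n_nets)
            ]
        ens = build_null_ensembles(
            network,
            rewired,
            scorable,
            input_mapped,
            params.n_perm,
            rng_sets,
            restart_probability=params.restart_probability,
            tolerance=params.tolerance,
            max_iterations=params.max_iterations,
            degree_matched=params.degree_matched,
        )
        for i, s in enumerate(scorable):
            if method == "netpea":
                z = netpea_zscore(ens.dn[i], ens.rn[i])
            else:
                z = netpea_prime_zscore(
                    ens.dn[i],
                    ens.dr[i],
                    ens.rn[i],
                    ens.rr[i],
                    grand_mean=params.rr_grand_mean,
                )
            if math.isnan(z):
                add(s, ens.dn[i], 0.0, 1.0, degenerate=True)
            else:
                add(s, ens.dn[i], z, z_to_p(z), degenerate=False)

    df = pd.DataFrame(records)
    df = _rank_and_flag(df, method, params.cutoff, params.bh)
    return EnrichmentResult(
        method=method,
        table=df,
        params=params,
        seed=seed,
        unscorable=unscorable,
        metadata={
            "n_input": len(input_set.genes),
            "n_input_mapped": len(input_mapped.mapped),
        },
    )


def _substreams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent generators for gene-set sampling and rewiring."""
    ss = np.random.SeedSequence(seed)
    child_sets, child_wire = ss.spawn(2)
    return np.random.default_rng(child_sets), np.random.default_rng(child_wire)
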