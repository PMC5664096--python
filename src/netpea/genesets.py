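"""Pathway collections (GMT) and input gene sets, with network mapping.

Pathways arrive in the Broad/MSigDB GMT dialect: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.  Input gene sets are plain
text, one gene per line, ``#`` comments allowed.

Before scoring, both are mapped onto a :class:`~netpea.network.GeneNetwork`:
the *mapped* members of a set are those present among the network's nodes.
Similarity scores average over mapped members only (unmapped genes have no
node value), and pathways with zero mapped members are unscorable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "InputGeneSet",
    "GmtParseError",
    "SeedError",
    "read_gmt",
    "read_gene_list",
    "map_to_network",
]


class GmtParseError(ValueError):
    """Malformed GMT line (fewer than 3 fields, or a duplicate set name)."""


class SeedError(ValueError):
    """An input gene set with no members mapped onto the network."""


def _dedup(genes: Iterable[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    for g in genes:
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return tuple(out)


@dataclass(frozen=True)
class GeneSet:
    """One named gene set (pathway)."""

    name: str
    description: str
    members: tuple[str, ...]
    #: members present in the reference network; None until mapped
    mapped: tuple[str, ...] | None = None

    @property
    def scorable(self) -> bool:
        return bool(self.mapped)

    def map_to(self, network: GeneNetwork) -> "GeneSet":
        return replace(
            self, mapped=tuple(g for g in self.members if g in network)
        )


class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise GmtParseError(f"duplicate gene-set name {s.name!r}")
            self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._sets)

    def map_to(self, network: GeneNetwork) -> "GeneSetCollection":
        """Annotate every set with its network-mapped members."""
        mapped = GeneSetCollection(s.map_to(network) for s in self)
        n_unscorable = sum(not s.scorable for s in mapped)
        if n_unscorable:
            logger.warning(
                "%d gene set(s) have no member on the network and are unscorable",
                n_unscorable,
            )
        return mapped

    def filter_by_size(
        self, min_size: int | None = None, max_size: int | None = None
    ) -> "GeneSetCollection":
        """Keep sets whose annotated size lies within [min_size, max_size]."""
        lo = min_size or 0
        hi = max_size if max_size is not None else float("inf")
        return GeneSetCollection(
            s for s in self if lo <= len(s.members) <= hi
        )

    def scorable(self) -> list[GeneSet]:
        return [s for s in self if s.scorable]

    def unscorable(self) -> list[GeneSet]:
        return [s for s in self if s.mapped is not None and not s.scorable]

    def to_gmt(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for s in self:
                fh.write("\t".join((s.name, s.description, *s.members)) + "\n")


@dataclass(frozen=True)
class InputGeneSet:
    """The query gene list; its mapped subset seeds the random walk."""

    genes: tuple[str, ...]
    mapped: tuple[str, ...] | None = None

    def map_to(self, network: GeneNetwork) -> "InputGeneSet":
        mapped = tuple(g for g in self.genes if g in network)
        dropped = len(self.genes) - len(mapped)
        if dropped:
            logger.warning(
                "%d of %d input gene(s) absent from the network were dropped",
                dropped,
                len(self.genes),
            )
        if not mapped:
            raise SeedError("no input gene maps onto the network")
        return replace(self, mapped=mapped)

    @classmethod
    def from_genes(cls, genes: Iterable[str]) -> "InputGeneSet":
        return cls(genes=_dedup(genes))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file.

    Raises :class:`GmtParseError` (naming the line number) for lines with
    fewer than three tab-separated fields or duplicated set names.  An empty
    file yields an empty collection with a logged warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected name, description and >=1 member"
                )
            name, description = fields[0], fields[1]
            if name in seen:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(
                GeneSet(name=name, description=description, members=_dedup(fields[2:]))
            )
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets)


def read_gene_list(path: str | Path) -> InputGeneSet:
    """Read a plain-text gene list (one gene per line, '#' comments)."""
    genes: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return InputGeneSet.from_genes(genes)


def map_to_network(
    sets: GeneSetCollection, network: GeneNetwork
) -> GeneSetCollection:
    """Functional alias for :meth:`GeneSetCollection.map_to`."""
    return sets.map_to(network)


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(g + "\n")
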