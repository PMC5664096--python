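"""Comparison procedures between method rankings.

Three utilities for judging agreement between enrichment methods run on the
same pathway collection:

* :func:`overlap_significance` — how unusual is the overlap between two
  methods' significant-pathway sets, under a hypergeometric model over a
  fixed background of candidate pathways;
* :func:`rank_correlation` — Spearman rank correlation between two full
  pathway rankings;
* :func:`cross_verification` — of one method's top-k pathways, how many are
  corroborated (also top-k) or contradicted (below a deeper cutoff) by the
  other methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

__all__ = [
    "MethodRanking",
    "OverlapSignificance",
    "overlap_significance",
    "rank_correlation",
    "cross_verification",
]


@dataclass(frozen=True)
class MethodRanking:
    """One method's ordered pathway list (rank 1 first) and significant set."""

    name: str
    order: tuple[str, ...]
    significant: frozenset[str] = frozenset()

    def __post_init__(self):
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranking contains duplicate pathway identifiers")
        if not self.significant <= set(self.order):
            raise ValueError("significant set must be a subset of the ranking")

    @classmethod
    def from_result(cls, result, name: str | None = None) -> "MethodRanking":
        """Build from an :class:`~netpea.enrichment.EnrichmentResult`."""
        return cls(
            name=name or result.method,
            order=result.ranking(),
            significant=result.significant(),
        )

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "MethodRanking":
        from .enrichment import EnrichmentResult

        result = EnrichmentResult.from_tsv(path)
        return cls.from_result(result, name=name or Path(path).stem)

    def rank_of(self, pathway_id: str) -> int:
        return self.order.index(pathway_id) + 1

    def top(self, k: int) -> frozenset[str]:
        return frozenset(self.order[:k])


@dataclass(frozen=True)
class OverlapSignificance:
    common: int
    ratio: float
    pvalue: float


def overlap_significance(
    sig_a: Iterable[str], sig_b: Iterable[str], background: int
) -> OverlapSignificance:
    """Overlap between two significant-pathway sets.

    Returns the common count, the Jaccard-style ratio |A∩B| / |A∪B| (0 when
    both sets are empty), and the upper-tail hypergeometric probability of
    drawing at least |A∩B| of A's pathways when |B| pathways are sampled from
    ``background`` candidates.
    """
    a, b = set(sig_a), set(sig_b)
    union = a | b
    if background < len(union):
        raise ValueError("background smaller than the union of the two sets")
    common = len(a & b)
    ratio = common / len(union) if union else 0.0
    p = float(stats.hypergeom.sf(common - 1, background, len(a), len(b)))
    return OverlapSignificance(common=common, ratio=ratio, pvalue=p)


def rank_correlation(r1: MethodRanking, r2: MethodRanking) -> float:
    """Spearman rank correlation between two rankings of the same pathways."""
    if set(r1.order) != set(r2.order):
        raise ValueError("rankings must cover the same pathway identifiers")
    pos2 = {p: i for i, p in enumerate(r2.order)}
    x = range(len(r1.order))
    y = [pos2[p] for p in r1.order]
    rho = stats.spearmanr(list(x), y).statistic
    return float(rho)


def cross_verification(
    focal: MethodRanking,
    others: Sequence[MethodRanking],
    top_k: int = 20,
    deep_k: int = 100,
    mode: str = "any",
) -> tuple[int, int]:
    """Positive / negative corroboration counts for a method's top pathways.

    positive — top-``top_k`` pathways of ``focal`` that also appear in the
    top-``top_k`` of at least one other method (``mode="any"``, default) or
    of every other method (``mode="all"``).

    negative — top-``top_k`` pathways of ``focal`` ranked below ``deep_k``
    by *every* other method.
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    if not others:
        raise ValueError("need at least one other ranking")
    if not top_k < deep_k:
        raise ValueError("top_k must be smaller than deep_k")
    for r in (focal, *others):
        if len(r.order) < deep_k:
            raise ValueError(f"ranking {r.name!r} shorter than deep_k={deep_k}")
    focal_top = focal.order[:top_k]
    other_tops = [m.top(top_k) for m in others]
    other_deeps = [m.top(deep_k) for m in others]
    agree = any if mode == "any" else all
    positive = sum(1 for p in focal_top if agree(p in t for t in other_tops))
    negative = sum(1 for p in focal_top if all(p not in d for d in other_deeps))
    return positive, negative
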