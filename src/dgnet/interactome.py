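"""Disease interactome construction and interactome-overlap statistics.

A disease interactome is the set of top-ranked disease-associated seed genes
together with their immediate neighbors in the protein-protein interaction
network, plus all interactions among those members (the induced subgraph).
Overlap between two interactomes is scored against a gene universe with the
one-sided hypergeometric tail; families of pairwise comparisons are
Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .enrichment_profiles import bh_adjust, hypergeom_tail, log10_hypergeom_tail
from .io_formats import GDARecord, PPIEdge

logger = logging.getLogger(__name__)

__all__ = [
    "SeedGeneSet",
    "Interactome",
    "GeneUniverse",
    "OverlapResult",
    "select_top_seeds",
    "build_interactome",
    "overlap_stats",
    "overlap_stats_from_counts",
    "cross_disorder_validation",
]


@dataclass
class SeedGeneSet:
    """Top-k disease-associated genes, ranked by association score."""

    disease_id: str
    genes: list[str]
    k_requested: int


@dataclass
class Interactome:
    """Seed genes plus their 1-hop PPI neighborhood and induced edges."""

    disease_id: str
    seeds: set[str]
    members: set[str]
    edges: list[PPIEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seeds <= self.members:
            raise ValueError("interactome seeds must be a subset of members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneUniverse:
    """The background gene set against which overlaps are scored."""

    genes: set[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene universe must be non-empty")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_edges(cls, edges: Iterable[PPIEdge], source: str = "ppi") -> "GeneUniverse":
        """Universe = every symbol incident to at least one retained edge."""
        genes: set[str] = set()
        for e in edges:
            genes.add(e.gene_a)
            genes.add(e.gene_b)
        return cls(genes, source)


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two gene sets in a shared universe.

    ``size_a`` (K) and ``size_b`` (n) are the set sizes after intersection with
    the N-gene universe, ``intersection`` (k) their common genes.  The expected
    overlap under independence is K*n/N and ``fold_enrichment`` = k/expected.
    """

    id_a: str
    id_b: str
    size_a: int
    size_b: int
    universe_size: int
    intersection: int
    expected: float
    fold_enrichment: float
    p_value: float
    log10_p: float
    adjusted_p: float | None = None


def select_top_seeds(records: Sequence[GDARecord], disease_id: str, k: int) -> SeedGeneSet:
    """Pick the k genes most strongly associated with a disease.

    Genes are ranked by descending association score; ties at the cut are
    broken by ascending lexicographic symbol so that exactly
    ``min(k, available)`` genes are returned deterministically.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    pool = [r for r in records if r.disease_id == disease_id]
    if not pool:
        raise ValueError(f"no gene-disease records for disease {disease_id!r}")
    ranked = sorted(pool, key=lambda r: (-r.gda_score, r.gene))
    genes = [r.gene for r in ranked[:k]]
    if len(genes) < k:
        logger.warning(
            "select_top_seeds(%s): only %d records available for k=%d",
            disease_id, len(genes), k,
        )
    return SeedGeneSet(disease_id, genes, k)


def build_interactome(seeds: SeedGeneSet, edges: Sequence[PPIEdge]) -> Interactome:
    """Expand a seed set to its 1-hop PPI neighborhood with induced edges.

    Members are the seeds plus every gene adjacent to a seed; the edge list is
    the full induced subgraph on the members (including neighbor-neighbor
    edges).  Seeds absent from the network stay as isolated members so that
    they still carry expression signal downstream.
    """
    seed_set = set(seeds.genes)
    if not seed_set:
        raise ValueError("empty seed set")
    adjacency: dict[str, set[str]] = {}
    for e in edges:
        adjacency.setdefault(e.gene_a, set()).add(e.gene_b)
        adjacency.setdefault(e.gene_b, set()).add(e.gene_a)
    members = set(seed_set)
    for s in seed_set:
        members |= adjacency.get(s, set())
    isolated = [s for s in seed_set if s not in adjacency]
    if isolated:
        logger.info(
            "build_interactome(%s): %d seeds have no PPI edges and remain isolated members",
            seeds.disease_id, len(isolated),
        )
    induced = [e for e in edges if e.gene_a in members and e.gene_b in members]
    return Interactome(seeds.disease_id, seed_set, members, induced)


def overlap_stats_from_counts(
    K: int, n: int, N: int, k: int, id_a: str = "a", id_b: str = "b"
) -> OverlapResult:
    """Overlap statistic from printed counts (set sizes and intersection).

    The p-value is the hypergeometric upper tail P(X >= k | N, K, n), computed
    in log space; fold enrichment is k*N/(K*n).
    """
    if N <= 0:
        raise ValueError("universe size must be positive")
    if k > min(K, n):
        raise ValueError(f"intersection k={k} exceeds min(K, n)=({K}, {n})")
    expected = K * n / N
    fold = (k / expected) if expected > 0 else 0.0
    log10p = log10_hypergeom_tail(k, N, K, n)
    p = hypergeom_tail(k, N, K, n)
    return OverlapResult(id_a, id_b, K, n, N, k, expected, fold, p, log10p)


def overlap_stats(
    set_a: "set[str] | Interactome",
    set_b: "set[str] | Interactome",
    universe: GeneUniverse,
) -> OverlapResult:
    """Hypergeometric overlap of two gene sets within a universe.

    Both sets are intersected with the universe before testing, making the
    statistic symmetric in its two arguments.
    """
    id_a = set_a.disease_id if isinstance(set_a, Interactome) else "a"
    id_b = set_b.disease_id if isinstance(set_b, Interactome) else "b"
    a = (set_a.members if isinstance(set_a, Interactome) else set(set_a)) & universe.genes
    b = (set_b.members if isinstance(set_b, Interactome) else set(set_b)) & universe.genes
    return overlap_stats_from_counts(
        len(a), len(b), len(universe), len(a & b), id_a=id_a, id_b=id_b
    )


def cross_disorder_validation(
    interactomes: Sequence[Interactome],
    universe: GeneUniverse,
    focal: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overlap of a focal interactome with every other, BH-corrected.

    One hypergeometric overlap test per unordered pair involving the focal
    interactome (default: the first one); BH adjustment is applied over that
    family and pairs significant at adjusted p < ``alpha`` are flagged.
    """
    if len(interactomes) < 2:
        raise ValueError("need at least two interactomes")
    ids = [i.disease_id for i in interactomes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate disease ids among interactomes: {ids}")
    focal = focal if focal is not None else ids[0]
    if focal not in ids:
        raise ValueError(f"focal disease {focal!r} not among {ids}")
    focal_i = interactomes[ids.index(focal)]
    results = [
        overlap_stats(focal_i, other, universe)
        for other in interactomes
        if other.disease_id != focal
    ]
    adj = bh_adjust([r.p_value for r in results])
    rows = []
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
        rows.append(
            {
                "disease_a": r.id_a,
                "disease_b": r.id_b,
                "size_a": r.size_a,
                "size_b": r.size_b,
                "universe_size": r.universe_size,
                "intersection": r.intersection,
                "expected": r.expected,
                "fold_enrichment": r.fold_enrichment,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "significant": r.adjusted_p < alpha,
            }
        )
    return pd.DataFrame(rows)
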