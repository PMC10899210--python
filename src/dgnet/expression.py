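"""Spatiotemporal expression matrix assembly and expression-derived gene sets.

The central container is a genes x spatiotemporal-coordinates matrix of
log10-transformed RPKM.  Replicate measurements at the same (gene, region,
stage) coordinate are averaged in linear space first; a coordinate whose mean
is exactly zero (the gene was unexpressed in every replicate) becomes a
missing cell rather than -inf.  Stage order is always supplied explicitly —
developmental stage labels ("8pcw", "4yrs", ...) do not sort lexically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionRecord, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "SpatioTemporalCoordinate",
    "ExpressionMatrix",
    "assemble_matrix",
    "filter_brain_expressed",
    "build_region_gene_sets",
]


@dataclass(frozen=True)
class SpatioTemporalCoordinate:
    """One (brain region, developmental stage) sampling point."""

    region: str
    stage: str
    period: str  # "prenatal" or "postnatal"


@dataclass
class ExpressionMatrix:
    """Genes x coordinates matrix of log10-averaged RPKM with missing cells.

    ``values`` is a DataFrame indexed by gene with a (region, stage)
    MultiIndex on the columns; NaN marks coordinates where the gene was
    unexpressed.  ``stage_order`` fixes the developmental ordering of the
    stage labels, and ``prenatal_stages`` the prenatal/postnatal split.
    """

    values: pd.DataFrame
    stage_order: list[str]
    prenatal_stages: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("expression matrix columns must be a (region, stage) MultiIndex")
        stages = set(self.values.columns.get_level_values(1))
        unknown = stages - set(self.stage_order)
        if unknown:
            raise ValueError(f"stages {sorted(unknown)} missing from the configured stage order")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def coordinates(self) -> list[SpatioTemporalCoordinate]:
        return [
            SpatioTemporalCoordinate(
                r, s, "prenatal" if s in self.prenatal_stages else "postnatal"
            )
            for r, s in self.values.columns
        ]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], list(self.stage_order), set(self.prenatal_stages))


def assemble_matrix(
    records: Sequence[ExpressionRecord],
    stage_order: Sequence[str],
    gene_filter: "set[str] | None" = None,
    prenatal_stages: "set[str] | None" = None,
) -> ExpressionMatrix:
    """Average replicates per coordinate and assemble the log10 matrix.

    Per (gene, region, stage) the arithmetic mean of all replicate RPKM values
    is taken — zeros participate in the average, so partial dropout only
    attenuates the cell.  A cell is missing iff the mean is zero; otherwise the
    value is log10(mean).  Rows are restricted to ``gene_filter`` when given,
    and genes left with no observed cell are dropped (and counted).
    """
    if not records:
        raise ValueError("no expression records")
    df = pd.DataFrame(
        [(r.gene, r.region, r.stage, r.rpkm) for r in records],
        columns=["gene", "region", "stage", "rpkm"],
    )
    if gene_filter is not None:
        df = df[df["gene"].isin(gene_filter)]
        if df.empty:
            raise ValueError("no expression records left after applying the gene filter")
    mean = df.pivot_table(index="gene", columns=["region", "stage"], values="rpkm", aggfunc="mean")
    with np.errstate(divide="ignore"):
        vals = np.log10(mean.where(mean > 0))
    # order columns by region, then by the configured stage order
    stage_rank = {s: i for i, s in enumerate(stage_order)}
    cols = sorted(vals.columns, key=lambda rs: (rs[0], stage_rank.get(rs[1], len(stage_rank))))
    vals = vals[cols]
    observed = vals.notna().any(axis=1)
    n_dropped = int((~observed).sum())
    if n_dropped:
        logger.info("assemble_matrix: dropped %d genes with zero observed cells", n_dropped)
    vals = vals.loc[observed].sort_index()
    return ExpressionMatrix(vals, list(stage_order), set(prenatal_stages or ()))


def filter_brain_expressed(
    matrix: ExpressionMatrix,
    reference: Mapping[str, float],
    threshold: float = 1.0,
) -> ExpressionMatrix:
    """Keep genes expressed above ``threshold`` (strict) in a tissue reference.

    ``reference`` maps gene symbols to an expression level (e.g. nTPM in whole
    brain); genes absent from the reference are treated as not expressed and
    logged.
    """
    if threshold < 0 and threshold != -1:
        raise ValueError("threshold must be >= 0 (or -1 for the identity filter)")
    absent = [g for g in matrix.genes if g not in reference]
    if absent:
        logger.info(
            "filter_brain_expressed: %d genes absent from the reference, treated as unexpressed",
            len(absent),
        )
    keep = [g for g in matrix.genes if reference.get(g, float("-inf")) > threshold]
    return matrix.subset_genes(keep)


def build_region_gene_sets(
    matrix: ExpressionMatrix,
    threshold: float = 2.0,
    collection_name: str = "region_expression",
) -> GeneSetCollection:
    """One gene set per brain region: genes exceeding ``threshold`` there.

    A gene belongs to a region's set iff its value strictly exceeds the
    threshold in at least one coordinate (any stage) of that region.  A region
    with no qualifying gene is omitted with a warning.
    """
    coll = GeneSetCollection(name=collection_name)
    for region in matrix.regions:
        block = matrix.values.xs(region, axis=1, level=0)
        hit = (block > threshold).any(axis=1)
        members = list(matrix.values.index[hit])
        if not members:
            logger.warning("build_region_gene_sets: region %s has no qualifying genes; omitted", region)
            continue
        coll.sets[region] = members
        coll.descriptions[region] = f"genes > {threshold} in >=1 coordinate of {region}"
    return coll
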