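"""Synthetic input generators with planted, recoverable structure.

These generators emulate the statistical shape of the pipeline's real inputs —
a gene-disease association table, degree-heterogeneous PPI edge tables,
long-format spatiotemporal expression with replicates and dropout, GMT gene
sets and a whole-brain expression reference — while planting known truth
(disease affiliations, temporal archetypes, dense modules) that downstream
stages must recover.

Planted temporal archetypes
---------------------------
Four archetypes mimic the temporal classes observed in disease interactomes:

1. consistently high across all stages (in a regional subcompartment),
2. high from infancy to adulthood (postnatal) in the complementary regions,
3. peaked at specific postnatal stages across all regions,
4. high during prenatal stages across all regions.

Active coordinates carry mean log10-RPKM 2.5, inactive ones 0.5, with
Gaussian noise on the log scale and a dropout probability per replicate
measurement.  Archetypes 1-2 are coupled to unique-SZ disease affiliation,
3 to unique-PD, and 4 to shared, with a configurable coupling purity.

Interactome overlap is planted by letting the two diseases draw a fraction of
their seed genes from a shared network community; communities are carved from
low-degree vertices of a preferential-attachment backbone so that at overlap
fraction 0 the two interactomes intersect only at chance level.

All generators are pure functions of (config, rng_seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionRecord,
    GDARecord,
    GeneSetCollection,
    PPIEdge,
    write_expression_long,
    write_gmt,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "archetype_active_coordinates",
    "gen_ppi_network",
    "gen_gda_table",
    "gen_expression",
    "gen_gene_sets",
    "gen_brain_reference",
    "gen_two_block_profiles",
    "write_bundle",
]

#: archetype -> implied disease affiliation
ARCHETYPE_AFFILIATION = {1: "SZ-unique", 2: "SZ-unique", 3: "PD-unique", 4: "shared"}
AFFILIATIONS = ("PD-unique", "SZ-unique", "shared")

DEFAULT_STAGES = ("8pcw", "12pcw", "16pcw", "21pcw", "10mos", "4yrs", "11yrs", "40yrs")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults are the desk-scale study conditions: 800 genes, 10 regions,
    8 stages (4 prenatal), log-scale noise sd 0.3, 5% dropout, two replicates
    per coordinate, archetype fractions proportional to the four temporal
    cluster sizes reported for real disease interactomes, and half of each
    disease's seed genes drawn from a shared community.
    """

    n_genes: int = 800
    n_seeds_per_disease: int = 20
    planted_overlap_fraction: float = 0.5
    attachment_edges_per_node: int = 2
    n_regions: int = 10
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_prenatal_stages: int = 4
    archetype_fractions: tuple[float, float, float, float] = (0.223, 0.252, 0.091, 0.434)
    noise_sd: float = 0.3
    dropout_rate: float = 0.05
    rng_seed: int = 0
    # network structure
    disease_ids: tuple[str, str] = ("C0030567", "C0036341")  # PD-like, SZ-like
    extra_disease_ids: tuple[str, ...] = ()
    community_size: int = 40
    community_edge_prob: float = 0.2
    n_planted_modules: int = 3
    planted_module_size: int = 10
    planted_module_edge_prob: float = 0.9
    # expression coupling
    archetype_purity: float = 0.8
    n_replicates: int = 2
    # brain-expression reference
    brain_expressed_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not 0.0 <= self.planted_overlap_fraction <= 1.0:
            raise ValueError("planted_overlap_fraction must be in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if abs(sum(self.archetype_fractions) - 1.0) > 1e-9:
            raise ValueError("archetype fractions must sum to 1")
        if any(f < 0 or f > 1 for f in self.archetype_fractions):
            raise ValueError("archetype fractions must be in [0, 1]")
        if not 1 <= self.n_prenatal_stages < len(self.stages):
            raise ValueError("stage list must contain prenatal and postnatal stages")
        needed = (2 + len(self.extra_disease_ids) + 1) * self.community_size + (
            self.n_planted_modules * self.planted_module_size
        )
        if needed > self.n_genes:
            raise ValueError(
                f"infeasible sizes: communities and modules need {needed} genes, "
                f"only {self.n_genes} available"
            )

    @property
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def prenatal_stages(self) -> set[str]:
        return set(self.stages[: self.n_prenatal_stages])

    @property
    def postnatal_stages(self) -> tuple[str, ...]:
        return self.stages[self.n_prenatal_stages:]

    @property
    def regions(self) -> list[str]:
        return [f"R{i:02d}" for i in range(self.n_regions)]


@dataclass
class SyntheticTruth:
    """The planted ground truth that the emitted files realise."""

    genes: list[str] = field(default_factory=list)
    archetype: dict[str, int] = field(default_factory=dict)
    affiliation: dict[str, str] = field(default_factory=dict)
    modules: dict[str, list[str]] = field(default_factory=dict)
    seeds: dict[str, list[str]] = field(default_factory=dict)
    communities: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def archetype_active_coordinates(config: SyntheticConfig) -> dict[int, set[tuple[str, str]]]:
    """Active (region, stage) coordinates per archetype.

    Archetypes carry both a temporal and a regional signature so that all four
    are mutually distinguishable under correlation distance (a profile that is
    uniformly high everywhere has no correlation structure) and separate into
    distinct quadrants of the first two principal components:

    1. first half of regions, all stages;
    2. second half of regions, postnatal stages;
    3. all regions, 2nd and 4th postnatal stages (stage-peaked);
    4. all regions, prenatal stages.
    """
    regions = config.regions
    half = (config.n_regions + 1) // 2
    pre = list(config.stages[: config.n_prenatal_stages])
    post = list(config.postnatal_stages)
    peaks = [post[i] for i in (1, 3) if i < len(post)] or post[-1:]
    return {
        1: {(r, s) for r in regions[:half] for s in config.stages},
        2: {(r, s) for r in regions[half:] for s in post},
        3: {(r, s) for r in regions for s in peaks},
        4: {(r, s) for r in regions for s in pre},
    }


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------


def gen_ppi_network(config: SyntheticConfig) -> tuple[list[PPIEdge], SyntheticTruth]:
    """Preferential-attachment backbone with planted communities and modules.

    Disease communities (one per disease plus one shared community) are carved
    from low-degree backbone vertices and densified with Bernoulli edges; each
    disease's seed genes are drawn from its own community, except for a
    ``planted_overlap_fraction`` share drawn from the shared community, so the
    expected interactome overlap tracks the planted fraction.  Additional
    near-clique modules are planted for topological module detection.
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = config.gene_names
    G = nx.barabasi_albert_graph(
        config.n_genes, config.attachment_edges_per_node, seed=int(rng.integers(2**31))
    )
    degree = dict(G.degree())
    # low-degree pool: avoids planting communities on backbone hubs, which
    # would make even unrelated interactomes share members
    pool = sorted(G.nodes, key=lambda v: (degree[v], v))
    pool = [v for v in pool if degree[v] <= 3] + [v for v in pool if degree[v] > 3]

    cs = config.community_size
    diseases = list(config.disease_ids) + list(config.extra_disease_ids)
    blocks: dict[str, list[int]] = {"shared": pool[:cs]}
    for i, d in enumerate(diseases):
        blocks[d] = pool[(i + 1) * cs : (i + 2) * cs]
    offset = (len(diseases) + 1) * cs
    module_blocks = [
        pool[offset + i * config.planted_module_size : offset + (i + 1) * config.planted_module_size]
        for i in range(config.n_planted_modules)
    ]

    for block in list(blocks.values()):
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                if rng.random() < config.community_edge_prob:
                    G.add_edge(block[i], block[j])
    for block in module_blocks:
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                if rng.random() < config.planted_module_edge_prob:
                    G.add_edge(block[i], block[j])

    n_shared = round(config.planted_overlap_fraction * config.n_seeds_per_disease)
    truth = SyntheticTruth(genes=list(genes))
    for d in diseases:
        # only the two focal diseases share seeds; extra (control) diseases
        # draw entirely from their own community
        n_sh = n_shared if d in config.disease_ids else 0
        own = rng.choice(blocks[d], config.n_seeds_per_disease - n_sh, replace=False)
        sh = rng.choice(blocks["shared"], n_sh, replace=False) if n_sh else []
        truth.seeds[d] = sorted(genes[v] for v in list(own) + list(sh))

    pd_id, sz_id = config.disease_ids
    for v in G.nodes:
        truth.affiliation[genes[v]] = "background"
    for v in blocks[pd_id]:
        truth.affiliation[genes[v]] = "PD-unique"
    for v in blocks[sz_id]:
        truth.affiliation[genes[v]] = "SZ-unique"
    for v in blocks["shared"]:
        truth.affiliation[genes[v]] = "shared"
    truth.communities = {name: sorted(genes[v] for v in block) for name, block in blocks.items()}
    truth.modules = {
        f"PM{i + 1}": sorted(genes[v] for v in block) for i, block in enumerate(module_blocks)
    }

    mi_codes = rng.choice(["MI:0407", "MI:0915"], size=G.number_of_edges())
    confidences = np.round(rng.uniform(0.4, 1.0, size=G.number_of_edges()), 3)
    edges = [
        PPIEdge(genes[min(u, v)], genes[max(u, v)], str(mi), "SYNTH", float(c))
        for (u, v), mi, c in zip(sorted(map(lambda e: tuple(sorted(e)), G.edges())), mi_codes, confidences)
    ]
    return edges, truth


# ---------------------------------------------------------------------------
# GDA table
# ---------------------------------------------------------------------------


def gen_gda_table(config: SyntheticConfig, truth: SyntheticTruth) -> list[GDARecord]:
    """Association scores under which top-k selection recovers the seeds.

    Planted seeds occupy the top-k scores of their disease.  The two
    lexicographically smallest seeds and one larger-named decoy share the
    lowest seed score, so the tie at the cut is decided by the ascending-symbol
    rule — in the planted seeds' favour, keeping recovery exact.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    records: list[GDARecord] = []
    for d, seeds in truth.seeds.items():
        k = len(seeds)
        ordered = sorted(seeds)
        tied = ordered[:2] if k >= 2 else ordered
        rest = [g for g in seeds if g not in tied]
        tie_score = 0.70
        decoy_pool = [g for g in config.gene_names if g not in set(seeds) and g > max(tied)]
        scores = np.linspace(0.95, 0.72, num=len(rest)) if rest else []
        for g, s in zip(rest, scores):
            records.append(GDARecord(g, d, float(round(s, 6))))
        for g in tied:
            records.append(GDARecord(g, d, tie_score))
        if decoy_pool:
            records.append(GDARecord(decoy_pool[-1], d, tie_score))
        background = [
            g for g in config.gene_names
            if g not in set(seeds) and (not decoy_pool or g != decoy_pool[-1])
        ]
        n_bg = min(3 * k, len(background))
        bg = rng.choice(background, n_bg, replace=False)
        for g, s in zip(bg, rng.uniform(0.05, 0.65, size=n_bg)):
            records.append(GDARecord(str(g), d, float(round(s, 6))))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _assign_archetypes(
    config: SyntheticConfig, truth: SyntheticTruth | None, rng: np.random.Generator
) -> tuple[list[str], dict[str, int], dict[str, str]]:
    fr = np.asarray(config.archetype_fractions)
    if truth is None or not truth.affiliation:
        genes = config.gene_names
        arch = {g: int(a) for g, a in zip(genes, rng.choice([1, 2, 3, 4], size=len(genes), p=fr))}
        affil = {}
        for g in genes:
            if rng.random() < config.archetype_purity:
                affil[g] = ARCHETYPE_AFFILIATION[arch[g]]
            else:
                affil[g] = str(rng.choice(AFFILIATIONS))
        return genes, arch, affil
    genes = list(truth.genes) if truth.genes else config.gene_names
    sz_split = fr[0] / (fr[0] + fr[1])  # archetype 1 share among SZ-unique genes
    arch: dict[str, int] = {}
    for g in genes:
        a = truth.affiliation.get(g, "background")
        if a == "background" or rng.random() > config.archetype_purity:
            arch[g] = int(rng.choice([1, 2, 3, 4], p=fr))
        elif a == "SZ-unique":
            arch[g] = 1 if rng.random() < sz_split else 2
        elif a == "PD-unique":
            arch[g] = 3
        else:
            arch[g] = 4
    return genes, arch, dict(truth.affiliation)


def gen_expression(
    config: SyntheticConfig, truth: SyntheticTruth | None = None
) -> tuple[list[ExpressionRecord], SyntheticTruth]:
    """Long-format expression records realising the planted archetypes.

    With a network truth, archetypes are drawn conditional on each gene's
    planted disease affiliation (coupling purity ``archetype_purity``);
    standalone (``truth=None``), archetypes follow the configured fractions
    and affiliations are implied from them with the same purity.  Per
    (gene, coordinate, replicate): RPKM = 10^(mu + N(0, noise_sd)) with mu the
    archetype mean (2.5 active / 0.5 inactive), zeroed with probability
    ``dropout_rate``.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    genes, arch, affil = _assign_archetypes(config, truth, rng)
    actives = archetype_active_coordinates(config)
    coords = [(r, s) for r in config.regions for s in config.stages]
    mu_by_arch = {
        a: np.array([2.5 if c in actives[a] else 0.5 for c in coords]) for a in (1, 2, 3, 4)
    }
    n_coords, n_rep = len(coords), config.n_replicates
    records: list[ExpressionRecord] = []
    for g in genes:
        mu = mu_by_arch[arch[g]]
        logv = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n_coords, n_rep))
        rpkm = 10.0 ** logv
        drop = rng.random(size=(n_coords, n_rep)) < config.dropout_rate
        rpkm[drop] = 0.0
        for ci, (r, s) in enumerate(coords):
            for rep in range(n_rep):
                records.append(ExpressionRecord(g, r, s, float(rpkm[ci, rep])))
    out = truth if truth is not None else SyntheticTruth(genes=list(genes))
    out.archetype = arch
    out.affiliation = affil
    if not out.genes:
        out.genes = list(genes)
    return records, out


# ---------------------------------------------------------------------------
# Gene sets and brain reference
# ---------------------------------------------------------------------------


def gen_gene_sets(config: SyntheticConfig, truth: SyntheticTruth) -> GeneSetCollection:
    """Marker sets aligned with the planted truth, plus size-matched decoys.

    One set per planted module (its genes), one per archetype (its genes, when
    archetypes have been assigned), and for each such set a decoy of identical
    size drawn at random from all genes.
    """
    rng = np.random.default_rng(config.rng_seed + 3)
    genes = truth.genes or config.gene_names
    coll = GeneSetCollection(name="synthetic_sets")
    real: list[tuple[str, list[str]]] = []
    for mid, members in truth.modules.items():
        real.append((f"{mid}_COMPLEX", sorted(members)))
    if truth.archetype:
        for a in (1, 2, 3, 4):
            members = sorted(g for g, aa in truth.archetype.items() if aa == a)
            if members:
                real.append((f"ARCHETYPE{a}_MARKERS", members))
    for name, members in real:
        coll.sets[name] = members
        coll.descriptions[name] = "planted"
        decoy = sorted(str(g) for g in rng.choice(genes, size=len(members), replace=False))
        coll.sets[f"DECOY_{name}"] = decoy
        coll.descriptions[f"DECOY_{name}"] = "size-matched random decoy"
    return coll


def gen_brain_reference(config: SyntheticConfig, truth: SyntheticTruth | None = None) -> dict[str, float]:
    """Gene -> nTPM reference; a configured fraction exceeds 1 nTPM."""
    rng = np.random.default_rng(config.rng_seed + 4)
    genes = (truth.genes if truth and truth.genes else config.gene_names)
    expressed = rng.random(len(genes)) < config.brain_expressed_fraction
    ntpm = np.where(expressed, rng.uniform(1.5, 60.0, len(genes)), rng.uniform(0.0, 1.0, len(genes)))
    return {g: float(round(v, 4)) for g, v in zip(genes, ntpm)}


# ---------------------------------------------------------------------------
# Enrichment-profile blocks
# ---------------------------------------------------------------------------


def gen_two_block_profiles(
    rng_seed: int,
    n_rows: int = 20,
    entities_per_block: int = 2,
    high: float = 6.0,
    low: float = 1.0,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """A two-block enrichment-profile matrix (rows: gene sets, cols: entities).

    Entities of block 0 are enriched (-log10 p = ``high``) on the first half
    of the rows and at ``low`` elsewhere; block 1 entities mirror this.
    Optional Gaussian noise is added on the -log10 p scale (clipped at 0).
    Returns the profile matrix and the planted column -> block map.
    """
    rng = np.random.default_rng(rng_seed)
    cols = [f"E{i + 1}" for i in range(2 * entities_per_block)]
    blocks = {c: (0 if i < entities_per_block else 1) for i, c in enumerate(cols)}
    half = n_rows // 2
    mat = np.full((n_rows, len(cols)), low, dtype=float)
    for j, c in enumerate(cols):
        rows = slice(0, half) if blocks[c] == 0 else slice(half, n_rows)
        mat[rows, j] = high
    if noise_sd > 0:
        mat = np.clip(mat + rng.normal(0.0, noise_sd, mat.shape), 0.0, None)
    index = [f"GS{i + 1:02d}" for i in range(n_rows)]
    return pd.DataFrame(mat, index=index, columns=cols), blocks


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------


def write_bundle(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit the complete synthetic input bundle plus the truth JSON.

    Files: ``ppi.tsv``, ``gda.tsv``, ``expression.csv``, ``gene_sets.gmt``,
    ``brain_reference.tsv`` and ``truth.json``; all readable by the io layer
    with zero warnings and byte-identical under the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges, truth = gen_ppi_network(config)
    records, truth = gen_expression(config, truth)
    gda = gen_gda_table(config, truth)
    sets = gen_gene_sets(config, truth)
    reference = gen_brain_reference(config, truth)

    paths = {name: outdir / fname for name, fname in [
        ("ppi", "ppi.tsv"), ("gda", "gda.tsv"), ("expression", "expression.csv"),
        ("gene_sets", "gene_sets.gmt"), ("reference", "brain_reference.tsv"),
        ("truth", "truth.json"),
    ]}
    pd.DataFrame(
        [(e.gene_a, e.gene_b, e.mi_code, e.source_db, e.confidence) for e in edges],
        columns=["gene_a", "gene_b", "mi_code", "source_db", "confidence"],
    ).to_csv(paths["ppi"], sep="\t", index=False, float_format="%.12g")
    pd.DataFrame(
        [(r.gene, r.disease_id, r.gda_score) for r in gda],
        columns=["gene", "disease_id", "gda_score"],
    ).to_csv(paths["gda"], sep="\t", index=False, float_format="%.12g")
    write_expression_long(records, paths["expression"])
    write_gmt(sets, paths["gene_sets"])
    pd.DataFrame(sorted(reference.items()), columns=["gene", "ntpm"]).to_csv(
        paths["reference"], sep="\t", index=False, float_format="%.12g"
    )
    truth.to_json(paths["truth"])
    return paths
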