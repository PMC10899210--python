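"""End-to-end orchestration: from input tables to DGNs, profiles and modules.

``run_all`` executes the full analysis — interactome construction, overlap
validation, expression-matrix assembly, temporal clustering, DGN assignment,
PCA/quadrants, over-representation profiles with co-clustering, and
topological module detection — from a single declarative config, writing each
stage's outputs as TSV under one run directory together with a JSON manifest
(parameters and input hashes).  Stages communicate only through those files
and the run is bit-identical when repeated with the same config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats, mcode
from .enrichment_profiles import (
    build_profile_matrix,
    cluster_profiles,
    hypergeom_ora,
    inverse_normal_z,
    results_to_frame,
)
from .expression import assemble_matrix, build_region_gene_sets, filter_brain_expressed
from .interactome import (
    GeneUniverse,
    build_interactome,
    cross_disorder_validation,
    select_top_seeds,
)
from .pca_quadrants import assign_quadrants, scale_unit_variance, svd_impute
from .temporal_clustering import assign_dgn, cut_tree, pearson_distance, upgma_cluster

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_all"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    gda_path: str
    ppi_paths: list[str]
    expression_path: str
    outdir: str
    disease_ids: list[str] = field(default_factory=list)
    disease_labels: dict[str, str] = field(default_factory=dict)
    gene_sets_path: str | None = None
    reference_path: str | None = None
    # interactome stage
    k_seeds: int = 100
    mi_filter: list[str] | None = None
    min_confidence: float | None = None
    # expression stage
    stage_order: list[str] = field(default_factory=list)
    prenatal_stages: list[str] = field(default_factory=list)
    ntpm_threshold: float = 1.0
    region_set_threshold: float = 2.0
    # clustering stage
    k_primary: int = 2
    k_sub: int = 5
    # PCA stage
    pca_components: int = 2
    pca_coordinates: list[str] | None = None  # "region|stage" subset, optional
    # profiles
    ora_universe_mode: str = "collection"  # or "ppi"
    profile_z_mode: str = "per_column"
    # module detection
    mcode_vwp: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    rng_seed: int = 0

    def label(self, disease_id: str) -> str:
        return self.disease_labels.get(disease_id, disease_id)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems (empty when the config is runnable)."""
    problems: list[str] = []
    for name, p in [("gda_path", config.gda_path), ("expression_path", config.expression_path)]:
        if not Path(p).is_file():
            problems.append(f"{name}: file not found: {p}")
    if not config.ppi_paths:
        problems.append("ppi_paths: at least one PPI table is required")
    for p in config.ppi_paths:
        if not Path(p).is_file():
            problems.append(f"ppi_paths: file not found: {p}")
    for name, p in [("gene_sets_path", config.gene_sets_path), ("reference_path", config.reference_path)]:
        if p is not None and not Path(p).is_file():
            problems.append(f"{name}: file not found: {p}")
    if len(config.disease_ids) < 2:
        problems.append("disease_ids: need at least two diseases")
    if config.k_seeds < 0:
        problems.append(f"k_seeds: must be >= 0, got {config.k_seeds}")
    if not config.stage_order:
        problems.append("stage_order: the ordered stage vocabulary must be supplied")
    if not 1 <= config.k_primary <= config.k_sub:
        problems.append(f"k_primary/k_sub: need 1 <= {config.k_primary} <= {config.k_sub}")
    if config.pca_components < 2:
        problems.append("pca_components: quadrant analysis needs >= 2 components")
    if not 0.0 <= config.mcode_vwp <= 1.0:
        problems.append(f"mcode_vwp: must be in [0, 1], got {config.mcode_vwp}")
    if config.ora_universe_mode not in ("collection", "ppi"):
        problems.append(f"ora_universe_mode: unknown mode {config.ora_universe_mode!r}")
    if config.profile_z_mode not in ("per_column", "per_row", "global"):
        problems.append(f"profile_z_mode: unknown mode {config.profile_z_mode!r}")
    if config.min_confidence is not None and not 0.0 <= config.min_confidence <= 1.0:
        problems.append(f"min_confidence: must be in [0, 1], got {config.min_confidence}")
    return problems


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("=== stage %s ===", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Partial outputs of completed stages are preserved if a later stage fails.
    """
    problems = validate_config(config)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    @_stage("read_inputs")
    def read_inputs():
        gda = io_formats.read_gda_table(config.gda_path)
        mi = set(config.mi_filter) if config.mi_filter else None
        seen = set()
        edges = []
        for p in config.ppi_paths:
            for e in io_formats.read_ppi_table(p, mi_filter=mi, min_confidence=config.min_confidence):
                if e.key not in seen:
                    seen.add(e.key)
                    edges.append(e)
        records = io_formats.read_expression_long(config.expression_path)
        sets = io_formats.read_gmt(config.gene_sets_path) if config.gene_sets_path else None
        reference = None
        if config.reference_path:
            ref = pd.read_csv(config.reference_path, sep="\t")
            reference = dict(zip(ref["gene"].astype(str), ref["ntpm"].astype(float)))
        return gda, edges, records, sets, reference

    gda, edges, records, gene_sets, reference = read_inputs()
    universe = GeneUniverse.from_edges(edges)

    # --- interactomes and overlap ----------------------------------------
    @_stage("interactomes")
    def interactomes():
        inters = []
        for d in config.disease_ids:
            seeds = select_top_seeds(gda, d, config.k_seeds)
            inters.append(build_interactome(seeds, edges))
        table = cross_disorder_validation(inters, universe)
        io_formats.write_results(table, outdir / "overlap.tsv")
        return inters

    inters = interactomes()
    a, b = inters[0], inters[1]
    affiliations = {
        f"{config.label(a.disease_id)}-unique": a.members - b.members,
        f"{config.label(b.disease_id)}-unique": b.members - a.members,
        "shared": a.members & b.members,
    }

    # --- expression matrix ------------------------------------------------
    @_stage("expression_matrix")
    def expression_matrix():
        members = a.members | b.members
        matrix = assemble_matrix(
            records, config.stage_order, gene_filter=members,
            prenatal_stages=set(config.prenatal_stages),
        )
        if reference is not None:
            matrix = filter_brain_expressed(matrix, reference, config.ntpm_threshold)
        io_formats.write_matrix_tsv(matrix.values, outdir / "matrix.tsv")
        return matrix

    matrix = expression_matrix()

    # --- temporal clustering ----------------------------------------------
    @_stage("temporal_clustering")
    def temporal_clustering():
        dist = pearson_distance(matrix)
        dend = upgma_cluster(dist)
        merge = pd.DataFrame(dend.merges, columns=["left", "right", "height", "size"])
        io_formats.write_results(merge, outdir / "merge_tree.tsv")
        primary = cut_tree(dend, config.k_primary, matrix)
        sub = cut_tree(dend, config.k_sub, matrix)
        rows = [
            {"gene": g, "primary": p.id, "subcluster": s.id}
            for p in primary for g in sorted(p.genes)
            for s in sub if g in s.genes
        ]
        io_formats.write_results(pd.DataFrame(rows), outdir / "clusters.tsv")
        return sub

    subclusters = temporal_clustering()

    # --- PCA and quadrants --------------------------------------------------
    @_stage("pca_quadrants")
    def pca_stage():
        values = matrix.values
        if config.pca_coordinates:
            want = [tuple(c.split("|", 1)) for c in config.pca_coordinates]
            values = values[[c for c in values.columns if c in want]]
        scaled = scale_unit_variance(values)
        pca = svd_impute(scaled, n_components=config.pca_components)
        io_formats.write_results(
            pca.scores.reset_index().rename(columns={"index": "gene"}),
            outdir / "pca_scores.tsv",
        )
        quads = assign_quadrants(pca)
        io_formats.write_results(
            pd.DataFrame(sorted(quads.assignments.items()), columns=["gene", "quadrant"]),
            outdir / "quadrants.tsv",
        )
        return pca, quads

    pca, quads = pca_stage()

    # --- DGN assignment -----------------------------------------------------
    @_stage("assign_dgn")
    def dgn_stage():
        dgns = assign_dgn(subclusters, affiliations, universe, pca_quadrants=quads)
        rows = [
            {
                "dgn_id": d.dgn_id,
                "subclusters": "+".join(d.subcluster_ids),
                "affiliation": d.affiliation,
                "n_genes": len(d.genes),
                "dominant_quadrant": d.dominant_quadrant,
                "min_adjusted_p": min(e.adjusted_p for e in d.enrichment),
            }
            for d in dgns
        ]
        io_formats.write_results(pd.DataFrame(rows), outdir / "dgn.tsv")
        return dgns

    dgns = dgn_stage()

    # --- enrichment profiles ------------------------------------------------
    @_stage("enrichment_profiles")
    def profiles_stage():
        region_sets = build_region_gene_sets(matrix, config.region_set_threshold)
        collections = [region_sets] + ([gene_sets] if gene_sets else [])
        all_results = []
        by_entity: dict[str, list] = {}
        for d in dgns:
            if config.ora_universe_mode == "ppi":
                uni = universe.genes
            else:
                uni = region_sets.all_genes() | (gene_sets.all_genes() if gene_sets else set())
            query = d.genes & uni
            if not query:
                continue
            ent_results = []
            for coll in collections:
                res = hypergeom_ora(query, coll, uni, query_id=d.dgn_id)
                ent_results.extend(res)
            by_entity[d.dgn_id] = [r for r in ent_results if r.set_id in region_sets.sets]
            all_results.extend(ent_results)
        io_formats.write_results(results_to_frame(all_results), outdir / "enrichment.tsv")
        if len(by_entity) >= 2 and all(len(v) >= 3 for v in by_entity.values()):
            profile = build_profile_matrix(by_entity)
            z = inverse_normal_z(profile, mode=config.profile_z_mode)
            io_formats.write_results(profile.reset_index(names="set_id"), outdir / "profile.tsv")
            io_formats.write_results(z.reset_index(names="set_id"), outdir / "profile_z.tsv")
            _, _, groups = cluster_profiles(z)
            io_formats.write_results(
                pd.DataFrame(sorted(groups.items()), columns=["entity", "group"]),
                outdir / "profile_groups.tsv",
            )

    profiles_stage()

    # --- topological modules -------------------------------------------------
    @_stage("mcode_modules")
    def modules_stage():
        members = a.members | b.members
        joint = [e for e in edges if e.gene_a in members and e.gene_b in members]
        graph = mcode.graph_from_edges(joint)
        modules = mcode.find_modules(
            graph, vwp=config.mcode_vwp, haircut=config.mcode_haircut, fluff=config.mcode_fluff
        )
        if modules and gene_sets:
            mcode.annotate_modules(modules, gene_sets, gene_sets.all_genes() | members)
        rows = [
            {"module_id": m.module_id, "gene": g, "score": m.score}
            for m in modules for g in sorted(m.genes)
        ]
        io_formats.write_results(
            pd.DataFrame(rows, columns=["module_id", "gene", "score"]),
            outdir / "modules.tsv",
        )
        return modules

    modules_stage()

    io_formats.write_manifest(
        outdir / "manifest.json",
        parameters=dataclasses.asdict(config),
        input_paths={
            "gda": config.gda_path,
            "expression": config.expression_path,
            **{f"ppi_{i}": p for i, p in enumerate(config.ppi_paths)},
            **({"gene_sets": config.gene_sets_path} if config.gene_sets_path else {}),
            **({"reference": config.reference_path} if config.reference_path else {}),
        },
    )
    return outdir
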