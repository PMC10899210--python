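"""Readers and writers for the external table formats used by the pipeline.

Everything here is plumbing: tab-delimited protein-protein interaction (PPI)
tables, GMT gene-set collections, long-format expression tables, result TSVs
and JSON run manifests.  No science logic lives in this module.

Gene identifiers are treated as case-sensitive symbols in a single namespace;
no alias mapping is performed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "GDARecord",
    "PPIEdge",
    "ExpressionRecord",
    "GeneSetCollection",
    "read_gda_table",
    "read_ppi_table",
    "read_gmt",
    "write_gmt",
    "read_expression_long",
    "write_expression_long",
    "write_results",
    "read_results",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_manifest",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """A well-formed file carries values that violate an invariant."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GDARecord:
    """One gene-disease association with its strength score in [0, 1]."""

    gene: str
    disease_id: str
    gda_score: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty")
        if not math.isfinite(self.gda_score):
            raise ValidationError(f"non-finite GDA score for {self.gene}")


@dataclass(frozen=True)
class PPIEdge:
    """An undirected interaction between two gene symbols.

    ``mi_code`` is the PSI-MI interaction type (e.g. MI:0407 direct
    interaction, MI:0915 physical association); ``confidence`` is an optional
    score in [0, 1] used by confidence-filtered database variants.
    """

    gene_a: str
    gene_b: str
    mi_code: str = ""
    source_db: str = ""
    confidence: float | None = None

    @property
    def key(self) -> frozenset[str]:
        """Undirected identity: (a, b) == (b, a)."""
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class ExpressionRecord:
    """One expression measurement (a replicate) at a spatiotemporal point."""

    gene: str
    region: str
    stage: str
    rpkm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.rpkm) or self.rpkm < 0:
            raise ValidationError(
                f"RPKM must be finite and >= 0; got {self.rpkm!r} for "
                f"{self.gene}/{self.region}/{self.stage}"
            )


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (GMT container)."""

    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    universe_hint: list[str] | None = None

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Column resolution helpers
# ---------------------------------------------------------------------------

_PPI_COLUMNS = {
    "gene_a": ("gene_a", "interactor_a", "interactor a", "symbol_a", "official symbol interactor a"),
    "gene_b": ("gene_b", "interactor_b", "interactor b", "symbol_b", "official symbol interactor b"),
    "mi_code": ("mi_code", "interaction_type", "interaction type", "mi code"),
    "source_db": ("source_db", "source", "source database"),
    "confidence": ("confidence", "score", "confidence_score", "confidence value"),
}


def _resolve_column(df: pd.DataFrame, candidates: Sequence[str]) -> str | None:
    lowered = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_gda_table(path: str | Path) -> list[GDARecord]:
    """Read a gene-disease association table (TSV/CSV with a header).

    Requires columns ``gene``, ``disease_id`` and ``gda_score``.  The
    (gene, disease_id) pairs must be unique.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    for col in ("gene", "disease_id", "gda_score"):
        if col not in df.columns:
            raise FormatError(f"GDA table {path} is missing mandatory column {col!r}")
    dup = df.duplicated(subset=["gene", "disease_id"])
    if dup.any():
        raise ValidationError(
            f"GDA table {path} has {int(dup.sum())} duplicate (gene, disease_id) pairs"
        )
    return [
        GDARecord(str(r.gene), str(r.disease_id), float(r.gda_score))
        for r in df.itertuples(index=False)
    ]


def read_ppi_table(
    path: str | Path,
    mi_filter: set[str] | None = None,
    min_confidence: float | None = None,
) -> list[PPIEdge]:
    """Read a tab-delimited PPI edge table into deduplicated undirected edges.

    Parameters
    ----------
    mi_filter:
        If given, only edges whose PSI-MI interaction-type code is in this set
        are retained.  If ``None``, every code (including unknown ones) is kept.
    min_confidence:
        If given, only edges with ``confidence >= min_confidence`` are
        retained (inclusive threshold, matching the convention of a named
        "medium confidence" cutoff value).  Rows without a confidence value
        fail the filter.

    Self-loops are dropped and duplicate undirected pairs collapse to a single
    edge (first occurrence wins).  Counts of dropped rows are logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {k: _resolve_column(df, v) for k, v in _PPI_COLUMNS.items()}
    for mandatory in ("gene_a", "gene_b"):
        if cols[mandatory] is None:
            raise FormatError(
                f"PPI table {path} is missing mandatory interactor column {mandatory!r}"
            )

    edges: list[PPIEdge] = []
    seen: set[frozenset[str]] = set()
    n_self = n_dup = n_mi = n_conf = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        a = str(rec[cols["gene_a"]])
        b = str(rec[cols["gene_b"]])
        mi = str(rec[cols["mi_code"]]) if cols["mi_code"] else ""
        src = str(rec[cols["source_db"]]) if cols["source_db"] else ""
        conf: float | None = None
        if cols["confidence"]:
            raw = rec[cols["confidence"]]
            if raw is not None and not pd.isna(raw) and str(raw).strip() not in ("", "-"):
                try:
                    conf = float(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"unparsable confidence score {raw!r} at line {i} of {path}"
                    ) from exc
        if a == b:
            n_self += 1
            continue
        if mi_filter is not None and mi not in mi_filter:
            n_mi += 1
            continue
        if min_confidence is not None and (conf is None or conf < min_confidence):
            n_conf += 1
            continue
        key = frozenset((a, b))
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append(PPIEdge(a, b, mi, src, conf))

    logger.info(
        "read_ppi_table(%s): %d edges kept; dropped %d self-loops, %d duplicates, "
        "%d by MI filter, %d by confidence filter",
        path, len(edges), n_self, n_dup, n_mi, n_conf,
    )
    return edges


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (set id, description, members; tab-separated).

    Duplicate members within a set are collapsed (first occurrence order is
    preserved); a line with fewer than 3 fields is a format error, and a line
    whose members collapse to nothing is rejected.
    """
    coll = GeneSetCollection(name=Path(path).stem)
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} of {path} has fewer than 3 fields")
            set_id, desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if not uniq:
                raise FormatError(f"GMT set {set_id!r} at line {lineno} of {path} is empty")
            if set_id in coll.sets:
                raise FormatError(f"duplicate GMT set id {set_id!r} at line {lineno} of {path}")
            coll.sets[set_id] = uniq
            coll.descriptions[set_id] = desc
    if n_lines == 0:
        logger.warning("read_gmt(%s): empty file, returning empty collection", path)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, members in coll.sets.items():
            desc = coll.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def read_expression_long(path: str | Path) -> list[ExpressionRecord]:
    """Read long-format expression (gene, region, stage, rpkm) from CSV/TSV.

    Repeated (gene, region, stage) rows are replicates and are preserved.
    Negative RPKM values raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    for col in ("gene", "region", "stage", "rpkm"):
        if col not in df.columns:
            raise FormatError(f"expression table {path} is missing column {col!r}")
    return [
        ExpressionRecord(str(r.gene), str(r.region), str(r.stage), float(r.rpkm))
        for r in df.itertuples(index=False)
    ]


def write_expression_long(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene, r.region, r.stage, r.rpkm) for r in records],
        columns=["gene", "region", "stage", "rpkm"],
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Result tables, matrices, manifests
# ---------------------------------------------------------------------------


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a fixed column order.

    Reals are serialized at 12 significant digits so that
    ``read_results(write_results(x)) == x`` round-trips for result tables.
    """
    results.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix_tsv(values: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x coordinates matrix; coordinate header is ``region|stage``."""
    out = values.copy()
    if isinstance(out.columns, pd.MultiIndex):
        out.columns = [f"{r}|{s}" for r, s in out.columns]
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split("|", 1)) for c in df.columns], names=["region", "stage"]
        )
    except ValueError as exc:
        raise FormatError(f"matrix {path} header is not in region|stage form") from exc
    return df


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    parameters: Mapping[str, object],
    input_paths: Mapping[str, str | Path] | None = None,
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Write a JSON run manifest recording parameters and input file hashes."""
    manifest: dict[str, object] = {"parameters": dict(parameters)}
    if input_paths:
        manifest["inputs"] = {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in input_paths.items()
        }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
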