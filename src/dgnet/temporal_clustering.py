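"""Correlation-distance UPGMA clustering of expression profiles and DGN labels.

Genes are clustered by the similarity of their spatiotemporal expression
profiles: the distance between two genes is 1 - r, with r the Pearson
correlation over their pairwise-complete coordinates.  The tree is built with
average linkage (UPGMA), cut into a requested number of clusters, and each
sub-cluster is labelled by the disease affiliation (unique to one interactome
or shared) for which it is significantly enriched — yielding Disease Gene
Networks (DGNs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment_profiles import EnrichmentResult, bh_adjust, hypergeom_tail
from .expression import ExpressionMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .interactome import GeneUniverse
    from .pca_quadrants import QuadrantAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "GeneCluster",
    "DGNAssignment",
    "pearson_distance",
    "upgma_cluster",
    "cut_tree",
    "assign_dgn",
]

_VAR_EPS = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    items: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.items)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match item count")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")


@dataclass
class Dendrogram:
    """An agglomerative merge tree in scipy linkage form.

    ``merges`` is the (n-1) x 4 linkage matrix (left, right, height, size);
    UPGMA guarantees the heights are non-decreasing (ultrametric tree).
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]


@dataclass
class GeneCluster:
    """A flat cluster of genes cut from the dendrogram."""

    id: str
    genes: set[str]
    temporal_profile_summary: np.ndarray | None = None


@dataclass
class DGNAssignment:
    """A disease gene network: sub-cluster(s) with a disease-affiliation label."""

    dgn_id: str
    subcluster_ids: list[str]
    affiliation: str
    genes: set[str]
    dominant_quadrant: str | None = None
    enrichment: list[EnrichmentResult] = field(default_factory=list)


def _as_frame(matrix: "ExpressionMatrix | pd.DataFrame") -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


def pearson_distance(
    matrix: "ExpressionMatrix | pd.DataFrame", axis: str = "genes"
) -> DistanceMatrix:
    """Pairwise 1 - Pearson distances over pairwise-complete coordinates.

    ``axis="genes"`` compares rows; ``axis="coordinates"`` compares columns.
    Every pair must share at least 2 non-missing positions, and no profile may
    have zero variance over the shared positions of any pair.
    """
    df = _as_frame(matrix)
    if axis == "coordinates":
        df = df.T
    elif axis != "genes":
        raise ValueError(f"axis must be 'genes' or 'coordinates', got {axis!r}")
    items = [str(i) if not isinstance(i, str) else i for i in df.index]
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two profiles to compute distances")
    M = np.isfinite(X)
    A = np.where(M, X, 0.0)
    Mf = M.astype(float)
    n = Mf @ Mf.T
    if np.any(n < 2):
        i, j = np.argwhere(n < 2)[0]
        raise ValueError(
            f"profiles {items[i]!r} and {items[j]!r} share fewer than 2 observed positions"
        )
    Sx = A @ Mf.T
    Sy = Mf @ A.T
    Sxy = A @ A.T
    Sxx = (A * A) @ Mf.T
    Syy = Mf @ (A * A).T
    cov = Sxy - Sx * Sy / n
    varx = Sxx - Sx**2 / n
    vary = Syy - Sy**2 / n
    scale = max(float(np.nanmax(np.abs(X))) ** 2, 1.0)
    degenerate = (varx <= _VAR_EPS * scale) | (vary <= _VAR_EPS * scale)
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        i, j = np.argwhere(degenerate)[0]
        raise ValueError(
            f"zero-variance profile over shared positions for pair "
            f"({items[i]!r}, {items[j]!r}); correlation distance undefined"
        )
    with np.errstate(invalid="ignore"):
        r = cov / np.sqrt(varx * vary)
    r = np.clip(r, -1.0, 1.0)
    d = 1.0 - r
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(items, d)


def upgma_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At each step the pair of clusters with the smallest mean cross-pair
    distance is merged at that height.  The resulting heights are checked to
    be non-decreasing (the UPGMA ultrametric property).
    """
    if len(dist.items) < 2:
        raise ValueError("need at least 2 items to cluster")
    condensed = squareform(dist.d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    heights = Z[:, 2]
    if np.any(np.diff(heights) < -1e-10):
        raise AssertionError("UPGMA produced non-monotone merge heights")
    return Dendrogram(Z, list(dist.items))


def cut_tree(
    dend: Dendrogram,
    k: int,
    matrix: "ExpressionMatrix | pd.DataFrame | None" = None,
) -> list[GeneCluster]:
    """Cut the dendrogram into k flat clusters (the k-1 highest merges removed).

    Cluster ids ("A", "B", ...) are assigned in dendrogram leaf order.  When
    the clustered matrix is supplied, each cluster carries the mean profile of
    its genes (ignoring missing cells) as a temporal summary.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    flat = hierarchy.cut_tree(dend.merges, n_clusters=k).ravel()
    order = hierarchy.leaves_list(dend.merges)
    label_by_raw: dict[int, str] = {}
    for leaf in order:
        raw = int(flat[leaf])
        if raw not in label_by_raw:
            idx = len(label_by_raw)
            label_by_raw[raw] = chr(ord("A") + idx) if idx < 26 else f"C{idx + 1}"
    df = _as_frame(matrix) if matrix is not None else None
    clusters = []
    for raw, label in label_by_raw.items():
        genes = {dend.labels[i] for i in np.nonzero(flat == raw)[0]}
        profile = None
        if df is not None:
            rows = [g for g in genes if g in df.index]
            if rows:
                profile = np.nanmean(df.loc[rows].to_numpy(dtype=float), axis=0)
        clusters.append(GeneCluster(label, genes, profile))
    return clusters


def assign_dgn(
    subclusters: Sequence[GeneCluster],
    affiliation_sets: Mapping[str, "set[str]"],
    universe: "GeneUniverse",
    pca_quadrants: "QuadrantAssignment | None" = None,
    alpha: float = 0.05,
) -> list[DGNAssignment]:
    """Label sub-clusters by disease affiliation and merge them into DGNs.

    Every sub-cluster is tested against every affiliation set (hypergeometric
    upper tail, BH correction across all tests in the call); its label is the
    most significant affiliation at adjusted p < ``alpha``, or "unassigned".
    Sub-clusters sharing a label and — when a quadrant assignment is provided —
    the same dominant PCA quadrant are merged into a single DGN.  Without
    quadrant evidence no merging is performed.  DGNs are numbered DGN1, DGN2,
    ... in sub-cluster (dendrogram leaf) order.
    """
    names = list(affiliation_sets)
    sets = {a: set(affiliation_sets[a]) & universe.genes for a in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            common = sets[a] & sets[b]
            if common:
                raise ValueError(
                    f"affiliation sets {a!r} and {b!r} overlap ({len(common)} genes); "
                    "they must partition the interactome genes"
                )
    N = len(universe)
    tests: list[tuple[str, str, EnrichmentResult]] = []
    for sc in subclusters:
        q = sc.genes & universe.genes
        for a in names:
            K = len(sets[a])
            k = len(q & sets[a])
            p = hypergeom_tail(k, N, K, len(q)) if K and q else 1.0
            expected = K * len(q) / N
            fold = k / expected if expected > 0 else float("nan")
            tests.append(
                (sc.id, a, EnrichmentResult(sc.id, a, k, K, len(q), N, p, None, fold))
            )
    adj = bh_adjust([t[2].p_value for t in tests])
    for (_, _, res), a in zip(tests, adj):
        res.adjusted_p = float(a)

    label_of: dict[str, str] = {}
    evidence: dict[str, EnrichmentResult] = {}
    for sc in subclusters:
        mine = [t for t in tests if t[0] == sc.id]
        best = min(mine, key=lambda t: (t[2].adjusted_p, t[1]))
        if best[2].adjusted_p < alpha:
            label_of[sc.id] = best[1]
            evidence[sc.id] = best[2]
        else:
            label_of[sc.id] = "unassigned"
            evidence[sc.id] = best[2]
            logger.warning("assign_dgn: sub-cluster %s has no significant affiliation", sc.id)

    def dominant_quadrant(sc: GeneCluster) -> str | None:
        if pca_quadrants is None:
            return None
        quads = [pca_quadrants.assignments[g] for g in sc.genes if g in pca_quadrants.assignments]
        if not quads:
            return None
        counts = pd.Series(quads).value_counts()
        top = counts.max()
        return sorted(q for q, c in counts.items() if c == top)[0]

    # group sub-clusters into DGNs
    groups: list[dict] = []
    for sc in subclusters:
        label = label_of[sc.id]
        quad = dominant_quadrant(sc)
        merged = False
        if label != "unassigned" and pca_quadrants is not None:
            for g in groups:
                if g["affiliation"] == label and g["quadrant"] == quad:
                    g["subclusters"].append(sc)
                    merged = True
                    break
        if not merged:
            groups.append({"affiliation": label, "quadrant": quad, "subclusters": [sc]})

    out: list[DGNAssignment] = []
    n_dgn = 0
    for g in groups:
        ids = [sc.id for sc in g["subclusters"]]
        genes = set().union(*(sc.genes for sc in g["subclusters"]))
        if g["affiliation"] == "unassigned":
            dgn_id = f"unassigned_{'+'.join(ids)}"
        else:
            n_dgn += 1
            dgn_id = f"DGN{n_dgn}"
        out.append(
            DGNAssignment(
                dgn_id,
                ids,
                g["affiliation"],
                genes,
                g["quadrant"],
                [evidence[i] for i in ids],
            )
        )
    return out
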