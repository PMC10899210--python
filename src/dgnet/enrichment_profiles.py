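"""Over-representation analysis, FDR control, and enrichment-profile clustering.

The core statistic throughout the package is the one-sided hypergeometric
upper tail: for a query of size n and an annotated set of size K inside a
universe of N genes, the probability of observing at least the k genes found
in both, P(X >= k).  The tail is accumulated in log space so that extreme
enrichments (p ~ 1e-310, as arise when two disease interactomes share over a
thousand genes) do not underflow.

Profiles of -log10 p-values across many gene sets are the coordinates in
which entities (disease gene networks, external interactomes) are compared:
they are z-scored with a rank-based inverse normal transform and co-clustered
with correlation-distance UPGMA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtri
from scipy.stats import false_discovery_control, hypergeom, rankdata

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeom_tail",
    "log10_hypergeom_tail",
    "bh_adjust",
    "hypergeom_ora",
    "build_profile_matrix",
    "inverse_normal_z",
    "cluster_profiles",
]

#: floor applied to p-values before -log10 transformation, to keep profile
#: matrices finite even for enrichments at the limit of double precision.
P_FLOOR = 1e-300


@dataclass
class EnrichmentResult:
    """One hypergeometric over-representation test.

    k genes of an n-gene query fall in a K-gene set within an N-gene universe.
    ``fold_enrichment`` is k*N/(K*n), the ratio of observed to expected overlap.
    """

    query_id: str
    set_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    adjusted_p: float | None = None
    fold_enrichment: float = float("nan")

    @property
    def expected(self) -> float:
        return self.K * self.n / self.N if self.N else float("nan")


def log10_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """log10 of the upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed by log-space summation of exact log-pmf terms, which remains
    accurate far below the smallest normal double.
    """
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    kmax = min(K, n)
    if k > kmax:
        return -np.inf  # impossible overlap: empty tail
    kmin_support = max(0, K + n - N)
    if k <= kmin_support:
        return 0.0  # whole support: p = 1
    ks = np.arange(k, kmax + 1)
    logp = logsumexp(hypergeom.logpmf(ks, N, K, n))
    return float(min(logp, 0.0)) / np.log(10)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail p-value P(X >= k); may be subnormal but never exactly -inf."""
    return float(10.0 ** log10_hypergeom_tail(k, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Each raw p is multiplied by the number of tests and divided by its
    ascending rank, then monotonicity is enforced from the largest rank down
    and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must all lie in [0, 1]")
    return false_discovery_control(p, method="bh")


def hypergeom_ora(
    query: set[str],
    sets: GeneSetCollection,
    universe: "set[str] | Sequence[str]",
    query_id: str = "query",
) -> list[EnrichmentResult]:
    """Test a query gene set against every set of a collection.

    The query and each set are intersected with the universe first; BH
    adjustment is applied across the collection (one family per call).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    if not q:
        raise ValueError("query is empty after intersection with the universe")
    N, n = len(uni), len(q)
    results: list[EnrichmentResult] = []
    for set_id, members in sets.sets.items():
        s = set(members) & uni
        K = len(s)
        k = len(q & s)
        p = hypergeom_tail(k, N, K, n) if K else 1.0
        expected = K * n / N
        fold = (k / expected) if expected > 0 else float("nan")
        results.append(EnrichmentResult(query_id, set_id, k, K, n, N, p, None, fold))
    adj = bh_adjust([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results into a tidy table."""
    return pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "set_id": r.set_id,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "fold_enrichment": r.fold_enrichment,
            }
            for r in results
        ]
    )


def build_profile_matrix(
    results_by_entity: Mapping[str, Sequence[EnrichmentResult]],
    use_adjusted: bool = False,
    p_floor: float = P_FLOOR,
) -> pd.DataFrame:
    """Assemble -log10 p-values into a gene-sets x entities profile matrix.

    Raw p-values are used by default (``use_adjusted`` switches to BH-adjusted
    ones); p is floored at ``p_floor`` to avoid infinities.  A test missing for
    some (set, entity) cell becomes 0 with a log note; a duplicate cell is an
    error.
    """
    cells: dict[tuple[str, str], float] = {}
    rows: list[str] = []
    cols: list[str] = []
    for entity, results in results_by_entity.items():
        if entity not in cols:
            cols.append(entity)
        for r in results:
            key = (r.set_id, entity)
            if key in cells:
                raise ValueError(f"duplicate profile cell for set={r.set_id!r}, entity={entity!r}")
            p = r.adjusted_p if use_adjusted else r.p_value
            if p is None:
                raise ValueError(f"missing {'adjusted' if use_adjusted else 'raw'} p for {key}")
            cells[key] = -np.log10(max(float(p), p_floor))
            if r.set_id not in rows:
                rows.append(r.set_id)
    mat = pd.DataFrame(0.0, index=rows, columns=cols)
    n_missing = mat.size - len(cells)
    if n_missing:
        logger.info("build_profile_matrix: %d missing tests filled with 0", n_missing)
    for (set_id, entity), v in cells.items():
        mat.loc[set_id, entity] = v
    return mat


def inverse_normal_z(matrix: pd.DataFrame, mode: str = "per_column") -> pd.DataFrame:
    """Rank-based inverse normal transform of a profile matrix.

    Each vector (column, row, or the flattened matrix, per ``mode``) is mapped
    through z = ndtri((r - 3/8) / (m + 1/4)) with r the ascending rank (ties
    get the average rank).  An all-equal vector maps to zeros with a warning.
    """
    if mode not in ("per_column", "per_row", "global"):
        raise ValueError(f"unknown mode {mode!r}")

    def transform(v: np.ndarray) -> np.ndarray:
        m = v.size
        if m < 3:
            raise ValueError("inverse normal transform needs at least 3 values per vector")
        if np.all(v == v.flat[0]):
            logger.warning("inverse_normal_z: all-equal vector mapped to zeros")
            return np.zeros_like(v, dtype=float)
        r = rankdata(v, method="average").reshape(v.shape)
        return ndtri((r - 0.375) / (m + 0.25))

    z = matrix.astype(float).copy()
    if mode == "global":
        z.loc[:, :] = transform(z.to_numpy())
    elif mode == "per_column":
        for c in z.columns:
            z[c] = transform(z[c].to_numpy())
    else:
        for i in z.index:
            z.loc[i] = transform(z.loc[i].to_numpy())
    return z


def cluster_profiles(z: pd.DataFrame, n_column_groups: int = 2):
    """Co-cluster an enrichment z-score matrix by rows and by columns.

    Uses Pearson-correlation distance with UPGMA on both axes and reports the
    flat column grouping at the requested cut (default 2 groups, the split of
    entities into two families).

    Returns ``(row_dendrogram, column_dendrogram, column_groups)`` where
    ``column_groups`` maps each column label to a group index.
    """
    # local import: the tree primitives live in the clustering module, which
    # itself uses this module's statistics
    from .temporal_clustering import pearson_distance, upgma_cluster, cut_tree

    if not np.isfinite(z.to_numpy(dtype=float)).all():
        raise ValueError("z matrix must be finite")
    row_d = pearson_distance(z)
    col_d = pearson_distance(z.T)
    row_dend = upgma_cluster(row_d)
    col_dend = upgma_cluster(col_d)
    groups = cut_tree(col_dend, n_column_groups)
    column_groups = {label: gi for gi, cl in enumerate(groups) for label in cl.genes}
    return row_dend, col_dend, column_groups
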