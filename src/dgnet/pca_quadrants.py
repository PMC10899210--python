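"""Missing-value-tolerant PCA of expression matrices and quadrant analysis.

Principal components are extracted by singular value decomposition with
iterative imputation: missing cells start at their column means and are
refilled from a truncated-SVD reconstruction until they stabilise.  Genes are
then placed in the four quadrants of the (PC1, PC2) score plane, and each
quadrant is profiled by gene-set over-representation.

SVD component signs are arbitrary; each component is oriented so that its
largest-magnitude loading is positive, and the orientation is recorded so an
external plot's quadrant labels can be matched by a post-hoc flip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .enrichment_profiles import EnrichmentResult, bh_adjust, hypergeom_tail
from .expression import ExpressionMatrix
from .io_formats import GeneSetCollection

if TYPE_CHECKING:  # pragma: no cover
    from .interactome import GeneUniverse
    from .temporal_clustering import GeneCluster

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "QuadrantAssignment",
    "scale_unit_variance",
    "svd_impute",
    "assign_quadrants",
    "quadrant_enrichment",
]

QUADRANTS = ("I", "II", "III", "IV")


def _as_frame(matrix: "ExpressionMatrix | pd.DataFrame") -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


@dataclass
class PCAResult:
    """Scores, loadings and variance fractions from SVD-with-imputation."""

    scores: pd.DataFrame  # genes x components
    loadings: pd.DataFrame  # components x coordinates
    variance_explained: np.ndarray  # fraction per returned component
    n_iterations: int
    converged: bool
    sign_flips: list[int] = field(default_factory=list)  # components flipped for orientation


@dataclass
class QuadrantAssignment:
    """Gene -> quadrant of the (PC1, PC2) plane.

    Quadrant I = (PC1>0, PC2>0), II = (PC1<0, PC2>0), III = (PC1<0, PC2<0),
    IV = (PC1>0, PC2<0); exact zeros resolve to the positive side.
    ``convention`` records the component sign orientation used.
    """

    assignments: dict[str, str]
    convention: dict[str, object] = field(default_factory=dict)

    def genes_in(self, quadrant: str) -> set[str]:
        return {g for g, q in self.assignments.items() if q == quadrant}


def scale_unit_variance(matrix: "ExpressionMatrix | pd.DataFrame") -> pd.DataFrame:
    """Center each gene row to mean 0 and scale to unit sample variance.

    Statistics are computed over non-missing entries only (>= 2 required per
    row); constant rows make scaling undefined and raise an error listing the
    offending genes.
    """
    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float)
    obs = np.isfinite(X)
    n_obs = obs.sum(axis=1)
    too_few = n_obs < 2
    if too_few.any():
        raise ValueError(
            f"rows with fewer than 2 observed values: {list(df.index[too_few])[:10]}"
        )
    mean = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
    zero = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    if zero.any():
        raise ValueError(
            f"zero-variance rows cannot be unit-variance scaled: {list(df.index[zero])[:10]}"
        )
    return pd.DataFrame((X - mean) / sd, index=df.index, columns=df.columns)


def _truncated_svd(X: np.ndarray, r: int):
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    return U, S, Vt, U[:, :r] @ np.diag(S[:r]) @ Vt[:r]


def svd_impute(
    matrix: "ExpressionMatrix | pd.DataFrame",
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PCAResult:
    """Principal components by truncated SVD with iterative imputation.

    Missing cells are initialised with their column means, then alternately
    reconstructed from the rank-``n_components`` SVD and refilled, until the
    largest absolute change in any imputed cell drops below ``tol`` or
    ``max_iter`` is reached (non-convergence is a warning, not an error).
    Scores are U*S for the final decomposition; variance fractions are squared
    singular values over their total.  The whole procedure is deterministic.
    """
    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float).copy()
    n, m = X.shape
    if not 1 <= n_components <= min(n, m):
        raise ValueError(f"n_components must be in [1, {min(n, m)}], got {n_components}")
    missing = ~np.isfinite(X)
    n_iter = 0
    converged = True
    if missing.any():
        col_mean = np.nanmean(np.where(missing, np.nan, X), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        X[missing] = np.broadcast_to(col_mean, X.shape)[missing]
        converged = False
        for n_iter in range(1, max_iter + 1):
            *_, recon = _truncated_svd(X, n_components)
            delta = np.max(np.abs(recon[missing] - X[missing])) if missing.any() else 0.0
            X[missing] = recon[missing]
            if delta < tol:
                converged = True
                break
        if not converged:
            logger.warning(
                "svd_impute: not converged after %d iterations (last delta %.3g)",
                max_iter, delta,
            )
    U, S, Vt, _ = _truncated_svd(X, n_components)
    total = float(np.sum(S**2))
    varexp = (S[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].copy()
    flips = []
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
            flips.append(j + 1)
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    col_labels = (
        [f"{r}|{s}" for r, s in df.columns] if isinstance(df.columns, pd.MultiIndex) else list(df.columns)
    )
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=comp_names, columns=col_labels),
        variance_explained=np.asarray(varexp),
        n_iterations=n_iter,
        converged=converged,
        sign_flips=flips,
    )


def assign_quadrants(pca: PCAResult) -> QuadrantAssignment:
    """Place each gene in a quadrant by the signs of its (PC1, PC2) scores."""
    if pca.scores.shape[1] < 2:
        raise ValueError("quadrant assignment needs at least 2 components")
    pc1 = pca.scores.iloc[:, 0].to_numpy()
    pc2 = pca.scores.iloc[:, 1].to_numpy()
    n_zero = int(np.sum((pc1 == 0) | (pc2 == 0)))
    if n_zero:
        logger.info("assign_quadrants: %d exact-zero scores resolved to the positive side", n_zero)
    quad = np.where(
        pc1 >= 0,
        np.where(pc2 >= 0, "I", "IV"),
        np.where(pc2 >= 0, "II", "III"),
    )
    return QuadrantAssignment(
        assignments=dict(zip(pca.scores.index, quad)),
        convention={
            "orientation": "largest |loading| positive per component",
            "sign_flips_applied": list(pca.sign_flips),
        },
    )


def quadrant_enrichment(
    assignment: QuadrantAssignment,
    gene_sets: GeneSetCollection,
    universe: "GeneUniverse",
    clusters: "Sequence[GeneCluster] | None" = None,
) -> pd.DataFrame:
    """Gene-set over-representation per quadrant (optionally within clusters).

    Each quadrant — intersected with each cluster when clusters are given — is
    tested against every gene set; BH correction spans the whole family of
    tests in the call.  The table reports intersection counts and the
    percentage of each set's (assigned, in-universe) genes falling in the
    quadrant, so percentages per set sum to 100 across quadrants.
    """
    assigned = set(assignment.assignments) & universe.genes
    N = len(universe)
    queries: list[tuple[str, str | None, set[str]]] = []
    for quad in QUADRANTS:
        in_quad = {g for g in assigned if assignment.assignments[g] == quad}
        if clusters is None:
            queries.append((quad, None, in_quad))
        else:
            for cl in clusters:
                combo = in_quad & cl.genes
                if not combo:
                    logger.info("quadrant_enrichment: empty quadrant %s ∩ cluster %s skipped", quad, cl.id)
                    continue
                queries.append((quad, cl.id, combo))
    rows = []
    results: list[EnrichmentResult] = []
    for quad, cluster_id, q in queries:
        n = len(q)
        for set_id, members in gene_sets.sets.items():
            s = set(members) & assigned
            K = len(s)
            k = len(q & s)
            p = hypergeom_tail(k, N, K, n) if K and n else 1.0
            expected = K * n / N
            res = EnrichmentResult(
                f"{quad}" if cluster_id is None else f"{quad}∩{cluster_id}",
                set_id, k, K, n, N, p, None, k / expected if expected > 0 else float("nan"),
            )
            results.append(res)
            rows.append(
                {
                    "quadrant": quad,
                    "cluster": cluster_id,
                    "set_id": set_id,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "pct_of_set": 100.0 * k / K if K else float("nan"),
                    "p_value": p,
                    "fold_enrichment": res.fold_enrichment,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
    return table
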