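"""Cross-dataset similarity and the tissue-clustering test.

Datasets are compared through the Spearman rank correlation of their
log2 fold-change vectors over the genes the two platforms share.  The
correlation matrix becomes a distance matrix (two dialects, see
:class:`~crosstx.config.RunConfig`), classical (Torgerson)
multidimensional scaling embeds the datasets in two dimensions, and a
label-permutation test asks whether datasets from the same tissue sit
closer together than datasets from different tissues.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .config import RunConfig
from .diffexpr import DEResult

logger = logging.getLogger(__name__)


@dataclass
class DatasetDistanceModel:
    """Pairwise correlation/distance structure plus the 2-D MDS embedding."""

    dataset_ids: List[str]
    tissue: Dict[str, str]
    corr: np.ndarray
    n_common: np.ndarray
    dist: np.ndarray
    embedding: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class TissueTestResult:
    """Within- vs between-tissue distance gap and its permutation p-value."""

    within_tissue_means: Dict[str, float]
    observed: float  # T = mean(between) - mean(within)
    n_permutations: int
    n_ge: int
    p: float
    distance_space: str


# ---------------------------------------------------------------------------
# correlation and distance
# ---------------------------------------------------------------------------

def fc_correlation(
    results: Sequence[DEResult], min_common_genes: int = 100
) -> Tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman correlation of log2 fold-change vectors.

    Every pair is correlated over the intersection of the two datasets'
    gene universes; a pair sharing fewer than ``min_common_genes`` genes
    is a hard error (the correlation would be meaningless).
    """
    series = [
        pd.Series(r.records["log2fc"].to_numpy(), index=r.records["gene"]) for r in results
    ]
    n = len(series)
    corr = np.eye(n)
    n_common = np.zeros((n, n), dtype=int)
    for i in range(n):
        n_common[i, i] = series[i].size
    for i, j in combinations(range(n), 2):
        common = series[i].index.intersection(series[j].index)
        if len(common) < min_common_genes:
            raise ValueError(
                f"datasets '{results[i].dataset_id}' and '{results[j].dataset_id}' share "
                f"only {len(common)} genes (< {min_common_genes})"
            )
        rho = stats.spearmanr(series[i][common], series[j][common]).statistic
        corr[i, j] = corr[j, i] = rho
        n_common[i, j] = n_common[j, i] = len(common)
    return corr, n_common


def correlation_to_distance(corr: np.ndarray, dialect: str = "corr_rows") -> np.ndarray:
    """Turn a correlation matrix into a symmetric zero-diagonal distance matrix.

    ``corr_rows`` (default) takes the Euclidean distance between rows of
    the correlation matrix; ``direct`` uses sqrt(2(1 - rho)).
    """
    corr = np.asarray(corr, dtype=float)
    if dialect == "corr_rows":
        dist = squareform(pdist(corr, metric="euclidean"))
    elif dialect == "direct":
        dist = np.sqrt(np.maximum(2.0 * (1.0 - corr), 0.0))
        np.fill_diagonal(dist, 0.0)
    else:
        raise ValueError(f"unknown distance dialect '{dialect}'")
    return dist


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

def classical_mds(dist: np.ndarray, k: int = 2) -> Tuple[np.ndarray, np.ndarray]:
    """Torgerson classical scaling of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and returns
    the top-``k`` coordinates (axes ordered by eigenvalue) together with
    the full descending eigenvalue spectrum.  The sign of each axis is
    fixed so its largest-magnitude loading is positive, making the
    embedding deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points for a {k}-D embedding")

    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    n_pos = int((eigvals[:k] > 0).sum())
    if n_pos < k:
        logger.warning("only %d positive eigenvalues; zero-filling remaining axes", n_pos)
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords, eigvals


def build_distance_model(
    results: Sequence[DEResult],
    tissues: Dict[str, str],
    config: RunConfig,
) -> DatasetDistanceModel:
    """Correlate, convert to distances, and embed a set of DE results."""
    corr, n_common = fc_correlation(results, min_common_genes=config.min_common_genes)
    dist = correlation_to_distance(corr, dialect=config.distance_dialect)
    embedding, eigenvalues = classical_mds(dist, k=2)
    ids = [r.dataset_id for r in results]
    return DatasetDistanceModel(
        dataset_ids=ids,
        tissue={i: tissues[i] for i in ids},
        corr=corr,
        n_common=n_common,
        dist=dist,
        embedding=embedding,
        eigenvalues=eigenvalues,
    )


# ---------------------------------------------------------------------------
# tissue-clustering permutation test
# ---------------------------------------------------------------------------

def tissue_distance_test(
    model: DatasetDistanceModel,
    config: RunConfig,
    n_permutations: int | None = None,
) -> TissueTestResult:
    """Do same-tissue datasets sit closer together than different-tissue ones?

    The statistic is T = mean(between-tissue pairwise distance) -
    mean(within-tissue pairwise distance); the null is built by
    permuting tissue labels across datasets, and the empirical p-value
    uses the add-one rule (#{T_null >= T_obs} + 1)/(N + 1) so it is
    never zero.  Tissues represented by a single dataset contribute only
    between-tissue pairs.
    """
    n_perm = config.n_permutations if n_permutations is None else n_permutations
    ids = model.dataset_ids
    labels = np.asarray([model.tissue[i] for i in ids])
    n = len(ids)
    counts = pd.Series(labels).value_counts()
    if (counts >= 2).sum() < 1 or counts.size < 2:
        raise ValueError("tissue test needs >= 2 tissues with at least one multi-dataset tissue")
    if not (counts >= 2).any() or (counts == 1).all():
        raise ValueError("all tissues are singletons; no within-tissue pairs exist")
    singletons = counts[counts == 1].index.tolist()
    if singletons:
        logger.warning("tissues %s have a single dataset; excluded from within-tissue means", singletons)

    if config.mds_distance_space == "embedding":
        dmat = squareform(pdist(model.embedding, metric="euclidean"))
    else:
        dmat = model.dist

    pair_i, pair_j = np.triu_indices(n, k=1)
    pair_d = dmat[pair_i, pair_j]

    def gap(lab: np.ndarray) -> float:
        same = lab[pair_i] == lab[pair_j]
        if not same.any() or same.all():
            return np.nan
        return float(pair_d[~same].mean() - pair_d[same].mean())

    observed = gap(labels)
    if np.isnan(observed):
        raise ValueError("degenerate tissue layout: no within- or no between-tissue pairs")

    within_means = {
        t: float(pair_d[(labels[pair_i] == t) & (labels[pair_j] == t)].mean())
        for t in counts[counts >= 2].index
    }

    rng = np.random.default_rng(config.seed)
    # permute labels as index permutations; vectorise the same-label masks
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    perm_labels = labels[perms]  # n_perm x n
    same = perm_labels[:, pair_i] == perm_labels[:, pair_j]
    n_same = same.sum(axis=1)
    sum_same = np.where(same, pair_d, 0.0).sum(axis=1)
    total = pair_d.sum()
    n_pairs = pair_d.size
    with np.errstate(invalid="ignore", divide="ignore"):
        t_null = (total - sum_same) / (n_pairs - n_same) - sum_same / n_same
    # label permutations keep group sizes, so both pair classes stay non-empty
    n_ge = int(np.sum(t_null >= observed))
    p = (n_ge + 1) / (n_perm + 1)
    return TissueTestResult(
        within_tissue_means=within_means,
        observed=observed,
        n_permutations=n_perm,
        n_ge=n_ge,
        p=p,
        distance_space=config.mds_distance_space,
    )
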