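"""Per-dataset differential expression.

Each gene's differential expression between cases and controls is
evaluated by fold change and a two-sided Wilcoxon rank-sum test; a gene
is called ``up`` when fc > fc_threshold and p < p_threshold, ``down``
when fc < 1/fc_threshold and p < p_threshold, and ``ns`` otherwise
(strict inequalities on every threshold).  No multiple-testing
correction is applied unless the configuration asks for
Benjamini-Hochberg.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import ExpressionDataset

logger = logging.getLogger(__name__)

EXACT_MAX_N = 16  # largest total sample size for exact rank-sum enumeration


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def fold_change(
    case_values: Sequence[float], control_values: Sequence[float], scale: str
) -> Tuple[float, float]:
    """Case/control fold change of one gene.

    On linear scale fc = mean(case)/mean(control); on log2 scale
    log2fc = mean(case) - mean(control) and fc = 2**log2fc.

    Raises
    ------
    ValueError
        If either vector is empty, or the control mean is <= 0 on linear
        scale (the caller flags and excludes such genes).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("fold_change needs non-empty case and control vectors")
    if scale == "linear":
        mc, mk = case.mean(), control.mean()
        if mk <= 0:
            raise ValueError("control mean <= 0 on linear scale; fold change undefined")
        fc = mc / mk
        return fc, math.log2(fc) if fc > 0 else -math.inf
    if scale == "log2":
        log2fc = case.mean() - control.mean()
        return 2.0 ** log2fc, log2fc
    raise ValueError(f"unknown scale '{scale}'")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _ranksum_counts(n_x: int, n_y: int) -> np.ndarray:
    """Number of rank subsets of size n_x from 1..n_x+n_y per rank sum.

    Dynamic-programming table over W = sum of x's ranks; index 0
    corresponds to the minimum rank sum n_x(n_x+1)/2.
    """
    n = n_x + n_y
    w_min = n_x * (n_x + 1) // 2
    w_max = n_x * (2 * n - n_x + 1) // 2
    # counts[k][s]: ways to pick k ranks so far with shifted sum s
    counts = np.zeros((n_x + 1, w_max - w_min + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n_x), 0, -1):
            shifted = counts[k - 1].copy()
            # adding 'rank' to a (k-1)-subset shifts the sum by rank - k
            # relative to the minimal packing 1..k
            shift = rank - k
            if shift == 0:
                counts[k] += shifted
            else:
                counts[k, shift:] += shifted[:-shift]
    return counts[n_x]


def _exact_ranksum_p(x_ranks: np.ndarray, n_x: int, n_y: int) -> float:
    """Exact two-sided p from the full null distribution of the rank sum.

    The tie-free rank-sum distribution is symmetric, so the two-sided p
    equals twice the smaller tail probability, clamped to 1.
    """
    counts = _ranksum_counts(n_x, n_y)
    total = counts.sum()
    w = int(x_ranks.sum()) - n_x * (n_x + 1) // 2  # shifted statistic
    lower = counts[: w + 1].sum() / total
    upper = counts[w:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def _normal_ranksum_p(ranks: np.ndarray, n_x: int, n_y: int) -> float:
    """Normal approximation with midranks, tie correction and continuity."""
    n = n_x + n_y
    w = ranks[:n_x].sum()
    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks[:n], return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return 1.0
    diff = w - mu
    # continuity correction shrinks |diff| by 0.5 toward the mean
    z = (abs(diff) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, max(0.0, 2.0 * stats.norm.sf(z))))


def ranksum_test(x: Sequence[float], y: Sequence[float], mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``auto`` uses exact enumeration when the pooled sample size is at
    most 16 and there are no ties, otherwise a normal approximation with
    tie and continuity corrections.  ``exact`` refuses ties and falls
    back to the normal approximation with a log record.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("ranksum_test needs >= 2 observations per group")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    has_ties = np.unique(pooled).size < pooled.size
    n_x, n_y = x.size, y.size

    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode '{mode}'")
    if mode == "exact" and has_ties:
        logger.info("ranksum exact mode refuses ties; falling back to normal")
        mode = "normal"
    if mode == "auto":
        mode = "exact" if (n_x + n_y <= EXACT_MAX_N and not has_ties) else "normal"
    if mode == "exact":
        return _exact_ranksum_p(ranks[:n_x], n_x, n_y)
    return _normal_ranksum_p(ranks, n_x, n_y)


def _ranksum_matrix(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorised per-gene auto-mode rank-sum p-values.

    ``case`` and ``control`` are gene x sample matrices; returns one p per
    gene, identical to calling :func:`ranksum_test` row by row.
    """
    n_x, n_y = case.shape[1], control.shape[1]
    n = n_x + n_y
    pooled = np.concatenate([case, control], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    w = ranks[:, :n_x].sum(axis=1)
    mu = n_x * (n + 1) / 2.0

    srt = np.sort(pooled, axis=1)
    tied_mask = srt[:, 1:] == srt[:, :-1]
    has_ties = tied_mask.any(axis=1)

    # tie term sum(t^3 - t) per gene from run lengths of equal values
    tie_term = np.zeros(pooled.shape[0])
    for i in np.where(has_ties)[0]:
        _, cnt = np.unique(srt[i], return_counts=True)
        tie_term[i] = float((cnt ** 3 - cnt).sum())

    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(np.abs(w - mu) - 0.5, 0.0) / np.sqrt(var)
    p = np.where(var > 0, np.clip(2.0 * stats.norm.sf(z), 0.0, 1.0), 1.0)

    if n <= EXACT_MAX_N:
        counts = _ranksum_counts(n_x, n_y)
        total = counts.sum()
        cdf = np.cumsum(counts) / total
        sf = np.cumsum(counts[::-1])[::-1] / total
        exact_rows = np.where(~has_ties)[0]
        w_shift = (w[exact_rows] - n_x * (n_x + 1) // 2).astype(int)
        p[exact_rows] = np.minimum(1.0, 2.0 * np.minimum(cdf[w_shift], sf[w_shift]))
    return p


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene fold change, p-value and direction call for one dataset."""

    dataset_id: str
    records: pd.DataFrame  # columns: gene, fc, log2fc, p, direction
    excluded_genes: List[str] = field(default_factory=list)

    @property
    def genes(self) -> List[str]:
        return self.records["gene"].tolist()

    def gene_list(self, direction: str) -> List[str]:
        return self.records.loc[self.records["direction"] == direction, "gene"].tolist()

    @property
    def up_genes(self) -> List[str]:
        return self.gene_list("up")

    @property
    def down_genes(self) -> List[str]:
        return self.gene_list("down")


def _directions(fc: np.ndarray, p: np.ndarray, config: RunConfig) -> np.ndarray:
    up = (fc > config.fc_threshold) & (p < config.p_threshold)
    down = (fc < 1.0 / config.fc_threshold) & (p < config.p_threshold)
    out = np.full(fc.shape, "ns", dtype=object)
    out[up] = "up"
    out[down] = "down"
    return out


def call_de(records: pd.DataFrame, config: RunConfig, dataset_id: str = "") -> DEResult:
    """Assign up/down/ns calls to a (gene, fc, log2fc, p) table.

    With ``config.fdr == "bh"`` the Benjamini-Hochberg adjusted p-values
    are thresholded instead of the raw ones (and stored as ``p_adj``).
    """
    rec = records.copy()
    p_for_calls = rec["p"].to_numpy(dtype=float)
    if config.fdr == "bh":
        p_for_calls = multipletests(p_for_calls, method="fdr_bh")[1]
        rec["p_adj"] = p_for_calls
    rec["direction"] = _directions(rec["fc"].to_numpy(dtype=float), p_for_calls, config)
    return DEResult(dataset_id=dataset_id, records=rec.reset_index(drop=True))


def differential_expression(ds: ExpressionDataset, config: RunConfig) -> DEResult:
    """Full per-dataset DE: fold change + rank-sum p + direction calls.

    Genes whose control mean is <= 0 on linear scale are excluded from
    calling and listed in ``DEResult.excluded_genes``.
    """
    case = ds.case_matrix()
    control = ds.control_matrix()

    genes = np.asarray(ds.genes)
    if ds.scale == "log2":
        log2fc = case.mean(axis=1) - control.mean(axis=1)
        fc = 2.0 ** log2fc
        valid = np.ones(len(genes), dtype=bool)
    else:
        mc, mk = case.mean(axis=1), control.mean(axis=1)
        valid = mk > 0
        fc = np.full(len(genes), np.nan)
        fc[valid] = mc[valid] / mk[valid]
        with np.errstate(divide="ignore"):
            log2fc = np.where(fc > 0, np.log2(fc, where=fc > 0), -np.inf)
    excluded = genes[~valid].tolist()
    if excluded:
        logger.warning(
            "%s: %d genes excluded from DE (control mean <= 0)", ds.dataset_id, len(excluded)
        )

    p = _ranksum_matrix(case[valid], control[valid])
    rec = pd.DataFrame(
        {"gene": genes[valid], "fc": fc[valid], "log2fc": log2fc[valid], "p": p}
    )
    result = call_de(rec, config, dataset_id=ds.dataset_id)
    result.excluded_genes = excluded
    return result


# ---------------------------------------------------------------------------
# cross-dataset direction matrix
# ---------------------------------------------------------------------------

def direction_matrix(results: Sequence[DEResult], min_datasets: int = 3) -> pd.DataFrame:
    """Signed log2fc matrix of genes differentially expressed in several cohorts.

    A gene is retained when it is called up or down in at least
    ``min_datasets`` datasets; cells hold the signed log2 fold change
    where the call was made and NaN elsewhere.  Rows are ordered by the
    number of supporting datasets (descending) then gene symbol.
    """
    if len(results) < min_datasets:
        raise ValueError(
            f"need >= {min_datasets} DE results for a min_datasets={min_datasets} matrix"
        )
    cols = {}
    for res in results:
        rec = res.records
        called = rec[rec["direction"] != "ns"]
        cols[res.dataset_id] = pd.Series(
            called["log2fc"].to_numpy(), index=called["gene"], dtype=float
        )
    mat = pd.DataFrame(cols)
    support = mat.notna().sum(axis=1)
    mat = mat[support >= min_datasets]
    if mat.empty:
        logger.warning("direction matrix is empty at min_datasets=%d", min_datasets)
        return mat
    order = (
        pd.DataFrame({"support": support[mat.index].to_numpy(), "symbol": mat.index})
        .sort_values(["support", "symbol"], ascending=[False, True])["symbol"]
        .to_numpy()
    )
    return mat.loc[order]
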