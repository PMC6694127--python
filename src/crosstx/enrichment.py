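"""Over-representation analysis (ORA) of up- and down-regulated gene lists.

Up and down lists are tested separately with the hypergeometric upper
tail against a flat gene-set database, using the dataset's own measured
gene universe as background (platforms differ, so the genome is not the
right universe).  The same machinery serves drug-set enrichment, with
drugs in place of genes and the catalogue as universe.  No
multiple-testing correction is applied unless configured.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .diffexpr import DEResult
from .io import DrugSetDB, GeneSetDB

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    """One (dataset, direction, term) over-representation result."""

    dataset_id: str
    direction: str  # "up" | "down"
    term_id: str
    k: int  # overlap
    n: int  # query size
    K: int  # term size within universe
    N: int  # universe size
    p: float

    @property
    def neglog10p(self) -> float:
        return -math.log10(self.p)


def hypergeom_ora(
    query: Iterable[str], term: Iterable[str], universe: Iterable[str]
) -> Tuple[int, int, int, int, float]:
    """Hypergeometric upper-tail test of query/term overlap.

    Returns (k, n, K, N, p) where p = P(X >= k) for X ~
    Hypergeometric(N, K, n).  The term is intersected with the universe
    before testing; the query must be a subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query:
        raise ValueError("no significant genes to test")
    if not query <= universe:
        extra = sorted(query - universe)[:3]
        raise ValueError(f"query is not a subset of the universe (e.g. {extra})")
    term = set(term) & universe
    n, K, N = len(query), len(term), len(universe)
    k = len(query & term)
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, n, K, N, min(max(p, 0.0), 1.0)


def _vectorised_upper_tail(k: np.ndarray, N: int, K: np.ndarray, n: int) -> np.ndarray:
    return np.clip(stats.hypergeom.sf(k - 1, N, K, n), 0.0, 1.0)


def enrich_dataset(
    de: DEResult, db: GeneSetDB, config: RunConfig
) -> List[EnrichmentRecord]:
    """Test the up and down lists of one dataset against every term.

    The universe is the dataset's own gene universe; records with
    p < ``config.p_threshold`` are retained (after BH adjustment when
    ``config.fdr == "bh"``).
    """
    universe = set(de.genes)
    records: List[EnrichmentRecord] = []
    for direction in ("up", "down"):
        query = set(de.gene_list(direction))
        if not query:
            logger.warning("%s: empty %s list; direction skipped", de.dataset_id, direction)
            continue
        raw: List[EnrichmentRecord] = []
        for term_id, _, members in db.entries:
            k, n, K, N, p = hypergeom_ora(query, members, universe)
            raw.append(EnrichmentRecord(de.dataset_id, direction, term_id, k, n, K, N, p))
        pvals = np.array([r.p for r in raw])
        if config.fdr == "bh":
            pvals = multipletests(pvals, method="fdr_bh")[1]
            for r, q in zip(raw, pvals):
                r.p = float(q)
        records.extend(r for r, p in zip(raw, pvals) if p < config.p_threshold)
    return records


def term_overlap(
    records: Sequence[EnrichmentRecord], min_overlap: int
) -> pd.DataFrame:
    """Signed -log10(p) matrix of terms recurrent across datasets.

    Rows are (term, direction) pairs — a term significant in both
    directions in one dataset contributes two rows; a row is retained
    when its term is significant in that direction in at least
    ``min_overlap`` datasets.  Cells are +(-log10 p) for up-list
    enrichment and -(-log10 p) for down-list enrichment, NaN when the
    term was not significant in that dataset.
    """
    if not records:
        logger.warning("no enrichment records; empty overlap matrix")
        return pd.DataFrame()
    rows: Dict[Tuple[str, str], Dict[str, float]] = {}
    dataset_ids: List[str] = []
    for r in records:
        if r.dataset_id not in dataset_ids:
            dataset_ids.append(r.dataset_id)
        sign = 1.0 if r.direction == "up" else -1.0
        rows.setdefault((r.term_id, r.direction), {})[r.dataset_id] = sign * r.neglog10p
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=dataset_ids)
    mat = mat[mat.notna().sum(axis=1) >= min_overlap]
    if mat.empty:
        logger.warning("term overlap matrix empty at min_overlap=%d", min_overlap)
        return mat
    mat.index = pd.MultiIndex.from_tuples(mat.index, names=["term_id", "direction"])
    support = mat.notna().sum(axis=1)
    order = support.sort_values(ascending=False, kind="stable").index
    return mat.loc[order]


def drugset_enrichment(
    drugs: Sequence[str],
    db: DrugSetDB,
    universe: Iterable[str],
    config: RunConfig,
) -> List[EnrichmentRecord]:
    """Drug-set ORA: identical machinery with drugs in place of genes.

    ``universe`` is the full drug catalogue; sets with
    p < ``config.p_threshold`` are retained.  In the returned records
    the ``direction`` slot carries the drug-set category (target,
    pathway, ...) instead of up/down.
    """
    if not drugs:
        raise ValueError("no significant genes to test")
    universe = set(universe)
    records: List[EnrichmentRecord] = []
    for set_id, category, members in db.entries:
        k, n, K, N, p = hypergeom_ora(set(drugs), members, universe)
        if p < config.p_threshold:
            records.append(
                EnrichmentRecord("interested_drugs", category, set_id, k, n, K, N, p)
            )
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate enrichment records for TSV output."""
    return pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id,
                "direction": r.direction,
                "term_id": r.term_id,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "neglog10p": r.neglog10p,
            }
            for r in records
        ]
    )
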