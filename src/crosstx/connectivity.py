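"""Connectivity-style drug prediction against ranked reference profiles.

A disease signature (ordered up- and down-regulated gene lists, 10-150
valid up genes; down genes optional) is compared to each drug's full
ranked expression profile with a bidirectional Kolmogorov-Smirnov
enrichment statistic, combined into a connectivity score scaled to
[-100, 100].  Strongly negative scores mark candidate reversers; drugs
whose score falls in the configured window ([-100, -80] by default) and
recur across enough datasets become the "interested" drug list.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .config import RunConfig
from .diffexpr import DEResult
from .io import DrugProfileCatalogue

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    """Dataset cannot form a valid connectivity query signature."""


@dataclass
class Signature:
    """Ordered up/down gene lists for a connectivity query."""

    dataset_id: str
    up: List[str]  # descending fold change
    down: List[str]  # ascending fold change
    valid_up_count: int
    valid_down_count: int


@dataclass
class ConnectivityRecord:
    """Per-drug enrichment statistics and combined score for one signature."""

    drug: str
    es_up: float
    es_down: Optional[float]
    score: float


def trim_signature(
    de: DEResult, catalogue_universe: Iterable[str], config: RunConfig
) -> Signature:
    """Build the query signature from a DE result, applying the size rules.

    Valid genes are those present in the catalogue universe.  Up genes
    are sorted by descending fold change and truncated at
    ``signature_max``; down genes by ascending fold change, likewise
    truncated, and may be empty.  A dataset with fewer than
    ``signature_min`` valid up genes is rejected (mirroring the
    exclusion of datasets from the query).  Fold-change ties break by
    gene symbol for determinism.
    """
    universe = set(catalogue_universe)
    rec = de.records
    up = rec[(rec["direction"] == "up") & rec["gene"].isin(universe)]
    down = rec[(rec["direction"] == "down") & rec["gene"].isin(universe)]
    n_up, n_down = len(up), len(down)
    if n_up < config.signature_min:
        raise SignatureError(
            f"{de.dataset_id}: only {n_up} valid up-regulated genes "
            f"(< {config.signature_min}); dataset excluded from the connectivity query"
        )
    up_sorted = up.sort_values(["fc", "gene"], ascending=[False, True])
    down_sorted = down.sort_values(["fc", "gene"], ascending=[True, True])
    return Signature(
        dataset_id=de.dataset_id,
        up=up_sorted["gene"].head(config.signature_max).tolist(),
        down=down_sorted["gene"].head(config.signature_max).tolist(),
        valid_up_count=n_up,
        valid_down_count=n_down,
    )


def ks_enrichment_score(set_ranks: Sequence[int], n_profile: int) -> float:
    """Bidirectional KS enrichment of a gene set within a ranked profile.

    ``set_ranks`` are the 1-based profile ranks of the set's genes; with
    sorted ranks r_1 < ... < r_t,

        a = max_j (j/t - r_j/N),   b = max_j (r_j/N - (j-1)/t)

    and es = a if a > b else -b.  Positive scores mean the set
    concentrates at the top of the profile, negative at the bottom.
    """
    r = np.sort(np.asarray(set_ranks, dtype=float))
    t = r.size
    if t < 1:
        raise ValueError("gene set must contain at least one gene")
    if r[0] < 1 or r[-1] > n_profile or np.unique(r).size != t:
        raise ValueError("set ranks must be distinct integers in 1..N")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - r / n_profile))
    b = float(np.max(r / n_profile - (j - 1) / t))
    return a if a > b else -b


def _set_ranks(genes: Sequence[str], ranks: np.ndarray, index: Mapping[str, int]) -> np.ndarray:
    try:
        idx = [index[g] for g in genes]
    except KeyError as exc:
        raise ValueError(f"gene {exc} not in catalogue universe") from None
    return ranks[idx]


def connectivity_score(
    sig: Signature, drug: str, catalogue: DrugProfileCatalogue
) -> ConnectivityRecord:
    """Combined +/-100-scaled connectivity score of one drug for one signature.

    When both KS statistics share a sign the profile neither mimics nor
    reverses the signature coherently and the score is 0; otherwise the
    score is 100*(es_up - es_down)/2 (or 100*es_up when the down list is
    empty).  Negative scores denote reversers.
    """
    ranks = catalogue.ranks_of(drug)
    index = {g: i for i, g in enumerate(catalogue.gene_universe)}
    return _score_with_ranks(sig, drug, ranks, index, len(catalogue.gene_universe))


def _score_with_ranks(
    sig: Signature,
    drug: str,
    ranks: np.ndarray,
    index: Mapping[str, int],
    n_profile: int,
) -> ConnectivityRecord:
    es_up = ks_enrichment_score(_set_ranks(sig.up, ranks, index), n_profile)
    if not sig.down:
        return ConnectivityRecord(drug, es_up, None, 100.0 * es_up)
    es_down = ks_enrichment_score(_set_ranks(sig.down, ranks, index), n_profile)
    if np.sign(es_up) == np.sign(es_down):
        score = 0.0
    else:
        score = 100.0 * (es_up - es_down) / 2.0
    return ConnectivityRecord(drug, es_up, es_down, score)


def score_catalogue(sig: Signature, catalogue: DrugProfileCatalogue) -> List[ConnectivityRecord]:
    """Connectivity scores of every catalogue drug against one signature."""
    index = {g: i for i, g in enumerate(catalogue.gene_universe)}
    n = len(catalogue.gene_universe)
    out = []
    for drug in catalogue.drugs:
        out.append(_score_with_ranks(sig, drug, catalogue.ranks_of(drug), index, n))
    return out


def select_reversers(
    records: Sequence[ConnectivityRecord], config: RunConfig
) -> List[str]:
    """Drugs whose score lies in the closed reverser window [lo, hi]."""
    lo, hi = config.score_window
    return [r.drug for r in records if lo <= r.score <= hi]


def overlap_candidates(
    per_dataset_lists: Mapping[str, Sequence[str]], min_datasets: int
) -> Tuple[List[str], Dict[str, int]]:
    """Drugs recurring across enough per-dataset candidate lists.

    Datasets whose candidate list holds fewer than two compounds are
    dropped before counting (a single-compound list carries no overlap
    information).  Returns the interested-drug list (count >=
    ``min_datasets``, sorted by count descending then name) and the full
    per-drug dataset counts.
    """
    surviving = {d: list(dict.fromkeys(lst)) for d, lst in per_dataset_lists.items() if len(set(lst)) >= 2}
    dropped = sorted(set(per_dataset_lists) - set(surviving))
    if dropped:
        logger.info("datasets %s dropped: fewer than two candidate compounds", dropped)
    if not surviving:
        raise ValueError("no dataset contributed a candidate list with >= 2 compounds")
    counts: Counter = Counter()
    for lst in surviving.values():
        counts.update(set(lst))
    interested = sorted(
        (d for d, c in counts.items() if c >= min_datasets),
        key=lambda d: (-counts[d], d),
    )
    return interested, dict(counts)
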