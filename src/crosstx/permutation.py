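"""Random-experiment nulls for cross-group overlap statistics.

Two dataset groups (e.g. human cohorts and animal-model cohorts) yield a
shared-significant-term count and a shared-interested-drug count.  To
ask whether such overlaps could arise by chance, each replicate redraws
the per-dataset inputs at random — gene lists of the observed sizes from
each dataset's own universe for the enrichment statistic, candidate drug
lists of the observed sizes from the catalogue for the drug statistic —
reapplies the group-level criteria exactly as the real pipeline does,
and records the overlap.  The empirical p-value uses the add-one rule
(#{null >= observed} + 1)/(N + 1), so it is never zero and its smallest
achievable value is 1/(N + 1).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import RunConfig
from .io import GeneSetDB

__all__ = [
    "DatasetNullSpec",
    "PermutationTestResult",
    "permute_term_overlap",
    "permute_drug_overlap",
]


@dataclass
class DatasetNullSpec:
    """What a null replicate needs to know about one dataset."""

    dataset_id: str
    universe: List[str]
    n_up: int
    n_down: int


@dataclass
class PermutationTestResult:
    """Observed overlap, null histogram and empirical p-value."""

    statistic_name: str  # "shared_terms" | "shared_drugs"
    observed: int
    n_permutations: int
    null_counts: Dict[int, int]
    n_ge: int
    p: float
    seed: int

    def __post_init__(self) -> None:
        assert sum(self.null_counts.values()) == self.n_permutations
        assert 0 < self.p <= 1


def _add_one_p(n_ge: int, n_perm: int) -> float:
    return (n_ge + 1) / (n_perm + 1)


def _group_membership(db: GeneSetDB, universe: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean term x gene membership matrix over one dataset's universe."""
    gene_index = {g: i for i, g in enumerate(universe)}
    m = np.zeros((len(db), len(universe)), dtype=bool)
    for t, (_, _, members) in enumerate(db.entries):
        idx = [gene_index[g] for g in members if g in gene_index]
        m[t, idx] = True
    return m, m.sum(axis=1)


def _null_significant_terms(
    specs: Sequence[DatasetNullSpec],
    mats: Sequence[Tuple[np.ndarray, np.ndarray]],
    p_threshold: float,
    min_overlap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean vector over terms: significant in >= min_overlap group datasets."""
    n_terms = mats[0][0].shape[0]
    support = np.zeros(n_terms, dtype=int)
    for spec, (m, big_k) in zip(specs, mats):
        n_universe = len(spec.universe)
        sig = np.zeros(n_terms, dtype=bool)
        for n_query in (spec.n_up, spec.n_down):
            if n_query == 0:
                continue
            draw = rng.choice(n_universe, size=n_query, replace=False)
            k = m[:, draw].sum(axis=1)
            p = stats.hypergeom.sf(k - 1, n_universe, big_k, n_query)
            sig |= p < p_threshold
        support += sig
    return support >= min_overlap


def permute_term_overlap(
    group_a: Sequence[DatasetNullSpec],
    group_b: Sequence[DatasetNullSpec],
    db: GeneSetDB,
    config: RunConfig,
    observed: int,
    min_overlap_a: int | None = None,
    min_overlap_b: int | None = None,
    n_permutations: int | None = None,
) -> PermutationTestResult:
    """Null for the number of significant terms shared by two dataset groups.

    Each replicate draws uniform random up/down gene lists of the
    observed sizes from every dataset's own universe, runs the same
    per-dataset ORA and group-level recurrence criterion
    (significant in >= min_overlap datasets of the group, either
    direction) as the real pipeline, and counts terms shared between the
    groups.
    """
    if observed is None:
        raise ValueError("observed shared-term count must be supplied")
    n_perm = config.n_permutations if n_permutations is None else n_permutations
    mo_a = config.min_overlap if min_overlap_a is None else min_overlap_a
    mo_b = config.min_overlap if min_overlap_b is None else min_overlap_b
    rng = np.random.default_rng(config.seed)

    mats_a = [_group_membership(db, s.universe) for s in group_a]
    mats_b = [_group_membership(db, s.universe) for s in group_b]

    null_counts: Counter = Counter()
    n_ge = 0
    for _ in range(n_perm):
        sig_a = _null_significant_terms(group_a, mats_a, config.p_threshold, mo_a, rng)
        sig_b = _null_significant_terms(group_b, mats_b, config.p_threshold, mo_b, rng)
        shared = int(np.sum(sig_a & sig_b))
        null_counts[shared] += 1
        if shared >= observed:
            n_ge += 1
    return PermutationTestResult(
        statistic_name="shared_terms",
        observed=observed,
        n_permutations=n_perm,
        null_counts=dict(null_counts),
        n_ge=n_ge,
        p=_add_one_p(n_ge, n_perm),
        seed=config.seed,
    )


def _null_interested(
    sizes: Mapping[str, int],
    catalogue_size: int,
    min_datasets: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean vector over catalogue drugs: in >= min_datasets random lists.

    Mirrors the real overlap rule: datasets whose candidate list has
    fewer than two compounds are dropped before counting.
    """
    counts = np.zeros(catalogue_size, dtype=int)
    for size in sizes.values():
        if size < 2:
            continue
        draw = rng.choice(catalogue_size, size=size, replace=False)
        counts[draw] += 1
    return counts >= min_datasets


def permute_drug_overlap(
    group_a_sizes: Mapping[str, int],
    group_b_sizes: Mapping[str, int],
    catalogue_size: int,
    config: RunConfig,
    observed: int,
    min_datasets_a: int | None = None,
    min_datasets_b: int | None = None,
    n_permutations: int | None = None,
) -> PermutationTestResult:
    """Null for the number of interested drugs shared by two dataset groups.

    Each replicate samples, per dataset, a uniform random candidate list
    of the observed size (without replacement) from the catalogue,
    applies the per-group recurrence thresholds, and counts the shared
    interested drugs.
    """
    if observed is None:
        raise ValueError("observed shared-drug count must be supplied")
    for name, sizes in (("group A", group_a_sizes), ("group B", group_b_sizes)):
        for d, s in sizes.items():
            if s > catalogue_size:
                raise ValueError(
                    f"{name} dataset '{d}' candidate list size {s} exceeds catalogue size"
                )
    n_perm = config.n_permutations if n_permutations is None else n_permutations
    min_a = config.human_overlap_min if min_datasets_a is None else min_datasets_a
    min_b = config.animal_overlap_min if min_datasets_b is None else min_datasets_b
    rng = np.random.default_rng(config.seed)

    null_counts: Counter = Counter()
    n_ge = 0
    for _ in range(n_perm):
        int_a = _null_interested(group_a_sizes, catalogue_size, min_a, rng)
        int_b = _null_interested(group_b_sizes, catalogue_size, min_b, rng)
        shared = int(np.sum(int_a & int_b))
        null_counts[shared] += 1
        if shared >= observed:
            n_ge += 1
    return PermutationTestResult(
        statistic_name="shared_drugs",
        observed=observed,
        n_permutations=n_perm,
        null_counts=dict(null_counts),
        n_ge=n_ge,
        p=_add_one_p(n_ge, n_perm),
        seed=config.seed,
    )
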