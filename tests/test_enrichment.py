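"""Hypergeometric ORA, per-dataset enrichment, term overlap, drug sets."""
import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from crosstx.config import RunConfig
from crosstx.diffexpr import DEResult
from crosstx.enrichment import (
    drugset_enrichment,
    enrich_dataset,
    hypergeom_ora,
    term_overlap,
    EnrichmentRecord,
)
from crosstx.io import DrugSetDB, GeneSetDB


def enumeration_upper_tail(N, K, n, k):
    """P(X >= k) by enumerating every n-subset of an N-universe."""
    universe = list(range(N))
    term = set(range(K))
    total = 0
    hits = 0
    for subset in combinations(universe, n):
        total += 1
        if len(term & set(subset)) >= k:
            hits += 1
    return hits / total


def test_upper_tail_from_zero_is_one():
    k, n, K, N, p = hypergeom_ora({"a", "b"}, {"x", "y"}, {"a", "b", "x", "y", "z"})
    assert k == 0 and p == 1.0


def test_exact_value_1_over_42():
    universe = set(range(10))
    term = set(range(5))
    query = set(range(4))
    k, n, K, N, p = hypergeom_ora(query, term, universe)
    assert (k, n, K, N) == (4, 4, 5, 10)
    assert p == pytest.approx(1 / 42, abs=1e-12)


def test_query_equals_universe_certain():
    u = set(range(8))
    term = set(range(3))
    k, n, K, N, p = hypergeom_ora(u, term, u)
    assert k == K == 3 and p == pytest.approx(1.0)


def test_matches_enumeration_oracle_small_universes():
    """Upper-tail p equals brute-force subset enumeration to 1e-9."""
    rng = np.random.default_rng(0)
    for N in (5, 8, 10, 12):
        for _ in range(6):
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = set(range(N))
            term = set(range(K))
            query = set(rng.choice(N, size=n, replace=False).tolist())
            k, _, _, _, p = hypergeom_ora(query, term, universe)
            assert p == pytest.approx(enumeration_upper_tail(N, K, n, k), abs=1e-9)


def test_exact_formula_up_to_N_20():
    """For N in 13..20 compare against the exact combinatorial sum."""
    rng = np.random.default_rng(1)
    for N in range(13, 21):
        K = int(rng.integers(2, N - 1))
        n = int(rng.integers(2, N - 1))
        query = set(rng.choice(N, size=n, replace=False).tolist())
        k, _, _, _, p = hypergeom_ora(query, set(range(K)), set(range(N)))
        expect = sum(
            math.comb(K, i) * math.comb(N - K, n - i)
            for i in range(k, min(n, K) + 1)
        ) / math.comb(N, n)
        assert p == pytest.approx(expect, abs=1e-9)


def test_p_monotone_in_overlap():
    from scipy.stats import hypergeom

    N, K, n = 100, 20, 15
    ps = [float(hypergeom.sf(k - 1, N, K, n)) for k in range(0, min(n, K) + 1)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_errors():
    with pytest.raises(ValueError, match="no significant genes"):
        hypergeom_ora(set(), {"a"}, {"a", "b"})
    with pytest.raises(ValueError, match="universe"):
        hypergeom_ora({"a"}, {"a"}, set())
    with pytest.raises(ValueError, match="subset"):
        hypergeom_ora({"zz"}, {"a"}, {"a", "b"})


# ---------------------------------------------------------------------------
# per-dataset enrichment
# ---------------------------------------------------------------------------

def de_with_lists(dataset_id, universe, up, down):
    direction = ["up" if g in up else "down" if g in down else "ns" for g in universe]
    return DEResult(
        dataset_id=dataset_id,
        records=pd.DataFrame(
            {
                "gene": universe,
                "fc": [2.0 if d == "up" else 0.4 if d == "down" else 1.0 for d in direction],
                "log2fc": [1.0 if d == "up" else -1.3 if d == "down" else 0.0 for d in direction],
                "p": [0.01 if d != "ns" else 0.6 for d in direction],
                "direction": direction,
            }
        ),
    )


def test_term_equal_to_up_list_is_retained_maximal(config):
    universe = [f"g{i}" for i in range(40)]
    up = set(universe[:10])
    de = de_with_lists("d", universe, up, set())
    db = GeneSetDB([("T", "d", frozenset(up))])
    recs = enrich_dataset(de, db, config)
    assert len(recs) == 1
    r = recs[0]
    assert r.k == r.n == 10 and r.direction == "up" and r.p < 1e-6


def test_empty_direction_skipped(config):
    universe = [f"g{i}" for i in range(30)]
    de = de_with_lists("d", universe, set(universe[:5]), set())
    db = GeneSetDB([("T", "d", frozenset(universe[:5]))])
    recs = enrich_dataset(de, db, config)
    assert {r.direction for r in recs} == {"up"}


def attained_level(N, K, n, alpha=0.05):
    """Exact null rate of {upper-tail p < alpha} for a discrete hypergeometric."""
    from scipy.stats import hypergeom

    ks = np.arange(0, min(n, K) + 1)
    pmf = hypergeom.pmf(ks, N, K, n)
    sf = hypergeom.sf(ks - 1, N, K, n)
    return float(pmf[sf < alpha].sum())


def test_random_queries_calibrated(config):
    """Retained-record rate over random queries matches the exact attained level.

    The hypergeometric is discrete, so the attained level sits at or
    below the nominal 0.05; the measured rate must match it within 3
    binomial SDs.
    """
    rng = np.random.default_rng(2)
    universe = [f"g{i}" for i in range(400)]
    db = GeneSetDB(
        [
            (f"T{t}", "r", frozenset(rng.choice(universe, size=40, replace=False)))
            for t in range(60)
        ]
    )
    expect = attained_level(400, 40, 25)
    assert 0 < expect <= 0.05
    total = 0
    kept = 0
    for rep in range(30):
        up = set(rng.choice(universe, size=25, replace=False))
        de = de_with_lists(f"d{rep}", universe, up, set())
        kept += len(enrich_dataset(de, db, config))
        total += len(db)
    rate = kept / total
    sd = math.sqrt(expect * (1 - expect) / total)
    assert abs(rate - expect) < 3 * sd + 0.005


# ---------------------------------------------------------------------------
# term overlap matrix
# ---------------------------------------------------------------------------

def rec(ds, direction, term, p):
    return EnrichmentRecord(ds, direction, term, 5, 10, 20, 100, p)


def test_overlap_retention_threshold():
    records = [rec("d1", "up", "T1", 0.01), rec("d2", "up", "T2", 0.01)]
    mat = term_overlap(records, min_overlap=2)
    assert mat.empty
    mat1 = term_overlap(records, min_overlap=1)
    assert len(mat1) == 2


def test_overlap_signs_by_direction():
    records = [
        rec("b1", "up", "T", 0.001),
        rec("b2", "up", "T", 0.002),
        rec("p1", "down", "T", 0.003),
        rec("p2", "down", "T", 0.004),
    ]
    mat = term_overlap(records, min_overlap=2)
    assert ("T", "up") in mat.index and ("T", "down") in mat.index
    assert mat.loc[("T", "up"), "b1"] == pytest.approx(-math.log10(0.001))
    assert mat.loc[("T", "down"), "p1"] == pytest.approx(math.log10(0.003))


def test_overlap_antisymmetric_under_direction_swap():
    records = [
        rec("d1", "up", "T", 0.01),
        rec("d2", "up", "T", 0.02),
        rec("d1", "down", "S", 0.03),
        rec("d2", "down", "S", 0.04),
    ]
    swapped = [
        EnrichmentRecord(r.dataset_id, "down" if r.direction == "up" else "up",
                         r.term_id, r.k, r.n, r.K, r.N, r.p)
        for r in records
    ]
    a = term_overlap(records, min_overlap=2)
    b = term_overlap(swapped, min_overlap=2)
    for (term, direction), row in a.iterrows():
        other = "down" if direction == "up" else "up"
        np.testing.assert_allclose(row.to_numpy(), -b.loc[(term, other)].to_numpy())


def test_both_directions_in_one_dataset_two_rows():
    records = [
        rec("d1", "up", "T", 0.01),
        rec("d1", "down", "T", 0.02),
    ]
    mat = term_overlap(records, min_overlap=1)
    assert len(mat) == 2


# ---------------------------------------------------------------------------
# drug-set enrichment
# ---------------------------------------------------------------------------

def test_drugset_maximal_overlap_dominates(config):
    universe = [f"drug{i}" for i in range(50)]
    interested = universe[:6]
    db = DrugSetDB(
        [
            ("TGT", "target", frozenset(interested)),
            ("OTH", "other", frozenset(universe[10:30])),
        ]
    )
    recs = drugset_enrichment(interested, db, universe, config)
    assert recs and min(recs, key=lambda r: r.p).term_id == "TGT"


def test_drugset_empty_list_is_error(config):
    db = DrugSetDB([("S", "other", frozenset({"a", "b"}))])
    with pytest.raises(ValueError):
        drugset_enrichment([], db, ["a", "b", "c"], config)


def test_drugset_random_calibration(config):
    rng = np.random.default_rng(3)
    universe = [f"drug{i}" for i in range(300)]
    db = DrugSetDB(
        [
            (f"S{t}", "other", frozenset(rng.choice(universe, size=30, replace=False)))
            for t in range(40)
        ]
    )
    expect = attained_level(300, 30, 15)
    total = kept = 0
    for _ in range(25):
        drugs = rng.choice(universe, size=15, replace=False).tolist()
        kept += len(drugset_enrichment(drugs, db, universe, config))
        total += len(db)
    rate = kept / total
    sd = math.sqrt(expect * (1 - expect) / total)
    assert abs(rate - expect) < 3 * sd + 0.005
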