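"""Signature trimming, KS enrichment score, connectivity score, overlap."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from crosstx.config import RunConfig
from crosstx.connectivity import (
    ConnectivityRecord,
    Signature,
    SignatureError,
    connectivity_score,
    ks_enrichment_score,
    overlap_candidates,
    select_reversers,
    trim_signature,
)
from crosstx.diffexpr import DEResult
from crosstx.io import DrugProfileCatalogue


def brute_force_es(set_ranks, n):
    """Running-sum oracle: walk every profile position and track the
    maximum positive and negative deviation between the set's empirical
    CDF and the uniform CDF."""
    hits = set(int(r) for r in set_ranks)
    t = len(hits)
    cnt = 0
    a = b = -np.inf
    for i in range(1, n + 1):
        f_prev = cnt / t
        if i in hits:
            cnt += 1
        f = cnt / t
        a = max(a, f - i / n)
        b = max(b, i / n - f_prev)
    return a if a > b else -b


def de_for_signature(dataset_id, fc_by_gene, directions):
    genes = list(fc_by_gene)
    return DEResult(
        dataset_id=dataset_id,
        records=pd.DataFrame(
            {
                "gene": genes,
                "fc": [fc_by_gene[g] for g in genes],
                "log2fc": np.log2([fc_by_gene[g] for g in genes]),
                "p": 0.01,
                "direction": [directions.get(g, "ns") for g in genes],
            }
        ),
    )


# ---------------------------------------------------------------------------
# trim_signature
# ---------------------------------------------------------------------------

def test_trim_keeps_top_150_by_fold_change():
    genes = {f"g{i:03d}": 2.0 + i * 0.01 for i in range(200)}
    directions = {g: "up" for g in genes}
    de = de_for_signature("d", genes, directions)
    cfg = RunConfig()
    sig = trim_signature(de, set(genes), cfg)
    assert len(sig.up) == 150
    # exactly the 150 largest fold changes survive
    expected = sorted(genes, key=lambda g: -genes[g])[:150]
    assert set(sig.up) == set(expected)
    assert sig.up[0] == "g199"  # descending fc order
    assert sig.valid_up_count == 200


def test_trim_rejects_fewer_than_10_valid_up():
    genes = {f"g{i}": 2.0 for i in range(9)}
    de = de_for_signature("d", genes, {g: "up" for g in genes})
    with pytest.raises(SignatureError, match="excluded"):
        trim_signature(de, set(genes), RunConfig())


def test_trim_validity_means_in_catalogue():
    # 12 up genes but only 9 in the catalogue universe -> rejected
    genes = {f"g{i}": 2.0 for i in range(12)}
    de = de_for_signature("d", genes, {g: "up" for g in genes})
    with pytest.raises(SignatureError):
        trim_signature(de, set(list(genes)[:9]), RunConfig())


def test_down_genes_optional():
    genes = {f"g{i}": (2.0 if i < 20 else 1.0) for i in range(40)}
    de = de_for_signature("d", genes, {f"g{i}": "up" for i in range(20)})
    sig = trim_signature(de, set(genes), RunConfig())
    assert len(sig.up) == 20 and sig.down == []


def test_down_sorted_ascending_fc():
    genes = {"a": 0.2, "b": 0.4, "c": 0.3, **{f"u{i}": 2.0 for i in range(10)}}
    directions = {"a": "down", "b": "down", "c": "down", **{f"u{i}": "up" for i in range(10)}}
    de = de_for_signature("d", genes, directions)
    sig = trim_signature(de, set(genes), RunConfig())
    assert sig.down == ["a", "c", "b"]


# ---------------------------------------------------------------------------
# KS enrichment score
# ---------------------------------------------------------------------------

def test_ks_hand_example():
    assert ks_enrichment_score([1, 10], 10) == pytest.approx(-0.5)


@pytest.mark.parametrize("t,n", [(1, 5), (3, 10), (5, 50), (50, 1000)])
def test_ks_closed_forms_top_and_bottom(t, n):
    # top-t ranks maximise the a branch at j=t; bottom-t ranks maximise
    # the b branch at j=1, giving the extra 1/N of the b convention
    top = list(range(1, t + 1))
    bottom = list(range(n - t + 1, n + 1))
    assert ks_enrichment_score(top, n) == pytest.approx(1 - t / n)
    assert ks_enrichment_score(bottom, n) == pytest.approx(-(1 - (t - 1) / n))


def test_ks_equals_oracle_exhaustive_small_n():
    """Exact equality with the running-sum oracle for every subset, N <= 9."""
    for n in range(1, 10):
        for t in range(1, n + 1):
            for ranks in combinations(range(1, n + 1), t):
                assert ks_enrichment_score(list(ranks), n) == brute_force_es(ranks, n)


def test_ks_equals_oracle_random_up_to_50():
    rng = np.random.default_rng(0)
    for n in range(10, 51):
        for _ in range(5):
            t = int(rng.integers(1, n + 1))
            ranks = rng.choice(n, size=t, replace=False) + 1
            assert ks_enrichment_score(ranks.tolist(), n) == brute_force_es(ranks, n)


def test_ks_reversal_antisymmetry():
    """Reversing a profile's rank order negates es.

    Under the a/b convention the reversal maps the branch maxima exactly
    as a' = b - 1/N and b' = a + 1/N, so a top-enriched set (a branch
    wins) always flips to bottom-enriched with magnitude shifted by 1/N,
    and a clearly bottom-enriched set (b - a > 2/N) flips to
    top-enriched likewise; only bimodal near-ties escape the sign flip.
    The exact relation is asserted for every set.
    """
    rng = np.random.default_rng(1)
    for _ in range(60):
        n = int(rng.integers(5, 40))
        t = int(rng.integers(1, n))
        ranks = (rng.choice(n, size=t, replace=False) + 1).tolist()
        r = sorted(ranks)
        a = max(j / t - rj / n for j, rj in enumerate(r, start=1))
        b = max(rj / n - (j - 1) / t for j, rj in enumerate(r, start=1))
        es = ks_enrichment_score(ranks, n)
        es_rev = ks_enrichment_score([n + 1 - x for x in ranks], n)
        a_rev, b_rev = b - 1 / n, a + 1 / n
        expected = a_rev if a_rev > b_rev else -b_rev
        assert es_rev == pytest.approx(expected, abs=1e-12)
        if es > 0:  # top-enriched always flips
            assert es_rev < 0
            assert es_rev == pytest.approx(-es, abs=1.0 / n + 1e-12)
        elif b - a > 2.0 / n + 1e-9:  # clearly bottom-enriched always flips
            assert es_rev > 0
            assert es_rev == pytest.approx(-es, abs=1.0 / n + 1e-12)


def test_ks_rejects_bad_ranks():
    with pytest.raises(ValueError):
        ks_enrichment_score([0, 3], 10)
    with pytest.raises(ValueError):
        ks_enrichment_score([2, 2], 10)
    with pytest.raises(ValueError):
        ks_enrichment_score([], 10)


# ---------------------------------------------------------------------------
# connectivity score
# ---------------------------------------------------------------------------

def catalogue_with(profile_order):
    universe = sorted(profile_order)
    idx = {g: i for i, g in enumerate(universe)}
    return DrugProfileCatalogue(
        gene_universe=universe,
        profiles={"drug": np.array([idx[g] for g in profile_order])},
    )


def test_same_sign_gives_zero():
    # up and down genes both at the top of the profile
    order = ["u1", "u2", "d1", "d2"] + [f"x{i}" for i in range(16)]
    cat = catalogue_with(order)
    sig = Signature("ds", up=["u1", "u2"], down=["d1", "d2"],
                    valid_up_count=2, valid_down_count=2)
    rec = connectivity_score(sig, "drug", cat)
    assert rec.es_up > 0 and rec.es_down > 0
    assert rec.score == 0.0


def test_planted_perfect_reverser_scores_minus_95():
    """50 up genes at the bottom, 50 down genes at the top of N=1000.

    es_down = 1 - t/N = 0.95 exactly; es_up = -(1 - (t-1)/N) = -0.951
    (the b branch carries an extra 1/N), so the combined score is
    100*(es_up - es_down)/2 = -95.05 — the continuous-limit value -95
    plus the discrete 1/N correction.
    """
    n = 1000
    up = [f"u{i:02d}" for i in range(50)]
    down = [f"d{i:02d}" for i in range(50)]
    rest = [f"x{i:03d}" for i in range(n - 100)]
    cat = catalogue_with(down + rest + up)
    sig = Signature("ds", up=up, down=down, valid_up_count=50, valid_down_count=50)
    rec = connectivity_score(sig, "drug", cat)
    assert rec.es_up == pytest.approx(-0.951)
    assert rec.es_down == pytest.approx(0.95)
    assert rec.score == pytest.approx(-95.05)
    assert rec.score == pytest.approx(-95.0, abs=0.1)


def test_empty_down_uses_up_only():
    n = 100
    up = [f"u{i}" for i in range(10)]
    rest = [f"x{i}" for i in range(n - 10)]
    cat = catalogue_with(rest + up)  # up genes at the bottom
    sig = Signature("ds", up=up, down=[], valid_up_count=10, valid_down_count=0)
    rec = connectivity_score(sig, "drug", cat)
    assert rec.es_down is None
    assert rec.score == pytest.approx(100 * rec.es_up) and rec.score < 0


def test_random_profiles_mean_score_near_zero():
    rng = np.random.default_rng(2)
    n = 200
    universe = [f"g{i:03d}" for i in range(n)]
    cat = DrugProfileCatalogue(
        gene_universe=universe,
        profiles={f"d{i}": rng.permutation(n) for i in range(1000)},
    )
    sig = Signature("ds", up=universe[:30], down=universe[30:60],
                    valid_up_count=30, valid_down_count=30)
    from crosstx.connectivity import score_catalogue

    scores = [r.score for r in score_catalogue(sig, cat)]
    assert abs(np.mean(scores)) < 5.0
    assert max(np.abs(scores)) <= 100.0


# ---------------------------------------------------------------------------
# reverser selection and candidate overlap
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "score, included",
    [(-80.0, True), (-100.0, True), (-79.9, False), (90.0, False), (-90.0, True)],
)
def test_select_reversers_closed_window(score, included):
    recs = [ConnectivityRecord("d", -0.9, 0.9, score)]
    got = select_reversers(recs, RunConfig())
    assert (got == ["d"]) is included


def test_overlap_candidates_counting():
    lists = {
        "ds1": ["a", "b", "c"],
        "ds2": ["a", "b"],
        "ds3": ["a", "c"],
        "ds4": ["a", "b"],
    }
    interested, counts = overlap_candidates(lists, min_datasets=4)
    assert interested == ["a"]
    assert counts["a"] == 4 and counts["b"] == 3
    interested3, _ = overlap_candidates(lists, min_datasets=3)
    assert interested3 == ["a", "b"]  # sorted by count then name


def test_single_compound_lists_dropped_before_counting():
    lists = {
        "ds1": ["a", "b"],
        "ds2": ["a", "b"],
        "ds3": ["a"],  # single compound: carries no overlap information
    }
    interested, counts = overlap_candidates(lists, min_datasets=2)
    assert counts["a"] == 2  # ds3 did not contribute
    assert interested == ["a", "b"]


def test_overlap_no_surviving_datasets_is_error():
    with pytest.raises(ValueError):
        overlap_candidates({"ds1": ["a"], "ds2": []}, min_datasets=1)
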