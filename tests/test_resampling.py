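import numpy as np
import pandas as pd
import pytest

from episelect.resampling import (EmpiricalTest, colocalization_test,
                                  merge_sirna_targets, neighbor_distance_test,
                                  shared_sites_test)


def test_merge_sirna_boundary():
    # 9 bp between -> merged; exactly 10 bp -> kept separate (strict reading)
    assert merge_sirna_targets([(100, 123), (133, 156)]) == [(100, 156)]
    assert merge_sirna_targets([(100, 123), (134, 157)]) == [(100, 123), (134, 157)]
    assert merge_sirna_targets([(100, 123), (134, 157)], strict=False) == [(100, 157)]
    assert merge_sirna_targets([(5, 28)]) == [(5, 28)]
    assert merge_sirna_targets([]) == []


def test_merge_sirna_output_disjoint():
    rng = np.random.default_rng(2)
    starts = np.sort(rng.integers(1, 5000, size=100))
    ivs = [(int(s), int(s) + 23) for s in starts]
    merged = merge_sirna_targets(ivs)
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        assert s2 > e1


def test_empirical_p_never_zero_and_add_one_rule():
    t = EmpiricalTest(observed=10.0, null_draws=np.zeros(499), direction="enrichment")
    assert t.empirical_p == pytest.approx(1 / 500)
    t = EmpiricalTest(observed=0.0, null_draws=np.ones(499), direction="enrichment")
    assert t.empirical_p == 1.0


def test_neighbor_distance_clustered_hits_floor():
    rng = np.random.default_rng(4)
    tested = np.sort(rng.choice(1_000_000, size=20_000, replace=False))
    # 10 tight clusters of 20 DMCs each
    dmc = np.concatenate([c + np.arange(0, 40, 2) for c in
                          np.arange(10) * 90_000 + 1000])
    test, hist = neighbor_distance_test(dmc, tested, n_draws=200, seed=0)
    assert test.empirical_p == pytest.approx(1 / 201)
    assert hist["count"].sum() == len(dmc) - 1


def test_neighbor_distance_errors():
    with pytest.raises(ValueError):
        neighbor_distance_test([100], np.arange(1000), n_draws=10, seed=0)
    with pytest.raises(ValueError):
        neighbor_distance_test([100, 200], np.arange(1000), n_draws=0, seed=0)


def _tested_frame(rng, n=2000, span=1_000_000):
    return pd.DataFrame({
        "chrom": "chr1",
        "pos": np.sort(rng.choice(span, size=n, replace=False)),
        "context": rng.choice(["CG", "CHH"], size=n),
    })


def test_colocalization_maximal_enrichment_bound():
    rng = np.random.default_rng(6)
    tested = _tested_frame(rng)
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [1000]})
    inside = tested[tested["pos"] <= 1000]
    if len(inside) < 3:  # ensure some queries exist inside
        extra = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30],
                              "context": ["CG", "CG", "CHH"]})
        tested = pd.concat([tested, extra], ignore_index=True)
        inside = tested[tested["pos"] <= 1000]
    res = colocalization_test(inside, regions, tested, n_draws=500, seed=1)
    assert res["cooccurrence"].empirical_p == pytest.approx(1 / 501)
    assert res["distance"].empirical_p == pytest.approx(1 / 501)


def test_colocalization_preserves_stratum_counts():
    rng = np.random.default_rng(8)
    tested = _tested_frame(rng, n=400)
    # query = the whole tested set -> every null draw is exactly the tested set
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [500_000]})
    res = colocalization_test(tested, regions, tested, n_draws=30, seed=2)
    # observed equals every null draw -> p = (1 + n)/(n + 1) = 1
    assert res["cooccurrence"].empirical_p == 1.0
    assert np.all(res["cooccurrence"].null_draws == res["cooccurrence"].observed)


def test_colocalization_requires_regions_and_strata():
    rng = np.random.default_rng(9)
    tested = _tested_frame(rng, n=100)
    with pytest.raises(ValueError, match="empty target"):
        colocalization_test(tested.head(10), pd.DataFrame(columns=["chrom", "start", "end"]),
                            tested, n_draws=5, seed=0)
    small = tested.head(5).assign(context="CG")
    biased = tested.assign(context="CHH")
    with pytest.raises(ValueError, match="stratum"):
        colocalization_test(small, pd.DataFrame({"chrom": ["chr1"], "start": [1],
                                                 "end": [10]}),
                            biased, n_draws=5, seed=0)


def test_shared_sites_bounds():
    keys_a = [("chr1", i, "+") for i in range(100)]
    keys_b = [("chr2", i, "+") for i in range(100)]
    t = shared_sites_test(keys_a[:20], keys_b[:20], keys_a, keys_b,
                          n_draws=200, seed=3)
    assert t.observed == 0 and t.empirical_p > 0.9
    # identical DMC sets inside a much larger tested universe -> the observed
    # overlap (50) dwarfs any null draw (mean 50*50/1000 = 2.5)
    universe = [("chr1", i, "+") for i in range(1000)]
    sub = universe[:50]
    t = shared_sites_test(sub, sub, universe, universe, n_draws=200, seed=3)
    assert t.observed == 50
    assert t.empirical_p == pytest.approx(1 / 201)


def test_shared_sites_null_overlap_central():
    rng = np.random.default_rng(10)
    universe = [("chr1", int(p), "+") for p in rng.choice(10_000, 2000, replace=False)]
    a = [universe[i] for i in rng.choice(2000, 200, replace=False)]
    b = [universe[i] for i in rng.choice(2000, 200, replace=False)]
    t = shared_sites_test(a, b, universe, universe, n_draws=300, seed=5)
    lo, hi = np.quantile(t.null_draws, [0.005, 0.995])
    assert lo <= t.observed <= hi
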