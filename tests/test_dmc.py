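import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episelect.dmc import (call_dmcs, dmc_table, fit_population_model,
                           merge_dmrs, merge_dmrs_by_chromosome, snp_like_scan)

POPS = np.array(["D0"] * 8 + ["D1"] * 4 + ["D5"] * 4 + ["D6"] * 4)


def oneway_ss_oracle(y, pops):
    """Between-group SS of a one-way ANOVA from group means (independent route)."""
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    grand = y[ok].mean()
    ss = 0.0
    for g in np.unique(pops):
        v = y[ok & (pops == g)]
        ss += len(v) * (v.mean() - grand) ** 2
    return ss


def contrast_t_oracle(y, pops):
    """p for the ancestral-vs-selected contrast via an explicit OLS t-test."""
    y = np.asarray(y, dtype=float)
    groups = ["D0", "D1", "D5", "D6"]
    X = np.column_stack([np.asarray(pops) == g for g in groups]).astype(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - 4
    mse = resid @ resid / df
    c = np.array([1.0, -1 / 3, -1 / 3, -1 / 3])
    n_g = X.sum(axis=0)
    se = np.sqrt(mse * np.sum(c**2 / n_g))
    t = c @ beta / se
    return 2 * stats.t.sf(abs(t), df)


def test_ss_decomposition_matches_oneway_oracle():
    rng = np.random.default_rng(17)
    y = rng.normal(50, 10, size=(200, 20))
    # sprinkle missing values, keeping every population represented
    y[rng.random(y.shape) < 0.05] = np.nan
    fit = fit_population_model(y, POPS)
    for i in range(len(y)):
        if fit["skipped"].iloc[i]:
            continue
        ss_pop = oneway_ss_oracle(y[i], POPS)
        assert fit["ss_evo"].iloc[i] + fit["ss_rem"].iloc[i] == pytest.approx(
            ss_pop, rel=1e-9, abs=1e-9)


def test_p_evo_matches_explicit_contrast_t_test():
    rng = np.random.default_rng(23)
    y = rng.normal(40, 8, size=(50, 20))
    fit = fit_population_model(y, POPS)
    for i in range(len(y)):
        assert fit["p_evo"].iloc[i] == pytest.approx(contrast_t_oracle(y[i], POPS),
                                                     rel=1e-9)


def test_zero_effect_with_zero_noise_gives_p_one():
    y = np.tile(np.full(20, 30.0), (3, 1))  # all populations identical, no noise
    fit = fit_population_model(y, POPS)
    assert (fit["p_evo"] == 1.0).all() and (fit["p_rem"] == 1.0).all()
    assert fit["degenerate"].all()


def test_shared_selected_shift_detected_and_rempop_quiet():
    rng = np.random.default_rng(31)
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        y = rng.normal(20, 5, size=20)
        y[POPS != "D0"] += 50.0  # same shift in D1/D5/D6
        fit = fit_population_model(y[None, :], POPS)
        if fit["p_evo"].iloc[0] < 1e-6 and fit["p_rem"].iloc[0] > 0.05:
            hits += 1
    # p_rem alone is a null 5%-level test, so ~95% joint success is the truth
    assert hits >= 0.90 * n_rep
    # delta is mean(selected) - mean(ancestral)
    assert fit["delta"].iloc[0] == pytest.approx(50.0, abs=10.0)


def test_single_population_shift_caught_by_rempop():
    rng = np.random.default_rng(37)
    caught = 0
    for _ in range(20):
        y = rng.normal(20, 5, size=20)
        y[POPS == "D1"] += 50.0
        fit = fit_population_model(y[None, :], POPS)
        if fit["p_rem"].iloc[0] < 0.05:
            caught += 1
    assert caught >= 18


def test_population_entirely_missing_site_skipped():
    y = np.random.default_rng(0).normal(size=(1, 20))
    y[0, POPS == "D5"] = np.nan
    fit = fit_population_model(y, POPS)
    assert bool(fit["skipped"].iloc[0])
    assert np.isnan(fit["p_evo"].iloc[0])


@pytest.mark.parametrize("qe,qr,expected", [
    (0.01, 0.20, True),    # evoPOP significant, remPOP not
    (0.01, 0.01, False),   # both significant -> divergence among selected
    (0.06, 0.90, False),   # evoPOP not significant
])
def test_dmc_rule(qe, qr, expected):
    assert call_dmcs([qe], [qr])[0] == expected


# ----------------------------------------------------------------- DMRs


def brute_force_dmrs(positions, min_dmc, max_gap):
    """Independent clustering oracle: split sorted positions at large gaps."""
    pos = sorted(positions)
    clusters, cur = [], []
    for p in pos:
        if cur and p - cur[-1] > max_gap:
            clusters.append(cur)
            cur = []
        cur.append(p)
    if cur:
        clusters.append(cur)
    return [(c[0], c[-1], len(c)) for c in clusters if len(c) >= min_dmc]


def test_merge_dmrs_examples():
    out = merge_dmrs([100, 150, 190], min_dmc=3, max_gap=100)
    assert len(out) == 1
    r = out[0]
    assert (r.start, r.end, r.n_dmc, r.size) == (100, 190, 3, 91)
    assert merge_dmrs([100, 300], min_dmc=2, max_gap=100) == []
    assert merge_dmrs([], min_dmc=1, max_gap=10) == []


def test_merge_dmrs_against_brute_force_random_instances():
    rng = np.random.default_rng(41)
    for _ in range(300):
        n = int(rng.integers(0, 40))
        pos = np.unique(rng.integers(1, 2000, size=n))
        md = int(rng.integers(1, 5))
        mg = int(rng.integers(1, 300))
        got = [(r.start, r.end, r.n_dmc) for r in merge_dmrs(pos, md, mg)]
        assert got == brute_force_dmrs(pos, md, mg)


def test_merge_dmrs_order_invariance_and_monotonicity():
    rng = np.random.default_rng(43)
    pos = rng.choice(10_000, size=200, replace=False)
    a = merge_dmrs(pos, 3, 100)
    b = merge_dmrs(rng.permutation(pos), 3, 100)
    assert a == b
    counts_md = [len(merge_dmrs(pos, md, 100)) for md in (1, 2, 3, 5, 8)]
    assert counts_md == sorted(counts_md, reverse=True)
    counts_mg = [len(merge_dmrs(pos, 3, mg)) for mg in (10, 50, 100, 500)]
    # non-decreasing DMR count is not guaranteed (clusters merge), but the
    # number of DMCs inside DMRs is non-decreasing in max_gap
    dmcs_in = [sum(r.n_dmc for r in merge_dmrs(pos, 3, mg)) for mg in (10, 50, 100, 500)]
    assert dmcs_in == sorted(dmcs_in)


def test_merge_dmrs_mean_delta_tracks_input():
    out = merge_dmrs([10, 20], min_dmc=2, max_gap=50, deltas=[60.0, 40.0])
    assert out[0].mean_delta == pytest.approx(50.0)


# ------------------------------------------------------------- binary scan


def test_snp_like_scan_rules():
    all_high = np.full((1, 20), 0.99)
    assert snp_like_scan(all_high)[0] == 1
    one_mid = all_high.copy()
    one_mid[0, 3] = 0.50
    assert snp_like_scan(one_mid)[0] == 0
    split = np.concatenate([np.full((1, 10), 0.01), np.full((1, 10), 0.99)], axis=1)
    assert snp_like_scan(split, same_tail=True)[0] == 0
    assert snp_like_scan(split, same_tail=False)[0] == 1


def test_snp_like_scan_missing_sites_excluded():
    lv = np.array([[0.99, 0.99, np.nan], [0.01, 0.01, 0.01], [0.5, 0.5, 0.5]])
    count, frac = snp_like_scan(lv)
    assert count == 1 and frac == pytest.approx(0.5)  # 1 of 2 complete sites


# ------------------------------------------------------- integrated calling


def test_dmc_table_recovers_planted_sites(small_sim):
    table, design, truth = small_sim["table"], small_sim["design"], small_sim["truth"]
    g = design.genotypes[0]
    res = dmc_table(table, design, genotype=g)
    called = set(zip(res.loc[res["is_dmc"], "chrom"],
                     res.loc[res["is_dmc"], "pos"],
                     res.loc[res["is_dmc"], "strand"]))
    planted = truth.dmc_keys(g, "shared")
    assert len(planted & called) / len(planted) >= 0.8
    onepop = truth.dmc_keys(g, "onepop")
    assert len(onepop & called) / len(onepop) <= 0.1
    dmrs = merge_dmrs_by_chromosome(res[res["is_dmc"]], min_dmc=2, max_gap=5000)
    assert (dmrs["end"] >= dmrs["start"]).all()
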