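import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episelect.downstream import (accession_two_group_analysis, ddpcr_compare,
                                  ddpcr_log_ratio, ddpcr_ratio_table,
                                  phenotype_anova)
from episelect.simulate import SimulationConfig, simulate_ddpcr, simulate_phenotypes


def qr_sequential_ss_oracle(blocks, y):
    """Sequential SS via an accumulated orthonormal basis (independent route)."""
    n = len(y)
    Q = np.ones((n, 1)) / np.sqrt(n)
    out = []
    for name, cols in blocks:
        added = 0.0
        for j in range(cols.shape[1]):
            v = cols[:, j] - Q @ (Q.T @ cols[:, j])
            norm = np.linalg.norm(v)
            if norm > 1e-10:
                q = v / norm
                added += float((q @ y) ** 2)
                Q = np.column_stack([Q, q])
        out.append((name, added))
    return out


def test_anova_percent_ss_sums_to_100():
    cfg = SimulationConfig(seed=3, pheno_n_per_cell=4)
    table = simulate_phenotypes(cfg)
    rep = phenotype_anova(table, "bolting_day")
    assert rep["percent_of_total_SS"].sum() == pytest.approx(100.0, abs=1e-9)
    assert not rep.loc[rep["term"] == "GEN", "interpretable"].iloc[0]


def test_anova_ss_matches_qr_projection_oracle():
    from episelect.downstream import _design_blocks

    cfg = SimulationConfig(seed=5, pheno_n_per_cell=3)
    table = simulate_phenotypes(cfg)
    y = table["siliques"].to_numpy(float)
    rep = phenotype_anova(table, "siliques").set_index("term")
    oracle = dict(qr_sequential_ss_oracle(_design_blocks(table), y - 0.0))
    # oracle projects raw y; subtract the intercept projection implicitly
    for term, ss in oracle.items():
        assert rep.loc[term, "SS"] == pytest.approx(ss, rel=1e-9, abs=1e-9)


def test_anova_planted_evo_effect_detected():
    cfg = SimulationConfig(seed=7, pheno_n_per_cell=17, pheno_noise_sd=1.0)
    # 2 x 2 x 4 x 17 = 272 individuals, evoPOP shift of 2 residual SD
    table = simulate_phenotypes(cfg, effects={"trait": 2.0})
    rep = phenotype_anova(table, "trait").set_index("term")
    assert rep.loc["evoPOP", "p"] < 1e-3
    assert rep.loc["remPOP", "p"] > 0.001  # no divergence among selected


def test_anova_null_trait_not_significant():
    hits = 0
    for seed in range(5):
        cfg = SimulationConfig(seed=seed, pheno_n_per_cell=5)
        table = simulate_phenotypes(cfg, effects={"trait": 0.0})
        rep = phenotype_anova(table, "trait").set_index("term")
        if rep.loc["evoPOP", "p"] < 0.05:
            hits += 1
    assert hits <= 2


def test_anova_empty_cell_raises():
    cfg = SimulationConfig(seed=1, pheno_n_per_cell=2)
    table = simulate_phenotypes(cfg)
    broken = table[~((table["GEN"] == "G2") & (table["RIL"] == table["RIL"].iloc[0])
                     & (table["POP"] == "D5"))]
    with pytest.raises(ValueError, match="empty design cells"):
        phenotype_anova(broken, "bolting_day")


def test_ddpcr_log_ratio_hand_computed():
    assert ddpcr_log_ratio(7, (3, 1)) == pytest.approx(3 - (2 + 1) / 2)  # 1.5
    assert ddpcr_log_ratio(0, (0, 0)) == 0.0
    assert ddpcr_log_ratio(41, (41, 41)) == 0.0
    assert ddpcr_log_ratio(7, (3, 1)) == ddpcr_log_ratio(7, (1, 3))  # ref exchange


def test_ddpcr_identical_groups_null():
    rows = []
    for pop in ("D0", "D1"):
        for i in range(3):
            rows += [
                {"sample_id": f"{pop}{i}", "population": pop, "gene": "G",
                 "rt_plus_count": 100 + i, "is_reference": False},
                {"sample_id": f"{pop}{i}", "population": pop, "gene": "R1",
                 "rt_plus_count": 50, "is_reference": True},
                {"sample_id": f"{pop}{i}", "population": pop, "gene": "R2",
                 "rt_plus_count": 60, "is_reference": True},
            ]
    ratios = ddpcr_ratio_table(pd.DataFrame(rows))
    res = ddpcr_compare(ratios, grouping="evo")
    assert res["fold_change"].iloc[0] == pytest.approx(1.0)
    assert res["p_adj"].iloc[0] == pytest.approx(1.0)


def test_ddpcr_planted_shift_recovered():
    hits = 0
    for seed in range(10):
        cfg = SimulationConfig(seed=seed)
        t = simulate_ddpcr(cfg, {"G": 8.0}, log2_sd=0.5)
        res = ddpcr_compare(ddpcr_ratio_table(t), grouping="evo")
        fc = res["fold_change"].iloc[0]
        if 4.0 <= fc <= 16.0 and res["p_adj"].iloc[0] < 0.05:
            hits += 1
    assert hits >= 9


def test_ddpcr_pairwise_adjusts_within_gene():
    cfg = SimulationConfig(seed=2)
    t = simulate_ddpcr(cfg, {"G": 4.0, "H": 1.0})
    res = ddpcr_compare(ddpcr_ratio_table(t), grouping="pairwise")
    assert set(res["gene"]) == {"G", "H"}
    assert (res.groupby("gene")["comparison"].count() == 6).all()  # C(4,2)
    assert (res["p_adj"] >= res["p"] - 1e-12).all()


def test_ddpcr_ttest_matches_scipy():
    rng = np.random.default_rng(6)
    a, b = rng.normal(0, 1, 5), rng.normal(1, 1.5, 7)
    rows = []
    for i, v in enumerate(a):
        rows.append({"sample_id": f"a{i}", "population": "D0", "gene": "G",
                     "log2_ratio": v})
    for i, v in enumerate(b):
        rows.append({"sample_id": f"b{i}", "population": "D1", "gene": "G",
                     "log2_ratio": v})
    res = ddpcr_compare(pd.DataFrame(rows), grouping="evo")
    expected = stats.ttest_ind(b, a, equal_var=False).pvalue
    assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-10)


# ------------------------------------------------ accession two-group split


def test_accession_split_recovers_bimodal_groups():
    rng = np.random.default_rng(12)
    low = rng.normal(0.05, 0.02, 60)
    high = rng.normal(0.90, 0.05, 61)
    meth = np.concatenate([low, high])
    truth = np.concatenate([np.zeros(60), np.ones(61)])
    expr = np.where(truth == 0, 13.0, 1.0) * (1 + rng.normal(0, 0.05, 121))
    res = accession_two_group_analysis(meth, pd.DataFrame({"expression": expr}))
    assert res.bimodal
    np.testing.assert_array_equal(res.labels, truth)
    assert 0.05 < res.threshold < 0.90
    assert res.tests.loc[0, "p_adj"] < 1e-3  # 13-fold difference detected


def test_accession_split_degenerate_flagged():
    meth = np.full(20, 0.4)
    res = accession_two_group_analysis(meth, pd.DataFrame({"x": np.arange(20.0)}))
    assert not res.bimodal
    assert res.threshold == 0.5
    assert (res.labels == 0).all()


def test_accession_split_unimodal_falls_back():
    rng = np.random.default_rng(14)
    meth = rng.normal(0.4, 0.05, 80)  # one mode
    res = accession_two_group_analysis(meth, pd.DataFrame({"x": rng.normal(size=80)}))
    assert not res.bimodal
    assert res.threshold == 0.5
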