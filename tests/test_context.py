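import numpy as np
import pandas as pd
import pytest

from episelect.genomic_context import (FeatureSet, assign_context,
                                       context_proportions, metagene_profile,
                                       summarize_gene_dmcs)

COLS = ["chrom", "start", "end", "strand", "feature_class", "feature_id", "gene_id"]


def fs(rows, lengths=None):
    return FeatureSet(pd.DataFrame(rows, columns=COLS),
                      lengths or {"chr1": 100_000})


def test_single_exon_full_score():
    f = fs([("chr1", 100, 200, "+", "exon", "e1", "gA")])
    assert assign_context("chr1", 150, f) == {"exon": 1.0}


def test_overlapping_features_split_score():
    f = fs([("chr1", 100, 200, "+", "exon", "e1", "gA"),
            ("chr1", 150, 300, "-", "intron", "i1", "gB")])
    assert assign_context("chr1", 160, f) == {"exon": 0.5, "intron": 0.5}


def test_no_overlap_is_intergenic():
    f = fs([("chr1", 100, 200, "+", "exon", "e1", "gA")])
    assert assign_context("chr1", 5000, f) == {"intergenic": 1.0}


def test_scores_always_sum_to_one(small_sim):
    features = small_sim["annotation"].with_flanks()
    rng = np.random.default_rng(1)
    for pos in rng.integers(1, 300_000, size=200):
        scores = assign_context("chr1", int(pos), features)
        assert sum(scores.values()) == pytest.approx(1.0)


def test_flanks_truncated_at_chromosome_ends():
    f = fs([("chr1", 400, 900, "+", "gene", "gA", "gA")],
           lengths={"chr1": 1200}).with_flanks()
    up = f.of_class("upstream_1kb").iloc[0]
    down = f.of_class("downstream_1kb").iloc[0]
    assert (up["start"], up["end"]) == (1, 399)
    assert (down["start"], down["end"]) == (901, 1200)


def test_gene_summary_counts_and_mean_delta():
    f = fs([("chr1", 1000, 3000, "+", "gene", "gA", "gA"),
            ("chr1", 9000, 9500, "+", "gene", "gB", "gB")])
    dmcs = pd.DataFrame({
        "chrom": ["chr1"] * 3, "pos": [1500, 2500, 3500],
        "context": ["CG", "CG", "CHH"], "delta": [60.0, 40.0, -10.0],
    })
    out = summarize_gene_dmcs(dmcs, f)
    ga = out[out["gene_id"] == "gA"].iloc[0]
    # 3500 is inside the 1-kb downstream flank of gA
    assert ga["n_dmc"] == 3
    assert ga["mean_delta"] == pytest.approx((60 + 40 - 10) / 3)
    assert ga["n_CG"] == 2 and ga["n_CHH"] == 1
    assert "gB" not in set(out["gene_id"])  # no DMC -> absent


def test_dmc_in_two_gene_windows_counts_for_both():
    f = fs([("chr1", 1000, 2000, "+", "gene", "gA", "gA"),
            ("chr1", 2500, 3500, "+", "gene", "gB", "gB")])
    dmcs = pd.DataFrame({"chrom": ["chr1"], "pos": [2250],
                         "context": ["CG"], "delta": [50.0]})
    out = summarize_gene_dmcs(dmcs, f)
    assert set(out["gene_id"]) == {"gA", "gB"}


def test_context_proportions():
    sites = pd.DataFrame({"context": ["CG"] * 9 + ["CHH"]})
    assert context_proportions(sites) == {"CG": 0.9, "CHG": 0.0, "CHH": 0.1}
    assert context_proportions(pd.DataFrame({"context": ["CHH"] * 4})) == \
        {"CG": 0.0, "CHG": 0.0, "CHH": 1.0}
    with pytest.raises(ValueError):
        context_proportions(pd.DataFrame({"context": []}))


def test_generator_context_mixture_recovered(small_sim):
    table, config = small_sim["table"], small_sim["config"]
    props = context_proportions(table.sites)
    for p, expected in zip((props["CG"], props["CHG"], props["CHH"]),
                           config.context_probs):
        se = np.sqrt(expected * (1 - expected) / table.n_sites)
        assert abs(p - expected) < 5 * se


# -------------------------------------------------------------- metagene


def _metagene_fixture():
    rows = [("chr1", 5000, 6999, "+", "gene", "g1", "g1"),
            ("chr1", 20_000, 21_999, "-", "gene", "g2", "g2"),
            ("chr1", 40_000, 40_098, "+", "gene", "g99", "g99"),   # 99 bp
            ("chr1", 500, 2000, "+", "gene", "gEnd", "gEnd")]      # near chrom start
    return fs(rows, lengths={"chr1": 50_000})


def test_metagene_exclusion_rules():
    f = _metagene_fixture()
    sites = pd.DataFrame({"chrom": ["chr1"], "pos": [5500]})
    prof = metagene_profile(sites, f)
    assert prof.n_genes == 2  # 99-bp gene and near-end gene excluded


def test_metagene_conservation_and_flatness():
    f = _metagene_fixture()
    rng = np.random.default_rng(8)
    pos = np.sort(rng.integers(1, 50_000, size=20_000))
    sites = pd.DataFrame({"chrom": "chr1", "pos": pos})
    prof = metagene_profile(sites, f)
    in_body = ((pos >= 5000) & (pos <= 6999)).sum() + \
        ((pos >= 20_000) & (pos <= 21_999)).sum()
    assert prof.body_counts.sum() == in_body
    # uniform scatter -> flat profile: every bin within 4 SE of the mean
    mean = prof.body_counts.mean()
    se = np.sqrt(mean)
    assert (np.abs(prof.body_counts - mean) < 4 * se).all()


def test_metagene_strand_flip_mirrors_profile():
    rows = [("chr1", 5000, 6999, "+", "gene", "g1", "g1")]
    f_plus = fs(rows, lengths={"chr1": 50_000})
    rows_minus = [("chr1", 5000, 6999, "-", "gene", "g1", "g1")]
    f_minus = fs(rows_minus, lengths={"chr1": 50_000})
    # sites piled at the left end of the gene
    sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(5000, 5100)})
    p_plus = metagene_profile(sites, f_plus)
    p_minus = metagene_profile(sites, f_minus)
    np.testing.assert_allclose(p_plus.body_counts, p_minus.body_counts[::-1])
    np.testing.assert_allclose(p_plus.upstream, p_minus.downstream[::-1])


def test_gff3_round_trip(tmp_path, small_sim):
    features = small_sim["annotation"]
    p = tmp_path / "ann.gff3"
    features.to_gff3(p)
    back = FeatureSet.from_gff3(p)
    assert back.chromosome_lengths == features.chromosome_lengths
    a = features.table.sort_values(["chrom", "start", "feature_id"]).reset_index(drop=True)
    b = back.table.sort_values(["chrom", "start", "feature_id"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a[["chrom", "start", "end", "feature_class"]],
                                  b[["chrom", "start", "end", "feature_class"]])
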