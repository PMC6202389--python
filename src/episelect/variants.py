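"""Pooled-resequencing SNP filter and TE-insertion evidence rules.

Candidate SNPs between 2 ancestral and 7 selected lines must pass three
rules: per-line coverage inside [20, 200]; a two-sided Fisher exact test on
pooled ancestral vs pooled selected allele counts at P < 0.05; and a
majority-allele difference between at least 4 selected lines (> 50%) and at
least one ancestral line.  Novel TE insertions need >= 30 supporting read
pairs, >= 4 kb distance to the reference TE copy, and presence in >= 4
selected lines while absent from *both* ancestral lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def fisher_allele_test(counts_a, counts_b) -> float:
    """Two-sided Fisher exact p for a 2x2 allele-count table.

    ``counts_a``/``counts_b`` are (major, minor) counts for the two groups.
    """
    table = np.array([list(counts_a), list(counts_b)], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def snp_candidate_filter(allele_counts: pd.DataFrame,
                         min_cov: int = 20, max_cov: int = 200,
                         min_divergent_selected: int = 4,
                         alpha: float = 0.05,
                         pooling: str = "pooled") -> pd.DataFrame:
    """Apply the coverage / Fisher / divergent-line rules to an allele table.

    ``allele_counts`` is long-format with columns chrom/pos/line/count_major/
    count_minor/coverage; lines named ``anc_*`` are ancestral, ``sel_*``
    selected.  The coverage rule is applied per line (every line must sit in
    the band — the stricter reading of a position-level rule).  ``pooling``
    chooses the Fisher table: "pooled" sums counts over each group (default);
    "worst_line" takes the maximum p over per-line ancestral-vs-selected
    pooled tests.  Returns the retained positions with p and the divergent
    line count.
    """
    rows = []
    for (chrom, pos), grp in allele_counts.groupby(["chrom", "pos"], sort=True):
        cov = grp["coverage"].to_numpy()
        if (cov < min_cov).any() or (cov > max_cov).any():
            continue
        anc = grp[grp["line"].str.startswith("anc_")]
        sel = grp[grp["line"].str.startswith("sel_")]
        if anc.empty or sel.empty:
            continue
        a = (int(anc["count_major"].sum()), int(anc["count_minor"].sum()))
        s = (int(sel["count_major"].sum()), int(sel["count_minor"].sum()))
        if sum(a) + sum(s) == 0:
            continue
        if pooling == "pooled":
            p = fisher_allele_test(a, s)
        elif pooling == "worst_line":
            p = max(
                fisher_allele_test(a, (int(r["count_major"]), int(r["count_minor"])))
                for _, r in sel.iterrows()
            )
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        if p >= alpha:
            continue
        anc_major = (anc["count_minor"] > anc["count_major"]).to_numpy()
        sel_major = (sel["count_minor"] > sel["count_major"]).to_numpy()
        divergent = sum(int((sm != anc_major).any()) for sm in sel_major)
        if divergent < min_divergent_selected:
            continue
        rows.append({"chrom": chrom, "pos": pos, "p": p,
                     "n_divergent_selected": divergent})
    return pd.DataFrame(rows, columns=["chrom", "pos", "p", "n_divergent_selected"])


def te_insertion_filter(evidence: pd.DataFrame, min_pairs: int = 30,
                        min_distance: int = 4000,
                        min_selected: int = 4) -> pd.DataFrame:
    """Accept candidate TE insertions meeting the pair/distance/line rules.

    ``evidence`` is long-format with columns te_id/chrom/pos/line/
    supporting_pairs/ref_distance; ``anc_*`` lines are ancestral.  A line
    carries the insertion when its supporting pairs reach ``min_pairs`` and
    its distance to the reference TE location is >= ``min_distance``.
    Accepted candidates are present in >= ``min_selected`` selected lines
    and in *neither* ancestral line.
    """
    rows = []
    for (te_id, chrom, pos), grp in evidence.groupby(["te_id", "chrom", "pos"], sort=True):
        supported = grp[(grp["supporting_pairs"] >= min_pairs)
                        & (grp["ref_distance"] >= min_distance)]
        anc_carriers = supported["line"].str.startswith("anc_").sum()
        sel_carriers = supported["line"].str.startswith("sel_").sum()
        if anc_carriers == 0 and sel_carriers >= min_selected:
            rows.append({"te_id": te_id, "chrom": chrom, "pos": pos,
                         "n_selected_lines": int(sel_carriers)})
    return pd.DataFrame(rows, columns=["te_id", "chrom", "pos", "n_selected_lines"])
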