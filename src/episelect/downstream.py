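"""Phenotype ANOVA, ddPCR relative expression, and two-group accession splits.

The phenotype model is a crossed factorial GEN x RIL x POP fit by OLS with
sequential (type-I) sums of squares: GEN enters first as a block (its SS is
confounded with time and not interpreted), then RIL, then POP decomposed
into the 1-df evoPOP contrast (D0 vs mean of D1/D5/D6) and the 2-df remPOP
remainder, then all interactions.  Each term's share of the total SS is
reported alongside F and p.

ddPCR expression is summarised as log2 ratios to the geometric mean of >= 2
reference genes: log2(test + 1) minus the mean of log2(ref + 1) — the
log-space mean *is* the geometric-mean construction.  Group comparisons are
two-sided t-tests on the ratios with Benjamini-Hochberg adjustment within
each gene across its comparisons; fold-change = 2^(mean difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ("bolting_day", "rosette_leaves", "branches", "siliques")


# ------------------------------------------------------------ phenotype ANOVA


def _design_blocks(table: pd.DataFrame, ancestral: str = "D0"):
    """Ordered (name, columns) blocks for the sequential fit."""
    gen = pd.get_dummies(table["GEN"], drop_first=True).to_numpy(float)
    ril = pd.get_dummies(table["RIL"], drop_first=True).to_numpy(float)
    pops = sorted(table["POP"].unique())
    if ancestral not in pops:
        raise ValueError(f"ancestral population {ancestral!r} absent")
    sel = [p for p in pops if p != ancestral]
    evo = np.where(table["POP"] == ancestral, 1.0, -1.0 / len(sel))[:, None]
    rem = np.stack(
        [np.where(table["POP"] == p, 1.0, 0.0) - np.where(table["POP"] == sel[-1], 1.0, 0.0)
         for p in sel[:-1]], axis=1) if len(sel) > 1 else np.empty((len(table), 0))
    blocks = [("GEN", gen), ("RIL", ril), ("evoPOP", evo), ("remPOP", rem)]
    inter = []
    for (na, a), (nb, b) in [(blocks[0], blocks[1]), (blocks[0], blocks[2]),
                             (blocks[0], blocks[3]), (blocks[1], blocks[2]),
                             (blocks[1], blocks[3])]:
        inter.append((f"{na}:{nb}", _interact(a, b)))
    inter.append(("GEN:RIL:evoPOP", _interact(_interact(gen, ril), evo)))
    inter.append(("GEN:RIL:remPOP", _interact(_interact(gen, ril), rem)))
    return blocks + inter


def _interact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.size == 0 or b.size == 0:
        return np.empty((a.shape[0], 0))
    return np.concatenate([a * b[:, [j]] for j in range(b.shape[1])], axis=1)


def phenotype_anova(table: pd.DataFrame, trait: str,
                    ancestral: str = "D0") -> pd.DataFrame:
    """Sequential-SS ANOVA report for one trait.

    Returns one row per term (plus residual) with df, SS, percent of total
    SS, F, p.  The GEN block row carries ``interpretable=False``.  Raises if
    any GEN x RIL x POP cell is empty.
    """
    if trait not in table.columns:
        raise KeyError(trait)
    cells = table.groupby(["GEN", "RIL", "POP"]).size()
    full = set(
        (g, r, p)
        for g in table["GEN"].unique()
        for r in table["RIL"].unique()
        for p in table["POP"].unique()
    )
    missing = sorted(full - set(cells.index))
    if missing:
        raise ValueError(f"empty design cells: {missing}")
    y = table[trait].to_numpy(float)
    n = len(y)
    blocks = _design_blocks(table, ancestral)
    X = np.ones((n, 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    ss_total = rss_prev
    rows = []
    for name, cols in blocks:
        if cols.shape[1] == 0:
            continue
        X = np.concatenate([X, cols], axis=1)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        rows.append((name, cols.shape[1], rss_prev - rss))
        rss_prev = rss
    df_res = n - X.shape[1]
    mse = rss_prev / df_res
    out = []
    for name, df, ss in rows:
        F = (ss / df) / mse if mse > 0 else np.inf
        p = float(stats.f.sf(F, df, df_res))
        out.append({"term": name, "df": df, "SS": ss,
                    "percent_of_total_SS": 100.0 * ss / ss_total,
                    "F": F, "p": p, "interpretable": name != "GEN"})
    out.append({"term": "residual", "df": df_res, "SS": rss_prev,
                "percent_of_total_SS": 100.0 * rss_prev / ss_total,
                "F": np.nan, "p": np.nan, "interpretable": True})
    return pd.DataFrame(out)


# ------------------------------------------------------------------ ddPCR


def ddpcr_log_ratio(rt_plus: float, references) -> float:
    """log2(test + 1) - mean over references of log2(ref + 1).

    Subtracting the log-space mean of the references equals dividing by
    their geometric mean.  Invariant under permuting the references.
    """
    refs = np.asarray(references, dtype=float)
    if refs.size < 2:
        raise ValueError("need >= 2 reference genes")
    return float(np.log2(rt_plus + 1.0) - np.log2(refs + 1.0).mean())


def ddpcr_ratio_table(ddpcr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample log2 ratios of every test gene to the reference geometric mean.

    Expects columns sample_id/population/gene/rt_plus_count/is_reference.
    RT- counts are carried through for the contamination check but never
    enter the ratio.
    """
    rows = []
    for sid, grp in ddpcr.groupby("sample_id", sort=True):
        refs = grp.loc[grp["is_reference"], "rt_plus_count"].to_numpy(float)
        pop = grp["population"].iloc[0]
        for _, r in grp[~grp["is_reference"]].iterrows():
            rows.append({"sample_id": sid, "population": pop, "gene": r["gene"],
                         "log2_ratio": ddpcr_log_ratio(r["rt_plus_count"], refs)})
    return pd.DataFrame(rows)


def ddpcr_compare(ratios: pd.DataFrame, grouping: str = "evo",
                  ancestral: str = "D0") -> pd.DataFrame:
    """Fold-change and adjusted p per gene.

    ``grouping="evo"``: selected (all non-ancestral populations pooled) vs
    ancestral, one comparison per gene.  ``grouping="pairwise"``: all
    population pairs, BH-adjusted within each gene across its comparisons.
    Fold-change is 2^(mean log2-ratio difference); t-tests are two-sided
    with Welch correction.
    """
    rows = []
    for gene, grp in ratios.groupby("gene", sort=True):
        comparisons = []
        if grouping == "evo":
            a = grp.loc[grp["population"] == ancestral, "log2_ratio"].to_numpy()
            b = grp.loc[grp["population"] != ancestral, "log2_ratio"].to_numpy()
            comparisons.append(("selected_vs_ancestral", b, a))
        elif grouping == "pairwise":
            pops = sorted(grp["population"].unique())
            for i, p1 in enumerate(pops):
                for p2 in pops[i + 1:]:
                    comparisons.append(
                        (f"{p2}_vs_{p1}",
                         grp.loc[grp["population"] == p2, "log2_ratio"].to_numpy(),
                         grp.loc[grp["population"] == p1, "log2_ratio"].to_numpy()))
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        pvals, recs = [], []
        for name, b, a in comparisons:
            if len(a) < 2 or len(b) < 2:
                raise ValueError("need >= 2 samples per group")
            diff = float(b.mean() - a.mean())
            if np.isclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
                p = 1.0 if np.isclose(diff, 0.0) else 0.0  # degenerate variance
            else:
                p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
            pvals.append(p)
            recs.append((name, diff, p))
        p_adj = _bh(np.array(pvals))
        for (name, diff, p), q in zip(recs, p_adj):
            rows.append({"gene": gene, "comparison": name,
                         "fold_change": float(2.0 ** diff),
                         "log2_fold_change": diff, "p": p, "p_adj": float(q)})
    return pd.DataFrame(rows)


def _bh(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ------------------------------------------- two-group accession analysis


@dataclass
class AccessionSplit:
    labels: np.ndarray       # 0 = low-methylation group, 1 = high
    threshold: float         # midpoint between the two cluster means
    bimodal: bool
    tests: pd.DataFrame      # per-variable two-group comparisons


def _two_means_1d(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact 1-d 2-means by scanning split points of the sorted values."""
    order = np.argsort(x)
    xs = x[order]
    n = len(xs)
    csum = np.cumsum(xs)
    total = csum[-1]
    best_k, best_ss = 1, np.inf
    for k in range(1, n):
        m1, m2 = csum[k - 1] / k, (total - csum[k - 1]) / (n - k)
        ss = (np.sum((xs[:k] - m1) ** 2) + np.sum((xs[k:] - m2) ** 2))
        if ss < best_ss:
            best_k, best_ss = k, ss
    m1 = csum[best_k - 1] / best_k
    m2 = (total - csum[best_k - 1]) / (n - best_k)
    labels = (x > (m1 + m2) / 2.0).astype(int)
    return labels, float((m1 + m2) / 2.0)


def accession_two_group_analysis(methylation: np.ndarray,
                                 variables: pd.DataFrame,
                                 separation_factor: float = 3.5) -> AccessionSplit:
    """Split accessions by average methylation; t-test each variable between groups.

    ``methylation`` holds one average level per accession; ``variables`` has
    one column per response (expression, traits; NaN allowed).  The split is
    exact 1-d 2-means with the midpoint threshold reported.  When the
    cluster separation is below ``separation_factor`` x the pooled
    within-cluster SD (or a cluster is empty), the input is flagged
    non-bimodal and split at the 50% level instead; splitting a single
    Gaussian yields a separation ratio near 2.7, so the default factor of
    3.5 clears unimodal data while genuinely bimodal mixtures score far
    higher.  Variable p-values are
    BH-adjusted across variables.
    """
    x = np.asarray(methylation, dtype=float)
    if len(x) != len(variables):
        raise ValueError("methylation and variables must align")
    if np.allclose(x, x[0]):
        labels = np.zeros(len(x), dtype=int)
        threshold, bimodal = 0.5, False
    else:
        labels, threshold = _two_means_1d(x)
        lo, hi = x[labels == 0], x[labels == 1]
        if len(lo) == 0 or len(hi) == 0:
            labels = (x > 0.5).astype(int)
            threshold, bimodal = 0.5, False
        else:
            pooled_sd = np.sqrt((np.var(lo) * len(lo) + np.var(hi) * len(hi)) / len(x))
            sep = hi.mean() - lo.mean()
            bimodal = bool(sep > separation_factor * max(pooled_sd, 1e-12))
            if not bimodal:
                labels = (x > 0.5).astype(int)
                threshold = 0.5
    rows, pvals = [], []
    for col in variables.columns:
        v = variables[col].to_numpy(float)
        a = v[(labels == 0) & ~np.isnan(v)]
        b = v[(labels == 1) & ~np.isnan(v)]
        if len(a) < 2 or len(b) < 2:
            rows.append((col, np.nan, np.nan))
            pvals.append(np.nan)
            continue
        t = stats.ttest_ind(b, a, equal_var=False)
        rows.append((col, float(b.mean() - a.mean()), float(t.pvalue)))
        pvals.append(float(t.pvalue))
    parr = np.array(pvals, dtype=float)
    adj = np.full(len(parr), np.nan)
    ok = ~np.isnan(parr)
    if ok.any():
        adj[ok] = _bh(parr[ok])
    tests = pd.DataFrame(rows, columns=["variable", "high_minus_low", "p"])
    tests["p_adj"] = adj
    return AccessionSplit(labels, threshold, bimodal, tests)
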