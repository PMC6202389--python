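"""Per-cytosine selection test, DMC calling, DMR consolidation, binary-state scan.

At every cytosine the methylation level (in percent) is modelled by ordinary
least squares on the population factor POP (D0/D1/D5/D6), decomposed into

* ``evoPOP`` — a 1-df contrast of the ancestral population against the mean
  of the selected population means, D0 vs (D1 + D5 + D6)/3;
* ``remPOP`` — the remaining 2 df of differences among D1/D5/D6.

Both share the residual mean square (df = n - 4).  With 8 ancestral and
4+4+4 selected samples the two pieces are orthogonal; for data unbalanced
across the selected populations the decomposition is sequential (type-I)
with evoPOP entered first.  A cytosine is a DMC when evoPOP is significant
but remPOP is not (Storey Q < alpha for evoPOP, Q >= alpha for remPOP): a
consistent ancestral-vs-selected shift that is *shared* by the independently
selected populations, i.e. a signature of selection rather than drift in one
population.  Each genotype is analysed separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CytosineTable, SampleDesign
from .qvalue import storey_qvalues

_ZERO_SS = 1e-12


def fit_population_model(levels: np.ndarray, populations,
                         ancestral: str = "D0") -> pd.DataFrame:
    """Vectorised per-site OLS with the evoPOP/remPOP decomposition.

    ``levels`` is (n_sites, n_samples) with NaN for missing (zero-coverage)
    values; ``populations`` assigns each sample column to a population.
    Returns a DataFrame with columns p_evo, p_rem, delta, ss_evo, ss_rem,
    ss_res, df_res and a boolean ``skipped`` for sites where a population has
    no data at all.  ``delta`` is mean(selected population means) - mean
    (ancestral), in the units of ``levels``.
    """
    y = np.atleast_2d(np.asarray(levels, dtype=float))
    pops = np.asarray(populations)
    if y.shape[1] != pops.size:
        raise ValueError("one population label per sample column required")
    groups = [ancestral] + sorted(g for g in pd.unique(pops) if g != ancestral)
    if len(groups) < 3:
        raise ValueError("need the ancestral and at least two selected populations")
    k_sel = len(groups) - 1

    counts, sums = [], []
    for g in groups:
        cols = pops == g
        if not cols.any():
            raise ValueError(f"population {g!r} has no samples")
        block = y[:, cols]
        counts.append((~np.isnan(block)).sum(axis=1).astype(float))
        sums.append(np.nansum(block, axis=1))
    n_g = np.stack(counts)  # (n_groups, n_sites)
    s_g = np.stack(sums)
    skipped = (n_g == 0).any(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        N = n_g.sum(axis=0)
        Sy = s_g.sum(axis=0)
        Syy = np.nansum(y * y, axis=1)
        x_g = np.array([1.0] + [-1.0 / k_sel] * k_sel)[:, None]
        xbar = (n_g * x_g).sum(axis=0) / N
        Sxy = (s_g * x_g).sum(axis=0) - xbar * Sy
        Sxx = (n_g * x_g * x_g).sum(axis=0) - N * xbar * xbar
        ss_evo = Sxy * Sxy / Sxx
        group_term = np.where(n_g > 0, s_g * s_g / np.where(n_g > 0, n_g, 1.0), 0.0).sum(axis=0)
        ss_pop = group_term - Sy * Sy / N
        ss_rem = np.maximum(ss_pop - ss_evo, 0.0)  # sequential: evoPOP first
        ss_res = np.maximum(Syy - group_term, 0.0)
        df_res = N - len(groups)
        df_rem = k_sel - 1
        mse = ss_res / np.maximum(df_res, 1)

        p_evo = stats.f.sf(ss_evo / mse, 1, np.maximum(df_res, 1))
        p_rem = stats.f.sf((ss_rem / df_rem) / mse, df_rem, np.maximum(df_res, 1))

        # degenerate residual variance: significant iff the contrast SS is nonzero
        degen = (ss_res <= _ZERO_SS) & ~skipped & (df_res > 0)
        p_evo = np.where(degen, np.where(ss_evo > _ZERO_SS, 0.0, 1.0), p_evo)
        p_rem = np.where(degen, np.where(ss_rem > _ZERO_SS, 0.0, 1.0), p_rem)

        means = s_g / np.where(n_g > 0, n_g, np.nan)
        delta = means[1:].mean(axis=0) - means[0]

    bad = skipped | (df_res <= 0)
    for arr in (p_evo, p_rem, delta, ss_evo, ss_rem):
        arr[bad] = np.nan
    return pd.DataFrame({
        "p_evo": p_evo, "p_rem": p_rem, "delta": delta,
        "ss_evo": ss_evo, "ss_rem": ss_rem, "ss_res": ss_res,
        "df_res": df_res, "skipped": bad, "degenerate": degen,
    })


def call_dmcs(q_evo, q_rem, alpha: float = 0.05) -> np.ndarray:
    """DMC flag: evoPOP significant AND remPOP not (both at the same alpha)."""
    q_evo = np.asarray(q_evo, dtype=float)
    q_rem = np.asarray(q_rem, dtype=float)
    if q_evo.shape != q_rem.shape:
        raise ValueError("q_evo and q_rem must have equal length")
    with np.errstate(invalid="ignore"):
        return (q_evo < alpha) & (q_rem >= alpha)


def dmc_table(table: CytosineTable, design: SampleDesign,
              genotype: str | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Full per-site DMC analysis for one genotype.

    Levels are modelled in percent.  Sites that cannot be tested (a
    population with no covered sample) keep NaN statistics and are never
    DMCs.  q-values are computed separately for the evoPOP and remPOP
    p-value families.
    """
    if genotype is not None:
        design = design.subset(genotype)
        table = table.select_samples(design.sample_ids)
    pops = design.table.set_index("sample_id").loc[table.samples, "population"].to_numpy()
    fit = fit_population_model(table.levels() * 100.0, pops,
                               ancestral=design.ancestral_population)
    out = pd.concat([table.sites.reset_index(drop=True), fit], axis=1)
    tested = ~out["skipped"].to_numpy()
    q_evo = np.full(len(out), np.nan)
    q_rem = np.full(len(out), np.nan)
    if tested.any():
        q_evo[tested], _ = storey_qvalues(out.loc[tested, "p_evo"].to_numpy())
        q_rem[tested], _ = storey_qvalues(out.loc[tested, "p_rem"].to_numpy())
    out["q_evo"] = q_evo
    out["q_rem"] = q_rem
    out["is_dmc"] = False
    out.loc[tested, "is_dmc"] = call_dmcs(q_evo[tested], q_rem[tested], alpha)
    return out


# ----------------------------------------------------------------- DMRs


@dataclass(frozen=True)
class Dmr:
    chrom: str
    start: int
    end: int
    n_dmc: int
    mean_delta: float

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def merge_dmrs(positions, min_dmc: int, max_gap: int,
               chrom: str = "chr", deltas=None) -> list[Dmr]:
    """Greedy single-linkage consolidation of sorted DMC positions.

    Consecutive DMCs at most ``max_gap`` bp apart join one cluster; clusters
    with at least ``min_dmc`` members become DMRs spanning first to last DMC
    (size = end - start + 1).
    """
    pos = np.asarray(sorted(positions), dtype=int)
    if deltas is None:
        d = np.zeros(len(pos))
    else:
        order = np.argsort(np.asarray(positions), kind="mergesort")
        d = np.asarray(deltas, dtype=float)[order]
    out: list[Dmr] = []
    i = 0
    while i < len(pos):
        j = i
        while j + 1 < len(pos) and pos[j + 1] - pos[j] <= max_gap:
            j += 1
        if j - i + 1 >= min_dmc:
            out.append(Dmr(chrom, int(pos[i]), int(pos[j]), j - i + 1,
                           float(np.mean(d[i:j + 1]))))
        i = j + 1
    return out


def merge_dmrs_by_chromosome(dmc_sites: pd.DataFrame, min_dmc: int,
                             max_gap: int) -> pd.DataFrame:
    """Apply :func:`merge_dmrs` per chromosome of a DMC table."""
    rows = []
    for chrom, grp in dmc_sites.groupby("chrom", sort=True):
        deltas = grp["delta"].to_numpy() if "delta" in grp else None
        for r in merge_dmrs(grp["pos"].to_numpy(), min_dmc, max_gap, chrom, deltas):
            rows.append((r.chrom, r.start, r.end, r.n_dmc, r.mean_delta, r.size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_dmc", "mean_delta", "size"])


def dmr_parameter_sweep(dmc_sites: pd.DataFrame,
                        min_dmc_values=(2, 3, 4, 5, 6, 8, 10),
                        max_gap_values=(10, 25, 50, 100, 200, 500, 1000)) -> pd.DataFrame:
    """DMR counts over a (min_dmc, max_gap) grid — the parameter-dependence surface."""
    rows = []
    for md in min_dmc_values:
        for mg in max_gap_values:
            dmrs = merge_dmrs_by_chromosome(dmc_sites, md, mg)
            rows.append((md, mg, len(dmrs), int(dmrs["n_dmc"].sum()) if len(dmrs) else 0,
                         float(dmrs["size"].mean()) if len(dmrs) else float("nan")))
    return pd.DataFrame(rows, columns=["min_dmc", "max_gap", "n_dmr", "n_dmc_in_dmrs", "mean_size"])


# -------------------------------------------------- binary-methylation scan


def snp_like_scan(levels: np.ndarray, low: float = 0.05, high: float = 0.95,
                  same_tail: bool = True) -> tuple[int, float]:
    """Count cytosines whose methylation state is binary across individuals.

    A site counts when every individual's level is below ``low`` or every
    individual's level is above ``high``.  ``same_tail=True`` (default)
    requires all individuals in the *same* tail; ``same_tail=False`` lets
    each individual sit in either tail.  Sites with any missing value are
    excluded from both numerator and denominator.  Returns (count, fraction
    of evaluated sites).
    """
    lv = np.atleast_2d(np.asarray(levels, dtype=float))
    complete = ~np.isnan(lv).any(axis=1)
    lv = lv[complete]
    if lv.size == 0:
        return 0, float("nan")
    below = lv < low
    above = lv > high
    if same_tail:
        hits = below.all(axis=1) | above.all(axis=1)
    else:
        hits = (below | above).all(axis=1)
    return int(hits.sum()), float(hits.mean())
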