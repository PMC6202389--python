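"""Epigenetic diversity: mean pairwise distances and parental-similarity bins.

The distance between two individuals, for one sequence context and
chromosome, is the mean over shared covered cytosines of the absolute
difference of methylation levels (an L1 mean, so it is symmetric and obeys
the triangle inequality on complete data).  The mean pairwise distance (MPD)
of a population is the unweighted mean of that distance over all unordered
sample pairs; its expectation does not depend on the number of individuals,
which makes the 8-sample ancestral and 4-sample selected populations
comparable.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .io import CONTEXTS, CytosineTable, SampleDesign


def pairwise_distance(levels_a: np.ndarray, levels_b: np.ndarray) -> float:
    """Mean |level_a - level_b| over sites covered in both samples.

    NaN (zero-coverage) sites are dropped pairwise; returns NaN if no site is
    shared.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("level vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        return float("nan")
    return float(np.mean(np.abs(a[ok] - b[ok])))


def mpd(levels: np.ndarray) -> tuple[float, int]:
    """MPD of a (n_sites, k_samples) level matrix: mean distance over all
    k(k-1)/2 unordered pairs.  Returns (mpd, n_pairs)."""
    k = levels.shape[1]
    if k < 2:
        raise ValueError("MPD needs at least 2 samples")
    dists = [
        pairwise_distance(levels[:, i], levels[:, j])
        for i, j in itertools.combinations(range(k), 2)
    ]
    return float(np.nanmean(dists)), len(dists)


def mpd_table(table: CytosineTable, design: SampleDesign,
              genome_wide: bool = False) -> pd.DataFrame:
    """MPD per (genotype, population, context, chromosome).

    With ``genome_wide=True`` a per-context roll-up across chromosomes is
    appended (chromosome = "genome"), computed over all sites jointly so
    chromosomes contribute in proportion to their covered cytosines.
    """
    lv = table.levels()
    ctx = table.sites["context"].to_numpy()
    chroms = table.sites["chrom"].to_numpy()
    rows = []
    for g in design.genotypes:
        for pop in design.populations:
            samples = design.samples_of(genotype=g, population=pop)
            if len(samples) < 2:
                continue
            cols = table.sample_index(samples)
            for context in CONTEXTS:
                cmask = ctx == context
                units = [("genome", cmask)] if genome_wide else []
                units += [(c, cmask & (chroms == c)) for c in pd.unique(chroms)]
                for chrom, mask in units:
                    if not mask.any():
                        continue
                    value, n_pairs = mpd(lv[np.ix_(mask, cols)])
                    rows.append((g, pop, context, chrom, value, n_pairs))
    return pd.DataFrame(
        rows, columns=["genotype", "population", "context", "chromosome", "mpd", "n_pairs"]
    )


def parental_similarity(sample_levels: np.ndarray, positions: np.ndarray,
                        parent_a_levels: np.ndarray, parent_b_levels: np.ndarray,
                        chromosome_length: int, bin_size: int = 10_000) -> pd.DataFrame:
    """Per 10-kb bin: (mean |sample - parent A|) - (mean |sample - parent B|).

    Negative values mean the bin is closer to parent A.  Bins with no covered
    cytosine in common get NaN.  All inputs are for one chromosome and one
    context; bins tile [1, chromosome_length] without overlap.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    s = np.asarray(sample_levels, dtype=float)
    pa = np.asarray(parent_a_levels, dtype=float)
    pb = np.asarray(parent_b_levels, dtype=float)
    pos = np.asarray(positions)
    if not (len(s) == len(pa) == len(pb) == len(pos)):
        raise ValueError("all level vectors must align with positions")
    n_bins = int(np.ceil(chromosome_length / bin_size))
    bin_idx = np.minimum((pos - 1) // bin_size, n_bins - 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = bin_idx == b
        if not m.any():
            continue
        da = pairwise_distance(s[m], pa[m])
        db = pairwise_distance(s[m], pb[m])
        out[b] = da - db
    return pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_size + 1,
        "delta_similarity": out,
    })
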