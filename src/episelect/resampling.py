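"""Empirical-null tests by random sampling of tested cytosines.

The null model for every test is the same: sets of positions of the same
size (and, where requested, the same genotype/context composition) as the
query set, drawn uniformly without replacement from all *tested* cytosines.
Empirical p-values use the add-one rule p = (1 + #{null as-or-more-extreme})
/ (n_draws + 1), so p is never 0 and its minimum is 1/(n_draws + 1) — with
the 500 draws used for feature co-localisation that minimum is 1/501, i.e.
"P < 0.002".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_CHROM_SENTINEL = None  # chromosome-length sentinel for chroms without regions


@dataclass
class EmpiricalTest:
    observed: float
    null_draws: np.ndarray
    direction: str  # "enrichment" (null >= observed extreme) or "depletion"
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return len(self.null_draws)

    @property
    def empirical_p(self) -> float:
        null = np.asarray(self.null_draws, dtype=float)
        if self.direction == "enrichment":
            extreme = (null >= self.observed).sum()
        elif self.direction == "depletion":
            extreme = (null <= self.observed).sum()
        else:
            raise ValueError(f"unknown direction {self.direction!r}")
        return (1.0 + extreme) / (self.n_draws + 1.0)

    def to_dict(self) -> dict:
        return {"observed": float(self.observed), "n_draws": self.n_draws,
                "empirical_p": self.empirical_p, "direction": self.direction,
                "seed": self.seed}


# ---------------------------------------------------------- siRNA targets


def merge_sirna_targets(intervals, gap: int = 10, strict: bool = True) -> list[tuple[int, int]]:
    """Merge 24-nt siRNA loci closer than ``gap`` bp into single target regions.

    ``strict=True`` merges only when the distance between intervals is
    strictly below ``gap`` ("closer than 10 bp"); set ``strict=False`` for
    the <=-gap reading.  Input intervals are (start, end) 1-based inclusive
    and must be sorted by start; output regions are disjoint.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        dist = s - out[-1][1] - 1  # bp strictly between the two intervals
        close = dist < gap if strict else dist <= gap
        if close:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ------------------------------------------------- neighbor-distance test


def neighbor_distance_test(dmc_positions, tested_positions, n_draws: int,
                           seed: int, short_cutoff: int = 100) -> tuple[EmpiricalTest, pd.DataFrame]:
    """Are neighbouring DMCs closer together than random cytosines?

    Statistic: fraction of nearest-neighbour gaps below ``short_cutoff`` bp
    among the sorted query positions.  Null: draws of |query| positions
    without replacement from the tested positions.  Also returns a gap
    histogram with gaps of 1-2 bp tallied separately (these largely reflect
    the two strands of symmetric CG/CHG sites).
    """
    q = np.sort(np.asarray(dmc_positions, dtype=np.int64))
    t = np.asarray(tested_positions, dtype=np.int64)
    if len(q) < 2:
        raise ValueError("need at least 2 query positions")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if len(t) < len(q):
        raise ValueError("tested set smaller than query set")
    rng = np.random.default_rng(seed)
    observed = _short_gap_fraction(q, short_cutoff)
    null = np.empty(n_draws)
    for i in range(n_draws):
        draw = np.sort(rng.choice(t, size=len(q), replace=False))
        null[i] = _short_gap_fraction(draw, short_cutoff)
    gaps = np.diff(q)
    hist = pd.DataFrame({
        "gap_class": ["1-2 bp (symmetric-context)", f"3-{short_cutoff - 1} bp",
                      f">={short_cutoff} bp"],
        "count": [int(((gaps >= 1) & (gaps <= 2)).sum()),
                  int(((gaps > 2) & (gaps < short_cutoff)).sum()),
                  int((gaps >= short_cutoff).sum())],
    })
    return EmpiricalTest(observed, null, "enrichment", seed), hist


def _short_gap_fraction(sorted_pos: np.ndarray, cutoff: int) -> float:
    gaps = np.diff(sorted_pos)
    return float((gaps < cutoff).mean()) if len(gaps) else 0.0


# ------------------------------------------------------ co-localisation


def colocalization_test(query: pd.DataFrame, target_regions: pd.DataFrame,
                        tested: pd.DataFrame, n_draws: int = 500,
                        stratify_by: tuple[str, ...] = ("context",),
                        seed: int = 0) -> dict[str, EmpiricalTest]:
    """Co-occurrence with, and distance to, a set of target regions.

    ``query``/``tested`` need chrom/pos columns plus any ``stratify_by``
    columns (e.g. context, genotype); ``target_regions`` needs
    chrom/start/end.  Null draws preserve the per-stratum counts of the
    query exactly.  Returns two one-sided tests: "cooccurrence" (number of
    query positions inside regions; enrichment) and "distance" (mean
    distance to the nearest region edge, 0 inside; depletion = closer than
    chance).
    """
    if target_regions.empty:
        raise ValueError("empty target regions")
    for col in stratify_by:
        if col not in query.columns or col not in tested.columns:
            raise ValueError(f"stratification column {col!r} missing")
    lookup = _RegionLookup(target_regions)
    rng = np.random.default_rng(seed)

    obs_in, obs_dist = lookup.stats(query)
    strata = list(query.groupby(list(stratify_by), sort=True, dropna=False)) \
        if stratify_by else [((), query)]
    pools = []
    for key, grp in strata:
        mask = np.ones(len(tested), dtype=bool)
        keyvals = key if isinstance(key, tuple) else (key,)
        for col, val in zip(stratify_by, keyvals):
            mask &= (tested[col] == val).to_numpy()
        pool = tested[mask]
        if len(pool) < len(grp):
            raise ValueError(f"tested stratum {key!r} smaller than query stratum")
        pools.append((len(grp), pool[["chrom", "pos"]].reset_index(drop=True)))

    null_in = np.empty(n_draws)
    null_dist = np.empty(n_draws)
    for i in range(n_draws):
        parts = [pool.iloc[rng.choice(len(pool), size=k, replace=False)]
                 for k, pool in pools]
        draw = pd.concat(parts, ignore_index=True)
        null_in[i], null_dist[i] = lookup.stats(draw)
    return {
        "cooccurrence": EmpiricalTest(obs_in, null_in, "enrichment", seed),
        "distance": EmpiricalTest(obs_dist, null_dist, "depletion", seed),
    }


class _RegionLookup:
    """Nearest-region distances via sorted edge arrays, per chromosome."""

    def __init__(self, regions: pd.DataFrame, chrom_length_sentinel: float = 1e8):
        self.sentinel = chrom_length_sentinel
        self.by_chrom = {}
        for c, grp in regions.groupby("chrom"):
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            order = np.argsort(starts)
            self.by_chrom[c] = (starts[order], ends[order])

    def stats(self, points: pd.DataFrame) -> tuple[float, float]:
        n_in = 0
        dists = []
        for c, grp in points.groupby("chrom"):
            pos = grp["pos"].to_numpy(dtype=np.int64)
            if c not in self.by_chrom:
                dists.append(np.full(len(pos), self.sentinel))
                continue
            starts, ends = self.by_chrom[c]
            idx = np.searchsorted(starts, pos, side="right") - 1
            d_inside = np.zeros(len(pos), dtype=bool)
            prev_end_dist = np.full(len(pos), np.inf)
            valid = idx >= 0
            if valid.any():
                e = ends[idx[valid]]
                inside = pos[valid] <= e
                tmp = np.where(inside, 0, pos[valid] - e)
                d_inside[np.where(valid)[0][inside]] = True
                prev_end_dist[valid] = tmp
            nxt = np.searchsorted(starts, pos, side="right")
            next_start_dist = np.full(len(pos), np.inf)
            has_next = nxt < len(starts)
            next_start_dist[has_next] = starts[nxt[has_next]] - pos[has_next]
            d = np.minimum(prev_end_dist, next_start_dist)
            d = np.where(d_inside, 0.0, d)
            n_in += int(d_inside.sum())
            dists.append(d)
        all_d = np.concatenate(dists) if dists else np.array([])
        return float(n_in), float(all_d.mean()) if len(all_d) else float("nan")


# ------------------------------------------------------ shared-site test


def shared_sites_test(dmcs_a, dmcs_b, tested_a, tested_b,
                      n_draws: int = 10_000, seed: int = 0) -> EmpiricalTest:
    """Cross-genotype DMC overlap vs independent random draws.

    Arguments are site-key collections (e.g. (chrom, pos, strand) tuples).
    Observed statistic: |dmcs_a intersect dmcs_b|.  Null: one draw per
    genotype of |dmcs| keys from its own tested set, intersected.
    """
    set_a, set_b = set(dmcs_a), set(dmcs_b)
    ta = list(tested_a)
    tb = list(tested_b)
    if len(ta) < len(set_a) or len(tb) < len(set_b):
        raise ValueError("tested sets must be at least as large as the DMC sets")
    rng = np.random.default_rng(seed)
    observed = len(set_a & set_b)
    # integer-code the union of site keys so each draw intersects with numpy
    codes = {k: i for i, k in enumerate(dict.fromkeys(ta + tb))}
    ta_codes = np.fromiter((codes[k] for k in ta), dtype=np.int64, count=len(ta))
    tb_codes = np.fromiter((codes[k] for k in tb), dtype=np.int64, count=len(tb))
    null = np.empty(n_draws)
    for i in range(n_draws):
        da = ta_codes[rng.choice(len(ta), size=len(set_a), replace=False)]
        db = tb_codes[rng.choice(len(tb), size=len(set_b), replace=False)]
        null[i] = np.intersect1d(da, db, assume_unique=False).size
    return EmpiricalTest(float(observed), null, "enrichment", seed)
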