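"""Cytosine count tables, sample metadata, and the per-genotype coverage filter.

The on-disk format follows the Bismark-style per-cytosine report: one file per
sample, seven tab-separated columns::

    chromosome  position  strand  count_methylated  count_unmethylated  context  trinucleotide

Positions are 1-based and per-strand; symmetric CG sites are *not* collapsed
across strands (each strand keeps its own record).  In memory, a
:class:`CytosineTable` stores one row per (chromosome, position, strand) site
and dense per-sample count matrices, which is what the vectorised per-site
linear models downstream operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

SITE_COLUMNS = ["chrom", "pos", "strand", "context"]
REPORT_COLUMNS = ["chrom", "pos", "strand", "count_met", "count_unmet", "context", "tri"]


class CytosineReportError(ValueError):
    """Malformed cytosine report (bad line, duplicate site, negative count)."""


@dataclass
class SampleDesign:
    """Sample metadata: genotype, population, and the derived ancestral/selected role.

    ``role`` is "ancestral" iff ``population == ancestral_population`` (D0 by
    default); everything else is "selected".
    """

    table: pd.DataFrame
    ancestral_population: str = "D0"

    def __post_init__(self) -> None:
        required = {"sample_id", "genotype", "population"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        t = self.table.copy()
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        t["role"] = np.where(
            t["population"] == self.ancestral_population, "ancestral", "selected"
        )
        counts = t.groupby(["genotype", "population"])["sample_id"].count()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(
                f"need >=2 samples per (genotype, population) for variance estimation; got {bad}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.table["genotype"].unique())

    @property
    def populations(self) -> list[str]:
        pops = sorted(self.table["population"].unique())
        # ancestral population listed first
        if self.ancestral_population in pops:
            pops.remove(self.ancestral_population)
            pops.insert(0, self.ancestral_population)
        return pops

    def samples_of(self, genotype: str | None = None, population: str | None = None,
                   role: str | None = None) -> list[str]:
        t = self.table
        if genotype is not None:
            t = t[t["genotype"] == genotype]
        if population is not None:
            t = t[t["population"] == population]
        if role is not None:
            t = t[t["role"] == role]
        return t["sample_id"].tolist()

    def subset(self, genotype: str) -> "SampleDesign":
        sub = self.table[self.table["genotype"] == genotype]
        if sub.empty:
            raise KeyError(f"no samples for genotype {genotype!r}")
        return SampleDesign(sub[["sample_id", "genotype", "population"]],
                            self.ancestral_population)

    def to_tsv(self, path) -> None:
        self.table[["sample_id", "genotype", "population"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, ancestral_population: str = "D0") -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype=str), ancestral_population)


@dataclass
class CytosineTable:
    """Per-cytosine methylated/unmethylated counts for a set of samples.

    ``sites`` has columns chrom/pos/strand/context (one row per site);
    ``meth`` and ``total`` are (n_sites, n_samples) integer arrays with
    ``total = methylated + unmethylated`` coverage.
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray
    tri: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n, k = len(self.sites), len(self.samples)
        if self.meth.shape != (n, k) or self.total.shape != (n, k):
            raise ValueError("count matrices must be (n_sites, n_samples)")
        if (self.meth < 0).any() or (self.total < self.meth).any():
            raise CytosineReportError("negative counts")
        bad = ~self.sites["context"].isin(CONTEXTS)
        if bad.any():
            raise CytosineReportError(
                f"unknown context values: {sorted(self.sites.loc[bad, 'context'].unique())}"
            )
        if self.sites.duplicated(subset=["chrom", "pos", "strand"]).any():
            raise CytosineReportError("duplicate (chrom, pos, strand) sites")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def levels(self) -> np.ndarray:
        """Per-sample methylation levels in [0, 1]; NaN where coverage is zero."""
        return methylation_level(self.meth, self.total - self.meth)

    def sample_index(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in table") from None

    def select_sites(self, mask: np.ndarray) -> "CytosineTable":
        mask = np.asarray(mask)
        return CytosineTable(
            self.sites.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.meth[mask],
            self.total[mask],
            None if self.tri is None else self.tri.loc[mask].reset_index(drop=True),
        )

    def select_samples(self, sample_ids) -> "CytosineTable":
        idx = self.sample_index(sample_ids)
        return CytosineTable(self.sites.copy(), list(sample_ids),
                             self.meth[:, idx], self.total[:, idx], self.tri)

    def site_keys(self) -> pd.Index:
        s = self.sites
        return pd.Index(zip(s["chrom"], s["pos"], s["strand"]))


def methylation_level(methylated, unmethylated):
    """level = methylated / (methylated + unmethylated); NaN at zero coverage.

    Accepts scalars or arrays; zero total coverage yields a missing value
    rather than 0, so uncovered sites never masquerade as unmethylated.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("counts must be non-negative")
    tot = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        lvl = np.where(tot > 0, m / np.where(tot > 0, tot, 1.0), np.nan)
    if np.ndim(methylated) == 0 and np.ndim(unmethylated) == 0:
        return float(lvl)
    return lvl


def read_cytosine_report(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read one sample's 7-column cytosine report into a site-keyed DataFrame.

    Malformed lines raise :class:`CytosineReportError` with 1-based line
    numbers.  Returns a DataFrame with REPORT_COLUMNS; combine several samples
    with :func:`combine_reports`.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise CytosineReportError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, got {len(parts)}"
                )
            chrom, pos, strand, met, unmet, context, tri = parts
            try:
                pos_i, met_i, unmet_i = int(pos), int(met), int(unmet)
            except ValueError:
                raise CytosineReportError(f"{path}:{lineno}: non-integer field") from None
            if met_i < 0 or unmet_i < 0:
                raise CytosineReportError(f"{path}:{lineno}: negative count")
            if strand not in ("+", "-"):
                raise CytosineReportError(f"{path}:{lineno}: bad strand {strand!r}")
            if context not in CONTEXTS:
                raise CytosineReportError(f"{path}:{lineno}: bad context {context!r}")
            rows.append((chrom, pos_i, strand, met_i, unmet_i, context, tri))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if df.duplicated(subset=["chrom", "pos", "strand"]).any():
        dup = df[df.duplicated(subset=["chrom", "pos", "strand"], keep=False)]
        raise CytosineReportError(
            f"{path}: duplicate sites, e.g. {tuple(dup.iloc[0][['chrom', 'pos', 'strand']])}"
        )
    if sample_id is not None:
        df.attrs["sample_id"] = sample_id
    return df


def combine_reports(reports: dict[str, pd.DataFrame]) -> CytosineTable:
    """Merge per-sample report frames into one CytosineTable.

    The union of sites is kept; a sample without a record at a site gets zero
    coverage there (missing downstream).  Context/trinucleotide must agree
    across samples at shared sites.
    """
    if not reports:
        raise ValueError("no reports given")
    samples = list(reports)
    frames = []
    for s in samples:
        df = reports[s].set_index(["chrom", "pos", "strand"])
        frames.append(df)
    all_sites = frames[0][["context", "tri"]]
    for df in frames[1:]:
        new = df.index.difference(all_sites.index)
        both = df.index.intersection(all_sites.index)
        if len(both) and not (
            df.loc[both, "context"].to_numpy() == all_sites.loc[both, "context"].to_numpy()
        ).all():
            raise CytosineReportError("context disagreement between samples at shared sites")
        all_sites = pd.concat([all_sites, df.loc[new, ["context", "tri"]]])
    all_sites = all_sites.sort_index()
    n = len(all_sites)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    total = np.zeros((n, len(samples)), dtype=np.int64)
    for j, df in enumerate(frames):
        sub = df.reindex(all_sites.index)
        m = sub["count_met"].fillna(0).to_numpy(dtype=np.int64)
        u = sub["count_unmet"].fillna(0).to_numpy(dtype=np.int64)
        meth[:, j] = m
        total[:, j] = m + u
    sites = all_sites.index.to_frame(index=False)
    sites.columns = ["chrom", "pos", "strand"]
    sites["context"] = all_sites["context"].to_numpy()
    return CytosineTable(sites, samples, meth, total,
                         tri=all_sites["tri"].reset_index(drop=True))


def write_cytosine_report(table: CytosineTable, sample_id: str, path) -> None:
    """Write one sample of a table back to the 7-column report format."""
    j = table.sample_index([sample_id])[0]
    tri = table.tri if table.tri is not None else pd.Series(["NNN"] * table.n_sites)
    out = pd.DataFrame(
        {
            "chrom": table.sites["chrom"],
            "pos": table.sites["pos"],
            "strand": table.sites["strand"],
            "count_met": table.meth[:, j],
            "count_unmet": table.total[:, j] - table.meth[:, j],
            "context": table.sites["context"],
            "tri": tri,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def filter_by_coverage(table: CytosineTable, design: SampleDesign,
                       min_avg: float = 5.0, max_avg: float = 100.0,
                       genotype: str | None = None) -> CytosineTable:
    """Keep sites whose mean per-sample coverage within a genotype is in [min_avg, max_avg].

    Bounds are inclusive ("below 5 and above 100" removed).  Filtering is per
    genotype: the returned table contains only that genotype's samples and the
    sites passing for it, so a site can survive in one genotype but not the
    other.  With ``genotype=None`` the design must contain a single genotype.
    """
    if min_avg > max_avg:
        raise ValueError("min_avg must be <= max_avg")
    genotypes = design.genotypes
    if genotype is None:
        if len(genotypes) != 1:
            raise ValueError(f"multiple genotypes {genotypes}; pass genotype=")
        genotype = genotypes[0]
    samples = design.samples_of(genotype=genotype)
    sub = table.select_samples(samples)
    mean_cov = sub.total.mean(axis=1)
    keep = (mean_cov >= min_avg) & (mean_cov <= max_avg)
    return sub.select_sites(keep)
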