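"""Mapping cytosines to genomic features and summarising DMCs per gene.

Feature classes are the gene parts (exon, intron, 5'UTR, 3'UTR), 1-kb
flanks, transposable elements, and 24-nt siRNA target regions; positions
overlapping none of them are intergenic.  When a position overlaps several
features at once, each receives an equal fractional score 1/k, so the scores
always sum to one per position.  Gene-level DMC summaries, in contrast,
count a DMC fully for every gene whose body-plus-flank window contains it:
the fractional rule serves genome-wide tallies, the full rule serves
per-gene candidate lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import CONTEXTS

GENE_PART_CLASSES = ("exon", "intron", "5'UTR", "3'UTR")
FLANK_CLASSES = ("upstream_1kb", "downstream_1kb")
SCORED_CLASSES = GENE_PART_CLASSES + FLANK_CLASSES + ("TE", "sirna_target")

_GFF_TYPES = {"gene": "gene", "exon": "exon", "intron": "intron",
              "5'UTR": "five_prime_UTR", "3'UTR": "three_prime_UTR",
              "TE": "transposable_element", "sirna_target": "siRNA_target_region",
              "upstream_1kb": "upstream_region", "downstream_1kb": "downstream_region"}
_GFF_TYPES_INV = {v: k for k, v in _GFF_TYPES.items()}


@dataclass
class FeatureSet:
    """Interval annotation (1-based inclusive coordinates) with interval-tree lookup."""

    table: pd.DataFrame
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand", "feature_class", "feature_id", "gene_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        if (self.table["end"] < self.table["start"]).any():
            raise ValueError("feature end < start")
        self.table = self.table.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] | None = None

    # -------------------------------------------------------------- views

    def genes(self) -> pd.DataFrame:
        return self.table[self.table["feature_class"] == "gene"].reset_index(drop=True)

    def of_class(self, feature_class: str) -> pd.DataFrame:
        return self.table[self.table["feature_class"] == feature_class].reset_index(drop=True)

    def with_flanks(self, flank: int = 1000) -> "FeatureSet":
        """Add strand-aware upstream/downstream 1-kb flank features per gene,
        truncated at chromosome ends."""
        rows = []
        for _, g in self.genes().iterrows():
            L = self.chromosome_lengths.get(g["chrom"], None)
            left = (max(1, g["start"] - flank), g["start"] - 1)
            right = (g["end"] + 1, g["end"] + flank if L is None else min(L, g["end"] + flank))
            if g["strand"] == "+":
                up, down = left, right
            else:
                up, down = right, left
            for (s, e), cls in ((up, "upstream_1kb"), (down, "downstream_1kb")):
                if e >= s:
                    rows.append((g["chrom"], int(s), int(e), g["strand"], cls,
                                 f"{g['gene_id']}.{cls}", g["gene_id"]))
        extra = pd.DataFrame(rows, columns=self.table.columns[:7])
        combined = pd.concat([self.table, extra], ignore_index=True)
        return FeatureSet(combined, dict(self.chromosome_lengths))

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            self._trees = {}
            scored = self.table[self.table["feature_class"].isin(SCORED_CLASSES)]
            for c, grp in scored.groupby("chrom"):
                t = IntervalTree()
                for s, e, cls, gid in zip(grp["start"], grp["end"],
                                          grp["feature_class"], grp["gene_id"]):
                    t.addi(int(s), int(e) + 1, (cls, gid))  # half-open internally
                self._trees[c] = t
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        """(feature_class, gene_id) pairs of scored features covering a position."""
        return [iv.data for iv in self._tree(chrom).at(int(pos))]

    # ---------------------------------------------------------------- io

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, L in sorted(self.chromosome_lengths.items()):
                fh.write(f"##sequence-region {chrom} 1 {L}\n")
            for _, r in self.table.iterrows():
                attrs = f"ID={r['feature_id']}"
                if r["gene_id"]:
                    attrs += f";Parent={r['gene_id']}" if r["feature_class"] != "gene" \
                        else f";Name={r['gene_id']}"
                fh.write("\t".join([
                    r["chrom"], "episelect", _GFF_TYPES[r["feature_class"]],
                    str(r["start"]), str(r["end"]), ".", r["strand"], ".", attrs,
                ]) + "\n")

    @classmethod
    def from_gff3(cls, path) -> "FeatureSet":
        rows, lengths = [], {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##sequence-region"):
                    _, chrom, _, end = line.split()
                    lengths[chrom] = int(end)
                    continue
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                cls_name = _GFF_TYPES_INV.get(f[2])
                if cls_name is None:
                    continue
                gene_id = attrs.get("Parent", attrs.get("Name", ""))
                rows.append((f[0], int(f[3]), int(f[4]), f[6], cls_name,
                             attrs.get("ID", ""), gene_id))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                         "feature_class", "feature_id", "gene_id"])
        return cls(df, lengths)

    def to_bed(self, path, feature_class: str | None = None) -> None:
        t = self.table if feature_class is None else self.of_class(feature_class)
        with open(path, "w") as fh:
            for _, r in t.iterrows():
                fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t"
                         f"{r['feature_id']}\t0\t{r['strand']}\n")


# ------------------------------------------------------------ assignment


def assign_context(chrom: str, pos: int, features: FeatureSet) -> dict[str, float]:
    """Fractional feature scores at one position; k overlapping features get
    1/k each, no overlap yields {'intergenic': 1.0}.  Scores sum to 1."""
    hits = features.overlapping(chrom, pos)
    if not hits:
        return {"intergenic": 1.0}
    w = 1.0 / len(hits)
    out: dict[str, float] = {}
    for cls, _ in hits:
        out[cls] = out.get(cls, 0.0) + w
    return out


def context_score_table(sites: pd.DataFrame, features: FeatureSet) -> pd.DataFrame:
    """Summed fractional scores per feature class for a set of sites."""
    totals: dict[str, float] = {c: 0.0 for c in SCORED_CLASSES + ("intergenic",)}
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        for cls, w in assign_context(chrom, int(pos), features).items():
            totals[cls] = totals.get(cls, 0.0) + w
    return pd.DataFrame(sorted(totals.items()), columns=["feature_class", "score"])


def summarize_gene_dmcs(dmc_sites: pd.DataFrame, features: FeatureSet,
                        flank: int = 1000) -> pd.DataFrame:
    """Per-gene DMC summaries over gene body + 1-kb flanks.

    ``dmc_sites`` needs chrom/pos/context/delta columns (DMC rows only).
    Output: gene_id, n_dmc, mean_delta (signed average change), and
    per-context counts.  Genes without DMCs are absent.  A DMC inside two
    genes' windows counts fully for each.
    """
    if dmc_sites.empty:
        return pd.DataFrame(columns=["gene_id", "n_dmc", "mean_delta",
                                     *[f"n_{c}" for c in CONTEXTS]])
    genes = features.genes()
    trees: dict[str, IntervalTree] = {}
    for c, grp in genes.groupby("chrom"):
        t = IntervalTree()
        for s, e, gid in zip(grp["start"], grp["end"], grp["gene_id"]):
            t.addi(max(1, int(s) - flank), int(e) + flank + 1, gid)
        trees[c] = t
    acc: dict[str, list] = {}
    for chrom, pos, ctx, delta in zip(dmc_sites["chrom"], dmc_sites["pos"],
                                      dmc_sites["context"], dmc_sites["delta"]):
        for iv in trees.get(chrom, IntervalTree()).at(int(pos)):
            acc.setdefault(iv.data, []).append((ctx, float(delta)))
    rows = []
    for gid, hits in acc.items():
        deltas = [d for _, d in hits]
        ctx_counts = {f"n_{c}": sum(1 for x, _ in hits if x == c) for c in CONTEXTS}
        rows.append({"gene_id": gid, "n_dmc": len(hits),
                     "mean_delta": float(np.mean(deltas)), **ctx_counts})
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def context_proportions(sites: pd.DataFrame | pd.Series) -> dict[str, float]:
    """Proportions of CG/CHG/CHH among sites (summing to 1)."""
    ctx = sites["context"] if isinstance(sites, pd.DataFrame) else sites
    if len(ctx) == 0:
        raise ValueError("no sites given")
    counts = ctx.value_counts()
    n = counts.sum()
    return {c: float(counts.get(c, 0)) / n for c in CONTEXTS}


# -------------------------------------------------------------- metagene


@dataclass
class MetageneProfile:
    body: np.ndarray          # 100 bins, average site density (sites/bp/gene-set)
    upstream: np.ndarray      # 1-kb flank, smoothed, 1-bp resolution
    downstream: np.ndarray
    body_counts: np.ndarray   # raw in-body site counts per bin
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": np.arange(len(self.body)), "density": self.body})


def metagene_profile(sites: pd.DataFrame, features: FeatureSet,
                     n_bins: int = 100, flank: int = 1000,
                     min_length: int = 100, smooth_window: int = 50) -> MetageneProfile:
    """Average distribution of sites along a generic gene model.

    Genes shorter than ``min_length`` or within ``flank`` bp of a chromosome
    end are excluded.  Each gene body is split into ``n_bins`` equal bins
    (site -> bin by floor(n_bins * (pos - start) / length), clamped; for
    minus-strand genes the relative position is measured from the 3' end so
    profiles read 5'->3').  Flank tracks are per-bp site counts averaged over
    genes and smoothed with a centred moving average.
    """
    genes = features.genes()
    keep = []
    for _, g in genes.iterrows():
        L = features.chromosome_lengths.get(g["chrom"])
        length = g["end"] - g["start"] + 1
        if length < min_length:
            continue
        if g["start"] <= flank:
            continue
        if L is not None and g["end"] > L - flank:
            continue
        keep.append(g)
    if not keep:
        raise ValueError("no gene passes the metagene inclusion rules")
    body_counts = np.zeros(n_bins)
    up = np.zeros(flank)
    down = np.zeros(flank)
    width_sum = 0.0
    by_chrom = {c: grp["pos"].to_numpy() for c, grp in sites.groupby("chrom")}
    for g in keep:
        pos = by_chrom.get(g["chrom"])
        length = g["end"] - g["start"] + 1
        width_sum += length / n_bins
        if pos is None:
            continue
        inside = pos[(pos >= g["start"]) & (pos <= g["end"])]
        if g["strand"] == "+":
            rel = inside - g["start"]
            before = pos[(pos >= g["start"] - flank) & (pos < g["start"])]
            after = pos[(pos > g["end"]) & (pos <= g["end"] + flank)]
            up_off = before - (g["start"] - flank)
            down_off = after - (g["end"] + 1)
        else:
            rel = g["end"] - inside
            before = pos[(pos > g["end"]) & (pos <= g["end"] + flank)]
            after = pos[(pos >= g["start"] - flank) & (pos < g["start"])]
            up_off = (g["end"] + flank) - before
            down_off = (g["start"] - 1) - after
        bins = np.minimum((n_bins * rel) // length, n_bins - 1).astype(int)
        np.add.at(body_counts, bins, 1)
        np.add.at(up, up_off.astype(int), 1)
        np.add.at(down, down_off.astype(int), 1)
    density = body_counts / (width_sum / len(keep)) / len(keep)
    return MetageneProfile(
        body=density,
        upstream=_smooth(up / len(keep), smooth_window),
        downstream=_smooth(down / len(keep), smooth_window),
        body_counts=body_counts,
        n_genes=len(keep),
    )


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    # centred moving average with edge renormalisation
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
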