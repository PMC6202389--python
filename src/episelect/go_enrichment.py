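"""Robust GO-term enrichment over a (DMC count x methylation change) grid.

Candidate genes are selected at every cell of an 11 x 11 grid of thresholds
on the number of DMCs per gene (1, 2, 4, ..., 20) and the absolute average
methylation change (0, 5, ..., 50 percent) — 121 combinations.  Each cell
runs a one-sided Fisher exact (hypergeometric) over-representation test of
every GO term against the protein-coding universe, with gene-to-term
annotation propagated to ancestor terms.  A term is *robust* when it is
significant (p < 0.05) in at least 50 of the 121 cells; with two genotypes
the union is taken (robust in either).  The decorrelating "weight"
refinement of topGO is deliberately not re-implemented; the default is the
classic test, with an "elim"-style variant (drop the genes of significant
descendants) available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

N_DMC_THRESHOLDS = (1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20)
DELTA_THRESHOLDS = (0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass(frozen=True)
class ThresholdGrid:
    n_dmc_thresholds: tuple[int, ...] = N_DMC_THRESHOLDS
    delta_thresholds: tuple[int, ...] = DELTA_THRESHOLDS

    @property
    def cells(self) -> list[tuple[int, int]]:
        return list(itertools.product(self.n_dmc_thresholds, self.delta_thresholds))

    def __len__(self) -> int:
        return len(self.n_dmc_thresholds) * len(self.delta_thresholds)


def select_genes(gene_summaries: pd.DataFrame, n_dmc_min: int,
                 abs_delta_min: float) -> set[str]:
    """Genes with >= n_dmc_min DMCs and |mean_delta| >= abs_delta_min (percent).

    The magnitude is used so hyper- and hypo-methylated genes both qualify.
    """
    t = gene_summaries
    keep = (t["n_dmc"] >= n_dmc_min) & (t["mean_delta"].abs() >= abs_delta_min)
    return set(t.loc[keep, "gene_id"])


def propagate_annotation(gene_to_terms: dict[str, set[str]],
                         term_parents: dict[str, set[str]] | None) -> dict[str, set[str]]:
    """Extend each gene's term set with all ancestors in the GO graph."""
    if not term_parents:
        return {g: set(ts) for g, ts in gene_to_terms.items()}
    ancestors: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        if term not in ancestors:
            out = set()
            for p in term_parents.get(term, ()):  # noqa: B023 - simple DAG walk
                out.add(p)
                out |= anc(p)
            ancestors[term] = out
        return ancestors[term]

    return {g: set(ts) | set().union(*(anc(t) for t in ts)) if ts else set()
            for g, ts in gene_to_terms.items()}


def term_parents_from_obo(path) -> dict[str, set[str]]:
    """is_a parent map from an OBO file (via obonet when available)."""
    import obonet

    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return parents


def term_enrichment(selected: set[str], universe: set[str],
                    annotation: dict[str, set[str]],
                    algorithm: str = "classic", alpha: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher exact over-representation p per term.

    ``annotation`` maps gene -> ancestor-propagated term set and must cover
    the universe (unannotated genes count as annotated to no term).  The
    hypergeometric tail P(X >= k) is computed directly; terms annotating no
    universe gene are skipped.  ``algorithm="elim"`` processes terms from
    smallest to largest and removes the genes of already-significant terms
    that are strict subsets (descendant gene sets) from later tables.
    """
    if not universe >= selected:
        raise ValueError("universe must contain all selected genes")
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in annotation.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    N, n = len(universe), len(selected)
    rows = []
    if algorithm == "classic":
        for term, genes in sorted(term_genes.items()):
            k = len(genes & selected)
            K = len(genes)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            rows.append((term, k, K, p))
    elif algorithm == "elim":
        removed: set[str] = set()
        for term, genes in sorted(term_genes.items(), key=lambda kv: (len(kv[1]), kv[0])):
            eff = genes - removed
            k = len(eff & selected)
            K = len(eff)
            p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
            rows.append((term, k, K, p))
            if p < alpha:
                removed |= genes
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return pd.DataFrame(rows, columns=["term_id", "n_selected_in_term",
                                       "n_term", "p"])


@dataclass
class GridEnrichment:
    term_id: str
    p_matrix: pd.DataFrame  # index n_dmc threshold, columns delta threshold
    n_significant_cells: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_significant_cells = int((self.p_matrix.to_numpy() < 0.05).sum())

    def robust(self, min_cells: int = 50) -> bool:
        return self.n_significant_cells >= min_cells


def grid_enrichment(gene_summaries: pd.DataFrame, universe: set[str],
                    annotation: dict[str, set[str]],
                    grid: ThresholdGrid = ThresholdGrid(),
                    algorithm: str = "classic") -> dict[str, GridEnrichment]:
    """Run term_enrichment in every grid cell; returns term -> GridEnrichment."""
    per_term: dict[str, pd.DataFrame] = {}
    for nd in grid.n_dmc_thresholds:
        for dl in grid.delta_thresholds:
            sel = select_genes(gene_summaries, nd, dl) & universe
            res = term_enrichment(sel, universe, annotation, algorithm=algorithm)
            for term, p in zip(res["term_id"], res["p"]):
                mat = per_term.setdefault(term, pd.DataFrame(
                    np.ones((len(grid.n_dmc_thresholds), len(grid.delta_thresholds))),
                    index=list(grid.n_dmc_thresholds), columns=list(grid.delta_thresholds),
                ))
                mat.loc[nd, dl] = p
    return {t: GridEnrichment(t, m) for t, m in per_term.items()}


def robust_terms(grid_results: dict[str, GridEnrichment] |
                 list[dict[str, GridEnrichment]],
                 alpha: float = 0.05, min_cells: int = 50,
                 grid: ThresholdGrid = ThresholdGrid()) -> pd.DataFrame:
    """Terms significant in >= min_cells of the full grid.

    Accepts one genotype's results or a list of them (union semantics:
    robust in either genotype).  Raises if any term's grid is incomplete.
    """
    result_sets = grid_results if isinstance(grid_results, list) else [grid_results]
    rows = {}
    for res in result_sets:
        for term, ge in res.items():
            if ge.p_matrix.shape != (len(grid.n_dmc_thresholds), len(grid.delta_thresholds)):
                raise ValueError(f"incomplete grid for term {term}")
            n_sig = int((ge.p_matrix.to_numpy() < alpha).sum())
            min_p = float(ge.p_matrix.to_numpy().min())
            prev = rows.get(term)
            if prev is None or n_sig > prev[0]:
                rows[term] = (n_sig, min_p)
    out = pd.DataFrame(
        [(t, n, p, n >= min_cells) for t, (n, p) in sorted(rows.items())],
        columns=["term_id", "n_significant_cells", "min_p", "robust"],
    )
    return out
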