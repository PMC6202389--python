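"""Synthetic data with the statistical structure of an ancestral-vs-selected design.

The generator emulates a selection experiment on two near-isogenic genotypes:
one ancestral population (D0, 8 individuals per genotype) and three
independently selected populations (D1/D5/D6, 4 individuals each).  Methylomes
are built from two epihaplotypes per genotype:

* *planted DMC sites* — the ancestral individuals carry epihaplotype A, all
  selected individuals carry B, whose level differs by a signed
  ``planted_delta``; these are epialleles driven to fixation by selection and
  are the true positives the DMC caller should recover;
* *epihaplotype diversity sites* — each individual carries one of the two
  epihaplotypes jointly across these sites, drawn with frequency
  ``epihaplotype_freq_ancestral`` in D0 and ``epihaplotype_freq_selected`` in
  the selected populations.  A frequency shift 0.5 -> 1.0 reproduces the loss
  of epigenetic diversity (lower MPD) after selection without creating
  divergence among the selected populations;
* optional *single-population sites* where only one selected population
  carries B — divergence among D1/D5/D6 that the remPOP guard must reject.

Counts are beta-binomial: coverage ~ negative binomial, an individual's
biological level ~ Beta around its epihaplotype level with concentration
``beta_precision``, and methylated reads ~ Binomial(coverage, level).
Every planted truth is recorded in :class:`GroundTruth`.  All outputs are
bit-identical for a given config (one RNG stream per output table).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTEXTS, CytosineTable, SampleDesign

# fixed stream ids so regenerating one table never perturbs another
_STREAMS = {"annotation": 11, "methylomes": 23, "phenotypes": 37,
            "ddpcr": 41, "alleles": 53}

SELECTED_POPULATIONS = ("D1", "D5", "D6")


class PlacementError(ValueError):
    """Requested features cannot be placed on the configured chromosomes."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 120
    n_tes: int = 60
    n_sirna_loci: int = 150
    n_sites_per_chromosome: int = 10_000
    # genome-wide cytosine context mixture (CG, CHG, CHH); CG share 13%
    context_probs: tuple[float, float, float] = (0.13, 0.15, 0.72)
    coverage_mean: float = 36.0
    coverage_dispersion: float = 10.0  # NB shape; var = mu + mu^2/shape
    beta_precision: float = 30.0  # beta-binomial concentration per individual
    n_planted_dmcs: int = 0
    planted_delta: float = 0.5
    n_planted_onepop: int = 0  # divergence in a single selected population
    n_epihaplotype_sites: int = 1000
    epihaplotype_delta: float = 0.6  # level difference between the two epihaplotypes
    epihaplotype_freq_ancestral: float = 0.5
    epihaplotype_freq_selected: float = 1.0
    genotypes: tuple[str, ...] = ("CVL39", "CVL125")
    n_ancestral: int = 8
    n_per_selected: int = 4
    # phenotype design: GEN (2 blocks) x RIL (2) x POP (4), individuals per cell
    pheno_n_per_cell: int = 17
    pheno_noise_sd: float = 1.0
    # pooled resequencing design: 2 ancestral + 7 selected lines
    n_ancestral_lines: int = 2
    n_selected_lines: int = 7
    n_allele_positions: int = 1000
    n_planted_snps: int = 5
    allele_coverage_mean: float = 50.0

    def __post_init__(self) -> None:
        if abs(sum(self.context_probs) - 1.0) > 1e-9:
            raise ValueError("context_probs must sum to 1")
        if not 0.0 <= self.planted_delta <= 1.0:
            raise ValueError("planted_delta must be in [0, 1]")
        for f in ("epihaplotype_freq_ancestral", "epihaplotype_freq_selected"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def null(self) -> "SimulationConfig":
        """The no-selection configuration: nothing planted, no frequency shift."""
        return self.replace(
            n_planted_dmcs=0, n_planted_onepop=0,
            epihaplotype_freq_selected=self.epihaplotype_freq_ancestral,
        )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), _STREAMS[stream]]))

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def populations(self) -> tuple[str, ...]:
        return ("D0",) + SELECTED_POPULATIONS

    def to_yaml(self, path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["context_probs"] = list(self.context_probs)
        d["genotypes"] = list(self.genotypes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["context_probs"] = tuple(d["context_probs"])
        d["genotypes"] = tuple(d["genotypes"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything planted by the generator, for scoring recovered calls."""

    planted_dmcs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["genotype", "chrom", "pos", "strand", "context", "delta", "kind", "population"]
        )
    )
    epihaplotype_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["genotype", "chrom", "pos", "strand", "delta"])
    )
    planted_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "pos", "anc_alt_freq", "sel_alt_freq"])
    )
    planted_te_insertions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["te_id", "chrom", "pos"])
    )
    phenotype_effects: dict = field(default_factory=dict)
    ddpcr_fold_changes: dict = field(default_factory=dict)

    def dmc_keys(self, genotype: str, kind: str = "shared") -> set:
        t = self.planted_dmcs
        t = t[(t["genotype"] == genotype) & (t["kind"] == kind)]
        return set(zip(t["chrom"], t["pos"], t["strand"]))

    def to_tsv(self, path) -> None:
        self.planted_dmcs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- annotation


def simulate_annotation(config: SimulationConfig):
    """Generate a deterministic gene/TE/siRNA annotation.

    Gene bodies are disjoint and carry 5'UTR / exon / intron / 3'UTR parts;
    TEs are placed in the space between genes (they may overlap siRNA loci),
    and 24-nt siRNA loci cluster near TEs.  Returns a
    :class:`~episelect.genomic_context.FeatureSet`.
    """
    from .genomic_context import FeatureSet

    rng = config.rng("annotation")
    rows = []
    genes_per_chrom = _split_count(config.n_genes, config.n_chromosomes)
    tes_per_chrom = _split_count(config.n_tes, config.n_chromosomes)
    sirna_per_chrom = _split_count(config.n_sirna_loci, config.n_chromosomes)
    min_gene, max_gene = 800, 3000
    for ci, chrom in enumerate(config.chromosomes):
        n_genes = genes_per_chrom[ci]
        L = config.chromosome_length
        if n_genes and n_genes * (max_gene + 200) > 0.9 * L:
            raise PlacementError(
                f"{n_genes} genes of up to {max_gene} bp cannot be placed on {L} bp"
            )
        # evenly spaced slots with jitter keep gene bodies disjoint
        gene_spans = []
        if n_genes:
            slot = L // n_genes
            for g in range(n_genes):
                length = int(rng.integers(min_gene, max_gene + 1))
                lo = g * slot + 1
                hi = min((g + 1) * slot - length, L - length)
                if hi < lo:
                    raise PlacementError("gene slot too small; reduce n_genes")
                start = int(rng.integers(lo, hi + 1))
                end = start + length - 1
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"gene_{chrom}_{g + 1:04d}"
                gene_spans.append((start, end))
                rows.extend(_gene_parts(rng, chrom, start, end, strand, gid))
        te_spans = []
        for t in range(tes_per_chrom[ci]):
            length = int(rng.integers(300, 3001))
            start = int(rng.integers(1, max(2, L - length)))
            te_spans.append((start, start + length - 1))
            rows.append((chrom, start, start + length - 1, "+", "TE",
                         f"te_{chrom}_{t + 1:04d}", ""))
        for s in range(sirna_per_chrom[ci]):
            if te_spans and rng.random() < 0.7:
                ts, te_ = te_spans[int(rng.integers(len(te_spans)))]
                center = int(rng.integers(max(1, ts - 500), min(L - 24, te_ + 500)))
            else:
                center = int(rng.integers(1, L - 24))
            rows.append((chrom, center, center + 23, "+", "sirna_target",
                         f"sirna_{chrom}_{s + 1:04d}", ""))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "feature_class", "feature_id", "gene_id"]
    )
    lengths = {c: config.chromosome_length for c in config.chromosomes}
    return FeatureSet(df, chromosome_lengths=lengths)


def _split_count(n: int, k: int) -> list[int]:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


def _gene_parts(rng, chrom, start, end, strand, gid):
    """Decompose a gene span into 5'UTR, alternating exons/introns, 3'UTR."""
    length = end - start + 1
    utr5 = int(rng.integers(80, 201))
    utr3 = int(rng.integers(100, 251))
    body = length - utr5 - utr3
    n_exons = int(rng.integers(2, 5))
    cuts = np.sort(rng.choice(np.arange(1, body), size=2 * n_exons - 2, replace=False)) \
        if body > 2 * n_exons else np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [body]])
    rows = [(chrom, start, end, strand, "gene", gid, gid)]
    left_utr, right_utr = ("5'UTR", "3'UTR") if strand == "+" else ("3'UTR", "5'UTR")
    rows.append((chrom, start, start + utr5 - 1, strand, left_utr, f"{gid}.utrL", gid))
    rows.append((chrom, end - utr3 + 1, end, strand, right_utr, f"{gid}.utrR", gid))
    body_start = start + utr5
    for i in range(len(bounds) - 1):
        s = body_start + int(bounds[i])
        e = body_start + int(bounds[i + 1]) - 1
        if e < s:
            continue
        cls = "exon" if i % 2 == 0 else "intron"
        rows.append((chrom, s, e, strand, cls, f"{gid}.{cls}{i}", gid))
    return rows


# ---------------------------------------------------------------- methylomes


def simulate_design(config: SimulationConfig) -> SampleDesign:
    rows = []
    for g in config.genotypes:
        for i in range(config.n_ancestral):
            rows.append((f"{g}_D0_{i + 1}", g, "D0"))
        for pop in SELECTED_POPULATIONS:
            for i in range(config.n_per_selected):
                rows.append((f"{g}_{pop}_{i + 1}", g, pop))
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "genotype", "population"]))


def simulate_methylomes(annotation, config: SimulationConfig,
                        truth_out: GroundTruth | None = None):
    """Emit a CytosineTable + SampleDesign for the full two-genotype design.

    Returns ``(table, design, truth)``; ``truth_out`` is filled in place when
    given.  Site coordinates are shared between genotypes (one genome), counts
    and epihaplotypes are independent per genotype.
    """
    truth = truth_out if truth_out is not None else GroundTruth()
    rng = config.rng("methylomes")
    design = simulate_design(config)

    sites = _draw_sites(rng, config)
    n = len(sites)
    ctx = sites["context"].to_numpy()

    # CG levels are bimodal (methylated vs unmethylated epialleles); CHG/CHH low
    base = np.empty(n)
    is_cg = ctx == "CG"
    meth_state = rng.random(n) < 0.35
    base[is_cg & meth_state] = rng.uniform(0.70, 0.95, (is_cg & meth_state).sum())
    base[is_cg & ~meth_state] = rng.uniform(0.02, 0.10, (is_cg & ~meth_state).sum())
    base[ctx == "CHG"] = np.clip(rng.beta(1.5, 6.0, (ctx == "CHG").sum()), 0.02, 0.98)
    base[ctx == "CHH"] = np.clip(rng.beta(1.2, 10.0, (ctx == "CHH").sum()), 0.02, 0.98)

    n_special = config.n_planted_dmcs + config.n_planted_onepop + config.n_epihaplotype_sites
    if n_special > n:
        raise PlacementError("more planted/epihaplotype sites than cytosines")

    all_meth = np.zeros((n, len(design.sample_ids)), dtype=np.int64)
    all_total = np.zeros_like(all_meth)
    dmc_rows, epi_rows = [], []

    for g in config.genotypes:
        special = rng.choice(n, size=n_special, replace=False)
        i_dmc = special[: config.n_planted_dmcs]
        i_one = special[config.n_planted_dmcs: config.n_planted_dmcs + config.n_planted_onepop]
        i_epi = special[config.n_planted_dmcs + config.n_planted_onepop:]

        level_a = base.copy()
        level_b = base.copy()
        for idx_set, delta_mag in ((i_dmc, config.planted_delta),
                                   (i_one, config.planted_delta)):
            if len(idx_set) == 0:
                continue
            sign = np.where(rng.random(len(idx_set)) < 0.5, 1.0, -1.0)
            # keep the full |delta| inside [0,1] by flipping infeasible signs
            target = level_a[idx_set] + sign * delta_mag
            flip = (target < 0) | (target > 1)
            sign[flip] *= -1
            level_b[idx_set] = np.clip(level_a[idx_set] + sign * delta_mag, 0.0, 1.0)
        if len(i_epi):
            sign = np.where(rng.random(len(i_epi)) < 0.5, 1.0, -1.0)
            target = level_a[i_epi] + sign * config.epihaplotype_delta
            flip = (target < 0) | (target > 1)
            sign[flip] *= -1
            level_b[i_epi] = np.clip(level_a[i_epi] + sign * config.epihaplotype_delta, 0.0, 1.0)

        onepop_assign = [SELECTED_POPULATIONS[k % 3] for k in range(len(i_one))]
        g_samples = design.samples_of(genotype=g)
        cols = [design.sample_ids.index(s) for s in g_samples]
        pops = design.table.set_index("sample_id").loc[g_samples, "population"].to_numpy()

        for j, (col, pop) in enumerate(zip(cols, pops)):
            mu = level_a.copy()
            if pop == "D0":
                carries_b = rng.random() < config.epihaplotype_freq_ancestral
            else:
                carries_b = rng.random() < config.epihaplotype_freq_selected
                mu[i_dmc] = level_b[i_dmc]  # fixed in every selected population
                onepop_here = [i for i, p in zip(i_one, onepop_assign) if p == pop]
                mu[onepop_here] = level_b[onepop_here]
            if carries_b:
                mu[i_epi] = level_b[i_epi]
            cov = rng.negative_binomial(
                config.coverage_dispersion,
                config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean),
                size=n,
            )
            nu = config.beta_precision
            p_ind = rng.beta(np.clip(mu, 1e-3, None) * nu,
                             np.clip(1 - mu, 1e-3, None) * nu)
            all_meth[:, col] = rng.binomial(cov, p_ind)
            all_total[:, col] = cov

        for kind, idx_set, pops_of in (("shared", i_dmc, [""] * len(i_dmc)),
                                       ("onepop", i_one, onepop_assign)):
            for i, pop in zip(idx_set, pops_of):
                dmc_rows.append((g, sites["chrom"].iat[i], int(sites["pos"].iat[i]),
                                 sites["strand"].iat[i], sites["context"].iat[i],
                                 float(level_b[i] - level_a[i]), kind, pop))
        for i in i_epi:
            epi_rows.append((g, sites["chrom"].iat[i], int(sites["pos"].iat[i]),
                             sites["strand"].iat[i], float(level_b[i] - level_a[i])))

    truth.planted_dmcs = pd.DataFrame(
        dmc_rows,
        columns=["genotype", "chrom", "pos", "strand", "context", "delta", "kind", "population"],
    )
    truth.epihaplotype_sites = pd.DataFrame(
        epi_rows, columns=["genotype", "chrom", "pos", "strand", "delta"]
    )
    table = CytosineTable(sites, design.sample_ids, all_meth, all_total)
    return table, design, truth


def _draw_sites(rng, config: SimulationConfig) -> pd.DataFrame:
    frames = []
    for chrom in config.chromosomes:
        m = config.n_sites_per_chromosome
        if m > config.chromosome_length:
            raise PlacementError("more sites than base pairs on a chromosome")
        pos = np.sort(rng.choice(config.chromosome_length, size=m, replace=False)) + 1
        strand = np.where(rng.random(m) < 0.5, "+", "-")
        context = rng.choice(CONTEXTS, size=m, p=config.context_probs)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "strand": strand, "context": context}
        ))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------- phenotypes


def simulate_phenotypes(config: SimulationConfig,
                        truth_out: GroundTruth | None = None,
                        effects: dict | None = None) -> pd.DataFrame:
    """Phenotype table for the GEN x RIL x POP crossed factorial.

    ``effects`` maps trait -> evoPOP effect (mean difference selected minus
    ancestral, in trait units).  Default traits mirror the measured ones with
    modest shifts; pass ``{trait: 0.0}`` for a null trait.
    """
    truth = truth_out if truth_out is not None else GroundTruth()
    rng = config.rng("phenotypes")
    if effects is None:
        effects = {"bolting_day": 1.5, "rosette_leaves": 1.0,
                   "branches": 0.8, "siliques": 0.8}
    gens = ("G2", "G3")
    rows = []
    gen_eff = {g: e for g, e in zip(gens, (0.0, 0.6))}
    ril_eff = {r: e for r, e in zip(config.genotypes, (0.0, 1.0))}
    k = 0
    for gen in gens:
        for ril in config.genotypes:
            for pop in config.populations:
                for _ in range(config.pheno_n_per_cell):
                    k += 1
                    row = {"individual_id": f"ind_{k:04d}", "GEN": gen, "RIL": ril, "POP": pop}
                    for trait, eff in effects.items():
                        mu = 20.0 + gen_eff[gen] + ril_eff[ril]
                        if pop != "D0":
                            mu += eff
                        row[trait] = mu + rng.normal(0.0, config.pheno_noise_sd)
                    rows.append(row)
    truth.phenotype_effects = dict(effects)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- ddPCR


def simulate_ddpcr(config: SimulationConfig, fold_changes: dict[str, float],
                   reference_genes: tuple[str, ...] = ("PP2A", "UBC9"),
                   n_per_population: int = 4, base_count: float = 400.0,
                   log2_sd: float = 0.35,
                   truth_out: GroundTruth | None = None) -> pd.DataFrame:
    """Droplet counts for test genes (planted selected/ancestral fold change)
    and reference genes (unaffected by group).  RT- counts are near zero
    (no genomic contamination)."""
    if len(reference_genes) < 2:
        raise ValueError("need at least two reference genes")
    truth = truth_out if truth_out is not None else GroundTruth()
    rng = config.rng("ddpcr")
    rows = []
    genes = list(fold_changes) + list(reference_genes)
    for pop in config.populations:
        for i in range(n_per_population):
            sid = f"ddpcr_{pop}_{i + 1}"
            sample_scale = float(2.0 ** rng.normal(0.0, 0.15))  # library-size wobble
            for gene in genes:
                fc = fold_changes.get(gene, 1.0)
                mu = base_count * sample_scale * (fc if pop != "D0" else 1.0)
                count = int(np.round(mu * 2.0 ** rng.normal(0.0, log2_sd)))
                rows.append({
                    "sample_id": sid, "population": pop, "gene": gene,
                    "rt_plus_count": max(count, 0),
                    "rt_minus_count": int(rng.integers(0, 3)),
                    "is_reference": gene in reference_genes,
                })
    truth.ddpcr_fold_changes = dict(fold_changes)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- allele counts


def simulate_allele_counts(config: SimulationConfig,
                           truth_out: GroundTruth | None = None) -> pd.DataFrame:
    """Per-line biallelic counts for the pooled-resequencing SNP filter.

    Most positions are monomorphic (all reference); planted SNPs are
    reference-fixed in the ancestral lines and alternate-fixed in >50% of the
    selected lines.  A few percent of positions get deliberately low or high
    coverage so the [20, 200] filter band has work to do.
    """
    truth = truth_out if truth_out is not None else GroundTruth()
    rng = config.rng("alleles")
    lines = ([f"anc_{i + 1}" for i in range(config.n_ancestral_lines)]
             + [f"sel_{i + 1}" for i in range(config.n_selected_lines)])
    n = config.n_allele_positions
    chrom = np.repeat("chr1", n)
    pos = np.sort(rng.choice(config.chromosome_length, size=n, replace=False)) + 1

    cov_mean = np.full(n, config.allele_coverage_mean)
    low = rng.choice(n, size=max(1, n // 50), replace=False)
    high = rng.choice(np.setdiff1d(np.arange(n), low), size=max(1, n // 50), replace=False)
    cov_mean[low] = 8.0
    cov_mean[high] = 300.0

    snp_idx = rng.choice(np.setdiff1d(np.arange(n), np.concatenate([low, high])),
                         size=config.n_planted_snps, replace=False)
    n_div = max(4, config.n_selected_lines // 2 + 1)
    rows = []
    for li, line in enumerate(lines):
        shape = 25.0  # pooled-resequencing coverage CV ~ 0.25
        cov = rng.negative_binomial(shape, shape / (shape + cov_mean)).astype(int)
        alt_p = np.full(n, 0.01)  # sequencing-error floor
        if line.startswith("sel_") and li - config.n_ancestral_lines < n_div:
            alt_p[snp_idx] = 0.98
        alt = rng.binomial(cov, alt_p)
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "line": line,
            "count_major": cov - alt, "count_minor": alt, "coverage": cov,
        }))
    truth.planted_snps = pd.DataFrame({
        "chrom": "chr1", "pos": pos[snp_idx],
        "anc_alt_freq": 0.0, "sel_alt_freq": n_div / config.n_selected_lines,
    })
    return pd.concat(rows, ignore_index=True)
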