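# episelect

Selection signatures in population methylomes.

`episelect` analyses whole-genome bisulfite data from a selection
experiment: one **ancestral** population (D0) and several **independently
selected** populations (D1/D5/D6) of the same, nearly isogenic genotype.
It asks whether selection shifted DNA methylation — per single cytosine —
and whether the selected populations lost epigenetic diversity, and it
carries the analysis through to regions, genes, GO terms, and the
surrounding phenotype/expression/variant statistics.  A first-class
synthetic-data generator emulates the whole design, so every statistical
property of the pipeline can be tested against planted ground truth.

## The model

At each cytosine the methylation level (percent, from methylated /
unmethylated read counts) is modelled per genotype by OLS on the population
factor POP ∈ {D0, D1, D5, D6}, decomposed into two contrasts:

* **evoPOP** (1 df): D0 versus the mean of the selected populations,
  (D1 + D5 + D6)/3 — the signature of selection;
* **remPOP** (2 df): the remaining differences among D1/D5/D6 — drift or
  divergence between the replicate selections.

Both F-tests share the residual mean square (df = n − 4; 8 + 4·3 = 20
samples per genotype by default).  P-values are converted to Storey
q-values (smoother π₀ estimate on λ = 0.05 … 0.95), and a cytosine is a
**DMC** iff

    q_evoPOP < 0.05  and  q_remPOP ≥ 0.05

— a consistent ancestral-vs-selected shift *shared* by the independent
selections.  Nearby DMCs consolidate into DMRs (≥ min_dmc DMCs, gaps ≤
max_gap).  Epigenetic diversity within a population is the **MPD** (mean
pairwise distance): the average over sample pairs of the mean per-cytosine
absolute level difference, whose expectation is independent of sample size.
Genomic co-localisation (siRNA targets, transposons, cross-genotype DMC
overlap) is tested against empirical nulls from random draws of tested
cytosines, stratified by context, with add-one p-values
(1 + #extreme)/(draws + 1).  GO over-representation runs on an 11 × 11 grid
of (DMCs-per-gene × |mean change|) thresholds; a term is *robust* when
significant in ≥ 50 of the 121 cells.

## Worked example

```python
from episelect import SimulationConfig, dmc_table, filter_by_coverage, mpd_table
from episelect.simulate import GroundTruth, simulate_annotation, simulate_methylomes

config = SimulationConfig(seed=42, n_chromosomes=1, chromosome_length=500_000,
                          n_sites_per_chromosome=5_000, genotypes=("CVL39",),
                          n_planted_dmcs=50)
truth = GroundTruth()
annotation = simulate_annotation(config)
table, design, _ = simulate_methylomes(annotation, config, truth)

filtered = filter_by_coverage(table, design, min_avg=5, max_avg=100)
result = dmc_table(filtered, design, alpha=0.05)
called = result[result["is_dmc"]]
planted = truth.dmc_keys("CVL39", "shared")
hits = planted & set(zip(called["chrom"], called["pos"], called["strand"]))

print(f"sites tested        : {int((~result['skipped']).sum())}")
print(f"DMCs called (Q<0.05): {len(called)}")
print(f"planted recovered   : {len(hits)}/{len(planted)}")
print(f"mean |delta| at DMCs: {called['delta'].abs().mean():.1f}%")

mpd = mpd_table(filtered, design, genome_wide=True)
gw = mpd[(mpd["chromosome"] == "genome") & (mpd["context"] == "CG")]
for _, row in gw.iterrows():
    print(f"CG MPD {row['population']}: {row['mpd']:.4f}  ({row['n_pairs']} pairs)")
```

prints

```
sites tested        : 5000
DMCs called (Q<0.05): 988
planted recovered   : 50/50
mean |delta| at DMCs: 37.9%
CG MPD D0: 0.1404  (28 pairs)
CG MPD D1: 0.0915  (6 pairs)
CG MPD D5: 0.0876  (6 pairs)
CG MPD D6: 0.0922  (6 pairs)
```

All 50 planted fixed epialleles are recovered.  The remaining calls are the
epihaplotype loci whose frequency the simulated selection drove from 0.5 to
1.0 — genuine methylation differences, which is also why the ancestral
population's CG diversity (MPD 0.140) exceeds every selected population's
(≈ 0.09).  `delta` is the mean selected-minus-ancestral level change in
percentage points.

The same stages are scriptable: `episelect run --seed 42 --outdir out/`
executes simulate → filter → MPD → DMC → DMR → annotation → enrichment and
writes TSV/BED/JSON plus a manifest; `episelect dmc`, `episelect dmr
--sweep`, `episelect mpd`, `episelect filter` operate on cytosine-report
files.

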