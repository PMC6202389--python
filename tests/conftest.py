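import numpy as np
import pandas as pd
import pytest

from episelect.io import CytosineTable, SampleDesign
from episelect.simulate import (GroundTruth, SimulationConfig,
                                simulate_annotation, simulate_methylomes)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Fast two-genotype simulation with planted signal of every kind."""
    return SimulationConfig(
        seed=7, n_chromosomes=1, chromosome_length=300_000,
        n_genes=30, n_tes=15, n_sirna_loci=40,
        n_sites_per_chromosome=4000,
        n_planted_dmcs=60, n_planted_onepop=30, n_epihaplotype_sites=300,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    truth = GroundTruth()
    annotation = simulate_annotation(small_config)
    table, design, _ = simulate_methylomes(annotation, small_config, truth)
    return {"config": small_config, "annotation": annotation,
            "table": table, "design": design, "truth": truth}


@pytest.fixture()
def tiny_design() -> SampleDesign:
    rows = [(f"s{p}{i}", "G1", f"D{p}") for p in (0, 1, 5, 6)
            for i in range(1, (5 if p == 0 else 3))]
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "genotype", "population"]))


def make_table(meth, total, contexts=None, chrom="chr1", samples=None) -> CytosineTable:
    meth = np.asarray(meth)
    total = np.asarray(total)
    n, k = meth.shape
    if samples is None:
        samples = [f"s{i}" for i in range(k)]
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, n + 1) * 10, "strand": "+",
        "context": contexts if contexts is not None else ["CG"] * n,
    })
    return CytosineTable(sites, list(samples), meth, total)
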