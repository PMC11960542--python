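import numpy as np
import pandas as pd
import pytest

from omicqtl.datatypes import GenotypePanel
from omicqtl.simulate import EffectSpec, simulate_genotype_panel, simulate_phenotypes


@pytest.fixture(scope="session")
def small_panel() -> GenotypePanel:
    """120-sample family-structured panel with 8 LD blocks."""
    panel = simulate_genotype_panel(
        n_founder_haplotypes=30,
        n_samples=120,
        family_spec=[5, 5, 4],
        n_blocks=8,
        variants_per_block=12,
        recomb_between_blocks=0.1,
        seed=11,
    )
    panel.validate()
    return panel


@pytest.fixture(scope="session")
def cohort_panel() -> GenotypePanel:
    """200-sample panel used by power / recovery scenarios."""
    panel = simulate_genotype_panel(
        n_founder_haplotypes=40,
        n_samples=200,
        family_spec=[6, 5, 5, 4],
        n_blocks=10,
        variants_per_block=10,
        recomb_between_blocks=0.2,
        seed=7,
    )
    panel.validate()
    return panel


def make_elements(n, tissue="tissueA", ptype="expression", spacing=30_000, chrom="chr1"):
    rows = []
    for i in range(n):
        start = 1_000 + i * spacing
        rows.append(
            dict(
                id=f"g{i}",
                phenotype_type=ptype,
                tissue=tissue,
                chrom=chrom,
                start=start,
                end=start + 1_000,
                strand="+",
                tss=start if ptype == "expression" else np.nan,
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def planted_dataset(cohort_panel):
    """10 elements; g0 carries a 1-SD effect at a MAF~0.3 variant."""
    elements = make_elements(10)
    af = cohort_panel.variants["af"].to_numpy()
    maf = np.minimum(af, 1 - af)
    causal = cohort_panel.variants["id"].iloc[int(np.argmin(np.abs(maf - 0.3)))]
    design = [EffectSpec(element="g0", variant=causal, beta=1.0)]
    res = simulate_phenotypes(
        cohort_panel,
        elements,
        design,
        n_hidden_factors=2,
        factor_sd=0.5,
        polygenic_sd=0.3,
        noise_sd=1.0,
        seed=23,
    )
    return res, causal
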