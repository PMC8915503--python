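import numpy as np
import pandas as pd
import pytest

import stabilityqtl as sq
from stabilityqtl.assoc import add_bh_q, genotype_pcs


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap simulated dataset shared by structural tests."""
    config = sq.SimConfig(n_samples=60, n_variants=300, n_genes=30, seed=11)
    return sq.simulate_dataset(config)


@pytest.fixture(scope="session")
def planted_dataset():
    """Noise-free kinetics with planted effects, for recovery tests."""
    config = sq.SimConfig(
        n_samples=150,
        n_variants=600,
        n_genes=60,
        seed=7,
        dispersion=0.0,
        prop_transcription_qtl=0.2,
        prop_stability_qtl=0.2,
    )
    return sq.simulate_dataset(config)


def run_trait_scan(dataset, include_pcs=True, stringency=0.01):
    """Full association scan for both traits; returns (eqtl, stqtl, pairs, extras)."""
    genotypes = sq.variant_qc(dataset.genotypes)
    pairs = sq.cis_pairs(dataset.annotation, genotypes)
    stab = sq.infer_stability(dataset.counts, stringency=stringency)
    lengths = pd.Series({g.gene_id: g.exonic_length for g in dataset.annotation})
    expression = sq.transform_expression(sq.compute_tpm(dataset.counts.exon, lengths))
    covariates = dataset.covariates
    if include_pcs:
        pcs = genotype_pcs(genotypes)
        covariates = pd.concat([covariates, pcs.loc[covariates.index]], axis=1)
    eqtl = add_bh_q(
        sq.associate_linear(expression, genotypes, covariates, pairs, "expression")
    )
    stqtl = add_bh_q(
        sq.associate_linear(stab.values, genotypes, covariates, pairs, "stability")
    )
    extras = {
        "genotypes": genotypes,
        "stability": stab,
        "expression": expression,
        "covariates": covariates,
    }
    return eqtl, stqtl, pairs, extras


@pytest.fixture(scope="session")
def planted_scan(planted_dataset):
    return run_trait_scan(planted_dataset)
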