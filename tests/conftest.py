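import numpy as np
import pytest

from gblupgwas import (
    MCMCConfig,
    SimConfig,
    build_design,
    build_marker_matrix,
    compute_grm,
    elicit_priors,
    fit,
    simulate_gaussian_trait,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_gaussian_dataset():
    """200 individuals x 300 SNPs, Gaussian teat-like trait with known truth."""
    cfg = SimConfig(
        n_individuals=200,
        n_snps_per_chrom=[300],
        n_qtl=20,
        var_additive=0.43,
        var_permanent=0.0,
        var_residual=0.71,
        records_per_individual=1,
        family="gaussian",
        intercept=15.3,
        fixed_effect_levels={"hys": [0.0, 0.3, -0.2]},
        seed=21,
    )
    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_gaussian_trait(geno, cfg)
    mm = build_marker_matrix(geno, center=True)
    grm = compute_grm(mm)
    design = build_design(pheno, geno.individual_ids)
    return {
        "config": cfg,
        "geno": geno,
        "pheno": pheno,
        "truth": truth,
        "mm": mm,
        "grm": grm,
        "design": design,
    }


@pytest.fixture(scope="session")
def gaussian_chains(small_gaussian_dataset):
    """A moderate-length Gaussian fit reused across summary-level tests."""
    d = small_gaussian_dataset
    priors = elicit_priors(0.43, None, 0.71)
    mc = MCMCConfig(n_iter=6000, burn_in=2000, thin=2, seed=77)
    return fit(d["pheno"], d["design"], d["grm"], "gaussian", priors, mc)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
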