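import math

import numpy as np
import pandas as pd
import pytest

from gblupgwas import (
    ChainStore,
    MCMCConfig,
    PhenotypeTable,
    SimConfig,
    build_design,
    build_marker_matrix,
    compare_models,
    compute_dic,
    compute_grm,
    elicit_priors,
    fit,
    geweke_diagnostic,
    simulate_genotypes,
    simulate_poisson_trait,
    solve_mme,
)
from gblupgwas.bayes_gblup import DICResult, solve_prior_dof


# ---------------------------------------------------------------------------
# Prior elicitation
# ---------------------------------------------------------------------------

def test_prior_dof_from_mode_constraint_is_two():
    assert solve_prior_dof() == 2.0


@pytest.mark.parametrize(
    "s2star, expected_S",
    [(0.3575, 0.7150), (0.33, 0.66), (3.9125, 7.8250), (0.43, 0.86), (0.0221, 0.0442), (0.71, 1.42)],
)
def test_elicit_priors_scale_is_v_times_mode(s2star, expected_S):
    spec = elicit_priors(s2star, None, 1.0)
    assert spec.u.V == 2.0
    assert math.isclose(spec.u.S, expected_S)
    # prior mode VS/(V+2) recovers sigma2_star exactly
    assert math.isclose(spec.u.V * spec.u.S / (spec.u.V + 2), s2star)


def test_elicit_priors_rejects_nonpositive():
    with pytest.raises(ValueError):
        elicit_priors(0.0, None, 1.0)
    with pytest.raises(ValueError):
        elicit_priors(0.5, -1.0, 1.0)


# ---------------------------------------------------------------------------
# MCMC bookkeeping
# ---------------------------------------------------------------------------

def test_retained_sample_count_formula():
    assert MCMCConfig(n_iter=100_000, burn_in=50_000, thin=2).n_retained == 25_000
    assert MCMCConfig(n_iter=1001, burn_in=500, thin=3).n_retained == 167
    with pytest.raises(ValueError):
        MCMCConfig(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        MCMCConfig(n_iter=100, burn_in=50, thin=0)


def test_fit_retains_exactly_configured_samples(gaussian_chains):
    cfg = gaussian_chains.config
    assert gaussian_chains.n_retained == (cfg.n_iter - cfg.burn_in) // cfg.thin
    assert gaussian_chains.retained_iters[0] == cfg.burn_in + cfg.thin
    assert gaussian_chains.retained_iters[-1] == cfg.n_iter


def test_fit_is_bit_reproducible(small_gaussian_dataset):
    d = small_gaussian_dataset
    priors = elicit_priors(0.43, None, 0.71)
    mc = MCMCConfig(n_iter=600, burn_in=200, thin=2, seed=5)
    c1 = fit(d["pheno"], d["design"], d["grm"], "gaussian", priors, mc)
    c2 = fit(d["pheno"], d["design"], d["grm"], "gaussian", priors, mc)
    assert np.array_equal(c1.u, c2.u)
    assert np.array_equal(c1.sigma2_e, c2.sigma2_e)


# ---------------------------------------------------------------------------
# Oracle equivalence and parameter recovery
# ---------------------------------------------------------------------------

def test_gaussian_sampler_matches_mme_at_fixed_variances(small_gaussian_dataset):
    d = small_gaussian_dataset
    priors = elicit_priors(0.43, None, 0.71)
    mc = MCMCConfig(
        n_iter=8000, burn_in=2000, thin=2, seed=22, fix_variances={"u": 0.43, "e": 0.71}
    )
    chains = fit(d["pheno"], d["design"], d["grm"], "gaussian", priors, mc)
    mme = solve_mme(d["pheno"], d["design"], d["grm"], 0.43, 0.71)
    upost = chains.u.mean(axis=0)
    assert np.corrcoef(upost, mme["u"])[0, 1] > 0.999
    # deviations behave like Monte-Carlo noise: nearly all coordinates within
    # 3 MCSE (batch means), none far outside
    nb = 40
    batches = chains.u.reshape(nb, -1, chains.u.shape[1]).mean(axis=1)
    mcse = batches.std(axis=0, ddof=1) / np.sqrt(nb)
    dev = np.abs(upost - mme["u"])
    assert np.mean(dev < 3 * mcse) >= 0.97
    assert np.all(dev < 5 * mcse)


def test_variance_chains_move_when_not_fixed(gaussian_chains):
    assert gaussian_chains.sigma2_u.std() > 0
    assert gaussian_chains.sigma2_e.std() > 0
    # posterior concentrates in a plausible range around the generating values
    assert 0.05 < gaussian_chains.sigma2_u.mean() < 2.0
    assert 0.2 < gaussian_chains.sigma2_e.mean() < 2.0


def test_sigma2_e_posterior_matches_conjugate_closed_form():
    """Intercept-only Gaussian model: sampled sigma_e^2 agrees with the
    analytic scaled-inverse-chi-square posterior moments."""
    rng = np.random.default_rng(3)
    n = 400
    y = rng.normal(5.0, 1.3, n)
    pheno = PhenotypeTable(
        y=y, individual=np.array([f"i{k}" for k in range(n)]),
        fixed=pd.DataFrame(index=range(n)),
    )
    geno_ids = [f"i{k}" for k in range(n)]
    design = build_design(pheno, geno_ids, has_pe=False)
    grm_like = compute_grm(
        build_marker_matrix(
            simulate_genotypes(
                SimConfig(n_individuals=n, n_snps_per_chrom=[50], n_qtl=0, seed=8)
            ),
            center=True,
        )
    )
    priors = elicit_priors(1.0, None, 1.0)
    mc = MCMCConfig(
        n_iter=6000, burn_in=1000, thin=1, seed=9, fix_variances={"u": 1e-8}
    )
    chains = fit(pheno, design, grm_like, "gaussian", priors, mc)
    # with u ~ 0 and a flat beta prior, sigma_e^2 | y is scaled-inv-chi2 with
    # dof V + n and scale sum VS + SSE about the sample mean
    V, S = priors.e.V, priors.e.S
    sse = float(((y - y.mean()) ** 2).sum())
    dof = V + n
    expected_mean = (V * S + sse) / (dof - 2)
    post = chains.sigma2_e
    mcse = post.std(ddof=1) / np.sqrt(len(post) / 20)  # conservative ESS discount
    assert abs(post.mean() - expected_mean) < max(4 * mcse, 0.02 * expected_mean)


# ---------------------------------------------------------------------------
# Poisson family
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def poisson_fit():
    cfg = SimConfig(
        n_individuals=75, n_snps_per_chrom=[100], n_qtl=10,
        var_additive=0.15, var_permanent=0.2, var_residual=0.5,
        records_per_individual=4, family="poisson",
        intercept=np.log(1.2) - 0.425, seed=31,
    )
    geno = simulate_genotypes(cfg)
    pheno, _ = simulate_poisson_trait(geno, cfg)
    mm = build_marker_matrix(geno, center=True)
    grm = compute_grm(mm)
    design = build_design(pheno, geno.individual_ids)
    priors = elicit_priors(0.3575, 0.33, 3.9125)
    mc = MCMCConfig(n_iter=4000, burn_in=1500, thin=2, seed=32)
    chains = fit(pheno, design, grm, "poisson", priors, mc)
    return {"pheno": pheno, "design": design, "grm": grm, "chains": chains, "priors": priors}


def test_poisson_mh_acceptance_in_tuned_band(poisson_fit):
    assert 0.2 <= poisson_fit["chains"].mh_accept_rate <= 0.7


def test_poisson_requires_integer_observations(poisson_fit):
    pheno = poisson_fit["pheno"]
    bad = PhenotypeTable(
        y=pheno.y + 0.5, individual=pheno.individual, fixed=pheno.fixed
    )
    with pytest.raises(ValueError, match="integer"):
        fit(bad, poisson_fit["design"], poisson_fit["grm"], "poisson",
            poisson_fit["priors"], MCMCConfig(n_iter=200, burn_in=100))


def test_poisson_all_zero_counts_shrink_rate_toward_zero(poisson_fit):
    pheno = poisson_fit["pheno"]
    zeros = PhenotypeTable(
        y=np.zeros_like(pheno.y), individual=pheno.individual, fixed=pheno.fixed
    )
    mc = MCMCConfig(n_iter=2000, burn_in=1000, thin=2, seed=41)
    chains = fit(zeros, poisson_fit["design"], poisson_fit["grm"], "poisson",
                 poisson_fit["priors"], mc)
    # initialization is l = log(y + 0.5), i.e. rate 0.5; posterior must fall
    assert np.exp(chains.l_mean).mean() < 0.25


# ---------------------------------------------------------------------------
# Geweke diagnostic
# ---------------------------------------------------------------------------

def test_geweke_null_calibration():
    rng = np.random.default_rng(0)
    rejections = sum(
        geweke_diagnostic(rng.standard_normal(10_000))[1] < 0.05 for _ in range(200)
    )
    assert 0.02 <= rejections / 200 <= 0.09


def test_geweke_detects_linear_trend():
    z, p = geweke_diagnostic(np.arange(1, 1001, dtype=float))
    assert abs(z) > 5
    assert p < 1e-6


def test_geweke_rejects_degenerate_chains():
    with pytest.raises(ZeroDivisionError):
        geweke_diagnostic(np.ones(5000))
    with pytest.raises(ValueError):
        geweke_diagnostic(np.arange(50, dtype=float))


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def test_dic_single_sample_has_zero_pd(gaussian_chains, small_gaussian_dataset):
    d = small_gaussian_dataset
    one = ChainStore(
        family="gaussian",
        u=gaussian_chains.u[:1],
        beta=gaussian_chains.beta[:1],
        p=None,
        sigma2_u=gaussian_chains.sigma2_u[:1],
        sigma2_p=None,
        sigma2_e=gaussian_chains.sigma2_e[:1],
        deviance=gaussian_chains.deviance[:1],
        l_mean=None,
        retained_iters=gaussian_chains.retained_iters[:1],
        mh_accept_rate=None,
        config=gaussian_chains.config,
    )
    dic = compute_dic(one, d["pheno"], d["design"], "gaussian")
    assert abs(dic.p_D) < 1e-8
    assert math.isclose(dic.DIC, dic.D_at_mean, rel_tol=1e-12)


def test_dic_pd_counts_location_parameters_in_conjugate_toy():
    """Fixed-variance Gaussian model with q fixed-effect levels and no real
    random-effect variance: p_D approximates q."""
    rng = np.random.default_rng(6)
    n = 600
    q = 5
    levels = rng.integers(0, q, n)
    y = 2.0 + 0.5 * levels + rng.normal(0, 1.0, n)
    pheno = PhenotypeTable(
        y=y,
        individual=np.array([f"i{k}" for k in range(n)]),
        fixed=pd.DataFrame({"grp": [f"g{v}" for v in levels]}),
    )
    geno = simulate_genotypes(
        SimConfig(n_individuals=n, n_snps_per_chrom=[50], n_qtl=0, seed=60)
    )
    geno.individual_ids = [f"i{k}" for k in range(n)]
    grm = compute_grm(build_marker_matrix(geno, center=True))
    design = build_design(pheno, geno.individual_ids, has_pe=False)
    priors = elicit_priors(1.0, None, 1.0)
    mc = MCMCConfig(
        n_iter=8000, burn_in=2000, thin=1, seed=61,
        fix_variances={"u": 1e-8, "e": 1.0},
    )
    chains = fit(pheno, design, grm, "gaussian", priors, mc)
    dic = compute_dic(chains, pheno, design, "gaussian")
    assert abs(dic.p_D - q) / q < 0.15


def test_dic_identity_holds(gaussian_chains, small_gaussian_dataset):
    d = small_gaussian_dataset
    dic = compute_dic(gaussian_chains, d["pheno"], d["design"], "gaussian")
    assert math.isclose(dic.DIC, dic.mean_deviance + dic.p_D, rel_tol=1e-12)
    assert dic.p_D > 0


# ---------------------------------------------------------------------------
# Model comparison rule
# ---------------------------------------------------------------------------

def _dic(v):
    return DICResult(D_at_mean=v, mean_deviance=v, p_D=0.0, DIC=v)


@pytest.mark.parametrize(
    "delta, label, preferred",
    [
        (1.5, "equivalent", None),
        (0.0, "equivalent", None),
        (-1.99, "equivalent", None),
        (2.0, "weak preference", "b"),
        (-5.0, "weak preference", "a"),
        (7.0, "weak preference", "b"),
        (7.01, "strong preference", "b"),
        (5000.0, "strong preference", "b"),
    ],
)
def test_compare_models_thresholds(delta, label, preferred):
    res = compare_models(_dic(100.0 + delta), _dic(100.0))
    assert res.label == label
    assert res.preferred == preferred
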