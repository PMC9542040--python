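"""Shared fixtures: record factories and a small fitted posterior reused
across model/compare/decomp tests."""

from __future__ import annotations

import numpy as np
import pytest

from phylocrit import model, synth
from phylocrit.data_io import CleanRecord


def make_clean_record(
    species="sp1",
    pcrit_kpa=5.0,
    temp_meas=15.0,
    rel_acclim=0.0,
    salinity=0.0,
    log10_mass=1.0,
    log10_gs=0.0,
    log10_maxbm=3.0,
    mr_umol_h=None,
    respirometry="intermittent",
    resid_mr=0.0,
):
    pct = 100.0 * 10.0 ** (log10_mass - log10_maxbm)
    return CleanRecord(
        species_name=species,
        pcrit_kpa=pcrit_kpa,
        temp_meas=temp_meas,
        rel_acclim=rel_acclim,
        salinity=salinity,
        log10_mass=log10_mass,
        log10_gs=log10_gs,
        log10_maxbm=log10_maxbm,
        pct_max_mass=pct,
        log10_pct=np.log10(pct),
        mr_umol_h=mr_umol_h,
        respirometry=respirometry,
        resid_mr=resid_mr,
        mr_imputed=mr_umol_h is None,
    )


@pytest.fixture
def record_factory():
    return make_clean_record


def make_posterior(beta, sds, X=None, colnames=None, log_lik=None, re_phylo=None, re_species=None):
    """Assemble a Posterior from explicit draw arrays (chains, draws, ...)."""
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[-1]
    if colnames is None:
        colnames = [f"b{j}" for j in range(p)]
    if X is None:
        X = np.ones((1, p))
    n = X.shape[0]
    spec = model.ModelSpec(name="manual", fixed_terms=("intercept",), random_terms=())
    design = model.Design(
        X=np.asarray(X, dtype=float),
        colnames=list(colnames),
        y=np.zeros(n),
        species=["sp"] * n,
        species_order=["sp"],
        Z=np.ones((n, 1)),
        groups={0: list(range(n))},
    )
    if log_lik is None:
        log_lik = np.zeros((beta.shape[0], beta.shape[1], 0))
    return model.Posterior(
        spec=spec,
        design=design,
        beta=beta,
        sds={k: np.asarray(v, dtype=float) for k, v in sds.items()},
        log_lik=np.asarray(log_lik, dtype=float),
        re_phylo=None if re_phylo is None else np.asarray(re_phylo, dtype=float),
        re_species=None if re_species is None else np.asarray(re_species, dtype=float),
        rhat={},
        converged=True,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """120 records / 25 species simulated from the published-coefficient truth."""
    truth = synth.default_truth(seed=5)
    records, traits, C, truth = synth.simulate_dataset(truth, 120, n_species=25)
    return records, traits, C, truth


@pytest.fixture(scope="session")
def small_posterior(small_dataset):
    """A quick fit of the generating model on the small dataset."""
    records, _, C, truth = small_dataset
    cfg = model.MCMCConfig(chains=2, iterations=800, warmup=300)
    return model.fit(records, truth.spec(), C=C, mcmc=cfg, seed=2)
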