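"""Synthetic data with known truth, mirroring the Pcrit study's structure.

The generator draws a pure-birth species tree, species traits (genome size,
maximum body mass, habitat salinity, residual metabolism) and record-level
covariates, then produces Pcrit responses from the multilevel model's own
generative process:

    y = Xβ + a[species] + u[species] + ε,
    a ~ MVN(0, σ²_phylo C(tree, ρ)),  u ~ N(0, σ²_species),  ε ~ N(0, σ²_resid)

so that every stage of the pipeline — unit handling, the metabolic-rate
baseline, the mixed-model fit, model comparison and variance decomposition —
can be checked by parameter recovery without the study's deposited data.

Default truth: the fitted model's published posterior means (β, σ_phylo,
σ_species) with σ_resid = 1.67, which puts the phylogenetic heritability at
λ ≈ 0.56. Covariate distributions emulate the study's reported ranges
(temperature uniform on 5–32 °C, which brackets the 15/28 °C quartiles;
log10 body mass N(0.8, 0.8); log10 genome size N(0, 0.25); salinity 0 for
freshwater species, 30–36 PSU for marine). Whole-organism metabolic rates
are generated from the baseline regression plane plus each species' residual
metabolism, so the baseline module can recover that residual.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import phylo
from .data_io import CleanRecord, SpeciesTraits
from .model import ModelSpec, build_design

__all__ = [
    "CovariateConfig",
    "SyntheticTruth",
    "default_truth",
    "simulate_tree",
    "simulate_dataset",
    "true_variance_fractions",
    "recovery_experiment",
    "raw_tables",
    "TABLE1_BETA",
]

#: published posterior-mean fixed effects of the final model (kPa scale)
TABLE1_BETA = {
    "intercept": 5.56,
    "temp": -0.03,
    "gs": -7.47,
    "bm": -1.37,
    "salinity": 0.08,
    "resid_mr": 2.20,
    "temp:gs": 0.44,
    "temp:bm": 0.06,
}


@dataclass(frozen=True)
class CovariateConfig:
    """Distributions the covariates are drawn from (study emulation)."""

    temp_range: tuple = (5.0, 32.0)  # °C, brackets the 15/28 °C quartiles
    log10_mass_mean: float = 0.8  # log10 g
    log10_mass_sd: float = 0.8
    log10_gs_mean: float = 0.0  # log10 pg
    log10_gs_sd: float = 0.25
    fresh_prob: float = 0.5  # fraction of freshwater species
    marine_salinities: tuple = (30, 31, 32, 33, 34, 35, 36)
    resid_mr_sd: float = 0.15  # species-level residual metabolism (log10)
    # metabolic-rate baseline plane: log10 MR = b0 + b_sal*S + b_T*T + b_BM*log10 M
    mr_plane: tuple = (0.2, -0.002, 0.02, 0.88)
    mr_noise_sd: float = 0.1  # record-level noise around the plane
    missing_mr_fraction: float = 0.2


@dataclass
class SyntheticTruth:
    """Generating parameters; the per-species effects are filled in by
    :func:`simulate_dataset` for the realized dataset."""

    beta: dict = field(default_factory=lambda: dict(TABLE1_BETA))
    sd_phylo: float = 2.22
    sd_species: float = 1.02
    sd_resid: float = 1.67
    rho: float = phylo.DEFAULT_RHO
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    seed: int = 0
    species: list = field(default_factory=list)
    a: np.ndarray | None = None  # phylogenetic species effects
    u: np.ndarray | None = None  # unstructured species effects

    def spec(self, name: str = "truth") -> ModelSpec:
        random_terms = tuple(
            t for t, sd in (("phylo", self.sd_phylo), ("species", self.sd_species)) if sd > 0
        ) or ("species",)
        return ModelSpec(name=name, fixed_terms=tuple(self.beta), random_terms=random_terms)

    def to_json(self) -> str:
        d = asdict(self)
        d["a"] = None if self.a is None else list(map(float, self.a))
        d["u"] = None if self.u is None else list(map(float, self.u))
        return json.dumps(d, indent=2, default=str)


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """The study-emulating default truth (published coefficients)."""
    return SyntheticTruth(seed=seed, **overrides)


def simulate_tree(n_tips: int, seed: int = 0) -> phylo.Tree:
    """Random pure-birth topology with tips labelled s001..sNNN.

    Branch lengths are irrelevant downstream (Grafen heights replace them).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=_random.Random(int(seed)),
    )
    width = max(3, len(str(n_tips)))
    for taxon in dtree.taxon_namespace:
        taxon.label = f"s{int(taxon.label[1:]):0{width}d}"
    for edge in dtree.preorder_edge_iter():
        edge.length = None
    return phylo.Tree(dtree=dtree)


def _allocate_records(n_records: int, n_species: int, rng, dist: str) -> np.ndarray:
    if n_records < n_species:
        raise ValueError(f"n_records={n_records} < n_species={n_species}")
    extra = n_records - n_species
    if dist == "multinomial":
        counts = rng.multinomial(extra, np.full(n_species, 1.0 / n_species))
    elif dist == "geometric":  # a few heavily studied species, many singletons
        w = rng.geometric(0.3, size=n_species).astype(float)
        counts = rng.multinomial(extra, w / w.sum())
    else:
        raise ValueError(f"unknown records-per-species distribution {dist!r}")
    return counts + 1


def simulate_dataset(
    truth: SyntheticTruth,
    n_records: int,
    tree: phylo.Tree | None = None,
    n_species: int | None = None,
    records_per_species_dist: str = "multinomial",
):
    """Generate (records, traits, C, truth) for a given truth.

    Supply either a ``tree`` or ``n_species`` (a pure-birth tree is then
    simulated from ``truth.seed``). The returned records are CleanRecords
    with the truth's species residual metabolism already attached; use
    :func:`raw_tables` for the un-standardized CSV schema. Same seed, same
    byte-for-byte output.
    """
    rng = np.random.default_rng(truth.seed)
    if tree is None:
        if n_species is None:
            raise ValueError("supply a tree or n_species")
        tree = simulate_tree(n_species, seed=truth.seed)
    species = sorted(tree.tip_labels)
    m = len(species)
    C = phylo.correlation_matrix(phylo.rho_transform(phylo.grafen_heights(tree), truth.rho))
    C = C.reorder(species)
    cfg = truth.covariates

    # species-level draws
    log10_gs = rng.normal(cfg.log10_gs_mean, cfg.log10_gs_sd, size=m)
    fresh = rng.uniform(size=m) < cfg.fresh_prob
    salinity_sp = np.where(fresh, 0.0, rng.choice(cfg.marine_salinities, size=m)).astype(float)
    resid_mr_sp = rng.normal(0.0, cfg.resid_mr_sd, size=m)
    a = truth.sd_phylo * (np.linalg.cholesky(C.matrix + 1e-10 * np.eye(m)) @ rng.standard_normal(m)) if truth.sd_phylo > 0 else np.zeros(m)
    u = rng.normal(0.0, truth.sd_species, size=m) if truth.sd_species > 0 else np.zeros(m)

    counts = _allocate_records(n_records, m, rng, records_per_species_dist)
    records: list[CleanRecord] = []
    sp_of_record: list[int] = []
    for k, sp in enumerate(species):
        for _ in range(counts[k]):
            t = rng.uniform(*cfg.temp_range)
            lm = rng.normal(cfg.log10_mass_mean, cfg.log10_mass_sd)
            records.append(
                CleanRecord(
                    species_name=sp,
                    pcrit_kpa=np.nan,  # filled below
                    temp_meas=t,
                    rel_acclim=0.0,
                    salinity=salinity_sp[k],
                    log10_mass=lm,
                    log10_gs=log10_gs[k],
                    log10_maxbm=np.nan,  # filled below
                    pct_max_mass=np.nan,
                    log10_pct=np.nan,
                    mr_umol_h=None,
                    respirometry="intermittent",
                    resid_mr=resid_mr_sp[k],
                    mr_imputed=False,
                )
            )
            sp_of_record.append(k)

    # species maximum mass: just above the largest simulated individual
    traits: list[SpeciesTraits] = []
    for k, sp in enumerate(species):
        masses = [r.log10_mass for r in records if r.species_name == sp]
        log10_maxbm = max(masses) + rng.uniform(0.05, 0.5)
        traits.append(SpeciesTraits(sp, float(10.0 ** log10_gs[k]), float(10.0**log10_maxbm)))
        for r in records:
            if r.species_name == sp:
                r.log10_maxbm = log10_maxbm
                r.pct_max_mass = 100.0 * 10.0 ** (r.log10_mass - log10_maxbm)
                r.log10_pct = np.log10(r.pct_max_mass)

    # metabolic rate from the baseline plane + species residual metabolism
    b0, b_sal, b_t, b_bm = cfg.mr_plane
    miss = rng.uniform(size=len(records)) < cfg.missing_mr_fraction
    for i, r in enumerate(records):
        if miss[i]:
            r.mr_umol_h = None
            continue
        log10_mr = (
            b0
            + b_sal * r.salinity
            + b_t * r.temp_meas
            + b_bm * r.log10_mass
            + r.resid_mr
            + rng.normal(0.0, cfg.mr_noise_sd)
        )
        r.mr_umol_h = float(10.0**log10_mr)

    # response from the generative model
    design = build_design(records, truth.spec(), species_order=species)
    beta_vec = np.array([truth.beta[t] for t in truth.beta], dtype=float)
    eps = rng.normal(0.0, truth.sd_resid, size=len(records)) if truth.sd_resid > 0 else np.zeros(len(records))
    y = design.X @ beta_vec + a[sp_of_record] + u[sp_of_record] + eps
    for i, r in enumerate(records):
        r.pcrit_kpa = float(y[i])

    truth.species = species
    truth.a = a
    truth.u = u
    return records, traits, C, truth


def true_variance_fractions(truth: SyntheticTruth, records, mode: str = "realized") -> dict:
    """Generating variance fractions for a simulated dataset.

    The fixed-effect variance is always the sample variance of Xβ_true over
    the records. For the random and residual parts, ``mode="realized"``
    (default) uses the variance of the effect draws that actually generated
    this dataset — the recovery target a fit to one dataset can see —
    while ``mode="theoretical"`` uses the generating σ². The two differ by
    the sampling noise of a single multivariate-normal realization, which is
    substantial for phylogenetically correlated effects even at 170 species.
    """
    design = build_design(records, truth.spec(), species_order=truth.species or None)
    beta_vec = np.array([truth.beta[t] for t in truth.beta], dtype=float)
    xb = design.X @ beta_vec
    v_fix = float(np.var(xb, ddof=1))
    if mode == "theoretical":
        v = {
            "marginal": v_fix,
            "phylo": truth.sd_phylo**2,
            "species": truth.sd_species**2,
            "residual": truth.sd_resid**2,
        }
    elif mode == "realized":
        if truth.a is None or truth.u is None:
            raise ValueError("realized mode needs the truth returned by simulate_dataset")
        za = design.Z @ truth.a
        zu = design.Z @ truth.u
        eps = design.y - xb - za - zu
        v = {
            "marginal": v_fix,
            "phylo": float(np.var(za, ddof=1)),
            "species": float(np.var(zu, ddof=1)),
            "residual": float(np.var(eps, ddof=1)),
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = sum(v.values())
    out = {f"f_{k}": val / total for k, val in v.items()}
    denom = v["phylo"] + v["species"] + v["residual"]
    out["lambda"] = v["phylo"] / denom if denom > 0 else 0.0
    return out


def recovery_experiment(
    truth: SyntheticTruth,
    n_replicates: int,
    n_species: int,
    n_records: int,
    fit_config,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated simulate-and-refit: 95% CI coverage and bias per coefficient.

    Each replicate draws a fresh tree and dataset (sub-seeded from ``seed``)
    and refits the generating model. Returns one row per fixed term with the
    empirical coverage of the central 95% interval, the mean posterior-mean
    bias, and the mean posterior SD.
    """
    from . import model as model_mod

    terms = list(truth.beta)
    cover = {t: 0 for t in terms}
    bias = {t: [] for t in terms}
    psd = {t: [] for t in terms}
    for rep in range(n_replicates):
        rep_truth = SyntheticTruth(
            beta=dict(truth.beta),
            sd_phylo=truth.sd_phylo,
            sd_species=truth.sd_species,
            sd_resid=truth.sd_resid,
            rho=truth.rho,
            covariates=truth.covariates,
            seed=int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31)),
        )
        records, _, C, rep_truth = simulate_dataset(rep_truth, n_records, n_species=n_species)
        post = model_mod.fit(records, rep_truth.spec(), C=C, mcmc=fit_config, seed=rep_truth.seed)
        flat = post.flat_beta()
        for j, t in enumerate(post.design.colnames):
            lo, hi = np.quantile(flat[:, j], [0.025, 0.975])
            if lo <= truth.beta[t] <= hi:
                cover[t] += 1
            bias[t].append(flat[:, j].mean() - truth.beta[t])
            psd[t].append(flat[:, j].std())
    return pd.DataFrame(
        {
            "term": terms,
            "coverage": [cover[t] / n_replicates for t in terms],
            "mean_bias": [float(np.mean(bias[t])) for t in terms],
            "mean_posterior_sd": [float(np.mean(psd[t])) for t in terms],
        }
    ).set_index("term")


def raw_tables(records, traits) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Un-standardized CSV tables in the measurement-database schema."""
    db = pd.DataFrame(
        {
            "species": [r.species_name for r in records],
            "pcrit": [r.pcrit_kpa for r in records],
            "pcrit_unit": "kPa",
            "temp_meas": [r.temp_meas for r in records],
            "temp_acclim": [r.temp_meas + r.rel_acclim for r in records],
            "salinity": [r.salinity for r in records],
            "body_mass_g": [10.0**r.log10_mass for r in records],
            "metabolic_rate": [r.mr_umol_h if r.mr_umol_h is not None else np.nan for r in records],
            "mr_unit": ["umol_O2_per_h" if r.mr_umol_h is not None else "" for r in records],
            "respirometry": [r.respirometry for r in records],
            "source_id": "synthetic",
        }
    )
    tr = pd.DataFrame(
        {
            "species": [t.species_name for t in traits],
            "genome_size_pg": [t.genome_size for t in traits],
            "max_body_mass_g": [t.max_body_mass for t in traits],
        }
    )
    return db, tr
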