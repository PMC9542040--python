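"""The Bayesian phylogenetic multilevel model of critical oxygen tension.

The response is Pcrit in kPa (untransformed). For record i of species s(i):

    y_i = x_i' β + a_{s(i)} + u_{s(i)} + ε_i
    a ~ MVN(0, σ²_phylo C)      — phylogenetically structured species intercepts
    u ~ MVN(0, σ²_species I)    — unstructured species intercepts
    ε_i ~ N(0, σ²_resid)

with C the Grafen/rho correlation matrix from :mod:`phylocrit.phylo`
(unit diagonal, so σ²_phylo is the phylogenetic variance on the trait
scale). Priors are weakly informative: β ~ N(0, 10²) per coefficient on the
natural covariate scales and half-N(0, 5) on each standard deviation.

Because every conditional distribution in this model is Gaussian, the fit
does not need a generic gradient sampler. β, a and u are integrated out
analytically, leaving a posterior over only the 1–3 log standard
deviations; that low-dimensional block is sampled by an adaptive
random-walk Metropolis chain, and β | σ, y and (a, u) | β, σ, y are then
drawn from their exact Gaussian conditionals per kept draw. The draws are
exact samples from the full joint posterior; convergence is monitored by
split-R̂ (flagged, never silently discarded).

Per-record log-likelihood contributions — the conditional normals
N(y_i | x_i'β + a + u, σ²_resid) — are stored for PSIS-LOO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .phylo import PhyloCorrelation

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "Design",
    "Posterior",
    "FIXED_TERMS",
    "final_model_spec",
    "build_design",
    "marginal_log_likelihood",
    "pointwise_log_likelihood",
    "fit",
    "summarize",
    "p_map",
]

logger = logging.getLogger(__name__)

RESPIROMETRY_REFERENCE = "intermittent"

# term -> per-record column value; interactions are literal products
_MAIN_TERMS = {
    "intercept": lambda r: 1.0,
    "temp": lambda r: r.temp_meas,
    "gs": lambda r: r.log10_gs,
    "bm": lambda r: r.log10_mass,
    "salinity": lambda r: r.salinity,
    "resid_mr": lambda r: r.resid_mr,
    "rel_acclim": lambda r: r.rel_acclim,
    "log10_pct": lambda r: r.log10_pct,
    "log10_pct_sq": lambda r: r.log10_pct**2,
    "log10_maxbm": lambda r: r.log10_maxbm,
}
_INTERACTIONS = {
    "temp:gs": ("temp", "gs"),
    "temp:bm": ("temp", "bm"),
    "temp:log10_pct": ("temp", "log10_pct"),
    "temp:log10_maxbm": ("temp", "log10_maxbm"),
}
FIXED_TERMS = tuple(_MAIN_TERMS) + ("respirometry",) + tuple(_INTERACTIONS)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate fixed + random effect structure with prior scales."""

    name: str
    fixed_terms: tuple
    random_terms: tuple = ("phylo", "species")
    beta_prior_scale: float = 10.0
    sd_prior_scale: float = 5.0

    def __post_init__(self) -> None:
        unknown = [t for t in self.fixed_terms if t not in FIXED_TERMS]
        if unknown:
            raise ValueError(f"unknown fixed terms: {unknown}")
        for t in self.fixed_terms:
            if t in _INTERACTIONS:
                a, b = _INTERACTIONS[t]
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise ValueError(f"interaction {t} requires main effects {a} and {b}")
        unknown = [t for t in self.random_terms if t not in ("phylo", "species")]
        if unknown:
            raise ValueError(f"unknown random terms: {unknown}")


def final_model_spec() -> ModelSpec:
    """The most-parsimonious model: T, GS, BM, salinity, residual MR and the
    two temperature interactions, with both random effects."""
    return ModelSpec(
        name="final",
        fixed_terms=(
            "intercept",
            "temp",
            "gs",
            "bm",
            "salinity",
            "resid_mr",
            "temp:gs",
            "temp:bm",
        ),
    )


@dataclass(frozen=True)
class MCMCConfig:
    """Chain geometry. ``iterations`` counts total iterations per chain,
    of which the first ``warmup`` adapt the proposal and are discarded."""

    chains: int = 3
    iterations: int = 15_000
    warmup: int = 7_500

    def __post_init__(self) -> None:
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("need 0 <= warmup < iterations")


#: lighter setting used during model selection; the winner is refit in full
LIGHT_MCMC = MCMCConfig(chains=2, iterations=4_000, warmup=1_000)


@dataclass
class Design:
    """Encoded design: fixed-effect matrix, response, species structure."""

    X: np.ndarray  # (n, p)
    colnames: list
    y: np.ndarray  # (n,)
    species: list  # per-record species name
    species_order: list  # row/col order of Z and C
    Z: np.ndarray  # (n, m) species indicator matrix
    groups: dict  # species row index -> list of record indices


def build_design(records, spec: ModelSpec, species_order: list | None = None) -> Design:
    """Build the design matrix in spec term order plus the species mapping.

    ``respirometry`` is dummy-coded against the reference level
    "intermittent". ``species_order`` (e.g. from a PhyloCorrelation) fixes
    the random-effect ordering; species in the data but absent from it are
    an error.
    """
    present: list = []
    for r in records:
        if r.species_name not in present:
            present.append(r.species_name)
    if species_order is None:
        species_order = present
    else:
        unseen = sorted(set(present) - set(species_order))
        if unseen:
            raise ValueError(f"records contain species missing from the correlation matrix: {unseen}")
        species_order = [s for s in species_order if s in set(present)]

    cols, names = [], []
    for term in spec.fixed_terms:
        if term in _MAIN_TERMS:
            cols.append([_MAIN_TERMS[term](r) for r in records])
            names.append(term)
        elif term == "respirometry":
            levels = [lv for lv in ("closed", "unknown") if any(r.respirometry == lv for r in records)]
            for lv in levels:
                cols.append([1.0 if r.respirometry == lv else 0.0 for r in records])
                names.append(f"respirometry[{lv}]")
        else:  # interaction
            a, b = _INTERACTIONS[term]
            cols.append([_MAIN_TERMS[a](r) * _MAIN_TERMS[b](r) for r in records])
            names.append(term)
    n = len(records)
    X = np.array(cols, dtype=float).T.reshape(n, len(names))

    sp_index = {s: k for k, s in enumerate(species_order)}
    Z = np.zeros((n, len(species_order)))
    groups: dict = {k: [] for k in range(len(species_order))}
    for i, r in enumerate(records):
        k = sp_index[r.species_name]
        Z[i, k] = 1.0
        groups[k].append(i)
    y = np.array([r.pcrit_kpa for r in records], dtype=float)
    return Design(
        X=X,
        colnames=names,
        y=y,
        species=[r.species_name for r in records],
        species_order=list(species_order),
        Z=Z,
        groups=groups,
    )


def _chol_logdet_solve(S: np.ndarray, y: np.ndarray):
    """Cholesky of S plus logdet and S⁻¹y; raises LinAlgError if not PD."""
    L = cholesky(S, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    alpha = solve_triangular(L, y, lower=True)
    return L, logdet, alpha


def marginal_log_likelihood(y, X, beta, sds: dict, Z, C: np.ndarray | None = None) -> float:
    """log N(y; Xβ, σ²_phylo ZCZᵀ + σ²_species ZZᵀ + σ²_resid I).

    Random effects are integrated out; β is fixed. ``sds`` holds
    "sd_phylo"/"sd_species" (optional, 0 if absent) and "sd_resid".
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    S = sds.get("sd_resid", 0.0) ** 2 * np.eye(n)
    if sds.get("sd_phylo", 0.0) > 0:
        if C is None:
            raise ValueError("phylo random effect requires a correlation matrix")
        S += sds["sd_phylo"] ** 2 * Z @ C @ Z.T
    if sds.get("sd_species", 0.0) > 0:
        S += sds["sd_species"] ** 2 * Z @ Z.T
    r = y - np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    _, logdet, alpha = _chol_logdet_solve(S, r)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + alpha @ alpha))


def pointwise_log_likelihood(y, mu, sd_resid: float) -> np.ndarray:
    """Per-record conditional normal log densities given the random effects."""
    return stats.norm.logpdf(np.asarray(y, float), loc=np.asarray(mu, float), scale=sd_resid)


@dataclass
class Posterior:
    """MCMC draws (chain × draw layout) with diagnostics.

    ``beta`` is (chains, draws, p); each entry of ``sds`` is
    (chains, draws); ``log_lik`` is (chains, draws, n) of per-record
    conditional log densities; random-effect draws ``re_phylo``/``re_species``
    are (chains, draws, m) when the corresponding term is in the spec.
    """

    spec: ModelSpec
    design: Design
    beta: np.ndarray
    sds: dict
    log_lik: np.ndarray
    re_phylo: np.ndarray | None
    re_species: np.ndarray | None
    rhat: dict
    converged: bool
    warnings: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def flat_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def flat_sd(self, name: str) -> np.ndarray:
        return self.sds[name].reshape(-1)

    def fixed_means(self) -> dict:
        b = self.flat_beta().mean(axis=0)
        return dict(zip(self.design.colnames, b))

    def to_inferencedata(self):
        """arviz InferenceData with posterior and log_likelihood groups."""
        import arviz as az

        post = {f"beta_{name}": self.beta[:, :, j] for j, name in enumerate(self.design.colnames)}
        for k, v in self.sds.items():
            post[k] = v
        return az.from_dict(
            posterior=post,
            log_likelihood={"y": self.log_lik},
            coords={"record": np.arange(self.log_lik.shape[-1])},
            dims={"y": ["record"]},
        )


def _adaptive_rwm(logpost, x0, iterations, warmup, rng):
    """Adaptive random-walk Metropolis; returns (draws, accept_rate).

    Proposal covariance adapts to the empirical chain covariance during
    warmup (Haario-style, 2.38²/d scaling) with a Robbins–Monro tweak of the
    global scale toward ~30% acceptance; frozen after warmup.
    """
    d = x0.size
    x = x0.copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")
    base = (2.38**2 / d) * np.eye(d) * 0.1
    log_scale = 0.0
    history = np.empty((warmup, d))
    draws = np.empty((iterations - warmup, d))
    n_acc = 0
    prop_chol = cholesky(base, lower=True)
    for t in range(iterations):
        step = np.exp(0.5 * log_scale) * (prop_chol @ rng.standard_normal(d))
        x_new = x + step
        lp_new = logpost(x_new)
        accept = np.log(rng.uniform()) < lp_new - lp
        if accept:
            x, lp = x_new, lp_new
        if t < warmup:
            history[t] = x
            log_scale += ((1.0 if accept else 0.0) - 0.3) / np.sqrt(t + 1)
            if t >= 19 and (t + 1) % 20 == 0:
                emp = np.cov(history[: t + 1].T) + 1e-8 * np.eye(d)
                emp = np.atleast_2d(emp)
                prop_chol = cholesky((2.38**2 / d) * emp, lower=True)
        else:
            draws[t - warmup] = x
            n_acc += bool(accept)
    return draws, n_acc / max(iterations - warmup, 1)


def fit(
    records,
    spec: ModelSpec,
    C: PhyloCorrelation | None = None,
    mcmc: MCMCConfig = MCMCConfig(),
    seed: int = 0,
) -> Posterior:
    """Sample the posterior of the phylogenetic multilevel model.

    ``C`` is required when "phylo" is in the spec's random terms; its species
    set must cover the records. With no records at all the draws come
    straight from the priors (useful as a prior-predictive check).
    """
    use_phylo = "phylo" in spec.random_terms
    use_species = "species" in spec.random_terms
    if use_phylo and C is None:
        raise ValueError("spec includes a phylogenetic effect but no correlation matrix given")

    design = build_design(records, spec, species_order=C.species if C is not None else None)
    n, p = design.X.shape
    m = len(design.species_order)
    if n == 0:
        return _prior_draws(spec, design, mcmc, seed)

    Cm = None
    if use_phylo:
        Cm = C.reorder(design.species_order).matrix
        if not np.allclose(np.diag(Cm), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")

    sd_names = (["sd_phylo"] if use_phylo else []) + (["sd_species"] if use_species else []) + ["sd_resid"]
    d = len(sd_names)
    X, y, Z = design.X, design.y, design.Z
    tau2 = spec.beta_prior_scale**2
    XBX = tau2 * (X @ X.T)
    ZZt = Z @ Z.T
    Ks = []
    if use_phylo:
        Ks.append(Z @ Cm @ Z.T)
    if use_species:
        Ks.append(ZZt)
    s_prior2 = spec.sd_prior_scale**2

    def logpost(x):
        if np.any(x > 12) or np.any(x < -14):
            return -np.inf
        sig2 = np.exp(2 * x)
        S = XBX + sig2[-1] * np.eye(n)
        for k, K in enumerate(Ks):
            S = S + sig2[k] * K
        try:
            _, logdet, alpha = _chol_logdet_solve(S, y)
        except np.linalg.LinAlgError:
            return -np.inf
        ll = -0.5 * (logdet + alpha @ alpha)
        # half-normal prior on each sd plus the log|dσ/dx| = log σ Jacobian
        lp = np.sum(-sig2 / (2 * s_prior2) + x)
        return ll + lp

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(2 * mcmc.chains)
    chain_seeds = child_seeds[: mcmc.chains]
    D = mcmc.iterations - mcmc.warmup
    sd_draws = np.empty((mcmc.chains, D, d))
    accept_rates = []
    scale0 = np.log(max(np.std(y), 1e-3) / np.sqrt(d))
    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[c])
        x0 = scale0 + 0.3 * rng.standard_normal(d)
        for _ in range(50):  # nudge a finite start if needed
            if np.isfinite(logpost(x0)):
                break
            x0 = scale0 + 0.5 * rng.standard_normal(d)
        draws, acc = _adaptive_rwm(logpost, x0, mcmc.iterations, mcmc.warmup, rng)
        sd_draws[c] = np.exp(draws)
        accept_rates.append(acc)

    # exact Gaussian conditionals per kept draw
    beta = np.empty((mcmc.chains, D, p))
    log_lik = np.empty((mcmc.chains, D, n))
    re_p = np.empty((mcmc.chains, D, m)) if use_phylo else None
    re_s = np.empty((mcmc.chains, D, m)) if use_species else None
    Cinv = np.linalg.inv(Cm) if use_phylo else None
    blocks = int(use_phylo) + int(use_species)
    G = np.hstack([Z] * blocks) if blocks else None
    GtG = np.tile(Z.T @ Z, (blocks, blocks)) if blocks else None
    for c in range(mcmc.chains):
        rng = np.random.default_rng(child_seeds[mcmc.chains + c])
        for t in range(D):
            sig = sd_draws[c, t]
            sig2 = sig**2
            Sr = sig2[-1] * np.eye(n)
            for k, K in enumerate(Ks):
                Sr = Sr + sig2[k] * K
            Lr = cho_factor(Sr, lower=True)
            SinvX = cho_solve(Lr, X)
            A = X.T @ SinvX + np.eye(p) / tau2
            La = cholesky(A, lower=True)
            mu_b = cho_solve((La, True), SinvX.T @ y)
            b = mu_b + solve_triangular(La.T, rng.standard_normal(p), lower=False)
            beta[c, t] = b
            resid = y - X @ b
            if blocks:
                Dinv_blocks = []
                k = 0
                if use_phylo:
                    Dinv_blocks.append(Cinv / sig2[k])
                    k += 1
                if use_species:
                    Dinv_blocks.append(np.eye(m) / sig2[k])
                Q = GtG / sig2[-1]
                for j, Db in enumerate(Dinv_blocks):
                    Q[j * m : (j + 1) * m, j * m : (j + 1) * m] += Db
                Lq = cholesky(Q, lower=True)
                mu_re = cho_solve((Lq, True), G.T @ resid / sig2[-1])
                re = mu_re + solve_triangular(Lq.T, rng.standard_normal(blocks * m), lower=False)
                j = 0
                mu_cond = X @ b
                if use_phylo:
                    re_p[c, t] = re[j * m : (j + 1) * m]
                    mu_cond = mu_cond + Z @ re_p[c, t]
                    j += 1
                if use_species:
                    re_s[c, t] = re[j * m : (j + 1) * m]
                    mu_cond = mu_cond + Z @ re_s[c, t]
            else:
                mu_cond = X @ b
            log_lik[c, t] = pointwise_log_likelihood(y, mu_cond, sig[-1])

    sds = {name: sd_draws[:, :, k] for k, name in enumerate(sd_names)}
    rhat, converged, warns = _diagnostics(beta, sds, design.colnames, accept_rates)
    return Posterior(
        spec=spec,
        design=design,
        beta=beta,
        sds=sds,
        log_lik=log_lik,
        re_phylo=re_p,
        re_species=re_s,
        rhat=rhat,
        converged=converged,
        warnings=warns,
    )


def _prior_draws(spec, design, mcmc, seed):
    """Draws straight from the priors (data-free fit)."""
    rng = np.random.default_rng(seed)
    D = mcmc.iterations - mcmc.warmup
    p = len(design.colnames) if design.colnames else len(spec.fixed_terms)
    names = design.colnames or list(spec.fixed_terms)
    beta = spec.beta_prior_scale * rng.standard_normal((mcmc.chains, D, p))
    sd_names = [f"sd_{t}" for t in spec.random_terms] + ["sd_resid"]
    sds = {nm: np.abs(spec.sd_prior_scale * rng.standard_normal((mcmc.chains, D))) for nm in sd_names}
    design.colnames = names
    rhat = {}
    return Posterior(
        spec=spec,
        design=design,
        beta=beta,
        sds=sds,
        log_lik=np.zeros((mcmc.chains, D, 0)),
        re_phylo=None,
        re_species=None,
        rhat=rhat,
        converged=True,
        warnings=["prior draws: no data supplied"],
    )


def _diagnostics(beta, sds, colnames, accept_rates):
    import arviz as az

    rhat = {}
    for j, name in enumerate(colnames):
        rhat[f"beta_{name}"] = float(az.rhat(az.convert_to_dataset(beta[:, :, j]))["x"].values)
    for k, v in sds.items():
        rhat[k] = float(az.rhat(az.convert_to_dataset(v))["x"].values)
    warns = []
    bad = {k: v for k, v in rhat.items() if not np.isfinite(v) or v > 1.01}
    converged = not bad
    if bad:
        msg = "split-Rhat > 1.01 for: " + ", ".join(f"{k}={v:.3f}" for k, v in bad.items())
        warns.append(msg)
        logger.warning(msg)
    if accept_rates and (min(accept_rates) < 0.1 or max(accept_rates) > 0.7):
        warns.append(f"unusual Metropolis acceptance rates: {np.round(accept_rates, 3).tolist()}")
    return rhat, converged, warns


def p_map(draws: np.ndarray) -> float:
    """MAP-based Bayesian p-value: KDE density at 0 over density at the mode."""
    draws = np.asarray(draws, dtype=float).ravel()
    if np.allclose(draws, draws[0]):
        return 1.0 if np.isclose(draws[0], 0.0) else 0.0
    kde = stats.gaussian_kde(draws)
    grid = np.linspace(draws.min(), draws.max(), 512)
    d_map = kde(grid).max()
    return float(np.clip(kde(0.0)[0] / d_map, 0.0, 1.0))


def summarize(posterior: Posterior) -> pd.DataFrame:
    """Posterior summary table: mean, central 95% interval, effective sample
    size and p(MAP) per parameter (p(MAP) for fixed effects only)."""
    import arviz as az

    rows = []

    def ess(arr2d):
        return float(az.ess(az.convert_to_dataset(arr2d))["x"].values)

    for name in posterior.sds:
        v = posterior.sds[name]
        flat = v.reshape(-1)
        rows.append(
            {
                "parameter": name,
                "mean": flat.mean(),
                "q2.5": np.quantile(flat, 0.025),
                "q97.5": np.quantile(flat, 0.975),
                "effective_sampling": ess(v),
                "p_map": np.nan,
            }
        )
    for j, name in enumerate(posterior.design.colnames):
        v = posterior.beta[:, :, j]
        flat = v.reshape(-1)
        rows.append(
            {
                "parameter": name,
                "mean": flat.mean(),
                "q2.5": np.quantile(flat, 0.025),
                "q97.5": np.quantile(flat, 0.975),
                "effective_sampling": ess(v),
                "p_map": p_map(flat),
            }
        )
    df = pd.DataFrame(rows).set_index("parameter")
    bad = df[(df["q2.5"] > df["mean"]) | (df["mean"] > df["q97.5"])]
    if len(bad):
        logger.warning("mean outside central interval for: %s", list(bad.index))
    return df
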