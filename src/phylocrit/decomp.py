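"""Variance partitioning of the fitted model and phylogenetic heritability.

Per posterior draw the total variance of the response is split into four
parts (finite-population fixed-effect variance plus the three model scale
parameters):

    V_fix     = Var over records of x_i'β      (marginal / fixed effects)
    V_phylo   = σ²_phylo                       (C has unit diagonal)
    V_species = σ²_species
    V_resid   = σ²_resid

and each fraction is the part over the sum. The phylogenetic heritability —
the lambda equivalent — conditions on the fixed effects:

    λ = σ²_phylo / (σ²_phylo + σ²_species + σ²_resid).

A supplementary diagnostic reports how much of the fixed-effect variation is
shared with phylogeny: per draw, the R² of regressing the record-level
fitted values x_i'β on the record's phylogenetic effect a_{s(i)}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Design, Posterior

__all__ = ["VarianceDecomposition", "partition", "heritability", "shared_fixed_phylo"]

_FRACTIONS = ("f_marginal", "f_phylo", "f_species", "f_residual")


@dataclass
class VarianceDecomposition:
    """Per-draw variance fractions plus λ, with posterior summaries."""

    draws: pd.DataFrame  # columns f_marginal, f_phylo, f_species, f_residual, lambda

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in (*_FRACTIONS, "lambda"):
            v = self.draws[col].to_numpy()
            rows.append(
                {
                    "component": col,
                    "mean": v.mean(),
                    "median": np.median(v),
                    "q2.5": np.quantile(v, 0.025),
                    "q97.5": np.quantile(v, 0.975),
                }
            )
        return pd.DataFrame(rows).set_index("component")


def partition(
    posterior: Posterior,
    design: Design | None = None,
    population: str = "super",
) -> VarianceDecomposition:
    """Variance partition of the fitted model, per draw.

    ``population="super"`` takes each random component's variance as its
    scale parameter σ² — the superpopulation convention that matches the
    reported-summary-table reading of the variances. ``population="finite"``
    is Gelman's ANOVA convention: the sample variance, over records, of the
    realized effect draws (Za, Zu, and the implied residuals). The finite
    variant is the estimand a single dataset identifies — for correlated
    phylogenetic effects the realized variance of one draw sits well below
    σ² (by roughly the mean off-diagonal correlation) — and is therefore
    what parameter-recovery experiments compare against.
    """
    if design is None:
        design = posterior.design
    X = design.X
    if X.shape[0] == 0:
        raise ValueError("cannot partition variance without records")
    beta = posterior.flat_beta()
    v_fix = np.var(X @ beta.T, axis=0, ddof=1)
    zeros = np.zeros_like(v_fix)
    if population == "super":
        v_phylo = posterior.flat_sd("sd_phylo") ** 2 if "sd_phylo" in posterior.sds else zeros
        v_species = posterior.flat_sd("sd_species") ** 2 if "sd_species" in posterior.sds else zeros
        v_resid = posterior.flat_sd("sd_resid") ** 2
    elif population == "finite":
        Z = design.Z
        fitted = X @ beta.T
        if posterior.re_phylo is not None:
            za = Z @ posterior.re_phylo.reshape(-1, Z.shape[1]).T
            v_phylo = np.var(za, axis=0, ddof=1)
            fitted = fitted + za
        elif "sd_phylo" in posterior.sds:
            raise ValueError("finite partition needs phylogenetic effect draws")
        else:
            v_phylo = zeros
        if posterior.re_species is not None:
            zu = Z @ posterior.re_species.reshape(-1, Z.shape[1]).T
            v_species = np.var(zu, axis=0, ddof=1)
            fitted = fitted + zu
        elif "sd_species" in posterior.sds:
            raise ValueError("finite partition needs species effect draws")
        else:
            v_species = zeros
        v_resid = np.var(design.y[:, None] - fitted, axis=0, ddof=1)
    else:
        raise ValueError(f"unknown population {population!r}")
    total = v_fix + v_phylo + v_species + v_resid
    if np.any(total <= 0):
        raise ValueError("zero total variance in some draws")
    cond = v_phylo + v_species + v_resid
    draws = pd.DataFrame(
        {
            "f_marginal": v_fix / total,
            "f_phylo": v_phylo / total,
            "f_species": v_species / total,
            "f_residual": v_resid / total,
            "lambda": np.divide(v_phylo, cond, out=np.zeros_like(v_phylo), where=cond > 0),
        }
    )
    return VarianceDecomposition(draws=draws)


def heritability(posterior: Posterior) -> dict:
    """λ = σ²_phylo / (σ²_phylo + σ²_species + σ²_resid), mean and 95% CI."""
    v_phylo = posterior.flat_sd("sd_phylo") ** 2 if "sd_phylo" in posterior.sds else 0.0
    v_species = posterior.flat_sd("sd_species") ** 2 if "sd_species" in posterior.sds else 0.0
    v_resid = posterior.flat_sd("sd_resid") ** 2
    denom = np.asarray(v_phylo + v_species + v_resid, dtype=float)
    lam = np.divide(np.asarray(v_phylo, float), denom, out=np.zeros_like(denom), where=denom > 0)
    lam = np.atleast_1d(lam)
    return {
        "mean": float(lam.mean()),
        "median": float(np.median(lam)),
        "q2.5": float(np.quantile(lam, 0.025)),
        "q97.5": float(np.quantile(lam, 0.975)),
    }


def shared_fixed_phylo(posterior: Posterior) -> np.ndarray:
    """Per draw: fraction of fixed-effect variation explained by phylogeny.

    The squared correlation between record-level fitted values x_i'β and the
    record's phylogenetic effect draw; a Venn-style overlap diagnostic, not
    part of the main partition.
    """
    if posterior.re_phylo is None:
        raise ValueError("posterior has no phylogenetic effect draws")
    X, Z = posterior.design.X, posterior.design.Z
    beta = posterior.flat_beta()
    a = posterior.re_phylo.reshape(-1, posterior.re_phylo.shape[-1])
    out = np.empty(beta.shape[0])
    for t in range(beta.shape[0]):
        fit_t = X @ beta[t]
        phy_t = Z @ a[t]
        if fit_t.std() == 0 or phy_t.std() == 0:
            out[t] = 0.0
        else:
            out[t] = np.corrcoef(fit_t, phy_t)[0, 1] ** 2
    return out
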