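"""Residual metabolic rate: the whole-organism metabolic rate corrected for
salinity, temperature and body mass.

log10 metabolic rate (μmol O2 h⁻¹) is regressed by OLS on salinity,
measurement temperature and log10 body mass over the records with an
observed rate. The residual of a record — observed minus expected log10
rate — expresses whether an individual's metabolism is high or low for its
size and water conditions, and enters the Pcrit model as a covariate.
Records without a metabolic rate get residual 0 (an average fish) and are
flagged as imputed so sensitivity refits can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import CleanRecord

__all__ = ["MRBaseline", "fit_mr_baseline", "residual_mr", "attach_residuals"]

_PREDICTORS = ("salinity", "temp_meas", "log10_mass")


@dataclass
class MRBaseline:
    """OLS fit of log10 MR ~ salinity + temperature + log10 body mass."""

    intercept: float
    b_salinity: float
    b_temp: float
    b_logmass: float
    r_squared: float
    n_used: int

    def predict(self, record: CleanRecord) -> float:
        return (
            self.intercept
            + self.b_salinity * record.salinity
            + self.b_temp * record.temp_meas
            + self.b_logmass * record.log10_mass
        )


def fit_mr_baseline(records: list[CleanRecord], *, species_means: bool = False) -> MRBaseline:
    """Fit the metabolic-rate baseline on records with an observed rate.

    By default one observation per measurement record; ``species_means=True``
    collapses to one observation per species first (means of response and
    predictors).
    """
    rows = [
        (r.species_name, r.salinity, r.temp_meas, r.log10_mass, np.log10(r.mr_umol_h))
        for r in records
        if r.mr_umol_h is not None and r.mr_umol_h > 0
    ]
    df = pd.DataFrame(rows, columns=["species", *_PREDICTORS, "log10_mr"])
    if species_means:
        df = df.groupby("species", as_index=False).mean(numeric_only=True)
    n = len(df)
    if n < len(_PREDICTORS) + 1 + 2:
        raise ValueError(f"need at least {len(_PREDICTORS) + 3} observed metabolic rates, got {n}")
    X = sm.add_constant(df[list(_PREDICTORS)].to_numpy(), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cols = X[:, 1:]
        culprits = [name for name, c in zip(_PREDICTORS, cols.T) if np.std(c) == 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            for i in range(len(_PREDICTORS)):
                for j in range(i + 1, len(_PREDICTORS)):
                    if np.std(cols[:, i]) > 0 and np.std(cols[:, j]) > 0:
                        r = np.corrcoef(cols[:, i], cols[:, j])[0, 1]
                        if abs(r) > 0.999999:
                            culprits.append(f"{_PREDICTORS[i]}~{_PREDICTORS[j]}")
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")
    with np.errstate(divide="ignore", invalid="ignore"):  # constant response -> R^2 of 0/0
        res = sm.OLS(df["log10_mr"].to_numpy(), X).fit()
        rsq = float(res.rsquared)
    return MRBaseline(
        intercept=float(res.params[0]),
        b_salinity=float(res.params[1]),
        b_temp=float(res.params[2]),
        b_logmass=float(res.params[3]),
        r_squared=rsq if np.isfinite(rsq) else 0.0,
        n_used=n,
    )


def residual_mr(record: CleanRecord, baseline: MRBaseline) -> tuple[float, bool]:
    """Observed − expected log10 metabolic rate; (0, imputed=True) when missing."""
    if record.mr_umol_h is None or record.mr_umol_h <= 0:
        return 0.0, True
    return float(np.log10(record.mr_umol_h) - baseline.predict(record)), False


def attach_residuals(records: list[CleanRecord], baseline: MRBaseline) -> list[CleanRecord]:
    """Fill ``resid_mr``/``mr_imputed`` on every record (in place; returns input)."""
    for r in records:
        r.resid_mr, r.mr_imputed = residual_mr(r, baseline)
    return records
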