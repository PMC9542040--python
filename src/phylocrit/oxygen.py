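"""Oxygen physics for respirometry data.

Conversions between the units in which critical oxygen tension (Pcrit) is
reported — partial pressure (kPa, mmHg), percent air saturation, and
dissolved-oxygen concentration (mg/L, μmol/L) — plus the mapping from Pcrit
to factorial aerobic scope (FAS).

Saturation concentrations follow the Garcia & Gordon (1992) refit of the
Benson & Krause data, the de-facto standard in aquatic respirometry.
Concentration units are converted to partial pressure by Henry-law
proportionality against the saturation concentration at the prevailing
temperature, salinity and atmospheric pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaterState",
    "FASResult",
    "water_vapor_pressure",
    "o2_saturation_concentration",
    "to_kpa",
    "from_kpa",
    "fas_from_pcrit",
    "project_fas_grid",
    "O2_MOLE_FRACTION",
    "STANDARD_PRESSURE_KPA",
    "FAS_NUMERATOR_KPA",
    "PCRIT_FLOOR_KPA",
]

#: mole fraction of O2 in dry air
O2_MOLE_FRACTION = 0.2095
#: one standard atmosphere (= 760 mmHg)
STANDARD_PRESSURE_KPA = 101.325
#: numerator of the FAS approximation FAS = 21 / Pcrit
FAS_NUMERATOR_KPA = 21.0
#: Pcrit values below this floor are clipped before the FAS division,
#: capping FAS at 21/2 = 10.5
PCRIT_FLOOR_KPA = 2.0

KPA_PER_MMHG = STANDARD_PRESSURE_KPA / 760.0
#: μmol O2 per mL O2 at STP (ideal molar volume 22.3916 L/mol for O2)
UMOL_PER_ML_O2 = 1000.0 / 22.3916
MG_PER_MMOL_O2 = 31.9988

PCRIT_UNITS = ("kPa", "mmHg", "percent_airsat", "mg_per_L", "umol_per_L")

# Garcia & Gordon (1992) combined fit, cm^3/dm^3 coefficient set.
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_GG_B = (-0.00624523, -0.00737614, -0.0103410, -0.00817083)
_GG_C0 = -4.88682e-7


@dataclass(frozen=True)
class WaterState:
    """Temperature (°C), salinity (PSU) and total atmospheric pressure (kPa)."""

    temperature: float
    salinity: float = 0.0
    pressure: float = STANDARD_PRESSURE_KPA

    def __post_init__(self) -> None:
        if not -2.0 <= self.temperature <= 45.0:
            raise ValueError(f"temperature {self.temperature} °C outside [-2, 45]")
        if self.salinity < 0:
            raise ValueError(f"salinity {self.salinity} PSU is negative")
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")


@dataclass(frozen=True)
class FASResult:
    """Factorial aerobic scope derived from a Pcrit value."""

    pcrit_input: float
    pcrit_clipped: float
    fas: float


def water_vapor_pressure(temperature):
    """Saturation vapor pressure of water (kPa) by the Arden Buck equation.

    Accurate to ~0.02% over 0–50 °C; also hits 101.3 kPa at 100 °C.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t < -2.0) or np.any(t > 100.0):
        raise ValueError("temperature outside supported range [-2, 100] °C")
    p = 0.61121 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))
    return p.item() if np.isscalar(temperature) else p


def o2_saturation_concentration(state: WaterState) -> float:
    """Equilibrium O2 concentration (μmol L⁻¹) of water under humid air.

    Garcia & Gordon (1992) combined fit (their cm³/dm³ coefficients,
    converted to μmol/L). The fit is for water-saturated air at one
    atmosphere; other total pressures are handled by scaling with the
    dry-air fraction (P − pv)/(P_std − pv).
    """
    t, s = state.temperature, state.salinity
    ts = np.log((298.15 - t) / (273.15 + t))  # scaled temperature
    a = sum(c * ts**i for i, c in enumerate(_GG_A))
    b = sum(c * ts**i for i, c in enumerate(_GG_B))
    ln_c = a + s * b + _GG_C0 * s**2
    conc = float(np.exp(ln_c)) * UMOL_PER_ML_O2
    pv = water_vapor_pressure(t)
    scale = (state.pressure - pv) / (STANDARD_PRESSURE_KPA - pv)
    return conc * scale


def _po2_saturation(state: WaterState) -> float:
    """pO2 (kPa) of air-equilibrated water: O2 fraction of the dry-air pressure."""
    return O2_MOLE_FRACTION * (state.pressure - water_vapor_pressure(state.temperature))


def to_kpa(value: float, unit: str, state: WaterState | None = None) -> float:
    """Convert an oxygen tension/concentration reading to kPa of O2.

    percent_airsat and the concentration units require a :class:`WaterState`
    (temperature/salinity/pressure control saturation); kPa and mmHg do not.
    """
    if unit not in PCRIT_UNITS:
        raise ValueError(f"unknown oxygen unit {unit!r}; expected one of {PCRIT_UNITS}")
    if unit == "kPa":
        return float(value)
    if unit == "mmHg":
        return float(value) * KPA_PER_MMHG
    if state is None:
        raise ValueError(f"unit {unit!r} requires temperature/salinity (WaterState)")
    if unit == "percent_airsat":
        return float(value) / 100.0 * _po2_saturation(state)
    if unit == "mg_per_L":
        conc_umol = float(value) * 1000.0 / MG_PER_MMOL_O2
    else:  # umol_per_L
        conc_umol = float(value)
    return conc_umol / o2_saturation_concentration(state) * _po2_saturation(state)


def from_kpa(pkpa: float, unit: str, state: WaterState | None = None) -> float:
    """Inverse of :func:`to_kpa` (used for round-trip checks and reporting)."""
    if unit not in PCRIT_UNITS:
        raise ValueError(f"unknown oxygen unit {unit!r}; expected one of {PCRIT_UNITS}")
    if unit == "kPa":
        return float(pkpa)
    if unit == "mmHg":
        return float(pkpa) / KPA_PER_MMHG
    if state is None:
        raise ValueError(f"unit {unit!r} requires temperature/salinity (WaterState)")
    if unit == "percent_airsat":
        return float(pkpa) / _po2_saturation(state) * 100.0
    conc_umol = float(pkpa) / _po2_saturation(state) * o2_saturation_concentration(state)
    if unit == "mg_per_L":
        return conc_umol * MG_PER_MMOL_O2 / 1000.0
    return conc_umol


def fas_from_pcrit(
    pcrit: float,
    *,
    numerator: float = FAS_NUMERATOR_KPA,
    floor: float = PCRIT_FLOOR_KPA,
) -> FASResult:
    """Factorial aerobic scope FAS = 21 / Pcrit with the low-Pcrit floor.

    Pcrit below ``floor`` (2 kPa) is clipped up to the floor before the
    division, capping FAS at 21/2 = 10.5. The numerator is the nominal
    atmospheric pO2 of 21 kPa, not a humidity-corrected value.
    """
    p = float(pcrit)
    if p <= 0:
        raise ValueError("pcrit must be positive")
    clipped = max(p, floor)
    return FASResult(pcrit_input=p, pcrit_clipped=clipped, fas=numerator / clipped)


def project_fas_grid(
    temps,
    salinity_class: str,
    log10_mass: float,
    log10_gs: float,
    coef,
    *,
    data_temp_range: tuple[float, float] | None = None,
):
    """Predicted FAS over a temperature grid for a fixed body mass / genome size.

    The linear predictor uses posterior-mean fixed effects (random effects at
    zero) of the final Pcrit model; salinity is 0 (fresh) or 35 PSU (marine)
    and residual metabolic rate 0 (an average fish). Predicted Pcrit is then
    pushed through :func:`fas_from_pcrit` cell by cell.

    Parameters
    ----------
    temps : array-like of °C, the grid cells.
    salinity_class : "fresh" or "marine".
    coef : mapping of term name -> posterior-mean coefficient, or a fitted
        :class:`~phylocrit.model.Posterior` (its fixed-effect means are used).
        Terms absent from the mapping contribute zero.

    Returns
    -------
    (pcrit, fas, extrapolated) arrays aligned with ``temps``; ``extrapolated``
    flags cells outside ``data_temp_range`` (a warning is emitted if any).
    """
    if salinity_class not in ("fresh", "marine"):
        raise ValueError("salinity_class must be 'fresh' or 'marine'")
    if hasattr(coef, "fixed_means"):
        coef = coef.fixed_means()
    t = np.atleast_1d(np.asarray(temps, dtype=float))
    salinity = 0.0 if salinity_class == "fresh" else 35.0
    g = dict(coef)

    def c(name):
        return float(g.get(name, 0.0))

    pcrit = (
        c("intercept")
        + c("temp") * t
        + c("gs") * log10_gs
        + c("bm") * log10_mass
        + c("salinity") * salinity
        + c("temp:gs") * t * log10_gs
        + c("temp:bm") * t * log10_mass
    )
    extrapolated = np.zeros_like(t, dtype=bool)
    if data_temp_range is not None:
        lo, hi = data_temp_range
        extrapolated = (t < lo) | (t > hi)
        if extrapolated.any():
            import warnings

            warnings.warn(
                f"{int(extrapolated.sum())} grid cells outside the fitted "
                f"temperature range [{lo}, {hi}] °C; predictions are extrapolations",
                stacklevel=2,
            )
    fas = np.array([fas_from_pcrit(max(p, 1e-12)).fas for p in pcrit])
    return pcrit, fas, extrapolated
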