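"""Reading, validation and unit standardization of the Pcrit database.

Two CSV inputs drive the pipeline:

* the measurement database — one row per respirometry record (species, Pcrit
  value + unit, measurement/acclimation temperature, salinity, body mass,
  optional whole-organism metabolic rate, respirometry method, source);
* the species-trait table — genome size (C-value, pg) and maximum body mass
  (g) per species.

Standardization recalculates every Pcrit to kPa (via :mod:`phylocrit.oxygen`)
and metabolic rates to μmol O2 h⁻¹, maps the qualitative salinity token
"seawater" to 35 PSU, derives relative acclimation temperature
(acclimation − measurement), expresses body mass as a percentage of the
species maximum, and log10-transforms the mass/genome-size covariates.

Canonical column names are documented in :data:`DB_COLUMNS` and
:data:`TRAITS_COLUMNS`; files with other headers can be adapted with a
``column_map`` renaming dictionary.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import oxygen
from .oxygen import WaterState, STANDARD_PRESSURE_KPA

__all__ = [
    "PcritRecord",
    "SpeciesTraits",
    "CleanRecord",
    "ValidationReport",
    "read_database",
    "resolve_salinity",
    "standardize",
    "records_to_frame",
    "frame_to_records",
    "DB_COLUMNS",
    "TRAITS_COLUMNS",
]

logger = logging.getLogger(__name__)

#: canonical measurement-database header
DB_COLUMNS = (
    "species",
    "pcrit",
    "pcrit_unit",
    "temp_meas",
    "temp_acclim",
    "salinity",
    "body_mass_g",
    "metabolic_rate",
    "mr_unit",
    "respirometry",
    "source_id",
)
#: canonical species-trait header
TRAITS_COLUMNS = ("species", "genome_size_pg", "max_body_mass_g")

MR_UNITS = ("umol_O2_per_h", "mg_O2_per_h", "mg_O2_per_kg_per_h")
RESPIROMETRY_LEVELS = ("closed", "intermittent", "unknown")
SEAWATER_PSU = 35.0


@dataclass
class PcritRecord:
    """One raw respirometry measurement as read from the database CSV."""

    species_name: str
    pcrit_value: float
    pcrit_unit: str
    temp_meas: float
    temp_acclim: float
    salinity_raw: object  # numeric PSU or the token "seawater"
    body_mass: float  # g
    metabolic_rate: float | None = None
    mr_unit: str | None = None
    respirometry: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pcrit_value <= 0:
            raise ValueError(f"pcrit must be positive, got {self.pcrit_value}")
        if self.body_mass <= 0:
            raise ValueError(f"body mass must be positive, got {self.body_mass}")
        if not -2.0 <= self.temp_meas <= 45.0:
            raise ValueError(f"temp_meas {self.temp_meas} °C outside [-2, 45]")
        if self.pcrit_unit not in oxygen.PCRIT_UNITS:
            raise ValueError(f"unknown pcrit unit {self.pcrit_unit!r}")
        if self.mr_unit is not None and self.mr_unit not in MR_UNITS:
            raise ValueError(f"unknown metabolic-rate unit {self.mr_unit!r}")
        if self.respirometry not in RESPIROMETRY_LEVELS:
            raise ValueError(f"unknown respirometry method {self.respirometry!r}")


@dataclass
class SpeciesTraits:
    """Species-level genome size (pg) and maximum body mass (g)."""

    species_name: str
    genome_size: float
    max_body_mass: float

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError(f"genome size must be positive ({self.species_name})")
        if self.max_body_mass <= 0:
            raise ValueError(f"max body mass must be positive ({self.species_name})")


@dataclass
class CleanRecord:
    """A unit-standardized record with the derived model covariates."""

    species_name: str
    pcrit_kpa: float
    temp_meas: float
    rel_acclim: float  # acclimation − measurement temperature, °C
    salinity: float  # PSU
    log10_mass: float  # log10 g
    log10_gs: float  # log10 pg
    log10_maxbm: float  # log10 g
    pct_max_mass: float  # 100 × body mass / species maximum
    log10_pct: float
    mr_umol_h: float | None  # μmol O2 h⁻¹, None when unreported
    respirometry: str
    resid_mr: float = 0.0  # filled by phylocrit.baseline
    mr_imputed: bool = True  # True until a real residual is computed
    salinity_imputed: bool = False


@dataclass
class ValidationReport:
    """Row-level diagnostics from reading and standardizing the database."""

    n_rows: int = 0
    n_accepted: int = 0
    rejections: list = field(default_factory=list)  # (row index, reason)
    warnings: list = field(default_factory=list)
    species_missing_traits: list = field(default_factory=list)
    duplicate_traits_averaged: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return isinstance(x, str) and x.strip() == ""


def resolve_salinity(salinity_raw) -> tuple[float, bool]:
    """Numeric PSU from a raw salinity entry.

    The qualitative token "seawater" maps to the average ocean salinity of
    35 PSU; numeric values pass through. Returns ``(psu, imputed)`` where
    ``imputed`` marks the seawater substitution.
    """
    if isinstance(salinity_raw, str):
        token = salinity_raw.strip().lower()
        if token == "seawater":
            return SEAWATER_PSU, True
        try:
            value = float(token)
        except ValueError:
            raise ValueError(f"unrecognized salinity entry {salinity_raw!r}") from None
    else:
        value = float(salinity_raw)
    if value < 0:
        raise ValueError(f"negative salinity {value}")
    return value, False


def read_database(
    path,
    species_traits_path,
    *,
    column_map: dict | None = None,
    traits_column_map: dict | None = None,
):
    """Read the measurement database and species-trait table.

    Rows missing a mandatory field (species, pcrit, unit, temp_meas,
    body_mass) or carrying an unknown unit token are rejected, each with a
    row-level diagnostic in the returned report; nothing is dropped silently.
    Duplicate trait rows for a species are averaged (logged). Records whose
    species lack a trait entry are retained but listed for downstream
    exclusion.

    Returns ``(records, traits, report)``.
    """
    db = pd.read_csv(path)
    if column_map:
        db = db.rename(columns=column_map)
    missing_cols = [c for c in ("species", "pcrit", "pcrit_unit", "temp_meas", "body_mass_g") if c not in db.columns]
    if missing_cols:
        raise ValueError(f"database is missing required columns: {missing_cols}")

    traits_df = pd.read_csv(species_traits_path)
    if traits_column_map:
        traits_df = traits_df.rename(columns=traits_column_map)
    missing_cols = [c for c in TRAITS_COLUMNS if c not in traits_df.columns]
    if missing_cols:
        raise ValueError(f"traits table is missing required columns: {missing_cols}")

    report = ValidationReport(n_rows=len(db))

    dupes = traits_df["species"][traits_df["species"].duplicated()].unique().tolist()
    if dupes:
        report.duplicate_traits_averaged = dupes
        logger.info("averaging duplicate trait rows for: %s", ", ".join(dupes))
        traits_df = traits_df.groupby("species", as_index=False).mean(numeric_only=True)
    traits = [
        SpeciesTraits(row.species, float(row.genome_size_pg), float(row.max_body_mass_g))
        for row in traits_df.itertuples()
    ]
    trait_species = {t.species_name for t in traits}

    records: list[PcritRecord] = []
    for i, row in db.iterrows():
        mandatory = {
            "species": row.get("species"),
            "pcrit": row.get("pcrit"),
            "pcrit_unit": row.get("pcrit_unit"),
            "temp_meas": row.get("temp_meas"),
            "body_mass_g": row.get("body_mass_g"),
        }
        absent = [k for k, v in mandatory.items() if _is_missing(v)]
        if absent:
            report.rejections.append((int(i), f"missing mandatory fields: {absent}"))
            continue
        mr = row.get("metabolic_rate")
        mr_unit = row.get("mr_unit")
        try:
            rec = PcritRecord(
                species_name=str(row["species"]).strip(),
                pcrit_value=float(row["pcrit"]),
                pcrit_unit=str(row["pcrit_unit"]).strip(),
                temp_meas=float(row["temp_meas"]),
                temp_acclim=float(row["temp_acclim"])
                if "temp_acclim" in db.columns and not _is_missing(row.get("temp_acclim"))
                else float(row["temp_meas"]),
                salinity_raw=row.get("salinity", 0.0),
                body_mass=float(row["body_mass_g"]),
                metabolic_rate=None if _is_missing(mr) else float(mr),
                mr_unit=None if _is_missing(mr_unit) else str(mr_unit).strip(),
                respirometry=str(row["respirometry"]).strip()
                if "respirometry" in db.columns and not _is_missing(row.get("respirometry"))
                else "unknown",
                source_id=str(row.get("source_id", "")),
            )
        except ValueError as exc:
            report.rejections.append((int(i), str(exc)))
            continue
        if rec.species_name not in trait_species:
            if rec.species_name not in report.species_missing_traits:
                report.species_missing_traits.append(rec.species_name)
        records.append(rec)

    report.n_accepted = len(records)
    for i, reason in report.rejections:
        logger.warning("rejected database row %d: %s", i, reason)

    # warn when observed masses exceed the species' recorded maximum
    max_by_species = {t.species_name: t.max_body_mass for t in traits}
    for rec in records:
        mx = max_by_species.get(rec.species_name)
        if mx is not None and rec.body_mass > mx:
            msg = (
                f"{rec.species_name}: observed body mass {rec.body_mass} g exceeds "
                f"recorded species maximum {mx} g"
            )
            report.warnings.append(msg)
            logger.warning(msg)

    return records, traits, report


def standardize(
    records,
    traits,
    pressure_kpa: float = STANDARD_PRESSURE_KPA,
    *,
    report: ValidationReport | None = None,
):
    """Unit-standardize raw records into :class:`CleanRecord` rows.

    Pcrit is converted to kPa (concentration and air-saturation units use the
    record's temperature, resolved salinity and ``pressure_kpa``), metabolic
    rate to μmol O2 h⁻¹, and the derived covariates are computed. Records of
    species absent from the trait table cannot be standardized and are
    dropped with a logged diagnostic (no silent drops).
    """
    if report is None:
        report = ValidationReport(n_rows=len(records))
    trait_map = {t.species_name: t for t in traits}
    clean: list[CleanRecord] = []
    for i, rec in enumerate(records):
        tr = trait_map.get(rec.species_name)
        if tr is None:
            report.rejections.append((i, f"no trait entry for {rec.species_name}"))
            logger.warning("dropping record %d: no trait entry for %s", i, rec.species_name)
            continue
        salinity, sal_imputed = resolve_salinity(rec.salinity_raw)
        if salinity > 45:
            raise ValueError(f"salinity {salinity} PSU outside [0, 45] (record {i})")
        state = WaterState(rec.temp_meas, salinity, pressure_kpa)
        pcrit_kpa = oxygen.to_kpa(rec.pcrit_value, rec.pcrit_unit, state)
        mr = _mr_to_umol_h(rec)
        pct = 100.0 * rec.body_mass / tr.max_body_mass
        if pct > 100:
            report.warnings.append(
                f"record {i} ({rec.species_name}): body mass is {pct:.0f}% of the species maximum"
            )
        clean.append(
            CleanRecord(
                species_name=rec.species_name,
                pcrit_kpa=pcrit_kpa,
                temp_meas=rec.temp_meas,
                rel_acclim=rec.temp_acclim - rec.temp_meas,
                salinity=salinity,
                log10_mass=math.log10(rec.body_mass),
                log10_gs=math.log10(tr.genome_size),
                log10_maxbm=math.log10(tr.max_body_mass),
                pct_max_mass=pct,
                log10_pct=math.log10(pct),
                mr_umol_h=mr,
                respirometry=rec.respirometry,
                salinity_imputed=sal_imputed,
            )
        )
    return clean, report


def _mr_to_umol_h(rec: PcritRecord) -> float | None:
    if rec.metabolic_rate is None:
        return None
    if rec.mr_unit is None:
        raise ValueError(f"metabolic rate given without a unit ({rec.species_name})")
    v = rec.metabolic_rate
    if rec.mr_unit == "umol_O2_per_h":
        return v
    if rec.mr_unit == "mg_O2_per_h":
        return v * 1000.0 / oxygen.MG_PER_MMOL_O2
    # mg O2 per kg per h: scale by individual mass first
    return v * (rec.body_mass / 1000.0) * 1000.0 / oxygen.MG_PER_MMOL_O2


def records_to_frame(records: list[CleanRecord]) -> pd.DataFrame:
    """Clean records as a DataFrame (the CSV schema the CLI writes/reads)."""
    return pd.DataFrame([asdict(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> list[CleanRecord]:
    """Inverse of :func:`records_to_frame`."""
    out = []
    for row in df.to_dict("records"):
        if "mr_umol_h" in row and (row["mr_umol_h"] is None or pd.isna(row["mr_umol_h"])):
            row["mr_umol_h"] = None
        out.append(CleanRecord(**{k: row[k] for k in CleanRecord.__dataclass_fields__ if k in row}))
    return out
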