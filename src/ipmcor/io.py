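"""Readers and writers: demographic panel CSV and the winter-NAO series.

The canonical panel dialect is a UTF-8, comma-separated table with a
header row and one individual-year record per line.  Internal column
names: id, year, mass, surv, repro, mass_next, off_mass, newborn; a
column mapping translates external headers, and a preset is bundled for
the published Soay sheep table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .inference import REQUIRED_COLUMNS, ValidationError, validate_records

#: mapping preset for the openly published Soay sheep demographic CSV
SOAY_COLUMN_PRESET: Dict[str, str] = {
    "id": "id",
    "year": "year",
    "mass": "mass",
    "surv": "survival",
    "repro": "reproduction",
    "mass_next": "mass.next",
    "off_mass": "offspring.mass",
}


@dataclass
class DemographyTable:
    """A validated individual-year panel plus provenance metadata."""

    records: pd.DataFrame
    source: Optional[str] = None
    column_mapping: Optional[Dict[str, str]] = None

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.records["year"].unique())

    @property
    def n_individuals(self) -> int:
        return self.records["id"].nunique()

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DriverSeries:
    """Annual environmental covariate (winter NAO, DJFM mean) by sheep-year."""

    values: Dict[int, float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.array(list(self.values.values()), dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("driver series contains non-finite values")
        self.mean = float(v.mean())
        self.sd = float(v.std(ddof=1)) if v.size > 1 else 0.0

    def __getitem__(self, year: int) -> float:
        return self.values[year]


def read_demography_csv(
    path,
    column_mapping: Optional[Dict[str, str]] = None,
    log_transform_mass: bool = False,
) -> DemographyTable:
    """Read and validate a demographic panel.

    ``column_mapping`` maps internal names to the file's headers (the Soay
    preset is tried for any name not mapped).  Blank cells become missing
    responses.  With ``log_transform_mass`` the mass columns are
    natural-log transformed on read (for files storing raw body mass).
    """
    raw = pd.read_csv(path)
    mapping = dict(column_mapping or {})
    df = pd.DataFrame()
    for internal in REQUIRED_COLUMNS:
        external = mapping.get(internal, internal)
        if external not in raw.columns:
            external = SOAY_COLUMN_PRESET.get(internal, internal)
        if external not in raw.columns:
            raise ValidationError(
                f"required column {internal!r} (mapped to {external!r}) not in file; "
                f"available: {list(raw.columns)}"
            )
        df[internal] = pd.to_numeric(raw[external], errors="coerce")
        mapping[internal] = external
    if "newborn" in raw.columns or mapping.get("newborn") in raw.columns:
        df["newborn"] = raw[mapping.get("newborn", "newborn")].astype(bool)
    if log_transform_mass:
        for col in ("mass", "mass_next", "off_mass"):
            bad = df[col] <= 0
            if bad.any():
                raise ValidationError(
                    f"cannot log-transform non-positive {col} at rows "
                    f"{list(df.index[bad][:5])}"
                )
            df[col] = np.log(df[col])
    if len(df):
        df = validate_records(df)
    return DemographyTable(df, source=str(path), column_mapping=mapping)


def write_demography_csv(table: DemographyTable | pd.DataFrame, path) -> None:
    df = table.records if isinstance(table, DemographyTable) else table
    df.to_csv(path, index=False)


def read_nao_monthly(path) -> DriverSeries:
    """DJFM winter means from a whitespace year-by-month table.

    Expects one row per calendar year: the year followed by 12 monthly
    values (extra trailing columns such as an annual mean are ignored;
    sentinel values <= -90 mark missing months).  The winter value
    assigned to sheep-year t averages December of calendar year t-1 with
    January-March of year t — the standard winter-NAO convention; rows
    whose four winter months are incomplete are skipped, and a missing
    month inside an otherwise covered winter is an error.
    """
    monthly: Dict[int, list] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 13:
                continue
            try:
                year = int(parts[0])
                vals = [float(v) for v in parts[1 : 13]]
            except ValueError:
                continue
            monthly[year] = [np.nan if v <= -90.0 else v for v in vals]
    if not monthly:
        raise ValueError(f"no monthly rows parsed from {path}")
    out = {}
    for year in sorted(monthly):
        prev = monthly.get(year - 1)
        if prev is None:
            continue
        winter = [prev[11], monthly[year][0], monthly[year][1], monthly[year][2]]
        if any(np.isnan(v) for v in winter):
            months = ["Dec", "Jan", "Feb", "Mar"]
            missing = [months[i] for i, v in enumerate(winter) if np.isnan(v)]
            raise ValueError(f"missing month(s) {missing} for winter of {year}")
        out[year] = float(np.mean(winter))
    return DriverSeries(out)
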