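"""Region-by-year resource panels: reading, validation, derived indicators.

A *panel* is a rectangular table with one row per (region, year, stratum)
holding the resident population, land area and four workforce/capacity
counts (registered nurses, practicing doctors, health technicians,
hospital beds).  This module reads such tables from delimited text,
validates the domain invariants, and derives the standard per-capita and
ratio indicators used by the equity and forecasting stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, PanelIntegrityError, SchemaError

logger = logging.getLogger(__name__)

#: Canonical CSV schema, in column order.
PANEL_COLUMNS = (
    "region_id",
    "year",
    "stratum",
    "population",
    "area_km2",
    "nurses",
    "doctors",
    "health_technicians",
    "beds",
)

COUNT_COLUMNS = ("nurses", "doctors", "health_technicians", "beds")


class Stratum(str, Enum):
    """Population stratum a record refers to."""

    URBAN = "urban"
    COUNTY = "county"
    WHOLE = "whole"


@dataclass(frozen=True)
class RegionYearRecord:
    """One region in one year.

    Invariants: ``population`` and ``area_km2`` strictly positive; all
    counts non-negative integers; ``nurses <= health_technicians``
    (nurses are a subset of the health-technician headcount).
    """

    region_id: str
    year: int
    stratum: Stratum
    population: float
    area_km2: float
    nurses: int
    doctors: int
    health_technicians: int
    beds: int

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if not self.population > 0:
            problems.append(f"population must be > 0, got {self.population}")
        if not self.area_km2 > 0:
            problems.append(f"area_km2 must be > 0, got {self.area_km2}")
        for name in COUNT_COLUMNS:
            value = getattr(self, name)
            if value < 0:
                problems.append(f"{name} must be >= 0, got {value}")
        if self.nurses > self.health_technicians:
            problems.append(
                f"nurses ({self.nurses}) exceed health_technicians "
                f"({self.health_technicians})"
            )
        return problems

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.region_id, self.year, self.stratum.value)


@dataclass(frozen=True)
class Panel:
    """An immutable, validated collection of :class:`RegionYearRecord`.

    Construct with :meth:`build` (or :func:`read_panel`) so that
    uniqueness and year-contiguity checks run.  Year gaps are *reported*
    in :attr:`warnings`, never silently filled.
    """

    records: tuple[RegionYearRecord, ...]
    provenance: str = ""
    warnings: tuple[str, ...] = field(default=())

    @classmethod
    def build(
        cls,
        records: list[RegionYearRecord] | tuple[RegionYearRecord, ...],
        provenance: str = "",
        strict: bool = True,
    ) -> "Panel":
        records = tuple(records)
        errors: list[str] = []
        bad_indices: set[int] = set()
        warnings: list[str] = []

        seen: dict[tuple, int] = {}
        for idx, rec in enumerate(records):
            for problem in rec.validate():
                errors.append(f"record {idx} {rec.key}: {problem}")
                bad_indices.add(idx)
            if rec.key in seen:
                errors.append(
                    f"duplicate (region_id, year, stratum) key {rec.key} "
                    f"at records {seen[rec.key]} and {idx}"
                )
                bad_indices.add(idx)
            else:
                seen[rec.key] = idx

        # year contiguity per (region, stratum): gaps are reported
        by_group: dict[tuple[str, str], list[int]] = {}
        for rec in records:
            by_group.setdefault((rec.region_id, rec.stratum.value), []).append(rec.year)
        for (region, stratum), years in by_group.items():
            years = sorted(years)
            missing = sorted(set(range(years[0], years[-1] + 1)) - set(years))
            if missing:
                warnings.append(
                    f"region {region!r} stratum {stratum!r} has year gaps: {missing}"
                )

        if errors:
            if strict:
                raise PanelIntegrityError(
                    f"{len(errors)} invalid record(s); first: {errors[0]}", errors
                )
            warnings.extend(errors)
            records = tuple(r for i, r in enumerate(records) if i not in bad_indices)

        for w in warnings:
            logger.warning("panel: %s", w)
        return cls(records=records, provenance=provenance, warnings=tuple(warnings))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted({r.region_id for r in self.records}))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({r.year for r in self.records}))

    def subset(self, stratum: Stratum | str = Stratum.WHOLE) -> "Panel":
        stratum = Stratum(stratum)
        return Panel(
            records=tuple(r for r in self.records if r.stratum is stratum),
            provenance=self.provenance,
            warnings=self.warnings,
        )

    def to_frame(self) -> pd.DataFrame:
        """Export as a DataFrame following the canonical column schema."""
        rows = [
            {
                "region_id": r.region_id,
                "year": r.year,
                "stratum": r.stratum.value,
                "population": r.population,
                "area_km2": r.area_km2,
                "nurses": r.nurses,
                "doctors": r.doctors,
                "health_technicians": r.health_technicians,
                "beds": r.beds,
            }
            for r in self.records
        ]
        df = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
        return df.sort_values(["region_id", "stratum", "year"]).reset_index(drop=True)

    def total_series(
        self, column: str = "nurses", stratum: Stratum | str = Stratum.WHOLE
    ) -> pd.Series:
        """Province-wide yearly totals of one count column (index = year)."""
        if column not in COUNT_COLUMNS:
            raise DomainError(f"unknown count column {column!r}")
        df = self.subset(stratum).to_frame()
        if df.empty:
            return pd.Series(dtype=float, name=column)
        return df.groupby("year")[column].sum().sort_index().astype(float)


def read_panel(
    path: str | Path,
    delimiter: str = ",",
    column_map: dict[str, str] | None = None,
    strict: bool = True,
    provenance: str | None = None,
) -> Panel:
    """Read a delimited-text panel file into a validated :class:`Panel`.

    Parameters
    ----------
    path : path to a UTF-8 delimited file with a header row.
    delimiter : field separator; comma by default, tab accepted.
    column_map : optional mapping ``canonical name -> file column name``
        to tolerate export variants (e.g. ``{"area_km2": "land_area"}``).
    strict : if True (default) any invariant violation aborts the load;
        if False, offending rows are dropped and reported in
        ``Panel.warnings``.

    Raises
    ------
    SchemaError
        if a required column cannot be resolved.
    PanelIntegrityError
        in strict mode, when any row is malformed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]

    rename = {}
    if column_map:
        for canonical, actual in column_map.items():
            if canonical not in PANEL_COLUMNS:
                raise SchemaError(f"unknown canonical column {canonical!r}")
            rename[actual] = canonical
    raw = raw.rename(columns=rename)

    missing = [c for c in PANEL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s): {', '.join(missing)} "
            f"(file columns: {', '.join(raw.columns)})"
        )

    if raw.empty:
        logger.warning("panel file %s contains a header but no rows", path)
        return Panel.build([], provenance=provenance or str(path), strict=strict)

    records: list[RegionYearRecord] = []
    row_errors: list[str] = []
    for pos, row in raw.iterrows():
        line_no = pos + 2  # header is line 1
        try:
            records.append(_parse_row(row))
        except (ValueError, TypeError) as exc:
            row_errors.append(f"line {line_no}: {exc}")

    if row_errors and strict:
        raise PanelIntegrityError(
            f"{len(row_errors)} malformed row(s); first: {row_errors[0]}", row_errors
        )

    panel = Panel.build(records, provenance=provenance or str(path), strict=strict)
    if row_errors:
        panel = Panel(
            records=panel.records,
            provenance=panel.provenance,
            warnings=panel.warnings + tuple(row_errors),
        )
    return panel


def _parse_row(row: pd.Series) -> RegionYearRecord:
    def as_count(name: str) -> int:
        value = row[name]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"{name} is missing")
        number = float(str(value).replace(",", ""))
        if not number.is_integer():
            raise ValueError(f"{name} must be an integer count, got {value!r}")
        return int(number)

    def as_positive(name: str) -> float:
        number = float(str(row[name]).replace(",", ""))
        return number

    return RegionYearRecord(
        region_id=str(row["region_id"]).strip(),
        year=as_count("year"),
        stratum=Stratum(str(row["stratum"]).strip().lower()),
        population=as_positive("population"),
        area_km2=as_positive("area_km2"),
        nurses=as_count("nurses"),
        doctors=as_count("doctors"),
        health_technicians=as_count("health_technicians"),
        beds=as_count("beds"),
    )


def write_panel(panel: Panel, path: str | Path) -> Path:
    """Write a panel to CSV in the canonical column schema (round-trip safe)."""
    path = Path(path)
    panel.to_frame().to_csv(path, index=False)
    return path


def derive_indicators(panel: Panel) -> pd.DataFrame:
    """Compute the allocation indicators, one row per panel record.

    Columns: ``nurses_per_1000`` (nurses per 1,000 population),
    ``nurses_per_km2``, ``nurses_per_doctor`` (the x of the "1:x"
    doctor-to-nurse figure), ``nurses_per_bed`` (x of "1:x" bed-to-nurse),
    ``nurse_share`` (nurses / health technicians, in [0, 1]).

    Ratios with a zero denominator are emitted as NaN (missing), never 0.
    """
    df = panel.to_frame()
    if df.empty:
        return pd.DataFrame(
            columns=[
                "region_id",
                "year",
                "stratum",
                "nurses_per_1000",
                "nurses_per_km2",
                "nurses_per_doctor",
                "nurses_per_bed",
                "nurse_share",
            ]
        )
    out = df[["region_id", "year", "stratum"]].copy()
    out["nurses_per_1000"] = 1000.0 * df["nurses"] / df["population"]
    out["nurses_per_km2"] = df["nurses"] / df["area_km2"]
    out["nurses_per_doctor"] = np.where(
        df["doctors"] > 0, df["nurses"] / df["doctors"].replace(0, np.nan), np.nan
    )
    out["nurses_per_bed"] = np.where(
        df["beds"] > 0, df["nurses"] / df["beds"].replace(0, np.nan), np.nan
    )
    out["nurse_share"] = np.where(
        df["health_technicians"] > 0,
        df["nurses"] / df["health_technicians"].replace(0, np.nan),
        np.nan,
    )
    return out


def format_ratio(x: float) -> str:
    """Render a per-one ratio in the conventional ``1:x`` style."""
    return f"1:{x:.2f}"


def average_annual_growth_rate(a0: float, an: float, n_years: int) -> float:
    """Average annual (compound) growth rate over ``n_years`` years.

    Returns ``(an / a0) ** (1 / n_years) - 1`` as a fraction per year;
    rendering as a percentage is left to the presentation layer.

    Raises
    ------
    DomainError
        if ``a0 <= 0``, ``an < 0`` or ``n_years < 1``.
    """
    if a0 <= 0:
        raise DomainError(f"initial count must be > 0, got {a0}")
    if an < 0:
        raise DomainError(f"final count must be >= 0, got {an}")
    n_years = int(n_years)
    if n_years < 1:
        raise DomainError(f"n_years must be >= 1, got {n_years}")
    return (an / a0) ** (1.0 / n_years) - 1.0
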