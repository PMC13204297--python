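"""Survey coverage data model, CSV I/O, wave filtering, and packaged fixture tables.

Coverage is stored internally as a proportion in (0, 1); all file I/O and
reporting happens on the percent scale, rounded to one decimal, matching the
source tables.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SEX_GROUPS = ("total", "men", "women")
DEFAULT_WAVES = frozenset({2013, 2016, 2019, 2022})

#: Sentinel used where the target year is never reached by the search horizon.
NEVER = "never"


class CoverageDataError(ValueError):
    """Raised for malformed coverage input (bad values, duplicates, missing columns)."""


@dataclass(frozen=True)
class CoverageObservation:
    """One unit-sex-year coverage measurement, as a proportion."""

    unit: str
    sex: str
    year: int
    coverage: float

    def __post_init__(self) -> None:
        if self.sex not in SEX_GROUPS:
            raise CoverageDataError(f"unknown sex group {self.sex!r}")
        if not 0.0 < self.coverage < 1.0:
            raise CoverageDataError(
                f"coverage must lie strictly in (0, 1), got {self.coverage!r} "
                f"for ({self.unit}, {self.sex}, {self.year})"
            )


@dataclass
class CoverageSeries:
    """All observations for one (unit, sex) pair, sorted by year."""

    unit: str
    sex: str
    observations: list[CoverageObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observations.sort(key=lambda o: o.year)
        years = [o.year for o in self.observations]
        if len(set(years)) != len(years):
            raise CoverageDataError(f"duplicate years in series ({self.unit}, {self.sex})")
        for o in self.observations:
            if (o.unit, o.sex) != (self.unit, self.sex):
                raise CoverageDataError(
                    f"observation ({o.unit}, {o.sex}) does not belong to "
                    f"series ({self.unit}, {self.sex})"
                )

    @property
    def years(self) -> list[int]:
        return [o.year for o in self.observations]

    @property
    def coverages(self) -> list[float]:
        return [o.coverage for o in self.observations]

    def __len__(self) -> int:
        return len(self.observations)


def read_coverage_csv(
    path: str | Path,
    wave_whitelist: Iterable[int] = DEFAULT_WAVES,
) -> list[CoverageSeries]:
    """Read a ``unit,sex,year,coverage_pct`` CSV into one series per (unit, sex).

    Rows whose year is not in ``wave_whitelist`` are dropped (the structural
    break filter). Percentages are converted to proportions on read.

    Raises
    ------
    CoverageDataError
        If required columns are missing, a coverage value lies outside the
        open interval (0, 100), or a (unit, sex, year) triple is duplicated.
    """
    whitelist = set(int(y) for y in wave_whitelist)
    df = pd.read_csv(path, comment="#")
    required = {"unit", "sex", "year", "coverage_pct"}
    missing = required - set(df.columns)
    if missing:
        raise CoverageDataError(f"missing required columns: {sorted(missing)}")

    for idx, row in df.iterrows():
        pct = float(row["coverage_pct"])
        if not 0.0 < pct < 100.0:
            raise CoverageDataError(
                f"row {idx + 2}: coverage_pct={pct} outside (0, 100) exclusive"
            )
    dupes = df.duplicated(subset=["unit", "sex", "year"])
    if dupes.any():
        first = df.index[dupes][0]
        raise CoverageDataError(f"row {first + 2}: duplicate (unit, sex, year)")

    df = df[df["year"].astype(int).isin(whitelist)]
    series: list[CoverageSeries] = []
    for (unit, sex), grp in df.groupby(["unit", "sex"], sort=True):
        obs = [
            CoverageObservation(str(unit), str(sex), int(r.year), float(r.coverage_pct) / 100.0)
            for r in grp.itertuples()
        ]
        series.append(CoverageSeries(str(unit), str(sex), obs))
    return series


def write_coverage_csv(
    series: Sequence[CoverageSeries],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write series to the standard CSV layout, percent to 1 decimal."""
    rows = [
        {"unit": s.unit, "sex": s.sex, "year": o.year, "coverage_pct": round(o.coverage * 100, 1)}
        for s in series
        for o in s.observations
    ]
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=["unit", "sex", "year", "coverage_pct"]).to_csv(fh, index=False)


@dataclass
class FixtureTable:
    """The two packaged reference tables: observed/projected coverage and attainment stats.

    ``coverage`` has one row per (unit, sex) with columns
    ``coverage_2013_pct, coverage_2022_pct, proj2028_mean_pct, proj2028_lo_pct,
    proj2028_hi_pct``; ``attainment`` has ``apc_mean, apc_lo, apc_hi,
    prob_target, prob_target_lo, prob_target_hi, target_year, on_track_flag``.
    ``target_year`` is an integer year or the string ``"never"``.
    """

    coverage: pd.DataFrame
    attainment: pd.DataFrame

    UNITS_EXPECTED = 48  # 47 prefectures + nationwide

    def __post_init__(self) -> None:
        for df, name in ((self.coverage, "coverage"), (self.attainment, "attainment")):
            n = df["unit"].nunique()
            if n != self.UNITS_EXPECTED or len(df) != self.UNITS_EXPECTED * len(SEX_GROUPS):
                raise CoverageDataError(
                    f"fixture {name} table malformed: {n} units, {len(df)} rows"
                )
        cov = self.coverage
        bad = (cov["proj2028_lo_pct"] > cov["proj2028_mean_pct"]) | (
            cov["proj2028_mean_pct"] > cov["proj2028_hi_pct"]
        )
        if bad.any():
            raise CoverageDataError("fixture projection interval ordering violated")

    @property
    def prefectures(self) -> list[str]:
        """Prefecture names in table order (nationwide excluded)."""
        units = list(dict.fromkeys(self.coverage["unit"]))
        return [u for u in units if u != "nationwide"]

    def lookup(self, unit: str, sex: str, column: str) -> float | str:
        """Fetch a single cell from whichever table holds ``column``."""
        df = self.coverage if column in self.coverage.columns else self.attainment
        if column not in df.columns:
            raise KeyError(column)
        rows = df[(df["unit"] == unit) & (df["sex"] == sex)]
        if rows.empty:
            raise KeyError(f"no fixture row ({unit}, {sex})")
        return rows.iloc[0][column]

    def column(self, column: str, sex: str, include_nationwide: bool = False) -> pd.Series:
        """One fixture column for one sex group, indexed by unit, in table order."""
        df = self.coverage if column in self.coverage.columns else self.attainment
        if column not in df.columns:
            raise KeyError(column)
        sub = df[df["sex"] == sex]
        if not include_nationwide:
            sub = sub[sub["unit"] != "nationwide"]
        return sub.set_index("unit")[column]


def load_fixture_tables() -> FixtureTable:
    """Load the packaged reference tables (48 units x 3 sex groups each)."""
    root = importlib.resources.files("screentrend") / "fixtures"
    coverage = pd.read_csv(str(root / "table1_coverage.csv"))
    attainment = pd.read_csv(str(root / "table2_attainment.csv"))
    return FixtureTable(coverage=coverage, attainment=attainment)
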