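"""Ingest LSOA-level weekly finisher counts and build stratum-level series.

Links small-area (LSOA) weekly finisher counts to area deprivation (IMD 2019)
and resident population, collapses IMD deciles to quintiles, and aggregates
to six weekly count series: one per deprivation quintile (1 = most deprived)
plus the national total.  Populations and deprivation are held constant over
the window; missing weeks are zero-filled so the pandemic shutdown appears as
genuine zeros.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .calendars import first_saturday_on_or_after, week_of_date

logger = logging.getLogger(__name__)

STRATA = ("q1", "q2", "q3", "q4", "q5", "total")

#: tidy stratum-level CSV schema, shared with the synthetic generator
SERIES_COLUMNS = ("stratum", "week_index", "date", "count", "population", "rate_per_1000")


class SchemaError(ValueError):
    """An input table is missing a required column or violates uniqueness."""


@dataclasses.dataclass(frozen=True)
class AreaRecord:
    """One LSOA with its deprivation decile/quintile and resident count."""

    area_code: str
    imd_decile: int
    population: int

    def __post_init__(self) -> None:
        if not 1 <= self.imd_decile <= 10:
            raise ValueError(f"IMD decile must be 1-10, got {self.imd_decile}")
        if self.population <= 0:
            raise ValueError(f"population must be positive, got {self.population}")

    @property
    def imd_quintile(self) -> int:
        return decile_to_quintile(self.imd_decile)


@dataclasses.dataclass(frozen=True)
class AreaTable:
    """Linked area records plus the exclusion tally from the join."""

    records: tuple[AreaRecord, ...]
    n_input: int
    n_excluded: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_code": [r.area_code for r in self.records],
                "imd_decile": [r.imd_decile for r in self.records],
                "imd_quintile": [r.imd_quintile for r in self.records],
                "population": [r.population for r in self.records],
            }
        )


@dataclasses.dataclass
class WeeklySeries:
    """One stratum's consecutive weekly counts with a fixed denominator.

    ``data`` has one row per week with columns ``week_index`` (consecutive
    integers), ``date`` (the Saturday), ``count`` and ``rate_per_1000``.
    """

    stratum: str
    population: int
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be positive")
        wk = self.data["week_index"].to_numpy()
        if len(wk) > 1 and not ((wk[1:] - wk[:-1]) == 1).all():
            raise ValueError(f"week_index not consecutive for stratum {self.stratum!r}")

    @property
    def counts(self):
        return self.data["count"].to_numpy()

    @property
    def dates(self) -> list[dt.date]:
        return list(self.data["date"])


def decile_to_quintile(decile: int) -> int:
    """Collapse an IMD decile (1-10) to its quintile (1-5)."""
    return math.ceil(decile / 2)


def participation_rate(count: int, population: int) -> float:
    """Finishes per 1000 residents."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count / population * 1000.0


def _require_columns(df: pd.DataFrame, cols: Iterable[str], source: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")


def load_area_table(
    imd_path: str | Path,
    population_path: str | Path,
    *,
    code_col: str = "lsoa_code",
    decile_col: str = "imd_decile",
    score_col: str = "imd_score",
    population_col: str = "population",
) -> AreaTable:
    """Read and link the IMD and population tables into one record per area.

    Areas present in only one table are excluded (never imputed) and counted
    in ``n_excluded``.  If the IMD table has no decile column but carries a
    score, deciles are assigned by ranking areas on score (higher score =
    more deprived = lower decile), the official release convention.
    """
    imd = pd.read_csv(imd_path)
    pop = pd.read_csv(population_path)
    _require_columns(imd, [code_col], "IMD table")
    _require_columns(pop, [code_col, population_col], "population table")

    for name, df in (("IMD table", imd), ("population table", pop)):
        dups = df[code_col][df[code_col].duplicated()]
        if not dups.empty:
            raise SchemaError(f"{name}: duplicate area codes, e.g. {dups.iloc[0]!r}")

    if decile_col not in imd.columns:
        if score_col not in imd.columns:
            raise SchemaError(f"IMD table: needs {decile_col!r} or {score_col!r}")
        # rank deciles over areas: highest scores (most deprived) -> decile 1
        ranks = imd[score_col].rank(method="first", ascending=False)
        imd = imd.assign(**{decile_col: ((ranks - 1) // (len(imd) / 10) + 1).astype(int).clip(1, 10)})

    merged = imd[[code_col, decile_col]].merge(
        pop[[code_col, population_col]], on=code_col, how="outer", indicator=True
    )
    linked = merged[merged["_merge"] == "both"]
    linked = linked[linked[population_col] > 0]
    linked = linked[linked[decile_col].between(1, 10)]
    n_input = len(merged)
    n_excluded = n_input - len(linked)
    if n_excluded:
        logger.info("load_area_table: excluded %d of %d areas lacking IMD/population", n_excluded, n_input)

    records = tuple(
        AreaRecord(str(row[code_col]), int(row[decile_col]), int(row[population_col]))
        for row in linked.to_dict("records")
    )
    return AreaTable(records=records, n_input=n_input, n_excluded=n_excluded)


def aggregate_weekly(
    finishers: pd.DataFrame,
    areas: AreaTable | Sequence[AreaRecord],
    start: dt.date,
    end: dt.date,
    *,
    code_col: str = "lsoa_code",
    date_col: str = "date",
    count_col: str = "finishers",
    on_unknown_area: str = "warn",
) -> list[WeeklySeries]:
    """Aggregate per-area weekly counts into quintile + total series.

    Rows dated outside ``[start, end]`` are discarded; weeks inside the
    window with no rows are zero-filled (the shutdown gap is genuinely zero).
    Returns six :class:`WeeklySeries` in stratum order ``q1..q5, total``.
    """
    if start > end:
        raise ValueError("start must be <= end")
    if on_unknown_area not in ("warn", "error", "ignore"):
        raise ValueError("on_unknown_area must be 'warn', 'error' or 'ignore'")

    records = areas.records if isinstance(areas, AreaTable) else tuple(areas)
    _require_columns(finishers, [code_col, date_col, count_col], "finisher table")
    if (finishers[count_col] < 0).any():
        raise ValueError("finisher table: negative counts")

    df = finishers[[code_col, date_col, count_col]].copy()
    df[date_col] = pd.to_datetime(df[date_col]).dt.date

    quintile = {r.area_code: r.imd_quintile for r in records}
    unknown = set(df[code_col].astype(str)) - set(quintile)
    if unknown:
        msg = f"{len(unknown)} area code(s) in finisher table absent from area table"
        if on_unknown_area == "error":
            raise ValueError(msg)
        if on_unknown_area == "warn":
            logger.warning("aggregate_weekly: dropping %s", msg)
        df = df[df[code_col].astype(str).isin(quintile)]

    anchor = first_saturday_on_or_after(start)
    last_week = week_of_date(end, anchor)
    if first_saturday_on_or_after(end) > end:  # end falls mid-week: its Saturday is outside
        last_week -= 1
    n_weeks = last_week + 1
    if n_weeks <= 0:
        raise ValueError("window contains no Saturdays")

    df = df[(df[date_col] >= anchor) & (df[date_col] <= end)]
    df["week_index"] = [week_of_date(d, anchor) for d in df[date_col]]
    df["stratum"] = df[code_col].astype(str).map(lambda c: f"q{quintile[c]}")

    pop_by_stratum = {s: 0 for s in STRATA}
    for r in records:
        pop_by_stratum[f"q{r.imd_quintile}"] += r.population
    pop_by_stratum["total"] = sum(pop_by_stratum[f"q{q}"] for q in range(1, 6))

    index = pd.RangeIndex(n_weeks, name="week_index")
    by_stratum = df.groupby(["stratum", "week_index"])[count_col].sum()

    out: list[WeeklySeries] = []
    for stratum in STRATA:
        pop = pop_by_stratum[stratum]
        if pop <= 0:
            continue  # stratum with no member areas
        if stratum == "total":
            counts = by_stratum.groupby("week_index").sum().reindex(index, fill_value=0)
        elif not by_stratum.empty and stratum in by_stratum.index.get_level_values("stratum"):
            counts = by_stratum.xs(stratum, level="stratum").reindex(index, fill_value=0)
        else:
            counts = pd.Series(0, index=index)
        n_filled = int((counts == 0).sum())
        if n_filled:
            logger.info("aggregate_weekly: stratum %s has %d zero weeks (filled or observed)", stratum, n_filled)
        data = pd.DataFrame(
            {
                "week_index": index,
                "date": [anchor + dt.timedelta(weeks=int(k)) for k in index],
                "count": counts.to_numpy().astype(int),
            }
        )
        data["rate_per_1000"] = data["count"] / pop * 1000.0
        out.append(WeeklySeries(stratum=stratum, population=pop, data=data))
    return out


def series_to_frame(series: Iterable[WeeklySeries]) -> pd.DataFrame:
    """Stack WeeklySeries into the tidy stratum-level CSV schema."""
    frames = []
    for s in series:
        f = s.data.copy()
        f.insert(0, "stratum", s.stratum)
        f["population"] = s.population
        frames.append(f[list(SERIES_COLUMNS)])
    return pd.concat(frames, ignore_index=True)


def write_series_csv(series: Iterable[WeeklySeries], path: str | Path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> list[WeeklySeries]:
    """Read the tidy stratum-level CSV back into WeeklySeries objects."""
    df = pd.read_csv(path)
    _require_columns(df, SERIES_COLUMNS, "series table")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    out = []
    for stratum, grp in df.groupby("stratum", sort=False):
        grp = grp.sort_values("week_index").reset_index(drop=True)
        pops = grp["population"].unique()
        if len(pops) != 1:
            raise SchemaError(f"stratum {stratum!r}: population not constant")
        out.append(
            WeeklySeries(
                stratum=str(stratum),
                population=int(pops[0]),
                data=grp[["week_index", "date", "count", "rate_per_1000"]].copy(),
            )
        )
    return out
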