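"""Diet-occurrence records and incidence-matrix construction.

Raw input is a long-format table of fecal-sample contents: one row per
(individual, site, season, capture date, food item).  Because individuals
are recaptured within a trapping season, the analysis retains a single
sample per individual per season before building the network, which keeps
matrix rows statistically independent.
"""

from __future__ import annotations

import csv
import datetime as _dt
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .incidence import IncidenceMatrix

__all__ = [
    "Season",
    "DietRecord",
    "DietRecordError",
    "read_diet_records",
    "dedupe_one_per_season",
    "build_incidence",
]


class Season(str, enum.Enum):
    """The two seasons of the Cerrado study system."""

    COOL_DRY = "cool_dry"
    WARM_WET = "warm_wet"

    @classmethod
    def parse(cls, label: str, aliases: Mapping[str, str] | None = None) -> "Season":
        key = str(label).strip().lower().replace("-", "_").replace(" ", "_")
        if aliases:
            key = str(aliases.get(key, key)).strip().lower()
        try:
            return cls(key)
        except ValueError:
            raise DietRecordError(
                f"unknown season label {label!r} (expected one of "
                f"{[s.value for s in cls]} or a configured alias)"
            ) from None


class DietRecordError(ValueError):
    """Raised for malformed diet-record input."""


@dataclass(frozen=True)
class DietRecord:
    """One food-item occurrence in one capture event of one individual."""

    individual_id: str
    site: str
    season: Season
    item: str
    capture_date: _dt.date | None = None

    def __post_init__(self) -> None:
        for name in ("individual_id", "site", "item"):
            if not str(getattr(self, name)).strip():
                raise DietRecordError(f"{name} must be non-empty")
        if not isinstance(self.season, Season):
            object.__setattr__(self, "season", Season.parse(self.season))


#: default mapping from canonical field name to accepted column headers
DEFAULT_COLUMNS: dict[str, tuple[str, ...]] = {
    "individual_id": ("individual_id", "individual", "id", "animal_id"),
    "site": ("site", "grid", "locality"),
    "season": ("season",),
    "item": ("item", "food_item", "category", "food_category"),
    "capture_date": ("capture_date", "date"),
}


def read_diet_records(
    path: str | Path,
    *,
    delimiter: str = "\t",
    column_aliases: Mapping[str, Sequence[str]] | None = None,
    season_aliases: Mapping[str, str] | None = None,
) -> list[DietRecord]:
    """Parse a delimited text file of diet occurrences.

    Parameters
    ----------
    path : path
        Delimited text file with a header row.
    delimiter : str
        Field separator; tab by default.
    column_aliases : mapping, optional
        Extra accepted header names per canonical field, merged over
        :data:`DEFAULT_COLUMNS`.
    season_aliases : mapping, optional
        Extra season labels, e.g. ``{"wet": "warm_wet"}``.

    Raises
    ------
    DietRecordError
        If a required column is missing, a season label is unknown, or the
        file contains no records.  Malformed rows are reported with their
        line numbers.
    """
    columns = {k: tuple(v) for k, v in DEFAULT_COLUMNS.items()}
    if column_aliases:
        for field_name, names in column_aliases.items():
            columns[field_name] = tuple(columns.get(field_name, ())) + tuple(names)

    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise DietRecordError(f"no records in {path}: file is empty") from None
        header_map = {h.strip().lower(): i for i, h in enumerate(header)}

        def locate(field_name: str, required: bool) -> int | None:
            for candidate in columns[field_name]:
                if candidate.lower() in header_map:
                    return header_map[candidate.lower()]
            if required:
                raise DietRecordError(
                    f"missing required column for {field_name!r}; accepted headers: "
                    f"{list(columns[field_name])}; found: {header}"
                )
            return None

        idx = {f: locate(f, f != "capture_date") for f in columns}

        records: list[DietRecord] = []
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                date_i = idx["capture_date"]
                raw_date = row[date_i].strip() if date_i is not None and date_i < len(row) else ""
                records.append(
                    DietRecord(
                        individual_id=row[idx["individual_id"]].strip(),
                        site=row[idx["site"]].strip(),
                        season=Season.parse(row[idx["season"]], season_aliases),
                        item=row[idx["item"]].strip(),
                        capture_date=_dt.date.fromisoformat(raw_date) if raw_date else None,
                    )
                )
            except (DietRecordError, ValueError, IndexError) as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        raise DietRecordError(
            f"{len(problems)} malformed row(s) in {path}:\n" + "\n".join(problems)
        )
    if not records:
        raise DietRecordError(f"no records in {path}")
    return records


def dedupe_one_per_season(
    records: Iterable[DietRecord], rule: str = "first"
) -> list[DietRecord]:
    """Retain one capture event per individual per site per season.

    A capture event is the set of records sharing (individual, site, season,
    capture date).  Under the default ``rule="first"`` the event with the
    earliest capture date is kept (dated events take precedence over undated
    ones; remaining ties resolve by input order), and all of its items are
    retained.  ``rule="union"`` instead pools the items of every event.

    Idempotent: applying it twice equals applying it once.
    """
    if rule not in ("first", "union"):
        raise ValueError(f"unknown dedupe rule {rule!r}; use 'first' or 'union'")

    records = list(records)
    if rule == "union":
        seen: set[tuple] = set()
        out: list[DietRecord] = []
        for r in records:
            key = (r.individual_id, r.site, r.season, r.item)
            if key not in seen:
                seen.add(key)
                out.append(r)
        return out

    # events[(ind, site, season)][date] -> [first input index, [(pos, record), ...]]
    events: dict[tuple, dict] = {}
    for pos, r in enumerate(records):
        group = events.setdefault((r.individual_id, r.site, r.season), {})
        ev = group.setdefault(r.capture_date, [pos, []])
        ev[1].append((pos, r))

    kept: list[tuple[int, DietRecord]] = []
    for group in events.values():
        _, (_, event_records) = min(
            group.items(),
            key=lambda kv: (kv[0] is None, kv[0] or _dt.date.min, kv[1][0]),
        )
        # drop duplicate items within the retained event, keep input order
        seen_items: set[str] = set()
        for pos, r in event_records:
            if r.item not in seen_items:
                seen_items.add(r.item)
                kept.append((pos, r))
    kept.sort(key=lambda pr: pr[0])
    return [r for _, r in kept]


def build_incidence(
    records: Iterable[DietRecord], site: str, season: Season | str
) -> IncidenceMatrix:
    """Build the binary individual x item matrix for one site and season.

    Rows are individuals (order of first appearance), columns food items
    (order of first appearance); a cell is 1 iff the individual's retained
    sample contained the item.  Repeated occurrences collapse to a single 1.
    """
    season = season if isinstance(season, Season) else Season.parse(season)
    subset = [r for r in records if r.site == site and r.season == season]
    if not subset:
        raise DietRecordError(f"no diet records for site={site!r}, season={season.value!r}")
    rows: list[str] = []
    cols: list[str] = []
    for r in subset:
        if r.individual_id not in rows:
            rows.append(r.individual_id)
        if r.item not in cols:
            cols.append(r.item)
    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    r_index = {r: i for i, r in enumerate(rows)}
    c_index = {c: j for j, c in enumerate(cols)}
    for r in subset:
        values[r_index[r.individual_id], c_index[r.item]] = 1
    return IncidenceMatrix(tuple(rows), tuple(cols), values)
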