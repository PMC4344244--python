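"""Reading, validating, filtering and tallying feeding-episode records.

File formats
------------
``episodes.csv`` — one row per episode with columns
``species, year, month, item, location, altitude_band, feeder_flag, site_note``.

``raw_reports.csv`` — same columns, but ``item`` and ``location`` may hold
semicolon-delimited lists: volunteer reports sometimes describe several
dietary items (and locations) in one record, which are separated into
distinct episodes on read (:func:`expand_multirecord`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import (
    N_MONTHS,
    UNIDENTIFIED,
    CategorySchema,
    FeedingEpisode,
    SchemaError,
    ValidationError,
)

EPISODE_COLUMNS = (
    "species",
    "year",
    "month",
    "item",
    "location",
    "altitude_band",
    "feeder_flag",
    "site_note",
)

_TRUE_STRINGS = {"true", "1", "yes", "t"}


@dataclass
class CountsTensor:
    """Per-species monthly counts indexed ``[month, item, location]``.

    This is the sufficient statistic for every estimator in the package:
    raw observation proportions, the Bayesian imputation model, and the
    seasonal contingency tests are all functions of it.  Months with zero
    episodes are kept as all-zero slices (the seasonal smoother needs the
    full 12-month cycle).
    """

    species: str
    counts: np.ndarray  # (12, n_items, n_locations) int64
    schema: CategorySchema

    def __post_init__(self) -> None:
        expected = (N_MONTHS, self.schema.n_items, self.schema.n_locations)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} != expected {expected}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def totals_by_month(self) -> np.ndarray:
        """Episode totals N_m per month (length 12)."""
        return self.counts.sum(axis=(1, 2))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_identified(self) -> int:
        u = self.schema.unidentified_item_index
        return int(self.total - self.counts[:, u, :].sum())

    @property
    def unidentified_proportion(self) -> float:
        """Fraction of all episodes whose diet item is unidentified."""
        total = self.total
        if total == 0:
            return float("nan")
        return (total - self.n_identified) / total

    def item_by_month(self) -> np.ndarray:
        """Counts summed over locations, shape (12, n_items)."""
        return self.counts.sum(axis=2)

    def location_by_month(self) -> np.ndarray:
        """Counts summed over items, shape (12, n_locations)."""
        return self.counts.sum(axis=1)


def _parse_row(row: dict, row_number: int, schema: CategorySchema) -> FeedingEpisode:
    try:
        episode = FeedingEpisode(
            species=row["species"].strip(),
            year=int(row["year"]),
            month=int(row["month"]),
            item=row["item"].strip(),
            location=row["location"].strip(),
            altitude_band=row["altitude_band"].strip() or "lowland",
            feeder_flag=row["feeder_flag"].strip().lower() in _TRUE_STRINGS,
            site_note=(row.get("site_note") or "").strip(),
        )
        episode.validate(schema)
    except (ValueError, ValidationError) as exc:
        raise ValidationError(f"row {row_number}: {exc}") from None
    return episode


def _open_reader(path: str | Path) -> tuple[csv.DictReader, object]:
    handle = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    if reader.fieldnames is None:
        handle.close()
        raise SchemaError(f"{path}: file has no header row")
    missing = [c for c in EPISODE_COLUMNS if c not in reader.fieldnames]
    if missing:
        handle.close()
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return reader, handle


def read_episodes(path: str | Path, schema: CategorySchema | None = None) -> list[FeedingEpisode]:
    """Read a one-episode-per-row CSV, validating every label against *schema*.

    Unknown category labels are rejected with the offending row number,
    never coerced.
    """
    schema = schema or CategorySchema.default()
    reader, handle = _open_reader(path)
    episodes: list[FeedingEpisode] = []
    with handle:
        for i, row in enumerate(reader, start=2):  # header is line 1
            episodes.append(_parse_row(row, i, schema))
    return episodes


def expand_multirecord(
    items: Sequence[str], locations: Sequence[str]
) -> list[tuple[str, str]]:
    """Pair up the delimited multi-item / multi-location fields of one report.

    Reports listing several diet items may give either one location per item
    (parallel lists) or a single location shared by all items.  Returns the
    ``(item, location)`` pairs in report order.
    """
    items = [s.strip() for s in items]
    locations = [s.strip() for s in locations]
    if not items or not locations:
        raise ValidationError("empty item or location list")
    if len(locations) == 1:
        return [(item, locations[0]) for item in items]
    if len(items) == 1:
        return [(items[0], loc) for loc in locations]
    if len(items) != len(locations):
        raise ValidationError(
            f"cannot pair {len(items)} items with {len(locations)} locations"
        )
    return list(zip(items, locations))


def read_raw_reports(
    path: str | Path, schema: CategorySchema | None = None, delimiter: str = ";"
) -> list[FeedingEpisode]:
    """Read a raw-report CSV whose item/location cells may be ``;``-lists.

    Each report expands to one episode per (item, location) pairing, in
    order; all other fields are copied to every resulting episode.
    """
    schema = schema or CategorySchema.default()
    reader, handle = _open_reader(path)
    episodes: list[FeedingEpisode] = []
    with handle:
        for i, row in enumerate(reader, start=2):
            try:
                pairs = expand_multirecord(
                    row["item"].split(delimiter), row["location"].split(delimiter)
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from None
            for item, location in pairs:
                sub = dict(row)
                sub["item"] = item
                sub["location"] = location
                episodes.append(_parse_row(sub, i, schema))
    return episodes


def write_episodes(path: str | Path, episodes: Iterable[FeedingEpisode]) -> None:
    """Write episodes as a one-row-per-episode CSV (inverse of read_episodes)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(EPISODE_COLUMNS)
        for e in episodes:
            writer.writerow(
                [e.species, e.year, e.month, e.item, e.location,
                 e.altitude_band, str(e.feeder_flag).lower(), e.site_note]
            )


def apply_filters(episodes: Iterable[FeedingEpisode]) -> list[FeedingEpisode]:
    """Apply the study's exclusion rules.

    Dropped: feeder records; non-lowland records; records with neither an
    identified item nor an identified location (no information at all).
    Retained: episodes with an unidentified item but a known location —
    these carry the location signal the imputation model exploits.
    """
    kept = []
    for e in episodes:
        if e.feeder_flag:
            continue
        if e.altitude_band != "lowland":
            continue
        if e.item == UNIDENTIFIED and e.location == UNIDENTIFIED:
            continue
        kept.append(e)
    return kept


def tally(
    episodes: Iterable[FeedingEpisode],
    species: str,
    schema: CategorySchema | None = None,
) -> CountsTensor:
    """Pool a species' episodes across years into monthly count cells.

    ``counts[m, k, l]`` is the number of episodes of *species* in month
    ``m+1`` with diet item ``k`` at location ``l``; years are pooled.
    """
    schema = schema or CategorySchema.default()
    counts = np.zeros((N_MONTHS, schema.n_items, schema.n_locations), dtype=np.int64)
    for e in episodes:
        if e.species != species:
            continue
        counts[e.month - 1, schema.item_index(e.item), schema.location_index(e.location)] += 1
    return CountsTensor(species=species, counts=counts, schema=schema)


def species_in(episodes: Iterable[FeedingEpisode]) -> list[str]:
    """Distinct species names, ordered by decreasing episode count."""
    tallies: dict[str, int] = {}
    for e in episodes:
        tallies[e.species] = tallies.get(e.species, 0) + 1
    return sorted(tallies, key=lambda s: (-tallies[s], s))


def summary_table(
    episodes: Iterable[FeedingEpisode], schema: CategorySchema | None = None
) -> pd.DataFrame:
    """Per-species tally table: totals, identified totals, unidentified
    proportion, and the 12 monthly episode counts."""
    schema = schema or CategorySchema.default()
    episodes = list(episodes)
    rows = []
    for species in species_in(episodes):
        t = tally(episodes, species, schema)
        row = {
            "species": species,
            "total_episodes": t.total,
            "identified_episodes": t.n_identified,
            "unidentified_proportion": round(t.unidentified_proportion, 4),
        }
        for m, n in enumerate(t.totals_by_month, start=1):
            row[f"m{m:02d}"] = int(n)
        rows.append(row)
    return pd.DataFrame(rows)
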