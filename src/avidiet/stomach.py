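"""Stomach-content count proportions (CPs) and composition comparisons.

Historical stomach-analysis studies list, per collected bird, the diet items
found in the stomach and their counts (parts for plant items, individuals
for animal items; uncountable material is recorded as one).  Pooling the
counts of all specimens of a species collected in the same calendar month —
across studies — gives the monthly *count proportion* of each item, the
benchmark the monitoring-based proportions are validated against.

Bird-month cells with fewer than five specimens are excluded before
comparison, and agreement is summarised per diet item by the root mean
square difference (RMSD) over paired bird-month cells, on the percentage
scale (0-100), so an RMSD of 5 means a typical gap of five percentage
points.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import CompositionTable
from .schema import N_MONTHS, CategorySchema, SchemaError, ValidationError

STOMACH_COLUMNS = ("study_id", "species", "month", "n_specimens", "item", "count")

MIN_SPECIMENS = 5


@dataclass
class StomachRecord:
    """Pooled stomach contents for one (study, species, month).

    ``item_counts`` maps identified diet items to total counts over the
    record's ``n_specimens`` specimens.
    """

    study_id: str
    species: str
    month: int
    n_specimens: int
    item_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= int(self.month) <= N_MONTHS:
            raise ValidationError(f"month must be in 1..12, got {self.month}")
        if self.n_specimens < 1:
            raise ValidationError("n_specimens must be >= 1")
        if any(v < 0 for v in self.item_counts.values()):
            raise ValidationError("item counts must be non-negative")

    def validate_items(self, schema: CategorySchema) -> None:
        for item in self.item_counts:
            if item not in schema.identified_items:
                raise ValidationError(f"unknown identified item {item!r}")


def read_stomach(path: str | Path, schema: CategorySchema | None = None) -> list[StomachRecord]:
    """Read a long-format stomach table (one row per study/species/month/item)."""
    schema = schema or CategorySchema.default()
    grouped: dict[tuple[str, str, int], dict] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: file has no header row")
        missing = [c for c in STOMACH_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                key = (row["study_id"].strip(), row["species"].strip(), int(row["month"]))
                entry = grouped.setdefault(
                    key, {"n_specimens": int(row["n_specimens"]), "items": {}}
                )
                item = row["item"].strip()
                if item not in schema.identified_items:
                    raise ValidationError(f"unknown identified item {item!r}")
                entry["items"][item] = entry["items"].get(item, 0) + int(row["count"])
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"row {i}: {exc}") from None
    return [
        StomachRecord(
            study_id=k[0], species=k[1], month=k[2],
            n_specimens=v["n_specimens"], item_counts=v["items"],
        )
        for k, v in grouped.items()
    ]


def write_stomach(path: str | Path, records: Iterable[StomachRecord]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(STOMACH_COLUMNS)
        for r in records:
            for item, count in r.item_counts.items():
                writer.writerow([r.study_id, r.species, r.month, r.n_specimens, item, count])


def filter_min_specimens(
    records: Iterable[StomachRecord], threshold: int = MIN_SPECIMENS
) -> list[StomachRecord]:
    """Drop bird-month combinations with fewer than *threshold* specimens,
    totalled across studies."""
    records = list(records)
    totals: dict[tuple[str, int], int] = defaultdict(int)
    for r in records:
        totals[(r.species, r.month)] += r.n_specimens
    return [r for r in records if totals[(r.species, r.month)] >= threshold]


def compute_cp(
    records: Iterable[StomachRecord],
    schema: CategorySchema | None = None,
    species: str | None = None,
) -> CompositionTable:
    """Monthly count proportions for one species, pooled across studies.

    CP[m, k] = (total count of item k in month m over all records)
             / (total count of all items in month m).
    Months with zero total items are undefined.
    """
    schema = schema or CategorySchema.default()
    records = list(records)
    if species is None:
        names = {r.species for r in records}
        if len(names) > 1:
            raise ValueError(f"records span several species: {sorted(names)}")
        species = names.pop() if names else "unknown"
    items = schema.identified_items
    counts = np.zeros((N_MONTHS, len(items)), dtype=np.int64)
    specimens = np.zeros(N_MONTHS, dtype=np.int64)
    for r in records:
        if r.species != species:
            continue
        r.validate_items(schema)
        specimens[r.month - 1] += r.n_specimens
        for item, c in r.item_counts.items():
            counts[r.month - 1, items.index(item)] += c
    return CompositionTable.from_counts(
        species=species, kind="CP", counts=counts, categories=items
    )


@dataclass
class ComparisonResult:
    """Agreement between a monitoring composition and stomach CPs for one
    diet item, over the bird-month cells defined in both tables.

    Proportions in ``paired_cells`` and ``rmsd`` are in percent.
    """

    item: str
    kind: str  # which monitoring estimate was compared (ROP or MOP)
    paired_cells: list[tuple[str, int, float, float]]  # species, month, monitoring%, CP%
    rmsd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.paired_cells,
            columns=["species", "month", "monitoring_pct", "cp_pct"],
        )


def rmsd_compare(
    monitoring: Mapping[str, CompositionTable] | CompositionTable,
    cp: Mapping[str, CompositionTable] | CompositionTable,
    item: str,
) -> ComparisonResult:
    """Root mean square difference between monitoring proportions and CPs
    for one diet item, pooling paired bird-month cells over species.

    Both arguments may be a single table or a ``{species: table}`` mapping;
    only cells defined in both tables are paired.  RMSD is computed on the
    percentage scale.
    """
    if isinstance(monitoring, CompositionTable):
        monitoring = {monitoring.species: monitoring}
    if isinstance(cp, CompositionTable):
        cp = {cp.species: cp}
    pairs: list[tuple[str, int, float, float]] = []
    kinds = set()
    for species, mon_table in monitoring.items():
        if species not in cp:
            continue
        kinds.add(mon_table.kind)
        cp_table = cp[species]
        mon_col = mon_table.column(item)
        cp_col = cp_table.column(item)
        both = mon_table.defined & cp_table.defined
        for m in np.nonzero(both)[0]:
            pairs.append(
                (species, int(m + 1), 100.0 * mon_col[m], 100.0 * cp_col[m])
            )
    if not pairs:
        raise ValueError(f"no paired bird-month cells for item {item!r}")
    diffs = np.array([p[2] - p[3] for p in pairs])
    return ComparisonResult(
        item=item,
        kind="/".join(sorted(kinds)),
        paired_cells=pairs,
        rmsd=float(np.sqrt(np.mean(diffs**2))),
    )


def rmsd_summary(
    monitoring: Mapping[str, CompositionTable],
    cp: Mapping[str, CompositionTable],
    items: Sequence[str],
) -> pd.DataFrame:
    """Per-item RMSD table for one monitoring estimator against CPs."""
    rows = []
    for item in items:
        try:
            res = rmsd_compare(monitoring, cp, item)
        except ValueError:
            continue
        rows.append(
            {"item": item, "kind": res.kind, "n_pairs": len(res.paired_cells),
             "rmsd_pct": res.rmsd}
        )
    return pd.DataFrame(rows)
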