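"""The month-by-category proportion table shared by all estimators.

ROPs (raw observation proportions), MOPs (model-aided observation
proportions), CPs (stomach count proportions) and foraging-location profiles
are all instances of one structure: a 12-month by category matrix of
fractions whose defined rows sum to one, plus the per-month support (episode
or item totals) that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import N_MONTHS

ROW_SUM_TOL = 1e-9

MONTH_INDEX = pd.RangeIndex(1, N_MONTHS + 1, name="month")


@dataclass
class CompositionTable:
    """A per-species month x category proportion matrix.

    Parameters
    ----------
    species
        Species the table describes.
    kind
        One of ``ROP``, ``ROP_identified_only``, ``MOP``, ``CP``,
        ``location_profile``.
    values
        ``(12, n_categories)`` array of fractions.  Rows whose support is
        zero are *undefined* (stored as NaN) rather than zero, so that
        downstream comparisons and plots skip them explicitly.
    categories
        Column labels, in order.
    support
        Per-month totals the proportions were computed from (episodes,
        specimens or item counts).
    """

    species: str
    kind: str
    values: np.ndarray
    categories: tuple[str, ...]
    support: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support = np.asarray(self.support)
        self.categories = tuple(self.categories)
        if self.values.shape != (N_MONTHS, len(self.categories)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({N_MONTHS}, {len(self.categories)})"
            )
        if self.support.shape != (N_MONTHS,):
            raise ValueError("support must have one entry per month")
        defined = self.defined
        vals = self.values[defined]
        if vals.size:
            if np.nanmin(vals) < -ROW_SUM_TOL or np.nanmax(vals) > 1 + ROW_SUM_TOL:
                raise ValueError("proportions must lie in [0, 1]")
            sums = vals.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError("defined rows must sum to 1")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of months whose proportions are defined."""
        return ~np.isnan(self.values).any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy wide DataFrame: month index, category columns + support."""
        df = pd.DataFrame(self.values, index=MONTH_INDEX, columns=list(self.categories))
        df["support"] = self.support
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    @classmethod
    def from_counts(
        cls,
        species: str,
        kind: str,
        counts: np.ndarray,
        categories: tuple[str, ...],
        support: np.ndarray | None = None,
    ) -> "CompositionTable":
        """Normalise a (12, n_categories) count matrix row-wise.

        Rows with zero total become undefined (NaN), not zero.
        """
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1)
        values = np.full_like(counts, np.nan)
        ok = totals > 0
        values[ok] = counts[ok] / totals[ok, None]
        return cls(
            species=species,
            kind=kind,
            values=values,
            categories=categories,
            support=totals.astype(np.int64) if support is None else support,
        )

    def column(self, category: str) -> np.ndarray:
        """One category's monthly proportions (NaN where undefined)."""
        return self.values[:, self.categories.index(category)]

    def restricted(self, categories: tuple[str, ...], kind: str | None = None) -> "CompositionTable":
        """Renormalise over a subset of categories (undefined where the
        subset has zero mass)."""
        idx = [self.categories.index(c) for c in categories]
        sub = self.values[:, idx]
        totals = sub.sum(axis=1)
        out = np.full_like(sub, np.nan)
        ok = ~np.isnan(totals) & (totals > 0)
        out[ok] = sub[ok] / totals[ok, None]
        return CompositionTable(
            species=self.species,
            kind=kind or self.kind,
            values=out,
            categories=categories,
            support=self.support,
        )

    def plot(self, ax=None, title: str | None = None):
        """Stacked monthly bar chart (convenience output)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        bottom = np.zeros(N_MONTHS)
        months = np.arange(1, N_MONTHS + 1)
        vals = np.nan_to_num(self.values, nan=0.0)
        for j, cat in enumerate(self.categories):
            ax.bar(months, vals[:, j], bottom=bottom, label=cat)
            bottom += vals[:, j]
        ax.set_xlabel("month")
        ax.set_ylabel("proportion")
        ax.set_xticks(months)
        ax.set_title(title or f"{self.species} — {self.kind}")
        ax.legend(fontsize=7, ncol=2)
        return ax


def total_variation(table: CompositionTable, reference: np.ndarray) -> float:
    """Mean over defined months of the total-variation distance between the
    table's rows and *reference* rows (a (12, n_categories) probability
    matrix)."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != table.values.shape:
        raise ValueError("reference shape must match table values")
    mask = table.defined
    if not mask.any():
        return float("nan")
    diffs = np.abs(table.values[mask] - reference[mask]).sum(axis=1) / 2.0
    return float(diffs.mean())
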