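"""Raw observation proportions (ROPs) and the seasonal contingency tests.

The ROP of a diet item in a month is simply the fraction of that month's
feeding episodes (pooled across years) recorded as that item, with
"unidentified" kept as its own category.  ``rop_identified_only``
renormalises over the identified items, which is the monitoring-side input
to stomach-content comparisons — and the estimator the Bayesian imputation
model is meant to improve on, since discarding unidentified episodes biases
proportions whenever identifiability varies with foraging location.

Seasonal shifts are tested with one-sided Pearson chi-square tests on a
2x2 table of episodes split by season (breeding, April–September, versus
wintering, October–March) and by a binary trait (animal vs non-animal diet
item, or ground vs non-ground foraging location).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .composition import CompositionTable
from .episodes import CountsTensor
from .schema import ANIMAL_ITEMS, BREEDING_MONTHS, UNIDENTIFIED


def compute_rop(counts: CountsTensor) -> CompositionTable:
    """Monthly proportions over all diet items, unidentified included."""
    return CompositionTable.from_counts(
        species=counts.species,
        kind="ROP",
        counts=counts.item_by_month(),
        categories=counts.schema.diet_items,
    )


def rop_identified_only(counts: CountsTensor) -> CompositionTable:
    """Monthly proportions renormalised over the identified items only.

    Months where every episode is unidentified become undefined rows.
    """
    schema = counts.schema
    item_counts = counts.item_by_month()
    keep = [i for i, k in enumerate(schema.diet_items) if k != UNIDENTIFIED]
    return CompositionTable.from_counts(
        species=counts.species,
        kind="ROP_identified_only",
        counts=item_counts[:, keep],
        categories=schema.identified_items,
    )


def location_profile(counts: CountsTensor) -> CompositionTable:
    """Monthly proportions of foraging locations (all 10 categories)."""
    return CompositionTable.from_counts(
        species=counts.species,
        kind="location_profile",
        counts=counts.location_by_month(),
        categories=counts.schema.locations,
    )


@dataclass
class SeasonalTestResult:
    """One-sided 2x2 chi-square test of a seasonal shift.

    ``table`` rows are (breeding, wintering) seasons; columns are the focal
    trait (animal item / ground location) versus its complement.
    ``direction_ok`` records whether the observed shift points in the
    hypothesised direction; the one-sided p is ``p_two_sided / 2`` when it
    does and ``1 - p_two_sided / 2`` otherwise.  ``defined`` is False when a
    margin is degenerate (a season or a trait column with no episodes).
    """

    species: str
    trait: str
    statistic: float
    p_one_sided: float
    table: np.ndarray
    direction_ok: bool
    defined: bool = True


def _one_sided_chi2(
    table: np.ndarray, species: str, trait: str, direction_ok: bool
) -> SeasonalTestResult:
    table = np.asarray(table, dtype=np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return SeasonalTestResult(
            species, trait, float("nan"), float("nan"), table, False, defined=False
        )
    res = stats.chi2_contingency(table, correction=False)
    p_two = float(res.pvalue)
    p_one = p_two / 2.0 if direction_ok else 1.0 - p_two / 2.0
    return SeasonalTestResult(
        species=species,
        trait=trait,
        statistic=float(res.statistic),
        p_one_sided=p_one,
        table=table,
        direction_ok=direction_ok,
    )


def _season_split(by_month: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum a (12, c) matrix into (breeding, wintering) season vectors."""
    months = np.arange(1, 13)
    breeding = np.isin(months, sorted(BREEDING_MONTHS))
    return by_month[breeding].sum(axis=0), by_month[~breeding].sum(axis=0)


def seasonal_animal_test(counts: CountsTensor) -> SeasonalTestResult:
    """Do animal diets make up a larger share of identified episodes in the
    breeding season than in the wintering season?

    Animal diets are invertebrates, fish, amphibians and reptiles, birds and
    mammals; the comparison uses identified episodes only.
    """
    schema = counts.schema
    item_counts = counts.item_by_month()
    animal = np.array([k in ANIMAL_ITEMS for k in schema.diet_items])
    identified = np.array([k != UNIDENTIFIED for k in schema.diet_items])
    per_month = np.stack(
        [
            item_counts[:, animal & identified].sum(axis=1),
            item_counts[:, ~animal & identified].sum(axis=1),
        ],
        axis=1,
    )
    breeding, wintering = _season_split(per_month)
    table = np.stack([breeding, wintering])
    # hypothesised direction: higher animal share while breeding
    totals = table.sum(axis=1)
    direction_ok = bool(
        totals[0] > 0
        and totals[1] > 0
        and table[0, 0] / totals[0] > table[1, 0] / totals[1]
    )
    return _one_sided_chi2(table, counts.species, "animal_diet", direction_ok)


def seasonal_ground_test(counts: CountsTensor) -> SeasonalTestResult:
    """Does ground foraging make up a larger share of episodes in the
    wintering season than in the breeding season?"""
    schema = counts.schema
    loc_counts = counts.location_by_month()
    ground = np.array([l == "ground" for l in schema.locations])
    per_month = np.stack(
        [loc_counts[:, ground].sum(axis=1), loc_counts[:, ~ground].sum(axis=1)],
        axis=1,
    )
    breeding, wintering = _season_split(per_month)
    table = np.stack([breeding, wintering])
    totals = table.sum(axis=1)
    # hypothesised direction: higher ground share while wintering
    direction_ok = bool(
        totals[0] > 0
        and totals[1] > 0
        and table[1, 0] / totals[1] > table[0, 0] / totals[0]
    )
    return _one_sided_chi2(table, counts.species, "ground_foraging", direction_ok)
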