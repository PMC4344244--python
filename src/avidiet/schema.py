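"""Category schemas and the feeding-episode record type.

A *feeding episode* is one reported observation of a bird consuming (or
catching) a dietary item at a foraging location — the unit record of the
volunteer monitoring data this package analyses.  Diet items and foraging
locations are closed categorical vocabularies; ``"unidentified"`` appears in
both, but plays two very different roles:

* an **unidentified diet item** is missing data — the observer saw foraging
  but could not tell what was eaten; the Bayesian model imputes it;
* an **unidentified foraging location** is an ordinary reporting outcome
  (e.g. the bird was seen only while handling the item) and is treated as a
  tenth observable location category, never as missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

UNIDENTIFIED = "unidentified"

#: The standard diet-item vocabulary (10 identified categories + unidentified).
DEFAULT_DIET_ITEMS = (
    "seed",
    "fleshy fruit",
    "flower",
    "leaf and bud",
    "invertebrate",
    "fish",
    "amphibian and reptile",
    "bird",
    "mammal",
    "man-made food",
    UNIDENTIFIED,
)

#: The standard foraging-location vocabulary (10 observable categories, of
#: which "unidentified" is an ordinary reporting outcome).
DEFAULT_LOCATIONS = (
    "ground",
    "puddle",
    "tree",
    "tree trunk",
    "tall grass",
    "short grass",
    "bush",
    "in the air",
    "man-made structure",
    UNIDENTIFIED,
)

#: Diet items counted as animal diets in the seasonal-shift tests.
ANIMAL_ITEMS = frozenset(
    {"invertebrate", "fish", "amphibian and reptile", "bird", "mammal"}
)

#: April–September; the complement (October–March) is the wintering season.
BREEDING_MONTHS = frozenset({4, 5, 6, 7, 8, 9})

N_MONTHS = 12


class SchemaError(ValueError):
    """A category vocabulary or input header violates the schema."""


class ValidationError(ValueError):
    """An input row carries a value outside the schema vocabularies."""


@dataclass(frozen=True)
class CategorySchema:
    """Closed vocabularies for diet items and foraging locations.

    Parameters
    ----------
    diet_items
        Ordered unique labels; must contain ``"unidentified"`` exactly once.
        All other labels are the *identified* items.
    locations
        Ordered unique labels.  ``"unidentified"`` may appear (once): it is
        an observable reporting category, not missing data.
    """

    diet_items: tuple[str, ...] = DEFAULT_DIET_ITEMS
    locations: tuple[str, ...] = DEFAULT_LOCATIONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "diet_items", tuple(self.diet_items))
        object.__setattr__(self, "locations", tuple(self.locations))
        for name, labels in (("diet_items", self.diet_items),
                             ("locations", self.locations)):
            if len(set(labels)) != len(labels):
                raise SchemaError(f"{name} labels must be unique: {labels}")
        # the item marker is mandatory (it is the missingness mechanism);
        # the location label is an ordinary category and merely optional
        if self.diet_items.count(UNIDENTIFIED) != 1:
            raise SchemaError(
                f"diet_items must contain {UNIDENTIFIED!r} exactly once"
            )
        if len(self.diet_items) < 2:
            raise SchemaError("diet_items needs at least one identified label")
        if not self.locations:
            raise SchemaError("locations must be non-empty")

    @classmethod
    def default(cls) -> "CategorySchema":
        """The standard 11-item / 10-location schema."""
        return cls()

    @property
    def identified_items(self) -> tuple[str, ...]:
        """Diet items excluding the unidentified marker, in schema order."""
        return tuple(k for k in self.diet_items if k != UNIDENTIFIED)

    @property
    def n_items(self) -> int:
        return len(self.diet_items)

    @property
    def n_identified(self) -> int:
        return len(self.diet_items) - 1

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    def item_index(self, label: str) -> int:
        try:
            return self.diet_items.index(label)
        except ValueError:
            raise ValidationError(f"unknown diet item {label!r}") from None

    def location_index(self, label: str) -> int:
        try:
            return self.locations.index(label)
        except ValueError:
            raise ValidationError(f"unknown location {label!r}") from None

    @property
    def unidentified_item_index(self) -> int:
        return self.diet_items.index(UNIDENTIFIED)


@dataclass
class FeedingEpisode:
    """One observed foraging event.

    ``item`` may be ``"unidentified"`` (missing datum, to be imputed);
    ``location`` may be ``"unidentified"`` (observed reporting outcome).
    ``altitude_band`` is a precomputed ``"lowland"``/``"highland"`` flag
    (episodes are filtered to lowland, <500 m); ``feeder_flag`` marks records
    from artificial bird feeders, which are excluded from analysis.
    """

    species: str
    year: int
    month: int
    item: str
    location: str
    altitude_band: str = "lowland"
    feeder_flag: bool = False
    site_note: str = ""

    def validate(self, schema: CategorySchema) -> None:
        if not 1 <= int(self.month) <= N_MONTHS:
            raise ValidationError(f"month must be in 1..12, got {self.month}")
        if self.item not in schema.diet_items:
            raise ValidationError(f"unknown diet item {self.item!r}")
        if self.location not in schema.locations:
            raise ValidationError(f"unknown location {self.location!r}")

    @property
    def is_identified(self) -> bool:
        return self.item != UNIDENTIFIED
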