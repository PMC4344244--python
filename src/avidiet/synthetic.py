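"""Synthetic feeding-episode and stomach-content generators with known truth.

The generator emulates the statistical structure the imputation model
assumes: each month a bird chooses a diet item from a smooth seasonal item
distribution, the foraging location is drawn from an item-specific law, and
the *item* of an episode is then lost (recorded as "unidentified") with a
probability that depends on the location — camouflaged locations such as
tree canopies hide what is being eaten, open ground does not.  Because
missingness depends only on the location, the data are missing at random
given location, exactly the mechanism the model exploits; an optional
item-dependent modulation creates a controlled violation for robustness
experiments.

Stomach tables are generated from the same monthly truth: each specimen
holds a Poisson number of items drawn from the month's item distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .schema import UNIDENTIFIED, N_MONTHS, CategorySchema, FeedingEpisode
from .stomach import StomachRecord


@dataclass
class SyntheticTruth:
    """Generating parameters paired with a category schema.

    Parameters
    ----------
    lambda_true
        (12, K) positive monthly expected frequencies over the K identified
        items; each row normalised gives the month's true item distribution.
    theta_true
        (K, L) location-given-item rows (sum to 1).
    miss_prob
        Length-L probability that an episode's item is recorded as
        unidentified, by location.
    miss_item_factor
        Optional length-K multiplier on the missingness probability
        (clipped to [0, 1]); any non-uniform value breaks the
        missing-at-random-given-location assumption on purpose.
    n_episodes_per_month
        Length-12 episode counts.
    """

    schema: CategorySchema
    lambda_true: np.ndarray
    theta_true: np.ndarray
    miss_prob: np.ndarray
    n_episodes_per_month: np.ndarray
    seed: int = 0
    species: str = "synthetic species"
    miss_item_factor: np.ndarray | None = None

    def __post_init__(self) -> None:
        K, L = self.schema.n_identified, self.schema.n_locations
        self.lambda_true = np.asarray(self.lambda_true, dtype=float)
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        self.miss_prob = np.asarray(self.miss_prob, dtype=float)
        self.n_episodes_per_month = np.asarray(self.n_episodes_per_month, dtype=np.int64)
        if self.lambda_true.shape != (N_MONTHS, K):
            raise ValueError(f"lambda_true must have shape (12, {K})")
        if (self.lambda_true <= 0).any():
            raise ValueError("lambda_true must be positive")
        if self.theta_true.shape != (K, L):
            raise ValueError(f"theta_true must have shape ({K}, {L})")
        if not np.allclose(self.theta_true.sum(axis=1), 1.0):
            raise ValueError("theta_true rows must sum to 1")
        if self.miss_prob.shape != (L,) or ((self.miss_prob < 0) | (self.miss_prob > 1)).any():
            raise ValueError("miss_prob must be L probabilities in [0, 1]")
        if self.n_episodes_per_month.shape != (N_MONTHS,):
            raise ValueError("n_episodes_per_month must have 12 entries")
        if self.miss_item_factor is not None:
            self.miss_item_factor = np.asarray(self.miss_item_factor, dtype=float)
            if self.miss_item_factor.shape != (K,):
                raise ValueError(f"miss_item_factor must have shape ({K},)")

    @property
    def pi_true(self) -> np.ndarray:
        """True monthly item distributions (rows sum to 1), shape (12, K)."""
        return self.lambda_true / self.lambda_true.sum(axis=1, keepdims=True)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "seed": self.seed,
            "diet_items": list(self.schema.diet_items),
            "locations": list(self.schema.locations),
            "lambda_true": self.lambda_true.tolist(),
            "theta_true": self.theta_true.tolist(),
            "miss_prob": self.miss_prob.tolist(),
            "miss_item_factor": (
                None if self.miss_item_factor is None else self.miss_item_factor.tolist()
            ),
            "n_episodes_per_month": self.n_episodes_per_month.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        schema = CategorySchema(
            diet_items=tuple(payload["diet_items"]),
            locations=tuple(payload["locations"]),
        )
        factor = payload.get("miss_item_factor")
        return cls(
            schema=schema,
            lambda_true=np.array(payload["lambda_true"]),
            theta_true=np.array(payload["theta_true"]),
            miss_prob=np.array(payload["miss_prob"]),
            n_episodes_per_month=np.array(payload["n_episodes_per_month"]),
            seed=payload["seed"],
            species=payload["species"],
            miss_item_factor=None if factor is None else np.array(factor),
        )


def seasonal_lambda(
    n_items: int,
    base_level: float = 2.0,
    amplitudes: np.ndarray | None = None,
    phases: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth cyclic truth curves log lambda[m,k] = c + A_k sin(2π(m-φ_k)/12).

    The default amplitudes/phases stagger the items around the year, giving
    each item a distinct season — the regime the cyclic random-walk prior is
    designed for.
    """
    months = np.arange(N_MONTHS)
    if amplitudes is None:
        amplitudes = np.linspace(0.6, 1.2, n_items)
    if phases is None:
        phases = np.linspace(0, N_MONTHS, n_items, endpoint=False)
    log_lam = base_level + np.asarray(amplitudes) * np.sin(
        2 * np.pi * (months[:, None] - np.asarray(phases)[None, :]) / N_MONTHS
    )
    return np.exp(log_lam)


def default_truth(
    n_items: int = 4,
    n_locations: int = 3,
    n_per_month: int = 40,
    miss_low: float = 0.1,
    miss_high: float = 0.6,
    theta_concentration: float = 0.8,
    seed: int = 0,
    species: str = "synthetic species",
) -> SyntheticTruth:
    """A study-scale synthetic species.

    Defaults follow the desk-scale recovery design: 12 months x 4 identified
    items x 3 locations, 40 episodes per month, and location-dependent
    missingness spanning 10-60%.  ``theta_concentration`` is the symmetric
    Dirichlet concentration used to draw distinct location-given-item rows
    (< 1 gives each item a pronounced location preference, which is what
    makes locations informative about unidentified items).
    """
    rng = np.random.default_rng(seed)
    items = tuple(f"item{i + 1}" for i in range(n_items)) + (UNIDENTIFIED,)
    locations = tuple(f"loc{j + 1}" for j in range(n_locations - 1)) + (UNIDENTIFIED,)
    schema = CategorySchema(diet_items=items, locations=locations)
    theta = rng.dirichlet(np.full(n_locations, theta_concentration), size=n_items)
    miss = np.linspace(miss_low, miss_high, n_locations)
    return SyntheticTruth(
        schema=schema,
        lambda_true=seasonal_lambda(n_items),
        theta_true=theta,
        miss_prob=miss,
        n_episodes_per_month=np.full(N_MONTHS, n_per_month),
        seed=seed,
        species=species,
    )


def generate_episodes(truth: SyntheticTruth) -> tuple[list[FeedingEpisode], SyntheticTruth]:
    """Simulate a feeding-episode table from known truth.

    Per month: item ~ Categorical(pi_true[m]), location ~ Categorical(theta
    row of the item), then the item is overwritten with "unidentified" with
    probability miss_prob[location] (times the item's factor, if any).
    Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    schema = truth.schema
    items = schema.identified_items
    locations = schema.locations
    pi = truth.pi_true
    episodes: list[FeedingEpisode] = []
    for m in range(N_MONTHS):
        n = int(truth.n_episodes_per_month[m])
        ks = rng.choice(len(items), size=n, p=pi[m])
        for k in ks:
            l = rng.choice(len(locations), p=truth.theta_true[k])
            p_miss = truth.miss_prob[l]
            if truth.miss_item_factor is not None:
                p_miss = min(1.0, p_miss * truth.miss_item_factor[k])
            item = UNIDENTIFIED if rng.random() < p_miss else items[k]
            episodes.append(
                FeedingEpisode(
                    species=truth.species,
                    year=2000,
                    month=m + 1,
                    item=item,
                    location=locations[l],
                )
            )
    return episodes, truth


def generate_stomach(
    truth: SyntheticTruth,
    items_per_specimen: float = 8.0,
    n_specimens_per_month: int = 8,
    study_id: str = "synthetic-study",
) -> list[StomachRecord]:
    """Simulate stomach-content records from the same monthly truth.

    Each specimen holds a Poisson(``items_per_specimen``) number of items
    drawn from the month's true item distribution; specimens of a month are
    aggregated into one record.  Uses a seed offset from ``truth.seed`` so
    stomach sampling is independent of the episode stream.
    """
    if items_per_specimen <= 0:
        raise ValueError("items_per_specimen must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    items = truth.schema.identified_items
    pi = truth.pi_true
    records: list[StomachRecord] = []
    for m in range(N_MONTHS):
        counts = np.zeros(len(items), dtype=np.int64)
        for _ in range(n_specimens_per_month):
            total = rng.poisson(items_per_specimen)
            if total > 0:
                counts += rng.multinomial(total, pi[m])
        records.append(
            StomachRecord(
                study_id=study_id,
                species=truth.species,
                month=m + 1,
                n_specimens=n_specimens_per_month,
                item_counts={items[k]: int(c) for k, c in enumerate(counts)},
            )
        )
    return records
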