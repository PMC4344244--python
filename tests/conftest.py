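import numpy as np
import pytest

from avidiet import CategorySchema, FeedingEpisode, default_truth, generate_episodes, tally


@pytest.fixture(scope="session")
def schema():
    return CategorySchema.default()


@pytest.fixture(scope="session")
def small_schema():
    """2 identified items x 2 locations, for enumerable model instances."""
    return CategorySchema(
        diet_items=("seed", "invertebrate", "unidentified"),
        locations=("ground", "tree"),
    )


def make_episode(species="test bird", month=1, item="seed", location="ground", **kw):
    return FeedingEpisode(species=species, year=2000, month=month,
                          item=item, location=location, **kw)


@pytest.fixture(scope="session")
def synthetic_counts():
    """One synthetic species with location-dependent missingness, tallied."""
    truth = default_truth(seed=11)
    episodes, _ = generate_episodes(truth)
    return tally(episodes, truth.species, truth.schema), truth
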