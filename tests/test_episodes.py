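"""Episode reading, validation, multi-record expansion, filters and tallies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from avidiet import (
    CategorySchema,
    SchemaError,
    ValidationError,
    apply_filters,
    expand_multirecord,
    read_episodes,
    read_raw_reports,
    summary_table,
    tally,
    write_episodes,
)
from avidiet.episodes import EPISODE_COLUMNS

from conftest import make_episode

HEADER = ",".join(EPISODE_COLUMNS)


def write_csv(path, rows):
    path.write_text(HEADER + "\n" + "".join(r + "\n" for r in rows))
    return path


class TestReadEpisodes:
    def test_well_formed_rows_give_one_episode_each(self, tmp_path, schema):
        p = write_csv(tmp_path / "e.csv", [
            "sparrow,1999,1,seed,ground,lowland,false,",
            "sparrow,2000,2,invertebrate,tree,lowland,false,note",
            "bulbul,2001,12,fleshy fruit,bush,lowland,false,",
        ])
        episodes = read_episodes(p, schema)
        assert len(episodes) == 3
        assert episodes[1].item == "invertebrate"
        assert episodes[2].month == 12

    def test_empty_file_with_header_gives_empty_list(self, tmp_path, schema):
        assert read_episodes(write_csv(tmp_path / "e.csv", []), schema) == []

    def test_unknown_item_rejected_with_row_number(self, tmp_path, schema):
        p = write_csv(tmp_path / "e.csv", [
            "sparrow,1999,1,seed,ground,lowland,false,",
            "sparrow,1999,1,stone,ground,lowland,false,",
        ])
        with pytest.raises(ValidationError, match="row 3.*stone"):
            read_episodes(p, schema)

    def test_missing_column_names_the_column(self, tmp_path, schema):
        p = tmp_path / "e.csv"
        p.write_text("species,year,month,item\n")
        with pytest.raises(SchemaError, match="location"):
            read_episodes(p, schema)

    def test_month_out_of_range_rejected(self, tmp_path, schema):
        p = write_csv(tmp_path / "e.csv", ["sparrow,1999,13,seed,ground,lowland,false,"])
        with pytest.raises(ValidationError, match="month"):
            read_episodes(p, schema)


class TestExpandMultirecord:
    @pytest.mark.parametrize(
        "items, locations, expected",
        [
            (["seed", "invertebrate"], ["ground"],
             [("seed", "ground"), ("invertebrate", "ground")]),
            (["seed"], ["tree"], [("seed", "tree")]),
            (["seed", "flower"], ["tree", "bush"],
             [("seed", "tree"), ("flower", "bush")]),
            (["seed"], ["tree", "bush"], [("seed", "tree"), ("seed", "bush")]),
        ],
    )
    def test_pairings(self, items, locations, expected):
        assert expand_multirecord(items, locations) == expected

    def test_unequal_lists_rejected(self):
        with pytest.raises(ValidationError):
            expand_multirecord(["seed", "flower"], ["tree", "bush", "ground"])

    def test_raw_report_reader_expands(self, tmp_path, schema):
        p = write_csv(tmp_path / "r.csv", [
            "sparrow,1999,1,seed;invertebrate,ground,lowland,false,",
        ])
        episodes = read_raw_reports(p, schema)
        assert [(e.item, e.location) for e in episodes] == [
            ("seed", "ground"), ("invertebrate", "ground")]


class TestApplyFilters:
    def test_feeder_records_dropped(self):
        assert apply_filters([make_episode(feeder_flag=True)]) == []

    def test_highland_records_dropped(self):
        assert apply_filters([make_episode(altitude_band="highland")]) == []

    def test_unidentified_item_with_known_location_retained(self):
        kept = apply_filters([make_episode(item="unidentified", location="ground")])
        assert len(kept) == 1

    def test_doubly_unidentified_dropped(self):
        kept = apply_filters(
            [make_episode(item="unidentified", location="unidentified")])
        assert kept == []

    def test_unidentified_location_with_known_item_retained(self):
        kept = apply_filters([make_episode(item="seed", location="unidentified")])
        assert len(kept) == 1


class TestTally:
    def test_empty_list_gives_zero_tensor(self, schema):
        t = tally([], "sparrow", schema)
        assert t.total == 0
        assert t.counts.shape == (12, 11, 10)

    def test_duplicate_episodes_accumulate(self, schema):
        t = tally([make_episode(), make_episode()], "test bird", schema)
        assert t.counts[0, schema.item_index("seed"),
                        schema.location_index("ground")] == 2

    def test_years_pooled_within_month(self, schema):
        episodes = [make_episode(), make_episode()]
        episodes[1].year = 2005
        t = tally(episodes, "test bird", schema)
        assert t.totals_by_month[0] == 2

    def test_other_species_excluded(self, schema):
        t = tally([make_episode(species="other")], "test bird", schema)
        assert t.total == 0

    def test_conservation_of_retained_episodes(self, synthetic_counts):
        counts, truth = synthetic_counts
        assert counts.total == int(truth.n_episodes_per_month.sum())
        assert (counts.totals_by_month == truth.n_episodes_per_month).all()


episode_strategy = hst.builds(
    make_episode,
    month=hst.integers(1, 12),
    item=hst.sampled_from(CategorySchema.default().diet_items),
    location=hst.sampled_from(CategorySchema.default().locations),
)


@settings(max_examples=25, deadline=None)
@given(hst.lists(episode_strategy, max_size=30), hst.randoms())
def test_tally_invariant_to_row_order(episodes, rand):
    schema = CategorySchema.default()
    before = tally(episodes, "test bird", schema).counts
    rand.shuffle(episodes)
    assert (tally(episodes, "test bird", schema).counts == before).all()


@settings(max_examples=25, deadline=None)
@given(hst.lists(episode_strategy, max_size=30))
def test_write_read_round_trip(tmp_path_factory, episodes):
    path = tmp_path_factory.mktemp("rt") / "episodes.csv"
    write_episodes(path, episodes)
    assert read_episodes(path) == episodes


def test_summary_table_reports_tallies(schema):
    episodes = [make_episode(), make_episode(item="unidentified"),
                make_episode(month=2)]
    table = summary_table(episodes, schema)
    row = table.iloc[0]
    assert row["total_episodes"] == 3
    assert row["identified_episodes"] == 2
    assert row["unidentified_proportion"] == pytest.approx(1 / 3, abs=1e-4)
    assert row["m01"] == 2 and row["m02"] == 1
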