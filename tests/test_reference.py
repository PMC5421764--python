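import json

import pytest

from sobrenome.labels import AncestryLabel
from sobrenome.reference import (
    BuilderConfig,
    BuildLog,
    ReferenceTable,
    SourceRecord,
    apply_min_count_filter,
    build_reference_table,
    load_source_records,
    merge_sources,
    resolve_within_source,
)

from conftest import builder_fixture_config, builder_fixture_sources

IBR, ITA, GER, JPN, EAS = AncestryLabel


def rec(surname, label, source="src", count=1):
    return SourceRecord(surname, label, source, count)


class TestWithinSource:
    cfg = BuilderConfig()

    def test_above_threshold_kept_with_summed_count(self):
        out = resolve_within_source(
            [rec("SMITH", GER, count=95), rec("SMITH", EAS, count=5)], self.cfg
        )
        assert out == [SourceRecord("SMITH", GER, "src", 100)]

    def test_below_threshold_dropped(self):
        out = resolve_within_source(
            [rec("NOWAK", EAS, count=60), rec("NOWAK", GER, count=40)], self.cfg
        )
        assert out == []

    def test_share_exactly_at_threshold_dropped(self):
        # "more than 90%" is strict: 9 of 10 is not enough
        out = resolve_within_source(
            [rec("FONSECA", IBR, count=9), rec("FONSECA", ITA, count=1)], self.cfg
        )
        assert out == []

    def test_unanimous_single_record_kept(self):
        out = resolve_within_source([rec("LIMA", IBR)], self.cfg)
        assert out == [SourceRecord("LIMA", IBR, "src", 1)]

    def test_mixed_sources_rejected(self):
        with pytest.raises(ValueError):
            resolve_within_source(
                [rec("A" , IBR, source="s1"), rec("B", IBR, source="s2")], self.cfg
            )


class TestMinCount:
    cfg = BuilderConfig(min_count_sources={"census": 8})

    @pytest.mark.parametrize("count,kept", [(7, False), (8, True), (100, True)])
    def test_census_boundary(self, count, kept):
        out = apply_min_count_filter(
            [rec("KLEIN", GER, source="census", count=count)], self.cfg
        )
        assert bool(out) is kept

    def test_unconfigured_source_defaults_to_one(self):
        out = apply_min_count_filter([rec("VITALE", ITA, source="lista")], self.cfg)
        assert len(out) == 1


class TestMerge:
    cfg = BuilderConfig(priority_source="museum")

    def test_agreement_merges(self):
        table = merge_sources(
            [[rec("BRAUN", GER, "census", 12)], [rec("BRAUN", GER, "museum", 2)]],
            self.cfg,
        )
        assert table.entries == {"BRAUN": GER}

    def test_priority_source_wins_conflict(self):
        table = merge_sources(
            [[rec("MARTIN", GER, "census", 30)], [rec("MARTIN", IBR, "museum", 5)]],
            self.cfg,
        )
        assert table.entries == {"MARTIN": IBR}
        assert table.provenance["MARTIN"] == "museum"

    def test_larger_count_wins_without_priority(self):
        table = merge_sources(
            [[rec("WAGNER", GER, "census", 10)], [rec("WAGNER", ITA, "lista", 1)]],
            self.cfg,
        )
        assert table.entries == {"WAGNER": GER}

    def test_equal_count_tie_dropped_and_logged(self):
        log = BuildLog()
        table = merge_sources(
            [[rec("BARBOSA", IBR, "lista", 1)], [rec("BARBOSA", ITA, "heraldica", 1)]],
            self.cfg,
            log,
        )
        assert "BARBOSA" not in table.entries
        assert log.dropped[0]["reason"] == "cross_source_tie"


class TestBuilderProperties:
    def test_output_subset_of_input_surnames(self):
        sources = builder_fixture_sources()
        table, _ = build_reference_table(sources, builder_fixture_config())
        input_surnames = {r.surname for recs in sources.values() for r in recs}
        assert set(table.entries) <= input_surnames

    def test_idempotence_on_own_output(self):
        table, _ = build_reference_table(
            builder_fixture_sources(), builder_fixture_config()
        )
        again, _ = build_reference_table(
            {
                "ref": [
                    SourceRecord(s, label, "ref", 1)
                    for s, label in table.entries.items()
                ]
            },
            BuilderConfig(),
        )
        assert again.entries == table.entries

    def test_raising_threshold_never_retains_more(self):
        sources = builder_fixture_sources()
        sizes = []
        for threshold in (0.6, 0.75, 0.90, 0.99):
            cfg = BuilderConfig(
                agreement_threshold=threshold,
                min_count_sources={"census": 8},
                priority_source="museum",
            )
            table, _ = build_reference_table(sources, cfg)
            sizes.append(len(table))
        assert sizes == sorted(sizes, reverse=True)


class TestLoading:
    def test_parse_normalizes_and_maps_alias(self, tmp_path):
        path = tmp_path / "src.csv"
        path.write_text("surname,ancestry,count\nRossi,Italian,3\nMüller,GER,2\n")
        records = load_source_records(path, "s1", alias={"Italian": "ITA"})
        assert records == [
            SourceRecord("ROSSI", ITA, "s1", 3),
            SourceRecord("MULLER", GER, "s1", 2),
        ]

    def test_unmapped_ancestry_dropped_and_counted(self, tmp_path):
        path = tmp_path / "src.csv"
        path.write_text("surname,ancestry\nROSSI,ITA\nSMITH,Others\n")
        log = BuildLog()
        records = load_source_records(path, "s1", log=log)
        assert len(records) == 1 and log.unmapped_rows == 1

    def test_all_rows_unparseable_raises(self, tmp_path):
        path = tmp_path / "src.csv"
        path.write_text("surname,ancestry\nSMITH,Others\n")
        with pytest.raises(ValueError, match="no parseable rows"):
            load_source_records(path, "s1")

    def test_missing_file_and_columns(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_source_records(tmp_path / "absent.csv", "s1")
        path = tmp_path / "bad.csv"
        path.write_text("name,label\nROSSI,ITA\n")
        with pytest.raises(ValueError, match="missing mandatory columns"):
            load_source_records(path, "s1")

    def test_count_defaults_to_one_per_row(self, tmp_path):
        path = tmp_path / "src.csv"
        path.write_text("surname,ancestry\nGOMES,IBR\n")
        assert load_source_records(path, "s1")[0].count == 1


def test_table_csv_round_trip(tmp_path):
    table, log = build_reference_table(
        builder_fixture_sources(), builder_fixture_config()
    )
    path = tmp_path / "ref.csv"
    table.to_csv(path)
    log_path = tmp_path / "ref.log.json"
    log.to_json(log_path)
    loaded = ReferenceTable.from_csv(path)
    assert loaded.entries == table.entries
    assert loaded.provenance == table.provenance
    parsed = json.loads(log_path.read_text())
    assert parsed["n_dropped"] == len(log.dropped)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        BuilderConfig(agreement_threshold=0.4)
    with pytest.raises(ValueError):
        BuilderConfig(min_count_sources={"census": 0})
    with pytest.raises(ValueError):
        AncestryLabel.parse("XXX")
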