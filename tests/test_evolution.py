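from datetime import datetime, timedelta, timezone

import pytest

from modelevo.evolution import (
    ModelHistory,
    VersionRecord,
    build_diffstats,
    build_filestats,
    build_repo_evolution,
    default_date_grid,
    load_corpus,
    summarize,
)
from modelevo.model_io import count_entities, parse_model
from modelevo.synthetic import write_corpus

UTC = timezone.utc


@pytest.fixture(scope="module")
def corpus(tmp_path_factory):
    root = tmp_path_factory.mktemp("corpus")
    write_corpus(root, n_models=6, n_versions=4, rng_seed=11)
    return root


@pytest.fixture(scope="module")
def histories(corpus):
    return load_corpus(corpus)


class TestLoadCorpus:
    def test_models_and_versions(self, histories):
        assert len(histories) == 6
        assert all(len(h.versions) == 4 for h in histories)
        repos = {h.repository for h in histories}
        assert repos == {"biomodels-like", "pmr-like"}

    def test_timestamps_ordered(self, histories):
        for h in histories:
            ts = [v.timestamp for v in h.versions]
            assert ts == sorted(ts)

    def test_invalid_timestamps_rejected(self):
        t = datetime(2010, 1, 1, tzinfo=UTC)
        with pytest.raises(ValueError):
            ModelHistory("m", "other", [
                VersionRecord("m", "v1", t, None),
                VersionRecord("m", "v2", t - timedelta(days=1), None),
            ])

    def test_duplicate_version_ids_rejected(self):
        t = datetime(2010, 1, 1, tzinfo=UTC)
        with pytest.raises(ValueError):
            ModelHistory("m", "other", [
                VersionRecord("m", "v1", t, None),
                VersionRecord("m", "v1", t, None),
            ])


class TestFilestats:
    def test_row_per_version(self, histories):
        table, exclusions = build_filestats(histories)
        assert len(table) == sum(len(h.versions) for h in histories) == 24
        assert exclusions == []

    def test_counts_match_per_file_oracle(self, histories):
        table, _ = build_filestats(histories)
        h = histories[0]
        rec = h.versions[0]
        doc = parse_model(rec.path.read_bytes(), model_id=h.model_id,
                          version_id=rec.version_id)
        expected = count_entities(doc)
        row = table[(table["model_id"] == h.model_id)
                    & (table["version_id"] == rec.version_id)].iloc[0]
        for f in expected.COUNT_FIELDS:
            assert row[f] == getattr(expected, f)

    def test_empty_histories(self):
        table, exclusions = build_filestats([])
        assert len(table) == 0
        assert "nodes" in table.columns

    def test_unparseable_version_skipped(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml not well formed")
        h = ModelHistory("m", "other", [
            VersionRecord("m", "v1", datetime(2010, 1, 1, tzinfo=UTC), bad)])
        table, exclusions = build_filestats([h])
        assert len(table) == 0
        assert len(exclusions) == 1
        assert exclusions[0]["model_id"] == "m"


class TestDiffstats:
    def test_single_version_no_rows(self, histories):
        h = histories[0]
        solo = ModelHistory(h.model_id, h.repository, h.versions[:1])
        table, _ = build_diffstats([solo])
        assert len(table) == 0

    def test_row_count(self, histories):
        table, _ = build_diffstats(histories)
        assert len(table) == sum(len(h.versions) - 1 for h in histories) == 18

    def test_linkage_to_filestats(self, histories):
        files, _ = build_filestats(histories)
        diffs, _ = build_diffstats(histories)
        known = set(zip(files["model_id"], files["version_id"]))
        for _, row in diffs.iterrows():
            assert (row["model_id"], row["version_from"]) in known
            assert (row["model_id"], row["version_to"]) in known

    def test_identical_versions_zero_row_not_dropped(self, tmp_path):
        # a re-release without changes is still a recorded transition
        src = None
        for i, vid in enumerate(["v1", "v2"]):
            d = tmp_path / f"00{i}_{vid}"
            d.mkdir()
            text = ('<sbml xmlns="http://www.sbml.org/sbml/level2/version4">'
                    "<model id='m'/></sbml>")
            (d / "model.xml").write_text(text)
        h = ModelHistory("m", "other", [
            VersionRecord("m", "v1", datetime(2010, 1, 1, tzinfo=UTC),
                          tmp_path / "000_v1" / "model.xml"),
            VersionRecord("m", "v2", datetime(2010, 2, 1, tzinfo=UTC),
                          tmp_path / "001_v2" / "model.xml"),
        ])
        table, _ = build_diffstats([h])
        assert len(table) == 1
        row = table.iloc[0]
        for col in ("line_inserts", "line_deletes", "bives_inserts",
                    "bives_deletes", "bives_updates", "bives_moves",
                    "triggered_count"):
            assert row[col] == 0

    def test_column_sums_equal_delta_summaries(self, histories):
        table, deltas = build_diffstats(histories, keep_deltas=True)
        assert table["bives_inserts"].sum() == sum(d.summary["insert"] for d in deltas)
        assert table["bives_deletes"].sum() == sum(d.summary["delete"] for d in deltas)
        assert table["bives_updates"].sum() == sum(d.summary["update"] for d in deltas)
        assert table["bives_moves"].sum() == sum(d.summary["move"] for d in deltas)
        assert table["triggered_count"].sum() == sum(d.summary["triggered"] for d in deltas)


class TestRepoEvolution:
    def test_before_all_timestamps_zero(self, histories):
        early = datetime(1999, 1, 1, tzinfo=UTC)
        table = build_repo_evolution(histories, [early])
        assert (table["models"] == 0).all()

    def test_model_appearance_order(self, tmp_path):
        text = ('<sbml xmlns="http://www.sbml.org/sbml/level2/version4">'
                "<model id='m'/></sbml>")
        f = tmp_path / "m.xml"
        f.write_text(text)
        t1 = datetime(2010, 1, 1, tzinfo=UTC)
        t2 = datetime(2011, 1, 1, tzinfo=UTC)
        hs = [
            ModelHistory("m1", "repoA", [VersionRecord("m1", "v1", t1, f)]),
            ModelHistory("m2", "repoA", [VersionRecord("m2", "v1", t2, f)]),
        ]
        table = build_repo_evolution(hs, [t1, t2])
        repoA = table[table["repository"] == "repoA"]
        assert list(repoA["models"]) == [1, 2]

    def test_combined_equals_sum(self, histories):
        grid = default_date_grid(histories)
        table = build_repo_evolution(histories, grid)
        for date, grp in table.groupby("date"):
            combined = grp[grp["repository"] == "combined"]
            parts = grp[grp["repository"] != "combined"]
            for col in table.columns[2:]:
                assert combined[col].sum() == parts[col].sum()

    def test_monotone_model_counts(self, histories):
        grid = default_date_grid(histories)
        table = build_repo_evolution(histories, grid)
        for repo, grp in table.groupby("repository"):
            counts = list(grp.sort_values("date")["models"])
            assert counts == sorted(counts)

    def test_unsorted_grid_rejected(self, histories):
        t = datetime(2010, 1, 1, tzinfo=UTC)
        with pytest.raises(ValueError):
            build_repo_evolution(histories, [t, t - timedelta(days=1)])


class TestSummarize:
    def test_single_model_mean_ops(self, histories):
        diffs, _ = build_diffstats(histories[:1])
        files, _ = build_filestats(histories[:1])
        s = summarize(diffs, files, histories[:1])
        total = (diffs["bives_inserts"] + diffs["bives_deletes"]
                 + diffs["bives_updates"] + diffs["bives_moves"])
        assert s["mean_ops_per_transition"] == pytest.approx(total.mean())

    def test_window_count(self, tmp_path):
        text = ('<sbml xmlns="http://www.sbml.org/sbml/level2/version4">'
                "<model id='m'/></sbml>")
        f = tmp_path / "m.xml"
        f.write_text(text)
        t0 = datetime(2010, 1, 1, tzinfo=UTC)
        versions = [
            VersionRecord("m", f"v{i}", t0 + timedelta(days=400 * i), f)
            for i in range(6)
        ]  # versions at 0, 400, ..., 2000 days; 5y window keeps first 5
        h = ModelHistory("m", "other", versions)
        files, _ = build_filestats([h])
        diffs, _ = build_diffstats([h])
        s = summarize(diffs, files, [h])
        assert s["mean_versions_per_model_window"] == 5

    def test_empty_diffstats_absent_not_zero(self):
        import pandas as pd
        from modelevo.evolution import DIFFSTATS_COLUMNS, FILESTATS_COLUMNS
        s = summarize(pd.DataFrame(columns=DIFFSTATS_COLUMNS),
                      pd.DataFrame(columns=FILESTATS_COLUMNS))
        assert "mean_ops_per_transition" not in s
        assert "mean_nodes_latest_by_format" not in s

    def test_release_matrix_shape(self, histories):
        diffs, _ = build_diffstats(histories)
        files, _ = build_filestats(histories)
        s = summarize(diffs, files, histories)
        matrix = s["release_change_matrix"]
        assert matrix.to_numpy().sum() == (
            diffs["bives_inserts"] + diffs["bives_deletes"]
            + diffs["bives_updates"] + diffs["bives_moves"]).sum()

    def test_triggered_toggle(self, histories):
        diffs, _ = build_diffstats(histories)
        files, _ = build_filestats(histories)
        with_t = summarize(diffs, files)["mean_ops_per_transition"]
        without_t = summarize(diffs, files, include_triggered=False)[
            "mean_ops_per_transition"]
        assert without_t <= with_t
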