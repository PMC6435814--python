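import pytest

from curated_blast.query import Query
from curated_blast.report import (
    SearchReport,
    read_report_json,
    run_pipeline,
    write_report,
    write_report_json,
    write_report_tsv,
)


def all_hits(report):
    return ([h for g in report.protein_groups for h in g.hits]
            + [h for g in report.frame_groups for h in g.hits])


class TestPipeline:
    def test_annotated_plant_found_at_full_identity(self, planted,
                                                    planted_report):
        sid = planted["seq_ids"]["annotated"]
        (group,) = [g for g in planted_report.protein_groups
                    if g.target_id == "pred_annotated"]
        top = group.hits[0]
        assert top.curated_seq_id == sid
        assert top.identity_frac == 1.0
        assert top.coverage_frac == 1.0

    def test_annotated_plant_has_no_sixframe_lines(self, planted,
                                                   planted_report):
        """A gene already in the proteome cannot beat 1.1x its own score."""
        sid = planted["seq_ids"]["annotated"]
        assert not [h for g in planted_report.frame_groups for h in g.hits
                    if h.curated_seq_id == sid]

    def test_unannotated_plant_found_only_in_sixframe(self, planted,
                                                      planted_report):
        sid = planted["seq_ids"]["unannotated"]
        protein_hits = [h for g in planted_report.protein_groups
                        for h in g.hits if h.curated_seq_id == sid]
        frame_hits = [h for g in planted_report.frame_groups
                      for h in g.hits if h.curated_seq_id == sid]
        # the gene is absent from the proteome, so at most weak chance
        # similarity to the decoy proteins can appear at the protein stage
        assert all(h.score < 0.2 for h in protein_hits)
        assert frame_hits, "recovered by the six-frame stage"
        assert max(h.coverage_frac for h in frame_hits) >= 0.95

    def test_absent_plant_never_hit(self, planted, planted_report):
        sid = planted["seq_ids"]["missing"]
        assert not [h for h in all_hits(planted_report)
                    if h.curated_seq_id == sid]

    def test_every_hit_references_a_matched_sequence(self, planted_report):
        matched = set(planted_report.curated_descriptions)
        assert {h.curated_seq_id for h in all_hits(planted_report)} <= matched

    def test_zero_match_query_gives_valid_empty_report(self, planted):
        report = run_pipeline(planted["db"], planted["genome"].proteome,
                              Query("unmatchable-query-text"),
                              genome=planted["genome"].contigs)
        assert report.n_curated_matched == 0
        assert report.protein_groups == []
        assert report.frame_groups == []
        assert report.sixframe_skipped_reason

    def test_sixframe_skipped_without_genome(self, planted):
        report = run_pipeline(planted["db"], planted["genome"].proteome,
                              Query("planted protein"))
        assert report.frame_groups == []
        assert "no nucleotide genome" in report.sixframe_skipped_reason


class TestWriters:
    def test_json_roundtrip_is_lossless(self, planted_report, tmp_path):
        path = tmp_path / "r.json"
        write_report_json(planted_report, path)
        back = read_report_json(path)
        assert back == planted_report

    def test_tsv_one_row_per_hit(self, planted_report, tmp_path):
        path = tmp_path / "r.tsv"
        write_report_tsv(planted_report, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) - 1 == len(all_hits(planted_report))

    def test_empty_report_is_header_only(self, planted, tmp_path):
        report = run_pipeline(planted["db"], planted["genome"].proteome,
                              Query("unmatchable-query-text"))
        path = tmp_path / "empty.tsv"
        write_report_tsv(report, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("stage\t")

    def test_tsv_marks_hidden_rows(self, tmp_path):
        from curated_blast.ranking import rank_protein_hits
        from test_ranking import hit
        groups = rank_protein_hits(
            [hit(f"c{i}", "P1", 0.9 - 0.1 * i) for i in range(5)])
        report = SearchReport(
            query_text="q", word_mode=False, n_curated_matched=5,
            protein_groups=groups, frame_groups=[],
            sixframe_skipped_reason="no nucleotide genome provided",
            curated_descriptions={f"c{i}": ["d"] for i in range(5)})
        path = tmp_path / "r.tsv"
        write_report_tsv(report, path)
        flags = [l.split("\t")[-1] for l in
                 path.read_text().strip().splitlines()[1:]]
        assert flags == ["shown"] * 3 + ["hidden"] * 2

    def test_percentages_rendered_as_integers(self, tmp_path):
        from test_ranking import hit as mkhit
        h = mkhit("c1", "P1", 0.43)
        report = SearchReport(
            query_text="q", word_mode=False, n_curated_matched=1,
            protein_groups=[], frame_groups=[],
            sixframe_skipped_reason=None,
            curated_descriptions={"c1": ["some reductase"]})
        from curated_blast.ranking import rank_protein_hits
        report.protein_groups = rank_protein_hits([h])
        tsv = tmp_path / "r.tsv"
        write_report_tsv(report, tsv)
        row = tsv.read_text().splitlines()[1].split("\t")
        assert row[6] == "43" and row[7] == "100"
        html = tmp_path / "r.html"
        write_report(report, "html", html)
        assert "43% id., 100% cov" in html.read_text()

    def test_byte_identical_across_runs(self, planted, tmp_path):
        for name in ("one", "two"):
            report = run_pipeline(
                planted["db"], planted["genome"].proteome,
                Query("planted protein"), genome=planted["genome"].contigs)
            write_report_tsv(report, tmp_path / f"{name}.tsv")
            write_report_json(report, tmp_path / f"{name}.json")
        assert (tmp_path / "one.tsv").read_bytes() == \
            (tmp_path / "two.tsv").read_bytes()
        assert (tmp_path / "one.json").read_bytes() == \
            (tmp_path / "two.json").read_bytes()

    def test_unknown_format_rejected(self, planted_report, tmp_path):
        with pytest.raises(ValueError):
            write_report(planted_report, "xlsx", tmp_path / "r.xlsx")


class TestCli:
    def test_end_to_end_via_cli(self, tmp_path):
        from click.testing import CliRunner

        from curated_blast.cli import main

        runner = CliRunner()
        fixdir = tmp_path / "fix"
        r = runner.invoke(main, ["fixtures", "--kind", "genome",
                                 "--outdir", str(fixdir), "--seed", "3"])
        assert r.exit_code == 0, r.output
        out = tmp_path / "res"
        r = runner.invoke(main, [
            "search", "--db", str(fixdir / "curated.db.json"),
            "--proteins", str(fixdir / "proteins.faa"),
            "--genome", str(fixdir / "genome.fna"),
            "--query", "synthetic planted protein",
            "--out", str(out), "--format", "tsv,json,html", "--quiet"])
        assert r.exit_code == 0, r.output
        report = read_report_json(f"{out}.json")
        assert report.n_curated_matched == 3
        assert report.protein_groups and report.frame_groups
        assert (tmp_path / "res.tsv").exists()
        assert (tmp_path / "res.html").exists()

    def test_build_db_and_list_matches(self, tmp_path, curated_fixture):
        from click.testing import CliRunner

        from curated_blast.cli import main
        from curated_blast.fixtures import write_curated_fixture

        runner = CliRunner()
        fixdir = tmp_path / "cur"
        write_curated_fixture(curated_fixture, fixdir)
        dbpath = tmp_path / "db.json"
        r = runner.invoke(main, [
            "build-db", "--entries", str(fixdir / "entries.tsv"),
            "--sequences", str(fixdir / "sequences.faa"),
            "--out", str(dbpath), "--stats", str(tmp_path / "stats.tsv")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, [
            "search", "--db", str(dbpath),
            "--proteins", str(fixdir / "sequences.faa"),
            "--query", "histidinol dehydrogenase", "--list-matches"])
        assert r.exit_code == 0, r.output
        assert "histidinol dehydrogenase" in r.output
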