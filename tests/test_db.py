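import dataclasses

import pytest

from curated_blast.db import (
    CuratedEntry,
    apply_source_filters,
    build_database,
    deduplicate_sequences,
    load_database,
    save_database,
    sequence_digest,
    write_build_stats,
)
from curated_blast.errors import DatabaseLoadError, UnknownSourceError


def entry(**kw):
    base = dict(
        entry_id="e1", source="EcoCyc", description="beta-galactosidase",
        publication_ids=["PMID:1"], uniprot_id="P00001",
        sequence_id="s1",
    )
    base.update(kw)
    return CuratedEntry(**base)


@pytest.mark.parametrize("e,retained", [
    # BRENDA/MetaCyc need a UniProt id and >=1 publication, no fragments
    (entry(source="BRENDA", uniprot_id=None, publication_ids=["a", "b"]), False),
    (entry(source="BRENDA", publication_ids=[]), False),
    (entry(source="BRENDA", is_fragment=True), False),
    (entry(source="BRENDA"), True),
    (entry(source="MetaCyc", uniprot_id=None), False),
    (entry(source="MetaCyc"), True),
    # CAZy needs an EC; 'fragment'/'frameshift' in the description excludes
    (entry(source="CAZy", ec_numbers=["3.2.1.4"],
           description="endoglucanase"), True),
    (entry(source="CAZy", ec_numbers=["3.2.1.4"],
           description="putative endoglucanase fragment"), False),
    (entry(source="CAZy", ec_numbers=["3.2.1.4"],
           description="endoglucanase Frameshift variant"), False),
    (entry(source="CAZy", ec_numbers=[]), False),
    # CharProtDB drops trusted_uniprot and trusted_aspgd record types
    (entry(source="CharProtDB", entry_type="trusted_uniprot"), False),
    (entry(source="CharProtDB", entry_type="trusted_aspgd"), False),
    (entry(source="CharProtDB", entry_type="trusted"), True),
    # REBASE kept only when sequence specificity is known
    (entry(source="REBASE", specificity_known=False), False),
    (entry(source="REBASE", specificity_known=True), True),
    # Swiss-Prot kept only with experimental evidence
    (entry(source="SwissProt", has_experimental_evidence=False), False),
    (entry(source="SwissProt", has_experimental_evidence=True), True),
    # EcoCyc / Fitness Browser pass; fragment exclusion does not apply
    (entry(source="EcoCyc", is_fragment=True, uniprot_id=None,
           publication_ids=[]), True),
    (entry(source="FitnessBrowser", is_fragment=True), True),
])
def test_source_retention_rules(e, retained):
    assert (apply_source_filters([e]) == [e]) is retained


def test_empty_input_and_order_preserved():
    assert apply_source_filters([]) == []
    kept = [entry(entry_id=f"e{i}") for i in range(5)]
    dropped = entry(source="REBASE", specificity_known=False)
    mixed = kept[:2] + [dropped] + kept[2:]
    assert apply_source_filters(mixed) == kept


def test_filter_is_idempotent(curated_fixture):
    once = apply_source_filters(curated_fixture.entries)
    assert apply_source_filters(once) == once


def test_unknown_source_rejected():
    with pytest.raises(UnknownSourceError):
        apply_source_filters([entry(source="PDB")])
    with pytest.raises(UnknownSourceError):
        apply_source_filters([entry()], source="PDB")
    with pytest.raises(UnknownSourceError):
        apply_source_filters([entry(source="BRENDA")], source="EcoCyc")


def test_dedup_merges_identical_sequences():
    entries = [entry(entry_id=f"e{i}", sequence_id=f"s{i}") for i in range(4)]
    lookup = {"s0": "MKVA", "s1": "MPLV", "s2": "MKVA", "s3": "MWWA"}
    db = deduplicate_sequences(entries, lookup)
    assert db.n_distinct == 3
    shared = db.sequences[sequence_digest("MKVA")]
    assert sorted(e.entry_id for e in shared.entries) == ["e0", "e2"]


def test_dedup_normalizes_case_and_trailing_stop():
    entries = [entry(entry_id="a", sequence_id="s1"),
               entry(entry_id="b", sequence_id="s2")]
    db = deduplicate_sequences(entries, {"s1": "MKV*", "s2": "mkv"})
    assert db.n_distinct == 1
    assert next(iter(db.sequences.values())).sequence == "MKV"


def test_dedup_rejects_internal_stop_and_missing_sequence():
    entries = [entry(entry_id="a", sequence_id="s1"),
               entry(entry_id="b", sequence_id="s2"),
               entry(entry_id="c", sequence_id="gone")]
    db = deduplicate_sequences(entries, {"s1": "MK*V", "s2": "MAAG"})
    assert db.n_distinct == 1
    assert db.build_metadata["n_dropped_unresolved"] == 2


def test_dedup_empty_input():
    db = deduplicate_sequences([], {})
    assert db.n_entries == db.n_distinct == 0
    assert db.per_source_counts == {}


def test_dedup_is_order_independent(curated_fixture):
    import random
    entries = apply_source_filters(curated_fixture.entries)
    db1 = deduplicate_sequences(entries, curated_fixture.sequences)
    shuffled = entries[:]
    random.Random(3).shuffle(shuffled)
    db2 = deduplicate_sequences(shuffled, curated_fixture.sequences)
    assert db1.sequences.keys() == db2.sequences.keys()
    for k in db1.sequences:
        assert db1.sequences[k] == db2.sequences[k]
    assert db1.per_source_counts == db2.per_source_counts


def test_distinct_never_exceeds_entries(curated_db):
    assert curated_db.n_distinct <= curated_db.n_entries
    for n_e, n_d in curated_db.per_source_counts.values():
        assert n_d <= n_e


def test_roundtrip_identity(curated_db, tmp_path):
    path = tmp_path / "db.json"
    save_database(curated_db, path)
    loaded = load_database(path)
    assert loaded.sequences == curated_db.sequences
    assert loaded.per_source_counts == curated_db.per_source_counts
    assert loaded.build_metadata == curated_db.build_metadata


def test_load_errors(tmp_path):
    with pytest.raises(DatabaseLoadError):
        load_database(tmp_path / "nope.json")
    bad = tmp_path / "bad.json"
    bad.write_text("{ not json")
    with pytest.raises(DatabaseLoadError):
        load_database(bad)
    partial = tmp_path / "partial.json"
    partial.write_text('{"format": "curated-blast-db/1", "sequences": []}')
    with pytest.raises(DatabaseLoadError):
        load_database(partial)


def test_build_stats_table(curated_db, tmp_path):
    path = tmp_path / "stats.tsv"
    write_build_stats(curated_db, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "source\tn_entries\tn_distinct"
    total = lines[-1].split("\t")
    assert total[0] == "Total"
    assert int(total[1]) == curated_db.n_entries
    assert int(total[2]) == curated_db.n_distinct
    per_source_sum = sum(int(l.split("\t")[1]) for l in lines[1:-1])
    assert per_source_sum == curated_db.n_entries
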