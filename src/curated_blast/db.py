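"""Curated-protein database: ingestion filters, deduplication, persistence.

The database collects proteins whose functions were experimentally
characterized, together with human-written descriptions of those functions,
drawn from eight curated source databases (BRENDA, CAZy, CharProtDB, EcoCyc,
MetaCyc, REBASE, Swiss-Prot, Fitness Browser). Each source has its own
retention rule — e.g. BRENDA and MetaCyc entries are kept only when they
carry a UniProt identifier and at least one publication — so that what
remains is, as far as the curation allows, experimentally supported.

Input is a normalized per-source table plus a protein FASTA; parsing the
native distribution formats of the eight sources is out of scope. Entries
sharing an identical amino-acid sequence are merged into one
:class:`CuratedSequence`, the unit that is later aligned; this is the
"distinct sequences" notion, distinct from the (larger) entry count.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from curated_blast.errors import (
    DatabaseLoadError,
    InvalidSequenceError,
    UnknownSourceError,
)

logger = logging.getLogger(__name__)

#: Recognized source database tags.
SOURCES = (
    "BRENDA",
    "CAZy",
    "CharProtDB",
    "EcoCyc",
    "MetaCyc",
    "REBASE",
    "SwissProt",
    "FitnessBrowser",
    "other",
)

_AA_ALLOWED = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@dataclass
class CuratedEntry:
    """One curated record from one source database."""

    entry_id: str
    source: str
    description: str
    organism: str = ""
    ec_numbers: list[str] = field(default_factory=list)
    publication_ids: list[str] = field(default_factory=list)
    uniprot_id: str | None = None
    entry_type: str | None = None
    is_fragment: bool = False
    specificity_known: bool = True
    has_experimental_evidence: bool = True
    sequence_id: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CuratedEntry":
        return cls(**dict(d))


@dataclass
class CuratedSequence:
    """A distinct amino-acid sequence plus every entry that shares it.

    This is the unit that is aligned against the genome: several curated
    entries (possibly from different source databases) may describe the same
    protein sequence.
    """

    seq_id: str
    sequence: str
    entries: list[CuratedEntry] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_dict(self) -> dict:
        return {
            "seq_id": self.seq_id,
            "sequence": self.sequence,
            "entries": [e.to_dict() for e in self.entries],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CuratedSequence":
        return cls(
            seq_id=d["seq_id"],
            sequence=d["sequence"],
            entries=[CuratedEntry.from_dict(e) for e in d["entries"]],
        )


@dataclass
class CuratedDatabase:
    """Deduplicated collection of curated sequences with per-source counts."""

    sequences: dict[str, CuratedSequence] = field(default_factory=dict)
    #: source -> (n_entries, n_distinct_sequences_with_an_entry_from_source)
    per_source_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    build_metadata: dict = field(default_factory=dict)

    @property
    def n_entries(self) -> int:
        return sum(len(s.entries) for s in self.sequences.values())

    @property
    def n_distinct(self) -> int:
        return len(self.sequences)

    def iter_sequences(self) -> Iterable[CuratedSequence]:
        """Sequences in deterministic (seq_id) order."""
        return (self.sequences[k] for k in sorted(self.sequences))


def sequence_digest(sequence: str) -> str:
    """Deterministic sequence identifier: sha1 of the normalized residues."""
    return "cseq_" + hashlib.sha1(sequence.encode("ascii")).hexdigest()[:16]


def normalize_sequence(raw: str) -> str:
    """Uppercase, strip one trailing '*'; reject internal stops / bad chars.

    Curated proteins must be stop-free: an internal '*' indicates a
    mistranslated or fragmentary record and the entry is rejected.
    """
    seq = raw.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise InvalidSequenceError("empty sequence after normalization")
    bad = set(seq) - _AA_ALLOWED
    if bad:
        raise InvalidSequenceError(
            f"invalid residue(s) {sorted(bad)} in sequence"
        )
    return seq


def _passes_source_rule(entry: CuratedEntry) -> bool:
    """Retention rule for one entry, dispatched on its source.

    BRENDA, MetaCyc : UniProt id present and >=1 publication; no fragments.
    CAZy            : >=1 EC number; description must not mention
                      "frameshift" or "fragment".
    CharProtDB      : entry types trusted_uniprot (redundant with Swiss-Prot)
                      and trusted_aspgd (vague) are dropped.
    REBASE          : kept only when the enzyme's sequence specificity is known.
    Swiss-Prot      : kept only with experimental evidence for the function.
    EcoCyc, Fitness Browser, other: pass unchanged (already curated by
    construction; the fragment exclusion does not apply to them).
    """
    src = entry.source
    if src in ("BRENDA", "MetaCyc"):
        return (
            bool(entry.uniprot_id)
            and len(entry.publication_ids) >= 1
            and not entry.is_fragment
        )
    if src == "CAZy":
        desc = entry.description.lower()
        return (
            len(entry.ec_numbers) >= 1
            and "frameshift" not in desc
            and "fragment" not in desc
        )
    if src == "CharProtDB":
        return entry.entry_type not in ("trusted_uniprot", "trusted_aspgd")
    if src == "REBASE":
        return entry.specificity_known
    if src == "SwissProt":
        return entry.has_experimental_evidence
    if src in ("EcoCyc", "FitnessBrowser", "other"):
        return True
    raise UnknownSourceError(f"unknown source tag {src!r}")


def apply_source_filters(
    raw_entries: Sequence[CuratedEntry],
    source: str | None = None,
) -> list[CuratedEntry]:
    """Return exactly the entries passing their source's retention rule.

    Order is preserved and the operation is idempotent. If ``source`` is
    given, every record must carry that tag. A record whose source tag is
    unrecognized raises :class:`UnknownSourceError`; a record missing a field
    its rule needs is dropped with a log message.
    """
    if source is not None and source not in SOURCES:
        raise UnknownSourceError(f"unknown source tag {source!r}")
    retained: list[CuratedEntry] = []
    for entry in raw_entries:
        if source is not None and entry.source != source:
            raise UnknownSourceError(
                f"entry {entry.entry_id!r} tagged {entry.source!r}, "
                f"expected {source!r}"
            )
        try:
            keep = _passes_source_rule(entry)
        except UnknownSourceError:
            raise
        except (TypeError, AttributeError) as exc:
            logger.warning(
                "entry %s (%s) missing a field needed by its source rule: %s",
                entry.entry_id, entry.source, exc,
            )
            continue
        if keep:
            retained.append(entry)
    return retained


def deduplicate_sequences(
    retained_entries: Sequence[CuratedEntry],
    sequence_lookup: Mapping[str, str],
) -> CuratedDatabase:
    """Merge entries sharing an identical normalized sequence.

    ``sequence_lookup`` maps each entry's ``sequence_id`` to its raw
    amino-acid string. Sequences are normalized (uppercased, one trailing
    '*' stripped); entries whose sequence is missing or invalid are dropped,
    with the drop count recorded in ``build_metadata``. Sequence identifiers
    are content digests, so the result is independent of input order.
    """
    by_seq: dict[str, CuratedSequence] = {}
    n_dropped = 0
    for entry in retained_entries:
        raw = sequence_lookup.get(entry.sequence_id)
        if raw is None:
            logger.warning("entry %s: sequence %r not found; dropped",
                           entry.entry_id, entry.sequence_id)
            n_dropped += 1
            continue
        try:
            seq = normalize_sequence(raw)
        except InvalidSequenceError as exc:
            logger.warning("entry %s: %s; dropped", entry.entry_id, exc)
            n_dropped += 1
            continue
        sid = sequence_digest(seq)
        rec = by_seq.get(sid)
        if rec is None:
            rec = CuratedSequence(seq_id=sid, sequence=seq)
            by_seq[sid] = rec
        entry = CuratedEntry(**{**entry.to_dict(), "sequence_id": sid})
        rec.entries.append(entry)

    # canonical entry order inside each sequence, for order-independence
    for rec in by_seq.values():
        rec.entries.sort(key=lambda e: (e.source, e.entry_id))

    per_source: dict[str, tuple[int, int]] = {}
    for src in SOURCES:
        n_ent = sum(
            sum(1 for e in rec.entries if e.source == src)
            for rec in by_seq.values()
        )
        n_dis = sum(
            1 for rec in by_seq.values()
            if any(e.source == src for e in rec.entries)
        )
        if n_ent:
            per_source[src] = (n_ent, n_dis)

    return CuratedDatabase(
        sequences=by_seq,
        per_source_counts=per_source,
        build_metadata={
            "built_unix_time": int(time.time()),
            "n_input_entries": len(retained_entries),
            "n_dropped_unresolved": n_dropped,
        },
    )


def build_database(
    raw_entries: Sequence[CuratedEntry],
    sequence_lookup: Mapping[str, str],
) -> CuratedDatabase:
    """Filter entries by their source rules, then deduplicate sequences."""
    return deduplicate_sequences(apply_source_filters(raw_entries), sequence_lookup)


# ---------------------------------------------------------------------------
# normalized input readers

_TSV_COLUMNS = [
    "entry_id", "source", "description", "organism", "ec_numbers",
    "publication_ids", "uniprot_id", "entry_type", "is_fragment",
    "specificity_known", "has_experimental_evidence", "sequence_id",
]


def _parse_bool(v: str) -> bool:
    return v.strip().lower() in ("1", "true", "yes")


def read_entries_tsv(path: str | Path) -> list[CuratedEntry]:
    """Read a normalized per-source entries table (see module docstring).

    Columns: entry_id, source, description, organism, ec_numbers
    (semicolon-joined), publication_ids (semicolon-joined), uniprot_id,
    entry_type, is_fragment, specificity_known, has_experimental_evidence,
    sequence_id.
    """
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DatabaseLoadError(
                f"{path}: missing columns {sorted(missing)}"
            )
        for row in reader:
            entries.append(CuratedEntry(
                entry_id=row["entry_id"],
                source=row["source"],
                description=row["description"],
                organism=row["organism"],
                ec_numbers=[x for x in row["ec_numbers"].split(";") if x],
                publication_ids=[x for x in row["publication_ids"].split(";") if x],
                uniprot_id=row["uniprot_id"] or None,
                entry_type=row["entry_type"] or None,
                is_fragment=_parse_bool(row["is_fragment"]),
                specificity_known=_parse_bool(row["specificity_known"]),
                has_experimental_evidence=_parse_bool(row["has_experimental_evidence"]),
                sequence_id=row["sequence_id"],
            ))
    return entries


def read_sequences_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA keyed by sequence_id (the first header token)."""
    lookup: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        lookup[rec.id] = str(rec.seq)
    return lookup


# ---------------------------------------------------------------------------
# persistence: a single documented JSON file

_DB_FORMAT = "curated-blast-db/1"


def save_database(db: CuratedDatabase, path: str | Path) -> None:
    """Write the database to ``path`` as a single JSON document."""
    doc = {
        "format": _DB_FORMAT,
        "per_source_counts": {k: list(v) for k, v in db.per_source_counts.items()},
        "build_metadata": db.build_metadata,
        "sequences": [db.sequences[k].to_dict() for k in sorted(db.sequences)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_database(path: str | Path) -> CuratedDatabase:
    """Load a database saved by :func:`save_database`.

    A corrupt or partial file raises :class:`DatabaseLoadError`; a partial
    database is never returned silently.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except FileNotFoundError as exc:
        raise DatabaseLoadError(f"no database at {path}") from exc
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise DatabaseLoadError(f"corrupt database file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != _DB_FORMAT:
        raise DatabaseLoadError(f"{path}: not a {_DB_FORMAT} file")
    try:
        sequences = {
            d["seq_id"]: CuratedSequence.from_dict(d) for d in doc["sequences"]
        }
        counts = {k: tuple(v) for k, v in doc["per_source_counts"].items()}
        meta = doc["build_metadata"]
    except (KeyError, TypeError) as exc:
        raise DatabaseLoadError(f"{path}: incomplete database: {exc}") from exc
    return CuratedDatabase(
        sequences=sequences, per_source_counts=counts, build_metadata=meta
    )


def write_build_stats(db: CuratedDatabase, path: str | Path) -> None:
    """Write a per-source entries/distinct-sequences table (TSV).

    One row per source plus a Total row; the total distinct count is the
    number of distinct sequences overall, which is at most the entry total
    (a sequence curated by two sources counts once overall).
    """
    with open(path, "w") as fh:
        fh.write("source\tn_entries\tn_distinct\n")
        for src in SOURCES:
            if src in db.per_source_counts:
                n_e, n_d = db.per_source_counts[src]
                fh.write(f"{src}\t{n_e}\t{n_d}\n")
        fh.write(f"Total\t{db.n_entries}\t{db.n_distinct}\n")
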