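"""Protein local alignment of curated sequences against genome targets.

Curated sequences are the queries; the genome's predicted proteins and
six-frame reading frames are the subjects. Each (curated, target) pair
keeps at most its single best local alignment, reported as a :class:`Hit`
with

* ``identity_frac`` — identical columns / alignment columns (gap columns
  count in the denominator);
* ``coverage_frac`` — the fraction of the CURATED sequence spanned by the
  alignment (coverage of the characterized protein, not of the target);
* ``score`` — identity_frac x coverage_frac, the ranking key. Ranking by
  bit score would systematically favour homologs of longer proteins, which
  is why the product of identity and curated coverage is used instead;
* an E-value under the Karlin–Altschul model, with hits above the
  configured maximum (default 0.01) discarded.

The built-in engine is exact Smith–Waterman (via Bio.Align.PairwiseAligner)
under BLOSUM62 with affine gap costs: a gap of length k costs 11 + k, the
convention the gapped Karlin–Altschul constants λ=0.267, K=0.041 are
published for. Adapters for external aligners producing BLAST
tabular-format output can feed the same Hit schema (see
:func:`hits_from_tabular`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from curated_blast.db import CuratedSequence
from curated_blast.errors import (
    AlignmentEngineError,
    DuplicateIdError,
    InvalidSequenceError,
)

#: Gapped Karlin–Altschul parameters for BLOSUM62 with gap cost 11 + k.
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_MAX_EVALUE = 0.01

_MATRIX_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX")
# residues legal in input but absent from BLOSUM62; scored as X
_TO_X = str.maketrans({c: "X" for c in "UOJ"})


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein of the genome of interest."""

    protein_id: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class LocalAlignment:
    """Raw engine output: optimal local alignment of query vs subject.

    Coordinates are 1-based inclusive residue positions; ``n_columns``
    counts alignment columns including gap columns.
    """

    raw_score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_identical: int
    n_columns: int


class AlignmentEngine(Protocol):
    """Contract every aligner (built-in or external adapter) satisfies."""

    name: str

    def align(self, query: str, subject: str) -> Optional[LocalAlignment]:
        """Best local alignment, or None when no positive-scoring one exists."""
        ...


def _clean(seq: str, role: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    if bad or not seq:
        raise InvalidSequenceError(
            f"{role} sequence contains invalid residue(s) {sorted(bad)}"
            if bad else f"{role} sequence is empty"
        )
    return seq.translate(_TO_X)


class BuiltinAligner:
    """Exact Smith–Waterman under BLOSUM62, gap of length k costing 11 + k.

    Deterministic: among co-optimal alignments the engine's canonical
    traceback is returned, so identical inputs give identical output.
    """

    name = "builtin"

    def __init__(self, gap_open: int = 11, gap_extend: int = 1):
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        # PairwiseAligner charges open_gap_score for a gap's first column
        # and extend_gap_score for each further column.
        aligner.open_gap_score = -(gap_open + gap_extend)
        aligner.extend_gap_score = -gap_extend
        self._aligner = aligner

    def align(self, query: str, subject: str) -> Optional[LocalAlignment]:
        query = _clean(query, "query")
        subject = _clean(subject, "subject")
        try:
            alignments = self._aligner.align(query, subject)
            if len(alignments) == 0 or alignments.score <= 0:
                return None
            aln = alignments[0]
        except (ValueError, MemoryError, OverflowError) as exc:
            raise AlignmentEngineError(f"builtin aligner failed: {exc}") from exc
        q_blocks, s_blocks = aln.aligned
        counts = aln.counts()
        return LocalAlignment(
            raw_score=float(aln.score),
            q_start=int(q_blocks[0][0]) + 1,
            q_end=int(q_blocks[-1][1]),
            s_start=int(s_blocks[0][0]) + 1,
            s_end=int(s_blocks[-1][1]),
            n_identical=int(counts.identities),
            n_columns=int(aln.length),
        )


def evalue(raw_score: float, query_len: int, search_space_len: int) -> float:
    """Karlin–Altschul expected hit count: K * m * n * exp(-λ * S)."""
    return KA_K * query_len * search_space_len * math.exp(-KA_LAMBDA * raw_score)


@dataclass(frozen=True)
class Hit:
    """Best local alignment of one curated sequence against one target."""

    curated_seq_id: str
    target_id: str
    target_kind: str  # 'protein' or 'frame'
    identity_frac: float
    coverage_frac: float
    evalue: float
    aln_curated_start: int
    aln_curated_end: int
    aln_target_start: int
    aln_target_end: int
    raw_score: float = 0.0

    @property
    def score(self) -> float:
        """Ranking key: identity fraction x curated-coverage fraction."""
        return self.identity_frac * self.coverage_frac

    def to_dict(self) -> dict:
        d = {
            "curated_seq_id": self.curated_seq_id,
            "target_id": self.target_id,
            "target_kind": self.target_kind,
            "identity_frac": self.identity_frac,
            "coverage_frac": self.coverage_frac,
            "evalue": self.evalue,
            "aln_curated_start": self.aln_curated_start,
            "aln_curated_end": self.aln_curated_end,
            "aln_target_start": self.aln_target_start,
            "aln_target_end": self.aln_target_end,
            "raw_score": self.raw_score,
        }
        d["score"] = self.score
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Hit":
        d = dict(d)
        d.pop("score", None)
        return cls(**d)


def align_all(
    curated: Sequence[CuratedSequence],
    targets: Sequence[tuple[str, str, str]],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    engine: AlignmentEngine | None = None,
) -> list[Hit]:
    """Align every curated sequence against every target.

    ``targets`` are (id, kind, sequence) triples with kind 'protein' or
    'frame'. At most one Hit per pair — the best local alignment — and only
    hits with E-value <= ``max_evalue`` are emitted. The E-value search
    space is (sum of target lengths) x query length, i.e. the whole target
    set is one database. Deterministic given the engine and inputs.
    """
    if engine is None:
        engine = BuiltinAligner()
    ids = [t[0] for t in targets]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError("duplicate target ids in alignment target set")
    space = sum(len(t[2]) for t in targets)
    hits: list[Hit] = []
    for cur in curated:
        for target_id, kind, seq in targets:
            aln = engine.align(cur.sequence, seq)
            if aln is None:
                continue
            ev = evalue(aln.raw_score, cur.length, space)
            if ev > max_evalue:
                continue
            hits.append(Hit(
                curated_seq_id=cur.seq_id,
                target_id=target_id,
                target_kind=kind,
                identity_frac=aln.n_identical / aln.n_columns,
                coverage_frac=(aln.q_end - aln.q_start + 1) / cur.length,
                evalue=ev,
                aln_curated_start=aln.q_start,
                aln_curated_end=aln.q_end,
                aln_target_start=aln.s_start,
                aln_target_end=aln.s_end,
                raw_score=aln.raw_score,
            ))
    return hits


# ---------------------------------------------------------------------------
# I/O and external-engine adapter

def read_proteome_fasta(path: str | Path) -> list[ProteinRecord]:
    """Predicted proteins from FASTA; one trailing '*' is stripped.

    The description is the header remainder after the id (may be empty).
    Duplicate ids are an error.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise InvalidSequenceError(f"protein {rec.id!r} is empty")
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, seq, desc))
    return records


#: Column layout accepted by :func:`hits_from_tabular` — the BLAST
#: tabular ("outfmt 6") dialect:
#:   1 query id (curated seq_id)      7 query start (1-based)
#:   2 subject id (target)            8 query end
#:   3 percent identity (0-100)       9 subject start
#:   4 alignment length (columns)    10 subject end
#:   5 mismatches (ignored)          11 E-value
#:   6 gap opens (ignored)           12 bit score (ignored)
TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def hits_from_tabular(
    lines: Iterable[str],
    curated_lengths: dict[str, int],
    target_kind: str,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[Hit]:
    """Adapt an external aligner's BLAST-tabular output to the Hit schema.

    Keeps the best-scoring row per (query, subject) pair; identity is taken
    from the report, coverage is recomputed from the query span and the
    curated length so the score definition matches the built-in engine.
    """
    best: dict[tuple[str, str], Hit] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise AlignmentEngineError(
                f"tabular line has {len(f)} fields, expected 12: {line!r}"
            )
        qid, sid = f[0], f[1]
        if qid not in curated_lengths:
            raise AlignmentEngineError(f"unknown curated id {qid!r} in tabular input")
        ev = float(f[10])
        if ev > max_evalue:
            continue
        qstart, qend = int(f[6]), int(f[7])
        hit = Hit(
            curated_seq_id=qid,
            target_id=sid,
            target_kind=target_kind,
            identity_frac=float(f[2]) / 100.0,
            coverage_frac=(qend - qstart + 1) / curated_lengths[qid],
            evalue=ev,
            aln_curated_start=qstart,
            aln_curated_end=qend,
            aln_target_start=int(f[8]),
            aln_target_end=int(f[9]),
            raw_score=float(f[11]),
        )
        key = (qid, sid)
        if key not in best or hit.score > best[key].score:
            best[key] = hit
    return list(best.values())
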