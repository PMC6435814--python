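"""Pipeline orchestration and report writing.

``run_pipeline`` runs the stages in order: select curated sequences whose
descriptions match the query; align them against the predicted proteins and
rank those hits; then, when a nucleotide genome is supplied and is under
the six-frame size limit, extract reading frames, align against them, apply
the redundancy filter, and rank the surviving frame hits. The result is a
:class:`SearchReport` that serializes losslessly to JSON and renders to TSV
and a small static HTML page.

A query that matches no curated protein is a valid, empty report — not an
error.
"""

from __future__ import annotations

import hashlib
import html as _html
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from curated_blast.align import (
    DEFAULT_MAX_EVALUE,
    AlignmentEngine,
    BuiltinAligner,
    Hit,
    ProteinRecord,
    align_all,
)
from curated_blast.db import CuratedDatabase
from curated_blast.query import Query, select_curated
from curated_blast.ranking import (
    SIXFRAME_FACTOR,
    FrameResultGroup,
    ProteinResultGroup,
    filter_sixframe_hits,
    rank_frame_hits,
    rank_protein_hits,
)
from curated_blast.sixframe import (
    MIN_FRAME_AA,
    check_sixframe_eligible,
    extract_reading_frames,
    genome_size,
)

logger = logging.getLogger(__name__)

REPORT_FORMATS = ("tsv", "json", "html")


@dataclass
class SearchReport:
    """Ranked, grouped results of one search against one genome."""

    query_text: str
    word_mode: bool
    n_curated_matched: int
    protein_groups: list[ProteinResultGroup]
    frame_groups: list[FrameResultGroup]
    sixframe_skipped_reason: str | None
    #: curated seq_id -> descriptions of its query-matching entries
    curated_descriptions: dict[str, list[str]]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "query_text": self.query_text,
            "word_mode": self.word_mode,
            "n_curated_matched": self.n_curated_matched,
            "protein_groups": [g.to_dict() for g in self.protein_groups],
            "frame_groups": [g.to_dict() for g in self.frame_groups],
            "sixframe_skipped_reason": self.sixframe_skipped_reason,
            "curated_descriptions": self.curated_descriptions,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SearchReport":
        return cls(
            query_text=d["query_text"],
            word_mode=d["word_mode"],
            n_curated_matched=d["n_curated_matched"],
            protein_groups=[ProteinResultGroup.from_dict(g)
                            for g in d["protein_groups"]],
            frame_groups=[FrameResultGroup.from_dict(g)
                          for g in d["frame_groups"]],
            sixframe_skipped_reason=d["sixframe_skipped_reason"],
            curated_descriptions={k: list(v) for k, v in
                                  d["curated_descriptions"].items()},
            metadata=dict(d["metadata"]),
        )


def _digest(parts: Sequence[str]) -> str:
    h = hashlib.sha1()
    for p in parts:
        h.update(p.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def run_pipeline(
    db: CuratedDatabase,
    proteome: Sequence[ProteinRecord],
    query: Query,
    genome=None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_frame_aa: int = MIN_FRAME_AA,
    sixframe_factor: float = SIXFRAME_FACTOR,
    engine: AlignmentEngine | None = None,
    skip_sixframe: bool = False,
) -> SearchReport:
    """Execute the full search and return a populated report.

    ``genome`` is an optional mapping contig_id -> nucleotide sequence (or
    iterable of Contig); when absent, too large, or ``skip_sixframe`` is
    set, the six-frame stage is skipped with the reason recorded in the
    report.
    """
    if engine is None:
        engine = BuiltinAligner()
    t0 = time.monotonic()

    matched = select_curated(db, query)
    curated = [seq for seq, _ in matched]
    descriptions = {
        seq.seq_id: [e.description for e in entries]
        for seq, entries in matched
    }
    logger.info("query %r matched %d curated sequence(s)",
                query.text, len(curated))

    protein_groups: list[ProteinResultGroup] = []
    frame_groups: list[FrameResultGroup] = []
    protein_hits: list[Hit] = []
    skip_reason: str | None = None

    if curated:
        targets = [(p.protein_id, "protein", p.sequence) for p in proteome]
        protein_hits = align_all(curated, targets, max_evalue, engine)
        protein_groups = rank_protein_hits(
            protein_hits, {p.protein_id: p.description for p in proteome})
        logger.info("protein stage: %d hit(s) in %d group(s) [%.1fs]",
                    len(protein_hits), len(protein_groups),
                    time.monotonic() - t0)

    if not curated:
        skip_reason = "no curated proteins matched the query"
    elif skip_sixframe:
        skip_reason = "six-frame stage disabled"
    elif genome is None:
        skip_reason = "no nucleotide genome provided"
    elif not check_sixframe_eligible(genome):
        skip_reason = (f"genome is {genome_size(genome):,} nt; six-frame "
                       f"search requires under 30,000,000 nt")
        logger.info("skipping six-frame stage: %s", skip_reason)
    else:
        frames = extract_reading_frames(genome, min_aa=min_frame_aa)
        frame_targets = [(f.frame_id, "frame", f.aa_sequence) for f in frames]
        frame_hits = align_all(curated, frame_targets, max_evalue, engine)
        kept = filter_sixframe_hits(frame_hits, protein_hits, sixframe_factor)
        frame_groups = rank_frame_hits(
            kept, {f.frame_id: f.coordinates() for f in frames})
        logger.info(
            "six-frame stage: %d frame(s), %d hit(s), %d kept after "
            "redundancy filter [%.1fs]", len(frames), len(frame_hits),
            len(kept), time.monotonic() - t0)

    return SearchReport(
        query_text=query.text,
        word_mode=query.word_mode,
        n_curated_matched=len(curated),
        protein_groups=protein_groups,
        frame_groups=frame_groups,
        sixframe_skipped_reason=skip_reason,
        curated_descriptions=descriptions,
        metadata={
            "engine": engine.name,
            "max_evalue": max_evalue,
            "min_frame_aa": min_frame_aa,
            "sixframe_factor": sixframe_factor,
            "db_digest": _digest([s.sequence for s in db.iter_sequences()]),
            "proteome_digest": _digest(
                [p.protein_id + p.sequence for p in proteome]),
        },
    )


# ---------------------------------------------------------------------------
# writers

_TSV_HEADER = (
    "stage\ttarget_id\ttarget_kind\tcoords\tcurated_seq_id\t"
    "matched_descriptions\tidentity_pct\tcoverage_pct\tevalue\tscore\thidden\n"
)


def _pct(frac: float) -> str:
    """Fractions render as integer percentages ('43% id.' style)."""
    return str(round(frac * 100))


def _tsv_rows(report: SearchReport):
    for g in report.protein_groups:
        for i, h in enumerate(g.hits):
            hidden = "hidden" if i >= len(g.hits) - g.n_hidden else "shown"
            yield ("protein", g.target_id, h, g.description, hidden)
    for g in report.frame_groups:
        for h in g.hits:
            yield ("sixframe", g.frame_id, h, g.coordinates, "shown")


def write_report_tsv(report: SearchReport, path: str | Path) -> None:
    """One row per (group, hit); empty report writes the header only."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for stage, target, h, coords_or_desc, hidden in _tsv_rows(report):
            descs = "; ".join(report.curated_descriptions.get(h.curated_seq_id, []))
            coords = coords_or_desc if stage == "sixframe" else ""
            fh.write("\t".join([
                stage, target, h.target_kind, coords, h.curated_seq_id,
                descs, _pct(h.identity_frac), _pct(h.coverage_frac),
                f"{h.evalue:.3g}", f"{h.score:.6f}", hidden,
            ]) + "\n")


def write_report_json(report: SearchReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
        fh.write("\n")


def read_report_json(path: str | Path) -> SearchReport:
    with open(path) as fh:
        return SearchReport.from_dict(json.load(fh))


def _render_hit_html(report: SearchReport, h: Hit) -> str:
    descs = "; ".join(report.curated_descriptions.get(h.curated_seq_id, []))
    return (f"<li>{_html.escape(descs)} "
            f"({_pct(h.identity_frac)}% id., {_pct(h.coverage_frac)}% cov, "
            f"E = {h.evalue:.2g})</li>")


def write_report_html(report: SearchReport, path: str | Path) -> None:
    """Grouped static view with top-3 truncation and 'more' counts."""
    out = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>Curated search: {_html.escape(report.query_text)}</title>",
        "</head><body>",
        f"<h1>Query: {_html.escape(report.query_text)}"
        + (" (whole words)" if report.word_mode else "") + "</h1>",
        f"<p>{report.n_curated_matched} curated sequence(s) matched "
        "the query.</p>",
        "<h2>Hits to predicted proteins</h2>",
    ]
    if not report.protein_groups:
        out.append("<p>No hits.</p>")
    for g in report.protein_groups:
        out.append(f"<h3>{_html.escape(g.target_id)} "
                   f"{_html.escape(g.description)}</h3><ul>")
        out.extend(_render_hit_html(report, h) for h in g.shown_hits)
        if g.n_hidden:
            out.append(f"<li><em>... and {g.n_hidden} more hit(s)</em></li>")
        out.append("</ul>")
    out.append("<h2>Hits to the six-frame translation</h2>")
    if report.sixframe_skipped_reason:
        out.append(
            f"<p>Skipped: {_html.escape(report.sixframe_skipped_reason)}</p>")
    elif not report.frame_groups:
        out.append("<p>No additional hits beyond the predicted proteins.</p>")
    for g in report.frame_groups:
        out.append(f"<h3>{_html.escape(g.coordinates or g.frame_id)}</h3><ul>")
        out.extend(_render_hit_html(report, h) for h in g.hits)
        out.append("</ul>")
    out.append("</body></html>")
    Path(path).write_text("\n".join(out) + "\n")


def write_report(report: SearchReport, fmt: str, path: str | Path) -> None:
    """Write the report in one of 'tsv', 'json', 'html'."""
    writers = {
        "tsv": write_report_tsv,
        "json": write_report_json,
        "html": write_report_html,
    }
    if fmt not in writers:
        raise ValueError(f"unknown report format {fmt!r}; "
                         f"choose from {REPORT_FORMATS}")
    writers[fmt](report, path)
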