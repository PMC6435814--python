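"""Hit scoring, sorting, grouping, and the six-frame redundancy filter.

Hits are ranked by score = identity fraction x curated-coverage fraction,
highest first — deliberately not by bit score, which would bias results
toward homologs of longer proteins. Hits are grouped by target; a predicted
protein with four or more hits shows only its top three initially (the rest
are counted as hidden).

Reading-frame hits are only interesting when they are NOT already explained
by a predicted protein. A frame hit for a curated sequence is kept only if
its score is noticeably better — strictly greater than 1.1x — than the best
protein-stage score for that same curated sequence (0 when it has no
protein hit at all: the "missing gene" case). If a frame's best hit is
discarded by this rule, the whole frame is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from curated_blast.align import Hit

#: A six-frame hit must beat the best protein score by this factor.
SIXFRAME_FACTOR = 1.1

#: Groups with at least this many hits are truncated to the top 3.
_TRUNCATE_AT = 4
_SHOWN = 3


def _sort_hits(hits: Sequence[Hit]) -> list[Hit]:
    """Descending score; ties broken by (curated_seq_id, target_id)."""
    return sorted(hits, key=lambda h: (-h.score, h.curated_seq_id, h.target_id))


@dataclass
class ProteinResultGroup:
    """All hits to one predicted protein, best first, with top-3 truncation."""

    target_id: str
    description: str
    hits: list[Hit]
    n_hidden: int = 0

    @property
    def best_score(self) -> float:
        return self.hits[0].score

    @property
    def shown_hits(self) -> list[Hit]:
        return self.hits[: len(self.hits) - self.n_hidden]

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "description": self.description,
            "hits": [h.to_dict() for h in self.hits],
            "n_hidden": self.n_hidden,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProteinResultGroup":
        return cls(
            target_id=d["target_id"],
            description=d["description"],
            hits=[Hit.from_dict(h) for h in d["hits"]],
            n_hidden=d["n_hidden"],
        )


@dataclass
class FrameResultGroup:
    """Retained hits to one reading frame, best first."""

    frame_id: str
    coordinates: str
    hits: list[Hit] = field(default_factory=list)

    @property
    def best_score(self) -> float:
        return self.hits[0].score

    def to_dict(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "coordinates": self.coordinates,
            "hits": [h.to_dict() for h in self.hits],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FrameResultGroup":
        return cls(
            frame_id=d["frame_id"],
            coordinates=d["coordinates"],
            hits=[Hit.from_dict(h) for h in d["hits"]],
        )


def rank_protein_hits(
    hits: Sequence[Hit],
    descriptions: Mapping[str, str] | None = None,
) -> list[ProteinResultGroup]:
    """Group protein-stage hits by target, ordered by descending best score.

    Within a group hits are ordered by descending score; all ties break by
    identifier so the output is byte-reproducible. Truncation is display
    bookkeeping only — every hit stays in ``hits``; a group of four or more
    marks all but the top three as hidden.
    """
    descriptions = descriptions or {}
    by_target: dict[str, list[Hit]] = {}
    for h in hits:
        by_target.setdefault(h.target_id, []).append(h)
    groups = []
    for target_id, target_hits in by_target.items():
        ordered = _sort_hits(target_hits)
        n = len(ordered)
        groups.append(ProteinResultGroup(
            target_id=target_id,
            description=descriptions.get(target_id, ""),
            hits=ordered,
            n_hidden=(n - _SHOWN) if n >= _TRUNCATE_AT else 0,
        ))
    groups.sort(key=lambda g: (-g.best_score, g.target_id))
    return groups


def filter_sixframe_hits(
    frame_hits: Sequence[Hit],
    protein_hits: Sequence[Hit],
    factor: float = SIXFRAME_FACTOR,
) -> list[Hit]:
    """Drop six-frame hits already expected from the predicted proteins.

    Step 1: for each curated sequence, a frame hit is provisionally kept only
    when its score strictly exceeds ``factor`` x that sequence's best
    protein-stage score (taken as 0 when it has no protein hit).
    Step 2: if a frame's highest-scoring hit was not provisionally kept, all
    hits for that frame are dropped; otherwise exactly the provisionally
    kept hits survive. Input order is preserved.
    """
    best_protein: dict[str, float] = {}
    for h in protein_hits:
        cur = best_protein.get(h.curated_seq_id, 0.0)
        if h.score > cur:
            best_protein[h.curated_seq_id] = h.score

    def provisionally_kept(h: Hit) -> bool:
        return h.score > factor * best_protein.get(h.curated_seq_id, 0.0)

    # the frame's best hit under the same deterministic order used everywhere
    frames: dict[str, list[Hit]] = {}
    for h in frame_hits:
        frames.setdefault(h.target_id, []).append(h)
    frame_ok = {
        fid: provisionally_kept(_sort_hits(fhits)[0])
        for fid, fhits in frames.items()
    }
    return [h for h in frame_hits
            if frame_ok[h.target_id] and provisionally_kept(h)]


def rank_frame_hits(
    filtered_hits: Sequence[Hit],
    coordinates: Mapping[str, str] | None = None,
) -> list[FrameResultGroup]:
    """Group filtered six-frame hits per frame, best frame first."""
    coordinates = coordinates or {}
    by_frame: dict[str, list[Hit]] = {}
    for h in filtered_hits:
        by_frame.setdefault(h.target_id, []).append(h)
    groups = [
        FrameResultGroup(
            frame_id=fid,
            coordinates=coordinates.get(fid, ""),
            hits=_sort_hits(fhits),
        )
        for fid, fhits in by_frame.items()
    ]
    groups.sort(key=lambda g: (-g.best_score, g.frame_id))
    return groups
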