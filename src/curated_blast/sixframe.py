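"""Six-frame translation and candidate reading-frame extraction.

A nucleotide genome is translated in all six frames (three codon phases on
each strand) and every maximal stop-free stretch of at least 30 translated
residues is emitted as a candidate reading frame. No start codon is
required: the goal is to find any region that could encode part of a
protein, including genes split by frameshift errors and genes missed by
the gene caller. Splicing is not considered; the feature is designed for
bacterial and archaeal genomes (genetic code table 11 by default) but may
be useful for small eukaryotic genomes. Six-frame search is offered only
for genomes under 30 Mb.

Coordinates are 1-based inclusive on the forward strand of the contig,
regardless of the frame's strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from curated_blast.errors import DuplicateIdError, InvalidSequenceError

#: Genomes at or above this many nucleotides skip the six-frame stage.
SIXFRAME_MAX_NT = 30_000_000

#: Minimum stop-free stretch length, in residues.
MIN_FRAME_AA = 30

_IUPAC_NT: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Contig:
    """One nucleotide sequence of the genome, uppercased and validated."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise InvalidSequenceError(f"contig {self.contig_id!r} is empty")
        bad = set(seq) - set(_IUPAC_NT)
        if bad:
            raise InvalidSequenceError(
                f"contig {self.contig_id!r}: non-IUPAC character(s) {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadingFrame:
    """A maximal stop-free translated stretch of >= min_aa residues.

    ``nt_start``/``nt_end`` are 1-based inclusive on the forward strand;
    for strand '-' the addressed codons are reverse-complemented before
    translation. May contain 'X' where ambiguity codes leave the residue
    undetermined; never contains a stop.
    """

    frame_id: str
    contig_id: str
    strand: str          # '+' or '-'
    frame: int           # 1, 2, 3 (codon phase on its strand)
    nt_start: int
    nt_end: int
    aa_sequence: str

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)

    def coordinates(self) -> str:
        return f"{self.contig_id}:{self.nt_start}-{self.nt_end}({self.strand}{self.frame})"


class _Translator:
    """Codon -> residue under one genetic code, with IUPAC ambiguity rules.

    A codon containing ambiguity codes translates to the shared residue if
    every disambiguation agrees, to 'X' if disambiguations disagree, and to
    a stop ('*') if ANY disambiguation is a stop — the conservative choice
    that prevents runs of N from inflating apparent reading frames.
    """

    def __init__(self, table_id: int = 11):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self._aa = dict(table.forward_table)
        for stop in table.stop_codons:
            self._aa[stop] = "*"
        self._cache: dict[str, str] = dict(self._aa)

    def codon(self, codon: str) -> str:
        hit = self._cache.get(codon)
        if hit is not None:
            return hit
        residues = {
            self._aa["".join(c)]
            for c in product(*(_IUPAC_NT[b] for b in codon))
        }
        if "*" in residues:
            out = "*"
        elif len(residues) == 1:
            out = residues.pop()
        else:
            out = "X"
        self._cache[codon] = out
        return out

    def translate(self, nt: str) -> str:
        """Translate complete codons; a trailing partial codon is ignored."""
        return "".join(
            self.codon(nt[i:i + 3]) for i in range(0, len(nt) - 2, 3)
        )


def _as_contigs(genome) -> list[Contig]:
    if isinstance(genome, Mapping):
        items = [Contig(cid, seq) for cid, seq in genome.items()]
    else:
        items = [c if isinstance(c, Contig) else Contig(*c) for c in genome]
    seen = set()
    for c in items:
        if c.contig_id in seen:
            raise DuplicateIdError(f"duplicate contig id {c.contig_id!r}")
        seen.add(c.contig_id)
    return items


def genome_size(genome) -> int:
    return sum(len(c) for c in _as_contigs(genome))


def check_sixframe_eligible(genome) -> bool:
    """True when the genome is strictly under the 30 Mb six-frame limit."""
    return genome_size(genome) < SIXFRAME_MAX_NT


def extract_reading_frames(
    genome,
    min_aa: int = MIN_FRAME_AA,
    table_id: int = 11,
) -> list[ReadingFrame]:
    """All stop-free stretches of >= ``min_aa`` residues in six frames.

    ``genome`` is a mapping contig_id -> sequence, or an iterable of
    :class:`Contig`. Runs are bounded by stop codons and contig ends;
    trailing partial codons are ignored. Output is sorted by
    (contig_id, strand, frame, nt_start).
    """
    tr = _Translator(table_id)
    frames: list[ReadingFrame] = []
    for contig in _as_contigs(genome):
        L = len(contig)
        rc = str(Seq(contig.sequence).reverse_complement())
        for strand, s in (("+", contig.sequence), ("-", rc)):
            for phase in (1, 2, 3):
                aa = tr.translate(s[phase - 1:])
                for m in re.finditer(r"[^*]+", aa):
                    if m.end() - m.start() < min_aa:
                        continue
                    # codon positions on the translated strand, 1-based
                    s_start = (phase - 1) + 3 * m.start() + 1
                    s_end = (phase - 1) + 3 * m.end()
                    if strand == "+":
                        nt_start, nt_end = s_start, s_end
                    else:
                        nt_start, nt_end = L - s_end + 1, L - s_start + 1
                    frames.append(ReadingFrame(
                        frame_id=(f"{contig.contig_id}|{strand}{phase}"
                                  f"|{nt_start}"),
                        contig_id=contig.contig_id,
                        strand=strand,
                        frame=phase,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        aa_sequence=m.group(0),
                    ))
    frames.sort(key=lambda f: (f.contig_id, f.strand, f.frame, f.nt_start))
    return frames


# ---------------------------------------------------------------------------
# I/O

def read_genome_fasta(path: str | Path) -> list[Contig]:
    """Read contigs from a nucleotide FASTA file."""
    contigs = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, str(rec.seq)))
    return contigs


def write_frames_fasta(frames: Sequence[ReadingFrame], path: str | Path) -> None:
    """Frame peptides as FASTA; headers encode contig/strand/frame/coords."""
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f">{f.frame_id} {f.coordinates()}\n{f.aa_sequence}\n")


def write_frames_tsv(frames: Sequence[ReadingFrame], path: str | Path) -> None:
    """BED-like interval table of the frames (1-based inclusive coords)."""
    with open(path, "w") as fh:
        fh.write("contig_id\tnt_start\tnt_end\tstrand\tframe\tframe_id\taa_length\n")
        for f in frames:
            fh.write(f"{f.contig_id}\t{f.nt_start}\t{f.nt_end}\t{f.strand}"
                     f"\t{f.frame}\t{f.frame_id}\t{f.aa_length}\n")
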