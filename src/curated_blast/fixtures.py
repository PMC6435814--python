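"""Synthetic curated databases, proteomes and genomes with planted signal.

Everything the pipeline consumes can be generated here deterministically
from a seed, so every stage is testable without downloading any of the
curated source databases or a real genome.

Two generators:

* :func:`make_curated_fixture` emits normalized per-source entry tables and
  a protein FASTA that exercise every source retention rule (missing
  UniProt ids, fragments, ``trusted_uniprot`` records, missing EC numbers,
  unknown REBASE specificity, missing experimental evidence), together with
  a manifest of expected retain/exclude decisions and expected
  distinct-sequence counts computed by the generator's own bookkeeping.

* :func:`make_genome_with_plants` reverse-translates chosen proteins into a
  random background genome. A plant can appear as a predicted protein, as
  an intact unannotated open reading frame, as a frameshifted gene (one
  nucleotide deleted mid-gene, with the protein omitted from the
  proteome — the pattern a six-frame search should recover as two nearby
  reading frames covering the N- and C-terminal portions), or not at all.

The background is i.i.d. nucleotide sequence at the requested GC content;
there is no repeat structure or codon bias. Reverse translation draws
synonymous codons uniformly under the same genetic code table used for
six-frame translation, so plants are stop-free in frame by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from curated_blast.align import ProteinRecord
from curated_blast.db import CuratedEntry, sequence_digest
from curated_blast.errors import FixtureError

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Passthrough sources first so small fixtures retain everything.
SOURCE_ORDER = (
    "EcoCyc", "FitnessBrowser", "BRENDA", "CAZy",
    "CharProtDB", "MetaCyc", "REBASE", "SwissProt",
)

_DESCRIPTION_POOL = (
    "perchlorate reductase subunit alpha",
    "chlorate reductase",
    "nitrate reductase catalytic subunit",
    "histidinol dehydrogenase",
    "endoglucanase",
    "beta-galactosidase",
    "alcohol dehydrogenase 1.1.1.1",
    "tetrathionate reductase subunit",
)

# per-source cycle of generated cases; 'ok*' cases are expected retained
_SOURCE_CASES: dict[str, tuple[str, ...]] = {
    "EcoCyc": ("ok", "ok_fragment_flag"),
    "FitnessBrowser": ("ok",),
    "BRENDA": ("ok", "missing_uniprot", "no_publication", "fragment"),
    "CAZy": ("ok", "no_ec", "fragment_in_description",
             "frameshift_in_description"),
    "CharProtDB": ("ok", "trusted_uniprot", "trusted_aspgd"),
    "MetaCyc": ("ok", "missing_uniprot", "no_publication", "fragment"),
    "REBASE": ("ok", "specificity_unknown"),
    "SwissProt": ("ok", "no_experimental_evidence"),
}


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


@dataclass
class ManifestRow:
    entry_id: str
    source: str
    case: str
    expected_retained: bool
    sequence_id: str


@dataclass
class CuratedFixture:
    """Normalized inputs plus the generator's own expectations."""

    entries: list[CuratedEntry]
    sequences: dict[str, str]                 # sequence_id -> aa string
    manifest: list[ManifestRow]
    expected_per_source: dict[str, tuple[int, int]]  # (n_retained, n_distinct)
    expected_total_retained: int
    expected_total_distinct: int


def _make_entry(source: str, idx: int, case: str, seq_id: str,
                description: str) -> CuratedEntry:
    e = CuratedEntry(
        entry_id=f"{source}:{idx:04d}",
        source=source,
        description=description,
        organism=f"Synthetica exempli strain {idx % 5}",
        ec_numbers=["3.2.1.4"] if source == "CAZy" else ["1.1.1.1"] * (idx % 2),
        publication_ids=[f"PMID:{1000 + idx}"],
        uniprot_id=f"P{idx:05d}",
        entry_type="trusted" if source == "CharProtDB" else None,
        is_fragment=False,
        specificity_known=True,
        has_experimental_evidence=True,
        sequence_id=seq_id,
    )
    if case == "ok_fragment_flag":
        # fragment exclusion never applies to EcoCyc/FitnessBrowser
        e.is_fragment = True
    elif case == "missing_uniprot":
        e.uniprot_id = None
    elif case == "no_publication":
        e.publication_ids = []
    elif case == "fragment":
        e.is_fragment = True
    elif case == "no_ec":
        e.ec_numbers = []
    elif case == "fragment_in_description":
        e.description = description + " fragment"
    elif case == "frameshift_in_description":
        e.description = description + " (frameshift)"
    elif case == "trusted_uniprot":
        e.entry_type = "trusted_uniprot"
    elif case == "trusted_aspgd":
        e.entry_type = "trusted_aspgd"
    elif case == "specificity_unknown":
        e.specificity_known = False
    elif case == "no_experimental_evidence":
        e.has_experimental_evidence = False
    return e


def make_curated_fixture(
    n_sources: int = 8,
    n_entries_per_source: int = 15,
    dup_fraction: float = 0.0,
    seed: int = 0,
) -> CuratedFixture:
    """Generate normalized source tables exercising every retention rule.

    ``dup_fraction`` of the retained entries reuse the sequence of an
    earlier retained entry, so the expected number of distinct sequences is
    ``n_retained - floor(dup_fraction * n_retained)``. Fixed seed gives
    byte-identical output.
    """
    if not (1 <= n_sources <= len(SOURCE_ORDER)):
        raise FixtureError(f"n_sources must be in 1..{len(SOURCE_ORDER)}")
    if n_entries_per_source < 1:
        raise FixtureError("n_entries_per_source must be positive")
    if not (0.0 <= dup_fraction < 1.0):
        raise FixtureError("dup_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    entries: list[CuratedEntry] = []
    manifest: list[ManifestRow] = []
    sequences: dict[str, str] = {}
    for source in SOURCE_ORDER[:n_sources]:
        cases = _SOURCE_CASES[source]
        for i in range(n_entries_per_source):
            case = cases[i % len(cases)]
            seq_id = f"{source}_seq{i:04d}"
            sequences[seq_id] = random_protein(
                rng, int(rng.integers(60, 120)))
            desc = _DESCRIPTION_POOL[i % len(_DESCRIPTION_POOL)]
            entry = _make_entry(source, i, case, seq_id, desc)
            entries.append(entry)
            manifest.append(ManifestRow(
                entry_id=entry.entry_id,
                source=source,
                case=case,
                expected_retained=case.startswith("ok"),
                sequence_id=seq_id,
            ))

    retained = [m for m in manifest if m.expected_retained]
    n_dup = int(dup_fraction * len(retained))
    if 2 * n_dup > len(retained):
        raise FixtureError("dup_fraction too high for this fixture size")
    # the last n_dup retained entries reuse the first n_dup retained
    # entries' sequences (distinct donors, donors never dups themselves)
    for donor, dup in zip(retained[:n_dup], retained[-n_dup:] if n_dup else []):
        sequences[dup.sequence_id] = sequences[donor.sequence_id]

    # generator-side bookkeeping of what ingestion should report
    per_source: dict[str, tuple[int, int]] = {}
    for source in SOURCE_ORDER[:n_sources]:
        rows = [m for m in retained if m.source == source]
        distinct = {sequences[m.sequence_id] for m in rows}
        per_source[source] = (len(rows), len(distinct))
    total_distinct = len({sequences[m.sequence_id] for m in retained})

    return CuratedFixture(
        entries=entries,
        sequences=sequences,
        manifest=manifest,
        expected_per_source=per_source,
        expected_total_retained=len(retained),
        expected_total_distinct=total_distinct,
    )


def write_curated_fixture(fix: CuratedFixture, outdir: str | Path) -> None:
    """Write entries.tsv, sequences.faa and manifest.tsv (stable bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "entries.tsv", "w") as fh:
        fh.write("entry_id\tsource\tdescription\torganism\tec_numbers\t"
                 "publication_ids\tuniprot_id\tentry_type\tis_fragment\t"
                 "specificity_known\thas_experimental_evidence\tsequence_id\n")
        for e in fix.entries:
            fh.write("\t".join([
                e.entry_id, e.source, e.description, e.organism,
                ";".join(e.ec_numbers), ";".join(e.publication_ids),
                e.uniprot_id or "", e.entry_type or "",
                str(e.is_fragment).lower(), str(e.specificity_known).lower(),
                str(e.has_experimental_evidence).lower(), e.sequence_id,
            ]) + "\n")
    with open(outdir / "sequences.faa", "w") as fh:
        for sid, seq in fix.sequences.items():
            fh.write(f">{sid}\n{seq}\n")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("entry_id\tsource\tcase\texpected_retained\tsequence_id\n")
        for m in fix.manifest:
            fh.write(f"{m.entry_id}\t{m.source}\t{m.case}\t"
                     f"{str(m.expected_retained).lower()}\t{m.sequence_id}\n")


# ---------------------------------------------------------------------------
# genomes with planted genes

PLANT_MODES = (
    "as_predicted_protein", "as_intact_orf", "as_frameshifted_orf", "absent",
)


@dataclass(frozen=True)
class PlantSpec:
    """One protein to plant into the synthetic genome."""

    seq_id: str
    protein: str
    mode: str
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in PLANT_MODES:
            raise FixtureError(f"unknown plant mode {self.mode!r}")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise FixtureError("mutation_rate must be in [0, 1)")
        if self.mode == "as_frameshifted_orf" and len(self.protein) < 61:
            raise FixtureError(
                "frameshifted plants need >= 61 residues so both halves "
                "stay >= 30 aa")


@dataclass
class PlantTruth:
    """Where a plant landed and what the pipeline should find."""

    seq_id: str
    mode: str
    contig_id: str
    nt_start: int        # 1-based inclusive genome coords of the insert
    nt_end: int
    strand: str
    planted_protein: str         # after divergence mutations
    aa_break: int | None = None  # 1-based residue whose codon the deletion hits
    in_proteome: bool = False
    detectable_sixframe: bool = False


@dataclass
class GenomeFixture:
    contigs: dict[str, str]
    proteome: list[ProteinRecord]
    truth: list[PlantTruth] = field(default_factory=list)


def _codon_choices(table_id: int = 11) -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


def reverse_translate(protein: str, rng: np.random.Generator,
                      table_id: int = 11) -> str:
    """Uniform synonymous codon choice; stop-free in frame by construction."""
    choices = _codon_choices(table_id)
    try:
        return "".join(
            choices[aa][rng.integers(len(choices[aa]))] for aa in protein)
    except KeyError as exc:
        raise FixtureError(f"cannot reverse-translate residue {exc}") from exc


def _frameshifted_gene(
    protein: str, rng: np.random.Generator, table_id: int = 11
) -> tuple[str, int]:
    """Encode ``protein`` with one nucleotide deleted at a break codon.

    Returns (gene_with_deletion, aa_break) where ``aa_break`` is the
    1-based residue whose codon the deletion disrupts. The N-terminal half
    stays in the original frame and the C-terminal half shifts one phase
    over; each half is stop-free in its own frame because it still encodes
    real residues.

    Where the protein permits, synonymous codons around the break are
    chosen so that a stop codon terminates the upstream frame immediately
    after the junction and another terminates the downstream frame's
    backward extension one codon before it. That pins each frame's run to
    its own half, so the two hits' curated-coverage intervals cannot
    overlap through chance matches in the out-of-frame readings. When no
    break position admits both stops, the deletion simply lands mid-gene.
    """
    choices = _codon_choices(table_id)
    N = len(protein)
    codons = [choices[aa][rng.integers(len(choices[aa]))] for aa in protein]

    # candidate break codons keep both halves >= 30 aa, centre-outward;
    # the deleted nucleotide may be any of the break codon's three, which
    # broadens the set of break residues admitting a junction stop
    candidates = sorted(range(30, N - 30), key=lambda m: (abs(m - N // 2), m))
    placed = None
    for m in candidates:
        # upstream-phase codon straddling the junction is the break
        # codon's two surviving bases plus the next codon's first base;
        # it must read TAA/TAG/TGA
        pairs = []
        for del_off in (0, 1, 2):
            for cm in choices[protein[m]]:
                kept = cm[:del_off] + cm[del_off + 1:]
                if kept == "TA":
                    nxt = [c for c in choices[protein[m + 1]] if c[0] in "AG"]
                elif kept == "TG":
                    nxt = [c for c in choices[protein[m + 1]] if c[0] == "A"]
                else:
                    continue
                if nxt:
                    pairs.append((del_off, cm, nxt))
        # downstream-phase codon one step before the junction:
        # c_{m-2}[2] + c_{m-1}[0:2] must read TAA/TAG/TGA
        prev1 = [c for c in choices[protein[m - 1]]
                 if c[:2] in ("AA", "AG", "GA")]
        prev2 = [c for c in choices[protein[m - 2]] if c[2] == "T"]
        if pairs and prev1 and prev2:
            del_off, cm, nxt = pairs[rng.integers(len(pairs))]
            codons[m] = cm
            codons[m + 1] = nxt[rng.integers(len(nxt))]
            codons[m - 1] = prev1[rng.integers(len(prev1))]
            codons[m - 2] = prev2[rng.integers(len(prev2))]
            placed = (m, del_off)
            break
    if placed is None:
        placed = (N // 2, 0)
    m, del_off = placed
    gene = "".join(codons)
    pos = 3 * m + del_off
    return gene[:pos] + gene[pos + 1:], m + 1


def _mutate(protein: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return protein
    out = []
    for aa in protein:
        if rng.random() < rate:
            alt = _AA20.replace(aa, "")
            out.append(alt[rng.integers(len(alt))])
        else:
            out.append(aa)
    return "".join(out)


def make_genome_with_plants(
    plants: Sequence[PlantSpec],
    background_kb: float = 10.0,
    gc_frac: float = 0.5,
    seed: int = 0,
    contig_id: str = "contig1",
    n_decoy_proteins: int = 3,
) -> GenomeFixture:
    """Plant proteins into a random background contig.

    Plants are reverse-translated (after optional divergence mutations) and
    written over non-overlapping loci on random strands. A frameshifted
    plant has one nucleotide deleted near its middle codon (see
    :func:`_frameshifted_gene`), so the six-frame translation keeps two
    stop-free halves — the N-terminal part in the original frame and the
    C-terminal part one phase over — while only the disrupted break
    residue is lost. Frameshifted and intact-ORF plants are omitted from
    the predicted proteome.
    """
    rng = np.random.default_rng(seed)
    L = int(background_kb * 1000)
    need = sum(3 * len(p.protein) for p in plants if p.mode != "absent")
    if L < need:
        raise FixtureError(
            f"background of {L} nt cannot hold {need} nt of plants")

    p_gc = gc_frac / 2.0
    p_at = (1.0 - gc_frac) / 2.0
    background = rng.choice(list("ACGT"), size=L,
                            p=[p_at, p_gc, p_gc, p_at])

    # reverse-translate first so codon draws are independent of placement
    inserts: list[tuple[PlantSpec, str, str, str, int | None]] = []
    for spec in plants:
        mutated = _mutate(spec.protein, spec.mutation_rate, rng)
        if spec.mode == "absent":
            inserts.append((spec, mutated, "", "", None))
            continue
        aa_break = None
        if spec.mode == "as_frameshifted_orf":
            gene, aa_break = _frameshifted_gene(mutated, rng)
        else:
            gene = reverse_translate(mutated, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            gene = str(Seq(gene).reverse_complement())
        inserts.append((spec, mutated, gene, strand, aa_break))

    # non-overlapping placement by rejection sampling; a 90 nt (30 aa)
    # buffer keeps one plant's reading frames from running into another's
    occupied: list[tuple[int, int]] = []
    truth: list[PlantTruth] = []
    proteome: list[ProteinRecord] = []
    for spec, mutated, gene, strand, aa_break in inserts:
        if spec.mode == "absent":
            truth.append(PlantTruth(
                seq_id=spec.seq_id, mode=spec.mode, contig_id="",
                nt_start=0, nt_end=0, strand="", planted_protein=mutated))
            continue
        glen = len(gene)
        for _ in range(10_000):
            start = int(rng.integers(0, L - glen + 1))
            if all(start + glen + 90 <= s or e + 90 <= start
                   for s, e in occupied):
                break
        else:
            raise FixtureError("could not place plants without overlap")
        occupied.append((start, start + glen))
        background[start:start + glen] = list(gene)
        truth.append(PlantTruth(
            seq_id=spec.seq_id,
            mode=spec.mode,
            contig_id=contig_id,
            nt_start=start + 1,
            nt_end=start + glen,
            strand=strand,
            planted_protein=mutated,
            aa_break=aa_break,
            in_proteome=spec.mode == "as_predicted_protein",
            detectable_sixframe=spec.mode in
            ("as_intact_orf", "as_frameshifted_orf"),
        ))
        if spec.mode == "as_predicted_protein":
            proteome.append(ProteinRecord(
                protein_id=f"pred_{spec.seq_id}", sequence=mutated,
                description="hypothetical protein"))

    for i in range(n_decoy_proteins):
        proteome.append(ProteinRecord(
            protein_id=f"decoy_{i}",
            sequence=random_protein(rng, int(rng.integers(80, 120))),
            description="decoy protein"))

    return GenomeFixture(
        contigs={contig_id: "".join(background)},
        proteome=proteome,
        truth=truth,
    )


def write_genome_fixture(fix: GenomeFixture, outdir: str | Path) -> None:
    """Write genome.fna, proteins.faa and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fna", "w") as fh:
        for cid, seq in fix.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(outdir / "proteins.faa", "w") as fh:
        for p in fix.proteome:
            fh.write(f">{p.protein_id} {p.description}\n{p.sequence}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("seq_id\tmode\tcontig_id\tnt_start\tnt_end\tstrand\t"
                 "aa_break\tin_proteome\tdetectable_sixframe\n")
        for t in fix.truth:
            fh.write(f"{t.seq_id}\t{t.mode}\t{t.contig_id}\t{t.nt_start}\t"
                     f"{t.nt_end}\t{t.strand}\t{t.aa_break or ''}\t"
                     f"{str(t.in_proteome).lower()}\t"
                     f"{str(t.detectable_sixframe).lower()}\n")


def curated_sequences_for_plants(
    plants: Sequence[PlantSpec], description: str
) -> tuple[list[CuratedEntry], dict[str, str]]:
    """Normalized entries + lookup describing the plants' source proteins.

    Convenience for tests and demos: each plant's ORIGINAL protein becomes
    one EcoCyc-style entry whose description contains ``description``, so a
    query for it selects exactly the planted curated sequences.
    """
    entries = []
    lookup = {}
    for spec in plants:
        sid = f"fix_{spec.seq_id}"
        lookup[sid] = spec.protein
        entries.append(CuratedEntry(
            entry_id=f"EcoCyc:{spec.seq_id}",
            source="EcoCyc",
            description=f"{description} {spec.seq_id}",
            publication_ids=["PMID:1"],
            uniprot_id=None,
            sequence_id=sid,
        ))
    return entries, lookup
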