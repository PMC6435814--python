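# Methods

## Overview

The package answers one question: *given a capability described in words,
which genes in this genome might provide it?* It does so by transferring
annotations only from experimentally characterized proteins, in four
stages: text match against curated descriptions, local alignment against
the predicted proteome, local alignment against the six-frame translation,
and a redundancy filter that keeps only six-frame hits not already
explained by a predicted protein.

## Curated database

Input is a normalized table (one row per curated entry) plus a protein
FASTA. Parsing the native formats of the eight supported source databases
is deliberately out of scope: those formats drift, while the retention
rules are stable. The rules applied per source:

| source          | retained when |
|-----------------|---------------|
| BRENDA, MetaCyc | UniProt id present, ≥ 1 publication, not a fragment |
| CAZy            | ≥ 1 EC number; description free of "fragment"/"frameshift" |
| CharProtDB      | entry type not `trusted_uniprot` (redundant with Swiss-Prot) or `trusted_aspgd` (vague) |
| REBASE          | enzyme's sequence specificity known |
| Swiss-Prot      | experimental evidence for the function |
| EcoCyc, Fitness Browser | always (already curated by construction) |

Evidence flags (fragment status, specificity, experimental evidence) are
supplied in the normalized input, not re-derived. Sequences are uppercased
and one trailing `*` is stripped; an internal `*` rejects the entry.
Entries with identical normalized sequences merge into one *distinct
sequence* — the unit that is aligned — so one protein curated by three
databases is aligned once and reported with all three descriptions.
Sequence ids are content digests (sha1 prefix), making the build
order-independent and reproducible. The database round-trips through a
single JSON file; per-source entry and distinct-sequence counts are also
written as a TSV.

## Query matching

Default mode is case-insensitive substring containment. `%` matches any
run of ≥ 0 characters; `_` is literal (only `%` is special). Whole-word
mode requires both ends of the matched span to lie on word boundaries. A
*word character* is a letter or digit, plus `.` or `-` when flanked by
alphanumerics on both sides — chosen so EC numbers (`1.1.1.1`) and
hyphenated names behave as single words. When wildcards and word mode
combine, only the overall match's two ends are boundary-checked; the
treatment of `/` and `+` inside chemical names as boundaries is a
documented package choice, as is rejecting queries consisting only of `%`.
Word-mode matching tries every boundary-legal span; descriptions are short
(tens of characters) so the quadratic scan is irrelevant to runtime.

## Alignment and scoring

Curated sequences are queries; predicted proteins and reading frames are
subjects. The built-in engine is exact Smith–Waterman (via
`Bio.Align.PairwiseAligner`, which is C-backed) under BLOSUM62 with affine
gap cost 11 + k for a gap of k columns — the convention matching the
published gapped Karlin–Altschul constants λ = 0.267, K = 0.041 used for
E-values, with search space = query length × summed target length and a
default cutoff of E ≤ 0.01. Residues U/O/J are scored as X.

Per (curated, target) pair only the single best alignment is kept; HSPs
are never merged, so coverage is the span of one alignment on the curated
sequence. Identity counts identical columns over all alignment columns,
gaps included — percent identity is not uniquely defined across tools, so
the choice is fixed and used consistently. The ranking score is
identity × coverage as fractions; percentages appear only in reports.
Among co-optimal alignments the engine's canonical traceback is returned;
it is deterministic across runs, which is the property the pipeline's
byte-reproducibility rests on. E-values here are a filter, not a ranking:
remote homology below ~30% identity is explicitly not a goal, so tightening
or loosening the cutoff buys little.

## Six-frame stage

Frames are maximal stop-free runs of ≥ 30 residues (configurable) in all
six phases; no start codon is required and splicing is ignored. The stage
runs only for genomes strictly under 30,000,000 nt. Coordinates are
1-based inclusive on the forward strand. The genetic code defaults to NCBI
table 11 (bacteria/archaea) and is configurable. Ambiguity codes translate
to the consensus residue when all disambiguations agree, to `X` when they
disagree, and to a stop when *any* disambiguation is a stop — conservative,
so N-runs cannot stitch two runs into one inflated frame.

The redundancy filter implements "noticeably better": a frame hit for a
curated sequence survives only if its score strictly exceeds 1.1× that
sequence's best protein-stage score, with the empty maximum taken as 0 (a
curated protein with no protein-stage hit at all is exactly the missing-gene
case the stage exists for). If a frame's best hit fails, the whole frame is
suppressed. Strict inequality means a tie is "expected, not news". The
comparison is per distinct curated sequence (the aligned unit), not per
curated entry.

## Synthetic fixtures

The generator produces everything the pipeline consumes. The curated
fixture emits entries exercising every retention rule, with a manifest of
expected decisions and expected distinct counts kept by the generator's
own bookkeeping (independent of the ingestion code). A duplicate fraction
controls how many retained entries share sequences.

The genome fixture reverse-translates chosen proteins (uniform synonymous
codons, same code table as translation, hence stop-free in frame) into an
i.i.d. background at a requested GC content, on random strands at
non-overlapping loci with a 90 nt buffer. Scenarios: present-and-annotated,
present-but-unannotated, frameshifted (one nucleotide deleted near the
middle codon, protein omitted from the proteome), and absent. For the
frameshift, each half remains stop-free in its own phase because it still
encodes real residues; where the protein's local sequence permits,
synonymous codons around the break are chosen so stop codons bound both
out-of-phase readings at the junction, guaranteeing that the two frames'
coverage intervals cannot overlap through chance matches in out-of-frame
sequence (otherwise the deletion simply lands mid-gene and a 1–2 residue
chance overlap is possible).

What the fixtures do **not** emulate: codon bias, repeats, operons, real
intergenic composition, sequencing error beyond the single planted
deletion, and paralog families. Passing tests therefore demonstrate the
pipeline's mechanics — matching semantics, frame extraction, scoring,
filtering, ranking — not retrieval performance on real genomes, which
depends on the curated database's coverage of the capability in question.

## Problem sizes and numerical choices

The test suite and the reproduction script use 8 kb genomes (≈ 200 reading
frames), 60–150 residue proteins, 100 random genomes for the translation
oracle, and 200 random pairs for the alignment oracle — sizes at which the
brute-force oracles (exhaustive Gotoh dynamic programming;
translate/split/filter) are exact and fast. Ties anywhere in ranking break
on identifiers so repeated runs are byte-identical. Degenerate inputs have
defined behaviour: empty target sets give empty hit lists; a query matching
nothing yields a valid empty report with the six-frame stage skipped; an
all-wildcard query is rejected.

## Limitations

* Sensitivity is bounded by exact Smith–Waterman under BLOSUM62 — adequate
  above ~30% identity, and remote homology is out of scope by design.
* E-values use fixed gapped Karlin–Altschul constants rather than
  composition-based statistics; they gate hits at 0.01 and are not
  comparable across engines at fine precision.
* The identity denominator (all columns, gaps included) and one-HSP
  coverage are documented stand-ins; other tools' percentages may differ
  by a few points on gappy alignments.
* Six-frame search reports reading frames, not gene models: boundaries are
  stop-to-stop, not start-to-stop.
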