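# curated-blast

Find candidate genes for a capability in a microbial genome **without
relying on automated annotations**.

Automated genome annotations are often vague or wrong, so searching
annotation text for, say, "perchlorate reductase" can miss the gene you
want — or find a misannotated one. This package takes the opposite route:
given a text query, it first selects proteins whose functions were
**experimentally characterized** and whose human-curated descriptions match
the query; it then searches the genome of interest for proteins similar to
those characterized proteins and ranks the candidates. Because the genome's
predicted protein set may itself be incomplete (missed gene calls,
frameshift errors from long-read assemblies), the search is repeated
against the genome's **six-frame translation**, reporting only frames that
are not already explained by a predicted protein.

## Method

1. **Query match.** A curated description matches if it contains the query
   as a case-insensitive substring; `%` is a wildcard (`chl%reduct` matches
   "Perchlorate reductase subunit alpha"); a whole-word mode requires the
   match to sit on word boundaries (`chlorate` matches "Chlorate reductase"
   but not "Perchlorate reductase"), with EC numbers such as `1.1.1.1`
   treated as single words.
2. **Protein stage.** The matched curated sequences are aligned
   (Smith–Waterman, BLOSUM62, affine gaps, E ≤ 0.01) against the genome's
   predicted proteins. Each hit is scored

   *score = identity × coverage*,

   where identity is the fraction of identical alignment columns and
   coverage is the fraction of the **curated** protein spanned by the
   alignment. Ranking by bit score would favour homologs of long proteins;
   identity × coverage rewards alignments that are both close and
   full-length, which is what supports a functional call. Hits are grouped
   per predicted protein, best first; groups with ≥ 4 hits show the top 3.
3. **Six-frame stage** (genomes under 30 Mb). Every stop-free stretch of
   ≥ 30 translated residues in the six frames is a candidate reading frame
   (no start codon required). Frame hits are kept only when their score is
   noticeably better — strictly more than 1.1× — than the best
   protein-stage score for the same curated sequence; if a frame's best hit
   fails this test the whole frame is dropped. What survives is evidence of
   a gene the annotation missed, including frameshift-split genes that show
   up as two nearby frames covering the N- and C-terminal portions.

A deterministic built-in aligner is included; external aligners producing
BLAST tabular output can be adapted to the same hit schema.

## Worked example

All inputs can be generated synthetically — no downloads. This plants three
genes in a random 10 kb genome: one annotated normally, one present in the
DNA but missing from the predicted proteins, and one disrupted by a 1 nt
deletion (and also missing from the predicted proteins):

```sh
curated-blast fixtures --kind genome --outdir demo --seed 3
curated-blast search --db demo/curated.db.json \
    --proteins demo/proteins.faa --genome demo/genome.fna \
    --query "synthetic planted protein" --out demo/results --format tsv
```

```
INFO query 'synthetic planted protein' matched 3 curated sequence(s)
INFO protein stage: 1 hit(s) in 1 group(s) [0.0s]
INFO six-frame stage: 208 frame(s), 4 hit(s), 3 kept after redundancy filter [0.2s]
```

Selected columns of `demo/results.tsv`:

```
stage     target_id        coords                  identity_pct  coverage_pct  score
protein   pred_plantA                              100           100           1.000000
sixframe  contig1|+1|1753  contig1:1753-2238(+1)   100           100           1.000000
sixframe  contig1|+1|7465  contig1:7465-7713(+1)   100           51            0.507143
sixframe  contig1|+2|7256  contig1:7256-7465(+2)   100           49            0.485714
```

Reading the table: the annotated gene (`plantA`) is found at the protein
stage at 100% identity over 100% of the curated protein, and its own
reading frames are filtered out of the six-frame report (expected, not
news). The unannotated intact gene is recovered as a single reading frame
covering the whole curated protein. The frameshifted gene appears as **two
adjacent reading frames in different phases** (`+2` then `+1`, meeting at
position 7465) covering the C- and N-terminal halves — the signature of a
frameshift error in the assembly.

`curated-blast build-db` ingests a curated-protein collection from a
normalized per-source TSV + FASTA, applies each source database's retention
rule (e.g. BRENDA and MetaCyc entries need a UniProt id and a publication;
CAZy entries need an EC number; Swiss-Prot entries need experimental
evidence), deduplicates identical sequences, and writes a single JSON
database plus a per-source entries/distinct-sequences table.

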