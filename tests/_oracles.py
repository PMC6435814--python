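"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by the most direct method
available, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import re

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# six-frame: translate all 6 frames, regex-split on stops, filter by length

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _oracle_codon(codon: str, table) -> str:
    import itertools
    aas = set()
    for bases in itertools.product(*(_IUPAC[b] for b in codon)):
        c = "".join(bases)
        aas.add("*" if c in table.stop_codons else table.forward_table[c])
    if "*" in aas:
        return "*"
    return aas.pop() if len(aas) == 1 else "X"


def oracle_reading_frames(genome: dict[str, str], min_aa: int = 30,
                          table_id: int = 11):
    """(contig, strand, frame, nt_start, nt_end, aa) tuples, brute force."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out = []
    for cid, seq in genome.items():
        seq = seq.upper()
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else str(Seq(seq).reverse_complement())
            for phase in (1, 2, 3):
                codons = [s[i:i + 3]
                          for i in range(phase - 1, len(s) - 2, 3)]
                aa = "".join(_oracle_codon(c, table) for c in codons)
                for m in re.finditer("[^*]+", aa):
                    if len(m.group()) < min_aa:
                        continue
                    a = (phase - 1) + 3 * m.start() + 1
                    b = (phase - 1) + 3 * m.end()
                    if strand == "-":
                        a, b = L - b + 1, L - a + 1
                    out.append((cid, strand, phase, a, b, m.group()))
    return sorted(out)


# ---------------------------------------------------------------------------
# alignment: exhaustive Gotoh local alignment, scores only, no heuristics

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def oracle_sw_score(a: str, b: str, gap_open: int = 11,
                    gap_extend: int = 1) -> float:
    """Optimal Smith–Waterman score; a gap of length k costs open + k*extend."""
    first = gap_open + gap_extend  # cost of a gap's first column
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (left move)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (up move)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


# ---------------------------------------------------------------------------
# six-frame redundancy filter: direct transcription of the two-step rule

def oracle_filter_sixframe(frame_hits, protein_hits, factor=1.1):
    """Keep frame hits scoring > factor x best protein score for the same
    curated sequence (0 when none); drop a whole frame when its best hit
    was dropped."""
    best_protein = {}
    for h in protein_hits:
        if h.score > best_protein.get(h.curated_seq_id, 0.0):
            best_protein[h.curated_seq_id] = h.score

    def kept(h):
        return h.score > factor * best_protein.get(h.curated_seq_id, 0.0)

    by_frame = {}
    for h in frame_hits:
        by_frame.setdefault(h.target_id, []).append(h)
    out = []
    for h in frame_hits:
        peers = by_frame[h.target_id]
        top = sorted(peers,
                     key=lambda x: (-x.score, x.curated_seq_id, x.target_id))[0]
        if kept(top) and kept(h):
            out.append(h)
    return out
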