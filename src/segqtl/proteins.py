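"""Small protein-sequence utilities for candidate-gene reporting.

Residue counts and pairwise global alignment statistics (percent identity
and percent similarity) over a stated residue range, for comparing
candidate regulators such as paralogous transcription factors.
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -0.5


def read_protein_fasta(path: str) -> dict[str, str]:
    """FASTA -> {id: sequence}; trailing stop symbols are stripped."""
    seqs = {}
    for rec in SeqIO.parse(path, "fasta"):
        seqs[rec.id] = str(rec.seq).rstrip("*")
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def residue_count(sequence: str) -> int:
    """Length in residues, excluding any stop symbol."""
    seq = sequence.rstrip("*")
    if not seq:
        raise ValueError("empty sequence")
    return len(seq)


def align_pair(
    a: str,
    b: str,
    region: tuple[int, int] | None = None,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> dict:
    """Global alignment of two peptides over an optional 1-based residue range.

    Identity = identical column pairs / aligned columns (gaps included);
    similarity additionally counts substitutions with a positive matrix
    score.  The scoring scheme is recorded in the result so reports are
    self-describing.
    """
    if region is not None:
        lo, hi = region
        a = a[lo - 1 : hi]
        b = b[lo - 1 : hi]
    if not a or not b:
        raise ValueError("empty sequence after applying region")
    subs = substitution_matrices.load(matrix)
    aligner = PairwiseAligner()
    aligner.substitution_matrix = subs
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.mode = "global"
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    columns = len(sa)
    ident = sim = 0
    for ca, cb in zip(sa, sb):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            ident += 1
            sim += 1
        elif subs[ca, cb] > 0:
            sim += 1
    return {
        "identity_pct": 100.0 * ident / columns,
        "similarity_pct": 100.0 * sim / columns,
        "aligned_columns": columns,
        "score": float(aln.score),
        "matrix": matrix,
        "gap_open": gap_open,
        "gap_extend": gap_extend,
    }


def protein_stats(
    sequences: dict[str, str], region: tuple[int, int] | None = None
) -> dict:
    """Lengths of all sequences plus pairwise alignment stats over a region."""
    lengths = {name: residue_count(seq) for name, seq in sequences.items()}
    pairs = {}
    names = list(sequences)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs[(names[i], names[j])] = align_pair(
                sequences[names[i]], sequences[names[j]], region=region
            )
    return {"lengths": lengths, "pairs": pairs, "region": region}
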