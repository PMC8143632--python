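"""Global pairwise protein alignment with affine gaps, EMBOSS-needle style.

Defaults mirror the classic needle protein setup: BLOSUM62 scoring, gap
open 10.0, gap extend 0.5 (a gap of length L costs 10 + 0.5L), end gaps
unpenalized.  Statistics follow the EMBOSS conventions: identity is the
percentage of alignment columns with identical residues, similarity the
percentage of columns whose substitution score is positive (identities
included), gaps the percentage of columns containing a gap character; all
three are percentages of the full alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from apmskit.io import DomainAnnotation, EXTENDED_ALPHABET, ProteinRecord


@dataclass(frozen=True)
class AlignmentResult:
    """A scored global alignment and its summary statistics (percentages of
    alignment length)."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    gaps_pct: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def rounded(self) -> tuple[int, int, int]:
        """(identity, similarity, gaps) rounded to whole percent, for
        comparison with values as printed by alignment tools."""
        return (
            round(self.identity_pct),
            round(self.similarity_pct),
            round(self.gaps_pct),
        )


def _check_sequence(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    seq = seq.upper()
    for i, aa in enumerate(seq):
        if aa not in EXTENDED_ALPHABET:
            raise ValueError(
                f"sequence {name}: illegal residue {aa!r} at position {i + 1}"
            )
    return seq


def _make_aligner(
    matrix: str | object,
    gap_open: float,
    gap_extend: float,
    penalize_end_gaps: bool,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if isinstance(matrix, str):
        matrix = substitution_matrices.load(matrix)
    aligner.substitution_matrix = matrix
    # In the needle convention a length-L gap costs open + L * extend, so the
    # first gap position carries open + extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if not penalize_end_gaps:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    return aligner


def needleman_wunsch_affine(
    seq_a: str,
    seq_b: str,
    matrix: str | object = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    penalize_end_gaps: bool = False,
) -> AlignmentResult:
    """Optimal global alignment under affine gap scoring.

    ``matrix`` is a substitution-matrix name understood by
    :mod:`Bio.Align.substitution_matrices` or a loaded matrix object.  When
    several alignments share the optimal score the first in the aligner's
    deterministic traversal order is reported; the score and the summary
    statistics of the reported alignment are what downstream comparisons
    use.
    """
    seq_a = _check_sequence(seq_a, "a")
    seq_b = _check_sequence(seq_b, "b")
    aligner = _make_aligner(matrix, gap_open, gap_extend, penalize_end_gaps)
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    gapped_a, gapped_b = str(best[0]), str(best[1])
    return _with_statistics(gapped_a, gapped_b, float(best.score),
                            aligner.substitution_matrix)


def _with_statistics(gapped_a, gapped_b, score, matrix) -> AlignmentResult:
    length = len(gapped_a)
    identical = similar = gapped = 0
    for x, y in zip(gapped_a, gapped_b):
        if x == "-" or y == "-":
            gapped += 1
            continue
        if x == y:
            identical += 1
        if matrix[x, y] > 0:
            similar += 1
    return AlignmentResult(
        gapped_a,
        gapped_b,
        score,
        100.0 * identical / length,
        100.0 * similar / length,
        100.0 * gapped / length,
    )


def extract_domain_sequence(protein: ProteinRecord, domain: DomainAnnotation) -> str:
    """Slice a domain's residues out of its protein (1-based inclusive)."""
    if domain.protein_id != protein.accession:
        raise ValueError(
            f"domain {domain.domain_name!r} annotates {domain.protein_id!r}, "
            f"not {protein.accession!r}"
        )
    if domain.end > protein.length:
        raise ValueError(
            f"domain {domain.domain_name!r} [{domain.start}, {domain.end}] "
            f"exceeds {protein.accession!r} length {protein.length}"
        )
    return protein.sequence[domain.start - 1:domain.end]


def domain_similarity(
    protein_a: ProteinRecord,
    domain_a: DomainAnnotation,
    protein_b: ProteinRecord,
    domain_b: DomainAnnotation,
    **aligner_kwargs,
) -> AlignmentResult:
    """Globally align two domain sub-ranges and report their statistics.

    Used to compare conserved domains between paralogs (e.g. the corepressor
    and C-terminal domains of the two Sin3 scaffolds).
    """
    sub_a = extract_domain_sequence(protein_a, domain_a)
    sub_b = extract_domain_sequence(protein_b, domain_b)
    return needleman_wunsch_affine(sub_a, sub_b, **aligner_kwargs)
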