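"""Mapping SNV loci through transcripts to protein and structure coordinates.

A coding SNV is located by a (chromosome, position) pair. To attach
protein-level features to it we need two mappings:

1. genomic position -> coding-sequence offset -> codon / protein residue,
   via an explicit exon model of the transcript (strand-aware);
2. protein residue -> residue in a homologous PDB structure, via global
   pairwise alignment of the reference protein sequence against the
   sequence extracted from the structure.

Conventions: genomic intervals are 1-based inclusive; CDS offsets are
0-based; codon positions are 1..3; protein positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .tables import AA_ALPHABET

__all__ = [
    "VariantLocus",
    "TranscriptModel",
    "CDSPosition",
    "AlignmentMap",
    "NoCDSMappingError",
    "map_genomic_to_cds",
    "min_junction_distance",
    "global_align",
    "select_homologs",
    "map_protein_to_structure",
]


class NoCDSMappingError(ValueError):
    """Raised when a genomic position has no coding-sequence image."""

    def __init__(self, position: int, reason: str):
        self.position = position
        super().__init__(f"no CDS mapping for genomic position {position}: {reason}")


@dataclass(frozen=True)
class VariantLocus:
    """A single-nucleotide variant with gene context and optional label."""

    chromosome: str
    position: int  # 1-based genomic coordinate
    gene: str
    wt_aa: Optional[str] = None
    mut_aa: Optional[str] = None
    label: Optional[str] = None  # "Benign" / "Pathogenic"
    maf: Optional[float] = None
    diseases: tuple = ()

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt_aa is not None and self.wt_aa not in AA_ALPHABET:
            raise ValueError(f"wt_aa {self.wt_aa!r} not a standard residue")

    @property
    def key(self) -> tuple:
        return (self.gene, self.chromosome, self.position,
                self.wt_aa or "", self.mut_aa or "")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of a coding transcript.

    ``exons`` are 1-based inclusive genomic [start, end] intervals sorted by
    genomic coordinate; ``cds_start_offset`` is the 0-based offset of the
    first coding base within the spliced (5'->3') transcript.
    """

    exons: tuple
    strand: str = "+"
    cds_start_offset: int = 0
    cds_length: Optional[int] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = 0
        for start, end in exons:
            if start > end:
                raise ValueError(f"exon [{start}, {end}] reversed")
            if start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end

    @property
    def spliced_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    def transcript_offset(self, position: int) -> int:
        """0-based offset of a genomic position within the spliced transcript.

        On the minus strand the transcript runs from the 3'-most genomic
        exon end backwards.
        """
        exons = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        offset = 0
        for start, end in exons:
            if start <= position <= end:
                if self.strand == "+":
                    return offset + (position - start)
                return offset + (end - position)
            offset += end - start + 1
        raise NoCDSMappingError(position, "position not in any exon")


@dataclass(frozen=True)
class CDSPosition:
    """Location of a base within the coding sequence and encoded protein."""

    cds_offset: int  # 0-based
    codon_index: int  # 1-based
    codon_position: int  # 1..3 ("CodPos")

    @property
    def protein_position(self) -> int:
        return self.codon_index


def map_genomic_to_cds(locus: VariantLocus, tx: TranscriptModel) -> CDSPosition:
    """Map a genomic SNV position to CDS offset, codon index/phase and residue.

    Raises :class:`NoCDSMappingError` for intronic positions or positions in
    untranslated regions.
    """
    tx_offset = tx.transcript_offset(locus.position)
    cds_offset = tx_offset - tx.cds_start_offset
    if cds_offset < 0:
        raise NoCDSMappingError(locus.position, "upstream of CDS start (5' UTR)")
    cds_len = tx.cds_length
    if cds_len is None:
        cds_len = tx.spliced_length - tx.cds_start_offset
    if cds_offset >= cds_len:
        raise NoCDSMappingError(locus.position, "downstream of CDS end (3' UTR)")
    return CDSPosition(
        cds_offset=cds_offset,
        codon_index=cds_offset // 3 + 1,
        codon_position=cds_offset % 3 + 1,
    )


def min_junction_distance(locus: VariantLocus, tx: TranscriptModel) -> Optional[int]:
    """Genomic distance (nt) to the closest exon/intron junction base.

    A junction base is the exonic base adjacent to an intron (last base of
    an upstream exon or first base of a downstream exon). Single-exon
    transcripts have no junctions and return ``None``. Raises for intronic
    positions.
    """
    tx.transcript_offset(locus.position)  # validates exonic
    if len(tx.exons) < 2:
        return None
    boundaries = []
    for i, (start, end) in enumerate(tx.exons):
        if i > 0:
            boundaries.append(start)
        if i < len(tx.exons) - 1:
            boundaries.append(end)
    return min(abs(locus.position - b) for b in boundaries)


@dataclass
class AlignmentMap:
    """Column-level correspondence from a global pairwise alignment.

    ``pairs`` lists one (ref_position, other_position) tuple per alignment
    column, 1-based, with ``None`` on the gapped side. ``percent_identity``
    is matches over non-double-gap columns, in percent.
    """

    pairs: list
    percent_identity: float
    score: float
    _forward: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._forward = {a: b for a, b in self.pairs if a is not None and b is not None}

    def mapped(self, ref_position: int) -> Optional[int]:
        return self._forward.get(ref_position)


def _substitution_score(matrix, a: str, b: str, x_score: float = 0.0) -> float:
    if a == "X" or b == "X":
        return x_score
    return float(matrix[a, b])


def _load_matrix(matrix):
    if matrix is None or isinstance(matrix, str):
        return substitution_matrices.load(matrix or "BLOSUM62")
    return matrix


def global_align(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix=None,
) -> AlignmentMap:
    """Needleman-Wunsch global alignment with affine gaps (Gotoh recursion).

    A gap of length k costs ``gap_open + k * gap_extend``. ``matrix`` is a
    Biopython substitution matrix or its name (default BLOSUM62); pairs
    involving ``X`` score 0. Ties in the traceback resolve deterministically,
    preferring a substitution column over a gap in ``seq_b`` over a gap in
    ``seq_a``.

    Empty input on either side yields an all-gap map with identity 0.
    """
    if not seq_a or not seq_b:
        pairs = [(i + 1, None) for i in range(len(seq_a))]
        pairs += [(None, j + 1) for j in range(len(seq_b))]
        return AlignmentMap(pairs=pairs, percent_identity=0.0, score=0.0)

    sub = _load_matrix(matrix)
    n, m = len(seq_a), len(seq_b)
    neg = -np.inf
    # M: column consumes both; Ix: gap in seq_b (consumes a); Iy: gap in seq_a
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)
    open_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            s = _substitution_score(sub, ai, seq_b[j - 1])
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + s
            Ix[i, j] = max(M[i - 1, j] - open_cost, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - open_cost, Iy[i, j - 1] - gap_extend)

    # traceback with deterministic state preference M > Ix > Iy
    i, j = n, m
    state = max(("M", "Ix", "Iy"), key=lambda st: ({"M": M, "Ix": Ix, "Iy": Iy}[st][i, j], {"M": 2, "Ix": 1, "Iy": 0}[st]))
    score = {"M": M, "Ix": Ix, "Iy": Iy}[state][n, m]
    rev_pairs = []
    while i > 0 or j > 0:
        if state == "M":
            rev_pairs.append((i, j))
            s = _substitution_score(sub, seq_a[i - 1], seq_b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if np.isclose(mat[i, j], target):
                    state = st
                    break
        elif state == "Ix":
            rev_pairs.append((i, None))
            if i == 1 and j == 0:
                i, state = 0, "M"
            elif np.isclose(Ix[i, j], M[i - 1, j] - open_cost):
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "Ix"
        else:  # Iy
            rev_pairs.append((None, j))
            if j == 1 and i == 0:
                j, state = 0, "M"
            elif np.isclose(Iy[i, j], M[i, j - 1] - open_cost):
                j, state = j - 1, "M"
            else:
                j, state = j - 1, "Iy"
    pairs = rev_pairs[::-1]
    matches = sum(
        1 for a, b in pairs
        if a is not None and b is not None and seq_a[a - 1] == seq_b[b - 1]
    )
    identity = 100.0 * matches / len(pairs) if pairs else 0.0
    return AlignmentMap(pairs=pairs, percent_identity=identity, score=float(score))


def select_homologs(
    candidates: Sequence[tuple],
    min_identity: float = 60.0,
) -> list:
    """Keep (structure_id, AlignmentMap) candidates at or above the homology
    threshold (percent identity, default 60), preserving input order."""
    return [
        (sid, amap) for sid, amap in candidates
        if amap.percent_identity >= min_identity
    ]


def map_protein_to_structure(protein_position: int, amap: AlignmentMap) -> Optional[int]:
    """Structure residue index aligned to a 1-based reference position, or
    ``None`` when the position sits opposite a gap."""
    ref_positions = [a for a, _ in amap.pairs if a is not None]
    if not ref_positions:
        return None
    if protein_position < 1 or protein_position > max(ref_positions):
        raise IndexError(
            f"protein position {protein_position} outside reference range "
            f"1..{max(ref_positions)}"
        )
    return amap.mapped(protein_position)
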