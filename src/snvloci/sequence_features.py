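"""Sequence-based loci features from multiple sequence alignments.

For the alignment column under a variant position we compute:

* ``SeqCons`` — 1 minus the normalized Shannon entropy of the weighted
  residue distribution (1 = perfectly conserved, 0 = uniform over the
  20 amino acids);
* ``Nobs``   — the unweighted number of non-gap rows at the column
  (alignment depth);
* ``PSIC``   — a profile log-odds score log10(f_hat(a) / p(a)) of an amino
  acid against a background distribution, with weighted observed
  frequencies smoothed by one pseudocount mass of background.

Rows are weighted with Henikoff position-based weights so that redundant
sequences do not dominate the profile: duplicating every row leaves all
column statistics unchanged.

Wild-type-vs-mutant difference features (``delta_psic``, Grantham distance,
``delta_kd``) are computed here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .tables import AA_ALPHABET, GRANTHAM, KYTE_DOOLITTLE

__all__ = [
    "MSA", "ColumnProfile", "SequenceFeatureSet", "MutationFeatureSet",
    "henikoff_weights", "column_profile", "seq_conservation", "n_observed",
    "psic_score", "mutation_deltas", "sequence_features",
]

GAP_CHARS = set("-.")
UNIFORM_BACKGROUND = {aa: 1.0 / 20.0 for aa in AA_ALPHABET}


@dataclass
class MSA:
    """Equal-length gapped protein sequences; one row is the query."""

    sequences: List[str]
    ids: Optional[List[str]] = None
    query_index: int = 0

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("MSA needs at least one sequence")
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise ValueError("MSA rows must have equal length")
        if self.ids is None:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_cols(self) -> int:
        return len(self.sequences[0])

    def column(self, col: int) -> str:
        return "".join(s[col] for s in self.sequences)

    def query_column_index(self, ref_position: int) -> int:
        """Alignment column of the 1-based, gap-stripped query position."""
        seen = 0
        for col, ch in enumerate(self.sequences[self.query_index]):
            if ch not in GAP_CHARS:
                seen += 1
                if seen == ref_position:
                    return col
        raise IndexError(
            f"reference position {ref_position} beyond query length {seen}"
        )


def henikoff_weights(msa: MSA) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, normalized to
    sum to 1 over rows.

    At each column a row holding residue ``a`` receives 1 / (r * n_a) where
    r is the number of distinct residues in the column and n_a the count of
    ``a``; gap positions contribute nothing. With this scheme the raw
    per-column contributions already sum to 1, so the total column weight is
    invariant under row duplication.
    """
    n = msa.n_rows
    raw = np.zeros(n)
    for col in range(msa.n_cols):
        column = msa.column(col)
        counts: Dict[str, int] = {}
        for ch in column:
            if ch not in GAP_CHARS:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue
        r = len(counts)
        for row, ch in enumerate(column):
            if ch not in GAP_CHARS:
                raw[row] += 1.0 / (r * counts[ch])
    total = raw.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return raw / total


@dataclass
class ColumnProfile:
    """Weighted residue composition of one alignment column."""

    counts: Dict[str, float] = field(default_factory=dict)
    total_weight: float = 0.0
    n_nongap: int = 0
    background: Dict[str, float] = field(default_factory=lambda: dict(UNIFORM_BACKGROUND))

    @property
    def empty(self) -> bool:
        return self.n_nongap == 0 or self.total_weight <= 0

    def frequencies(self) -> Dict[str, float]:
        if self.empty:
            return {}
        return {aa: w / self.total_weight for aa, w in self.counts.items()}


def column_profile(
    msa: MSA,
    ref_position: int,
    background: Optional[Dict[str, float]] = None,
    weights: Optional[np.ndarray] = None,
) -> ColumnProfile:
    """Weighted residue profile at the column under a 1-based query position.

    Gaps contribute neither weight nor counts. ``weights`` may carry
    precomputed Henikoff weights to amortize across columns.
    """
    col = msa.query_column_index(ref_position)
    if weights is None:
        weights = henikoff_weights(msa)
    profile = ColumnProfile(background=dict(background or UNIFORM_BACKGROUND))
    for row, seq in enumerate(msa.sequences):
        ch = seq[col]
        if ch in GAP_CHARS:
            continue
        profile.n_nongap += 1
        if ch in AA_ALPHABET:
            profile.counts[ch] = profile.counts.get(ch, 0.0) + float(weights[row])
            profile.total_weight += float(weights[row])
    return profile


def seq_conservation(profile: ColumnProfile) -> float:
    """SeqCons = 1 - H(p) / log2(20) over normalized weighted counts."""
    freqs = profile.frequencies()
    if not freqs:
        return float("nan")
    h = -sum(p * math.log2(p) for p in freqs.values() if p > 0)
    return 1.0 - h / math.log2(20.0)


def n_observed(profile: ColumnProfile, distinct: bool = False) -> int:
    """Nobs: non-gap depth at the column (or distinct residue types when
    ``distinct`` is set)."""
    if distinct:
        return sum(1 for w in profile.counts.values() if w > 0)
    return profile.n_nongap


def psic_score(
    profile: ColumnProfile,
    aa: str,
    pseudocount: float = 1.0,
) -> float:
    """Profile log-odds of residue ``aa`` at the column.

    PSIC(a) = log10( f_hat(a) / p(a) ) with
    f_hat(a) = (c_w(a) + g * p(a)) / (W + g), where c_w is the weighted
    count, W the total column weight and g the pseudocount mass (default 1).
    """
    if profile.empty:
        return float("nan")
    p = profile.background.get(aa)
    if p is None or p <= 0:
        return float("nan")
    c = profile.counts.get(aa, 0.0)
    f_hat = (c + pseudocount * p) / (profile.total_weight + pseudocount)
    return math.log10(f_hat / p)


@dataclass
class SequenceFeatureSet:
    """The five sequence-based loci features."""

    PSIC: float = float("nan")
    Nobs: float = float("nan")
    SeqCons: float = float("nan")
    MinDJxn: float = float("nan")
    CodPos: float = float("nan")

    def as_dict(self) -> Dict[str, float]:
        return {
            "PSIC": self.PSIC, "Nobs": self.Nobs, "SeqCons": self.SeqCons,
            "MinDJxn": self.MinDJxn, "CodPos": self.CodPos,
        }


@dataclass
class MutationFeatureSet:
    """Wild-type-vs-mutant difference features."""

    delta_psic: float = float("nan")
    grantham: float = float("nan")
    delta_kd: float = float("nan")

    def as_dict(self) -> Dict[str, float]:
        return {
            "delta_psic": self.delta_psic,
            "grantham": self.grantham,
            "delta_kd": self.delta_kd,
        }


def mutation_deltas(
    wt: str,
    mut: str,
    profile: Optional[ColumnProfile] = None,
) -> MutationFeatureSet:
    """Differences between wild-type and mutant residue at the locus."""
    if wt not in AA_ALPHABET or mut not in AA_ALPHABET:
        return MutationFeatureSet()
    out = MutationFeatureSet(
        grantham=GRANTHAM[(wt, mut)],
        delta_kd=KYTE_DOOLITTLE[wt] - KYTE_DOOLITTLE[mut],
    )
    if profile is not None and not profile.empty:
        out.delta_psic = psic_score(profile, wt) - psic_score(profile, mut)
    return out


def sequence_features(
    msa: MSA,
    ref_position: int,
    wt_aa: str,
    min_junction_distance: Optional[float] = None,
    codon_position: Optional[int] = None,
    background: Optional[Dict[str, float]] = None,
) -> SequenceFeatureSet:
    """Bundle the five sequence features for one locus."""
    profile = column_profile(msa, ref_position, background=background)
    return SequenceFeatureSet(
        PSIC=psic_score(profile, wt_aa),
        Nobs=float(n_observed(profile)),
        SeqCons=seq_conservation(profile),
        MinDJxn=float("nan") if min_junction_distance is None else float(min_junction_distance),
        CodPos=float("nan") if codon_position is None else float(codon_position),
    )
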