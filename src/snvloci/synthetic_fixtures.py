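"""Synthetic structures, alignments and feature tables with known ground truth.

Everything the pipeline consumes can be generated here from a single seed:

* ideal alpha-helix PDB files (target dihedrals phi = -57, psi = -47) with
  optional extra chains and het groups, for the structure-feature stage;
* MSAs whose per-column conservation tracks a requested profile, for the
  sequence-feature stage;
* labeled two-class Gaussian feature tables over the named loci features,
  with configurable per-feature class separations and missing rate, for the
  classifier stage — including a set of four benchmark-shaped tables that
  mirror the class sizes of the published variant benchmarks
  (8,112-row train; 2,028 / 437 / 280-row test sets).

The default per-feature separations decrease with the published importance
rank of each feature, so that the strongest synthetic signal sits on the
features reported as most informative (PSIC first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset_assembly import (
    ALL_PRIOR_FEATURES,
    KEY_COLUMNS,
    LABEL_COLUMN,
    MUTATION_FEATURES,
)
from .sequence_features import MSA
from .tables import AA_ALPHABET, ONE_TO_THREE

__all__ = [
    "FixtureConfig", "make_helix_structure", "make_msa",
    "make_labeled_dataset", "make_benchmark_tables", "DEFAULT_EFFECT_SIZES",
]

# ideal backbone geometry (lengths in A, angles in degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA = 180.0

#: published importance ranks of the 16 loci features (1 = most important)
FEATURE_RANKS = {
    "PSIC": 1, "KDmean": 2, "Nobs": 3, "RSAmax": 4, "nRSA": 5, "nNum": 6,
    "Bstddev": 7, "nB": 8, "MinDJxn": 9, "nKD": 10, "CodPos": 11,
    "SeqCons": 12, "nSC": 13, "nBinding": 14, "Binding": 15, "Mapreg": 16,
}


def _rank_effect(rank: int, top: float = 1.5, decay: float = 0.87) -> float:
    return top * decay ** (rank - 1)


#: default class-mean separations (in SD units) per feature; rank-ordered
#: for the 16 loci features, with moderate extra signal on the three
#: wild-type-difference features.
DEFAULT_EFFECT_SIZES: Dict[str, float] = {
    **{name: _rank_effect(rank) for name, rank in FEATURE_RANKS.items()},
    "delta_psic": 1.3, "grantham": 1.0, "delta_kd": 0.7,
}


@dataclass
class FixtureConfig:
    seed: int = 0
    n_residues: int = 20
    n_sequences: int = 50
    n_rows: int = 500
    conservation_profile: Sequence[float] = ()
    effect_sizes: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if any(not 0.0 <= c <= 1.0 for c in self.conservation_profile):
            raise ValueError("conservation_profile values must be in [0, 1]")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position a new atom at the given internal coordinates
    relative to the chain a-b-c."""
    angle = math.radians(angle_deg)
    dihedral = -math.radians(dihedral_deg)  # frame below is left-handed w.r.t. IUPAC torsion sign
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resnum: int, xyz: np.ndarray, occ: float, b: float,
                   element: str, het: bool = False) -> str:
    record = "HETATM" if het else "ATOM  "
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:5d} {pad_name}{'':1s}{resname:>3s} {chain}"
        f"{resnum:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


def _helix_backbone(n_residues: int) -> List[Dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates of an ideal alpha-helix."""
    residues: List[Dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = residues[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"],
                             BOND_C_N, ANGLE_CA_C_N, HELIX_PSI)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next,
                              BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = _place_atom(prev["C"], n_next, ca_next,
                             BOND_CA_C, ANGLE_N_CA_C, HELIX_PHI)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            # carbonyl O anti to the next amide N
            res["O"] = _place_atom(residues[i + 1]["N"], res["CA"], res["C"],
                                   BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            res["O"] = _place_atom(res["N"], res["CA"], res["C"],
                                   BOND_C_O, ANGLE_CA_C_O, HELIX_PSI + 180.0)
    return residues


def make_helix_structure(
    n_residues: int,
    sequence: Optional[str] = None,
    bfactor_profile: Optional[Sequence[float]] = None,
    seed: int = 0,
    chain_ids: Sequence[str] = ("A",),
    chain_offset: float = 30.0,
    het_atoms: Sequence[tuple] = (),
) -> str:
    """PDB text for one or more ideal alpha-helix chains.

    ``sequence`` defaults to a seeded random 20-letter sequence;
    ``bfactor_profile`` gives one B-factor per residue (default: seeded
    values around 20 A^2). Extra ``chain_ids`` produce translated copies
    of the helix (``chain_offset`` A apart along x). ``het_atoms`` is a
    sequence of (element, resname, (x, y, z)) monoatomic het groups.
    Byte-identical output for equal arguments.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(AA_ALPHABET), size=n_residues))
    sequence = sequence.upper()
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    bad = [ch for ch in sequence if ch not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"invalid residue letters: {bad}")
    if bfactor_profile is None:
        bfactor_profile = 20.0 + 5.0 * rng.standard_normal(n_residues)
    if len(bfactor_profile) != n_residues:
        raise ValueError("bfactor_profile length must equal n_residues")

    backbone = _helix_backbone(n_residues)
    lines: List[str] = []
    serial = 1
    for ci, chain in enumerate(chain_ids):
        shift = np.array([chain_offset * ci, 0.0, 0.0])
        for i, res in enumerate(backbone):
            resname = ONE_TO_THREE[sequence[i]]
            for atom_name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                lines.append(_pdb_atom_line(
                    serial, atom_name, resname, chain, i + 1,
                    res[atom_name] + shift, 1.0, float(bfactor_profile[i]), element,
                ))
                serial += 1
        lines.append(f"TER   {serial:5d}      {ONE_TO_THREE[sequence[-1]]:>3s} {chain}{n_residues:4d}")
        serial += 1
    het_resnum = 900
    for element, resname, xyz in het_atoms:
        lines.append(_pdb_atom_line(
            serial, element.upper(), resname, "X", het_resnum,
            np.asarray(xyz, dtype=float), 1.0, 20.0, element.upper(), het=True,
        ))
        serial += 1
        het_resnum += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _q_for_conservation(target: float) -> float:
    """Consensus probability q such that the mixture (q on the consensus,
    1-q spread uniformly) has normalized-entropy conservation ~= target."""
    qs = np.linspace(0.0, 1.0, 401)
    best_q, best_err = 0.0, np.inf
    log20 = math.log2(20.0)
    for q in qs:
        p = np.full(20, (1.0 - q) / 20.0)
        p[0] += q
        cons = 1.0 - _entropy_bits(p) / log20
        err = abs(cons - target)
        if err < best_err:
            best_q, best_err = q, err
    return best_q


def make_msa(
    n_sequences: int,
    length: int,
    conservation_profile: Optional[Sequence[float]] = None,
    seed: int = 0,
    query_sequence: Optional[str] = None,
) -> MSA:
    """Sample an MSA whose realized column conservation tracks a profile.

    Each column draws from a consensus-plus-uniform mixture whose consensus
    weight is tuned to the requested conservation. The query row (row 0) is
    forced to the consensus residue so reference positions stay defined.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if conservation_profile is None:
        conservation_profile = [0.7] * length
    if len(conservation_profile) != length:
        raise ValueError("conservation_profile length must equal MSA length")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AA_ALPHABET))
    if query_sequence is not None:
        if len(query_sequence) != length:
            raise ValueError("query_sequence length mismatch")
        consensus = list(query_sequence.upper())
    else:
        consensus = list(rng.choice(alphabet, size=length))
    columns = []
    for col in range(length):
        q = _q_for_conservation(float(conservation_profile[col]))
        draws = rng.random(n_sequences)
        uniform = rng.choice(alphabet, size=n_sequences)
        col_chars = np.where(draws < q, consensus[col], uniform)
        col_chars[0] = consensus[col]
        columns.append(col_chars)
    rows = ["".join(columns[c][r] for c in range(length)) for r in range(n_sequences)]
    return MSA(sequences=rows, ids=[f"s{i}" for i in range(n_sequences)], query_index=0)


def _random_keys(n: int, rng: np.random.Generator) -> pd.DataFrame:
    positions = rng.choice(np.arange(1_000, 50_000_000), size=n, replace=False)
    return pd.DataFrame({
        "gene": [f"GENE{i:05d}" for i in range(n)],
        "chromosome": rng.choice([str(c) for c in range(1, 23)] + ["X"], size=n),
        "position": positions,
        "wt_aa": rng.choice(list(AA_ALPHABET), size=n),
        "mut_aa": rng.choice(list(AA_ALPHABET), size=n),
    })


def make_labeled_dataset(
    n_rows: int,
    effect_sizes: Optional[Dict[str, float]] = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    pathogenic_fraction: float = 0.679,
    include_mutation_features: bool = True,
    include_keys: bool = True,
) -> pd.DataFrame:
    """Two-class Gaussian feature table over the named loci features.

    Benign rows draw each feature from N(0, 1); pathogenic rows from
    N(d_f, 1) where d_f is the per-feature class separation in SD units.
    Missing values are injected uniformly at random at ``missing_rate``.
    The default pathogenic fraction matches the published benchmark
    composition (6,884 / 10,140).
    """
    if n_rows < 10:
        raise ValueError("n_rows must be >= 10")
    if effect_sizes is None:
        effect_sizes = DEFAULT_EFFECT_SIZES
    rng = np.random.default_rng(seed)
    feature_names = list(ALL_PRIOR_FEATURES)
    if include_mutation_features:
        feature_names += list(MUTATION_FEATURES)
    n_path = int(round(n_rows * pathogenic_fraction))
    labels = np.array(["Pathogenic"] * n_path + ["Benign"] * (n_rows - n_path))
    rng.shuffle(labels)
    is_path = labels == "Pathogenic"
    data = {}
    for name in feature_names:
        d = float(effect_sizes.get(name, 0.0))
        values = rng.standard_normal(n_rows)
        values[is_path] += d
        data[name] = values
    df = pd.DataFrame(data)
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask)
    df[LABEL_COLUMN] = labels
    if include_keys:
        keys = _random_keys(n_rows, rng)
        df = pd.concat([keys, df], axis=1)
    return df


#: class sizes of the four published benchmark tables
BENCHMARK_SIZES = {
    "humvd_train": (2591, 5521),
    "humvd_test": (665, 1363),
    "clinvar": (152, 285),
    "clinvar_rvrd": (117, 163),
}


def make_benchmark_tables(
    seed: int = 0,
    effect_sizes: Optional[Dict[str, float]] = None,
    missing_rate: float = 0.02,
    rare_disease_names: Sequence[str] = ("RareDisease1", "RareDisease2"),
) -> Dict[str, pd.DataFrame]:
    """Synthetic stand-ins for the four benchmark feature tables.

    Shapes and class balances mirror the published train / test / ClinVar /
    rare-variant-rare-disease splits; feature distributions follow
    :func:`make_labeled_dataset`. The ClinVar-like tables additionally carry
    ``maf`` and ``diseases`` columns so the rare-variant filter can be
    exercised end to end. These are synthetic emulations, not the published
    data.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, pd.DataFrame] = {}
    for i, (name, (n_benign, n_path)) in enumerate(BENCHMARK_SIZES.items()):
        n = n_benign + n_path
        df = make_labeled_dataset(
            n_rows=n,
            effect_sizes=effect_sizes,
            missing_rate=missing_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            pathogenic_fraction=n_path / n,
        )
        if name.startswith("clinvar"):
            maf = rng.uniform(0.0, 0.009, size=n)
            df["maf"] = maf
            diseases = rng.choice(list(rare_disease_names) + ["CommonDisease"], size=n)
            if name == "clinvar_rvrd":
                diseases = rng.choice(list(rare_disease_names), size=n)
            df["diseases"] = diseases
        out[name] = df
    return out
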