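"""Glue joining the mapping, structure and sequence stages per variant."""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import pandas as pd

from . import structure_features as sf
from .io import chain_sequence
from .locus_mapping import global_align, map_protein_to_structure, select_homologs
from .sequence_features import MSA, column_profile, mutation_deltas, sequence_features

__all__ = ["structure_block_for_position", "sequence_block_for_position"]


def structure_block_for_position(
    ref_seq: str,
    structures: Dict[str, sf.Structure],
    protein_position: int,
    min_identity: float = 60.0,
    radius: float = sf.DEFAULT_NEIGHBOR_RADIUS,
    conservation: Optional[Dict[str, Dict[tuple, float]]] = None,
    asa_cache: Optional[Dict[str, Dict[tuple, float]]] = None,
) -> sf.AggregatedStructureFeatures:
    """Aggregate structure features for one protein position.

    Each candidate structure's first protein chain is globally aligned to
    the reference sequence; structures passing the homology threshold and
    resolving the position contribute one per-structure feature set.
    ``conservation`` optionally maps structure id -> residue id -> SeqCons
    for the nSC neighborhood feature. Returns an all-missing record when no
    structure maps the position.
    """
    candidates = []
    chain_maps = {}
    for sid, structure in structures.items():
        chains = structure.protein_chains()
        if not chains:
            continue
        seq, residues = chain_sequence(chains[0])
        amap = global_align(ref_seq, seq)
        candidates.append((sid, amap))
        chain_maps[sid] = residues
    kept = select_homologs(candidates, min_identity=min_identity)
    per_structure = []
    for sid, amap in kept:
        pos = map_protein_to_structure(protein_position, amap)
        if pos is None:
            continue
        residue = chain_maps[sid][pos - 1]
        structure = structures[sid]
        asa = asa_cache.get(sid) if asa_cache is not None else None
        if asa is None:
            asa = sf.compute_asa(structure)
            if asa_cache is not None:
                asa_cache[sid] = asa
        per_structure.append(sf.per_structure_features(
            structure, residue,
            neighbor_conservation=(conservation or {}).get(sid),
            radius=radius, asa=asa,
        ))
    return sf.aggregate_structures(per_structure)


def sequence_block_for_position(
    msa: MSA,
    protein_position: int,
    wt_aa: str,
    mut_aa: Optional[str] = None,
    min_junction_distance: Optional[float] = None,
    codon_position: Optional[int] = None,
):
    """Sequence feature set (and mutation deltas when ``mut_aa`` is given)."""
    feats = sequence_features(
        msa, protein_position, wt_aa,
        min_junction_distance=min_junction_distance,
        codon_position=codon_position,
    )
    deltas = None
    if mut_aa is not None:
        profile = column_profile(msa, protein_position)
        deltas = mutation_deltas(wt_aa, mut_aa, profile)
    return feats, deltas
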