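"""Readers and writers for the file formats the pipeline touches.

FASTA (plain and aligned), BED12 and minimal GFF3 transcript models,
variant TSV tables, and a YAML schema manifest. Sequence parsing goes
through Biopython; tabular data through pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml
from Bio import SeqIO

from .locus_mapping import TranscriptModel
from .sequence_features import MSA

__all__ = [
    "read_fasta", "write_fasta", "read_msa_fasta", "read_bed12",
    "read_gff3_transcripts", "read_variant_table", "write_table",
    "write_schema_manifest", "chain_sequence",
]

VARIANT_COLUMNS = ["chromosome", "position", "gene", "wt_aa", "mut_aa", "label", "maf"]


def read_fasta(path) -> Dict[str, str]:
    """Id -> sequence mapping from a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_msa_fasta(path, query_id: Optional[str] = None) -> MSA:
    """Aligned FASTA -> MSA; the query row is ``query_id`` or the first record."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    query_index = ids.index(query_id) if query_id is not None else 0
    return MSA(
        sequences=[str(r.seq) for r in records],
        ids=ids,
        query_index=query_index,
    )


def read_bed12(path) -> Dict[str, TranscriptModel]:
    """BED12 -> TranscriptModel per record name.

    Exons come from the block structure; the CDS start offset within the
    spliced transcript is derived from thickStart/thickEnd, strand-aware.
    """
    models: Dict[str, TranscriptModel] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"BED12 requires 12 columns, got {len(f)}")
        chrom_start = int(f[1])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = tuple(
            (chrom_start + s + 1, chrom_start + s + size)
            for s, size in zip(starts, sizes)
        )
        model = TranscriptModel(exons=exons, strand=strand)
        if thick_end > thick_start:
            first_coding = thick_start + 1 if strand == "+" else thick_end
            offset = model.transcript_offset(first_coding)
            cds_len = sum(
                max(0, min(end, thick_end) - max(start, thick_start + 1) + 1)
                for start, end in exons
            )
            model = TranscriptModel(
                exons=exons, strand=strand,
                cds_start_offset=offset, cds_length=cds_len,
            )
        models[name] = model
    return models


def _gff_attributes(text: str) -> Dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_transcripts(path) -> Dict[str, TranscriptModel]:
    """Minimal GFF3 reader: groups exon/CDS features by Parent attribute."""
    exons: Dict[str, List[tuple]] = {}
    cds: Dict[str, List[tuple]] = {}
    strands: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            continue
        ftype, start, end, strand = f[2], int(f[3]), int(f[4]), f[6]
        parent = _gff_attributes(f[8]).get("Parent") or _gff_attributes(f[8]).get("ID")
        if parent is None:
            continue
        strands[parent] = strand
        if ftype == "exon":
            exons.setdefault(parent, []).append((start, end))
        elif ftype == "CDS":
            cds.setdefault(parent, []).append((start, end))
    models: Dict[str, TranscriptModel] = {}
    for name, ex in exons.items():
        ex = tuple(sorted(ex))
        strand = strands[name]
        model = TranscriptModel(exons=ex, strand=strand)
        if name in cds:
            spans = sorted(cds[name])
            first_coding = spans[0][0] if strand == "+" else spans[-1][1]
            offset = model.transcript_offset(first_coding)
            length = sum(e - s + 1 for s, e in spans)
            model = TranscriptModel(
                exons=ex, strand=strand,
                cds_start_offset=offset, cds_length=length,
            )
        models[name] = model
    return models


def read_variant_table(path, sep: str = "\t") -> pd.DataFrame:
    """Variant TSV with columns chromosome, position, gene, wt_aa, mut_aa,
    and optional label / maf / diseases."""
    df = pd.read_csv(path, sep=sep, dtype={"chromosome": str})
    required = {"chromosome", "position", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table lacks columns: {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    return df


def write_table(df: pd.DataFrame, path, sep: Optional[str] = None) -> None:
    sep = sep or ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    df.to_csv(path, sep=sep, index=False)


def write_schema_manifest(columns: Dict[str, Dict], path) -> None:
    """YAML manifest naming each column's kind and provenance."""
    with open(path, "w") as fh:
        yaml.safe_dump({"columns": columns}, fh, sort_keys=False)


def chain_sequence(chain) -> tuple:
    """One-letter sequence of a protein chain plus the parallel residue list.

    The i-th letter (1-based position i+1) corresponds to the i-th returned
    residue, which is how alignment columns map back onto structure
    residues.
    """
    seq = []
    residues = []
    for res in chain.residues:
        seq.append(res.one_letter)
        residues.append(res)
    return "".join(seq), residues
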