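# snvloci

Structure-aware prioritization of single-nucleotide variant (SNV) loci.

Most missense-variant predictors lean on sequence conservation and on the
wild-type/mutant difference. `snvloci` asks a complementary question: how
much of a variant's pathogenicity can be read off from *where* it sits —
independent of what it mutates into — once the locus is placed into 3-D
protein structure? The package computes 16 "prior" features of a coding
variant position and trains a random-forest classifier separating
pathogenic from benign variants, for use in rare-disease variant
prioritization where known cases are scarce.

## Features

For a variant residue mapped onto homologous PDB structures (global
alignment, ≥60% identity):

**Structure-based (11):** `KDmean` (mean Kyte–Doolittle hydropathy),
`RSAmax` (max relative solvent accessibility = Shrake–Rupley ASA over the
residue-type maximum), `Bstddev` (SD of the normalized B-factor across
homologs), `Binding` (number of binding-partner types — metal, ligand,
nucleic acid, other protein chain — within 4.5 Å), `Mapreg` (φ/ψ inside a
favored Ramachandran region), and the structural-neighborhood summaries
over all residues whose Cα lies within 9 Å of the variant's Cα: `nNum`,
`nRSA`, `nB`, `nKD`, `nSC`, `nBinding`. Values are pooled across all
homologous structures so transient features (e.g. a binding event seen in
only one crystal form) are not lost.

**Sequence-based (5):** `PSIC` (profile log-odds
log₁₀(f̂(aa)/p(aa)) at the alignment column, Henikoff-weighted with one
pseudocount mass), `Nobs` (alignment depth), `SeqCons`
(1 − H/log₂20), `MinDJxn` (distance to the closest exon/intron junction),
`CodPos` (position within the codon).

**Mutation deltas (optional):** `delta_psic`, Grantham distance,
`delta_kd`.

The classifier protocol mirrors common practice: stratified 80/20
train/validation split, hyperparameter selection by weighted F-score
(support-weighted mean of per-class F1) on the validation split,
train-statistics-only imputation of missing values, and a ROC threshold
scan maximizing weighted F. Seven algorithm families are exposed; the
random forest is the default.

## Worked example

Everything below runs offline from synthetic fixtures:

```python
from snvloci import (
    make_helix_structure, parse_structure, compute_asa,
    per_structure_features, aggregate_structures,
    make_msa, sequence_features,
)

seq = "ACDEFGHIKLMNPQRSTVWY"
structures = [parse_structure(make_helix_structure(20, sequence=seq, seed=s))
              for s in (0, 1)]                       # two "homologs"
sets = [per_structure_features(st, st.chains[0].residues[9],
                               asa=compute_asa(st)) for st in structures]
print(aggregate_structures(sets).as_dict())
# {'KDmean': 3.8, 'RSAmax': 0.253, 'nRSA': 0.262, 'nNum': 10.0,
#  'Bstddev': 0.858, 'nB': -0.018, 'nKD': -1.14, 'nSC': nan,
#  'nBinding': 0.0, 'Binding': 0.0, 'Mapreg': 1.0}

msa = make_msa(40, 20, seed=0, query_sequence=seq)
print(sequence_features(msa, 10, "L", min_junction_distance=12,
                        codon_position=1).as_dict())
# {'PSIC': 0.966, 'Nobs': 40.0, 'SeqCons': 0.83, 'MinDJxn': 12.0, 'CodPos': 1.0}
```

Reading: residue 10 (Leu, KD 3.8) sits buried (`RSAmax` 0.25) in a helical
core region (`Mapreg` 1) with 10 structural neighbors, no binding contacts,
and a well-conserved alignment column (`SeqCons` 0.83, positive `PSIC`).

The same stages are scriptable from the shell:

```bash
snvloci map --variants v.tsv --transcripts tx.bed12 --out mapped.tsv
snvloci struct-features --variants mapped.tsv --pdb-dir pdbs/ \
    --ref-fasta refs.fasta --radius 9 --out struct.csv
snvloci seq-features --variants mapped.tsv --msa-dir msas/ --out seq.csv
snvloci assemble --variants v.tsv --struct struct.csv --seq seq.csv \
    --out features.csv
snvloci train --features features.csv --feature-set seq+str --seed 13 \
    --out model.joblib
snvloci evaluate --model model.joblib --features test.csv --report report.json
```

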