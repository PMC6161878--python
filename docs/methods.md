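# Methods

## Problem and model

A coding SNV is located by (chromosome, position). The package scores the
*locus*: features computable from the position alone ("prior" features),
optionally augmented by wild-type/mutant difference features, feed a binary
classifier with labels Benign / Pathogenic. The intended use is
prioritization of candidate causal variants in rare disease, where
position-only features are attractive because they need no prior
observations of the specific variant.

## Coordinate mapping

Genomic intervals are 1-based inclusive; CDS offsets 0-based; codon
positions 1–3. A `TranscriptModel` (explicit exon list, strand, CDS start
offset) maps a genomic position to its spliced-transcript offset — on the
minus strand offsets count from the 3′-most genomic exon end — and from
there to codon index/phase and protein residue. Exon structure is an
*input* (BED12 or GFF3); the package does not re-derive splicing from
sequence alignment. Junction distance (`MinDJxn`) is measured in genomic
nucleotides to the nearest exonic base adjacent to an intron; spliced-
coordinate distance differs only across a junction and the genomic
definition keeps single-exon handling trivial (single-exon transcripts
yield a missing value).

## Structure mapping

Candidate structures are aligned to the reference protein sequence with a
Needleman–Wunsch/Gotoh affine-gap aligner (BLOSUM62; gap open 10, extend
0.5; a gap of length k costs open + k·extend; pairs involving X score 0;
traceback ties prefer substitution > gap-in-the-partner > gap-in-the-
reference, making maps deterministic). Identity is matches over
non-double-gap columns; structures at ≥60% identity are kept. The variant's
protein position follows alignment columns onto the structure residue, or
goes missing opposite a gap.

## Structure features

* **ASA / RSA.** Shrake–Rupley numerical integration: each heavy atom gets
  n=960 quasi-uniform points (deterministic golden-spiral set) on its
  solvent-expanded sphere (vdW radius + 1.4 Å probe); a point is accessible
  when inside no other expanded sphere. Per-residue ASA divides by the
  residue type's theoretical maximum (Tien et al. values) to give RSA,
  deliberately unclipped above 1. Verified against the analytic single- and
  two-sphere formulas to <2% and self-convergent to <1% between 960 and
  3,840 points.
* **B-factors.** Atom B-factors are z-scored per chain (population SD;
  zero-SD chains map to 0) so values compare across refinements; a
  residue's value is its atoms' mean z-score. `Bstddev` is the population
  SD of that value across homologous structures (0 for a single
  structure) — i.e. the cross-homolog variability of local flexibility.
* **Dihedrals.** φ/ψ from standard atan2 torsions; missing at chain
  termini, missing atoms, or degenerate (collinear) geometry. `Mapreg` is 1
  when (φ, ψ) falls in either default core box — α: φ∈[−180,−30],
  ψ∈[−80,−5]; β: φ∈[−180,−45], ψ∈[90,180] — and is aggregated across
  homologs by majority vote with ties resolved to 1 (core), on the view
  that consistent core assignment is the informative signal. A precomputed
  pass-through column is accepted via the schema adapter for tables whose
  Ramachandran flag came from an external tool.
* **Neighborhood.** All residues of any protein chain whose Cα lies within
  9 Å (boundary-inclusive) of the variant's Cα; a minimum-heavy-atom-
  distance mode is available. 9 Å is the default radius; the neighborhood
  count is monotone in radius over 5–15 Å (property-tested). Neighborhood
  summaries are means over members (`nRSA`, `nB`, `nKD`, `nSC`) plus the
  count `nNum`; all go missing when the center lacks a Cα.
* **Binding-site types.** Geometric detection at a 4.5 Å heavy-atom cutoff
  against four partner classes: monoatomic metallic het groups (metal),
  other non-water het groups (ligand), DNA/RNA chains (nucleic), protein
  residues on other chains (protein). `Binding`/`nBinding` count the union
  of types over homologs, so both are ≤4.
* **Aggregation.** Means (missing-aware) for `KDmean`, `nRSA`, `nNum`,
  `nB`, `nKD`, `nSC`; max for `RSAmax` (the most exposed view across
  crystal forms); union counts for binding; majority for `Mapreg`. An empty
  homolog set yields an all-missing record, which the assembly stage drops
  by default.

## Sequence features

MSA rows get Henikoff position-based weights (a row holding residue a at a
column with r distinct residues and count n_a contributes 1/(r·n_a));
because per-column contributions sum to 1, duplicating every row changes
nothing — property-tested. At the variant column: `SeqCons` = 1 − H/log₂20
on the weighted frequencies (no pseudocounts), `Nobs` = unweighted non-gap
depth (the column wording "number of amino acids observed" is read as
depth; a distinct-types variant sits behind a flag), and
`PSIC(a) = log₁₀(f̂(a)/p(a))` with `f̂(a) = (c_w(a)+g·p(a))/(W+g)`,
pseudocount mass g=1, uniform background by default (configurable to
empirical frequencies). This is a single-column weighted log-odds — a
concrete, testable stand-in for the original multi-stage PSIC procedure,
with the right qualitative behaviour (consensus scores highest; absent
residues in deep columns tend to −log₁₀(W+1)). Mutation deltas are
`delta_psic = PSIC(wt) − PSIC(mut)`, the Grantham distance, and
`delta_kd = KD(wt) − KD(mut)`; the classifier accepts arbitrary extra
numeric columns so externally computed mutation features pass through.

## Dataset assembly and evaluation protocol

Feature blocks inner-join on the variant key (gene, chromosome, position,
wt, mut); duplicate keys are an error; rows with an entirely-missing
structure block are dropped unless kept explicitly. Imputation fills
numeric columns with the training mean and binary columns (`Mapreg`) with
the training mode; test-time fills use training statistics only, and the
operation is idempotent. The rare-variant filter drops MAF > 1% (missing
MAF is treated as rare and kept, logged — clinical rows frequently lack
population frequencies) and keeps rows whose disease annotations intersect
a rare-disease list.

Training: stratified 80/20 train/validation split (the stratification
choice is ours; it stabilizes the imbalanced validation estimates),
hyperparameter selection maximizing validation weighted F (ties → first
declared grid point), refit on the full table. Default random-forest grid:
{100, 200, 500} trees × {unlimited, 10} depth, √p feature subsampling,
fixed seed. The other families (GaussianNB, SVC, logistic regression, MLP,
k-NN — each behind a standard scaler — and a depth-limited decision tree
standing in for a rule table) use library defaults plus small grids. The
decision threshold is chosen by scanning midpoints between adjacent
distinct scores (plus sentinels beyond both extremes) for the maximal
weighted F, ties resolving to the lowest threshold; by default the
threshold is tuned on the validation split, with a self-tuned mode
available and named in reports. Weighted F is the support-weighted mean of
per-class F1 (a class with zero support contributes nothing; zero
precision+recall gives F1 = 0), cross-checked against an independent
implementation on random confusions. Feature ranking averages random-forest
impurity importances over 5 stratified CV folds.

## Synthetic generators: what they emulate, what they do not

* **Helix structures.** Ideal α-helix backbones (φ=−57, ψ=−47, ω=180) built
  by NeRF chaining with standard bond lengths/angles (N–CA 1.458, CA–C
  1.525, C–N 1.329, C=O 1.231 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA
  121.7°), N/CA/C/O atoms only, optional translated extra chains and
  monoatomic het groups. Adequate for dihedral, neighborhood, ASA and
  parsing tests; no side chains (so absolute RSA of reference maxima is
  approached, not reached), no packing realism.
* **MSAs.** Per column, residues draw from a consensus-plus-uniform mixture
  whose consensus weight is tuned numerically to a target conservation.
  Endpoint targets (0 and 1) are realized exactly; mid-range targets come
  out biased low once Henikoff weighting flattens the profile — acceptable
  because tests pin the endpoints and qualitative ordering only.
* **Feature tables.** Two-class independent Gaussians over the named
  feature columns: benign rows N(0,1), pathogenic rows N(d_f,1). Default
  separations decay geometrically with the published importance rank of
  each feature (1.5·0.87^(rank−1), chosen once), with moderate signal
  (1.3/1.0/0.7) on the three mutation deltas; class balance defaults to the
  published benchmark composition (67.9% pathogenic), and the
  benchmark-shaped set reproduces the four published table sizes
  (8,112 / 2,028 / 437 / 280) with their exact class counts, plus MAF and
  disease annotations on the ClinVar-shaped tables. These tables exercise
  the full protocol but are *not* the published data: features are
  independent and unit-variance, there is no train/test distribution shift,
  and absolute classifier scores on them exceed what heterogeneous real
  benchmarks yield. Passing tests therefore demonstrate correctness and
  stability of the machinery, not real-data performance; the identical
  protocol runs on real supplementary-schema CSVs through
  `load_supplementary_csv`.

## Numerical choices and degenerate inputs

Population (not sample) SDs throughout the feature definitions; ASA
quadrature at 960 points by default (≥92 enforced); unknown elements fall
back to a 1.8 Å vdW radius with a warning; unknown residue types yield
missing RSA/KD; empty profiles, all-gap columns, chain termini, collinear
torsions, empty neighborhoods and empty homolog sets all propagate as
missing rather than erroring; empty alignment inputs give an all-gap map
with identity 0. Problem sizes in the test suite and acceptance script
(hundreds to a few thousand rows, 200-tree forests, single-point grids in
the repeated-seed protocol) were chosen to keep the full run comfortably
reproducible on one CPU while leaving every statistical assertion
well-powered.

## Known limitations

No homology modelling or structure prediction: loci without a mappable
experimental structure get missing structure blocks. The PSIC substitute is
single-column; it does not reproduce the original clustering-based values.
Binding-site detection is geometric and misses annotated-but-distant
functional sites. `Mapreg`'s two-box core region is a coarse stand-in for a
probabilistic Ramachandran density. Mutation features are limited to three
deltas unless supplied externally.
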