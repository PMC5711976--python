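# seqshift

Sequence-based prediction of protein NMR chemical shifts, for both
intrinsically disordered and natively folded proteins.

The method is purely statistical:

* **Disordered mode.** For each atom type and residue category, a Gaussian
  kernel density over the assigned shifts in a training collection gives a
  primary expectation. Neighbor corrections over a ±2 sequence window are
  derived from pair-conditioned densities, weighted by one minus the overlap
  between the pair and primary densities, and balanced against the primary
  term by a per-atom normalization factor calibrated by grid search. Pairs
  with fewer than 20 observations fall back to the pooled (averaged) effect
  of the neighbor type at that offset.
* **Folded mode.** The same kernel machinery is conditioned on a 3-state
  secondary-structure (Q3) label per residue (helix / strand / coil, with
  8-state labels merged H,G→H; E→E; rest→C). Residues near a boundary
  between Q3 segments receive an additive correction from empirical
  secondary-shift profiles as a function of the signed distance from the
  boundary. An optional feedforward refiner network (143 inputs — a
  7-residue Q3 window and a 5-residue BLOSUM-62 sequence window — 50 tanh
  hidden nodes, one output, Adam-trained per atom) makes predictions more
  robust when the Q3 labels themselves come from a secondary-structure
  predictor rather than from structure.

The package also ships the curation pipeline for training collections
(greedy sequence-identity clustering, per-nucleus referencing QC at
1.5 / 0.5 / 3.5 ppm for ¹³C / ¹H / ¹⁵N, 3.5-SD outlier removal), a
leave-one-out RMSD benchmark, and a synthetic-data generator that plants
known base shifts, neighbor effects, Q3 offsets, boundary ramps, noise,
outliers and referencing errors so every stage is testable offline.

## CLI

```sh
# make a synthetic database with known ground truth
seqshift simulate --preset idp --seed 7 --out db.tsv --truth-out truth.tsv

# curation (identity clustering, referencing QC, outlier removal)
seqshift curate --db db.tsv --out curated.tsv

# disordered pipeline
seqshift train-idp --db curated.tsv --out model.json
seqshift predict-idp --fasta target.fa --model model.json \
    --atoms CA,CB,C,N,H,HA --ph 6.4 --out shifts.tsv

# folded pipeline (Q3 labels: inline string, 2-column TSV, or psipred .ss2)
seqshift simulate --preset folded --seed 2 --out fdb.tsv
seqshift train-folded --db fdb.tsv --out folded.json --half-window 4 --with-nn
seqshift predict-folded --fasta target.fa --model folded.json \
    --q3 pred.ss2 --mode nn --out shifts.tsv

# leave-one-out benchmark
seqshift benchmark --db db.tsv --mode idp --loo --out report.tsv
```

Shift databases are TSV
(`entry_id  res_index  res_letter  variant  atom  shift_ppm  ph  q3`) or a
minimal NMR-STAR-like format (`--format nmrstar_lite`). Predictions are
written as TSV or TALOS-style tables (`--talos`). Residue variants
(oxidized cysteine, cis-proline, protonated histidine) are separate
categories throughout; FASTA input can carry them via a per-position
sidecar file (`--variants`).

## Layout

| module | role |
| --- | --- |
| `seqshift.database` | data model, TSV/NMR-STAR-lite/FASTA IO, curation |
| `seqshift.kernel` | kernel densities, expectations, corrections, N_W |
| `seqshift.idp` | disordered-mode predictor and writers |
| `seqshift.q3` | Q3 merging, per-state models, boundary profiles |
| `seqshift.nn` | 143-50-1 refiner network |
| `seqshift.benchmark` | RMSD and leave-one-out protocol |
| `seqshift.synthetic` | ground-truth generator and presets |
| `seqshift.cli` | `seqshift` command-line entry point |
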