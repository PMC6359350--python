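# ssv — structural signature variation

Toolkit for triaging enzyme point mutations by structural-signature
comparison. A protein pocket is fingerprinted as a cumulative
pairwise-distance count vector stratified by pharmacophore class pairs
(36 class pairs × 101 cutoffs from 0–10 Å = 3636 components). Wild-type
and mutant structures each pick their nearest template from a curated
database of "good" enzymes by Euclidean distance; the difference of those
two distances (ΔΔSSV = ΔSSV_mutant − ΔSSV_wild) scores the mutation:
negative predicts beneficial, positive predicts not beneficial.

## Features

- **structure_io** — PDB reading/writing with alt-loc resolution
  (highest occupancy, ties prefer `A`), hydrogen/water stripping, ligand
  routing, and an explicit, swappable pharmacophore typing table
  (`src/ssv/data/pharmacophores.tsv`).
- **pocket** — pocket definition by ligand distance (default 6.5 Å,
  inclusive), transfer to homologs via global sequence alignment
  (BLOSUM62, gap open 10 / extend 0.5), and Kabsch superposition for QC.
- **signature** — the 3636-component cumulative pair-count signature and
  Euclidean signature distance.
- **scoring** — template databases (PDB dirs or precomputed signature
  TSVs), nearest-template selection with deterministic tie-breaking, and
  the ΔΔSSV sign rule.
- **mutagenesis** — `X123Y` notation, 19-per-residue saturation
  enumeration, and a geometric mutant builder (truncate / graft modes; no
  homology modeling — externally modeled mutants are accepted as input).
- **filters** — conservation filter computed in-repo plus readers for
  externally produced SIFT and mCSM result tables, with a per-stage audit
  trail.
- **evaluation** — confusion-matrix panel (precision, accuracy,
  specificity, sensitivity, F-measure) over labeled mutation sets; ships
  a 27-mutation β-glucosidase benchmark.
- **fixtures** — deterministic toy structures, jittered template
  databases, planted beneficial-mutation cases, and a brute-force
  signature oracle; everything runs offline.

## CLI

```sh
# define a pocket around a bound ligand
ssv pocket --reference ref.pdb --ligand A:501 --cutoff 6.5 --out pocket.tsv

# compute a signature
ssv signature --pdb enzyme.pdb --pocket pocket.tsv --out sig.tsv

# score one or more mutant structures
ssv score --wild wild.pdb --mutant mut1.pdb --templates templates/ --pocket pocket.tsv

# full saturation screen with the post-hoc filter chain
ssv screen --wild wild.pdb --pocket pocket.tsv --templates templates/ \
    --alignment pocket_aln.fasta --sift sift.tsv --mcsm mcsm.tsv --out screen.tsv

# filter an existing candidate list
ssv filter --candidates cands.txt --alignment aln.fasta --sift sift.tsv --mcsm mcsm.tsv

# evaluate the shipped benchmark
ssv evaluate
```

Exit codes: 0 success, 2 input error, 3 configuration error.

## Notes and limitations

- Hydrogens are ignored; only the first MODEL of multi-model files is
  read.
- The graft-mode mutant builder places side chains at idealized geometry
  with a common rotamer and performs no clash resolution; for
  production-quality mutants, supply externally modeled PDBs.
- Template signatures and query signatures must use one consistent
  convention (pocket-only or whole-protein) — the caller chooses.
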