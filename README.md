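# repeatst

Annotation toolkit for **ST proteins** — a family of secreted plant
tandem-repeat proteins (found mainly in Fabaceae and Asteraceae) built
from a signal peptide, a conserved mature N-terminal region, and tandem
repeats of 22–27 residues that open with the signature motif

```
(D/E) F E P R P  X4  Y
 1    2 3 4 5 6  7-10 11
```

— a hexapeptide whose first residue may be Asp or Glu, four partially
conserved residues (X₄), and a fully conserved Tyr at repeat position 11.
The repeat region ends in a truncated terminal repeat (~13 aa). The X₄
determines whether each repeat carries an N-glycosylation sequon
(N-{P}-[ST]-{P}) and sorts family members into types: **I** (SxTx, no
sequon), **IIa** (NxSx, sequon in nearly every repeat), **IIb** (Nx[F/L]x)
and **III** (DxT/Sx).

The package is for sequence analysts characterizing this family (or
screening proteomes/EST sets for new members). It provides:

- `seqio` — FASTA IO, six-frame translation of nucleotide input, GFF3/TSV
  feature tables;
- `motif_repeats` — signature scanning, repeat segmentation, consensus
  derivation, repeat-perfection score *P*sim (fraction of repeat positions
  matching the column-majority consensus of the anchored repeat
  alignment), and a DUF2775-like domain proxy count;
- `maturation` — rule-based signal-peptide delineation (Arg-anchored
  Kyte–Doolittle hydrophobic-core heuristic, external cleavage sites
  accepted), mature N-terminal landmarks (Tyr-Trp dyad, single Cys), and
  completeness classification of EST-derived fragments;
- `typing_glyco` — sequon detection, per-repeat X₄ typing, majority-vote
  protein typing, within-species ST1/ST2/… naming;
- `profiles` — sequence-logo information content (bits = log₂20 − H) and
  two-sample-logo enrichment (Fisher exact) between repeat groups;
- `composition` — composition classes (charged set DEKRHYC), average-mass
  MW, isoelectric point by Henderson–Hasselbalch bisection (EMBOSS pKa),
  hydropathy profiles;
- `cluster_phylo` — Needleman–Wunsch identity distances, Saitou–Nei
  neighbor joining with deterministic tie-breaks, bootstrap supports,
  newick export;
- `synthetic_data` — ground-truthed generator of ST precursors,
  fragments, clade-structured families and cell-wall-protein decoys
  (PRP/HRGP/GRP/AGP/shuffles);
- `pipeline` + a `repeatst` CLI — annotate → classify → summarize.

## Worked example

```python
from repeatst.synthetic_data import GeneratorConfig, generate_st
from repeatst.pipeline import annotate_record

rec, truth = generate_st(GeneratorConfig(seed=1))   # default type-IIa precursor
ann = annotate_record(rec)
print(len(rec.residues))                  # 215
print(ann.mature.cleavage_after)          # 22
print(ann.mature.yw_position)             # 7
print([u.length for u in ann.region.units])  # [25, 25, 25, 25, 25, 13]
print(ann.region.units[-1].status)        # truncated_terminal
print(ann.type_call.st_type, ann.type_call.majority_fraction)  # IIa 1.0
print(round(ann.psim, 3))                 # 0.942
print(ann.completeness.value)             # full
```

The precursor is 215 aa: a 22-residue signal peptide (cleavage after
position 22, mature protein starting with Arg), a Tyr-Trp dyad at mature
positions 7–8, five canonical 25-aa repeats plus the 13-aa truncated
terminal repeat, a unanimous type-IIa call (every repeat contributes an
NxSx sequon), near-perfect repeats (*P*sim ≈ 0.94), and both termini
intact (`full`).

From the shell:

```bash
repeatst simulate --n 10 --seed 1 --decoys 2 --out sim/
repeatst annotate sim/sequences.fasta --out anno/
repeatst tree aligned.fasta --bootstrap 2000 --seed 1 --out tree.nwk
```

`anno/` then holds `features.gff3`/`features.tsv` (1-based inclusive
coordinates, source `repeatst`), `summary.json`/`summary.md` (completeness
census, size classes, repeat counts, type fractions, *P*sim thresholds),
and `rejected.tsv` naming every non-ST input with its reason.

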